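"""Annotation file I/O: parsing, clipping, round trips, study loading."""

import dataclasses

import pytest

from psgagree.annotations import (
    Annotation,
    ScoringSet,
    assemble_recording,
    load_study,
    read_annotation_file,
    write_annotation_file,
    write_study,
)
from psgagree.errors import (
    ConflictError,
    ConsistencyError,
    ParseError,
    StructuralError,
    VocabularyError,
)
from psgagree.simulate import StudyDesign, generate_study, study_context_maps

from conftest import random_event_recording


def _write_tab(path, rows):
    lines = ["label,onset_s,duration_s"] + [",".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestReading:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_tab(p, [("lights-off", 0, 0), ("lm-left", 100, 2),
                       ("lights-on", 3600, 0)])
        rec = read_annotation_file(p, "tabular")
        assert rec.tib == 3600.0
        assert rec.annotations == (Annotation(100.0, 2.0, "lm-left"),)

    def test_event_spanning_lights_on_is_clipped(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_tab(p, [("lights-off", 0, 0), ("arousal", 3590, 30),
                       ("lights-on", 3600, 0)])
        rec = read_annotation_file(p, "tabular")
        (ev,) = rec.annotations
        assert (ev.onset, ev.end) == (3590.0, 3600.0)

    def test_event_outside_tib_dropped_as_zero_length_residue(self):
        rec = assemble_recording([("lights-off", 100, 0), ("arousal", 10, 20),
                                  ("lights-on", 3700, 0)])
        assert rec.annotations == ()

    def test_unknown_label_names_token(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_tab(p, [("lights-off", 0, 0), ("snore", 5, 2),
                       ("lights-on", 100, 0)])
        with pytest.raises(VocabularyError, match="snore"):
            read_annotation_file(p, "tabular")

    def test_alias_map_translates_foreign_labels(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_tab(p, [("lights-off", 0, 0), ("PLM links", 5, 2),
                       ("lights-on", 100, 0)])
        rec = read_annotation_file(p, "tabular",
                                   aliases={"PLM links": "lm-left"})
        assert rec.annotations[0].label == "lm-left"

    def test_malformed_timestamp_names_line(self, tmp_path):
        p = tmp_path / "a.csv"
        _write_tab(p, [("lights-off", 0, 0), ("arousal", "ten", 2),
                       ("lights-on", 100, 0)])
        with pytest.raises(ParseError, match=":3"):
            read_annotation_file(p, "tabular")

    def test_missing_lights_markers(self):
        with pytest.raises(StructuralError, match="lights"):
            assemble_recording([("arousal", 5.0, 2.0)])

    def test_zero_duration_event_rejected(self):
        with pytest.raises(StructuralError, match="zero-duration"):
            assemble_recording([("lights-off", 0, 0), ("arousal", 5.0, 0.0),
                                ("lights-on", 100, 0)])

    def test_stage_annotations_become_hypnogram(self):
        rec = assemble_recording(
            [("lights-off", 0, 0), ("stage-W", 0, 30), ("stage-N1", 30, 30),
             ("stage-N2", 60, 30), ("lights-on", 90, 0)], task="staging")
        assert rec.hypnogram.stages == ("W", "N1", "N2")

    def test_hypnogram_gap_is_structural_error(self):
        with pytest.raises(StructuralError, match="gap"):
            assemble_recording(
                [("lights-off", 0, 0), ("stage-W", 0, 30),
                 ("stage-N2", 60, 30), ("lights-on", 90, 0)], task="staging")


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["tabular", "edfplus"])
    def test_read_write_identity_on_random_recordings(self, rng, tmp_path,
                                                      dialect):
        for i in range(5):
            rec = random_event_recording(
                rng, n_events=40, labels=("arousal", "lm-left", "hypopnea"))
            p = tmp_path / f"r{i}.{dialect}"
            write_annotation_file(rec, p, dialect)
            back = read_annotation_file(p, dialect)
            assert back.annotations == rec.annotations
            assert (back.lights_off, back.lights_on) == (rec.lights_off,
                                                         rec.lights_on)

    @pytest.mark.parametrize("dialect", ["tabular", "edfplus"])
    def test_hypnogram_round_trip(self, tmp_path, dialect):
        rec = assemble_recording(
            [("lights-off", 600, 0), ("stage-W", 600, 30),
             ("stage-N1", 630, 30), ("stage-N2", 660, 30),
             ("lights-on", 690, 0)], task="staging")
        p = tmp_path / f"h.{dialect}"
        write_annotation_file(rec, p, dialect)
        back = read_annotation_file(p, dialect, task="staging")
        assert back.hypnogram == rec.hypnogram
        # stage records are emitted per 30 s epoch, recording-anchored
        assert [a.onset for a in rec.annotations] == [600.0, 630.0, 660.0]

    @pytest.mark.parametrize("dialect", ["tabular", "edfplus"])
    def test_write_is_byte_stable(self, rng, tmp_path, dialect):
        rec = random_event_recording(rng, n_events=1000, tib=25200.0,
                                     labels=("arousal", "lm-right"))
        p1, p2 = tmp_path / "a1", tmp_path / "a2"
        write_annotation_file(rec, p1, dialect)
        write_annotation_file(rec, p2, dialect)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_event_list_writes_only_lights_markers(self, tmp_path):
        rec = assemble_recording([("lights-off", 0, 0), ("lights-on", 100, 0)])
        p = tmp_path / "empty.csv"
        write_annotation_file(rec, p, "tabular")
        body = p.read_text().strip().splitlines()
        assert body == ["label,onset_s,duration_s", "lights-off,0.0,0",
                        "lights-on,100.0,0"]

    def test_clipping_preserves_in_tib_event_time(self, rng):
        lo, hi = 500.0, 4100.0
        raw = [("lights-off", lo, 0.0)]
        expected = 0.0
        for _ in range(200):
            onset = float(rng.uniform(0.0, 5000.0))
            dur = float(rng.uniform(0.5, 60.0))
            raw.append(("arousal", onset, dur))
            expected += max(0.0, min(onset + dur, hi) - max(onset, lo))
        raw.append(("lights-on", hi, 0.0))
        rec = assemble_recording(raw)
        total = sum(a.duration for a in rec.annotations)
        assert total == pytest.approx(expected, abs=1e-9)

    def test_mne_reads_our_edfplus_files(self, rng, tmp_path):
        mne = pytest.importorskip("mne")
        rec = random_event_recording(rng, n_events=25,
                                     labels=("arousal", "hypopnea"))
        p = tmp_path / "x.edf"
        write_annotation_file(rec, p, "edfplus")
        ann = mne.read_annotations(p)
        got = [(a["onset"], a["duration"], a["description"]) for a in ann
               if a["description"] not in ("lights-off", "lights-on")]
        want = [(a.onset, a.duration, a.label) for a in rec.annotations]
        assert got == want


class TestStudyLoading:
    @staticmethod
    def _small_study(seed=1):
        design = StudyDesign(n_scorers=2, n_recordings=1)
        return design, *generate_study(seed, design)

    def test_written_study_reloads_completely(self, tmp_path):
        design, study, truths = self._small_study()
        hyps, resp = study_context_maps(truths)
        write_study(study, tmp_path / "study", context_hypnograms=hyps,
                    context_respiratory=resp)
        back = load_study(tmp_path / "study")
        assert back.n_cells == 2 * 2 * 4 * 1  # scorers x methods x tasks x recs
        assert back.missing == []
        assert len(back.timing) == len(study.timing)
        key = next(iter(study.cells))
        assert back.cells[key].annotations == study.cells[key].annotations
        # context hypnogram reattached to non-staging cells
        lm_key = next(k for k in back.cells if k[0] == "leg_movements")
        assert back.cells[lm_key].context_hypnogram is not None

    def test_missing_cell_reported_not_skipped(self, tmp_path):
        design, study, truths = self._small_study()
        write_study(study, tmp_path / "study")
        manifest = tmp_path / "study" / "manifest.yaml"
        import yaml

        spec = yaml.safe_load(manifest.read_text())
        dropped = spec["cells"].pop()
        manifest.write_text(yaml.safe_dump(spec))
        back = load_study(tmp_path / "study")
        assert len(back.missing) == 1
        task, rec_id, scorer, method = back.missing[0]
        assert (task, rec_id) == (dropped["task"], dropped["recording"])

    def test_duplicate_cell_is_conflict(self):
        _, study, _ = self._small_study()
        rec = next(iter(study.cells.values()))
        with pytest.raises(ConflictError):
            study.add(rec)

    def test_inconsistent_lights_markers_rejected(self, tmp_path):
        _, study, _ = self._small_study()
        sset = ScoringSet()
        for (task, rec_id, scorer, method), rec in study.cells.items():
            if task != "arousals":
                continue
            if scorer == "s01":
                rec = dataclasses.replace(rec, lights_on=rec.lights_on + 30.0)
            sset.add(rec)
        write_study(sset, tmp_path / "study")
        with pytest.raises(ConsistencyError, match="lights"):
            load_study(tmp_path / "study")

    def test_paper_scale_cell_count(self, paper_scale_study):
        study, _ = paper_scale_study
        assert study.n_cells == 12 * 2 * 4 * 5
        assert study.missing == []
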