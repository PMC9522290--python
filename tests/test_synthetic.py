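"""Synthetic study generator: determinism, identity limits, rate
calibration, agreement monotonicity, parameter recovery."""

import numpy as np
import pytest

from psgagree.agreement import cohen_kappa
from psgagree.discretize import build_contingency, discretize_events, discretize_stages
from psgagree.simulate import (
    DEFAULT_TIMING_MEDIANS,
    ScorerModel,
    StudyDesign,
    TruthModel,
    corrupt_scoring,
    generate_study,
    generate_timing,
    generate_truth,
)
from psgagree.stats import gain_factor

QUIET = TruthModel(event_rates={"arousal": 0.0}, plm_rate=0.0)


def _pair_kappa(a, b, labels=("arousal",)):
    sa = discretize_events(a, labels)
    sb = discretize_events(b, labels)
    return cohen_kappa(build_contingency(sa, sb)).kappa


class TestGenerateTruth:
    def test_zero_rates_give_no_events(self):
        truth = generate_truth(QUIET, seed=5)
        assert truth.annotations == ()

    def test_fixed_seed_reproduces_output(self):
        t1 = generate_truth(TruthModel(), seed=42)
        t2 = generate_truth(TruthModel(), seed=42)
        assert t1.annotations == t2.annotations
        assert t1.hypnogram == t2.hypnogram

    def test_poisson_event_count_concentration(self):
        # rate 10/h of TST: mean count over a fixed-seed batch stays
        # within 3 standard errors of rate x TST
        model = TruthModel(tib_hours=8.0, event_rates={"arousal": 10.0},
                           plm_rate=0.0)
        counts, lam = [], []
        for seed in range(30):
            truth = generate_truth(model, seed=seed)
            tst_h = sum(s != "W" for s in truth.hypnogram.stages) / 120.0
            counts.append(len(truth.annotations))
            lam.append(10.0 * tst_h)
        resid = np.mean(counts) - np.mean(lam)
        se = np.sqrt(np.mean(lam) / len(lam))
        assert abs(resid) < 3 * se

    def test_ahi_falls_in_configured_band_across_seeds(self):
        # Table-1-like AHI levels: rate 6.7/h of sleep should put the
        # realized index in a clinically typical apnea band for almost
        # every recording
        hits = 0
        for seed in range(100):
            truth = generate_truth(TruthModel(), seed=seed)
            tst_h = sum(s != "W" for s in truth.hypnogram.stages) / 120.0
            n = len([a for a in truth.annotations
                     if a.label.startswith("apnea") or a.label == "hypopnea"])
            hits += 4.0 <= n / tst_h <= 10.0
        assert hits >= 95

    def test_periodic_trains_have_qualifying_intervals(self):
        model = TruthModel(event_rates={"lm-isolated": 0.0}, plm_rate=20.0,
                           bilateral_prob=0.0)
        truth = generate_truth(model, seed=9)
        onsets = sorted(a.onset for a in truth.annotations)
        imis = np.diff(onsets)
        # within trains the intervals obey the periodic band
        assert ((imis >= 10.0) & (imis <= 90.0)).mean() > 0.8


class TestCorruptScoring:
    def test_identity_scorer_reproduces_truth_events(self):
        truth = generate_truth(TruthModel(), seed=3)
        out = corrupt_scoring(truth, ScorerModel(), seed=4, task="arousals")
        assert out.events(("arousal",)) == truth.events(("arousal",))

    def test_identity_scorer_reproduces_truth_staging(self):
        truth = generate_truth(QUIET, seed=3)
        out = corrupt_scoring(truth, ScorerModel(), seed=4, task="staging")
        assert out.hypnogram == truth.hypnogram

    def test_zero_sensitivity_no_fp_gives_empty_scoring(self):
        truth = generate_truth(TruthModel(), seed=3)
        out = corrupt_scoring(truth, ScorerModel(event_sensitivity=0.0),
                              seed=4, task="arousals")
        assert out.annotations == ()

    def test_identity_scorers_agree_perfectly_end_to_end(self):
        truth = generate_truth(TruthModel(), seed=6)
        a = corrupt_scoring(truth, ScorerModel(), seed=1, task="arousals")
        b = corrupt_scoring(truth, ScorerModel(), seed=2, task="arousals")
        assert _pair_kappa(a, b) == 1.0

    @staticmethod
    def _mean_kappa(jitter=0.0, fp=0.0, n_seeds=5):
        ks = []
        for seed in range(n_seeds):
            truth = generate_truth(TruthModel(tib_hours=6.0), seed=100 + seed)
            model = ScorerModel(event_sensitivity=0.95,
                                boundary_jitter_sd=jitter,
                                false_positive_rate=fp)
            a = corrupt_scoring(truth, model, seed=2 * seed, task="arousals")
            b = corrupt_scoring(truth, model, seed=2 * seed + 1,
                                task="arousals")
            ks.append(_pair_kappa(a, b))
        return float(np.mean(ks))

    def test_kappa_decreases_with_boundary_jitter(self):
        k0, k1, k2 = (self._mean_kappa(jitter=j) for j in (0.0, 1.5, 4.0))
        assert k0 > k1 > k2

    def test_kappa_decreases_with_false_positive_rate(self):
        k0, k1, k2 = (self._mean_kappa(fp=f) for f in (0.0, 5.0, 15.0))
        assert k0 > k1 > k2

    def test_staging_kappa_matches_symmetric_noise_closed_form(self):
        # two scorers with error rate e and a uniform off-diagonal
        # kernel: agreement of two independent symmetric noise channels
        e = 0.2
        model = TruthModel(tib_hours=100_000 * 30.0 / 3600.0,
                           event_rates={"arousal": 0.0}, plm_rate=0.0)
        truth = generate_truth(model, seed=8)
        scorer = ScorerModel(stage_error_rate=e)
        a = corrupt_scoring(truth, scorer, seed=21, task="staging")
        b = corrupt_scoring(truth, scorer, seed=22, task="staging")
        sa, sb = discretize_stages(a.hypnogram), discretize_stages(b.hypnogram)
        observed = cohen_kappa(build_contingency(sa, sb)).kappa

        stages = np.array(truth.hypnogram.stages)
        pi = np.array([(stages == s).mean()
                       for s in ("W", "N1", "N2", "N3", "R")])
        p_o = (1 - e) ** 2 + e ** 2 / 4.0
        marg = (1 - e) * pi + (e / 4.0) * (1 - pi)
        p_e = float((marg ** 2).sum())
        expected = (p_o - p_e) / (1 - p_e)
        assert observed == pytest.approx(expected, abs=0.015)


class TestGenerateStudy:
    def test_paper_scale_design_counts(self, paper_scale_study):
        study, truths = paper_scale_study
        assert study.n_cells == 480
        assert len(study.scorers) == 12
        assert len(study.timing) == 480
        for task in study.tasks:
            assert len(study.recordings(task)) == 5

    def test_master_seed_reproducibility(self):
        design = StudyDesign(n_scorers=2, n_recordings=1)
        s1, _ = generate_study(77, design)
        s2, _ = generate_study(77, design)
        assert sorted(s1.cells) == sorted(s2.cells)
        for key in s1.cells:
            assert s1.cells[key].annotations == s2.cells[key].annotations
        assert s1.timing == s2.timing

    def test_semiauto_scorers_agree_more_than_manual(self):
        design = StudyDesign(n_scorers=4, n_recordings=2)
        study, _ = generate_study(5, design)
        for task in ("staging", "arousals"):
            kappas = {"manual": [], "semiauto": []}
            for method in kappas:
                for rec_id in study.recordings(task):
                    recs = [study.get(task, rec_id, sid, method)
                            for sid in study.scorers]
                    for i in range(len(recs)):
                        for j in range(i + 1, len(recs)):
                            if task == "staging":
                                si = discretize_stages(recs[i].hypnogram)
                                sj = discretize_stages(recs[j].hypnogram)
                                k = cohen_kappa(
                                    build_contingency(si, sj)).kappa
                            else:
                                k = _pair_kappa(recs[i], recs[j])
                            kappas[method].append(k)
            assert np.median(kappas["semiauto"]) > np.median(kappas["manual"])

    def test_timing_medians_recovered_at_large_n(self):
        # configured manual/semiauto medians of 44.53 and 18.50 minutes
        # must reproduce the 2.41 gain factor within 5% at n = 5000
        design = StudyDesign(n_scorers=250)
        recs = {"leg_movements": [f"r{i:03d}" for i in range(20)]}
        records = generate_timing(123, design, recs)
        manual = [t.active_minutes for t in records if t.method == "manual"]
        semi = [t.active_minutes for t in records if t.method == "semiauto"]
        assert len(manual) == 5000
        target = (DEFAULT_TIMING_MEDIANS[("leg_movements", "manual")]
                  / DEFAULT_TIMING_MEDIANS[("leg_movements", "semiauto")])
        assert gain_factor(manual, semi) == pytest.approx(target, rel=0.05)
        assert np.median(manual) == pytest.approx(44.53, rel=0.05)
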