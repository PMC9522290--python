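"""Full study analysis: agreement, indices, timing, report tables.

Mirrors the study's reporting structure: a scoring-time comparison per
task (with gain factors), a kappa-agreement comparison per task and
context (TIB / wake / sleep for leg movements; all-respiratory /
apneas / hypopneas subsets for respiratory events), and per-index
ICC(A,1) agreement per method, with the semi-automatic ICC tested
against the manual level as baseline (r0).

Every test is reported at per-test alpha with no multiple-testing
correction; the rendered report says so in its header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import (
    KappaResult,
    average_channel_kappa,
    icc_a1,
    pairwise_kappa,
)
from .annotations import ScoringSet
from .discretize import (
    EpochGrid,
    LabelSequence,
    context_mask,
    discretize_events,
    discretize_stages,
)
from .errors import DegenerateDataError, DesignError, DomainError
from .indices import event_indices, recording_summary
from .stats import (
    ALPHA,
    ComparisonRow,
    PairedSample,
    build_comparison_table,
    median_iqr,
)
from .vocab import APNEA_LABELS, RESPIRATORY_LABELS, TASKS

#: kappa contexts per task: (context name, event labels or None for stages,
#: hypnogram mask context)
TASK_CONTEXTS: dict[str, list[tuple[str, tuple[str, ...] | None, str]]] = {
    "staging": [("tib", None, "tib")],
    "leg_movements": [("tib", None, "tib"), ("wake", None, "wake"),
                      ("sleep", None, "sleep")],
    "respiratory": [("apnea_hypopnea_rera", RESPIRATORY_LABELS, "tib"),
                    ("apneas", APNEA_LABELS, "tib"),
                    ("hypopneas", ("hypopnea",), "tib")],
    "arousals": [("tib", ("arousal",), "tib")],
}

#: diagnostic indices derived per task (column order of the ICC table)
TASK_INDICES: dict[str, tuple[str, ...]] = {
    "staging": ("SE", "SOL", "WASO"),
    "leg_movements": ("LMI", "PLMI"),
    "respiratory": ("AHI", "AI", "HI", "ODI"),
    "arousals": ("ArI",),
}


@dataclass(frozen=True)
class StudyConfig:
    alpha: float = ALPHA
    event_step: float = 0.5
    icc_r0_policy: str = "manual_baseline"  # or "zero"
    include_respiratory_in_plmi: bool = True
    tasks: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.event_step <= 0:
            raise ValueError("event_step must be positive")
        if self.icc_r0_policy not in ("manual_baseline", "zero"):
            raise ValueError(f"unknown icc_r0_policy {self.icc_r0_policy!r}")


@dataclass
class AgreementReport:
    """All result tables of one study analysis."""

    pair_kappas: pd.DataFrame      # raw per-pair kappa values
    kappa_table: pd.DataFrame      # per task x context comparison
    timing_table: pd.DataFrame     # per task timing comparison + gain
    index_table: pd.DataFrame      # per index ICC comparison
    index_values: pd.DataFrame     # raw per-scorer index values
    alpha: float = ALPHA

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_kappas.to_csv(out / "pair_kappas.csv", index=False)
        self.kappa_table.to_csv(out / "kappa_agreement.csv", index=False)
        self.timing_table.to_csv(out / "scoring_times.csv", index=False)
        self.index_table.to_csv(out / "icc_indices.csv", index=False)
        self.index_values.to_csv(out / "index_values.csv", index=False)
        (out / "report.txt").write_text(render_report(self), encoding="utf-8")
        return out


def _check_complete(study: ScoringSet, tasks: tuple[str, ...]) -> None:
    gaps = [c for c in study.missing if c[0] in tasks]
    if gaps:
        raise DesignError(f"study incomplete: missing cell {gaps[0]} "
                          f"({len(gaps)} missing in total)")


def _truncate(seq: LabelSequence, n: int) -> LabelSequence:
    if n >= seq.grid.n_epochs:
        return seq
    g = seq.grid
    return LabelSequence(EpochGrid(g.start, g.step, n, g.alphabet),
                         seq.codes[:n])


def _task_pair_kappas(study: ScoringSet, task: str,
                      cfg: StudyConfig) -> list[dict]:
    """Per-pair kappas for every recording, method and context of a task."""
    rows: list[dict] = []
    for rec_id in study.recordings(task):
        for method in ("manual", "semiauto"):
            recs = {sid: study.get(task, rec_id, sid, method)
                    for sid in study.scorers}
            any_rec = next(iter(recs.values()))
            hyp = any_rec.context_hypnogram
            for ctx_name, labels, mask_ctx in TASK_CONTEXTS[task]:
                if task == "staging":
                    seqs = {sid: discretize_stages(r.hypnogram)
                            for sid, r in recs.items()}
                    results = pairwise_kappa(seqs, context=ctx_name)
                elif task == "leg_movements":
                    results = _lm_channel_averaged(recs, hyp, mask_ctx,
                                                   ctx_name, cfg)
                else:
                    seqs = {sid: discretize_events(r, labels, cfg.event_step)
                            for sid, r in recs.items()}
                    results = pairwise_kappa(seqs, context=ctx_name)
                for res in results:
                    rows.append({
                        "task": task, "context": ctx_name, "method": method,
                        "recording": rec_id, "scorer_a": res.pair[0],
                        "scorer_b": res.pair[1], "kappa": res.kappa,
                        "n_epochs": res.n, "degenerate": res.degenerate,
                    })
    return rows


def _lm_channel_averaged(recs, hyp, mask_ctx: str, ctx_name: str,
                         cfg: StudyConfig) -> list[KappaResult]:
    """Leg movements: per-channel kappas on a (possibly masked) grid,
    averaged across left/right."""
    per_channel: list[list[KappaResult]] = []
    for label in ("lm-left", "lm-right"):
        seqs = {sid: discretize_events(r, [label], cfg.event_step)
                for sid, r in recs.items()}
        mask = None
        if mask_ctx != "tib":
            if hyp is None:
                raise DomainError("wake/sleep context requires the clinical "
                                  "context hypnogram")
            n_cov = int(math.floor(hyp.span / cfg.event_step + 1e-9))
            seqs = {sid: _truncate(s, n_cov) for sid, s in seqs.items()}
            grid = next(iter(seqs.values())).grid
            mask = context_mask(hyp, mask_ctx, grid)
        per_channel.append(pairwise_kappa(seqs, mask=mask, context=ctx_name))
    return [average_channel_kappa(l, r)
            for l, r in zip(per_channel[0], per_channel[1])]


def _matched_kappa_samples(pair_df: pd.DataFrame) -> dict[str, PairedSample]:
    """One PairedSample per (task, context), matched on
    recording x scorer pair."""
    samples: dict[str, PairedSample] = {}
    for (task, ctx), sub in pair_df.groupby(["task", "context"], sort=False):
        wide = sub.pivot_table(
            index=["recording", "scorer_a", "scorer_b"],
            columns="method", values="kappa", sort=True)
        if {"manual", "semiauto"} - set(wide.columns) or wide.isna().any().any():
            raise DesignError(f"{task}/{ctx}: unmatched kappa pairs")
        samples[f"{task}:{ctx}"] = PairedSample(
            tuple(wide["manual"]), tuple(wide["semiauto"]), unit="kappa",
            matching_key="scorer-pair x recording")
    return samples


def _timing_samples(study: ScoringSet,
                    tasks: tuple[str, ...]) -> dict[str, PairedSample]:
    df = pd.DataFrame([t.__dict__ for t in study.timing])
    if df.empty:
        return {}
    samples: dict[str, PairedSample] = {}
    totals: dict[str, dict[tuple[str, int], float]] = {
        "manual": {}, "semiauto": {}}
    for task in tasks:
        sub = df[df.task == task]
        if sub.empty:
            continue
        wide = sub.pivot_table(index=["recording_id", "scorer_id"],
                               columns="method", values="active_minutes",
                               sort=True)
        if {"manual", "semiauto"} - set(wide.columns) or wide.isna().any().any():
            raise DesignError(f"{task}: unmatched timing records")
        samples[task] = PairedSample(
            tuple(wide["manual"]), tuple(wide["semiauto"]), unit="minutes",
            matching_key="scorer x recording")
        # recordings differ between tasks: match "altogether" times on
        # scorer x within-task recording rank
        rec_rank = {r: i for i, r in
                    enumerate(sorted(sub.recording_id.unique()))}
        for (rec_id, scorer), row in wide.iterrows():
            for method in ("manual", "semiauto"):
                key = (scorer, rec_rank[rec_id])
                totals[method][key] = totals[method].get(key, 0.0) + row[method]
    if samples and len(tasks) > 1:
        keys = sorted(totals["manual"])
        samples["altogether"] = PairedSample(
            tuple(totals["manual"][k] for k in keys),
            tuple(totals["semiauto"][k] for k in keys),
            unit="minutes", matching_key="scorer x recording-rank")
    return samples


def _index_matrices(study: ScoringSet, task: str, cfg: StudyConfig
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-scorer diagnostic index values and 5x12 matrices per index
    and method."""
    rows = []
    for rec_id in study.recordings(task):
        for method in ("manual", "semiauto"):
            for sid in study.scorers:
                rec = study.get(task, rec_id, sid, method)
                summ = recording_summary(rec)
                vals = {"SE": summ.se_pct, "SOL": summ.sol_min,
                        "WASO": summ.waso_min}
                if task != "staging":
                    vals.update(event_indices(
                        rec, summ, cfg.include_respiratory_in_plmi).as_dict())
                for index in TASK_INDICES[task]:
                    rows.append({"task": task, "recording": rec_id,
                                 "scorer": sid, "method": method,
                                 "index": index, "value": vals[index]})
    df = pd.DataFrame(rows)
    matrices: dict[tuple[str, str], np.ndarray] = {}
    for (index, method), sub in df.groupby(["index", "method"]):
        mat = sub.pivot_table(index="recording", columns="scorer",
                              values="value", sort=True)
        matrices[(index, method)] = mat.to_numpy()
    return df, matrices


def _icc_rows(matrices: Mapping, task: str, cfg: StudyConfig) -> list[dict]:
    rows = []
    for index in TASK_INDICES[task]:
        man = matrices[(index, "manual")]
        semi = matrices[(index, "semiauto")]
        row: dict = {"task": task, "index": index}
        for method, mat in (("manual", man), ("semiauto", semi)):
            med, q1, q3 = median_iqr(mat.ravel())
            row[f"{method}_median"] = med
            row[f"{method}_q1"] = q1
            row[f"{method}_q3"] = q3
        try:
            icc_m = icc_a1(man, r0=0.0, alpha=cfg.alpha)
            r0 = icc_m.icc if cfg.icc_r0_policy == "manual_baseline" else 0.0
            r0 = min(max(r0, 0.0), 1.0 - 1e-9)
            icc_s = icc_a1(semi, r0=r0, alpha=cfg.alpha)
        except (DegenerateDataError, DomainError) as exc:
            row.update({"icc_manual": math.nan, "icc_semiauto": math.nan,
                        "r0": math.nan, "p_value": math.nan,
                        "note": str(exc)})
            rows.append(row)
            continue
        row.update({
            "icc_manual": icc_m.icc, "icc_manual_ci_low": icc_m.ci_low,
            "icc_manual_ci_high": icc_m.ci_high,
            "icc_manual_p_vs_zero": icc_m.p_value,
            "icc_semiauto": icc_s.icc, "icc_semiauto_ci_low": icc_s.ci_low,
            "icc_semiauto_ci_high": icc_s.ci_high,
            "r0": icc_s.r0, "p_value": icc_s.p_value,
            "significant": icc_s.p_value < cfg.alpha, "note": "",
        })
        rows.append(row)
    return rows


def _rows_to_df(rows: list[ComparisonRow], with_gain: bool) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {
            "label": r.label,
            "manual_median": r.manual_median_iqr[0],
            "manual_q1": r.manual_median_iqr[1],
            "manual_q3": r.manual_median_iqr[2],
            "semiauto_median": r.semiauto_median_iqr[0],
            "semiauto_q1": r.semiauto_median_iqr[1],
            "semiauto_q3": r.semiauto_median_iqr[2],
        }
        if with_gain:
            rec["gain_factor"] = r.gain_factor
        rec.update({"p_value": r.p_value, "effect_size": r.effect_size,
                    "n": r.n, "significant": r.significant})
        recs.append(rec)
    return pd.DataFrame(recs)


def run_agreement_analysis(study: ScoringSet,
                           cfg: StudyConfig | None = None) -> AgreementReport:
    """Compute the complete comparison battery for a loaded or
    generated study."""
    cfg = cfg or StudyConfig()
    if cfg.tasks:
        tasks = cfg.tasks
    else:  # canonical reporting order, then any extra tasks
        tasks = (tuple(t for t in TASKS if t in study.tasks)
                 + tuple(t for t in study.tasks if t not in TASKS))
    _check_complete(study, tuple(tasks))

    pair_rows: list[dict] = []
    index_rows: list[pd.DataFrame] = []
    icc_rows: list[dict] = []
    for task in tasks:
        pair_rows.extend(_task_pair_kappas(study, task, cfg))
        idx_df, matrices = _index_matrices(study, task, cfg)
        index_rows.append(idx_df)
        icc_rows.extend(_icc_rows(matrices, task, cfg))

    pair_df = pd.DataFrame(pair_rows)
    kappa_samples = _matched_kappa_samples(pair_df)
    kappa_table = _rows_to_df(
        build_comparison_table(kappa_samples, alpha=cfg.alpha), with_gain=False)

    timing_samples = _timing_samples(study, tuple(tasks))
    timing_table = _rows_to_df(
        build_comparison_table(timing_samples, alpha=cfg.alpha,
                               with_gain=True), with_gain=True)

    return AgreementReport(
        pair_kappas=pair_df,
        kappa_table=kappa_table,
        timing_table=timing_table,
        index_table=pd.DataFrame(icc_rows),
        index_values=pd.concat(index_rows, ignore_index=True),
        alpha=cfg.alpha,
    )


def _fmt_mi(med: float, q1: float, q3: float) -> str:
    return f"{med:7.2f} [{q1:6.2f},{q3:7.2f}]"


def render_report(report: AgreementReport) -> str:
    """Aligned-text rendering of the three comparison tables."""
    lines = [
        "Manual vs semi-automatic PSG scoring: agreement and timing report",
        f"alpha = {report.alpha} per test; no multiple-testing correction.",
        "",
        "== Scoring time per task (minutes; active scoring time) ==",
        f"{'task':<18}{'manual med [IQR]':>24}{'semiauto med [IQR]':>24}"
        f"{'gain':>7}{'p':>10}{'d':>9}",
    ]
    for _, r in report.timing_table.iterrows():
        lines.append(
            f"{r['label']:<18}"
            f"{_fmt_mi(r['manual_median'], r['manual_q1'], r['manual_q3']):>24}"
            f"{_fmt_mi(r['semiauto_median'], r['semiauto_q1'], r['semiauto_q3']):>24}"
            f"{r['gain_factor']:>7.2f}{r['p_value']:>10.4f}"
            f"{r['effect_size']:>9.4f}"
            + ("*" if r["significant"] else ""))
    lines += ["", "== Pairwise kappa agreement per task and context ==",
              f"{'task:context':<34}{'manual med [IQR]':>24}"
              f"{'semiauto med [IQR]':>24}{'p':>10}{'d':>9}"]
    for _, r in report.kappa_table.iterrows():
        lines.append(
            f"{r['label']:<34}"
            f"{_fmt_mi(r['manual_median'], r['manual_q1'], r['manual_q3']):>24}"
            f"{_fmt_mi(r['semiauto_median'], r['semiauto_q1'], r['semiauto_q3']):>24}"
            f"{r['p_value']:>10.4f}{r['effect_size']:>9.4f}"
            + ("*" if r["significant"] else ""))
    lines += ["", "== ICC(A,1) agreement on diagnostic indices ==",
              f"{'index':<8}{'manual ICC (CI)':>22}{'semiauto ICC (CI)':>22}"
              f"{'r0':>8}{'p':>10}"]
    for _, r in report.index_table.iterrows():
        if r.get("note"):
            lines.append(f"{r['index']:<8}  undefined: {r['note']}")
            continue
        lines.append(
            f"{r['index']:<8}"
            f"{r['icc_manual']:>8.2f} ({r['icc_manual_ci_low']:.2f}-"
            f"{r['icc_manual_ci_high']:.2f})"
            f"{r['icc_semiauto']:>8.2f} ({r['icc_semiauto_ci_low']:.2f}-"
            f"{r['icc_semiauto_ci_high']:.2f})"
            f"{r['r0']:>8.2f}{r['p_value']:>10.4f}"
            + ("*" if r["significant"] else ""))
    lines.append("")
    return "\n".join(lines)
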