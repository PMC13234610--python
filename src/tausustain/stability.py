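"""Frozen-model restaging of follow-up scans and longitudinal stability.

Follow-up scans are subtyped and staged with the model trained on baseline
data, each scan independently (no information flows between a subject's
visits).  Stability is the proportion of subjects retaining their baseline
subtype at the last usable visit, summarized by a confusion matrix and
Cohen's kappa; stage progression is the annualized first-to-last stage
change among subtype-stable subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa

from .assign import AssignmentRecord, assign_matrix
from .cohort import CohortTable
from .model import SubtypeModel
from .zscore import ZScoreModel, apply_zscore

__all__ = [
    "StabilityReport",
    "restage_followups",
    "stability_report",
    "annual_stage_change",
    "proportion_ci",
]


def proportion_ci(k: int, n: int, round_percent: bool = True):
    """Binomial proportion with a Wald 95% CI, in percent.

    p-hat +/- 1.96 sqrt(p(1-p)/n), clamped to [0, 1].  With
    ``round_percent`` (the reporting default) the three numbers are rounded
    to integer percent (half away from zero); otherwise full precision is
    returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = k / n
    half = 1.96 * math.sqrt(p * (1.0 - p) / n)
    lo, hi = max(0.0, p - half), min(1.0, p + half)
    if round_percent:
        rnd = lambda v: int(math.floor(100.0 * v + 0.5))
        return rnd(p), rnd(lo), rnd(hi)
    return 100.0 * p, 100.0 * lo, 100.0 * hi


@dataclass
class StabilityReport:
    """Baseline-vs-last-visit agreement and stage-progression summary."""

    confusion: np.ndarray  # counts, rows = baseline subtype, cols = last visit
    kappa: float
    kappa_ci: tuple[float, float]
    n_subjects: int
    retained: int
    retention_percent: tuple[int, int, int]  # (percent, lo, hi)
    rates: pd.DataFrame  # per-subject annual stage change (subtype-stable only)
    per_subtype: pd.DataFrame  # mean/SD/t/p of rates per subtype
    anova_f: float
    anova_p: float
    counts: dict = field(default_factory=dict)  # regressed/stable/progressed

    def summary(self) -> str:
        lines = [
            f"subjects with usable baseline and follow-up: {self.n_subjects}",
            f"retained baseline subtype: {self.retained}/{self.n_subjects} "
            f"= {self.retention_percent[0]}% "
            f"(95% CI: {self.retention_percent[1]}-{self.retention_percent[2]}%)",
            f"Cohen's kappa: {self.kappa:.2f} "
            f"(95% CI: {self.kappa_ci[0]:.2f}-{self.kappa_ci[1]:.2f})",
            "confusion matrix (rows baseline, cols last visit):",
            str(self.confusion),
            f"annual stage change: mean {self.rates['rate'].mean():.2f} "
            f"+/- {self.rates['rate'].std(ddof=1):.2f} stages/year "
            f"(n = {len(self.rates)})",
            f"ANOVA across subtypes: F = {self.anova_f:.2f}, p = {self.anova_p:.3g}",
        ]
        for name, (kk, nn) in self.counts.items():
            pct, lo, hi = proportion_ci(kk, nn)
            lines.append(f"{name}: {kk}/{nn} = {pct}% (95% CI: {lo}-{hi}%)")
        return "\n".join(lines)


def restage_followups(
    table: CohortTable,
    model: SubtypeModel,
    zscore_model: ZScoreModel,
    prob_threshold: float = 0.5,
) -> list[AssignmentRecord]:
    """Assign every scan in the table with the frozen baseline-trained model.

    Controls are ignored; each patient scan (baseline and follow-up alike) is
    assigned independently, so the output for a scan depends only on that
    scan's values and the frozen model.
    """
    m = table.group_mask("patient")
    Z = apply_zscore(table, zscore_model, mask=m)
    sub = table.data.loc[m]
    return assign_matrix(
        Z,
        model,
        prob_threshold,
        subject_ids=sub["subject_id"].tolist(),
        visit_indices=sub["visit_index"].tolist(),
    )


def _pair_baseline_last(
    records: list[AssignmentRecord],
) -> list[tuple[AssignmentRecord, AssignmentRecord]]:
    """(baseline, last usable visit) per subject with a usable follow-up.

    Usable = not flagged as poorly fitted.  Subjects whose baseline or whose
    every follow-up is excluded are dropped (counts of drops are warned).
    """
    by_subject: dict[str, list[AssignmentRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    pairs = []
    dropped = 0
    for sid, recs in by_subject.items():
        recs = sorted(recs, key=lambda r: r.visit_index)
        base = [r for r in recs if r.visit_index == 0]
        fups = [r for r in recs if r.visit_index > 0 and not r.excluded]
        if not base or not fups:
            continue
        if base[0].excluded:
            dropped += 1
            continue
        pairs.append((base[0], fups[-1]))
    if dropped:
        warnings.warn(f"{dropped} subject(s) dropped: baseline scan excluded", stacklevel=2)
    return pairs


def _pair_baseline_second(
    records: list[AssignmentRecord],
) -> list[tuple[AssignmentRecord, AssignmentRecord]]:
    """(baseline, earliest usable follow-up) pairs; see _pair_baseline_last."""
    by_subject: dict[str, list[AssignmentRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    pairs = []
    for recs in by_subject.values():
        recs = sorted(recs, key=lambda r: r.visit_index)
        base = [r for r in recs if r.visit_index == 0 and not r.excluded]
        fups = [r for r in recs if r.visit_index > 0 and not r.excluded]
        if base and fups:
            pairs.append((base[0], fups[0]))
    return pairs


def stability_report(
    records: list[AssignmentRecord],
    times: pd.DataFrame | None = None,
    n_subtypes: int | None = None,
) -> StabilityReport:
    """Confusion matrix, kappa, retention and stage-progression summaries.

    ``times`` maps (subject_id, visit_index) to time_from_baseline in years;
    required for annual stage-change rates (pass the cohort's data frame).
    """
    pairs = _pair_baseline_last(records)
    if not pairs:
        raise ValueError("no subject has a usable baseline and follow-up scan")
    C = n_subtypes or (max(max(b.subtype, l.subtype) for b, l in pairs) + 1)
    confusion = np.zeros((C, C), dtype=int)
    for b, l in pairs:
        confusion[b.subtype, l.subtype] += 1
    n = int(confusion.sum())
    retained = int(np.trace(confusion))
    if C > 1 and n > 0:
        with warnings.catch_warnings():
            # perfect agreement makes the asymptotic variance 0/0
            warnings.simplefilter("ignore", RuntimeWarning)
            kr = cohens_kappa(confusion)
        kappa, ci = float(kr.kappa), (float(kr.kappa_low), float(kr.kappa_upp))
        if not (math.isfinite(ci[0]) and math.isfinite(ci[1])):
            ci = (kappa, kappa)
    else:  # single subtype: agreement is trivially perfect
        kappa, ci = 1.0, (1.0, 1.0)
    rates = annual_stage_change(records, times) if times is not None else pd.DataFrame(
        columns=["subject_id", "subtype", "rate", "delta_stage", "delta_t"]
    )
    per_rows = []
    groups = []
    for c, grp in rates.groupby("subtype"):
        r = grp["rate"].to_numpy()
        groups.append(r)
        if len(r) >= 2 and np.std(r) > 0:
            t, p = stats.ttest_1samp(r, 0.0, alternative="greater")
        else:
            t, p = float("nan"), float("nan")
        per_rows.append(
            {
                "subtype": c,
                "n": len(r),
                "mean_rate": float(np.mean(r)),
                "sd_rate": float(np.std(r, ddof=1)) if len(r) > 1 else float("nan"),
                "t": float(t),
                "p": float(p),
            }
        )
    per_subtype = pd.DataFrame(per_rows)
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        if all(np.ptp(g) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
            anova_f, anova_p = 0.0, 1.0  # all rates identical
        else:
            anova_f, anova_p = (float(v) for v in stats.f_oneway(*groups))
    else:
        anova_f, anova_p = float("nan"), float("nan")
    counts = {}
    if len(rates):
        nr = len(rates)
        counts["regressed"] = (int((rates["delta_stage"] < 0).sum()), nr)
        counts["stable"] = (int((rates["delta_stage"] == 0).sum()), nr)
        counts["progressed"] = (int((rates["delta_stage"] > 0).sum()), nr)
        counts["progressed_or_stable"] = (int((rates["delta_stage"] >= 0).sum()), nr)
    return StabilityReport(
        confusion=confusion,
        kappa=kappa,
        kappa_ci=ci,
        n_subjects=n,
        retained=retained,
        retention_percent=proportion_ci(retained, n),
        rates=rates,
        per_subtype=per_subtype,
        anova_f=anova_f,
        anova_p=anova_p,
        counts=counts,
    )


def annual_stage_change(
    records: list[AssignmentRecord], times: pd.DataFrame, visit: str = "last"
) -> pd.DataFrame:
    """Per-subject annualized stage change, baseline vs a follow-up visit.

    ``visit="last"`` (the primary analysis) compares against the last usable
    visit; ``visit="second"`` against the earliest usable follow-up, as a
    sensitivity check for subjects with several follow-ups.  Computed only
    for subjects retaining their baseline subtype at the comparison visit.
    ``times`` must contain ``subject_id``, ``visit_index`` and
    ``time_from_baseline`` columns.
    """
    if visit not in ("last", "second"):
        raise ValueError("visit must be 'last' or 'second'")
    tmap = {
        (str(r.subject_id), int(r.visit_index)): float(r.time_from_baseline)
        for r in times.itertuples()
    }
    pairs = (
        _pair_baseline_last(records)
        if visit == "last"
        else _pair_baseline_second(records)
    )
    rows = []
    for base, last in pairs:
        if base.subtype != last.subtype:
            continue
        dt = tmap[(last.subject_id, last.visit_index)] - tmap[
            (base.subject_id, base.visit_index)
        ]
        if dt <= 0:
            warnings.warn(
                f"subject {base.subject_id}: non-positive follow-up interval; skipped",
                stacklevel=2,
            )
            continue
        dk = last.stage - base.stage
        rows.append(
            {
                "subject_id": base.subject_id,
                "subtype": base.subtype,
                "rate": dk / dt,
                "delta_stage": dk,
                "delta_t": dt,
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "subtype", "rate", "delta_stage", "delta_t"])
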