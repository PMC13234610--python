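"""Recovery scoring against simulated ground truth, and run reports."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .assign import AssignmentRecord, records_to_frame
from .events import EventSet, is_valid_sequence
from .model import CvResult, McmcSamples, SubtypeModel
from .stability import StabilityReport, proportion_ci

__all__ = [
    "RecoveryMetrics",
    "match_subtypes",
    "sequence_recovery",
    "score_recovery",
    "render_report",
]


@dataclass
class RecoveryMetrics:
    """How well a fit recovered the generating truth."""

    permutation: tuple[int, ...]  # estimated label c -> true label permutation[c]
    accuracy: float
    kendall_tau: list[float]  # per matched subtype
    stage_mae: float
    stage_bias: float
    fraction_error: float  # max abs error after matching
    n_scored: int


def match_subtypes(
    true_labels: np.ndarray, est_labels: np.ndarray, n_subtypes: int
) -> tuple[int, ...]:
    """Bijection over subtype indices maximizing label agreement.

    Exhaustive over permutations; practical up to 8 subtypes.  Returns the
    permutation mapping estimated label c to true label perm[c].
    """
    if n_subtypes > 8:
        raise ValueError("exhaustive matching is limited to <= 8 subtypes")
    true_labels = np.asarray(true_labels)
    est_labels = np.asarray(est_labels)
    if true_labels.shape != est_labels.shape:
        raise ValueError("label vectors must have the same length")
    best_perm, best_hits = None, -1
    for perm in itertools.permutations(range(n_subtypes)):
        hits = int(np.sum(np.array(perm)[est_labels] == true_labels))
        if hits > best_hits:
            best_perm, best_hits = perm, hits
    return tuple(best_perm)


def sequence_recovery(true_seq: np.ndarray, est_seq: np.ndarray, es: EventSet) -> float:
    """Kendall rank correlation between the two sequences' position maps."""
    for s in (true_seq, est_seq):
        if not is_valid_sequence(np.asarray(s), es):
            raise ValueError("sequence does not belong to this event set")
    n = es.n_events
    pos_true = np.empty(n, dtype=int)
    pos_est = np.empty(n, dtype=int)
    pos_true[np.asarray(true_seq)] = np.arange(n)
    pos_est[np.asarray(est_seq)] = np.arange(n)
    tau, _ = kendalltau(pos_true, pos_est)
    return float(tau)


def score_recovery(
    truth,
    model: SubtypeModel,
    records: list[AssignmentRecord],
    include_excluded: bool = False,
) -> RecoveryMetrics:
    """Score subtype/stage/sequence/fraction recovery for baseline records.

    By default scans flagged by the poor-fit exclusion are left out of the
    accuracy and staging scores, mirroring how poorly fitted scans are
    excluded from the study's post-clustering analyses.
    """
    base = [
        r
        for r in records
        if r.visit_index == 0 and (include_excluded or not r.excluded)
    ]
    true_c = np.array([truth.subtype_of[r.subject_id] for r in base])
    est_c = np.array([r.subtype for r in base])
    C = truth.n_subtypes
    perm = match_subtypes(true_c, est_c, C)
    acc = float(np.mean(np.array(perm)[est_c] == true_c))
    taus = [
        sequence_recovery(truth.sequences[perm[c]], model.sequences[c], model.event_set)
        for c in range(C)
    ]
    true_k = np.array([truth.stage_of[(r.subject_id, 0)] for r in base])
    est_k = np.array([r.stage for r in base])
    # Fractions are compared against the cohort's realized subtype
    # composition (what a mixture fitted to this sample actually estimates),
    # over every baseline scan the model was fitted to.
    all_base = np.array(
        [truth.subtype_of[r.subject_id] for r in records if r.visit_index == 0]
    )
    realized = np.bincount(all_base, minlength=C) / all_base.size
    frac_err = float(
        np.max(np.abs(np.array([realized[perm[c]] for c in range(C)]) - model.fractions))
    )
    return RecoveryMetrics(
        permutation=perm,
        accuracy=acc,
        kendall_tau=taus,
        stage_mae=float(np.mean(np.abs(est_k - true_k))),
        stage_bias=float(np.mean(est_k - true_k)),
        fraction_error=frac_err,
        n_scored=len(base),
    )


def render_report(
    out_dir: str | Path,
    model: SubtypeModel | None = None,
    records: list[AssignmentRecord] | None = None,
    stability: StabilityReport | None = None,
    recovery: RecoveryMetrics | None = None,
    cv: CvResult | None = None,
    mcmc: McmcSamples | None = None,
) -> dict[str, Path]:
    """Write CSV + plain-text summaries for whatever inputs are given.

    Every reported percentage/CI is recomputed from its counts through
    :func:`~tausustain.stability.proportion_ci`, so the printed report is
    self-consistent with the raw counts by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    lines: list[str] = []

    if model is not None:
        seq_df = pd.DataFrame(
            {
                f"subtype_{c + 1}": [model.event_set.event_labels()[e] for e in model.sequences[c]]
                for c in range(model.n_subtypes)
            }
        )
        seq_df.insert(0, "position", np.arange(1, model.event_set.n_events + 1))
        p = out_dir / "sequences.csv"
        seq_df.to_csv(p, index=False)
        written["sequences"] = p
        lines.append(
            "fitted subtypes: "
            + ", ".join(f"f_{c + 1} = {f:.3f}" for c, f in enumerate(model.fractions))
        )
        lines.append(f"training log-likelihood: {model.log_likelihood:.3f}")

    if records is not None:
        df = records_to_frame(records)
        p = out_dir / "assignments.csv"
        df.to_csv(p, index=False)
        written["assignments"] = p
        if len(df) == 0:
            lines.append("warning: no assignments to report")
        else:
            base = df[df["visit_index"] == 0]
            n_all = len(base)
            n_excl = int(base["excluded"].sum())
            pct, lo, hi = proportion_ci(n_all - n_excl, n_all) if n_all else (0, 0, 0)
            lines.append(
                f"baseline scans assigned with adequate fit: {n_all - n_excl}/{n_all} "
                f"= {pct}% (95% CI: {lo}-{hi}%)"
            )
            kept = base[~base["excluded"]]
            for c, cnt in kept["subtype"].value_counts().sort_index().items():
                pct, lo, hi = proportion_ci(int(cnt), len(kept))
                lines.append(
                    f"subtype {c + 1}: {cnt}/{len(kept)} = {pct}% (95% CI: {lo}-{hi}%)"
                )
            dev = kept["deviation"].dropna()
            if len(dev):
                lines.append(
                    f"mean deviation from assigned sequence: {dev.mean():.2f} events"
                )

    if cv is not None:
        cv_df = pd.DataFrame(
            {
                "n_subtypes": cv.c_values,
                "cvic": cv.cvic,
                **{
                    f"fold_{f + 1}_loglik": cv.fold_loglik[f]
                    for f in range(cv.fold_loglik.shape[0])
                },
            }
        )
        p = out_dir / "cvic.csv"
        cv_df.to_csv(p, index=False)
        written["cvic"] = p
        lines.append(
            "CVIC by subtype count: "
            + ", ".join(f"C={c}: {v:.1f}" for c, v in zip(cv.c_values, cv.cvic))
        )

    if mcmc is not None:
        for c, pv in enumerate(mcmc.positional_variance):
            p = out_dir / f"positional_variance_subtype_{c + 1}.csv"
            pd.DataFrame(pv).to_csv(p, index=False)
            written[f"positional_variance_{c + 1}"] = p
        lines.append(f"MCMC acceptance rate: {mcmc.acceptance_rate:.3f}")

    if stability is not None:
        p = out_dir / "confusion_matrix.csv"
        pd.DataFrame(stability.confusion).to_csv(p, index=False)
        written["confusion_matrix"] = p
        p = out_dir / "stage_rates.csv"
        stability.rates.to_csv(p, index=False)
        written["stage_rates"] = p
        lines.append(stability.summary())

    if recovery is not None:
        lines.append(
            f"recovery vs ground truth (n = {recovery.n_scored}): "
            f"accuracy = {recovery.accuracy:.3f}, "
            f"kendall tau = {['%.3f' % t for t in recovery.kendall_tau]}, "
            f"stage MAE = {recovery.stage_mae:.2f}, "
            f"fraction error = {recovery.fraction_error:.3f}"
        )

    text = "\n".join(lines) + "\n"
    p = out_dir / "report.txt"
    p.write_text(text)
    written["report"] = p
    return written
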