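"""End-to-end experiments on synthetic cohorts with known ground truth.

Each function runs one self-contained study — oracle comparison, EM
diagnostics, subtype/sequence recovery, or the longitudinal stability
pipeline — at the package's reference problem sizes, and returns plain
scalars.  They are the computational backbone of the acceptance checks and
of the numbered analysis drivers.
"""

from __future__ import annotations

import numpy as np

from .assign import assign_matrix
from .cohort import RunConfig
from .events import all_valid_sequences
from .model import (
    cross_validate,
    fit_em,
    hierarchical_fit,
    _Evaluator,
)
from .simulate import generate_truth, simulate_cohort, simulate_followups
from .stability import restage_followups, stability_report
from .evaluate import score_recovery
from .zscore import apply_zscore, fit_zscore_reference

__all__ = [
    "oracle_agreement",
    "em_diagnostics",
    "recovery_experiment",
    "longitudinal_experiment",
    "cvic_elbow",
]


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def oracle_agreement(seed: int, n_datasets: int = 100, n_subjects: int = 50) -> dict:
    """Greedy EM vs exhaustive enumeration at N = 6 events, one subtype.

    For each seeded dataset the maximum-likelihood sequence is found both by
    the greedy optimizer (with restarts) and by scoring all 90 valid
    permutations; returns the fraction of datasets where they coincide.
    """
    seeds = _spawn(seed, 3 * n_datasets)
    matches = 0
    for d in range(n_datasets):
        s_truth, s_cohort, s_fit = seeds[3 * d : 3 * d + 3]
        truth = generate_truth(n_regions=3, n_thresholds=2, n_subtypes=1, seed=s_truth)
        es = truth.event_set
        coh = simulate_cohort(truth, n_patients=n_subjects, n_controls=2,
                              sigma=1.0, seed=s_cohort)
        Z = coh.values(coh.group_mask("patient"))
        ev = _Evaluator(Z, es)
        w = np.ones(Z.shape[0])
        best, best_obj = None, -np.inf
        for s in all_valid_sequences(es):
            o = ev.weighted_objective(s, w)
            if o > best_obj:
                best, best_obj = s, o
        m = fit_em(Z, 1, es, RunConfig(em_startpoints=5),
                   np.random.default_rng(s_fit))
        matches += int(np.array_equal(m.sequences[0], best))
    return {"agreement": matches / n_datasets, "n_datasets": n_datasets}


def em_diagnostics(seed: int, n_datasets: int = 50, n_subjects: int = 30) -> dict:
    """EM sanity across random datasets: monotone trace and C-nesting.

    On each dataset (unstructured noise, the hardest case for EM stability)
    the total log-likelihood trace must never decrease, and the 2-subtype
    training log-likelihood must dominate the 1-subtype one.
    """
    seeds = _spawn(seed, 2 * n_datasets)
    monotone = nested = 0
    es = generate_truth(n_regions=3, n_thresholds=2, n_subtypes=1, seed=0).event_set
    for d in range(n_datasets):
        rng = np.random.default_rng(seeds[2 * d])
        Z = rng.normal(1.5, 2.5, (n_subjects, 3))
        fit_rng = np.random.default_rng(seeds[2 * d + 1])
        cfg = RunConfig(em_startpoints=2)
        models = hierarchical_fit(Z, 2, es, cfg, fit_rng)
        traces_ok = all(
            np.all(np.diff(m.ll_trace) >= -1e-6) for m in models
        )
        monotone += int(traces_ok)
        nested += int(models[1].log_likelihood >= models[0].log_likelihood - 1e-9)
    return {
        "monotone_fraction": monotone / n_datasets,
        "nested_fraction": nested / n_datasets,
        "n_datasets": n_datasets,
    }


def cvic_elbow(c_values, cvic, rel_tol: float = 0.05) -> int:
    """Smallest subtype count whose CVIC is within ``rel_tol`` of the minimum,
    measured against the total drop from the C=1 value."""
    cvic = np.asarray(cvic, dtype=float)
    drop = cvic[0] - cvic.min()
    if drop <= 0:
        return int(c_values[0])
    for c, v in zip(c_values, cvic):
        if v - cvic.min() <= rel_tol * drop:
            return int(c)
    return int(c_values[-1])


def recovery_experiment(
    seed: int,
    n_patients: int = 300,
    n_controls: int = 85,
    n_subtypes: int = 3,
    sigma: float = 1.0,
    c_values: tuple[int, ...] = (1, 2, 3, 4),
    cv_folds: int = 5,
    fit_startpoints: int = 10,
    cv_startpoints: int = 5,
    run_cv: bool = True,
    n_replicates: int = 3,
) -> dict:
    """Full-pipeline recovery at the reference scale: 20 events, 3 subtypes.

    Simulates a baseline cohort from a random truth, fits the subtype
    hierarchy, assigns every scan, and scores subtype accuracy, per-subtype
    sequence Kendall tau, stage error, fraction error, and the deviation
    statistic.  The recovery metrics are stochastic, so they are measured as
    the mean over ``n_replicates`` independent cohort/fit replicates (each
    with its own truth); the CVIC curve (if requested) is computed once, on
    the first replicate.
    """
    out: dict = {"n_patients": n_patients, "n_replicates": n_replicates}
    per_rep: list[dict] = []
    for rep in range(n_replicates):
        s_truth, s_cohort, s_fit, s_cv = _spawn(seed + 7919 * rep, 4)
        truth = generate_truth(n_subtypes=n_subtypes, seed=s_truth)
        coh = simulate_cohort(truth, n_patients=n_patients, n_controls=n_controls,
                              sigma=sigma, seed=s_cohort)
        ref = fit_zscore_reference(coh)
        pmask = coh.baseline_mask() & coh.group_mask("patient")
        Z = apply_zscore(coh, ref, mask=pmask)
        models = hierarchical_fit(
            Z, n_subtypes, truth.event_set,
            RunConfig(em_startpoints=fit_startpoints),
            np.random.default_rng(s_fit),
        )
        model = models[-1]
        ids = coh.data.loc[pmask, "subject_id"].tolist()
        records = assign_matrix(Z, model, subject_ids=ids)
        rec = score_recovery(truth, model, records)
        kept = [r for r in records if not r.excluded]
        per_rep.append(
            {
                "accuracy": rec.accuracy,
                "kendall_tau_min": min(rec.kendall_tau),
                "kendall_tau_mean": float(np.mean(rec.kendall_tau)),
                "fraction_error": rec.fraction_error,
                "stage_mae": rec.stage_mae,
                "mean_deviation": float(np.mean([r.deviation for r in kept])),
                "excluded_count": sum(r.excluded for r in records),
            }
        )
        if rep == 0:
            out["train_loglik_by_c"] = [m.log_likelihood for m in models]
            if run_cv:
                cv = cross_validate(
                    Z, list(c_values), cv_folds, truth.event_set,
                    RunConfig(em_startpoints=cv_startpoints), seed=s_cv,
                )
                out["cvic"] = [float(v) for v in cv.cvic]
                out["cvic_elbow"] = cvic_elbow(cv.c_values, cv.cvic)
    for key in per_rep[0]:
        out[key] = float(np.mean([r[key] for r in per_rep]))
    out["replicates"] = per_rep
    return out


def longitudinal_experiment(
    seed: int,
    n_patients: int = 200,
    n_controls: int = 85,
    n_subtypes: int = 3,
    sigma: float = 1.0,
    fit_startpoints: int = 5,
    n_replicates: int = 3,
) -> dict:
    """Frozen-model restaging of simulated follow-ups.

    Baseline cohort -> fit -> follow-ups at 0.56 +/- 0.70 stages/year with
    intervals of 1.90 +/- 0.94 years -> restage every scan with the frozen
    baseline model; reports subtype retention, Cohen's kappa, and the mean
    estimated annual stage-change rate among subtype-stable subjects.  The
    retention and rate estimates carry Monte-Carlo error of the same order
    as their recovery tolerances, so they are averaged over
    ``n_replicates`` independent replicates of the whole pipeline.
    """
    per_rep: list[dict] = []
    for rep in range(n_replicates):
        s_truth, s_cohort, s_fit, s_fup = _spawn(seed + 7919 * rep, 4)
        truth = generate_truth(n_subtypes=n_subtypes, seed=s_truth)
        coh = simulate_cohort(truth, n_patients=n_patients, n_controls=n_controls,
                              sigma=sigma, seed=s_cohort)
        coh = simulate_followups(coh, truth, switch_prob=0.0, seed=s_fup)
        ref = fit_zscore_reference(coh)
        pmask = coh.baseline_mask() & coh.group_mask("patient")
        Z = apply_zscore(coh, ref, mask=pmask)
        models = hierarchical_fit(
            Z, n_subtypes, truth.event_set,
            RunConfig(em_startpoints=fit_startpoints),
            np.random.default_rng(s_fit),
        )
        records = restage_followups(coh, models[-1], ref)
        report = stability_report(records, times=coh.data, n_subtypes=n_subtypes)
        nr = len(report.rates)
        per_rep.append(
            {
                "retention": report.retained / report.n_subjects,
                "kappa": report.kappa,
                "mean_annual_stage_change": float(report.rates["rate"].mean()),
                "sd_annual_stage_change": float(report.rates["rate"].std(ddof=1)),
                "regressed_fraction": report.counts["regressed"][0] / nr,
                "n_subjects": report.n_subjects,
            }
        )
    out = {"n_replicates": n_replicates, "replicates": per_rep}
    for key in ("retention", "kappa", "mean_annual_stage_change",
                "sd_annual_stage_change", "regressed_fraction"):
        out[key] = float(np.mean([r[key] for r in per_rep]))
    out["n_subjects_total"] = int(sum(r["n_subjects"] for r in per_rep))
    return out
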