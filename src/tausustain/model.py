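"""The linear z-score subtype-and-stage model.

Disease progression within a subtype is an ordered sequence of the N events
of an :class:`~tausustain.events.EventSet`; a subject at stage k (0..N) has
completed the first k events of their subtype's sequence.  Each region's
expected z-score is piecewise linear in stage, passing through its thresholds
at the stages where the corresponding events occur, and its ceiling z_max at
stage N.  Observed z-scores are the expected trajectory plus independent
Gaussian noise per region.

Subtypes are mixture components with their own sequence and mixing fraction;
they are fitted by expectation-maximization with a greedy coordinate-ascent
sequence optimizer, grown one subtype at a time by divisive splitting, and
their ordering uncertainty is summarized by Metropolis MCMC over sequences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .cohort import RunConfig
from .events import (
    EventSet,
    is_valid_sequence,
    random_valid_sequence,
    valid_positions,
)

__all__ = [
    "SubtypeModel",
    "McmcSamples",
    "CvResult",
    "expected_values",
    "stage_log_likelihoods",
    "subject_log_likelihood",
    "optimize_sequence",
    "fit_em",
    "hierarchical_fit",
    "run_mcmc",
    "cross_validate",
]

_LOG_2PI = math.log(2.0 * math.pi)


# -- expected trajectories and likelihoods --------------------------------

def expected_values(seq: np.ndarray, es: EventSet) -> np.ndarray:
    """Expected z per region at every stage: matrix g of shape (N+1, B).

    g[:, i] interpolates linearly through (0, 0), (p(i,1), z_i1), ...,
    (p(i,R), z_iR), (N, z_max_i), where p is the event's 1-based position in
    ``seq``; the z_max knot is dropped when the region's last event sits at
    position N.  Each column is non-decreasing in stage.
    """
    seq = np.asarray(seq)
    N, B = es.n_events, es.n_regions
    pos1 = np.empty(N, dtype=int)  # 1-based position of each event id
    pos1[seq] = np.arange(1, N + 1)
    k = np.arange(N + 1)
    g = np.empty((N + 1, B))
    for i in range(B):
        thr = es.thresholds[i]
        xs = [0] + [int(pos1[es.event_id(i, r)]) for r in range(len(thr))]
        ys = [0.0] + list(thr)
        if xs[-1] < N:
            xs.append(N)
            ys.append(es.z_max[i])
        g[:, i] = np.interp(k, xs, ys)
    return g


def stage_log_likelihoods(
    Z: np.ndarray, seq: np.ndarray, es: EventSet, sigma: np.ndarray | None = None
) -> np.ndarray:
    """log L[j, k] = sum_i log N(z_ji; g_i(k), sigma_i); shape (n, N+1)."""
    return _Evaluator(Z, es, sigma).stage_ll(seq)


def subject_log_likelihood(
    Z: np.ndarray, model: "SubtypeModel"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subtype marginal log P(x|S_c) and total mixture log-likelihood.

    The stage prior is uniform over 0..N.  Returns ``(logm, total)`` where
    ``logm`` has shape (n, C) and ``total`` is the per-subject mixture
    log-likelihood log sum_c f_c P(x|S_c), shape (n,).
    """
    ev = _Evaluator(Z, model.event_set, model.sigma)
    logm = np.column_stack([ev.log_marginal(s) for s in model.sequences])
    total = logsumexp(logm + np.log(model.fractions), axis=1)
    return logm, total


class _Evaluator:
    """Caches the data-dependent pieces of the stage likelihood.

    With scaled data Zs = Z/sigma and scaled trajectory gs = g/sigma,
    log L[j,k] = -0.5 (|Zs_j|^2 - 2 Zs_j.gs_k + |gs_k|^2) - const, which is a
    single (n x B)(B x N+1) matrix product per candidate sequence.
    """

    def __init__(self, Z: np.ndarray, es: EventSet, sigma: np.ndarray | None = None):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != es.n_regions:
            raise ValueError(
                f"z-matrix has {Z.shape[1]} columns, event set has {es.n_regions} regions"
            )
        if sigma is None:
            sigma = np.ones(es.n_regions)
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("noise scales sigma must be positive")
        self.es = es
        self.sigma = sigma
        self.Zs = Z / sigma
        self.sq = (self.Zs**2).sum(axis=1)
        self.const = float(np.log(sigma).sum() + es.n_regions * 0.5 * _LOG_2PI)
        self.log_n_stages = math.log(es.n_events + 1)

    def stage_ll(self, seq: np.ndarray) -> np.ndarray:
        gs = expected_values(seq, self.es) / self.sigma
        return (
            -0.5 * (self.sq[:, None] - 2.0 * (self.Zs @ gs.T) + (gs**2).sum(axis=1)[None, :])
            - self.const
        )

    def log_marginal(self, seq: np.ndarray) -> np.ndarray:
        """Uniform-stage-prior marginal log P(x | S) per subject."""
        return logsumexp(self.stage_ll(seq), axis=1) - self.log_n_stages

    def weighted_objective(self, seq: np.ndarray, w: np.ndarray) -> float:
        return float(w @ self.log_marginal(seq))


# -- model containers -----------------------------------------------------

@dataclass
class SubtypeModel:
    """Fitted mixture: per-subtype sequences, fractions, shared noise scales."""

    event_set: EventSet
    sequences: list[np.ndarray]
    fractions: np.ndarray
    sigma: np.ndarray
    log_likelihood: float = float("nan")
    ll_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one fraction per sequence required")
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {self.fractions.sum()!r}")
        for s in self.sequences:
            if not is_valid_sequence(s, self.event_set):
                raise ValueError(f"invalid event sequence {np.asarray(s).tolist()}")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def to_dict(self) -> dict:
        return {
            "sequences": [np.asarray(s).tolist() for s in self.sequences],
            "sequence_labels": [
                [self.event_set.event_labels()[e] for e in np.asarray(s)]
                for s in self.sequences
            ],
            "fractions": [float(f) for f in self.fractions],
            "sigma": [float(s) for s in self.sigma],
            "log_likelihood": float(self.log_likelihood),
            "ll_trace": [float(v) for v in self.ll_trace],
        }

    @classmethod
    def from_dict(cls, d: dict, es: EventSet) -> "SubtypeModel":
        return cls(
            event_set=es,
            sequences=[np.asarray(s, dtype=int) for s in d["sequences"]],
            fractions=np.asarray(d["fractions"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            ll_trace=list(d.get("ll_trace", [])),
        )


@dataclass
class McmcSamples:
    """Retained MCMC sequence samples and positional-variance matrices."""

    sequences: list[list[np.ndarray]]  # per subtype
    log_likelihoods: np.ndarray  # total data log-likelihood per retained draw
    positional_variance: list[np.ndarray]  # per subtype, (N, N): P(event e at position pos)
    acceptance_rate: float


@dataclass
class CvResult:
    """Cross-validated held-out log-likelihoods and the CVIC curve."""

    c_values: list[int]
    fold_loglik: np.ndarray  # (k_folds, len(c_values))
    cvic: np.ndarray  # -2 * summed held-out log-likelihood per C
    fold_of_subject: np.ndarray
    seed: int


# -- sequence optimization ------------------------------------------------

def optimize_sequence(
    Z: np.ndarray,
    w: np.ndarray,
    seq_init: np.ndarray,
    es: EventSet,
    sigma: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    max_sweeps: int = 100,
    _evaluator: "_Evaluator | None" = None,
) -> tuple[np.ndarray, float]:
    """Greedy coordinate ascent over valid sequences.

    Sweeps the events in a seeded-random order; each event is removed and
    re-inserted at the valid position maximizing the weighted data
    log-likelihood (ties resolved to the earliest position; moves require a
    strict improvement, so the objective never decreases and all-zero weights
    leave the initial sequence untouched).  Returns (sequence, objective).
    """
    ev = _evaluator if _evaluator is not None else _Evaluator(Z, es, sigma)
    if rng is None:
        rng = np.random.default_rng(0)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    seq = np.array(seq_init, dtype=int)
    if not is_valid_sequence(seq, es):
        raise ValueError("seq_init is not a valid event sequence")
    obj = ev.weighted_objective(seq, w)
    for _ in range(max_sweeps):
        improved = False
        for e in rng.permutation(es.n_events):
            cur = int(np.nonzero(seq == e)[0][0])
            rest = np.delete(seq, cur)
            best_obj, best_seq = obj, None
            for p in valid_positions(rest, int(e), es):
                cand = np.insert(rest, p, e)
                if p == cur:  # unchanged sequence
                    continue
                cand_obj = ev.weighted_objective(cand, w)
                if cand_obj > best_obj:
                    best_obj, best_seq = cand_obj, cand
            if best_seq is not None:
                seq, obj, improved = best_seq, best_obj, True
        if not improved:
            break
    return seq, obj


# -- expectation-maximization ---------------------------------------------

class DegenerateFitError(RuntimeError):
    """All EM starts collapsed a subtype to (near-)zero weight."""


def fit_em(
    Z: np.ndarray,
    C: int,
    es: EventSet,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    inits: list[tuple[list[np.ndarray], np.ndarray]] | None = None,
    sigma: np.ndarray | None = None,
) -> SubtypeModel:
    """Fit a C-subtype model by EM, best of several seeded starts.

    E-step: responsibilities w_jc from current fractions and sequence
    marginals.  M-step: each sequence re-optimized against its responsibility
    weights; fractions set to mean responsibility.  Iteration stops when the
    relative total log-likelihood change falls below the tolerance.  Starts
    whose smallest fraction collapses below 1/(10 n) are discarded; if every
    start collapses, :class:`DegenerateFitError` is raised.
    """
    config = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if C < 1:
        raise ValueError("C must be >= 1")
    if n < C:
        raise ValueError(f"need at least C={C} subjects, got {n}")
    ev = _Evaluator(Z, es, sigma)
    if inits is None:
        starts = [
            ([random_valid_sequence(es, rng) for _ in range(C)], np.full(C, 1.0 / C))
            for _ in range(config.em_startpoints)
        ]
    else:
        starts = [(list(seqs), np.asarray(fr, dtype=float)) for seqs, fr in inits]

    floor = 1.0 / (10.0 * n)
    best: SubtypeModel | None = None
    for seqs0, f0 in starts:
        seqs = [np.array(s, dtype=int) for s in seqs0]
        f = np.array(f0, dtype=float)
        f = f / f.sum()
        trace: list[float] = []
        degenerate = False
        for _ in range(config.em_max_iter):
            logm = np.column_stack([ev.log_marginal(s) for s in seqs])
            joint = logm + np.log(f)
            total = float(logsumexp(joint, axis=1).sum())
            if trace:
                assert total >= trace[-1] - 1e-8 * max(1.0, abs(trace[-1])), (
                    "EM log-likelihood decreased"
                )
                if abs(total - trace[-1]) <= config.em_tol * max(1.0, abs(trace[-1])):
                    trace.append(total)
                    break
            trace.append(total)
            w = np.exp(joint - logsumexp(joint, axis=1)[:, None])  # responsibilities
            f_new = w.mean(axis=0)
            if C > 1 and f_new.min() < floor:
                degenerate = True
                break
            f = f_new
            for c in range(C):
                seqs[c], _ = optimize_sequence(
                    Z, w[:, c], seqs[c], es, rng=rng, _evaluator=ev
                )
        if degenerate:
            continue
        logm = np.column_stack([ev.log_marginal(s) for s in seqs])
        total = float(logsumexp(logm + np.log(f), axis=1).sum())
        cand = SubtypeModel(
            event_set=es,
            sequences=seqs,
            fractions=f,
            sigma=ev.sigma,
            log_likelihood=total,
            ll_trace=trace,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    if best is None:
        raise DegenerateFitError(
            f"every EM start collapsed a subtype below weight {floor:.2g}"
        )
    return best


def hierarchical_fit(
    Z: np.ndarray,
    C_max: int,
    es: EventSet,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    sigma: np.ndarray | None = None,
) -> list[SubtypeModel]:
    """Divisive fitting of 1..C_max subtypes.

    The C-subtype solution is grown from the (C-1)-subtype one: subjects are
    hard-assigned to their maximum-likelihood subtype, each sufficiently
    large subtype is split in two by a 2-subtype EM fit on its members, and
    every resulting candidate (plus a duplicate-largest-subtype fallback,
    which guarantees the training log-likelihood is non-decreasing in C) is
    refined by EM on the full data; the best refined candidate is kept.
    """
    config = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if C_max < 1:
        raise ValueError("C_max must be >= 1")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    models = [fit_em(Z, 1, es, config, rng, sigma=sigma)]
    for C in range(2, C_max + 1):
        prev = models[-1]
        logm, _ = subject_log_likelihood(Z, prev)
        hard = np.argmax(logm, axis=1)
        candidates: list[tuple[list[np.ndarray], np.ndarray]] = []
        for c in range(prev.n_subtypes):
            members = np.nonzero(hard == c)[0]
            if members.size < 2 * C:
                warnings.warn(
                    f"subtype {c} has only {members.size} members; not split",
                    stacklevel=2,
                )
                continue
            try:
                sub = fit_em(Z[members], 2, es, config, rng, sigma=sigma)
            except DegenerateFitError:
                continue
            seqs = [np.array(s) for j, s in enumerate(prev.sequences) if j != c]
            fracs = [float(f) for j, f in enumerate(prev.fractions) if j != c]
            seqs += [np.array(s) for s in sub.sequences]
            fracs += [float(prev.fractions[c] * f) for f in sub.fractions]
            candidates.append((seqs, np.asarray(fracs)))
        # Fallback: duplicating the largest subtype reproduces the previous
        # mixture exactly, so refinement can only improve on it (nesting).
        dup = int(np.argmax(prev.fractions))
        seqs = [np.array(s) for s in prev.sequences] + [np.array(prev.sequences[dup])]
        fracs = np.array(list(prev.fractions) + [prev.fractions[dup]])
        fracs[dup] /= 2.0
        fracs[-1] = fracs[dup]
        candidates.append((seqs, fracs / fracs.sum()))

        best: SubtypeModel | None = None
        for cand in candidates:
            try:
                refined = fit_em(Z, C, es, config, rng, inits=[cand], sigma=sigma)
            except DegenerateFitError:
                continue
            if best is None or refined.log_likelihood > best.log_likelihood:
                best = refined
        if best is None:  # only possible if even the duplicate start collapsed
            raise DegenerateFitError(f"no viable {C}-subtype candidate")
        models.append(best)
    return models


# -- MCMC over sequences --------------------------------------------------

def run_mcmc(
    model: SubtypeModel,
    Z: np.ndarray,
    n_iter: int,
    seed: int,
    burn_frac: float = 0.1,
) -> McmcSamples:
    """Metropolis sampling of event orderings around a fitted model.

    Each iteration picks a subtype and an event uniformly, proposes a
    uniformly-random valid position for it, and accepts with probability
    min(1, L_new/L_old) on the total data likelihood; mixing fractions stay
    at their EM estimates.  Positional-variance matrices are assembled from
    the retained (post burn-in) samples.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    es = model.event_set
    ev = _Evaluator(Z, es, model.sigma)
    C, N = model.n_subtypes, es.n_events
    seqs = [np.array(s) for s in model.sequences]
    logm = np.column_stack([ev.log_marginal(s) for s in seqs])
    logf = np.log(model.fractions)
    total = float(logsumexp(logm + logf, axis=1).sum())

    burn = int(burn_frac * n_iter)
    kept: list[list[np.ndarray]] = [[] for _ in range(C)]
    kept_ll: list[float] = []
    accepted = 0
    for it in range(n_iter):
        c = int(rng.integers(C))
        e = int(rng.integers(N))
        cur = int(np.nonzero(seqs[c] == e)[0][0])
        rest = np.delete(seqs[c], cur)
        pos = valid_positions(rest, e, es)
        p = int(pos[rng.integers(pos.size)])
        cand = np.insert(rest, p, e)
        new_col = ev.log_marginal(cand)
        logm_new = logm.copy()
        logm_new[:, c] = new_col
        total_new = float(logsumexp(logm_new + logf, axis=1).sum())
        if math.log(rng.random()) < total_new - total:
            seqs[c], logm, total = cand, logm_new, total_new
            accepted += 1
        if it >= burn:
            for cc in range(C):
                kept[cc].append(seqs[cc].copy())
            kept_ll.append(total)

    pv = []
    for cc in range(C):
        m = np.zeros((N, N))
        for s in kept[cc]:
            m[s, np.arange(N)] += 1.0
        m /= len(kept[cc])
        pv.append(m)
    return McmcSamples(
        sequences=kept,
        log_likelihoods=np.asarray(kept_ll),
        positional_variance=pv,
        acceptance_rate=accepted / n_iter,
    )


# -- cross-validated model selection --------------------------------------

def cross_validate(
    Z: np.ndarray,
    c_values: list[int],
    k_folds: int,
    es: EventSet,
    config: RunConfig | None = None,
    seed: int = 0,
    sigma: np.ndarray | None = None,
) -> CvResult:
    """k-fold cross-validation of the subtype count.

    Subjects are partitioned into seeded random folds; for each fold the
    hierarchy of models is fitted on the training portion and the held-out
    log-likelihood of the test portion is computed (fractions from training).
    CVIC(C) = -2 x summed held-out log-likelihood.  The curve is reported;
    no automatic selection is applied.
    """
    config = config or RunConfig()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    c_values = sorted(c_values)
    c_max = c_values[-1]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k_folds)):
        fold_of[idx] = f
    fold_ll = np.zeros((k_folds, len(c_values)))
    for f in range(k_folds):
        train, test = fold_of != f, fold_of == f
        if train.sum() < c_max:
            raise ValueError(f"training fold {f} has fewer than {c_max} subjects")
        models = hierarchical_fit(
            Z[train], c_max, es, config, np.random.default_rng(rng.integers(2**31)),
            sigma=sigma,
        )
        for jc, C in enumerate(c_values):
            _, total = subject_log_likelihood(Z[test], models[C - 1])
            fold_ll[f, jc] = float(total.sum())
    cvic = -2.0 * fold_ll.sum(axis=0)
    return CvResult(
        c_values=list(c_values),
        fold_loglik=fold_ll,
        cvic=cvic,
        fold_of_subject=fold_of,
        seed=seed,
    )
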