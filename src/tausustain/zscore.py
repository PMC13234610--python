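"""Control-referenced z-scoring and GMM-based event-threshold derivation.

Raw regional values are standardized against the control group's baseline
mean and SD per region.  Per region, a 2-component univariate Gaussian
mixture fitted across pooled control + patient baseline z-scores separates a
"normal" from an "abnormal" component; two severity thresholds and a
trajectory ceiling are derived from the fit, defining that region's events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .cohort import CohortTable, CohortError
from .events import EventSet, build_event_set

__all__ = [
    "ZScoreModel",
    "GMMFit",
    "fit_zscore_reference",
    "apply_zscore",
    "fit_2gmm",
    "derive_thresholds",
    "prepare_inputs",
    "FIXED_POLICY_THRESHOLDS",
]

#: Fixed-threshold preset (z = 2 and 5, ceiling 10), after Vogel et al.
FIXED_POLICY_THRESHOLDS = ((2.0, 5.0), 10.0)


@dataclass
class ZScoreModel:
    """Per-region control baseline mean/SD reference (SD uses n-1)."""

    regions: tuple[str, ...]
    mean: np.ndarray  # value units
    sd: np.ndarray  # value units, > 0
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
            "n_controls": int(self.n_controls),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreModel":
        return cls(
            regions=tuple(d["regions"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            n_controls=int(d["n_controls"]),
        )


@dataclass
class GMMFit:
    """Univariate 2-component Gaussian mixture, components ordered m1 < m2."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    log_likelihood: float
    ll_trace: list[float]


def fit_zscore_reference(table: CohortTable) -> ZScoreModel:
    """Fit the per-region control reference on control baseline scans only."""
    ctrl = table.control_baseline()
    if len(ctrl) < 2:
        raise CohortError(
            f"need at least 2 control baseline scans for z-scoring, got {len(ctrl)}"
        )
    vals = ctrl[list(table.regions)].to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if not s > 0:
            raise CohortError(f"zero variance in control values for region {table.regions[j]!r}")
    return ZScoreModel(regions=table.regions, mean=mean, sd=sd, n_controls=len(ctrl))


def apply_zscore(table: CohortTable, ref: ZScoreModel, mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize every scan: z = (value - mu_i) / s_i, columns = regions."""
    if tuple(table.regions) != tuple(ref.regions):
        raise CohortError(
            f"region mismatch: table has {table.regions}, reference has {ref.regions}"
        )
    return (table.values(mask) - ref.mean) / ref.sd


def fit_2gmm(values: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> GMMFit:
    """Maximum-likelihood univariate 2-component Gaussian mixture via EM.

    Initialization is deterministic: the sample is split at its median and
    the lower/upper halves seed the two components.  Components are relabeled
    so m1 < m2.  Degenerate data (no spread in a half) yields a flagged,
    non-converged fit rather than an exception.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need >= 10 values to fit a 2-component mixture, got {x.size}")
    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    if upper.size == 0:  # all values at/below the median (e.g. constant data)
        lower, upper = x, x
    var_floor = max(1e-6 * float(np.var(x)), 1e-12)
    m = np.array([lower.mean(), upper.mean()])
    s = np.sqrt(np.maximum([lower.var(), upper.var()], var_floor))
    w = np.array([0.5, 0.5])

    from scipy.special import logsumexp

    ll_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_r = np.stack(
            [np.log(w[c]) + stats.norm.logpdf(x, m[c], s[c]) for c in range(2)]
        )  # (2, n)
        ll = float(logsumexp(log_r, axis=0).sum())
        if ll_trace:
            # EM monotonicity is a model invariant; tolerate only rounding
            assert ll >= ll_trace[-1] - 1e-8 * max(1.0, abs(ll_trace[-1])), (
                "mixture EM log-likelihood decreased"
            )
            if abs(ll - ll_trace[-1]) <= tol * max(1.0, abs(ll_trace[-1])):
                ll_trace.append(ll)
                converged = True
                break
        ll_trace.append(ll)
        r = np.exp(log_r - logsumexp(log_r, axis=0))  # responsibilities
        nk = r.sum(axis=1)
        if np.any(nk < 1e-10):
            break  # component collapsed; flagged below
        w = nk / x.size
        m = (r * x).sum(axis=1) / nk
        s = np.sqrt(np.maximum((r * (x - m[:, None]) ** 2).sum(axis=1) / nk, var_floor))
    order = np.argsort(m)
    m, s, w = m[order], s[order], w[order]
    if np.ptp(x) == 0 or not np.isfinite(ll_trace[-1] if ll_trace else np.nan):
        converged = False
    return GMMFit(
        means=(float(m[0]), float(m[1])),
        sds=(float(s[0]), float(s[1])),
        weights=(float(w[0]), float(w[1])),
        converged=converged,
        log_likelihood=float(ll_trace[-1]) if ll_trace else float("nan"),
        ll_trace=ll_trace,
    )


def derive_thresholds(
    fit: GMMFit,
    policy: str = "gmm",
    z1_floor: float = 1.0,
) -> tuple[float, float, float]:
    """Map a 2-GMM fit to (z1, z2, z_max) for one region.

    Default ("gmm") policy: z1 is the equal-posterior decision boundary
    between the two components (smallest z where the abnormal component's
    posterior reaches 0.5), floored at ``z1_floor``; z2 is the abnormal
    component's mean; z_max is that mean + 2 SD.  The returned triple is
    repaired to be strictly ascending if the pieces collide.

    The "fixed" policy ignores the fit and returns z = (2, 5), ceiling 10.
    """
    if policy == "fixed":
        (z1, z2), zmax = FIXED_POLICY_THRESHOLDS
        return z1, z2, zmax
    if policy != "gmm":
        raise ValueError(f"unknown threshold policy {policy!r}")
    m1, m2 = fit.means
    sd1, sd2 = fit.sds
    w1, w2 = fit.weights

    def diff(z: float) -> float:
        # posterior(comp2) - posterior(comp1), up to the positive denominator
        return (np.log(w2) + stats.norm.logpdf(z, m2, sd2)) - (
            np.log(w1) + stats.norm.logpdf(z, m1, sd1)
        )

    if diff(m1) < 0 and diff(m2) > 0:
        boundary = float(optimize.brentq(diff, m1, m2, xtol=1e-12))
    else:
        boundary = 0.5 * (m1 + m2)
        warnings.warn(
            "2-GMM components overlap too much to bracket an equal-posterior "
            f"boundary in ({m1:.3g}, {m2:.3g}); using their midpoint",
            stacklevel=2,
        )
    z1 = max(boundary, z1_floor)
    z2 = m2
    if z2 <= z1:  # heavy overlap after flooring: keep strict ascent
        warnings.warn(
            f"abnormal-component mean {z2:.3g} <= first threshold {z1:.3g}; "
            "repairing to keep thresholds strictly ascending",
            stacklevel=2,
        )
        z2 = z1 + 0.5
    z_max = m2 + 2.0 * sd2
    if z_max <= z2:
        z_max = z2 + 0.5
    return float(z1), float(z2), float(z_max)


def prepare_inputs(
    table: CohortTable,
    policy: str = "gmm",
    z1_floor: float = 1.0,
):
    """Full input preparation: reference fit, z-scoring, thresholds, events.

    Returns ``(zscore_model, event_set, Z_patient_baseline, gmm_fits)``.
    The mixtures are fitted per region on pooled control + patient baseline
    z-scores; only patient scans enter downstream model fitting.
    """
    ref = fit_zscore_reference(table)
    base = table.baseline_mask()
    z_all_baseline = apply_zscore(table, ref, mask=base)
    z_patients = apply_zscore(table, ref, mask=base & table.group_mask("patient"))
    fits: list[GMMFit | None] = []
    thresholds: list[tuple[float, float]] = []
    z_maxes: list[float] = []
    for j, region in enumerate(table.regions):
        if policy == "fixed":
            fits.append(None)
            (z1, z2), zmax = FIXED_POLICY_THRESHOLDS
        else:
            fit = fit_2gmm(z_all_baseline[:, j])
            fits.append(fit)
            z1, z2, zmax = derive_thresholds(fit, policy=policy, z1_floor=z1_floor)
        thresholds.append((z1, z2))
        z_maxes.append(zmax)
    es = build_event_set(table.regions, thresholds, z_maxes)
    return ref, es, z_patients, fits
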