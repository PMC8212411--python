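"""Per-cell-type composition shift test: BCa bootstrap for two independent samples.

For each annotated type the membership indicator of every unpruned cell is
the resampling unit; the two conditions are resampled independently with
replacement (the two-independent-samples construction). The statistic is

    theta = p_high - p_low,

the difference in the type's proportion between conditions. Bias correction
``z0`` comes from the fraction of bootstrap replicates below the observed
statistic (half-counting ties, which occur often for discrete proportions);
acceleration ``a`` from the standard jackknife skewness formula over pooled
delete-one deviations. The one-sided p-value inverts the BCa confidence
bound: it is the smallest alpha at which the one-sided BCa interval excludes
zero, found by bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .datatypes import ConfigurationError, EmptyResultError, InsufficientCellsError

logger = logging.getLogger(__name__)

_BISECT_TOL = 1e-4


@dataclass
class ProportionTestResult:
    """All reported quantities for one cell type's composition-shift test."""

    cell_type: str
    n_low: int
    n_high: int
    p_low: float
    p_high: float
    diff: float
    B: int
    z0: float
    a: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str
    degenerate: bool = False
    theta_star: np.ndarray | None = None  # sorted bootstrap draws, on request


def celltype_proportions(ann: pd.DataFrame) -> pd.DataFrame:
    """Per-condition cell-type proportions over unpruned cells.

    Returns a type x condition DataFrame whose columns each sum to 1.
    """
    kept = ann[~ann["pruned"].astype(bool)]
    conditions = list(dict.fromkeys(ann["condition"]))
    for cond in conditions:
        if (kept["condition"] == cond).sum() == 0:
            raise EmptyResultError(f"condition {cond!r} has zero unpruned cells")
    table = (
        kept.groupby(["best_type", "condition"], sort=True)
        .size()
        .unstack("condition", fill_value=0)
        .reindex(columns=conditions)
    )
    return table / table.sum(axis=0)


def _bca_quantile(theta_sorted: np.ndarray, z0: float, a: float, z: float) -> float:
    """BCa-adjusted percentile of the sorted bootstrap distribution."""
    zt = z0 + z
    denom = 1.0 - a * zt
    if denom <= 0:
        beta = 1.0 if a > 0 else 0.0
    else:
        beta = float(ndtr(z0 + zt / denom))
    beta = min(max(beta, 0.0), 1.0)
    return float(np.quantile(theta_sorted, beta))


def bca_test(
    x_low,
    x_high,
    B: int = 10_000,
    alpha: float = 0.05,
    direction: str = "greater",
    seed: int | None = None,
    cell_type: str = "",
    force_z0: float | None = None,
    force_a: float | None = None,
    keep_bootstrap: bool = False,
) -> ProportionTestResult:
    """BCa bootstrap test of ``mean(x_high) - mean(x_low)`` for two samples.

    Parameters
    ----------
    x_low, x_high
        Membership indicator vectors (0/1) of the cells in each condition.
        General real-valued vectors are also accepted.
    B
        Bootstrap replicates (>= 1000).
    alpha
        Two-sided level for the reported BCa interval.
    direction
        ``"greater"`` tests enrichment in the high condition, ``"less"``
        depletion.
    seed
        Seed for the bootstrap resampling; required for reproducibility.
    force_z0, force_a
        Override the bias-correction / acceleration (used by the
        percentile-bootstrap equivalence check; ``0`` for both reduces BCa
        to the plain percentile interval).
    """
    x_low = np.asarray(x_low, dtype=np.float64)
    x_high = np.asarray(x_high, dtype=np.float64)
    if x_low.size == 0 or x_high.size == 0:
        raise InsufficientCellsError("both condition samples must be non-empty")
    if B < 1000:
        raise ConfigurationError(f"B must be >= 1000, got {B}")
    if direction not in ("greater", "less"):
        raise ConfigurationError(f"direction must be 'greater' or 'less', got {direction!r}")

    rng = np.random.default_rng(seed)
    n_low, n_high = x_low.size, x_high.size
    p_low, p_high = float(x_low.mean()), float(x_high.mean())
    theta_hat = p_high - p_low

    # Bootstrap distribution of theta*. For binary membership vectors the
    # mean of an n-out-of-n with-replacement resample is exactly
    # Binomial(n, p_hat)/n, so the replicate means are drawn directly.
    def _boot_means(x: np.ndarray, n: int) -> np.ndarray:
        vals = np.unique(x)
        if vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all():
            return rng.binomial(n, x.mean(), size=B) / n
        idx = rng.integers(0, n, size=(B, n))
        return x[idx].mean(axis=1)

    theta_star = _boot_means(x_high, n_high) - _boot_means(x_low, n_low)
    theta_sorted = np.sort(theta_star)

    degenerate = bool(theta_sorted[0] == theta_sorted[-1])

    # bias correction with half-count tie convention
    frac_below = (np.count_nonzero(theta_star < theta_hat)
                  + 0.5 * np.count_nonzero(theta_star == theta_hat)) / B
    frac_below = min(max(frac_below, 0.5 / B), 1 - 0.5 / B)
    z0 = float(ndtri(frac_below)) if force_z0 is None else float(force_z0)

    # acceleration from pooled delete-one jackknife deviations
    if force_a is None:
        jack_low = p_high - (x_low.sum() - x_low) / (n_low - 1) if n_low > 1 else np.array([theta_hat])
        jack_high = (x_high.sum() - x_high) / (n_high - 1) - p_low if n_high > 1 else np.array([theta_hat])
        jack = np.concatenate([jack_low, jack_high])
        d = jack.mean() - jack
        s2, s3 = float((d**2).sum()), float((d**3).sum())
        a = s3 / (6.0 * s2**1.5) if s2 > 0 else 0.0
    else:
        a = float(force_a)

    ci_low = _bca_quantile(theta_sorted, z0, a, float(ndtri(alpha / 2)))
    ci_high = _bca_quantile(theta_sorted, z0, a, float(ndtri(1 - alpha / 2)))

    if degenerate:
        v = float(theta_sorted[0])
        wrong_sign = (direction == "greater" and theta_hat <= 0) or (
            direction == "less" and theta_hat >= 0
        )
        p_value = 1.0 if wrong_sign else 1.0 / B
        logger.warning(
            "degenerate bootstrap for %s: all replicates equal %.6g", cell_type or "sample", v
        )
    else:
        def excludes_zero(alpha1: float) -> bool:
            if direction == "greater":
                bound = _bca_quantile(theta_sorted, z0, a, float(ndtri(alpha1)))
                return bound > 0
            bound = _bca_quantile(theta_sorted, z0, a, float(ndtri(1 - alpha1)))
            return bound < 0

        lo, hi = 1.0 / B, 0.5
        if not excludes_zero(hi):
            p_value = 1.0
        elif excludes_zero(lo):
            p_value = lo
        else:
            while hi - lo > _BISECT_TOL:
                mid = 0.5 * (lo + hi)
                if excludes_zero(mid):
                    hi = mid
                else:
                    lo = mid
            p_value = hi

    return ProportionTestResult(
        cell_type=cell_type,
        n_low=n_low,
        n_high=n_high,
        p_low=p_low,
        p_high=p_high,
        diff=theta_hat,
        B=B,
        z0=z0,
        a=a,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p_value),
        direction=direction,
        degenerate=degenerate,
        theta_star=theta_sorted if keep_bootstrap else None,
    )


def run_proportion_tests(
    ann: pd.DataFrame,
    B: int = 10_000,
    alpha: float = 0.05,
    direction: str = "auto",
    seed: int = 0,
    conditions: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """BCa test for every annotated type; one row per type.

    ``direction="auto"`` tests enrichment (``greater``) for types whose
    observed proportion is higher in the high condition and depletion
    (``less``) otherwise; the direction used is recorded in the output.
    Types are tested marginally (no cross-type multiplicity correction).
    """
    low, high = conditions
    kept = ann[~ann["pruned"].astype(bool)]
    lab_low = kept.loc[kept["condition"] == low, "best_type"].to_numpy()
    lab_high = kept.loc[kept["condition"] == high, "best_type"].to_numpy()
    if lab_low.size == 0 or lab_high.size == 0:
        raise EmptyResultError("need unpruned cells in both conditions")

    types = sorted(set(lab_low) | set(lab_high))
    rows = []
    for i, t in enumerate(types):
        x_low = (lab_low == t).astype(float)
        x_high = (lab_high == t).astype(float)
        if direction == "auto":
            dir_t = "greater" if x_high.mean() >= x_low.mean() else "less"
        else:
            dir_t = direction
        sub_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        res = bca_test(
            x_low, x_high, B=B, alpha=alpha, direction=dir_t,
            seed=sub_seed, cell_type=t,
        )
        rows.append({k: v for k, v in res.__dict__.items() if k != "theta_star"})
    return pd.DataFrame(rows)
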