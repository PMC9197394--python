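"""Ridge regression of unit responses against latent factors.

Under both the network-dynamics and muscle-encoding views, a unit's response
is modeled as a weighted sum of population factors, r_i(t) = sum_j w_ij
x_j(t).  The two views are compared by regressing each unit against factors
derived (by PCA) from the network's own activity versus from muscle
activity, summarizing fit quality with the population R^2 — residual and
total sums of squares pooled across units, so a poorly fit low-variance unit
has proportionally little impact — and testing the per-speed difference
with a paired one-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge

from .datatypes import FactorProjection, PopulationRates
from .geometry import resample_trajectory
from .preprocess import pca

__all__ = [
    "FactorFit",
    "ridge_fit",
    "population_r2",
    "ModelComparison",
    "compare_factor_models",
    "choose_lambda",
]


@dataclass
class FactorFit:
    weights: np.ndarray  # unit × factor
    intercepts: np.ndarray
    per_unit_r2: np.ndarray
    rss: np.ndarray  # per unit
    tss: np.ndarray  # per unit
    lam: float
    n_factors: int
    factor_source: str = ""

    @property
    def population_r2(self) -> float:
        return population_r2(self)


def _pool(obj) -> np.ndarray:
    if isinstance(obj, (PopulationRates, FactorProjection)):
        return obj.pooled()
    return np.asarray(obj, dtype=float)


def ridge_fit(rates, factors, lam: float = 0.0, factor_source: str = "") -> FactorFit:
    """Per-unit ridge regression of rates on factors (intercept unpenalized).

    ``rates``: (units × T) or :class:`PopulationRates`; ``factors``:
    (k × T) or :class:`FactorProjection` on a matched time base.
    """
    y = _pool(rates)
    x = _pool(factors)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if y.shape[1] != x.shape[1]:
        raise ValueError(
            f"time bases differ: rates T={y.shape[1]}, factors T={x.shape[1]}"
        )
    xc = x - x.mean(axis=1, keepdims=True)
    if lam == 0 and np.linalg.matrix_rank(xc) < x.shape[0]:
        raise ValueError("factor matrix is rank-deficient; use lambda > 0")
    model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    model.fit(x.T, y.T)
    pred = model.predict(x.T).T
    rss = np.sum((y - pred) ** 2, axis=1)
    tss = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_unit = np.where(tss > 0, 1.0 - rss / tss, np.nan)
    return FactorFit(
        weights=model.coef_,
        intercepts=model.intercept_,
        per_unit_r2=per_unit,
        rss=rss,
        tss=tss,
        lam=lam,
        n_factors=x.shape[0],
        factor_source=factor_source,
    )


def population_r2(fit: FactorFit) -> float:
    """Variance-weighted mean R^2 across units: 1 - sum(RSS) / sum(TSS)."""
    total = fit.tss.sum()
    if total == 0:
        raise ValueError("zero total variance across units")
    return float(1.0 - fit.rss.sum() / total)


def choose_lambda(
    rates_per_speed: list[np.ndarray],
    factors_per_speed: list[np.ndarray],
    grid: np.ndarray | None = None,
) -> float:
    """Leave-one-speed-out cross-validation of the ridge penalty."""
    if grid is None:
        grid = np.logspace(-4, 2, 13)
    n = len(rates_per_speed)
    best, best_err = grid[0], np.inf
    for lam in grid:
        err = 0.0
        for hold in range(n):
            xtr = np.concatenate(
                [f for i, f in enumerate(factors_per_speed) if i != hold], axis=1
            )
            ytr = np.concatenate(
                [r for i, r in enumerate(rates_per_speed) if i != hold], axis=1
            )
            fit = ridge_fit(ytr, xtr, lam=max(lam, 1e-12))
            xte = factors_per_speed[hold]
            pred = fit.weights @ xte + fit.intercepts[:, None]
            err += np.sum((rates_per_speed[hold] - pred) ** 2)
        if err < best_err:
            best, best_err = lam, err
    return float(best)


@dataclass
class ModelComparison:
    r2_network: np.ndarray  # per speed
    r2_muscle: np.ndarray
    delta_r2: float
    t_statistic: float
    p_value: float
    n_pcs: int
    lam: float
    generalization_r2: tuple[float, float] | None = None  # (network, muscle)


def _factors_matched(source: PopulationRates, rates: PopulationRates, n_pcs: int):
    """Global PCA factors of a source population, resampled per speed to the
    rate population's cycle lengths."""
    proj = pca(source, scope="global", n_components=n_pcs)
    return [
        resample_trajectory(p, v.shape[1])
        for p, v in zip(proj.projected, rates.values)
    ]


def compare_factor_models(
    rates: PopulationRates,
    network_source: PopulationRates,
    muscle_source: PopulationRates,
    n_pcs: int = 3,
    lam: float | str = "auto",
    generalization: bool = False,
) -> ModelComparison:
    """Do network factors explain unit responses better than muscle factors?

    Factors are the top ``n_pcs`` global PCs of each source population,
    resampled per speed onto the rate population's time base.  Both factor
    sets are fit per speed; the per-speed difference in population R^2 is
    tested with a paired one-tailed t-test (network > muscle).
    """
    if rates.n_speeds < 3:
        raise ValueError("paired test needs at least 3 speeds")
    net_f = _factors_matched(network_source, rates, n_pcs)
    mus_f = _factors_matched(muscle_source, rates, n_pcs)
    if lam == "auto":
        lam_val = choose_lambda(rates.values, net_f)
    else:
        lam_val = float(lam)
    r2n, r2m = [], []
    for s in range(rates.n_speeds):
        fn = ridge_fit(rates.values[s], net_f[s], lam=lam_val, factor_source="network")
        fm = ridge_fit(rates.values[s], mus_f[s], lam=lam_val, factor_source="muscle")
        r2n.append(population_r2(fn))
        r2m.append(population_r2(fm))
    r2n, r2m = np.array(r2n), np.array(r2m)
    diffs = r2n - r2m
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 0.5
    else:
        t_stat, p = stats.ttest_rel(r2n, r2m, alternative="greater")
    gen = None
    if generalization:
        gen = (
            _loo_generalization(rates, net_f, lam_val),
            _loo_generalization(rates, mus_f, lam_val),
        )
    return ModelComparison(
        r2_network=r2n,
        r2_muscle=r2m,
        delta_r2=float(diffs.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_pcs=n_pcs,
        lam=lam_val,
        generalization_r2=gen,
    )


def _loo_generalization(
    rates: PopulationRates, factors: list[np.ndarray], lam: float
) -> float:
    """Population R^2 on held-out speeds, leave-one-speed-out."""
    rss_total, tss_total = 0.0, 0.0
    n = rates.n_speeds
    for hold in range(n):
        xtr = np.concatenate([f for i, f in enumerate(factors) if i != hold], axis=1)
        ytr = np.concatenate(
            [v for i, v in enumerate(rates.values) if i != hold], axis=1
        )
        fit = ridge_fit(ytr, xtr, lam=max(lam, 1e-12))
        pred = fit.weights @ factors[hold] + fit.intercepts[:, None]
        y = rates.values[hold]
        rss_total += np.sum((y - pred) ** 2)
        tss_total += np.sum((y - y.mean(axis=1, keepdims=True)) ** 2)
    return float(1.0 - rss_total / tss_total)
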