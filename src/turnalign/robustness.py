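"""Robustness procedures for the progressive (interaction) effect.

Covers the standard battery for clustered longitudinal designs: a pairs
cluster bootstrap with a BCa interval for b3, OLS with conversation-
clustered sandwich standard errors, re-running the full pipeline under
multiple between-sampling seeds, and analysis-window sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FIXED_EFFECTS, DissociationModel, DissociationResults, _design_matrix

_BETA3 = FIXED_EFFECTS.index("is_within:centered_turn")


def _cluster_blocks(table: pd.DataFrame, similarity_col: str):
    """Per-conversation (X'X, X'y) blocks for fast cluster-resampled OLS."""
    x = _design_matrix(table)
    y = table[similarity_col].to_numpy(dtype=float)
    codes, _ = pd.factorize(table["conversation_id"], sort=False)
    n_clusters = codes.max() + 1
    k = x.shape[1]
    xtx = np.zeros((n_clusters, k, k))
    xty = np.zeros((n_clusters, k))
    for c in range(n_clusters):
        mask = codes == c
        xc = x[mask]
        yc = y[mask]
        xtx[c] = xc.T @ xc
        xty[c] = xc.T @ yc
    return xtx, xty


def _ols_beta(xtx_sum: np.ndarray, xty_sum: np.ndarray) -> np.ndarray:
    return np.linalg.solve(xtx_sum, xty_sum)


@dataclass(frozen=True)
class BootstrapInterval:
    lower: float
    upper: float
    estimate: float
    n_boot: int
    n_failed: int
    z0: float
    acceleration: float
    level: float = 0.95


def pairs_cluster_bootstrap(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    similarity_col: str = "similarity",
    level: float = 0.95,
    refit: str = "ols",
) -> BootstrapInterval:
    """BCa confidence interval for b3 from a pairs cluster bootstrap.

    Conversations (clusters) are resampled with replacement and the fixed-
    effect design refitted on each resample.  The default refit is the OLS
    fixed-effects estimator: with the cluster structure carried by the
    resampling itself, the OLS point estimate is the appropriate fast
    surrogate for the mixed-model fixed effects (their point estimates
    coincide up to GLS weighting).  ``refit="mixed"`` refits the full REML
    model on every resample instead.

    Bias correction z0 comes from the bootstrap distribution's position
    relative to the point estimate; acceleration comes from a leave-one-
    conversation-out jackknife.
    """
    if table["conversation_id"].nunique() < 10:
        raise ValueError("cluster bootstrap needs >= 10 conversations")
    rng = np.random.default_rng(seed)

    if refit == "mixed":
        point = DissociationModel(table, similarity_col).fit().beta3
        clusters = table["conversation_id"].unique()
        groups = {c: g for c, g in table.groupby("conversation_id", sort=False)}
        thetas = []
        n_failed = 0
        for _ in range(n_boot):
            picks = rng.choice(clusters, size=len(clusters), replace=True)
            parts = []
            for j, c in enumerate(picks):
                g = groups[c].copy()
                g["conversation_id"] = f"b{j}"
                parts.append(g)
            boot = pd.concat(parts, ignore_index=True)
            try:
                thetas.append(DissociationModel(boot, similarity_col).fit().beta3)
            except Exception:
                n_failed += 1
        thetas_arr = np.asarray(thetas)
        # jackknife still uses the fast OLS path (acceleration only)
        xtx, xty = _cluster_blocks(table, similarity_col)
    elif refit == "ols":
        xtx, xty = _cluster_blocks(table, similarity_col)
        n_clusters = len(xtx)
        point = float(_ols_beta(xtx.sum(axis=0), xty.sum(axis=0))[_BETA3])
        thetas = []
        n_failed = 0
        for _ in range(n_boot):
            counts = np.bincount(
                rng.integers(n_clusters, size=n_clusters), minlength=n_clusters
            ).astype(float)
            xtx_b = np.tensordot(counts, xtx, axes=1)
            xty_b = counts @ xty
            try:
                thetas.append(float(_ols_beta(xtx_b, xty_b)[_BETA3]))
            except np.linalg.LinAlgError:
                n_failed += 1
        thetas_arr = np.asarray(thetas)
    else:
        raise ValueError(f"unknown refit {refit!r}")

    if thetas_arr.size == 0:
        raise RuntimeError("all bootstrap refits failed")

    # BCa: bias correction + jackknife acceleration over conversations
    prop = np.clip((thetas_arr < point).mean(), 1.0 / (2 * thetas_arr.size), 1 - 1.0 / (2 * thetas_arr.size))
    z0 = float(stats.norm.ppf(prop))
    xtx_total = xtx.sum(axis=0)
    xty_total = xty.sum(axis=0)
    jack = np.array(
        [
            _ols_beta(xtx_total - xtx[c], xty_total - xty[c])[_BETA3]
            for c in range(len(xtx))
        ]
    )
    diffs = jack.mean() - jack
    denom = (diffs**2).sum() ** 1.5
    accel = float((diffs**3).sum() / (6 * denom)) if denom > 0 else 0.0

    alpha = (1 - level) / 2
    lo_p, hi_p = (
        stats.norm.cdf(z0 + (z0 + stats.norm.ppf(q)) / (1 - accel * (z0 + stats.norm.ppf(q))))
        for q in (alpha, 1 - alpha)
    )
    lower, upper = np.quantile(thetas_arr, [lo_p, hi_p])
    return BootstrapInterval(
        lower=float(lower),
        upper=float(upper),
        estimate=float(point),
        n_boot=int(thetas_arr.size),
        n_failed=int(n_failed),
        z0=z0,
        acceleration=accel,
        level=level,
    )


def cluster_robust_ols(table: pd.DataFrame, similarity_col: str = "similarity") -> pd.DataFrame:
    """OLS on the fixed-effect design with conversation-clustered SEs.

    Point estimates equal plain OLS; only the covariance differs.  Returns a
    coefficient table with columns coef/se/t/p.
    """
    import statsmodels.api as sm

    if table["conversation_id"].nunique() < 2:
        raise ValueError("cluster-robust SEs need >= 2 clusters")
    x = _design_matrix(table)
    y = table[similarity_col].to_numpy(dtype=float)
    res = sm.OLS(y, x).fit(
        cov_type="cluster", cov_kwds={"groups": table["conversation_id"].to_numpy()}
    )
    return pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=list(FIXED_EFFECTS),
    )


@dataclass(frozen=True)
class MultiSeedSummary:
    fits: list[DissociationResults]
    beta3_min: float
    beta3_max: float
    beta3_mean: float
    n_significant: int
    alpha: float = 0.05


def multi_seed_run(
    convs,
    direction,
    seeds: Sequence[int],
    window: tuple[int, int] = (1, 10),
    indicator: str = "cosine_fw",
    alpha: float = 0.05,
    **kwargs,
) -> MultiSeedSummary:
    """Re-run the full pipeline once per seed, varying only the between-
    conversation draws, and summarize the spread of b3."""
    if len(seeds) < 2:
        raise ValueError("need >= 2 seeds")
    fits = [
        DissociationModel.from_conversations(
            convs, direction, window=window, indicator=indicator, seed=s, **kwargs
        ).fit()
        for s in seeds
    ]
    beta3s = np.array([f.beta3 for f in fits])
    pvals = np.array([f.pvalues["is_within:centered_turn"] for f in fits])
    return MultiSeedSummary(
        fits=fits,
        beta3_min=float(beta3s.min()),
        beta3_max=float(beta3s.max()),
        beta3_mean=float(beta3s.mean()),
        n_significant=int((pvals < alpha).sum()),
        alpha=alpha,
    )


def window_sensitivity(
    convs,
    direction,
    windows: Sequence[tuple[int, int]],
    indicator: str = "cosine_fw",
    seed: int = 42,
    **kwargs,
) -> dict[tuple[int, int], DissociationResults]:
    """Refit the dissociation model over each analysis window."""
    out: dict[tuple[int, int], DissociationResults] = {}
    for window in windows:
        out[tuple(window)] = DissociationModel.from_conversations(
            convs, direction, window=tuple(window), indicator=indicator, seed=seed, **kwargs
        ).fit()
    return out
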