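"""The multilevel within-versus-between dissociation model.

The model for similarity observation i in conversation j is

    S_ij = b0 + b1*IsWithin_ij + b2*Turn_ij + b3*IsWithin_ij*Turn_ij
           + u_0j + e_ij,     u_0j ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

with Turn centered at the sample mean.  b1 is the *static* effect (mean
within-minus-between gap), b2 the between-baseline trajectory, and b3 the
*progressive* effect (change in the gap per turn).  Estimation is REML via
``statsmodels`` MixedLM with a random intercept per conversation; p-values
are Wald z-tests on the fixed effects.

Organized in the statsmodels idiom: :class:`DissociationModel` is built from
an observation table (or directly from conversations) and ``fit()`` returns
a :class:`DissociationResults` carrying estimates, uncertainties, variance
components and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FIXED_EFFECTS = ("intercept", "is_within", "centered_turn", "is_within:centered_turn")

#: Optimizer fallback chain; ends in derivative-free methods so a fit always
#: produces a (possibly flagged) result rather than an exception.
OPTIMIZERS = ("lbfgs", "powell", "nm")


class FitError(RuntimeError):
    """Model could not be estimated at all."""


def compute_icc(sigma_u2: float, sigma_e2: float) -> float:
    """Intraclass correlation sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
    if sigma_u2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be nonnegative")
    total = sigma_u2 + sigma_e2
    if total == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return sigma_u2 / total


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    x = np.empty((len(table), 4))
    x[:, 0] = 1.0
    x[:, 1] = table["is_within"].to_numpy(dtype=float)
    x[:, 2] = table["centered_turn"].to_numpy(dtype=float)
    x[:, 3] = x[:, 1] * x[:, 2]
    return x


@dataclass
class DissociationResults:
    """REML estimates of the dissociation model for one direction/indicator."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma_u2: float
    sigma_e2: float
    n_obs: int
    n_conversations: int
    converged: bool
    method: str
    direction: str | None = None
    indicator: str | None = None
    random_effects: dict = field(default_factory=dict, repr=False)

    @property
    def icc(self) -> float:
        return compute_icc(self.sigma_u2, self.sigma_e2)

    @property
    def beta0(self) -> float:
        return float(self.params["intercept"])

    @property
    def beta1(self) -> float:
        return float(self.params["is_within"])

    @property
    def beta2(self) -> float:
        return float(self.params["centered_turn"])

    @property
    def beta3(self) -> float:
        return float(self.params["is_within:centered_turn"])

    def summary(self) -> pd.DataFrame:
        """Coefficient table plus variance components, one row per term."""
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        rows.attrs.update(
            sigma_u2=self.sigma_u2,
            sigma_e2=self.sigma_e2,
            icc=self.icc,
            n_obs=self.n_obs,
            n_conversations=self.n_conversations,
            converged=self.converged,
            direction=self.direction,
            indicator=self.indicator,
        )
        return rows

    def to_row(self) -> dict:
        """Flat record for results CSVs (one model per row)."""
        rec = {
            "direction": self.direction,
            "indicator": self.indicator,
            "n_obs": self.n_obs,
            "n_conversations": self.n_conversations,
            "converged": self.converged,
        }
        for name, short in zip(FIXED_EFFECTS, ("beta0", "beta1", "beta2", "beta3")):
            rec[short] = float(self.params[name])
            rec[f"se_{short}"] = float(self.bse[name])
            rec[f"p_{short}"] = float(self.pvalues[name])
        rec.update(sigma_u2=self.sigma_u2, sigma_e2=self.sigma_e2, icc=self.icc)
        return rec


class DissociationModel:
    """Mixed-effects within-versus-between model bound to an observation table.

    Parameters
    ----------
    table:
        Paired observation table with columns ``similarity``, ``is_within``,
        ``centered_turn`` and ``conversation_id`` (as produced by
        ``design.build_observation_table``).
    """

    def __init__(self, table: pd.DataFrame, similarity_col: str = "similarity"):
        if table[similarity_col].isna().any():
            raise ValueError("observation table contains NaN similarities")
        groups = table["conversation_id"]
        if groups.nunique() < 2:
            raise ValueError("need >= 2 conversations to fit a random intercept")
        if table["is_within"].nunique() < 2:
            raise ValueError("both within and between rows are required")
        self.table = table
        self.similarity_col = similarity_col
        self.direction = table["direction"].iloc[0] if "direction" in table else None
        self.indicator = (
            table["indicator"].iloc[0]
            if "indicator" in table
            else similarity_col.removeprefix("sim_") if similarity_col != "similarity" else None
        )

    @classmethod
    def from_conversations(
        cls,
        convs,
        direction,
        window: tuple[int, int] = (1, 10),
        indicator: str = "cosine_fw",
        seed: int = 42,
        **kwargs,
    ) -> "DissociationModel":
        """Build the observation table from conversations, then the model."""
        from .design import build_observation_table

        table = build_observation_table(
            convs, direction, window=window, indicator=indicator, seed=seed, **kwargs
        )
        return cls(table)

    def fit(
        self,
        reml: bool = True,
        methods: Sequence[str] = OPTIMIZERS,
        random_slopes: Sequence[str] = (),
    ) -> DissociationResults:
        """Estimate by REML, walking the optimizer fallback chain.

        ``random_slopes`` optionally adds random slopes for ``is_within``
        and/or ``centered_turn`` (robustness specification); the returned
        ``sigma_u2`` is then the random-intercept variance alone and slope
        variances are reported in ``random_effects``.
        """
        from statsmodels.regression.mixed_linear_model import MixedLM

        endog = self.table[self.similarity_col].to_numpy(dtype=float)
        exog = _design_matrix(self.table)
        groups = self.table["conversation_id"].to_numpy()
        exog_re = np.ones((len(endog), 1))
        re_names = ["intercept"]
        for slope in random_slopes:
            if slope not in ("is_within", "centered_turn"):
                raise ValueError(f"unsupported random slope {slope!r}")
            col = self.table[slope].to_numpy(dtype=float)
            exog_re = np.column_stack([exog_re, col])
            re_names.append(slope)

        model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        result = None
        used = None
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in methods:
                try:
                    candidate = model.fit(reml=reml, method=method, maxiter=200)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                result = candidate
                used = method
                converged = bool(getattr(candidate, "converged", False))
                if converged:
                    break
        if result is None:
            raise FitError("all optimizers failed on this observation table")

        names = list(FIXED_EFFECTS)
        params = pd.Series(np.asarray(result.fe_params), index=names)
        bse = pd.Series(np.asarray(result.bse_fe), index=names)
        z = params / bse
        p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        cov_re = np.atleast_2d(np.asarray(result.cov_re))
        random_effects = {
            f"var_{name}": float(cov_re[k, k]) for k, name in enumerate(re_names)
        }
        return DissociationResults(
            params=params,
            bse=bse,
            zvalues=z,
            pvalues=p,
            sigma_u2=float(cov_re[0, 0]),
            sigma_e2=float(result.scale),
            n_obs=len(endog),
            n_conversations=int(self.table["conversation_id"].nunique()),
            converged=converged,
            method=used or "none",
            direction=self.direction,
            indicator=self.indicator,
            random_effects=random_effects,
        )


def fit_dissociation_model(table: pd.DataFrame, **kwargs) -> DissociationResults:
    """Functional wrapper: build the model from a table and fit it."""
    return DissociationModel(table).fit(**kwargs)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeSummary:
    """Distribution of per-conversation OLS slopes with a one-sample t-test."""

    slopes: np.ndarray
    mean_slope: float
    t_stat: float
    df: int
    p_value: float
    pct_positive: float
    n_excluded: int = 0


def per_conversation_slopes(series: dict[str, Sequence[tuple[float, float]]]) -> SlopeSummary:
    """OLS slope of value on turn within each conversation, then a two-sided
    one-sample t-test of the slope distribution against zero.

    Conversations with fewer than two distinct turn values are excluded (the
    slope is undefined); the excluded count is reported.
    """
    slopes = []
    n_excluded = 0
    for _cid, points in series.items():
        pts = np.asarray(points, dtype=float)
        if len(pts) < 2 or np.unique(pts[:, 0]).size < 2:
            n_excluded += 1
            continue
        x = pts[:, 0]
        y = pts[:, 1]
        xc = x - x.mean()
        slopes.append(float(np.dot(xc, y - y.mean()) / np.dot(xc, xc)))
    if not slopes:
        raise ValueError("no conversation has >= 2 distinct turn values")
    arr = np.asarray(slopes)
    if arr.size > 1 and np.ptp(arr) > 0:
        t_stat, p_value = stats.ttest_1samp(arr, 0.0)
    elif arr.size > 1:
        # all slopes identical: t is +/-inf unless the common value is 0
        t_stat = float("inf") * np.sign(arr[0]) if arr[0] != 0 else 0.0
        p_value = 0.0 if arr[0] != 0 else 1.0
    else:
        t_stat, p_value = float("nan"), float("nan")
    return SlopeSummary(
        slopes=arr,
        mean_slope=float(arr.mean()),
        t_stat=float(t_stat),
        df=arr.size - 1,
        p_value=float(p_value),
        pct_positive=100.0 * float((arr > 0).mean()),
        n_excluded=n_excluded,
    )


def within_similarity_series(table: pd.DataFrame) -> dict[str, list[tuple[float, float]]]:
    """Per-conversation (turn, within-similarity) series from an observation
    table, for the per-conversation slope analysis."""
    within = table[table["is_within"] == 1]
    series: dict[str, list[tuple[float, float]]] = {}
    for cid, group in within.groupby("conversation_id", sort=False):
        series[str(cid)] = list(zip(group["N"].astype(float), group["similarity"].astype(float)))
    return series


@dataclass(frozen=True)
class EffectSize:
    d: float
    kind: str  # "static" or "cumulative_progressive"


def static_effect_size(table: pd.DataFrame, similarity_col: str = "similarity") -> EffectSize:
    """Cohen's d of within vs between similarity (pooled SD)."""
    within = table.loc[table["is_within"] == 1, similarity_col].to_numpy(dtype=float)
    between = table.loc[table["is_within"] == 0, similarity_col].to_numpy(dtype=float)
    if len(within) < 2 or len(between) < 2:
        raise ValueError("both groups need >= 2 observations")
    n1, n2 = len(within), len(between)
    pooled_var = ((n1 - 1) * within.var(ddof=1) + (n2 - 1) * between.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return EffectSize(d=float((within.mean() - between.mean()) / np.sqrt(pooled_var)), kind="static")


def cumulative_progressive_d(beta3: float, span: int, sd_pooled: float) -> EffectSize:
    """Cumulative progressive effect size d = beta3 * span / sd_pooled.

    ``span`` is the number of turn steps the trajectory accumulates over
    (9 for the turns 1-10 window).
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if sd_pooled <= 0:
        raise ValueError("pooled SD must be positive")
    return EffectSize(d=beta3 * span / sd_pooled, kind="cumulative_progressive")
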