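"""Experience/environment modelling of the flight characteristics.

Each characteristic is modelled against trial number (experience) and
training environment with a per-bee random intercept.  The default family
is a linear mixed model on the log scale (``lognormal_lmm``): the
characteristics are strictly positive and right-skewed, and a log-LMM
keeps likelihood-ratio tests standard.  Sinuosity, bounded below by 1, is
transformed as log(sinuosity - 1 + delta).  A fixed-effects gamma GLM with
log link (``gamma_log``) is available as an alternative family.  Fits feed
likelihood-ratio comparisons, so maximum likelihood (not REML) is used
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .metrics import METRIC_NAMES

SINUOSITY_DELTA = 1e-3
FAMILIES = ("lognormal_lmm", "gamma_log")


class NestingError(ValueError):
    """Raised when a likelihood-ratio comparison is not between nested fits."""


class ConvergenceError(RuntimeError):
    """Raised when a likelihood ratio is negative beyond numerical noise."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed effects, random intercept, family."""

    response: str
    fixed_effects: tuple[str, ...] = ("trial", "environment")
    random_intercept: str = "bee"
    family: str = "lognormal_lmm"

    def __post_init__(self) -> None:
        if self.response not in METRIC_NAMES:
            raise ValueError(f"response must be one of {METRIC_NAMES}, got {self.response!r}")
        bad = set(self.fixed_effects) - {"trial", "environment"}
        if bad:
            raise ValueError(f"unknown fixed effects: {sorted(bad)}")
        if self.random_intercept not in ("bee", "none"):
            raise ValueError("random_intercept must be 'bee' or 'none'")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "gamma_log" and self.random_intercept != "none":
            raise ValueError("gamma_log is a fixed-effects family; use random_intercept='none'")

    def n_parameters(self) -> int:
        # intercept + fixed effects + residual scale (+ random-intercept variance)
        return 2 + len(self.fixed_effects) + (1 if self.random_intercept == "bee" else 0)


def transform_response(values: np.ndarray, response: str) -> np.ndarray:
    """Map a strictly positive characteristic onto the modelling scale."""
    v = np.asarray(values, dtype=float)
    if response == "sinuosity":
        return np.log(v - 1.0 + SINUOSITY_DELTA)
    return np.log(v)


@dataclass
class FlightModelResults:
    """Fitted model: coefficients, uncertainties, likelihood and diagnostics."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    random_effect_var: float
    log_likelihood: float
    n_obs: int
    n_dropped: int
    converged: bool
    _sm_result: object = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Model: {self.spec.family}  response={self.spec.response}",
            f"fixed effects: {', '.join(self.spec.fixed_effects) or '(intercept only)'}"
            f"   random intercept: {self.spec.random_intercept}",
            f"n_obs={self.n_obs}  dropped={self.n_dropped}  logLik={self.log_likelihood:.3f}"
            f"  converged={self.converged}",
            "",
            pd.DataFrame(
                {"coef": self.params, "se": self.bse, "ci_lo": ci["lower"], "ci_hi": ci["upper"]}
            ).to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if self.spec.random_intercept == "bee":
            lines.append(f"\nrandom-intercept variance (bee): {self.random_effect_var:.4f}")
        return "\n".join(lines)


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series, int]:
    df = table.dropna(subset=[spec.response]).copy()
    n_dropped = len(table) - len(df)
    cols = {"const": np.ones(len(df))}
    if "trial" in spec.fixed_effects:
        cols["trial"] = df["trial"].astype(float).to_numpy()
    if "environment" in spec.fixed_effects:
        env_levels = sorted(df["environment_id"].unique())
        if len(env_levels) > 2:
            raise ValueError("at most two environments supported")
        cols["environment"] = (df["environment_id"] == env_levels[-1]).astype(float).to_numpy() \
            if len(env_levels) == 2 else np.zeros(len(df))
    X = pd.DataFrame(cols, index=df.index)
    y = pd.Series(transform_response(df[spec.response].to_numpy(), spec.response)
                  if spec.family == "lognormal_lmm" else df[spec.response].to_numpy(),
                  index=df.index, name=spec.response)
    return X, y, df["bee_id"], n_dropped


class FlightCharacteristicsModel:
    """Model object tying a flight-characteristics table to a :class:`ModelSpec`.

    ``fit()`` returns a :class:`FlightModelResults`; rows with a missing
    response are dropped and counted, never silently imputed.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        if spec.random_intercept == "bee" and table["bee_id"].nunique() < 2:
            raise ValueError("random-intercept model needs >= 2 bees")
        if table["trial"].nunique() < 2:
            raise ValueError("need >= 2 distinct trials")
        self.table = table
        self.spec = spec

    @classmethod
    def from_metrics(cls, table: pd.DataFrame, response: str, **spec_kwargs) -> "FlightCharacteristicsModel":
        return cls(table, ModelSpec(response=response, **spec_kwargs))

    def fit(self) -> FlightModelResults:
        X, y, groups, n_dropped = _design(self.table, self.spec)
        if self.spec.family == "gamma_log":
            res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
            return FlightModelResults(
                spec=self.spec, params=res.params, bse=res.bse,
                random_effect_var=0.0, log_likelihood=float(res.llf),
                n_obs=int(res.nobs), n_dropped=n_dropped, converged=True,
                _sm_result=res,
            )
        if self.spec.random_intercept == "none":
            res = sm.OLS(y, X).fit()
            return FlightModelResults(
                spec=self.spec, params=res.params, bse=res.bse,
                random_effect_var=0.0, log_likelihood=float(res.llf),
                n_obs=int(res.nobs), n_dropped=n_dropped, converged=True,
                _sm_result=res,
            )
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        with warnings.catch_warnings():
            # boundary / singular-Hessian warnings are expected when the
            # bee variance is near 0; the results carry a converged flag.
            # several optimizers are tried and the best likelihood kept,
            # since the profiled variance occasionally stalls short of the
            # optimum under a single method
            warnings.simplefilter("ignore")
            for method in (None, "powell", "cg"):
                try:
                    cand = model.fit(reml=False, **({} if method is None else {"method": method}))
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-10):
                    res = cand
        if res is None:
            raise ConvergenceError("mixed-model fit failed with every optimizer")
        converged = bool(getattr(res, "converged", True))
        re_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re is not None else float("nan")
        fixed = res.params[: X.shape[1]]
        try:
            bse = res.bse[: X.shape[1]]
        except (np.linalg.LinAlgError, ValueError):
            bse = pd.Series(np.nan, index=fixed.index)
            converged = False
        return FlightModelResults(
            spec=self.spec, params=fixed, bse=bse,
            random_effect_var=re_var, log_likelihood=float(res.llf),
            n_obs=int(res.nobs), n_dropped=n_dropped, converged=converged,
            _sm_result=res,
        )


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> FlightModelResults:
    """Functional wrapper: build and fit in one call."""
    return FlightCharacteristicsModel(table, spec).fit()


def lrt_compare(full: FlightModelResults, reduced: FlightModelResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full one.

    Returns (chi2, df, p).  Both fits must be ML on the same rows; the
    degrees of freedom are the parameter-count difference.
    """
    if full.spec.response != reduced.spec.response or full.spec.family != reduced.spec.family:
        raise NestingError("models differ in response or family")
    if not set(reduced.spec.fixed_effects) <= set(full.spec.fixed_effects):
        raise NestingError("reduced fixed effects not a subset of the full model's")
    if reduced.spec.random_intercept == "bee" and full.spec.random_intercept == "none":
        raise NestingError("reduced model has a random effect the full model lacks")
    if full.n_obs != reduced.n_obs:
        raise NestingError(f"fits use different rows ({full.n_obs} vs {reduced.n_obs})")
    df = full.spec.n_parameters() - reduced.spec.n_parameters()
    if df < 0:
        raise NestingError("reduced model has more parameters than the full one")
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if chi2 < -1e-6:
        raise ConvergenceError(f"negative likelihood ratio ({chi2:.3g}): a fit did not converge")
    chi2 = max(chi2, 0.0)
    if df == 0:  # identical specs: nothing to test
        return chi2, 0, 1.0
    return chi2, df, float(sps.chi2.sf(chi2, df))


def random_effect_gain(table: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """Does the per-bee random intercept earn its keep?

    Likelihood-ratio comparison of the model with vs without the bee
    intercept.  The variance is tested on its boundary (0), so the p-value
    is the halved chi-square(1) upper tail.
    """
    if spec.random_intercept != "bee":
        raise ValueError("spec must request the bee random intercept")
    full = fit_mixed_model(table, spec)
    reduced = fit_mixed_model(
        table, ModelSpec(spec.response, spec.fixed_effects, "none", spec.family)
    )
    chi2 = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if chi2 < -1e-6:
        raise ConvergenceError(f"negative likelihood ratio ({chi2:.3g})")
    chi2 = max(chi2, 0.0)
    return chi2, float(0.5 * sps.chi2.sf(chi2, 1))


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum z-test with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = r1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _select_trial(table: pd.DataFrame, trial_sel: str) -> pd.DataFrame:
    """Each bee's first (earliest recorded) or last (final recorded) flight."""
    if trial_sel not in ("first", "last"):
        raise ValueError("trial_sel must be 'first' or 'last'")
    agg = "min" if trial_sel == "first" else "max"
    sel = table.groupby("bee_id")["trial"].transform(agg)
    return table[table["trial"] == sel]


def compare_groups(
    table_env1: pd.DataFrame,
    table_env2: pd.DataFrame,
    trial_sel: str,
    m_tests: int = 6,
    metrics: tuple[str, ...] = tuple(METRIC_NAMES),
) -> pd.DataFrame:
    """Between-environment rank-sum tests at one experience level.

    For each characteristic, a two-sided Wilcoxon rank-sum test between the
    two environments at the selected trial ("first" = each bee's earliest
    recorded flight, "last" = its final one), Bonferroni-corrected over
    ``m_tests``.
    """
    g1 = _select_trial(table_env1, trial_sel)
    g2 = _select_trial(table_env2, trial_sel)
    rows = []
    for metric in metrics:
        a = g1[metric].dropna().to_numpy()
        b = g2[metric].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group for metric {metric!r} at trial_sel={trial_sel!r}")
        z, p = ranksum_test(a, b)
        rows.append(
            {
                "metric": metric,
                "experience": "naive" if trial_sel == "first" else "experienced",
                "statistic": z,
                "raw_p": p,
                "adjusted_p": min(1.0, p * m_tests),
                "n_env1": len(a),
                "n_env2": len(b),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ModelSpec",
    "FlightCharacteristicsModel",
    "FlightModelResults",
    "fit_mixed_model",
    "lrt_compare",
    "random_effect_gain",
    "ranksum_test",
    "compare_groups",
    "transform_response",
    "NestingError",
    "ConvergenceError",
    "SINUOSITY_DELTA",
    "FAMILIES",
]
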