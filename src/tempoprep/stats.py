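"""Statistical battery for saccadic-latency foreperiod experiments.

The module is organised statsmodels-style: model classes are built from a
trial table (or binned summaries) and ``fit()`` returns a results object
carrying estimates, uncertainties, diagnostics and a ``summary()`` table.

* :class:`LatencyMixedModel` — trial-by-trial linear mixed model of latency on
  one predictor (foreperiod ``fp_n``, previous foreperiod ``fp_prev``,
  ``sequence`` = fp_prev - fp_n, or the reciprocal hazard ``hr_rec``), with a
  subject random intercept (``rs1``) or random-slope variants (``rs2``-``rs4``),
  Gaussian family, REML or ML.
* :func:`select_structure` — BIC selection: random structures compared under
  REML, fixed structures (main effect vs. + trial index) under ML.
* :class:`BinnedLatencyModel` — ordinary least squares on latencies averaged
  over subjects within 50-ms foreperiod bins (latency ~ FPn or ~ HRrec).
* :class:`WeberSlopeModel` — slope analysis of scalar timing:
  var(latency) = k^2 * FP^2 + c; a positive k^2 (Weber fraction squared)
  indicates scalar variability, a negative estimate rejects it.
* :func:`sd_vs_hazard_regression` — binned latency SD on the classic hazard.
* :func:`paired_sd_test` — paired t-test of per-subject latency SDs between
  conditions.
* :func:`tost_paired` / :func:`tost_coefficient` — TOST equivalence tests at
  alpha = 0.01 (98% CI): bounds in Cohen's d_z units for paired contrasts and
  on a signed Cohen's f^2 scale for mixed-model coefficients.

The sequence predictor follows the convention sequence = FP_{n-1} - FP_n; the
convention is recorded in each result's metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import DEFAULT_BOUNDS, bin_edges

ALPHA = 0.01  # study-wide significance level
SEQUENCE_CONVENTION = "sequence = fp_prev - fp_n"

#: Equivalence bounds (smallest effect sizes of interest) used by the study:
#: Cohen's d_z for paired SD contrasts; Cohen's f^2 for the previous-foreperiod
#: coefficient (per anchor).
SESOI_DZ = 1.125
SESOI_F2 = {"short": 0.09, "long": 0.02}

PREDICTOR_ALIASES = {
    "FPn": "fp_n", "fp_n": "fp_n",
    "FPn-1": "fp_prev", "FPn_1": "fp_prev", "fp_prev": "fp_prev",
    "sequence": "sequence",
    "HRrec": "hr_rec", "hr_rec": "hr_rec",
}

RANDOM_STRUCTURES = ("rs1", "rs2", "rs3", "rs4")


def _resolve_predictor(name: str) -> str:
    try:
        return PREDICTOR_ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown predictor {name!r}; choose from {sorted(set(PREDICTOR_ALIASES))}"
        ) from None


# ---------------------------------------------------------------------------
# Linear mixed model


@dataclass
class MixedModelResult:
    """Fitted fixed/random effects of one latency mixed model."""

    predictor: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p
    random_sd: dict  # term -> SD in ms (includes "residual")
    bic: float
    loglik: float
    method: str
    family: str
    random_structure: str
    n_obs: int
    n_subjects: int
    converged: bool
    predictor_sd: float  # SD of the predictor column (for effect-size scaling)
    metadata: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        return float(self.fixed_effects.loc[self.predictor, "estimate"])

    @property
    def slope_se(self) -> float:
        return float(self.fixed_effects.loc[self.predictor, "se"])

    def slope_ci(self) -> tuple[float, float]:
        row = self.fixed_effects.loc[self.predictor]
        return float(row["ci_low"]), float(row["ci_high"])

    def summary(self) -> str:
        lines = [
            f"Linear mixed model: latency ~ {self.predictor} "
            f"({self.random_structure}, {self.method}, {self.family})",
            f"n_obs={self.n_obs}  n_subjects={self.n_subjects}  "
            f"logLik={self.loglik:.3f}  BIC={self.bic:.3f}  converged={self.converged}",
            f"{'term':<12}{'beta':>12}{'SE':>10}{'95% CI':>26}{'p':>12}",
        ]
        for term, row in self.fixed_effects.iterrows():
            lines.append(
                f"{term:<12}{row['estimate']:>12.3f}{row['se']:>10.3f}"
                f"{'[%.3f, %.3f]' % (row['ci_low'], row['ci_high']):>26}"
                f"{row['p']:>12.3g}"
            )
        lines.append(
            "Random SDs [ms]: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.random_sd.items())
        )
        return "\n".join(lines)

    def to_table_row(self, dataset: str = "") -> pd.DataFrame:
        rows = []
        for term, r in self.fixed_effects.iterrows():
            rows.append(
                {
                    "Dataset": dataset,
                    "Model": f"{self.predictor}.{self.random_structure}",
                    "Fixed terms": term,
                    "beta": r["estimate"],
                    "SE": r["se"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                }
            )
        out = pd.DataFrame(rows)
        out["sigma_residual"] = self.random_sd.get("residual", np.nan)
        out["sigma_subject"] = self.random_sd.get("subject", np.nan)
        return out


class LatencyMixedModel:
    """Trial-by-trial Gaussian mixed model of saccadic latency.

    Parameters
    ----------
    data : DataFrame
        Trial table with ``latency``, ``subject_id`` and the predictor column;
        rows with missing latency or predictor (e.g., first trials of a block
        for history predictors) are dropped.
    predictor : str
        ``fp_n``/``FPn``, ``fp_prev``/``FPn-1``, ``sequence`` or ``hr_rec``/``HRrec``.
    random_structure : str
        ``rs1`` subject random intercept; ``rs2`` random slope only; ``rs3``
        uncorrelated intercept + slope; ``rs4`` correlated intercept + slope.
    method : str
        ``REML`` (default) or ``ML``.
    family : str
        Only ``gaussian`` (identity link) is fitted; other names are accepted
        for residual diagnostics of alternative families and otherwise treated
        as Gaussian.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictor: str,
        random_structure: str = "rs1",
        method: str = "REML",
        family: str = "gaussian",
        group_col: str = "subject_id",
    ):
        self.predictor = _resolve_predictor(predictor)
        if random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"random_structure must be one of {RANDOM_STRUCTURES}")
        self.random_structure = random_structure
        self.method = method.upper()
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be REML or ML")
        self.family = family.lower()
        self.group_col = group_col
        cols = ["latency", group_col, self.predictor]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"trial table lacks columns: {missing}")
        self.data = data.dropna(subset=["latency", self.predictor]).copy()
        if self.data[group_col].nunique() < 2:
            raise ValueError("need >= 2 subjects")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, predictor: str, **kw) -> "LatencyMixedModel":
        return cls(data, predictor, **kw)

    def fit(self, extra_fixed: tuple[str, ...] = ()) -> MixedModelResult:
        x = self.predictor
        fixed = " + ".join((x,) + tuple(extra_fixed))
        formula = f"latency ~ {fixed}"
        re_formula, vc_formula = {
            "rs1": ("1", None),
            "rs2": (f"0 + {x}", None),
            "rs3": ("1", {"slope": f"0 + {x}"}),
            "rs4": (f"1 + {x}", None),
        }[self.random_structure]
        model = smf.mixedlm(
            formula,
            self.data,
            groups=self.data[self.group_col],
            re_formula=re_formula,
            vc_formula=vc_formula,
        )
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=(self.method == "REML"))
                converged = bool(getattr(res, "converged", True))
            except (np.linalg.LinAlgError, ValueError):
                res = None
                converged = False
        if res is None:
            return MixedModelResult(
                predictor=x, fixed_effects=pd.DataFrame(), random_sd={},
                bic=np.inf, loglik=-np.inf, method=self.method, family=self.family,
                random_structure=self.random_structure,
                n_obs=len(self.data), n_subjects=self.data[self.group_col].nunique(),
                converged=False, predictor_sd=float(self.data[x].std(ddof=1)),
                metadata={"sequence_convention": SEQUENCE_CONVENTION},
            )
        fe_names = list(res.fe_params.index)
        ci = res.conf_int(alpha=0.05).loc[fe_names]
        fixed_effects = pd.DataFrame(
            {
                "estimate": res.fe_params,
                "se": res.bse.loc[fe_names],
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": res.pvalues.loc[fe_names],
            }
        )
        random_sd = {"residual": float(np.sqrt(res.scale))}
        cov = np.atleast_2d(np.asarray(res.cov_re))
        re_names = list(res.cov_re.index) if hasattr(res.cov_re, "index") else []
        for i, name in enumerate(re_names):
            label = "subject" if name in ("Group", "Intercept", "groups") else f"subject_{name}"
            random_sd[label] = float(np.sqrt(max(cov[i, i], 0.0)))
        if res.vcomp is not None and len(res.vcomp):
            for name, v in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
                random_sd[f"subject_{name}"] = float(np.sqrt(max(v, 0.0)))
        # lme4-style BIC: -2 logLik + npar * log(nobs), npar = fixed effects +
        # random covariance parameters + residual variance
        n_cov = cov.shape[0] * (cov.shape[0] + 1) // 2 if len(re_names) else 0
        n_vc = len(np.atleast_1d(res.vcomp)) if res.vcomp is not None else 0
        npar = len(fe_names) + n_cov + n_vc + 1
        nobs = len(self.data)
        bic = -2.0 * res.llf + npar * np.log(nobs)
        # degenerate (singular) random structures are reported, not hidden
        if not converged:
            bic = np.inf
        return MixedModelResult(
            predictor=x,
            fixed_effects=fixed_effects,
            random_sd=random_sd,
            bic=float(bic),
            loglik=float(res.llf),
            method=self.method,
            family=self.family,
            random_structure=self.random_structure,
            n_obs=nobs,
            n_subjects=self.data[self.group_col].nunique(),
            converged=converged,
            predictor_sd=float(self.data[x].std(ddof=1)),
            metadata={"sequence_convention": SEQUENCE_CONVENTION},
        )


def fit_latency_mixed(
    table: pd.DataFrame,
    predictor: str,
    random_structure: str = "rs1",
    method: str = "REML",
    family: str = "gaussian",
) -> MixedModelResult:
    """Convenience wrapper: build and fit a :class:`LatencyMixedModel`."""
    return LatencyMixedModel(table, predictor, random_structure, method, family).fit()


@dataclass
class StructureSelection:
    """BIC ledger of the random- and fixed-structure comparison."""

    predictor: str
    chosen_random: str
    chosen_fixed: str  # "main" or "full" (+ trial index)
    ledger: pd.DataFrame

    def summary(self) -> str:
        return (
            f"Structure selection for {self.predictor}: random={self.chosen_random}, "
            f"fixed={self.chosen_fixed}\n" + self.ledger.to_string(index=False)
        )


def select_structure(
    table: pd.DataFrame,
    predictor: str,
    random_candidates: tuple[str, ...] = RANDOM_STRUCTURES,
    trial_col: str = "trial_index",
) -> StructureSelection:
    """Choose the random structure by REML-BIC, then the fixed structure by ML-BIC.

    The random-slope candidates are fitted on a standardised copy of the
    predictor (the likelihood, hence BIC, is invariant to linear rescaling of
    the predictor, and raw millisecond scales make slope variances
    numerically tiny).  Non-convergent candidates enter the ledger with
    infinite BIC.
    """
    x = _resolve_predictor(predictor)
    data = table.dropna(subset=["latency", x]).copy()
    zcol = f"_{x}_z"
    data[zcol] = (data[x] - data[x].mean()) / data[x].std(ddof=1)
    rows = []
    best_rs, best_rs_bic = None, np.inf
    for rs in random_candidates:
        res = LatencyMixedModel(
            data.rename(columns={x: f"_{x}_raw", zcol: x}), x, rs, method="REML"
        ).fit(extra_fixed=(trial_col,) if trial_col in data.columns else ())
        rows.append(
            {"stage": "random", "candidate": rs, "method": "REML",
             "bic": res.bic, "converged": res.converged}
        )
        if res.bic < best_rs_bic:
            best_rs, best_rs_bic = rs, res.bic
    # fixed structure under ML with the chosen random structure
    fixed_candidates = {"main": (), }
    if trial_col in data.columns:
        fixed_candidates["full"] = (trial_col,)
    best_fixed, best_fixed_bic = "main", np.inf
    for name, extra in fixed_candidates.items():
        res = LatencyMixedModel(data, x, best_rs, method="ML").fit(extra_fixed=extra)
        rows.append(
            {"stage": "fixed", "candidate": name, "method": "ML",
             "bic": res.bic, "converged": res.converged}
        )
        if res.bic < best_fixed_bic:
            best_fixed, best_fixed_bic = name, res.bic
    return StructureSelection(x, best_rs, best_fixed, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Binned summaries and simple linear models


def bin_latency_stats(
    table: pd.DataFrame,
    bin_width: float = 50.0,
    bounds=DEFAULT_BOUNDS,
    min_count: int = 2,
) -> pd.DataFrame:
    """Per-foreperiod-bin latency summaries (n, mean, sd, var, mean hr columns).

    Uses the same half-open 50-ms bins as the hazard regressors.  Bins with
    fewer than ``min_count`` trials are dropped.
    """
    data = table.dropna(subset=["latency"]).copy()
    edges = bin_edges(bounds, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = np.clip(
        np.searchsorted(edges, data["fp_n"].to_numpy(), side="right") - 1,
        0, len(centers) - 1,
    )
    data["fp_bin"] = centers[idx]
    agg = {"latency": ["count", "mean", "std", "var"]}
    extra_cols = [c for c in ("hr_classic", "hr_rec") if c in data.columns]
    for c in extra_cols:
        agg[c] = "mean"
    g = data.groupby("fp_bin").agg(agg)
    out = pd.DataFrame(
        {
            "fp_bin": g.index,
            "n": g[("latency", "count")].to_numpy(),
            "mean": g[("latency", "mean")].to_numpy(),
            "sd": g[("latency", "std")].to_numpy(),
            "var": g[("latency", "var")].to_numpy(),
        }
    ).reset_index(drop=True)
    for c in extra_cols:
        out[c] = g[(c, "mean")].to_numpy()
    return out[out["n"] >= min_count].reset_index(drop=True)


@dataclass
class SimpleRegressionResult:
    """OLS slope/intercept with Wald inference and adjusted R^2."""

    formula: str
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    p: float
    adj_r2: float
    intercept: float
    n: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.formula}: slope={self.slope:.3f} +- {self.slope_se:.3f} "
            f"95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}] p={self.p:.3g} "
            f"adj.R2={self.adj_r2:.2f} (n={self.n} bins)"
        )


def _ols(y: np.ndarray, x: np.ndarray, formula: str, weights=None) -> SimpleRegressionResult:
    X = sm.add_constant(np.asarray(x, dtype=float))
    if weights is None:
        fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    else:
        fit = sm.WLS(np.asarray(y, dtype=float), X, weights=weights).fit()
    ci = fit.conf_int(alpha=0.05)
    return SimpleRegressionResult(
        formula=formula,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        intercept=float(fit.params[0]),
        n=int(fit.nobs),
    )


class BinnedLatencyModel:
    """OLS of bin-mean latency on the foreperiod or the reciprocal hazard."""

    def __init__(self, table: pd.DataFrame, regressor: str = "FPn",
                 bin_width: float = 50.0, bounds=DEFAULT_BOUNDS):
        self.regressor = _resolve_predictor(regressor) if regressor != "FPn" else "fp_n"
        self.binned = bin_latency_stats(table, bin_width, bounds)
        if len(self.binned) < 3:
            raise ValueError("need >= 3 foreperiod bins")
        if self.regressor == "hr_rec" and "hr_rec" not in self.binned.columns:
            raise ValueError("table lacks an hr_rec column (attach hazard first)")

    def fit(self) -> SimpleRegressionResult:
        x = self.binned["fp_bin"] if self.regressor == "fp_n" else self.binned[self.regressor]
        name = "FPn" if self.regressor == "fp_n" else "HRrec"
        return _ols(self.binned["mean"], x, f"latency ~ {name}")


def fit_latency_lm_binned(table: pd.DataFrame, regressor: str = "FPn", **kw) -> SimpleRegressionResult:
    return BinnedLatencyModel(table, regressor, **kw).fit()


# ---------------------------------------------------------------------------
# Weber slope analysis


@dataclass
class SlopeAnalysisResult:
    """Scalar-timing slope analysis: var(latency) = k^2 * FP^2 + c."""

    k_squared: float
    k_squared_se: float
    c: float
    ci_low: float
    ci_high: float
    p: float
    adj_r2: float
    weber_obeyed: bool
    n_bins: int

    def summary(self) -> str:
        verdict = "obeyed" if self.weber_obeyed else "not obeyed"
        return (
            f"var(latency) ~ k^2*FP^2 + c: k^2={self.k_squared:.4g} +- "
            f"{self.k_squared_se:.4g} (p={self.p:.3g}, adj.R2={self.adj_r2:.2f}), "
            f"c={self.c:.4g}; Weber's law {verdict}"
        )


class WeberSlopeModel:
    """Slope analysis of binned latency variance against squared foreperiod."""

    def __init__(self, fp: np.ndarray, variance: np.ndarray, weights=None):
        fp = np.asarray(fp, dtype=float)
        variance = np.asarray(variance, dtype=float)
        if len(fp) != len(variance):
            raise ValueError("fp and variance must align")
        if len(fp) < 3:
            raise ValueError("need >= 3 bins")
        self.fp = fp
        self.variance = variance
        self.weights = weights

    @classmethod
    def from_trials(cls, table: pd.DataFrame, bin_width: float = 50.0,
                    bounds=DEFAULT_BOUNDS, weighted: bool = False) -> "WeberSlopeModel":
        b = bin_latency_stats(table, bin_width, bounds)
        return cls(b["fp_bin"], b["var"], weights=b["n"] if weighted else None)

    def fit(self) -> SlopeAnalysisResult:
        r = _ols(self.variance, self.fp**2, "var ~ FP^2", weights=self.weights)
        return SlopeAnalysisResult(
            k_squared=r.slope, k_squared_se=r.slope_se, c=r.intercept,
            ci_low=r.ci_low, ci_high=r.ci_high, p=r.p, adj_r2=r.adj_r2,
            weber_obeyed=bool(r.slope > 0), n_bins=r.n,
        )


def weber_slope_analysis(fp, variance, weights=None) -> SlopeAnalysisResult:
    return WeberSlopeModel(fp, variance, weights).fit()


def sd_vs_hazard_regression(sd, hazard_values, weights=None) -> SimpleRegressionResult:
    """OLS of binned latency SD on the classic hazard at the same bins."""
    sd = np.asarray(sd, dtype=float)
    hazard_values = np.asarray(hazard_values, dtype=float)
    if sd.shape != hazard_values.shape:
        raise ValueError("sd and hazard bins are misaligned")
    if len(sd) < 3:
        raise ValueError("need >= 3 bins")
    return _ols(sd, hazard_values, "sd(latency) ~ HRclassic", weights=weights)


# ---------------------------------------------------------------------------
# Paired tests and equivalence (TOST)


def paired_sd_test(sd_a, sd_b) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-subject latency SDs; returns (t, df, p)."""
    a = np.asarray(sd_a, dtype=float)
    b = np.asarray(sd_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences: t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


@dataclass
class TOSTResult:
    """Two one-sided tests of equivalence against +-SESOI bounds."""

    bounds: tuple[float, float]
    effect_size_type: str  # "cohen_dz" or "cohen_f2"
    effect: float  # estimated effect on the bound scale (signed)
    ci: tuple[float, float]  # (1 - 2*alpha) CI on the bound scale
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    df: float
    alpha: float
    equivalent: bool

    @property
    def ci_level(self) -> float:
        return 1.0 - 2.0 * self.alpha

    @property
    def p(self) -> float:
        return max(self.p_lower, self.p_upper)

    def summary(self) -> str:
        verdict = "equivalent (negligible effect)" if self.equivalent else "not conclusive"
        return (
            f"TOST [{self.effect_size_type}] bounds [{self.bounds[0]:.3g}, "
            f"{self.bounds[1]:.3g}], alpha={self.alpha}: effect={self.effect:.3g}, "
            f"{self.ci_level*100:.0f}% CI [{self.ci[0]:.3g}, {self.ci[1]:.3g}], "
            f"p={self.p:.3g} -> {verdict}"
        )


def _nct_cdf(t: float, df: int, nc: float) -> float:
    # scipy's noncentral t underflows to NaN deep in the tails; substitute limits
    v = sps.nct.cdf(t, df, nc)
    if np.isnan(v):
        return 0.0 if nc > t else 1.0
    return float(v)


def _nct_sf(t: float, df: int, nc: float) -> float:
    v = sps.nct.sf(t, df, nc)
    if np.isnan(v):
        return 1.0 if nc > t else 0.0
    return float(v)


def _nct_ci(t_obs: float, df: int, alpha: float) -> tuple[float, float]:
    """(1 - 2 alpha) CI for the noncentrality parameter of a noncentral t."""
    from scipy.optimize import brentq

    span = abs(t_obs) + 10.0 * np.sqrt(1.0 + t_obs**2 / df) + 10.0
    lo = brentq(lambda nc: _nct_sf(t_obs, df, nc) - alpha, t_obs - span, t_obs + span)
    hi = brentq(lambda nc: _nct_cdf(t_obs, df, nc) - alpha, t_obs - span, t_obs + span)
    return float(lo), float(hi)


def tost_paired(diffs, sesoi_dz: float = SESOI_DZ, alpha: float = ALPHA) -> TOSTResult:
    """Paired-samples TOST with symmetric bounds in Cohen's d_z units.

    d_z = mean(diff)/sd(diff).  Because the bounds are standardised, the
    observed t = d_z * sqrt(n) follows a *noncentral* t under either boundary
    null (noncentrality +-sesoi * sqrt(n)); the two one-sided p-values use that
    exact distribution, so the rejection rate at the bound equals alpha.  The
    reported (1 - 2 alpha) CI on d_z inverts the same tests, making
    "equivalent" identical to "CI inside the bounds".
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need n >= 3 differences")
    sd = d.std(ddof=1)
    if np.allclose(sd, 0.0):
        raise ValueError("zero-variance differences")
    if sesoi_dz < 0:
        raise ValueError("sesoi_dz must be >= 0")
    dz = d.mean() / sd
    df = n - 1
    rt_n = np.sqrt(n)
    t_obs = dz * rt_n
    p_lower = _nct_sf(t_obs, df, -sesoi_dz * rt_n)   # H0: dz <= -sesoi
    p_upper = _nct_cdf(t_obs, df, sesoi_dz * rt_n)   # H0: dz >= +sesoi
    nc_lo, nc_hi = _nct_ci(t_obs, df, alpha)
    return TOSTResult(
        bounds=(-sesoi_dz, sesoi_dz),
        effect_size_type="cohen_dz",
        effect=float(dz),
        ci=(nc_lo / rt_n, nc_hi / rt_n),
        t_lower=float(t_obs),
        t_upper=float(t_obs),
        p_lower=p_lower,
        p_upper=p_upper,
        df=df,
        alpha=alpha,
        equivalent=bool(max(p_lower, p_upper) < alpha),
    )


def tost_coefficient(
    model_result: MixedModelResult,
    sesoi_f2: float,
    alpha: float = ALPHA,
) -> TOSTResult:
    """Equivalence test of a mixed-model coefficient with Cohen's f^2 bounds.

    The coefficient's local effect is put on a signed f^2 scale via
    f = beta * sd(x) / sigma_resid (so f^2 = beta^2 var(x) / sigma^2); the
    +-sesoi_f2 bounds translate to a raw-coefficient bound
    beta* = sqrt(sesoi_f2) * sigma_resid / sd(x), and the two one-sided Wald
    t-tests run on the raw coefficient.  This conversion is a reconstruction
    of the standardised local-effect definition (the exact published formula
    is not printed with the bounds).
    """
    if model_result.predictor not in model_result.fixed_effects.index:
        raise ValueError(f"coefficient {model_result.predictor!r} missing from fit")
    if sesoi_f2 < 0:
        raise ValueError("sesoi_f2 must be >= 0")
    beta = model_result.slope
    se = model_result.slope_se
    sd_x = model_result.predictor_sd
    sigma = model_result.random_sd.get("residual", np.nan)
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("residual SD unavailable; cannot scale to f^2")
    df = model_result.n_obs - len(model_result.fixed_effects)
    beta_bound = np.sqrt(sesoi_f2) * sigma / sd_x
    t_lower = (beta + beta_bound) / se
    t_upper = (beta - beta_bound) / se
    p_lower = float(sps.t.sf(t_lower, df))
    p_upper = float(sps.t.cdf(t_upper, df))
    tcrit = sps.t.ppf(1.0 - alpha, df)

    def to_f2(b: float) -> float:
        f = b * sd_x / sigma
        return float(np.sign(f) * f**2)

    return TOSTResult(
        bounds=(-sesoi_f2, sesoi_f2),
        effect_size_type="cohen_f2",
        effect=to_f2(beta),
        ci=(to_f2(beta - tcrit * se), to_f2(beta + tcrit * se)),
        t_lower=float(t_lower),
        t_upper=float(t_upper),
        p_lower=p_lower,
        p_upper=p_upper,
        df=df,
        alpha=alpha,
        equivalent=bool(max(p_lower, p_upper) < alpha),
    )


# ---------------------------------------------------------------------------
# Residual diagnostics for alternative families


def family_residual_diagnostics(table: pd.DataFrame, predictor: str = "fp_n") -> pd.DataFrame:
    """Residual summaries of latency fits under alternative response families.

    Gaussian-identity, Gaussian on log latency, and gamma / inverse-Gaussian
    GLMs are fitted (fixed effects only) and their residual skewness/kurtosis
    reported — a diagnostic aid, not a model-selection procedure.
    """
    x = _resolve_predictor(predictor)
    data = table.dropna(subset=["latency", x])
    if (data["latency"] <= 0).any():
        data = data[data["latency"] > 0]
    X = sm.add_constant(data[x].to_numpy())
    y = data["latency"].to_numpy()
    rows = []
    fits = {
        "gaussian_identity": sm.OLS(y, X).fit(),
        "gaussian_log_latency": sm.OLS(np.log(y), X).fit(),
        "gamma_identity": sm.GLM(
            y, X, family=sm.families.Gamma(sm.families.links.Identity())
        ).fit(),
        "inverse_gaussian_identity": sm.GLM(
            y, X, family=sm.families.InverseGaussian(sm.families.links.Identity())
        ).fit(),
    }
    for name, fit in fits.items():
        resid = np.asarray(fit.resid if hasattr(fit, "resid") else fit.resid_deviance)
        rows.append(
            {
                "family": name,
                "resid_mean": float(np.mean(resid)),
                "resid_sd": float(np.std(resid, ddof=1)),
                "skewness": float(sps.skew(resid)),
                "excess_kurtosis": float(sps.kurtosis(resid)),
            }
        )
    return pd.DataFrame(rows)
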