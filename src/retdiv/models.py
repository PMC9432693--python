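"""Mixed-model treatment comparisons for richness, functional richness and vegetation.

Stand-scale species richness (Chao1) and functional richness are modelled as
Gaussian responses; cover-type-scale richness as a Poisson response after
rounding Chao1 to the nearest integer (half-up); vegetation cover groups as
Gaussian with a block intercept and a patch/clearcut fixed effect (shrub
cover square-root transformed).  Treatments are coded as deviations from the
riparian-aggregated (RA) reference, so the intercept is the RA mean and each
treatment coefficient is its difference from RA on the link scale.  Year
enters as a centred numeric covariate; week of sampling optionally.  Random
intercepts for stand (repeated measures across years) and block (the
randomized complete block design) are included where requested; the
treatment-by-year interaction model drops the block intercept (it does not
converge with one at this design size).

Estimation delegates to statsmodels: MixedLM (REML) for Gaussian responses
and PoissonBayesMixedGLM (MAP with Laplace posterior SDs) for the Poisson
response; the reporting contract (coefficients, 95% intervals, variance
components, predicted treatment means) is this module's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one treatment-comparison model."""

    response: str = "chao1"
    family: Literal["gaussian", "poisson"] = "gaussian"
    reference: str = "RA"
    include_year: bool = True
    include_week: bool = False
    year_by_treatment: bool = False
    include_cover_type: bool = False
    random_intercepts: tuple[str, ...] = ("stand", "block")
    transform: Literal["sqrt"] | None = None

    def __post_init__(self) -> None:
        bad = set(self.random_intercepts) - {"stand", "block"}
        if bad:
            raise ValueError(f"unknown random intercepts: {sorted(bad)}")


@dataclass
class FitResult:
    """Summaries of a fitted mixed model.

    ``coefficients`` has one row per fixed effect (estimate, se, ci_low,
    ci_high); ``predicted_means`` one row per treatment level with the
    unconditional predicted mean on the response scale and its 95% interval;
    ``variance_components`` maps random-effect names (plus ``residual``) to
    variances.
    """

    coefficients: pd.DataFrame
    variance_components: dict[str, float]
    predicted_means: pd.DataFrame
    converged: bool
    degenerate: bool = False
    family: str = "gaussian"

    def coef(self, name_contains: str) -> pd.Series:
        """First coefficient row whose name contains the given substring."""
        hits = self.coefficients[
            self.coefficients["name"].str.contains(name_contains, regex=False)
        ]
        if hits.empty:
            raise KeyError(f"no coefficient matching {name_contains!r}")
        return hits.iloc[0]


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with halves away from zero upward (4.5 -> 5)."""
    x = np.asarray(x, dtype=float)
    return np.floor(x + 0.5).astype(int)


def _fixed_formula(spec: ModelSpec, response: str, data: pd.DataFrame) -> str:
    terms = [f"C(treatment, Treatment('{spec.reference}'))"]
    if spec.include_cover_type and "cover_type" in data.columns:
        terms.append("C(cover_type, Treatment('clearcut'))")
    if spec.include_year and data["year"].nunique() > 1:
        terms.append("year_c")
    if spec.year_by_treatment:
        terms.append(f"C(treatment, Treatment('{spec.reference}')):year_c")
    if spec.include_week and "week" in data.columns and data["week"].nunique() > 1:
        terms.append("week_c")
    return f"{response} ~ " + " + ".join(terms)


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str]:
    df = table.copy()
    if spec.response not in df.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    response = spec.response
    if spec.transform == "sqrt":
        if (df[response] < 0).any():
            raise ValueError("cannot sqrt-transform negative responses")
        df["_resp"] = np.sqrt(df[response].astype(float))
        response = "_resp"
    if df["treatment"].nunique() < 2:
        raise ValueError("need at least 2 treatment levels")
    if spec.reference not in set(df["treatment"]):
        raise ValueError(f"reference level {spec.reference!r} absent from data")
    if "year" in df.columns:
        df["year_c"] = df["year"].astype(float) - df["year"].astype(float).mean()
    else:
        df["year_c"] = 0.0
    if "week" in df.columns:
        df["week_c"] = df["week"].astype(float) - df["week"].astype(float).mean()
    return df, response


def _clean_name(raw: str, spec: ModelSpec) -> str:
    name = raw.replace(f"C(treatment, Treatment('{spec.reference}'))", "treatment")
    name = name.replace("C(cover_type, Treatment('clearcut'))", "cover_type")
    name = name.replace("[T.", "[").replace("]", "]")
    return name


def _treatment_means(
    fe: pd.Series,
    cov: pd.DataFrame,
    exog_names: Sequence[str],
    treatments: Sequence[str],
    spec: ModelSpec,
    link_inverse=None,
) -> pd.DataFrame:
    """Predicted mean per treatment at covariate means (year_c = week_c = 0)."""
    rows = []
    z = scipy.stats.norm.ppf(0.975)
    for t in treatments:
        x = np.zeros(len(exog_names))
        for idx, nm in enumerate(exog_names):
            if nm == "Intercept":
                x[idx] = 1.0
            elif nm == f"C(treatment, Treatment('{spec.reference}'))[T.{t}]":
                x[idx] = 1.0
        est = float(x @ fe.values)
        se = float(np.sqrt(x @ cov.values @ x))
        lo, hi = est - z * se, est + z * se
        if link_inverse is not None:
            est, lo, hi = link_inverse(est), link_inverse(lo), link_inverse(hi)
        rows.append({"treatment": t, "mean": est, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Gaussian linear mixed model with treatment-coded fixed effects.

    Fits by REML via statsmodels MixedLM.  With both ``stand`` and ``block``
    random intercepts, blocks are the independence groups and stands enter
    as a variance component nested within block.  A response that the fixed
    effects explain perfectly (zero residual variance) is fit by OLS and
    flagged ``degenerate``; a constant response raises.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian family spec")
    df, response = _prepare(table, spec)
    if np.isclose(df[response].var(ddof=0), 0.0):
        raise ValueError("zero-variance response")
    formula = _fixed_formula(spec, response, df)
    treatments = sorted(df["treatment"].unique())

    # perfectly explained response: REML is undefined, fall back to OLS
    ols = smf.ols(formula, data=df).fit()
    if float(np.max(np.abs(ols.resid))) < 1e-10:
        return _ols_result(ols, df, treatments, spec, degenerate=True)

    re = tuple(spec.random_intercepts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if re == ():
            return _ols_result(ols, df, treatments, spec, degenerate=False)
        if set(re) == {"stand", "block"}:
            model = smf.mixedlm(
                formula, data=df, groups=df["block"], re_formula="1",
                vc_formula={"stand": "0 + C(stand)"},
            )
        elif re == ("stand",):
            model = smf.mixedlm(formula, data=df, groups=df["stand"])
        else:  # block only
            model = smf.mixedlm(formula, data=df, groups=df["block"])
        fit = model.fit(reml=True)

    fe_names = list(model.exog_names)
    fe = fit.fe_params
    cov = fit.cov_params().loc[fe_names, fe_names]
    z = scipy.stats.norm.ppf(0.975)
    coefs = pd.DataFrame(
        {
            "name": [_clean_name(n, spec) for n in fe_names],
            "estimate": fe.values,
            "se": fit.bse_fe.values,
            "ci_low": fe.values - z * fit.bse_fe.values,
            "ci_high": fe.values + z * fit.bse_fe.values,
        }
    )
    vc: dict[str, float] = {"residual": float(fit.scale)}
    if set(re) == {"stand", "block"}:
        vc["block"] = float(fit.cov_re.iloc[0, 0])
        vc["stand"] = float(fit.vcomp[0])
    elif re == ("stand",):
        vc["stand"] = float(fit.cov_re.iloc[0, 0])
    else:
        vc["block"] = float(fit.cov_re.iloc[0, 0])
    means = _treatment_means(fe, cov, fe_names, treatments, spec)
    return FitResult(
        coefficients=coefs,
        variance_components=vc,
        predicted_means=means,
        converged=bool(fit.converged),
        family="gaussian",
    )


def _ols_result(
    ols, df: pd.DataFrame, treatments: Sequence[str], spec: ModelSpec, degenerate: bool
) -> FitResult:
    z = scipy.stats.norm.ppf(0.975)
    fe = ols.params
    cov = ols.cov_params()
    coefs = pd.DataFrame(
        {
            "name": [_clean_name(n, spec) for n in fe.index],
            "estimate": fe.values,
            "se": ols.bse.values,
            "ci_low": fe.values - z * ols.bse.values,
            "ci_high": fe.values + z * ols.bse.values,
        }
    )
    means = _treatment_means(fe, cov, list(fe.index), treatments, spec)
    return FitResult(
        coefficients=coefs,
        variance_components={"residual": float(ols.scale)},
        predicted_means=means,
        converged=True,
        degenerate=degenerate,
        family="gaussian",
    )


def fit_poisson_glmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Poisson GLMM (log link) for cover-type-scale richness counts.

    Responses must already be integers (round Chao1 with
    :func:`round_half_up` first).  Stand and block random intercepts enter
    as variance components; estimation is MAP with Laplace posterior
    standard deviations (statsmodels ``PoissonBayesMixedGLM``), and 95%
    intervals are normal-approximation posterior intervals.
    """
    if spec.family != "poisson":
        raise ValueError("fit_poisson_glmm requires a poisson family spec")
    df, response = _prepare(table, spec)
    vals = df[response].to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError(
            "Poisson response must be integer; round Chao1 with round_half_up first"
        )
    df[response] = vals.astype(int)
    if (df[response] < 0).any():
        raise ValueError("Poisson response must be nonnegative")
    formula = _fixed_formula(spec, response, df)
    treatments = sorted(df["treatment"].unique())

    vcf = {}
    if "stand" in spec.random_intercepts:
        vcf["stand"] = "0 + C(stand)"
    if "block" in spec.random_intercepts:
        vcf["block"] = "0 + C(block)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PoissonBayesMixedGLM.from_formula(formula, vcf, df)
        # the optimizer's start point draws from the global RNG; pin it so
        # identical inputs give identical fits
        state = np.random.get_state()
        np.random.seed(1)
        try:
            fit = model.fit_map()
        finally:
            np.random.set_state(state)

    fe = pd.Series(fit.fe_mean, index=model.fep_names)
    sd = np.asarray(fit.fe_sd)
    z = scipy.stats.norm.ppf(0.975)
    coefs = pd.DataFrame(
        {
            "name": [_clean_name(n, spec) for n in model.fep_names],
            "estimate": fe.values,
            "se": sd,
            "ci_low": fe.values - z * sd,
            "ci_high": fe.values + z * sd,
        }
    )
    vc = {
        name: float(np.exp(2 * s))  # vcp are log-SDs
        for name, s in zip(model.vcp_names, fit.vcp_mean)
    }
    cov = pd.DataFrame(np.diag(sd**2), index=model.fep_names, columns=model.fep_names)
    means = _treatment_means(
        fe, cov, model.fep_names, treatments, spec, link_inverse=np.exp
    )
    return FitResult(
        coefficients=coefs,
        variance_components=vc,
        predicted_means=means,
        converged=True,
        family="poisson",
    )


def fit_vegetation_lmm(veg_table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Gaussian LMM for one vegetation cover group.

    Fixed effects: treatment (RA reference) and cover type (clearcut
    reference); random intercept for block.  Shrub cover is square-root
    transformed via ``spec.transform='sqrt'``.  Percent covers must lie in
    [0, 100]; an all-constant response is returned flagged degenerate
    rather than raised, since zero cover of a group is a legitimate field
    outcome.
    """
    df = veg_table.copy()
    resp = df[spec.response].astype(float)
    if ((resp < 0) | (resp > 100)).any():
        raise ValueError("cover values outside [0, 100]")
    if np.isclose(resp.var(ddof=0), 0.0):
        treatments = sorted(df["treatment"].unique())
        const = float(np.sqrt(resp.iloc[0]) if spec.transform == "sqrt" else resp.iloc[0])
        coefs = pd.DataFrame(
            {"name": ["Intercept"], "estimate": [const], "se": [0.0],
             "ci_low": [const], "ci_high": [const]}
        )
        means = pd.DataFrame(
            {"treatment": treatments, "mean": const, "ci_low": const, "ci_high": const}
        )
        return FitResult(
            coefficients=coefs,
            variance_components={"residual": 0.0},
            predicted_means=means,
            converged=False,
            degenerate=True,
        )
    veg_spec = ModelSpec(
        response=spec.response,
        family="gaussian",
        reference=spec.reference,
        include_year=False,
        include_cover_type=True,
        random_intercepts=("block",),
        transform=spec.transform,
    )
    return fit_lmm(df, veg_spec)
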