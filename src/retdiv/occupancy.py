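"""Hierarchical multi-species Royle-Nichols occupancy model fit by MCMC.

Occurrence is modelled through latent abundance: species i at subplot-year j
has N_ij ~ Poisson(lambda_ij), so occupancy is psi_ij = 1 - exp(-lambda_ij)
and per-night detection probability is abundance-induced,

    P(detected on one night) = 1 - (1 - r_ij)^N_ij,

where r_ij is the individual-level nightly capture probability.  Covariates:

    log lambda_ij = beta0_i + beta_i[class(j)] + alpha_stand(j)
    logit r_ij    = a0_i + a1_i * week_j   (week standardised)

with grid-location class (clearcut reference, upland patch, riparian patch,
rotation-aged forest) on abundance, a stand random intercept linking
repeated measures across years, and sampling week on detection.  Species
level parameters are drawn from community-level Normal distributions
(mean + SD hyperparameters), so effects are estimable by shrinkage even for
species rarely or never detected in a class.

Latent N is marginalised over 0..N_max (Poisson tail mass folded into the
top bin), so the posterior is sampled directly over the regression and
hyper-parameters with an adaptive Metropolis-within-Gibbs scheme:
random-walk updates for species-level parameters and stand intercepts
(proposal scales adapted to ~44% acceptance during warmup, then frozen),
conjugate Gibbs draws for community means, and log-scale random-walk
updates for community SDs.  Convergence is summarised by split-R-hat and
effective sample size (via arviz) for every retained parameter; model fit
by a posterior predictive check with the Freeman-Tukey discrepancy on
per-unit detection frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammainc, gammaincc, gammaln, logit
from scipy.stats import poisson

import arviz as az
from numba import njit

from retdiv.capture_data import DetectionArray, SUBPLOT_CLASSES

__all__ = [
    "MCMCConfig",
    "RNModelSpec",
    "RNPosterior",
    "rn_detection_prob",
    "occupancy_from_lambda",
    "cumulative_detection",
    "rn_marginal_loglik",
    "fit_community_rn",
    "posterior_predictive_check",
]


def rn_detection_prob(r: float, n: int) -> float:
    """Per-occasion species detection probability 1 - (1-r)^N.

    ``r`` is the individual-level detection probability and ``N`` the latent
    number of individuals present; with no individuals the species cannot be
    detected.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if n < 0 or int(n) != n:
        raise ValueError(f"N must be a nonnegative integer, got {n}")
    return float(-np.expm1(n * np.log1p(-r))) if r < 1.0 else float(n > 0)


def occupancy_from_lambda(lam: float) -> float:
    """Occupancy probability psi = 1 - exp(-lambda) implied by Poisson abundance."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    return float(-np.expm1(-lam))


def cumulative_detection(p: float, k: int) -> float:
    """Probability of at least one detection in ``k`` occasions, 1 - (1-p)^k."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k < 0:
        raise ValueError("k must be nonnegative")
    return float(1.0 - (1.0 - p) ** k)


def rn_marginal_loglik(
    history: Sequence[float],
    lam: float,
    r: float | Sequence[float],
    n_max: int = 50,
) -> float:
    """Log marginal likelihood of one detection history under the RN model.

    ``history`` holds 0/1 per occasion with NaN for missing (unsampled)
    occasions, which contribute nothing to the likelihood.  ``r`` may be a
    scalar or per-occasion vector.  The latent abundance N is summed over
    0..``n_max`` with the Poisson tail mass above ``n_max`` folded into the
    top term, so the result is a true (normalised) log-probability.
    """
    y = np.asarray(history, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("history is entirely missing")
    y = y[obs]
    r_arr = np.broadcast_to(np.asarray(r, dtype=float), np.asarray(history).shape)[obs]
    if np.any((r_arr < 0) | (r_arr > 1)):
        raise ValueError("r must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if lam == 0.0:
        return 0.0 if not y.any() else -np.inf

    n_grid = np.arange(n_max + 1)
    log_pois = n_grid * np.log(lam) - lam - gammaln(n_grid + 1)
    log_pois[-1] = poisson.logsf(n_max - 1, lam)  # fold the tail

    logq = np.log1p(-r_arr)  # log(1-r) per occasion, may be -inf at r=1
    with np.errstate(divide="ignore", invalid="ignore"):
        x = n_grid[:, None] * logq[None, :]  # log (1-r)^N
        log_det = np.where(x < 0, np.log1p(-np.exp(x)), -np.inf)
        contrib = np.where(y[None, :] > 0, log_det, x)
        contrib = np.where(np.isnan(contrib), 0.0, contrib)
    terms = log_pois + contrib.sum(axis=1)
    m = terms.max()
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.exp(terms - m).sum()))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; ``iterations`` counts post-warmup iterations per chain."""

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


@dataclass(frozen=True)
class RNModelSpec:
    """Model structure and priors for the community RN model.

    The first entry of ``subplot_classes`` is the reference class (no
    effect parameter).  Community means have Normal(0, prior_mean_sd^2)
    priors; community SDs and the stand-intercept SD have half-Normal
    priors with the given scales.
    """

    subplot_classes: tuple[str, ...] = SUBPLOT_CLASSES
    n_max: int = 50
    prior_mean_sd: float = 2.5
    prior_sd_scale: float = 1.0
    stand_sd_scale: float = 1.0
    stand_random_intercept: bool = True
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("N_max must be >= 1")
        if min(self.prior_mean_sd, self.prior_sd_scale, self.stand_sd_scale) <= 0:
            raise ValueError("prior scales must be positive")
        if len(self.subplot_classes) < 1:
            raise ValueError("at least one subplot class required")


@dataclass
class RNPosterior:
    """Posterior draws and summaries for the community RN model.

    ``draws`` arrays are shaped (chain, draw, ...): ``species_params``
    (..., n_species, P) with columns [beta0, class effects..., a0, a1],
    ``alpha`` (..., n_stands), ``mu``/``sigma`` (..., P), ``sigma_stand``.
    ``effects`` summarises per-species subplot-class effects with 95%
    credible intervals (the forest-plot layout); ``psi`` the derived
    occupancy per species and class at the average stand and week.
    ``diagnostics`` reports split-R-hat and bulk ESS for every parameter.
    """

    species: tuple[str, ...]
    class_names: tuple[str, ...]
    param_names: tuple[str, ...]
    stand_names: tuple[str, ...]
    draws: dict[str, np.ndarray]
    effects: pd.DataFrame
    psi: pd.DataFrame
    hyper_summary: pd.DataFrame
    diagnostics: pd.DataFrame
    converged: bool
    accept_rates: dict[str, float]
    spec: RNModelSpec
    bayes_p: float | None = None
    _data: dict = field(default_factory=dict, repr=False)

    @property
    def n_draws(self) -> int:
        v = next(iter(self.draws.values()))
        return v.shape[0] * v.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes flattened."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])


def _prepare_data(data: DetectionArray, spec: RNModelSpec) -> dict:
    y = data.y
    d = np.nansum(y, axis=2)  # detections per species x unit
    K = (~np.isnan(y)).sum(axis=2)  # realized occasions per unit (same all species)
    K_unit = K.max(axis=0)
    keep = K_unit > 0
    if not keep.all():
        d, K_unit = d[:, keep], K_unit[keep]
    units = data.units.reset_index(drop=True).loc[keep].reset_index(drop=True)

    classes = list(spec.subplot_classes)
    seen = set(units["subplot_class"])
    unknown = seen - set(classes)
    if unknown:
        raise ValueError(f"subplot classes not in model spec: {sorted(unknown)}")
    cls_idx = units["subplot_class"].map({c: i for i, c in enumerate(classes)}).to_numpy()

    stands = tuple(sorted(units["stand"].unique()))
    stand_idx = units["stand"].map({s: i for i, s in enumerate(stands)}).to_numpy()

    week = units["week"].to_numpy(dtype=float)
    wsd = week.std()
    week_std = (week - week.mean()) / wsd if wsd > 0 else np.zeros_like(week)

    C = len(classes)
    onehot = np.zeros((len(units), max(C - 1, 1)))
    for ci in range(1, C):
        onehot[cls_idx == ci, ci - 1] = 1.0
    return {
        "d": d.astype(float),
        "K": K_unit.astype(float),
        "units": units,
        "classes": classes,
        "cls_onehot": onehot[:, : C - 1] if C > 1 else np.zeros((len(units), 0)),
        "stands": stands,
        "stand_idx": stand_idx,
        "week_std": week_std,
        "lgamma_n": gammaln(np.arange(spec.n_max + 1) + 1.0),
        "dropped_units": int((~keep).sum()),
    }


def _batch_loglik(
    lam: np.ndarray, r: np.ndarray, d: np.ndarray, K: np.ndarray, n_max: int
) -> np.ndarray:
    """Per-unit RN log marginal likelihood, vectorised over leading axes.

    Valid when r is constant across a unit's occasions (week enters at the
    unit level), so (d, K) are sufficient.  Shapes broadcast: lam/r/d of
    shape (..., J), K of shape (J,).
    """
    n_grid = np.arange(n_max + 1)
    loglam = np.log(lam)
    log_pois = (
        n_grid * loglam[..., None] - lam[..., None] - gammaln(n_grid + 1)
    )
    # fold the Poisson tail into the top bin: P(N >= n_max) = gammainc(n_max, lam)
    with np.errstate(divide="ignore"):
        log_pois[..., -1] = np.log(gammainc(n_max, lam))
    logq = np.log1p(-r)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = n_grid * logq[..., None]  # (..., J, N): log (1-r)^N
        x[..., 0] = 0.0  # 0 * log(0) guard when r = 1
        log_det = np.where(x < 0, np.log1p(-np.exp(x)), -np.inf)
        det_term = np.where(d[..., None] > 0, d[..., None] * log_det, 0.0)
        nondet = (K - d)[..., None] * x
        nondet = np.where((K - d)[..., None] > 0, nondet, 0.0)
    terms = log_pois + det_term + nondet
    m = terms.max(axis=-1)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.exp(terms - m[..., None]).sum(axis=-1))
    return np.where(np.isfinite(m), out, -np.inf)


@njit(cache=True)
def _rn_loglik_kernel(lam, r, d, K, logtail, lgamma_n, n_hi):  # pragma: no cover
    """Jitted per-(species, unit) RN log marginal; numerics match _batch_loglik.

    ``n_hi[i, j]`` is the per-cell truncation bound (Poisson mass above it is
    folded into the top bin via ``logtail``); keeping the bound adaptive to
    lambda spares the long tail loop for the many rare species.
    """
    S, J = lam.shape
    out = np.empty((S, J))
    for i in range(S):
        for j in range(J):
            la = lam[i, j]
            ri = r[i, j]
            dd = d[i, j]
            kk = K[j]
            hi = n_hi[i, j]
            logla = np.log(la)
            q = 1.0 - ri
            logq = np.log(q) if q > 0.0 else -np.inf
            m = -np.inf
            acc = 0.0
            qn = 1.0
            for n in range(hi + 1):
                if n > 0:
                    qn *= q
                if n == hi:
                    lp = logtail[i, j]
                else:
                    lp = n * logla - la - lgamma_n[n]
                if n == 0:
                    if dd > 0.0:
                        continue
                    w = 0.0
                else:
                    w = 0.0
                    if dd > 0.0:
                        if qn >= 1.0:
                            continue
                        w = dd * np.log1p(-qn)
                    if kk - dd > 0.0:
                        if logq == -np.inf:
                            continue
                        w += (kk - dd) * n * logq
                t = lp + w
                if t == -np.inf:
                    continue
                if t > m:
                    acc = acc * np.exp(m - t) + 1.0
                    m = t
                else:
                    acc += np.exp(t - m)
            out[i, j] = m + np.log(acc) if m > -np.inf else -np.inf
    return out


def _full_loglik(theta, alpha, prep, n_max):
    """Cached-likelihood matrix L[i, j] for all species x units.

    Valid because week (hence r) is constant across a unit's occasions, so
    (detections, occasions) are sufficient per species-unit.
    """
    onehot = prep["cls_onehot"]
    P = theta.shape[1]
    eff = theta[:, 1 : P - 2] @ onehot.T if onehot.shape[1] else 0.0
    # cap log-lambda at 30 (far beyond plausible abundance) to avoid overflow
    lam = np.exp(
        np.minimum(theta[:, [0]] + eff + alpha[prep["stand_idx"]][None, :], 30.0)
    )
    r = expit(theta[:, [P - 2]] + theta[:, [P - 1]] * prep["week_std"][None, :])
    # adaptive truncation: mass above lam + 10*sqrt(lam) + 15 is < 1e-12
    n_hi = np.minimum(n_max, (lam + 10.0 * np.sqrt(lam) + 15.0).astype(np.int64))
    with np.errstate(divide="ignore"):
        logtail = np.log(gammainc(n_hi, lam))
    return _rn_loglik_kernel(
        lam, r, prep["d"], prep["K"], logtail, prep["lgamma_n"], n_hi
    )


def fit_community_rn(data: DetectionArray, spec: RNModelSpec) -> RNPosterior:
    """Fit the hierarchical community RN model by adaptive MCMC.

    Runs ``spec.mcmc.chains`` independent chains (seeded deterministically
    from ``spec.mcmc.seed``), each with ``warmup`` adaptation iterations
    discarded and ``iterations`` retained (thinned).  Units with no realized
    occasions are dropped.  Non-convergence (any split-R-hat >= 1.1) is
    flagged on the result, never silent.
    """
    if data.n_species == 0:
        raise ValueError("detection data contain no species")
    prep = _prepare_data(data, spec)
    d, K = prep["d"], prep["K"]
    S, J = d.shape
    C = len(prep["classes"])
    P = 1 + (C - 1) + 2
    n_stands = len(prep["stands"])
    use_stand = spec.stand_random_intercept and n_stands > 1

    param_names = (
        ["log_lambda_intercept"]
        + [f"effect_{c}" for c in prep["classes"][1:]]
        + ["detection_intercept", "detection_week"]
    )

    mc = spec.mcmc
    n_save = mc.iterations // mc.thin
    save = {
        "species_params": np.empty((mc.chains, n_save, S, P)),
        "alpha": np.empty((mc.chains, n_save, n_stands)),
        "mu": np.empty((mc.chains, n_save, P)),
        "sigma": np.empty((mc.chains, n_save, P)),
        "sigma_stand": np.empty((mc.chains, n_save)),
    }
    accept_tot = {"theta": 0, "alpha": 0}
    prop_tot = {"theta": 0, "alpha": 0}

    # data-informed initial centre, jittered per chain
    naive_occ = np.clip((d > 0).mean(axis=1), 0.03, 0.9)
    beta0_init = np.log(-np.log1p(-naive_occ))
    prior_mean_var = spec.prior_mean_sd**2
    stand_idx = prep["stand_idx"]

    def _halfnorm_logpdf(s, scale):
        return -0.5 * (s / scale) ** 2  # constants cancel in MH ratios

    for chain in range(mc.chains):
        rng = np.random.default_rng([int(mc.seed), chain])
        theta = np.zeros((S, P))
        theta[:, 0] = beta0_init + rng.normal(0, 0.1, S)
        theta[:, P - 2] = logit(0.3) + rng.normal(0, 0.1, S)
        theta[:, 1 : P - 2] = rng.normal(0, 0.1, (S, P - 3))
        theta[:, P - 1] = rng.normal(0, 0.1, S)
        alpha = np.zeros(n_stands)
        mu = theta.mean(axis=0)
        sigma = np.full(P, 0.5)
        sigma_stand = 0.3

        L = _full_loglik(theta, alpha, prep, spec.n_max)

        s_theta = np.full((S, P), 0.3)
        s_ridge = np.full(S, 0.4)
        s_alpha = np.full(n_stands, 0.2)
        s_logsig = np.full(P, 0.3)
        s_logsig_nc = np.full(P, 0.3)
        s_logsig_stand = 0.3
        s_logsig_stand_nc = 0.3

        total_iter = mc.warmup + mc.iterations
        saved = 0
        for t in range(total_iter):
            adapting = t < mc.warmup
            gamma = 1.0 / (1.0 + t) ** 0.6 if adapting else 0.0

            # --- species-level parameters: per column p, propose for every
            # species at once (their posteriors are independent given the
            # hyperparameters and stand intercepts) and accept per species
            for p in range(P):
                prop = theta.copy()
                prop[:, p] = theta[:, p] + rng.normal(0, s_theta[:, p])
                L_new = _full_loglik(prop, alpha, prep, spec.n_max)
                dll = (L_new - L).sum(axis=1)
                dprior = (
                    (theta[:, p] - mu[p]) ** 2 - (prop[:, p] - mu[p]) ** 2
                ) / (2 * sigma[p] ** 2)
                acc = np.log(rng.random(S)) < dll + dprior
                theta[acc, p] = prop[acc, p]
                L[acc] = L_new[acc]
                if adapting:
                    s_theta[:, p] *= np.exp(gamma * (acc.astype(float) - 0.44))
                else:
                    prop_tot["theta"] += S
                    accept_tot["theta"] += int(acc.sum())

            # --- joint abundance/detection ridge: lambda and r trade off
            # (similar data fit with higher abundance and lower detection),
            # so move beta0 and the detection intercept in opposition
            delta = rng.normal(0, s_ridge)
            prop = theta.copy()
            prop[:, 0] = theta[:, 0] + delta
            prop[:, P - 2] = theta[:, P - 2] - delta
            L_new = _full_loglik(prop, alpha, prep, spec.n_max)
            dll = (L_new - L).sum(axis=1)
            dprior = (
                (theta[:, 0] - mu[0]) ** 2 - (prop[:, 0] - mu[0]) ** 2
            ) / (2 * sigma[0] ** 2) + (
                (theta[:, P - 2] - mu[P - 2]) ** 2
                - (prop[:, P - 2] - mu[P - 2]) ** 2
            ) / (2 * sigma[P - 2] ** 2)
            acc = np.log(rng.random(S)) < dll + dprior
            theta[acc, 0] = prop[acc, 0]
            theta[acc, P - 2] = prop[acc, P - 2]
            L[acc] = L_new[acc]
            if adapting:
                s_ridge *= np.exp(gamma * (acc.astype(float) - 0.44))

            # --- stand random intercepts: stands own disjoint unit sets, so
            # propose all jointly and accept independently per stand
            if use_stand:
                a_prop = alpha + rng.normal(0, s_alpha)
                L_new = _full_loglik(theta, a_prop, prep, spec.n_max)
                unit_delta = (L_new - L).sum(axis=0)
                dll = np.bincount(stand_idx, weights=unit_delta, minlength=n_stands)
                dprior = (alpha**2 - a_prop**2) / (2 * sigma_stand**2)
                acc = np.log(rng.random(n_stands)) < dll + dprior
                alpha[acc] = a_prop[acc]
                unit_acc = acc[stand_idx]
                L[:, unit_acc] = L_new[:, unit_acc]
                if adapting:
                    s_alpha *= np.exp(gamma * (acc.astype(float) - 0.44))
                else:
                    prop_tot["alpha"] += n_stands
                    accept_tot["alpha"] += int(acc.sum())

            # --- community means: conjugate Gibbs
            prec = S / sigma**2 + 1.0 / prior_mean_var
            mean = (theta.sum(axis=0) / sigma**2) / prec
            mu = rng.normal(mean, 1.0 / np.sqrt(prec))

            # --- community SDs: centered random walk on log scale ...
            for p in range(P):
                ls_new = np.log(sigma[p]) + rng.normal(0, s_logsig[p])
                s_new = np.exp(ls_new)
                sq = ((theta[:, p] - mu[p]) ** 2).sum()
                dpost = (
                    -S * (ls_new - np.log(sigma[p]))
                    - sq / (2 * s_new**2)
                    + sq / (2 * sigma[p] ** 2)
                    + _halfnorm_logpdf(s_new, spec.prior_sd_scale)
                    - _halfnorm_logpdf(sigma[p], spec.prior_sd_scale)
                    + ls_new
                    - np.log(sigma[p])
                )
                acc = np.log(rng.random()) < dpost
                if acc:
                    sigma[p] = s_new
                if adapting:
                    s_logsig[p] *= np.exp(gamma * (float(acc) - 0.44))

            # ... interwoven with a non-centered step: rescale every species'
            # deviation from the community mean together with the SD, so the
            # scale can move even when the deviations are informative (breaks
            # the centered-parameterization funnel)
            for p in range(P):
                ls_new = np.log(sigma[p]) + rng.normal(0, s_logsig_nc[p])
                s_new = np.exp(ls_new)
                prop = theta.copy()
                prop[:, p] = mu[p] + (theta[:, p] - mu[p]) * (s_new / sigma[p])
                L_new = _full_loglik(prop, alpha, prep, spec.n_max)
                dpost = (
                    (L_new - L).sum()
                    + _halfnorm_logpdf(s_new, spec.prior_sd_scale)
                    - _halfnorm_logpdf(sigma[p], spec.prior_sd_scale)
                    + ls_new
                    - np.log(sigma[p])
                )
                acc = np.log(rng.random()) < dpost
                if acc:
                    sigma[p] = s_new
                    theta = prop
                    L = L_new
                if adapting:
                    s_logsig_nc[p] *= np.exp(gamma * (float(acc) - 0.234))

            if use_stand:
                ls_new = np.log(sigma_stand) + rng.normal(0, s_logsig_stand)
                s_new = np.exp(ls_new)
                sq = (alpha**2).sum()
                dpost = (
                    -n_stands * (ls_new - np.log(sigma_stand))
                    - sq / (2 * s_new**2)
                    + sq / (2 * sigma_stand**2)
                    + _halfnorm_logpdf(s_new, spec.stand_sd_scale)
                    - _halfnorm_logpdf(sigma_stand, spec.stand_sd_scale)
                    + ls_new
                    - np.log(sigma_stand)
                )
                acc = np.log(rng.random()) < dpost
                if acc:
                    sigma_stand = s_new
                if adapting:
                    s_logsig_stand *= np.exp(gamma * (float(acc) - 0.44))

                # non-centered counterpart: rescale all stand intercepts
                ls_new = np.log(sigma_stand) + rng.normal(0, s_logsig_stand_nc)
                s_new = np.exp(ls_new)
                a_prop = alpha * (s_new / sigma_stand)
                L_new = _full_loglik(theta, a_prop, prep, spec.n_max)
                dpost = (
                    (L_new - L).sum()
                    + _halfnorm_logpdf(s_new, spec.stand_sd_scale)
                    - _halfnorm_logpdf(sigma_stand, spec.stand_sd_scale)
                    + ls_new
                    - np.log(sigma_stand)
                )
                acc = np.log(rng.random()) < dpost
                if acc:
                    sigma_stand = s_new
                    alpha = a_prop
                    L = L_new
                if adapting:
                    s_logsig_stand_nc *= np.exp(gamma * (float(acc) - 0.234))

            if not adapting and (t - mc.warmup) % mc.thin == 0 and saved < n_save:
                save["species_params"][chain, saved] = theta
                save["alpha"][chain, saved] = alpha
                save["mu"][chain, saved] = mu
                save["sigma"][chain, saved] = sigma
                save["sigma_stand"][chain, saved] = sigma_stand
                saved += 1

    return _summarise(save, prep, spec, param_names, accept_tot, prop_tot, data)


def _summarise(save, prep, spec, param_names, accept_tot, prop_tot, data) -> RNPosterior:
    species = data.species
    classes = tuple(prep["classes"])
    C = len(classes)
    P = 1 + (C - 1) + 2

    arviz_logger = logging.getLogger("arviz")
    old_level = arviz_logger.level
    arviz_logger.setLevel(logging.ERROR)  # single-chain runs trip a shape notice
    try:
        idata = az.from_dict(
            posterior={
                "species_params": save["species_params"],
                "alpha": save["alpha"],
                "mu": save["mu"],
                "sigma": save["sigma"],
                "sigma_stand": save["sigma_stand"],
            }
        )
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    finally:
        arviz_logger.setLevel(old_level)

    diag_rows = []
    for var in ("species_params", "alpha", "mu", "sigma", "sigma_stand"):
        r = np.atleast_1d(np.asarray(rhat[var]).ravel())
        e = np.atleast_1d(np.asarray(ess[var]).ravel())
        for k, (rv, ev) in enumerate(zip(r, e)):
            diag_rows.append({"parameter": f"{var}[{k}]", "rhat": float(rv), "ess": float(ev)})
    diagnostics = pd.DataFrame(diag_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN R-hat with a single chain
        max_rhat = float(np.nanmax(diagnostics["rhat"]))
    converged = bool(max_rhat < 1.1) if np.isfinite(max_rhat) else False

    sp = save["species_params"]  # (chains, draws, S, P)
    flat = sp.reshape(-1, *sp.shape[2:])
    eff_rows = []
    for i, sp_code in enumerate(species):
        for ci, cname in enumerate(classes[1:]):
            draws = flat[:, i, 1 + ci]
            lo, hi = np.percentile(draws, [2.5, 97.5])
            eff_rows.append(
                {
                    "species": sp_code,
                    "class": cname,
                    "mean": float(draws.mean()),
                    "sd": float(draws.std(ddof=1)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    effects = pd.DataFrame(eff_rows)

    psi_rows = []
    for i, sp_code in enumerate(species):
        for ci, cname in enumerate(classes):
            eta = flat[:, i, 0] + (flat[:, i, ci] if ci >= 1 else 0.0)
            psi_draws = -np.expm1(-np.exp(eta))
            lo, hi = np.percentile(psi_draws, [2.5, 97.5])
            psi_rows.append(
                {
                    "species": sp_code,
                    "class": cname,
                    "psi_mean": float(psi_draws.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    psi = pd.DataFrame(psi_rows)

    hyp_rows = []
    for p, pname in enumerate(param_names):
        mu_d = save["mu"][..., p].ravel()
        sd_d = save["sigma"][..., p].ravel()
        hyp_rows.append(
            {
                "parameter": f"mu_{pname}",
                "mean": float(mu_d.mean()),
                "ci_low": float(np.percentile(mu_d, 2.5)),
                "ci_high": float(np.percentile(mu_d, 97.5)),
            }
        )
        hyp_rows.append(
            {
                "parameter": f"sigma_{pname}",
                "mean": float(sd_d.mean()),
                "ci_low": float(np.percentile(sd_d, 2.5)),
                "ci_high": float(np.percentile(sd_d, 97.5)),
            }
        )
    ss = save["sigma_stand"].ravel()
    hyp_rows.append(
        {
            "parameter": "sigma_stand",
            "mean": float(ss.mean()),
            "ci_low": float(np.percentile(ss, 2.5)),
            "ci_high": float(np.percentile(ss, 97.5)),
        }
    )
    hyper_summary = pd.DataFrame(hyp_rows)

    acc = {
        k: (accept_tot[k] / prop_tot[k] if prop_tot[k] else float("nan"))
        for k in accept_tot
    }
    return RNPosterior(
        species=species,
        class_names=classes[1:],
        param_names=tuple(param_names),
        stand_names=prep["stands"],
        draws=save,
        effects=effects,
        psi=psi,
        hyper_summary=hyper_summary,
        diagnostics=diagnostics,
        converged=converged,
        accept_rates=acc,
        spec=spec,
        _data=prep,
    )


def posterior_predictive_check(
    fit: RNPosterior,
    data: DetectionArray | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> float:
    """Bayesian p-value from a Freeman-Tukey posterior predictive check.

    For each retained posterior draw (subsampled to ``n_draws``), the
    discrepancy T = sum_ij (sqrt(d_ij) - sqrt(E[d_ij]))^2 on per-unit
    detection counts is computed for the observed data and for a dataset
    replicated from that draw (N ~ Poisson(lambda), detections ~
    Binomial(K, 1-(1-r)^N)).  The returned Bayesian p-value is the fraction
    of draws where the replicated discrepancy is at least the observed one;
    values near 0 or 1 indicate lack of fit.
    """
    prep = fit._data if data is None else _prepare_data(data, fit.spec)
    if not prep:
        raise ValueError("fit carries no data; pass the DetectionArray explicitly")
    sp = fit.stacked("species_params")
    al = fit.stacked("alpha")
    total = sp.shape[0]
    if total == 0:
        raise ValueError("posterior has no retained draws")
    rng = np.random.default_rng(seed)
    take = (
        np.arange(total)
        if total <= n_draws
        else np.sort(rng.choice(total, size=n_draws, replace=False))
    )

    d_obs = prep["d"]
    K = prep["K"]
    onehot = prep["cls_onehot"]
    week = prep["week_std"]
    stand_idx = prep["stand_idx"]
    S, J = d_obs.shape
    P = sp.shape[-1]

    n_max = fit.spec.n_max
    n_exceed = 0
    for t in take:
        theta = sp[t]
        alpha = al[t]
        eff = theta[:, 1 : P - 2] @ onehot.T if P > 3 else 0.0
        lam = np.exp(np.minimum(theta[:, [0]] + eff + alpha[stand_idx], 30.0))
        r = expit(theta[:, [P - 2]] + theta[:, [P - 1]] * week)
        # expectation and replication under the same truncated-latent model
        # the likelihood uses: N ~ Poisson(lam) with mass above n_hi folded
        # into n_hi, so E[(1-r)^N] has a closed form via Poisson(lam*(1-r))
        n_hi = np.minimum(n_max, (lam + 10.0 * np.sqrt(lam) + 15.0).astype(np.int64))
        q = 1.0 - r
        mean_qn = np.exp(-lam * r) * gammaincc(n_hi, lam * q) + q**n_hi * gammainc(
            n_hi, lam
        )
        e_det = K * (1.0 - mean_qn)
        t_obs = np.sum((np.sqrt(d_obs) - np.sqrt(e_det)) ** 2)
        n_lat = np.minimum(rng.poisson(lam), n_hi)
        p_det = -np.expm1(n_lat * np.log1p(-np.minimum(r, 1 - 1e-15)))
        d_rep = rng.binomial(np.broadcast_to(K.astype(int), (S, J)), p_det)
        t_rep = np.sum((np.sqrt(d_rep) - np.sqrt(e_det)) ** 2)
        n_exceed += int(t_rep >= t_obs)
    bayes_p = n_exceed / len(take)
    fit.bayes_p = float(bayes_p)
    return float(bayes_p)
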