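"""Symmetric binary-probit social-relations network regression.

The model for the undirected binary outcome y_ij (dyad (i, j) bred together
at least once in the focal period) with a lagged dyadic covariate x_ij
(indicator of co-breeding in the previous period) is a probit regression with
additive individual random effects:

    z_ij = beta0 + beta_dyad * x_ij + a_i + a_j + e_ij
    y_ij = 1(z_ij > 0),   a_i ~ N(0, sigma2_a),   e_ij ~ N(0, 1)

The dyadic error variance is fixed at 1 for probit identification. The
additive effects a_i absorb individual gregariousness (how often an
individual co-occurs with anyone), so beta_dyad isolates dyad-specific
persistence — the social-tie signal — from mere sociability.

Inference is by Gibbs sampling: latent z from truncated normals, regression
coefficients and additive effects from their conjugate normal full
conditionals, sigma2_a from its conjugate inverse-gamma. Missing dyads
(either member unobserved in the focal period) are imputed at every
iteration from their conditional distribution given current parameters,
which is valid when individuals are missing at random.

Coefficients are summarized in the social-relations reporting convention:
posterior mean (pmean), posterior standard deviation (psd), nominal z-score
z = pmean/psd, and the two-sided normal tail probability p = 2(1 - Phi(|z|)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr, ndtri

from cobreed.association import DyadState, Sociomatrix
from cobreed.errors import (
    ConfigError,
    DataError,
    DegenerateSummaryError,
    NonIdentifiableError,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings.

    ``n_iter`` total iterations, the first ``burn_in`` discarded, keeping
    every ``thin``-th retained draw. The default is a desk-scale chain that
    mixes well for the additive-effects probit on a few thousand dyads; use
    :func:`production_scale` for a long production chain (100,000 iterations,
    burn-in 500). ``fix_sigma2_a`` pins the additive-effect variance (0
    disables the random effects entirely), mainly for cross-checks against
    plain probit regression.
    """

    n_iter: int = 4000
    burn_in: int = 500
    thin: int = 5
    seed: int = 0
    prior_beta_var: float = 100.0
    prior_var_shape: float = 2.0
    prior_var_scale: float = 1.0
    fix_sigma2_a: float | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.prior_beta_var <= 0:
            raise ConfigError("prior_beta_var must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def production_scale(seed: int = 0) -> McmcConfig:
    """Long-chain preset: 100,000 iterations, burn-in 500, thin 25."""
    return McmcConfig(n_iter=100_000, burn_in=500, thin=25, seed=seed)


def reduced_scale(seed: int = 0) -> McmcConfig:
    """Short chain for permutation replicates (null-location precision only)."""
    return McmcConfig(n_iter=2000, burn_in=200, thin=2, seed=seed)


@dataclass
class AmeData:
    """Outcome and lagged-predictor dyad matrices on one individual ordering.

    ``y``: N x N symmetric float matrix with entries 1 (together at least
    once), 0 (apart) or NaN (missing). ``x``: same layout for the
    prior-period together indicator; NaN not allowed (resolve the predictor's
    missingness when building, see :func:`ame_data_from_sociomatrices`).
    """

    y: np.ndarray
    x: np.ndarray
    individuals: list[str] = field(default_factory=list)
    n_x_imputed_zero: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y.shape != self.x.shape or self.y.ndim != 2:
            raise DataError("y and x must be square matrices of equal shape")
        if self.y.shape[0] != self.y.shape[1]:
            raise DataError("y must be square")

    @property
    def n(self) -> int:
        return self.y.shape[0]


def _state_to_binary(s: Sociomatrix) -> np.ndarray:
    out = s.state.astype(float)
    out[s.state == int(DyadState.MISSING)] = np.nan
    return out


def ame_data_from_sociomatrices(
    outcome: Sociomatrix,
    predictor: Sociomatrix,
    xdyad_missing: str = "zero",
) -> AmeData:
    """Build the regression data from an outcome and a predictor sociomatrix.

    ``xdyad_missing`` controls the predictor's missing dyads: "zero" (default)
    codes them as 0 — no evidence of prior association — and reports the
    count; "listwise" drops them by marking the outcome missing as well, so
    they leave the likelihood.
    """
    if outcome.individuals != predictor.individuals:
        raise DataError("outcome and predictor must share the individual ordering")
    y = _state_to_binary(outcome)
    x = _state_to_binary(predictor)
    iu, ju = np.triu_indices(len(outcome.individuals), k=1)
    n_missing_x = int(np.isnan(x[iu, ju]).sum())
    if xdyad_missing == "zero":
        x = np.nan_to_num(x, nan=0.0)
    elif xdyad_missing == "listwise":
        y[np.isnan(x)] = np.nan
        x = np.nan_to_num(x, nan=0.0)
    else:
        raise ConfigError("xdyad_missing must be 'zero' or 'listwise'")
    return AmeData(
        y=y, x=x, individuals=list(outcome.individuals),
        n_x_imputed_zero=n_missing_x if xdyad_missing == "zero" else 0,
    )


@dataclass
class CoefficientSummary:
    """Posterior mean, SD, nominal z-score and two-sided normal p-value."""

    pmean: float
    psd: float
    z: float
    p_value: float


@dataclass
class AmeFit:
    """Retained posterior draws and coefficient summaries."""

    draws: dict[str, np.ndarray]
    summaries: dict[str, CoefficientSummary]
    imputation_rate: float
    rhat: dict[str, float]
    warnings: list[str]
    config: McmcConfig

    @property
    def converged(self) -> bool:
        return not any(w.startswith("convergence") for w in self.warnings)


def posterior_summary(draws: np.ndarray) -> CoefficientSummary:
    """Summarize retained draws as pmean, psd, z = pmean/psd, p = 2(1-Phi(|z|))."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise DegenerateSummaryError("need at least 2 retained draws")
    pmean = float(np.mean(draws))
    psd = float(np.std(draws, ddof=1))
    if psd == 0.0:
        raise DegenerateSummaryError("zero posterior spread; z undefined")
    z = pmean / psd
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    return CoefficientSummary(pmean=pmean, psd=psd, z=z, p_value=p)


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor on one chain of draws."""
    import arviz as az

    half = len(x) // 2
    chains = np.stack([x[:half], x[half : 2 * half]])
    with np.errstate(invalid="ignore"):
        return float(az.rhat(chains))


def fit_ame_probit(
    data: AmeData,
    config: McmcConfig,
    rng: np.random.Generator | None = None,
) -> AmeFit:
    """Gibbs sampler for the symmetric additive-effects probit regression.

    Cycles (1) latent z_ij from truncated normals given observed y_ij, (2)
    for missing y_ij an unconstrained draw of z_ij from the current model
    (equivalently, imputing y then z), (3) the coefficient vector
    (beta0, beta_dyad) from its conjugate normal full conditional, (4) the
    additive effects jointly from their structured normal full conditional,
    (5) sigma2_a from its conjugate inverse-gamma. Fully reproducible given
    ``config.seed`` (or an explicit generator).
    """
    n = data.n
    if n < 3:
        raise DataError(f"need at least 3 individuals, got {n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    iu, ju = np.triu_indices(n, k=1)
    y = data.y[iu, ju]
    x = data.x[iu, ju]
    if np.isnan(x).any():
        raise DataError("x may not contain missing values; see ame_data_from_sociomatrices")
    obs = ~np.isnan(y)
    n_dyads = len(y)
    observed_vals = np.unique(y[obs])
    if len(observed_vals) < 2:
        raise NonIdentifiableError(
            "observed outcome is constant; intercept-only separation — "
            "the model is not identifiable"
        )
    is_one = obs & (y == 1.0)
    is_zero = obs & (y == 0.0)

    design = np.column_stack([np.ones(n_dyads), x])
    q_beta = design.T @ design + np.eye(2) / config.prior_beta_var
    l_beta = np.linalg.cholesky(q_beta)

    fix = config.fix_sigma2_a
    beta = np.zeros(2)
    a = np.zeros(n)
    sigma2 = fix if fix is not None else 1.0
    use_additive = fix is None or fix > 0

    n_keep = config.n_retained
    out = {
        "beta0": np.empty(n_keep),
        "beta_dyad": np.empty(n_keep),
        "sigma2_a": np.empty(n_keep),
    }

    keep = 0
    for it in range(1, config.n_iter + 1):
        m = beta[0] + beta[1] * x + a[iu] + a[ju]
        # 1-2. latent scale: truncated normal where observed, free where missing
        u = rng.random(n_dyads)
        p_neg = ndtr(-m)  # P(z < 0 | m)
        t = np.where(is_one, p_neg + u * (1.0 - p_neg), np.where(is_zero, u * p_neg, u))
        z = m + ndtri(np.clip(t, _EPS, 1.0 - _EPS))

        # 3. coefficients: conjugate normal given z and a
        resid = z - a[iu] - a[ju]
        mean_beta = np.linalg.solve(q_beta, design.T @ resid)
        beta = mean_beta + np.linalg.solve(l_beta.T, rng.standard_normal(2))

        # 4. additive effects jointly: precision Q = c*I + 1 1', with
        #    c = (n - 2) + 1/sigma2 (each a_i enters n-1 dyads)
        if use_additive:
            r2 = z - beta[0] - beta[1] * x
            b = np.bincount(iu, weights=r2, minlength=n) + np.bincount(
                ju, weights=r2, minlength=n
            )
            c = (n - 2) + 1.0 / sigma2
            mean_a = b / c - b.sum() / (c * (c + n))
            eps = rng.standard_normal(n)
            em = eps.mean()
            a = mean_a + (eps - em) / np.sqrt(c) + em / np.sqrt(c + n)
            # 5. variance of additive effects (inverse-gamma conjugacy)
            if fix is None:
                shape = config.prior_var_shape + n / 2.0
                scale = config.prior_var_scale + float(a @ a) / 2.0
                sigma2 = scale / rng.gamma(shape)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            if keep < n_keep:
                out["beta0"][keep] = beta[0]
                out["beta_dyad"][keep] = beta[1]
                out["sigma2_a"][keep] = sigma2
                keep += 1

    summaries = {
        "intercept": posterior_summary(out["beta0"]),
        ".dyad": posterior_summary(out["beta_dyad"]),
    }
    warnings_list: list[str] = []
    rhat: dict[str, float] = {}
    monitored = ["beta0", "beta_dyad"] + (["sigma2_a"] if fix is None and use_additive else [])
    for name in monitored:
        r = _split_rhat(out[name])
        rhat[name] = r
        if np.isfinite(r) and r > config.rhat_threshold:
            warnings_list.append(
                f"convergence: split-chain R-hat for {name} is {r:.3f} "
                f"(> {config.rhat_threshold}); lengthen the chain"
            )
    for w in warnings_list:
        logger.warning(w)

    return AmeFit(
        draws=out,
        summaries=summaries,
        imputation_rate=float((~obs).sum() / n_dyads),
        rhat=rhat,
        warnings=warnings_list,
        config=config,
    )


def predict_tie_probability(fit: AmeFit, x: float) -> float:
    """Posterior-mean probability of co-breeding at covariate value ``x``.

    Marginalizes the two additive effects analytically — a_i + a_j ~
    N(0, 2 sigma2_a) folds into the probit scale — and averages
    Phi((beta0 + beta_dyad*x) / sqrt(1 + 2 sigma2_a)) over retained draws.
    """
    b0 = fit.draws["beta0"]
    b1 = fit.draws["beta_dyad"]
    s2 = fit.draws["sigma2_a"]
    return float(np.mean(ndtr((b0 + b1 * x) / np.sqrt(1.0 + 2.0 * s2))))


def summaries_as_table(fit: AmeFit) -> Mapping[str, Mapping[str, float]]:
    """Coefficient summaries keyed like a results table (pmean, psd, z-stat, P value)."""
    return {
        name: {
            "pmean": s.pmean,
            "psd": s.psd,
            "z-stat": s.z,
            "P value": s.p_value,
        }
        for name, s in fit.summaries.items()
    }
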