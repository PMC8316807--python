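"""Bayesian Gaussian mixed models with nested random effects.

Fits, by conjugate Gibbs sampling, the individual-level model

    log10(rate_i) = x_iᵀ β + u_species(i) + u_group(i) + ε_i

with exchangeable random intercepts for species and for group nested in
species, a diffuse normal prior on the fixed effects (mean 0, variance
1e10 per coefficient) and univariate inverse-Wishart priors on each
variance component (V = 1, ν = 0.002 — equivalently inverse-gamma with
shape ν/2 and scale νV/2).  All full conditionals are conjugate: the fixed
effects are multivariate normal, each random-intercept block normal, each
variance inverse-gamma.  Summaries are posterior means, central 95%
credible intervals and pMCMC (twice the smaller tail proportion of draws
relative to zero, floored at one draw).

Nesting is the caller's responsibility: group labels must be unique within
species (the pipeline indexes groups as species×group) so identical group
names in different species never pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tables import ValidationError
from .vocal import VocalRateRecord

DEFAULT_LOG_OFFSET = 0.01  # bouts/hour added before log10 for zero rates


@dataclass(frozen=True)
class PriorConfig:
    """Priors: diffuse normal on β; inverse-Wishart (V, ν) on variances."""

    beta_mean: float = 0.0
    beta_variance: float = 1e10
    V: float = 1.0
    nu: float = 0.002

    def __post_init__(self) -> None:
        if self.V <= 0 or self.nu <= 0 or self.beta_variance <= 0:
            raise ValidationError("prior scales must be positive")


@dataclass(frozen=True)
class ChainConfig:
    n_iter: int = 13000
    burn_in: int = 3000
    thin: int = 10
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def __post_init__(self) -> None:
        if self.n_retained < 100:
            raise ValidationError(
                f"chain retains {self.n_retained} samples; need >= 100")


@dataclass
class FixedEffectSummary:
    name: str
    posterior_mean: float
    ci_lower: float
    ci_upper: float
    pmcmc: float


@dataclass
class PosteriorResult:
    """Posterior summaries and retained draws from one fitted model."""

    fixed: list[FixedEffectSummary]
    var_species: float
    var_group: float
    var_residual: float
    variance_partition: dict[str, float]
    beta_draws: np.ndarray       # retained draws, shape (n_kept, p)
    var_draws: np.ndarray        # columns: species, group, residual
    fixed_names: list[str] = field(default_factory=list)


def prepare_response(rates: Sequence[VocalRateRecord],
                     offset: float = 0.0) -> np.ndarray:
    """log10-transformed vocal rates, with a uniform additive offset.

    The offset (bouts/hour) keeps zero-rate individuals in the analysis;
    with offset 0 a zero rate is an error.
    """
    r = np.array([rec.rate for rec in rates], dtype=float)
    if np.any(r < 0):
        raise ValidationError("negative vocal rate")
    shifted = r + offset
    if np.any(shifted <= 0):
        raise ValidationError(
            "zero vocal rate with zero offset: log10 undefined "
            "(set a positive offset)")
    return np.log10(shifted)


def pmcmc(samples: np.ndarray) -> float:
    """Twice the smaller tail proportion of draws relative to zero.

    Floored at one draw in the minority tail so 0 is never reported;
    capped at 1.
    """
    samples = np.asarray(samples)
    n = samples.size
    if n < 100:
        raise ValidationError(f"pmcmc needs >= 100 draws, got {n}")
    pos = int(np.sum(samples > 0))
    neg = int(np.sum(samples < 0))
    return min(1.0, 2.0 * max(1, min(pos, neg)) / n)


def fit_lmm(y: np.ndarray,
            X: np.ndarray,
            fixed_names: Sequence[str],
            species_index: np.ndarray,
            group_index: np.ndarray,
            priors: PriorConfig = PriorConfig(),
            chain: ChainConfig = ChainConfig(),
            fix_variances: Optional[tuple[float, float, float]] = None,
            ) -> PosteriorResult:
    """Gibbs sampler for the Gaussian nested random-intercept model.

    Parameters
    ----------
    y, X
        Response vector and design matrix (include the intercept column).
    species_index, group_index
        Integer codes per observation; group codes must already be unique
        within species.
    fix_variances
        Optional (species, group, residual) variances held fixed instead of
        sampled — used for numerical cross-checks against generalized least
        squares.

    The sampler is fully reproducible given ``chain.seed``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValidationError("y and X disagree in length")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("design matrix is rank deficient")
    sidx = np.asarray(species_index, dtype=np.intp)
    gidx = np.asarray(group_index, dtype=np.intp)
    q_s = int(sidx.max()) + 1
    q_g = int(gidx.max()) + 1
    n_per_s = np.bincount(sidx, minlength=q_s).astype(float)
    n_per_g = np.bincount(gidx, minlength=q_g).astype(float)

    rng = np.random.default_rng(chain.seed)
    XtX = X.T @ X
    prior_prec = np.eye(p) / priors.beta_variance
    ig_shape = priors.nu / 2.0
    ig_scale0 = priors.nu * priors.V / 2.0

    # init at OLS residual scale
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta
    v_e = float(np.var(resid0)) or 1.0
    v_s = v_g = v_e / 2.0
    if fix_variances is not None:
        v_s, v_g, v_e = fix_variances
    u_s = np.zeros(q_s)
    u_g = np.zeros(q_g)

    kept_beta = np.empty((chain.n_retained, p))
    kept_var = np.empty((chain.n_retained, 3))
    k = 0
    for it in range(chain.n_iter):
        # fixed effects | rest ~ MVN
        r = y - u_s[sidx] - u_g[gidx]
        prec = XtX / v_e + prior_prec
        L = np.linalg.cholesky(prec)
        rhs = X.T @ r / v_e + prior_prec @ np.full(p, priors.beta_mean)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        # species intercepts | rest
        r_s = y - X @ beta - u_g[gidx]
        prec_s = n_per_s / v_e + 1.0 / v_s
        mean_s = np.bincount(sidx, weights=r_s, minlength=q_s) / v_e / prec_s
        u_s = mean_s + rng.standard_normal(q_s) / np.sqrt(prec_s)

        # group-in-species intercepts | rest
        r_g = y - X @ beta - u_s[sidx]
        prec_g = n_per_g / v_e + 1.0 / v_g
        mean_g = np.bincount(gidx, weights=r_g, minlength=q_g) / v_e / prec_g
        u_g = mean_g + rng.standard_normal(q_g) / np.sqrt(prec_g)

        if fix_variances is None:
            v_s = 1.0 / rng.gamma(ig_shape + q_s / 2.0,
                                  1.0 / (ig_scale0 + 0.5 * u_s @ u_s))
            v_g = 1.0 / rng.gamma(ig_shape + q_g / 2.0,
                                  1.0 / (ig_scale0 + 0.5 * u_g @ u_g))
            resid = r_g - u_g[gidx]
            v_e = 1.0 / rng.gamma(ig_shape + n / 2.0,
                                  1.0 / (ig_scale0 + 0.5 * resid @ resid))

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept_beta[k] = beta
            kept_var[k] = (v_s, v_g, v_e)
            k += 1
    kept_beta = kept_beta[:k]
    kept_var = kept_var[:k]
    if k < 100:
        raise ValidationError(f"retained only {k} samples; need >= 100")

    fixed = []
    for j, name in enumerate(fixed_names):
        draws = kept_beta[:, j]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        fixed.append(FixedEffectSummary(
            name=name, posterior_mean=float(draws.mean()),
            ci_lower=float(lo), ci_upper=float(hi), pmcmc=pmcmc(draws)))

    vs, vg, ve = kept_var.mean(axis=0)
    partition = variance_partition(kept_beta.mean(axis=0), X,
                                   float(vs), float(vg), float(ve))
    return PosteriorResult(
        fixed=fixed, var_species=float(vs), var_group=float(vg),
        var_residual=float(ve), variance_partition=partition,
        beta_draws=kept_beta, var_draws=kept_var,
        fixed_names=list(fixed_names))


def variance_partition(beta_mean: np.ndarray, X: np.ndarray,
                       var_species: float, var_group: float,
                       var_residual: float) -> dict[str, float]:
    """Share of variance attributed to fixed effects, species, group and
    residual, evaluated at posterior means.

    The fixed-effect share uses the variance of the fitted linear predictor
    Xβ̂ across individuals; shares are normalized to sum to 1.
    """
    fixed_var = float(np.var(X @ np.asarray(beta_mean), ddof=1)) if X.shape[0] > 1 else 0.0
    total = fixed_var + var_species + var_group + var_residual
    return {"fixed": fixed_var / total,
            "species": var_species / total,
            "group": var_group / total,
            "residual": var_residual / total}
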