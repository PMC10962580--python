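"""Stratified, hierarchical and calibrated-hierarchical analysis models.

Three analyses of increasing pooling behaviour:

- the independent (stratified) model analyses each basket alone with a
  weakly informative logit-normal prior centred at the null rate; it is
  evaluated exactly by 1-D quadrature, no MCMC involved;
- the Bayesian hierarchical model (BHM) shrinks all basket log-odds
  toward a common mean with a Half-Cauchy(0, 25) prior on the
  between-basket SD;
- the calibrated BHM (CBHM) replaces that prior with a deterministic
  shrinkage variance sigma^2 = exp{a + b log T}, where T is the Pearson
  chi-squared homogeneity statistic of the observed counts and (a, b)
  come from a simulation calibration (see :mod:`baskex.calibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BasketData, ModelConfig, PosteriorResult
from .posterior import (
    MixtureModel,
    SamplerSettings,
    independent_posterior_quadrature,
    run_mcmc,
)

__all__ = [
    "HomogeneityStatistic",
    "fit_independent",
    "fit_bhm",
    "homogeneity_statistic",
    "homogeneity_statistic_batch",
    "fit_cbhm",
]

#: Floor inserted for log(T) when the observed rates are perfectly
#: homogeneous (T = 0), driving the CBHM to its strong-pooling limit.
T_FLOOR = 1e-10


@dataclass(frozen=True)
class HomogeneityStatistic:
    """Pearson chi-squared homogeneity statistic and its count table.

    Expected counts use the pooled maximum-likelihood rate
    pbar = sum(Y_k) / sum(n_k): E1_k = n_k * pbar responses and
    E0_k = n_k * (1 - pbar) failures, so observed and expected counts
    match in total by construction.
    """

    T: float
    O0: np.ndarray
    O1: np.ndarray
    E0: np.ndarray
    E1: np.ndarray


def homogeneity_statistic(data: BasketData) -> HomogeneityStatistic:
    """Chi-squared homogeneity statistic T of the observed counts.

    T = sum_k (O0k - E0k)^2 / E0k + sum_k (O1k - E1k)^2 / E1k with
    pooled-rate expectations.  When the pooled rate is 0 or 1 every
    basket is identical and T is defined as 0 (perfect homogeneity).
    """
    if data.K < 2:
        raise ValueError("homogeneity requires at least two baskets")
    n = np.asarray(data.n, dtype=float)
    O1 = np.asarray(data.Y, dtype=float)
    O0 = n - O1
    pbar = O1.sum() / n.sum()
    if pbar in (0.0, 1.0):
        return HomogeneityStatistic(T=0.0, O0=O0, O1=O1, E0=n - n * pbar, E1=n * pbar)
    E1 = n * pbar
    E0 = n * (1.0 - pbar)
    T = float(((O1 - E1) ** 2 / E1).sum() + ((O0 - E0) ** 2 / E0).sum())
    return HomogeneityStatistic(T=T, O0=O0, O1=O1, E0=E0, E1=E1)


def homogeneity_statistic_batch(Y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized T over a batch of trials: Y (B, K), n (K,) -> T (B,).

    Same pooled-rate construction as :func:`homogeneity_statistic`;
    trials with pooled rate 0 or 1 get T = 0.
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    pbar = Y.sum(axis=1, keepdims=True) / n.sum()
    E1 = n * pbar
    E0 = n * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = ((Y - E1) ** 2 / E1).sum(1) + ((n - Y - E0) ** 2 / E0).sum(1)
    return np.where((pbar[:, 0] == 0.0) | (pbar[:, 0] == 1.0), 0.0, T)


def fit_independent(data: BasketData, config: ModelConfig | None = None) -> PosteriorResult:
    """Stratified analysis: each basket fit alone, exactly, by quadrature.

    Per-basket results carry no cross-basket dependence at all, so the
    output is equivariant under basket permutations and deterministic.
    """
    config = config or ModelConfig(method="independent")
    if config.method != "independent":
        raise ValueError(f"config.method is {config.method!r}, expected 'independent'")
    rows = [
        independent_posterior_quadrature(
            Y=yk, n=nk, prior_mean=config.mu_mean, prior_var=config.mu_var, q0=data.q0
        )
        for yk, nk in zip(data.Y, data.n)
    ]
    mean, sd, prob = map(np.asarray, zip(*rows))
    return PosteriorResult(
        method="independent",
        p_mean=mean,
        p_sd=sd,
        prob_exceed=prob,
        labels=data.labels,
        diagnostics={"backend": "quadrature"},
    )


def _summarize_mixture(method, data, result, extras=None) -> PosteriorResult:
    p = result.draws["p"]  # (1, chains, kept, K)
    flat = p.reshape(-1, p.shape[-1])
    out = PosteriorResult(
        method=method,
        p_mean=flat.mean(0),
        p_sd=flat.std(0, ddof=1),
        prob_exceed=(flat > data.q0).mean(0),
        labels=data.labels,
        draws={k: v[0] for k, v in result.draws.items()},
        extras=extras or {},
        diagnostics=dict(result.diagnostics, warnings=list(result.warnings)),
    )
    return out


def fit_bhm(data: BasketData, config: ModelConfig | None = None, *, settings: SamplerSettings | None = None) -> PosteriorResult:
    """Bayesian hierarchical model: full exchangeability across baskets.

    All log-odds share theta_k ~ N(mu, sigma^2); estimates are shrunk
    toward the posterior common mean relative to a stratified analysis.
    """
    config = config or ModelConfig(method="bhm")
    if config.method != "bhm":
        raise ValueError(f"config.method is {config.method!r}, expected 'bhm'")
    if data.K < 2:
        raise ValueError("the hierarchical model needs K >= 2; use the independent model")
    settings = settings or config.sampler
    model = MixtureModel(
        Y=np.asarray(data.Y, dtype=float),
        n=np.asarray(data.n, dtype=float),
        pi=np.ones(data.K),
        mu_mean=config.mu_mean,
        mu_var=config.mu_var,
        nex_mean=config.nex_mean,
        nex_var=config.nex_variance,
        sigma_prior=(config.sigma_prior_family, config.sigma_prior_scale),
    )
    res = run_mcmc(model, settings)
    sig = res.draws["sigma"].ravel()
    mu = res.draws["mu"].ravel()
    return _summarize_mixture(
        "bhm", data, res, extras={"sigma2_mean": float((sig**2).mean()), "mu_mean": float(mu.mean())}
    )


def fit_cbhm(data: BasketData, config: ModelConfig | None = None, *, settings: SamplerSettings | None = None) -> PosteriorResult:
    """Calibrated BHM: hierarchical fit with sigma^2 fixed from the data.

    Computes the homogeneity statistic T, sets sigma^2 = exp{a + b log T}
    with the calibrated coefficients from ``config`` (no cap is applied),
    and fits the hierarchical model with that variance held constant.
    """
    config = config or ModelConfig(method="cbhm")
    if config.method != "cbhm":
        raise ValueError(f"config.method is {config.method!r}, expected 'cbhm'")
    if data.K < 2:
        raise ValueError("the calibrated hierarchical model needs K >= 2")
    if config.cbhm_a is None or config.cbhm_b is None:
        raise ValueError("CBHM needs calibrated (a, b); run calibrate_cbhm_ab first")
    settings = settings or config.sampler
    hom = homogeneity_statistic(data)
    degenerate = hom.T <= 0.0
    logT = np.log(T_FLOOR if degenerate else hom.T)
    sigma2 = float(np.exp(config.cbhm_a + config.cbhm_b * logT))
    model = MixtureModel(
        Y=np.asarray(data.Y, dtype=float),
        n=np.asarray(data.n, dtype=float),
        pi=np.ones(data.K),
        mu_mean=config.mu_mean,
        mu_var=config.mu_var,
        nex_mean=config.nex_mean,
        nex_var=config.nex_variance,
        sigma_prior=("fixed", sigma2),
    )
    res = run_mcmc(model, settings)
    extras = {"T": hom.T, "sigma2": sigma2, "a": config.cbhm_a, "b": config.cbhm_b}
    out = _summarize_mixture("cbhm", data, res, extras=extras)
    if degenerate:
        out.diagnostics["degenerate_T"] = (
            "T = 0 (perfectly homogeneous rates); sigma^2 evaluated at the "
            f"strong-pooling floor log T = log({T_FLOOR})"
        )
    return out
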