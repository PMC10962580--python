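"""EX/NEX mixture models, including the Hellinger-weighted modification.

The exchangeability-nonexchangeability (EXNEX) model lets each basket
choose, with prior probability pi_k, between a shared hierarchical EX
component and an independent NEX component.  The modified procedure
(mEXNEXc) replaces the fixed pi_k = 0.5 by a data-driven two-step
construction:

1. *exclusion* -- a basket whose observed rate differs from every other
   basket's by more than a cut-off c is removed from borrowing entirely
   (pi_k = 0);
2. *Hellinger weighting* -- for the retained set S, flat-prior beta
   posteriors Beta(Y_k + 1, n_k - Y_k + 1) are compared pairwise through
   Hellinger distances h, and pi_k is the average of (1 - h) over the
   retained partners.

The mixture is then fit as one joint model; excluded baskets stay inside
the MCMC with weight zero, so the EX mean and SD are informed only by the
EX-eligible baskets.  mEXNEXc also moves the Half-Normal(0, 1) shrinkage
prior from sigma onto sigma^2, placing less mass near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .data import BasketData, ModelConfig, PosteriorResult
from .posterior import (
    BetaPosterior,
    MixtureModel,
    SamplerSettings,
    beta_binomial_posterior,
    hellinger_beta,
    run_mcmc,
)

__all__ = [
    "ExWeights",
    "exclude_heterogeneous",
    "hellinger_beta",
    "exnex_prior_weights",
    "fit_exnex",
    "fit_mexnex",
]


@dataclass(frozen=True)
class ExWeights:
    """Prior exchangeability weights from the two-step construction."""

    pi: np.ndarray
    retained: frozenset
    hellinger: np.ndarray
    c: float

    def __post_init__(self):
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "hellinger", np.asarray(self.hellinger, dtype=float))


def _cutoff_fraction(c) -> Fraction:
    """Snap a cut-off to an exact rational.

    Grid values in practice are small rationals (0, 1/13, 0.05, ...); a
    float input is snapped to the nearest fraction with denominator up to
    10^6 so comparisons against the rational rate differences are exact.
    """
    if isinstance(c, Fraction):
        return c
    if isinstance(c, str):
        return Fraction(c)
    if isinstance(c, (int, np.integer)):
        return Fraction(int(c))
    return Fraction(float(c)).limit_denominator(10**6)


def exclude_heterogeneous(data: BasketData, c) -> frozenset:
    """Step 1: the index set S of baskets retained for borrowing.

    Basket k is excluded iff min_{k' != k} |phat_k - phat_k'| is strictly
    greater than c.  The comparison |Y_k n_k' - Y_k' n_k| * den(c) vs
    num(c) * n_k n_k' is carried out in integer arithmetic, so ties at
    exactly c (which retain the basket) are decided exactly.
    """
    if data.K < 2:
        raise ValueError("exclusion requires at least two baskets")
    frac = _cutoff_fraction(c)
    if frac < 0:
        raise ValueError("cut-off c must be >= 0")
    num, den = frac.numerator, frac.denominator
    Y, n = data.Y, data.n
    retained = []
    for k in range(data.K):
        all_far = True
        for j in range(data.K):
            if j == k:
                continue
            # |Y_k/n_k - Y_j/n_j| <= c  <=>  |Y_k n_j - Y_j n_k| den <= num n_k n_j
            if abs(Y[k] * n[j] - Y[j] * n[k]) * den <= num * n[k] * n[j]:
                all_far = False
                break
        if not all_far:
            retained.append(k)
    return frozenset(retained)


def exnex_prior_weights(data: BasketData, c) -> ExWeights:
    """Two-step prior exchangeability weights pi_k.

    Excluded baskets get pi_k = 0.  Retained baskets average (1 - h) over
    their retained partners, where h is the Hellinger distance between
    flat-prior beta posteriors.  If one or zero baskets survive the
    exclusion there is no partner to borrow from and every pi_k is 0
    (the fit degrades to a fully independent analysis).
    """
    S = exclude_heterogeneous(data, c)
    K = data.K
    pi = np.zeros(K)
    H = np.full((K, K), np.nan)
    if len(S) >= 2:
        post = {k: beta_binomial_posterior(data.Y[k], data.n[k]) for k in S}
        for k in S:
            H[k, k] = 0.0
        members = sorted(S)
        for i, k in enumerate(members):
            for j in members[i + 1 :]:
                h = hellinger_beta(post[k], post[j])
                H[k, j] = H[j, k] = h
        for k in members:
            others = [j for j in members if j != k]
            pi[k] = float(np.mean([1.0 - H[k, j] for j in others]))
    return ExWeights(pi=pi, retained=S, hellinger=H, c=float(_cutoff_fraction(c)))


def _fit_mixture(
    method: str,
    data: BasketData,
    config: ModelConfig,
    pi: np.ndarray,
    settings: SamplerSettings | None,
    extras: dict,
) -> PosteriorResult:
    if data.K < 2:
        raise ValueError("the mixture model needs K >= 2; use the independent model")
    settings = settings or config.sampler
    model = MixtureModel(
        Y=np.asarray(data.Y, dtype=float),
        n=np.asarray(data.n, dtype=float),
        pi=pi,
        mu_mean=config.mu_mean,
        mu_var=config.mu_var,
        nex_mean=config.nex_mean,
        nex_var=config.nex_variance,
        sigma_prior=(config.sigma_prior_family, config.sigma_prior_scale),
    )
    res = run_mcmc(model, settings)
    p = res.draws["p"][0]
    delta = res.draws["delta"][0]
    flat = p.reshape(-1, data.K)
    post_pi = delta.reshape(-1, data.K).mean(0)
    return PosteriorResult(
        method=method,
        p_mean=flat.mean(0),
        p_sd=flat.std(0, ddof=1),
        prob_exceed=(flat > data.q0).mean(0),
        labels=data.labels,
        draws={k: v[0] for k, v in res.draws.items()},
        extras=dict(extras, prior_pi=np.asarray(pi, dtype=float), posterior_pi=post_pi),
        diagnostics=dict(res.diagnostics, warnings=list(res.warnings)),
    )


def fit_exnex(data: BasketData, config: ModelConfig | None = None, *, settings: SamplerSettings | None = None) -> PosteriorResult:
    """Standard EXNEX fit with fixed prior weights (default 0.5 each).

    Shrinkage prior: Half-Normal(0, 1) on sigma.  ``extras`` carries the
    posterior exchangeability probabilities P(delta_k = 1 | D) (posterior
    means of the mixture indicators).
    """
    config = config or ModelConfig(method="exnex")
    if config.method != "exnex":
        raise ValueError(f"config.method is {config.method!r}, expected 'exnex'")
    pi = np.full(data.K, 0.5) if config.pi is None else np.asarray(config.pi, dtype=float)
    if pi.shape != (data.K,):
        raise ValueError("pi must have one weight per basket")
    return _fit_mixture("exnex", data, config, pi, settings, {})


def fit_mexnex(data: BasketData, config: ModelConfig | None = None, *, settings: SamplerSettings | None = None) -> PosteriorResult:
    """Modified EXNEX fit: two-step weights, Half-Normal(0, 1) on sigma^2.

    The cut-off is taken from ``config.c``.  Excluded baskets are fit
    within the same joint model with pi_k = 0, i.e. as pure NEX baskets.
    """
    config = config or ModelConfig(method="mexnex")
    if config.method != "mexnex":
        raise ValueError(f"config.method is {config.method!r}, expected 'mexnex'")
    weights = exnex_prior_weights(data, config.c)
    extras = {"c": weights.c, "retained": sorted(weights.retained), "hellinger": weights.hellinger}
    return _fit_mixture("mexnex", data, config, weights.pi, settings, extras)
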