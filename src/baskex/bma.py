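"""Closed-form Bayesian model averaging over EX/NEX basket allocations.

With a single exchangeability component, each candidate model pools one
subset of baskets (size >= 2) under a shared response rate and leaves
the rest independent; the subset of size zero or one is the same
all-independent model, so the deduplicated space has

    1 + (2^K - K - 1)

members.  Beta-binomial conjugacy gives every model's marginal
likelihood in closed form (binomial coefficients are constant across
models and omitted consistently), the model prior is proportional to
Pj^power with Pj the number of distinct response-rate parameters, and
the averaged posterior of each basket's rate is a finite beta mixture -
no sampling anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import betaln, logsumexp
from scipy.stats import beta as beta_dist

from .data import BasketData, ModelConfig, PosteriorResult
from .posterior import BetaPosterior

__all__ = ["AllocationModel", "enumerate_models", "pooled_group_posterior", "fit_bma"]


@dataclass
class AllocationModel:
    """One EX/NEX allocation: which baskets share a pooled rate."""

    ex_subset: frozenset
    groups: tuple  # tuple of frozensets partitioning the baskets
    Pj: int
    log_prior: float = np.nan
    log_marginal: float = np.nan
    log_posterior_weight: float = np.nan


def enumerate_models(K: int, prior_power: float = 2.0) -> list[AllocationModel]:
    """The deduplicated single-EX-component model space with its prior.

    Contains the all-independent model plus one model per EX subset of
    size >= 2; priors f(Mj) proportional to Pj^prior_power, normalized
    over this space.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    models = [
        AllocationModel(
            ex_subset=frozenset(),
            groups=tuple(frozenset([k]) for k in range(K)),
            Pj=K,
        )
    ]
    for r in range(2, K + 1):
        for S in combinations(range(K), r):
            S = frozenset(S)
            groups = (S,) + tuple(frozenset([k]) for k in range(K) if k not in S)
            models.append(AllocationModel(ex_subset=S, groups=groups, Pj=K - len(S) + 1))
    log_prior = prior_power * np.log([m.Pj for m in models])
    log_prior -= logsumexp(log_prior)
    for m, lp in zip(models, log_prior):
        m.log_prior = float(lp)
    return models


def pooled_group_posterior(
    group, data: BasketData, prior: tuple[float, float] = (0.45, 0.55)
) -> tuple[BetaPosterior, float]:
    """Conjugate posterior and log marginal likelihood of one pooled group.

    The group's baskets share a single rate with prior Beta(a0, b0);
    the posterior is Beta(a0 + sum Y, b0 + sum(n - Y)) and the log
    marginal is log B(a0 + sum Y, b0 + sum(n-Y)) - log B(a0, b0)
    (binomial coefficients omitted, consistently across models).
    """
    group = sorted(group)
    if not group:
        raise ValueError("group must be nonempty")
    a0, b0 = prior
    sy = sum(data.Y[k] for k in group)
    sn = sum(data.n[k] for k in group)
    post = BetaPosterior(a0 + sy, b0 + sn - sy)
    logml = float(betaln(post.a, post.b) - betaln(a0, b0))
    return post, logml


def fit_bma(data: BasketData, config: ModelConfig | None = None) -> PosteriorResult:
    """Exact model-averaged posterior for every basket.

    Enumerates the allocation space, weights each model by prior x
    marginal likelihood (log-sum-exp normalization), and reduces each
    basket's posterior to its beta-mixture mean, SD and exceedance
    probability P(p_k > q0 | D) in closed form.  ``extras['models']``
    carries the full weight table.
    """
    config = config or ModelConfig(method="bma")
    if config.method != "bma":
        raise ValueError(f"config.method is {config.method!r}, expected 'bma'")
    K = data.K
    models = enumerate_models(K, prior_power=config.bma_prior_power)
    prior = tuple(config.bma_beta)

    group_posts = []
    for m in models:
        posts = {}
        logml = 0.0
        for g in m.groups:
            post, lm = pooled_group_posterior(g, data, prior)
            logml += lm
            for k in g:
                posts[k] = post
        m.log_marginal = logml
        group_posts.append(posts)

    log_w = np.array([m.log_prior + m.log_marginal for m in models])
    log_w -= logsumexp(log_w)
    for m, lw in zip(models, log_w):
        m.log_posterior_weight = float(lw)
    w = np.exp(log_w)

    p_mean = np.zeros(K)
    p_m2 = np.zeros(K)
    prob = np.zeros(K)
    for wt, posts in zip(w, group_posts):
        for k in range(K):
            post = posts[k]
            p_mean[k] += wt * post.mean
            p_m2[k] += wt * (post.sd**2 + post.mean**2)
            prob[k] += wt * post.prob_exceed(data.q0)
    p_sd = np.sqrt(np.maximum(p_m2 - p_mean**2, 0.0))

    return PosteriorResult(
        method="bma",
        p_mean=p_mean,
        p_sd=p_sd,
        prob_exceed=np.clip(prob, 0.0, 1.0),
        labels=data.labels,
        extras={
            "models": [
                {
                    "ex_subset": sorted(m.ex_subset),
                    "Pj": m.Pj,
                    "log_prior": m.log_prior,
                    "log_marginal": m.log_marginal,
                    "posterior_weight": float(np.exp(m.log_posterior_weight)),
                }
                for m in models
            ],
        },
        diagnostics={"backend": "closed-form"},
    )


def bma_prob_exceed_batch(
    Y: np.ndarray,
    n: np.ndarray,
    q0: float,
    prior: tuple[float, float] = (0.45, 0.55),
    prior_power: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized model-averaged (prob_exceed, p_mean) over many trials.

    ``Y`` has shape (B, K) with common ``n`` of shape (K,).  Used by the
    simulation engine; identical arithmetic to :func:`fit_bma`, organized
    model-by-model so the beta-function calls vectorize over replicates.
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    B, K = Y.shape
    a0, b0 = prior
    models = enumerate_models(K, prior_power=prior_power)

    # per-basket singleton sufficient statistics, shared across models
    log_ml_single = betaln(a0 + Y, b0 + n - Y) - betaln(a0, b0)  # (B, K)
    total_single = log_ml_single.sum(axis=1)  # all-independent marginal

    n_models = len(models)
    log_w = np.empty((B, n_models))
    group_a = np.empty((B, n_models, K))
    group_b = np.empty((B, n_models, K))
    for j, m in enumerate(models):
        lm = total_single.copy()
        a_jk = np.broadcast_to(a0 + Y, (B, K)).copy()
        b_jk = np.broadcast_to(b0 + n - Y, (B, K)).copy()
        if m.ex_subset:
            idx = sorted(m.ex_subset)
            sy = Y[:, idx].sum(1)
            sn = n[idx].sum()
            pooled = betaln(a0 + sy, b0 + sn - sy) - betaln(a0, b0)
            lm += pooled - log_ml_single[:, idx].sum(1)
            a_jk[:, idx] = (a0 + sy)[:, None]
            b_jk[:, idx] = (b0 + sn - sy)[:, None]
        log_w[:, j] = m.log_prior + lm
        group_a[:, j, :] = a_jk
        group_b[:, j, :] = b_jk

    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    w = np.exp(log_w)[:, :, None]  # (B, M, 1)
    prob = (w * beta_dist.sf(q0, group_a, group_b)).sum(1)
    mean = (w * (group_a / (group_a + group_b))).sum(1)
    return prob, mean
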