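"""Trial simulation and operating-characteristic computation.

The engine simulates basket trials under a truth scenario, fits any of
the analysis methods to every replicate, applies a calibrated decision
rule, and aggregates the standard design metrics: per-basket rejection
percentage (type I error where the basket is truly null, power where it
is sensitive), the percentage of trials with correct conclusions in all
baskets, and the family-wise error rate.

Replicates are fit in a single vectorized pass: the stratified model
goes through the cached quadrature oracle (so its whole pipeline is
deterministic given the seed), model averaging through the closed-form
batch evaluator, and the MCMC-based methods through the batch axis of
the Metropolis-within-Gibbs sampler with streaming summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

from .bma import bma_prob_exceed_batch
from .calibrate import DecisionRule
from .data import BasketData, ModelConfig, ResponseScenario
from .exnex import _cutoff_fraction
from .hierarchy import T_FLOOR, homogeneity_statistic_batch
from .posterior import (
    MixtureModel,
    SamplerSettings,
    independent_posterior_quadrature,
    run_mcmc,
)

__all__ = [
    "SIM_SAMPLER",
    "OperatingCharacteristics",
    "RandomTruthResult",
    "simulate_trial",
    "posterior_probs_batch",
    "run_operating_characteristics",
    "random_truth_study",
]

#: Lighter sampler settings used for batched replicate fits.  Two chains
#: of 5000 iterations (half burn-in) leave ~5000 retained draws per
#: replicate - Monte Carlo error on P(p_k > q0 | D) of about 0.01, the
#: same order as a routine JAGS-style analysis of a single trial.
SIM_SAMPLER = SamplerSettings(chains=2, iterations=5_000, burn_in=2_500)


@dataclass
class OperatingCharacteristics:
    """Aggregated design metrics for one method under one scenario.

    Percentages are on the 0-100 scale.  ``fwer_pct`` is None when the
    scenario has no truly-null basket.
    """

    method: str
    scenario: str
    p_true: tuple
    n: tuple
    reject_pct: np.ndarray
    null_mask: np.ndarray
    all_correct_pct: float
    fwer_pct: float | None
    est_mean: np.ndarray
    est_sd: np.ndarray
    replicates: int
    seed: int
    decisions: np.ndarray | None = None

    @property
    def type_I_pct(self) -> np.ndarray:
        """Per-basket rejection % restricted to truly-null baskets."""
        return np.where(self.null_mask, self.reject_pct, np.nan)

    @property
    def power_pct(self) -> np.ndarray:
        """Per-basket rejection % restricted to truly-sensitive baskets."""
        return np.where(~self.null_mask, self.reject_pct, np.nan)


@dataclass
class RandomTruthResult:
    """Metrics aggregated over randomly drawn truth vectors.

    Type I error pools all basket-draws whose true rate fell at or below
    q0; power pools the rest.  ``all_correct_pct`` and ``fwer_pct`` are
    per-trial summaries as usual (FWER over trials with >= 1 null basket).
    """

    method: str
    n: tuple
    type_I_pct: float
    power_pct: float
    all_correct_pct: float
    fwer_pct: float
    null_fraction: float
    replicates: int
    seed: int


def simulate_trial(scenario: ResponseScenario, n, rng: np.random.Generator, q0: float = 0.15, q1: float = 0.45) -> BasketData:
    """Draw one trial: Y_k ~ Binomial(n_k, p_k), independent across baskets."""
    n = np.asarray(n, dtype=int)
    p = np.asarray(scenario.p, dtype=float)
    if n.shape != p.shape:
        raise ValueError("scenario and sample sizes must have equal length")
    Y = rng.binomial(n, p)
    return BasketData(n=tuple(n), Y=tuple(Y), q0=q0, q1=q1)


def _independent_batch(Y, n, q0, config):
    """(prob, mean) through the cached quadrature oracle."""
    B, K = Y.shape
    prob = np.empty((B, K))
    mean = np.empty((B, K))
    for k in range(K):
        nk = int(n[k])
        uniq = np.unique(Y[:, k])
        table = {
            int(y): independent_posterior_quadrature(
                int(y), nk, config.mu_mean, config.mu_var, q0
            )
            for y in uniq
        }
        for y, (m, _s, pr) in table.items():
            sel = Y[:, k] == y
            prob[sel, k] = pr
            mean[sel, k] = m
    return prob, mean


def mexnex_prior_weights_batch(Y: np.ndarray, n: np.ndarray, c) -> np.ndarray:
    """Vectorized two-step prior weights over a batch of trials.

    Same construction as :func:`baskex.exnex.exnex_prior_weights`:
    integer-arithmetic exclusion at cut-off ``c``, then averaged
    (1 - Hellinger) weights among the retained baskets of each trial.
    """
    Y = np.asarray(Y, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    B, K = Y.shape
    frac = _cutoff_fraction(c)
    num, den = frac.numerator, frac.denominator
    # close[b, k, j]: |phat_k - phat_j| <= c, exactly
    cross = np.abs(Y[:, :, None] * n[None, None, :] - Y[:, None, :] * n[None, :, None])
    close = cross * den <= num * (n[None, :, None] * n[None, None, :])
    off = ~np.eye(K, dtype=bool)
    retained = (close & off).any(axis=2)  # (B, K)

    a = (Y + 1.0)
    b = (n - Y + 1.0)
    log_bc = betaln(
        (a[:, :, None] + a[:, None, :]) / 2.0, (b[:, :, None] + b[:, None, :]) / 2.0
    ) - 0.5 * (betaln(a, b)[:, :, None] + betaln(a, b)[:, None, :])
    h = np.sqrt(np.clip(1.0 - np.exp(log_bc), 0.0, None))

    pair_ok = retained[:, :, None] & retained[:, None, :] & off
    cnt = pair_ok.sum(axis=2)
    s = np.where(pair_ok, 1.0 - h, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        pi = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
    # a trial with |S| <= 1 has no borrowing partners anywhere
    pi[retained.sum(axis=1) <= 1] = 0.0
    return pi


def posterior_probs_batch(
    method: str,
    Y: np.ndarray,
    n: np.ndarray,
    q0: float,
    config: ModelConfig | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit ``method`` to a batch of trials; return (prob_exceed, p_mean).

    ``Y`` has shape (B, K); ``n`` shape (K,).  MCMC methods run all
    replicates through one batched sampler call with streaming summaries.
    """
    Y = np.asarray(Y)
    n = np.asarray(n)
    config = config or ModelConfig.defaults(method)
    if config.method != method:
        raise ValueError(f"config.method {config.method!r} does not match {method!r}")
    settings = settings or SIM_SAMPLER

    if method == "independent":
        return _independent_batch(Y, n, q0, config)
    if method == "bma":
        return bma_prob_exceed_batch(
            Y, n, q0, prior=tuple(config.bma_beta), prior_power=config.bma_prior_power
        )

    B, K = Y.shape
    if method == "bhm":
        pi = np.ones((B, K))
        sigma_prior = (config.sigma_prior_family, config.sigma_prior_scale)
    elif method == "cbhm":
        pi = np.ones((B, K))
        T = homogeneity_statistic_batch(Y, n)
        sigma2 = np.exp(
            config.cbhm_a + config.cbhm_b * np.log(np.where(T > 0, T, T_FLOOR))
        )
        sigma_prior = ("fixed", sigma2)
    elif method == "exnex":
        pi = (
            np.full((B, K), 0.5)
            if config.pi is None
            else np.broadcast_to(np.asarray(config.pi, dtype=float), (B, K))
        )
        sigma_prior = (config.sigma_prior_family, config.sigma_prior_scale)
    elif method == "mexnex":
        pi = mexnex_prior_weights_batch(Y, n, config.c)
        sigma_prior = (config.sigma_prior_family, config.sigma_prior_scale)
    else:
        raise ValueError(f"unknown method {method!r}")

    model = MixtureModel(
        Y=Y.astype(float),
        n=np.broadcast_to(n.astype(float), Y.shape),
        pi=pi,
        mu_mean=config.mu_mean,
        mu_var=config.mu_var,
        nex_mean=config.nex_mean,
        nex_var=config.nex_variance,
        sigma_prior=sigma_prior,
    )
    res = run_mcmc(
        model,
        settings,
        rng=np.random.default_rng(seed),
        keep_draws=False,
        prob_threshold=q0,
    )
    return res.draws["prob_exceed"], res.draws["p_mean"]


def run_operating_characteristics(
    method: str,
    scenario: ResponseScenario,
    n,
    rule: DecisionRule,
    replicates: int,
    seed: int = 0,
    config: ModelConfig | None = None,
    settings: SamplerSettings | None = None,
    q0: float = 0.15,
    q1: float = 0.45,
    keep_decisions: bool = False,
) -> OperatingCharacteristics:
    """Simulate, fit, decide, aggregate - for one method and scenario."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rule.check_method(method)
    n = np.asarray(n, dtype=int)
    p = np.asarray(scenario.p, dtype=float)
    ss = np.random.SeedSequence(seed)
    rng_data, rng_fit, rng_decide = (np.random.default_rng(s) for s in ss.spawn(3))

    Y = rng_data.binomial(n, p, size=(replicates, n.size))
    probs, est = posterior_probs_batch(
        method, Y, n, q0, config=config, settings=settings,
        seed=int(rng_fit.integers(2**31)),
    )
    decisions = rule.decide(probs, rng_decide)

    null_mask = p <= q0
    reject_pct = 100.0 * decisions.mean(axis=0)
    correct = decisions == ~null_mask  # reject iff truly sensitive
    all_correct_pct = 100.0 * correct.all(axis=1).mean()
    fwer_pct = (
        100.0 * decisions[:, null_mask].any(axis=1).mean() if null_mask.any() else None
    )
    return OperatingCharacteristics(
        method=method,
        scenario=scenario.name,
        p_true=tuple(p),
        n=tuple(int(v) for v in n),
        reject_pct=reject_pct,
        null_mask=null_mask,
        all_correct_pct=float(all_correct_pct),
        fwer_pct=None if fwer_pct is None else float(fwer_pct),
        est_mean=est.mean(axis=0),
        est_sd=est.std(axis=0, ddof=1),
        replicates=replicates,
        seed=seed,
        decisions=decisions if keep_decisions else None,
    )


def random_truth_study(
    method: str,
    n,
    rule: DecisionRule,
    replicates: int,
    seed: int = 0,
    config: ModelConfig | None = None,
    settings: SamplerSettings | None = None,
    q0: float = 0.15,
    q1: float = 0.45,
    null_range: tuple = (0.0, 0.15),
    alt_range: tuple = (0.35, 0.5),
) -> RandomTruthResult:
    """Operating characteristics averaged over random truth vectors.

    Each basket's true rate is drawn independently: with probability 1/2
    uniformly from ``null_range`` and otherwise uniformly from
    ``alt_range`` (ranges chosen to give equal chances of the null and
    non-null case).  Type I error aggregates over basket-draws with
    p <= q0, power over the rest; all-correct and FWER per trial.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rule.check_method(method)
    n = np.asarray(n, dtype=int)
    K = n.size
    ss = np.random.SeedSequence(seed)
    rng_data, rng_fit, rng_decide = (np.random.default_rng(s) for s in ss.spawn(3))

    in_null = rng_data.random((replicates, K)) < 0.5
    u = rng_data.random((replicates, K))
    p = np.where(
        in_null,
        null_range[0] + u * (null_range[1] - null_range[0]),
        alt_range[0] + u * (alt_range[1] - alt_range[0]),
    )
    Y = rng_data.binomial(n, p)
    probs, _est = posterior_probs_batch(
        method, Y, n, q0, config=config, settings=settings,
        seed=int(rng_fit.integers(2**31)),
    )
    decisions = rule.decide(probs, rng_decide)

    null_mask = p <= q0
    type_I = 100.0 * decisions[null_mask].mean() if null_mask.any() else float("nan")
    power = 100.0 * decisions[~null_mask].mean() if (~null_mask).any() else float("nan")
    correct = decisions == ~null_mask
    all_correct = 100.0 * correct.all(axis=1).mean()
    has_null = null_mask.any(axis=1)
    fwer = 100.0 * (decisions & null_mask).any(axis=1)[has_null].mean()
    return RandomTruthResult(
        method=method,
        n=tuple(int(v) for v in n),
        type_I_pct=float(type_I),
        power_pct=float(power),
        all_correct_pct=float(all_correct),
        fwer_pct=float(fwer),
        null_fraction=float(null_mask.mean()),
        replicates=replicates,
        seed=seed,
    )
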