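"""Design calibration: decision thresholds, CBHM coefficients, cut-offs.

Three pre-trial simulation procedures:

- :func:`calibrate_delta_alpha` fixes the posterior-probability decision
  threshold so that, under the homogeneous all-null scenario, either the
  basket-wise type I error or the family-wise error rate equals the
  nominal level;
- :func:`calibrate_cbhm_ab` tunes the CBHM log-linear shrinkage function
  sigma^2 = exp{a + b log T} so that the median homogeneity statistic
  under an all-sensitive truth maps to strong borrowing (sigma^2 = 1)
  and the worst heterogeneous configuration maps to near-independence
  (sigma^2 = 80), with an unequal-sample-size generalization that scans
  every mixed assignment of q0/q1 across baskets;
- :func:`select_cutoff_c` picks the mEXNEXc exclusion cut-off from a
  candidate grid by maximizing x * Power + (1 - x)(1 - Error) across a
  scenario set, re-calibrating the decision threshold for every
  candidate.

Because the stratified model is evaluated exactly, its posterior
probabilities sit on discrete atoms (one per response count) and no
strict threshold can achieve the nominal level exactly.  The decision
rule therefore carries a tie-break probability: trials landing exactly
on the threshold atom reject with probability gamma, the classical
randomized-test construction, making the calibrated null rejection rate
exactly alpha.  For MCMC-based methods the posterior probabilities are
effectively continuous and the tie branch never fires.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import ModelConfig, ResponseScenario
from .hierarchy import homogeneity_statistic_batch
from .posterior import SamplerSettings

__all__ = [
    "DecisionRule",
    "CBHMCalibration",
    "CutoffSelection",
    "calibrate_delta_alpha",
    "calibrate_cbhm_ab",
    "select_cutoff_c",
    "solve_cbhm_ab",
]


@dataclass
class DecisionRule:
    """Calibrated efficacy decision rule.

    Basket k is declared sensitive when P(p_k > q0 | D) > delta_alpha,
    or with probability ``tie_prob`` when it equals delta_alpha exactly
    (randomized tie-break at the threshold atom; see the module
    docstring).  A rule is bound to the method it was calibrated for and
    refuses to be applied across methods.
    """

    method: str
    delta_alpha: float
    tie_prob: float
    alpha: float
    control: str  # "basketwise" | "fwer"
    calibrated_under: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.delta_alpha <= 1.0):
            raise ValueError("delta_alpha must lie in [0, 1]")
        if not (0.0 <= self.tie_prob <= 1.0):
            raise ValueError("tie_prob must lie in [0, 1]")
        if self.control not in ("basketwise", "fwer"):
            raise ValueError("control must be 'basketwise' or 'fwer'")

    def check_method(self, method: str) -> None:
        if method != self.method:
            raise ValueError(
                f"decision rule was calibrated for {self.method!r}; refusing to "
                f"apply it to {method!r}"
            )

    def decide(self, probs: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Boolean rejection decisions for posterior probabilities."""
        probs = np.asarray(probs, dtype=float)
        reject = probs > self.delta_alpha
        if self.tie_prob > 0.0:
            ties = probs == self.delta_alpha
            if ties.any():
                if rng is None:
                    rng = np.random.default_rng(0)
                reject = reject | (ties & (rng.random(probs.shape) < self.tie_prob))
        return reject

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "DecisionRule":
        doc = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in names})


@dataclass
class CBHMCalibration:
    """Calibrated CBHM coefficients with their defining quantities.

    Invariants exp{a + b log H_B} = sigma_B2 and exp{a + b log H_Bbar} =
    sigma_Bbar2 hold to machine precision by construction.
    """

    a: float
    b: float
    HB: float
    HB_bar: float
    sigma_B2: float = 1.0
    sigma_Bbar2: float = 80.0
    n_calibration: tuple = ()
    mode: str = "equal"
    replicates: int = 0
    seed: int = 0
    n_heterogeneity_configs: int = 0


@dataclass
class CutoffSelection:
    """Grid search result for the mEXNEXc exclusion cut-off."""

    grid: tuple
    x: float
    power: np.ndarray  # mean power per candidate, 0-1 scale
    error: np.ndarray  # mean type I error per candidate, 0-1 scale
    objective: np.ndarray
    chosen_c: float
    scenarios: tuple = ()
    replicates: int = 0
    seed: int = 0


def solve_cbhm_ab(
    HB: float, HB_bar: float, sigma_B2: float = 1.0, sigma_Bbar2: float = 80.0
) -> tuple[float, float]:
    """Solve exp{a + b log H} = sigma^2 at the two calibration anchors."""
    if HB_bar <= HB:
        raise ValueError(
            f"calibration medians not separated (H_B={HB:.4g}, H_Bbar={HB_bar:.4g})"
        )
    b = (np.log(sigma_Bbar2) - np.log(sigma_B2)) / (np.log(HB_bar) - np.log(HB))
    a = np.log(sigma_B2) - b * np.log(HB)
    return float(a), float(b)


def _pooled_threshold(values: np.ndarray, alpha: float) -> tuple[float, float]:
    """Threshold and tie probability from a pooled calibration sample.

    Picks the smallest observed value v with frac(P > v) <= alpha, then
    sets gamma = (alpha - frac(P > v)) / frac(P == v) so the rejection
    rate on the calibration distribution is exactly alpha.
    """
    values = np.sort(values.ravel())
    N = values.size
    if alpha >= 1.0:
        return 0.0, 1.0
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size == 1:
        raise ValueError(
            "degenerate calibration distribution: all posterior probabilities equal"
        )
    n_greater = N - np.cumsum(counts)  # #(P > uniq[i])
    ok = n_greater <= alpha * N
    i = int(np.argmax(ok))  # smallest qualifying value
    delta = float(uniq[i])
    gamma = (alpha - n_greater[i] / N) / (counts[i] / N)
    return delta, float(min(max(gamma, 0.0), 1.0))


def _fwer_threshold(probs: np.ndarray, alpha: float) -> tuple[float, float]:
    """Threshold and tie probability controlling P(any rejection) = alpha.

    Chooses the smallest per-trial-maximum value with strict-rejection
    FWER <= alpha, then solves for gamma by bisection on the empirical
    sample: with per-basket independent tie coins, a trial with no
    strict exceedance and t ties rejects something with probability
    1 - (1 - gamma)^t.
    """
    if alpha >= 1.0:
        return 0.0, 1.0
    m = probs.max(axis=1)
    uniq = np.unique(m)
    if uniq.size == 1 and (probs == uniq[0]).all():
        raise ValueError(
            "degenerate calibration distribution: all posterior probabilities equal"
        )
    R = probs.shape[0]
    n_greater = np.array([(m > v).sum() for v in uniq])
    ok = n_greater <= alpha * R
    i = int(np.argmax(ok))
    delta = float(uniq[i])
    strict = (m > delta)
    t = ((probs == delta).sum(axis=1))[~strict]  # ties among non-strict trials

    def fwer(g):
        return (strict.sum() + (1.0 - (1.0 - g) ** t).sum()) / R

    if fwer(1.0) <= alpha:
        return delta, 1.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if fwer(mid) <= alpha:
            lo = mid
        else:
            hi = mid
    return delta, lo


def calibrate_delta_alpha(
    method: str,
    n,
    q0: float,
    alpha: float = 0.10,
    replicates: int = 10_000,
    seed: int = 0,
    control: str = "basketwise",
    config: ModelConfig | None = None,
    settings: SamplerSettings | None = None,
    q1: float = 0.45,
) -> DecisionRule:
    """Calibrate the decision threshold under the all-null scenario.

    Simulates ``replicates`` trials with every basket at the null rate
    q0, fits ``method`` to each, and sets the threshold from the pooled
    per-basket posterior probabilities (basket-wise control) or from the
    per-trial maxima (FWER control).  The randomized tie-break makes the
    achieved null error rate exactly alpha on the calibration
    distribution (see module docstring).
    """
    from .simulate import posterior_probs_batch  # local import; avoids a cycle

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = np.asarray(n, dtype=int)
    ss = np.random.SeedSequence(seed)
    rng_data, rng_fit = (np.random.default_rng(s) for s in ss.spawn(2))
    Y = rng_data.binomial(n, q0, size=(replicates, n.size))
    probs, _ = posterior_probs_batch(
        method, Y, n, q0, config=config, settings=settings,
        seed=int(rng_fit.integers(2**31)),
    )
    if control == "basketwise":
        delta, gamma = _pooled_threshold(probs, alpha)
    elif control == "fwer":
        delta, gamma = _fwer_threshold(probs, alpha)
    else:
        raise ValueError("control must be 'basketwise' or 'fwer'")
    cfg = config or ModelConfig.defaults(method)
    return DecisionRule(
        method=method,
        delta_alpha=delta,
        tie_prob=gamma,
        alpha=alpha,
        control=control,
        calibrated_under={
            "scenario": "all-null",
            "q0": q0,
            "q1": q1,
            "n": [int(v) for v in n],
            "replicates": replicates,
            "seed": seed,
            "c": cfg.c if method == "mexnex" else None,
        },
    )


def calibrate_cbhm_ab(
    n,
    q0: float,
    q1: float,
    replicates: int = 10_000,
    seed: int = 0,
    mode: str = "auto",
    K: int | None = None,
    sigma_B2: float = 1.0,
    sigma_Bbar2: float = 80.0,
) -> CBHMCalibration:
    """Simulation calibration of the CBHM coefficients (a, b).

    H_B is the median homogeneity statistic under the all-sensitive
    truth (every basket at q1).  H_Bbar is the minimum over
    heterogeneous configurations of the median statistic: with equal
    sample sizes the first-j-sensitive scenarios j = 1..K-1 suffice;
    with unequal sizes the ordering matters and ``mode='permutations'``
    scans all 2^K - 2 mixed q0/q1 assignments.

    ``mode='auto'`` follows the recommended practice for realized
    unequal sizes: calibrate with the per-basket sample size fixed at
    the rounded average, using the equal-size scenario set.  Then
    (a, b) solve exp{a + b log H_B} = sigma_B2 and
    exp{a + b log H_Bbar} = sigma_Bbar2.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = np.asarray([n] * K if np.isscalar(n) else n, dtype=int)
    K = n.size
    if K < 2:
        raise ValueError("CBHM calibration needs K >= 2")
    if mode not in ("auto", "equal", "permutations"):
        raise ValueError("mode must be 'auto', 'equal' or 'permutations'")
    n_cal = n
    eff_mode = mode
    if mode == "auto":
        if np.all(n == n[0]):
            eff_mode = "equal"
        else:
            n_cal = np.full(K, int(round(n.mean())))
            eff_mode = "equal"
    if eff_mode == "equal" and not np.all(n_cal == n_cal[0]):
        raise ValueError("equal mode requires equal sample sizes; use 'permutations'")

    rng = np.random.default_rng(seed)
    HB = float(
        np.median(
            homogeneity_statistic_batch(
                rng.binomial(n_cal, q1, size=(replicates, K)), n_cal
            )
        )
    )
    if eff_mode == "equal":
        masks = [[1] * j + [0] * (K - j) for j in range(1, K)]
    else:
        masks = [
            [(m >> k) & 1 for k in range(K)]
            for m in range(1, 2**K - 1)
        ]
    medians = []
    for mask in masks:
        p = np.where(np.asarray(mask) == 1, q1, q0)
        medians.append(
            float(
                np.median(
                    homogeneity_statistic_batch(
                        rng.binomial(n_cal, p, size=(replicates, K)), n_cal
                    )
                )
            )
        )
    HB_bar = min(medians)
    a, b = solve_cbhm_ab(HB, HB_bar, sigma_B2, sigma_Bbar2)
    return CBHMCalibration(
        a=a,
        b=b,
        HB=HB,
        HB_bar=HB_bar,
        sigma_B2=sigma_B2,
        sigma_Bbar2=sigma_Bbar2,
        n_calibration=tuple(int(v) for v in n_cal),
        mode=eff_mode if mode != "permutations" else "permutations",
        replicates=replicates,
        seed=seed,
        n_heterogeneity_configs=len(masks),
    )


def select_cutoff_c(
    grid,
    x: float,
    n,
    q0: float,
    q1: float,
    scenarios: list[ResponseScenario] | None = None,
    replicates: int = 1_000,
    cal_replicates: int | None = None,
    seed: int = 0,
    alpha: float = 0.10,
    settings: SamplerSettings | None = None,
) -> CutoffSelection:
    """Choose the mEXNEXc exclusion cut-off by pre-trial simulation.

    For every candidate c the decision threshold is re-calibrated, the
    operating characteristics are simulated across the scenario set
    (default: the null, every first-j-sensitive, and the all-sensitive
    scenario), and power / type I error are averaged over the truly
    sensitive / truly null basket-draws.  The chosen c maximizes
    x * Power_c + (1 - x)(1 - Error_c); exact ties break toward the
    smaller, more conservative cut-off.
    """
    from .data import table1_scenarios
    from .simulate import run_operating_characteristics

    grid = sorted(float(c) for c in grid)
    if not grid:
        raise ValueError("candidate grid must be nonempty")
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must lie in [0, 1]")
    n = np.asarray(n, dtype=int)
    K = n.size
    if scenarios is None:
        scenarios = [
            ResponseScenario(p=(q1,) * j + (q0,) * (K - j), name=f"first-{j}-sensitive")
            for j in range(0, K + 1)
        ]
    if not scenarios:
        raise ValueError("scenario set must be nonempty")
    cal_replicates = cal_replicates or replicates

    power = np.zeros(len(grid))
    error = np.zeros(len(grid))
    ss = np.random.SeedSequence(seed)
    for i, c in enumerate(grid):
        sub = ss.spawn(1)[0]
        cfg = ModelConfig.defaults("mexnex", c=c)
        rule = calibrate_delta_alpha(
            "mexnex", n, q0, alpha=alpha, replicates=cal_replicates,
            seed=int(np.random.default_rng(sub).integers(2**31)),
            config=cfg, settings=settings, q1=q1,
        )
        pw, pw_n, er, er_n = 0.0, 0, 0.0, 0
        for j, sc in enumerate(scenarios):
            oc = run_operating_characteristics(
                "mexnex", sc, n, rule, replicates,
                seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)),
                config=cfg, settings=settings, q0=q0, q1=q1,
            )
            null = oc.null_mask
            if (~null).any():
                pw += oc.reject_pct[~null].sum() / 100.0
                pw_n += int((~null).sum())
            if null.any():
                er += oc.reject_pct[null].sum() / 100.0
                er_n += int(null.sum())
        power[i] = pw / pw_n if pw_n else 0.0
        error[i] = er / er_n if er_n else 0.0

    objective = x * power + (1.0 - x) * (1.0 - error)
    best = int(np.argmax(objective))  # first max = smallest c on the sorted grid
    return CutoffSelection(
        grid=tuple(grid),
        x=x,
        power=power,
        error=error,
        objective=objective,
        chosen_c=grid[best],
        scenarios=tuple(sc.name for sc in scenarios),
        replicates=replicates,
        seed=seed,
    )
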