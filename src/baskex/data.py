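"""Domain types, validation, file I/O and packaged fixtures.

The central container is :class:`BasketData`: per-basket sample sizes and
response counts together with the null and target response rates that
define the hypotheses H0: p_k <= q0 vs Ha: p_k > q0.  Trial files are
plain CSV (``basket,n,y`` plus optional ``label``) or an equivalent JSON
document carrying ``q0``/``q1`` at top level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .posterior import SamplerSettings, logit

__all__ = [
    "BasketData",
    "ResponseScenario",
    "ModelConfig",
    "PosteriorResult",
    "load_basket_data",
    "write_basket_data",
    "ve_basket_fixture",
    "table1_scenarios",
    "write_results",
]

METHODS = ("independent", "bhm", "cbhm", "exnex", "mexnex", "bma")


@dataclass(frozen=True)
class BasketData:
    """Summary data of a binary-endpoint basket trial.

    Baskets are 0-indexed internally; labels carry the reporting names.
    """

    n: tuple
    Y: tuple
    q0: float
    q1: float
    labels: tuple | None = None

    def __post_init__(self):
        n = tuple(int(v) for v in self.n)
        Y = tuple(int(v) for v in self.Y)
        if len(n) != len(Y):
            raise ValueError("n and Y must have equal length")
        if len(n) < 1:
            raise ValueError("need at least one basket")
        for k, (nk, yk) in enumerate(zip(n, Y)):
            if nk < 1:
                raise ValueError(f"basket {k + 1}: sample size must be >= 1, got {nk}")
            if not (0 <= yk <= nk):
                raise ValueError(
                    f"basket {k + 1}: need 0 <= Y <= n, got Y={yk}, n={nk}"
                )
        if not (0.0 < self.q0 < self.q1 < 1.0):
            raise ValueError(f"need 0 < q0 < q1 < 1, got q0={self.q0}, q1={self.q1}")
        labels = self.labels
        if labels is None:
            labels = tuple(f"basket_{k + 1}" for k in range(len(n)))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != len(n):
                raise ValueError("labels must match the number of baskets")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "labels", labels)

    @property
    def K(self) -> int:
        return len(self.n)

    @property
    def phat(self) -> np.ndarray:
        """Observed response rates Y_k / n_k."""
        return np.asarray(self.Y, dtype=float) / np.asarray(self.n, dtype=float)

    def permuted(self, order) -> "BasketData":
        """Reorder baskets; useful for equivariance checks."""
        order = list(order)
        return BasketData(
            n=tuple(self.n[i] for i in order),
            Y=tuple(self.Y[i] for i in order),
            q0=self.q0,
            q1=self.q1,
            labels=tuple(self.labels[i] for i in order),
        )


@dataclass(frozen=True)
class ResponseScenario:
    """A truth vector of per-basket response rates."""

    p: tuple
    name: str = ""

    def __post_init__(self):
        p = tuple(float(v) for v in self.p)
        if any(not (0.0 <= v <= 1.0) for v in p):
            raise ValueError("true response rates must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    def null_mask(self, q0: float) -> np.ndarray:
        """Baskets that are truly null (p_k <= q0)."""
        return np.asarray(self.p) <= q0


@dataclass
class ModelConfig:
    """Prior hyperparameters and sampler settings for one analysis method.

    Field defaults follow the standard specification used throughout:
    EX mean mu ~ N(logit(0.15), 10^2) for every hierarchical method; the
    plain hierarchical model takes sigma ~ Half-Cauchy(0, 25); the EX/NEX
    mixture takes sigma ~ Half-Normal(0, 1) and NEX component
    M2k ~ N(-0.62, 4.42) (a unit-information prior centered at a plausible
    rate of 0.35, variance scale); its modified variant places the
    Half-Normal(0, 1) on sigma^2 instead; model averaging pools with a
    Beta(0.45, 0.55) prior and weights models by (number of distinct
    rates)^2.

    ``nex_var`` is read as a variance (4.42); set ``nex_scale_is_sd=True``
    to reinterpret it as a standard deviation (squared internally).
    """

    method: str = "independent"
    mu_mean: float = logit(0.15)
    mu_var: float = 100.0
    sigma_prior_family: str | None = None  # resolved per method if None
    sigma_prior_scale: float | None = None
    nex_mean: float = -0.62
    nex_var: float = 4.42
    nex_scale_is_sd: bool = False
    pi: tuple | None = None  # EX prior weights; default 0.5 each for exnex
    c: float = 0.0  # heterogeneity-exclusion cut-off (mexnex)
    cbhm_a: float = -7.25
    cbhm_b: float = 5.86
    bma_beta: tuple = (0.45, 0.55)
    bma_prior_power: float = 2.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.sigma_prior_family is None:
            fam = {
                "bhm": ("half-cauchy", 25.0),
                "cbhm": ("fixed", None),
                "exnex": ("half-normal", 1.0),
                "mexnex": ("half-normal-var", 1.0),
            }.get(self.method)
            if fam is not None:
                self.sigma_prior_family, self.sigma_prior_scale = fam
        if self.c < 0:
            raise ValueError("cut-off c must be >= 0")

    @property
    def nex_variance(self) -> float:
        return self.nex_var**2 if self.nex_scale_is_sd else self.nex_var

    @classmethod
    def defaults(cls, method: str, **overrides) -> "ModelConfig":
        return cls(method=method, **overrides)


@dataclass
class PosteriorResult:
    """Per-basket posterior summaries from one analysis method."""

    method: str
    p_mean: np.ndarray
    p_sd: np.ndarray
    prob_exceed: np.ndarray
    labels: tuple | None = None
    draws: dict | None = None
    extras: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.p_mean = np.asarray(self.p_mean, dtype=float)
        self.p_sd = np.asarray(self.p_sd, dtype=float)
        self.prob_exceed = np.asarray(self.prob_exceed, dtype=float)
        if np.any((self.p_mean < 0) | (self.p_mean > 1)):
            raise ValueError("posterior means must lie in [0, 1]")
        if np.any((self.prob_exceed < 0) | (self.prob_exceed > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        idx = list(self.labels) if self.labels else list(range(1, len(self.p_mean) + 1))
        return pd.DataFrame(
            {
                "basket": idx,
                "p_mean": self.p_mean,
                "p_sd": self.p_sd,
                "prob_exceed": self.prob_exceed,
            }
        )


def load_basket_data(path, fmt: str | None = None, q0: float | None = None, q1: float | None = None) -> BasketData:
    """Read trial data from CSV (``basket,n,y`` [+ ``label``]) or JSON.

    ``q0``/``q1`` act as overrides and are required for CSV files that do
    not carry them as columns (constant per file).  Basket order is
    preserved as given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        doc = json.loads(path.read_text())
        q0 = q0 if q0 is not None else doc.get("q0")
        q1 = q1 if q1 is not None else doc.get("q1")
        baskets = doc["baskets"]
        n = [b["n"] for b in baskets]
        Y = [b["y"] for b in baskets]
        labels = [b.get("label", f"basket_{i + 1}") for i, b in enumerate(baskets)]
    elif fmt == "csv":
        df = pd.read_csv(path)
        missing = {"basket", "n", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        if q0 is None and "q0" in df.columns:
            q0 = float(df["q0"].iloc[0])
        if q1 is None and "q1" in df.columns:
            q1 = float(df["q1"].iloc[0])
        n = df["n"].tolist()
        Y = df["y"].tolist()
        labels = (
            df["label"].astype(str).tolist()
            if "label" in df.columns
            else df["basket"].astype(str).tolist()
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if q0 is None or q1 is None:
        raise ValueError("q0 and q1 must be supplied in the file or as overrides")
    for k, (nk, yk) in enumerate(zip(n, Y)):
        if float(nk) != int(nk) or float(yk) != int(yk):
            raise ValueError(f"basket {k + 1}: counts must be integers, got n={nk}, Y={yk}")
    return BasketData(n=n, Y=Y, q0=float(q0), q1=float(q1), labels=labels)


def write_basket_data(data: BasketData, path, fmt: str | None = None) -> None:
    """Serialize a :class:`BasketData`; inverse of :func:`load_basket_data`."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        doc = {
            "q0": data.q0,
            "q1": data.q1,
            "baskets": [
                {"label": lab, "n": nk, "y": yk}
                for lab, nk, yk in zip(data.labels, data.n, data.Y)
            ],
        }
        path.write_text(json.dumps(doc, indent=2))
    else:
        pd.DataFrame(
            {
                "basket": range(1, data.K + 1),
                "label": data.labels,
                "n": data.n,
                "y": data.Y,
                "q0": data.q0,
                "q1": data.q1,
            }
        ).to_csv(path, index=False)


def ve_basket_fixture() -> BasketData:
    """The packaged VE-BASKET dataset (vemurafenib in BRAF-V600 tumors).

    Five solid-tumor baskets with realized sizes (20, 10, 8, 18, 7) and
    response counts (8, 0, 1, 6, 2); null rate 15%, target 45%.
    """
    ref = resources.files("baskex.datasets") / "ve_basket.csv"
    with resources.as_file(ref) as p:
        return load_basket_data(p, fmt="csv")


def table1_scenarios(
    K: int = 5, q0: float = 0.15, q1: float = 0.45, q_mid: float = 0.35
) -> list[ResponseScenario]:
    """The standard true-response-rate scenario grid.

    For ``K = 5`` this is the full 16-scenario set used throughout the
    simulation studies (null, first-j-sensitive, marginally effective
    mixes, and reordered variants for unequal sample sizes).  For other
    ``K`` it degrades to the null scenario, every first-j-sensitive
    scenario, and the all-sensitive scenario.
    """
    if K == 5:
        rows = [
            (q0, q0, q0, q0, q0),
            (q1, q0, q0, q0, q0),
            (q1, q1, q0, q0, q0),
            (q1, q1, q1, q0, q0),
            (q1, q1, q1, q1, q0),
            (q1, q1, q1, q1, q1),
            (q_mid, q0, q0, q0, q0),
            (q_mid, q_mid, q_mid, q0, q0),
            (q1, q_mid, q_mid, q0, q0),
            (q1, q1, q_mid, q_mid, q0),
            (q0, q0, q0, q0, q1),
            (q0, q0, q1, q0, q1),
            (q0, q1, q1, q0, q1),
            (q0, q1, q1, q1, q1),
            (q1, q0, q0, q0, q1),
            (q1, q0, q1, q0, q1),
        ]
        return [
            ResponseScenario(p=row, name=f"Scenario {i + 1}") for i, row in enumerate(rows)
        ]
    out = [ResponseScenario(p=(q0,) * K, name="Scenario 1 (null)")]
    for j in range(1, K + 1):
        out.append(
            ResponseScenario(
                p=(q1,) * j + (q0,) * (K - j), name=f"Scenario {j + 1} (first {j} sensitive)"
            )
        )
    return out


def write_results(result, path, fmt: str | None = None, *, config: ModelConfig | None = None, seed: int | None = None) -> None:
    """Write a :class:`PosteriorResult` or operating-characteristics object.

    CSV output is one row per basket; JSON output carries full precision
    plus a config echo and seed for reproducibility.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if isinstance(result, PosteriorResult):
        if fmt == "csv":
            result.to_frame().to_csv(path, index=False)
        else:
            doc = {
                "method": result.method,
                "labels": list(result.labels) if result.labels else None,
                "p_mean": result.p_mean.tolist(),
                "p_sd": result.p_sd.tolist(),
                "prob_exceed": result.prob_exceed.tolist(),
                "extras": _jsonable(result.extras),
            }
            if config is not None:
                doc["config"] = _jsonable(asdict(config))
            if seed is not None:
                doc["seed"] = seed
            path.write_text(json.dumps(doc, indent=2))
        return
    # operating characteristics / anything dataclass-like
    doc = _jsonable(asdict(result) if hasattr(result, "__dataclass_fields__") else result)
    if fmt == "csv":
        pd.json_normalize(doc).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(doc, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
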