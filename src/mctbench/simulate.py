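"""Synthetic-data generator for the Monte-Carlo comparison of MCTs.

The study crosses four factors into a 16-cell grid:

* balance — balanced (equal group sizes) vs unbalanced;
* error type — typeI (all group means 0; every rejection is a false
  positive) vs typeII (one group mean shifted to 1; every missed rejection of
  a shifted-vs-null pair is a false negative);
* treatment — LSFG / LSMG / HSFG / HSMG: low (n = 10) or high (n = 100)
  sample size crossed with few (k = 3) or many (k = 7) groups.

Observations are i.i.d. normal with common standard deviation 3 (a noise
level that separates the competing tests without saturating them either way).
Unbalanced cells draw group sizes from the menus {5, 10, 15} (low) or
{85, 100, 115} (high), assigned by deterministic cycling so the mean group
size equals the balanced size.  The shifted group under typeII is the first
group ("control vs treatments" reading).

Reproducibility: iteration ``i`` of design ``d`` uses an independent
``numpy.random.SeedSequence([master_seed, d, i])`` stream, so any dataset can
be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .core import Dataset
from .exceptions import InvalidConfigError

__all__ = [
    "StudyConfig",
    "SimulationDesign",
    "RngPolicy",
    "make_design_grid",
    "simulate_dataset",
    "BALANCES",
    "ERROR_TYPES",
    "TREATMENTS",
]

BALANCES = ("balanced", "unbalanced")
ERROR_TYPES = ("typeI", "typeII")
TREATMENTS = ("LSFG", "LSMG", "HSFG", "HSMG")


@dataclass(frozen=True)
class StudyConfig:
    """Generator and study parameters; defaults are the study conditions."""

    iterations: int = 100
    alpha: float = 0.05
    sigma: float = 3.0
    shift: float = 1.0
    low_n: int = 10
    high_n: int = 100
    unbalanced_low: tuple[int, ...] = (5, 10, 15)
    unbalanced_high: tuple[int, ...] = (85, 100, 115)
    few_groups: int = 3
    many_groups: int = 7
    shifted_group: int = 0
    master_seed: int = 20240501

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InvalidConfigError("iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.sigma <= 0:
            raise InvalidConfigError("sigma must be > 0")
        for name in ("low_n", "high_n"):
            if getattr(self, name) < 2:
                raise InvalidConfigError(f"{name} must be >= 2")
        for name in ("unbalanced_low", "unbalanced_high"):
            menu = tuple(getattr(self, name))
            object.__setattr__(self, name, menu)
            if len(menu) == 0 or min(menu) < 2:
                raise InvalidConfigError(f"{name} sizes must all be >= 2")
        for name in ("few_groups", "many_groups"):
            if getattr(self, name) < 2:
                raise InvalidConfigError(f"{name} must be >= 2")
        if not 0 <= self.shifted_group < min(self.few_groups, self.many_groups):
            raise InvalidConfigError("shifted_group index out of range")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise InvalidConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["unbalanced_low"] = list(d["unbalanced_low"])
        d["unbalanced_high"] = list(d["unbalanced_high"])
        return d


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the 16-cell simulation grid."""

    balance: str
    error_type: str
    treatment: str
    n_groups: int
    group_sizes: tuple[int, ...]
    mu: tuple[float, ...]
    sigma: float
    iterations: int
    index: int  # position in the grid; part of the RNG stream key

    def __post_init__(self) -> None:
        if self.balance not in BALANCES:
            raise InvalidConfigError(f"balance must be in {BALANCES}")
        if self.error_type not in ERROR_TYPES:
            raise InvalidConfigError(f"error_type must be in {ERROR_TYPES}")
        if self.treatment not in TREATMENTS:
            raise InvalidConfigError(f"treatment must be in {TREATMENTS}")
        if len(self.group_sizes) != self.n_groups or len(self.mu) != self.n_groups:
            raise InvalidConfigError("group_sizes and mu must have length n_groups")
        if self.balance == "balanced" and len(set(self.group_sizes)) != 1:
            raise InvalidConfigError("balanced design requires equal group sizes")
        n_shifted = sum(1 for m in self.mu if m != 0.0)
        if self.error_type == "typeI" and n_shifted != 0:
            raise InvalidConfigError("typeI design must have all means 0")
        if self.error_type == "typeII" and n_shifted != 1:
            raise InvalidConfigError("typeII design must have exactly one shifted mean")
        if self.sigma <= 0 or self.iterations < 1:
            raise InvalidConfigError("sigma must be > 0 and iterations >= 1")

    @property
    def design_id(self) -> str:
        return f"{self.balance}:{self.error_type}:{self.treatment}"

    @property
    def shifted_group(self) -> int | None:
        """Index of the shifted group, or None for a typeI design."""
        for g, m in enumerate(self.mu):
            if m != 0.0:
                return g
        return None

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(f"g{i + 1}" for i in range(self.n_groups))


@dataclass(frozen=True)
class RngPolicy:
    """Keyed substream rule: (master_seed, design index, iteration) -> stream."""

    master_seed: int = 20240501

    def generator(self, design_index: int, iteration: int) -> np.random.Generator:
        seq = np.random.SeedSequence([int(self.master_seed), int(design_index), int(iteration)])
        return np.random.default_rng(seq)


def _cycled_sizes(menu: Sequence[int], k: int) -> tuple[int, ...]:
    """Deterministic cycling of the size menu across k groups.

    A trailing partial cycle is replaced by mean-preserving picks (the middle
    size for one leftover group, the extremes for two), so the average group
    size equals the balanced n for the symmetric default menus: 3 groups ->
    (5, 10, 15), 7 groups -> (5, 10, 15, 5, 10, 15, 10).
    """
    m = len(menu)
    sizes = [menu[i % m] for i in range(k)]
    rem = k % m
    srt = sorted(menu)
    if rem == 1:
        sizes[-1] = srt[m // 2]
    elif rem == 2 and m == 3:
        sizes[-2:] = [srt[0], srt[2]]
    return tuple(sizes)


def make_design_grid(config: StudyConfig | None = None) -> list[SimulationDesign]:
    """The 16 designs: 2 balance x 2 error-type x 4 treatments."""
    cfg = config or StudyConfig()
    designs: list[SimulationDesign] = []
    idx = 0
    for balance in BALANCES:
        for error_type in ERROR_TYPES:
            for treatment in TREATMENTS:
                k = cfg.few_groups if treatment.endswith("FG") else cfg.many_groups
                if balance == "balanced":
                    n = cfg.low_n if treatment.startswith("LS") else cfg.high_n
                    sizes = (n,) * k
                else:
                    menu = cfg.unbalanced_low if treatment.startswith("LS") else cfg.unbalanced_high
                    sizes = _cycled_sizes(menu, k)
                mu = [0.0] * k
                if error_type == "typeII":
                    mu[cfg.shifted_group] = cfg.shift
                designs.append(
                    SimulationDesign(
                        balance=balance,
                        error_type=error_type,
                        treatment=treatment,
                        n_groups=k,
                        group_sizes=sizes,
                        mu=tuple(mu),
                        sigma=cfg.sigma,
                        iterations=cfg.iterations,
                        index=idx,
                    )
                )
                idx += 1
    return designs


def simulate_dataset(design: SimulationDesign, rng: RngPolicy, iteration: int) -> Dataset:
    """Draw one dataset for the given design cell and iteration.

    Group g receives ``design.group_sizes[g]`` i.i.d. Normal(mu[g], sigma)
    values; identical (master_seed, design, iteration) keys reproduce the
    dataset bit-identically.
    """
    gen = rng.generator(design.index, iteration)
    values = [
        gen.normal(loc=m, scale=design.sigma, size=n)
        for m, n in zip(design.mu, design.group_sizes)
    ]
    return Dataset(design.group_labels, tuple(values))
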