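"""Synthetic juvenile populations of scale circulus spacing index (SCSI) values.

The simulated study population is a finite collection of normally
distributed SCSI values (default: one million individuals, mean 30, SD 5).
Mixtures of two or more normal components model the scenario in which an
adult sample is drawn from several juvenile populations, only one of which
was available to juvenile sampling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

RngLike = "int | np.random.SeedSequence | np.random.Generator"


def _as_generator(seed) -> np.random.Generator:
    """Coerce an int, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a normal SCSI-generating distribution.

    Attributes
    ----------
    mean, sd : float
        Mean and standard deviation of the SCSI in the population
        (defaults 30 and 5, the study population).
    size : int
        Number of individuals in the finite population (default 10**6).
    label : str
        Free-text identifier carried into output headers.
    """

    mean: float = 30.0
    sd: float = 5.0
    size: int = 1_000_000
    label: str = ""

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if int(self.size) < 1:
            raise ValueError(f"size must be >= 1, got {self.size}")
        object.__setattr__(self, "size", int(self.size))


@dataclass
class Population:
    """A realised finite population of SCSI values.

    Regenerating with the same ``(spec, seed)`` pair reproduces ``values``
    bit for bit.
    """

    values: np.ndarray
    spec: PopulationSpec
    seed: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.size,):
            raise ValueError(
                f"values length {self.values.size} != spec.size {self.spec.size}"
            )


def generate_population(spec: PopulationSpec, seed) -> Population:
    """Draw a finite population of i.i.d. Normal(spec.mean, spec.sd) values.

    Parameters
    ----------
    spec : PopulationSpec
    seed : int, SeedSequence or Generator
        Source of randomness; the same integer seed always yields the same
        population.
    """
    rng = _as_generator(seed)
    values = rng.normal(spec.mean, spec.sd, spec.size)
    return Population(values=values, spec=spec, seed=seed)


def component_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer per-component counts for an exact-composition mixture sample.

    Fractions are rounded half away from zero; any discrepancy from ``n``
    is absorbed by the largest component so the counts always sum to ``n``.
    For the study designs every ``fraction * n`` is already an integer, so
    the adjustment only matters for user-supplied designs.
    """
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions * n
    counts = np.floor(raw + 0.5).astype(int)  # round half away from zero (fractions >= 0)
    diff = n - counts.sum()
    if diff != 0:
        counts[int(np.argmax(fractions))] += diff
    if (counts < 0).any():
        raise ValueError("component counts became negative after adjustment")
    return counts


@dataclass
class MixtureDesign:
    """Composition of an adult sample drawn from several juvenile populations.

    Attributes
    ----------
    components : sequence of (PopulationSpec, float)
        Component distributions and their contribution fractions; fractions
        must sum to 1. The study pairs a Normal(30, 5) component with a
        Normal(35, 5) or Normal(40, 5) component at contributions
        90:10 down to 40:60.
    adult_n : int
        Adult sample size.
    juvenile_reference_n : int or None
        Size of the juvenile reference sample drawn from the reference
        component; ``None`` means "same as adult_n".
    juvenile_reference_population : int
        Index of the component representing the juvenile population that
        was actually sampled (default 0, i.e. population 1).
    composition : {"exact", "binomial"}
        "exact" (default) uses deterministic per-component counts
        ``round(fraction * adult_n)``; "binomial" draws each individual's
        component at random — provided for sensitivity analysis.
    """

    components: Sequence[tuple[PopulationSpec, float]]
    adult_n: int = 200
    juvenile_reference_n: int | None = None
    juvenile_reference_population: int = 0
    composition: str = "exact"

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("at least one mixture component is required")
        fracs = np.array([f for _, f in self.components], dtype=float)
        if (fracs < 0).any() or (fracs > 1).any():
            raise ValueError("contribution fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"contribution fractions sum to {fracs.sum()}, not 1")
        if int(self.adult_n) < 1:
            raise ValueError("adult_n must be >= 1")
        if self.composition not in ("exact", "binomial"):
            raise ValueError(f"unknown composition mode {self.composition!r}")
        if not 0 <= self.juvenile_reference_population < len(self.components):
            raise ValueError("juvenile_reference_population out of range")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.components], dtype=float)

    @property
    def reference_spec(self) -> PopulationSpec:
        return self.components[self.juvenile_reference_population][0]

    @property
    def reference_n(self) -> int:
        return self.adult_n if self.juvenile_reference_n is None else self.juvenile_reference_n


def generate_mixture_sample(design: MixtureDesign, seed) -> np.ndarray:
    """Draw one adult sample of size ``design.adult_n`` from the mixture.

    Under exact composition each component contributes exactly
    ``round(fraction * adult_n)`` values; the assembled sample is returned
    in randomised order.
    """
    rng = _as_generator(seed)
    if design.composition == "exact":
        counts = component_counts(design.fractions, design.adult_n)
    else:
        counts = rng.multinomial(design.adult_n, design.fractions)
    parts = [
        rng.normal(spec.mean, spec.sd, k)
        for (spec, _), k in zip(design.components, counts)
    ]
    sample = np.concatenate(parts)
    rng.shuffle(sample)
    return sample


def sample_without_replacement(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """Draw ``k`` distinct elements from ``pool`` (uniformly, without replacement).

    Uses collision rejection on indices, which is O(k) for k much smaller
    than the pool instead of the O(len(pool)) cost of a partial shuffle —
    the regime of every study design (samples of at most 10**3 from a pool
    of order 10**5 or more).
    """
    n = len(pool)
    if k > n:
        raise ValueError(f"cannot draw {k} values without replacement from a pool of {n}")
    if k * 2 > n:  # dense draws: fall back to a permutation-based pick
        return pool[rng.permutation(n)[:k]]
    idx = rng.integers(0, n, k)
    uniq = np.unique(idx)
    while uniq.size < k:
        extra = rng.integers(0, n, k - uniq.size)
        uniq = np.unique(np.concatenate([uniq, extra]))
    return pool[uniq]


def write_values_csv(path, values: np.ndarray, header_fields: dict | None = None) -> None:
    """Serialise a value collection to single-column CSV.

    ``header_fields`` (e.g. spec parameters and the seed) are recorded as
    ``# key=value`` comment lines so the file is self-describing.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_fields or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("scsi\n")
        np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.17g")


def read_values_csv(path) -> np.ndarray:
    """Read a single-column CSV written by :func:`write_values_csv`."""
    with open(path, "r", encoding="utf-8") as fh:
        text = "\n".join(
            line for line in fh.read().splitlines()
            if line and not line.startswith("#")
        )
    return np.loadtxt(io.StringIO(text), skiprows=1, ndmin=1)
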