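"""Knife-edge size-selective mortality and its analytic expectations.

Under the critical-size hypothesis every individual whose SCSI falls below
a critical limit dies before adulthood, so the adult distribution is the
parent normal left-truncated at that limit. This module computes the
quantile-based critical limits, applies the knife-edge cut, and provides
closed-form moments of left-truncated normals and of normal mixtures —
the analytic expectations against which simulated samples are judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Tolerance (SCSI units) within which a user-supplied critical limit must
#: agree with the quantile implied by (mean, sd, rate).
LIMIT_TOLERANCE = 0.005


def critical_limit(mean: float, sd: float, rate: float) -> float:
    """Critical SCSI limit producing a given knife-edge mortality rate.

    Returns ``mean + sd * Phi^{-1}(rate)``: the value below which the
    stated fraction of the parent Normal(mean, sd) lies. For the study
    population Normal(30, 5) the limits at 20/40/60/80% mortality are
    25.79, 28.73, 31.27 and 34.21 (2 dp).
    """
    if not 0 <= rate < 1:
        raise ValueError(f"mortality rate must lie in [0, 1), got {rate}")
    if not sd > 0:
        raise ValueError(f"sd must be positive, got {sd}")
    return float(mean + sd * stats.norm.ppf(rate))


@dataclass(frozen=True)
class MortalityScenario:
    """A knife-edge mortality rate and its critical SCSI limit."""

    rate: float
    critical_limit: float

    def __post_init__(self):
        if not 0 <= self.rate < 1:
            raise ValueError(f"mortality rate must lie in [0, 1), got {self.rate}")

    @classmethod
    def from_rate(cls, rate: float, spec=None, mean: float = 30.0, sd: float = 5.0):
        """Build a scenario whose limit is the exact rate-quantile of the
        reference population (full floating precision, not the 2-dp display)."""
        if spec is not None:
            mean, sd = spec.mean, spec.sd
        return cls(rate=rate, critical_limit=critical_limit(mean, sd, rate))

    def validate_against(self, spec) -> None:
        """Warn if the stored limit is not the rate-quantile of ``spec``.

        Printed limits are treated as rounded displays; a discrepancy
        beyond ``LIMIT_TOLERANCE`` suggests the limit and rate disagree.
        """
        implied = critical_limit(spec.mean, spec.sd, self.rate)
        if abs(implied - self.critical_limit) > LIMIT_TOLERANCE:
            warnings.warn(
                f"critical limit {self.critical_limit} differs from the "
                f"{self.rate:.0%} quantile of the reference population "
                f"({implied:.4f}) by more than {LIMIT_TOLERANCE}",
                stacklevel=2,
            )


def apply_knife_edge(values, limit: float) -> np.ndarray:
    """Survivors of knife-edge mortality: values >= limit, order preserved.

    A value exactly equal to the limit survives (mortality strikes those
    *below* the critical size); an empty survivor set is legal.
    """
    values = np.asarray(values, dtype=float)
    return values[values >= limit]


@dataclass(frozen=True)
class TruncatedNormalMoments:
    """Closed-form moments of a left-truncated normal distribution."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    truncation_point: float


def truncated_normal_moments(mean: float, sd: float, truncation_point: float) -> TruncatedNormalMoments:
    """Moments of Normal(mean, sd) conditioned on values >= truncation_point.

    Standardised raw moments of the lower-truncated standard normal obey
    the recursion ``m_k = (k-1) m_{k-2} + a^{k-1} * lam`` where ``a`` is the
    standardised cut point and ``lam = phi(a) / (1 - Phi(a))`` the hazard
    (inverse Mills ratio); central moments follow by binomial expansion.
    Left truncation raises the mean, shrinks the SD and induces positive
    skewness and excess kurtosis — the signature the knife-edge hypothesis
    predicts for adult samples.
    """
    if not sd > 0:
        raise ValueError(f"sd must be positive, got {sd}")
    a = (truncation_point - mean) / sd
    sf = stats.norm.sf(a)
    if sf <= 0 or not np.isfinite(sf):
        raise ValueError(
            f"survival probability underflows for truncation at {truncation_point} "
            f"(standardised cut {a:.2f})"
        )
    lam = stats.norm.pdf(a) / sf
    m1 = lam
    m2 = 1.0 + a * lam
    m3 = 2.0 * m1 + a**2 * lam
    m4 = 3.0 * m2 + a**3 * lam
    c2 = m2 - m1**2
    c3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    c4 = m4 - 4.0 * m1 * m3 + 6.0 * m1**2 * m2 - 3.0 * m1**4
    return TruncatedNormalMoments(
        mean=float(mean + sd * m1),
        sd=float(sd * np.sqrt(c2)),
        skewness=float(c3 / c2**1.5),
        excess_kurtosis=float(c4 / c2**2 - 3.0),
        truncation_point=float(truncation_point),
    )


@dataclass(frozen=True)
class MixtureMoments:
    """Exact population moments of a weighted normal mixture."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float


def mixture_moments(components: Sequence[tuple[float, float, float]]) -> MixtureMoments:
    """Population moments of a mixture of normals.

    Parameters
    ----------
    components : sequence of (mean, sd, weight)
        Weights must sum to 1.

    Central moments combine as
    ``c2 = sum w (s^2 + d^2)``, ``c3 = sum w (d^3 + 3 d s^2)``,
    ``c4 = sum w (d^4 + 6 d^2 s^2 + 3 s^4)`` with ``d = mu_i - mu``.
    """
    if len(components) == 0:
        raise ValueError("at least one mixture component is required")
    mu_i = np.array([c[0] for c in components], dtype=float)
    sd_i = np.array([c[1] for c in components], dtype=float)
    w = np.array([c[2] for c in components], dtype=float)
    if (sd_i <= 0).any():
        raise ValueError("component sds must be positive")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, not 1")
    mean = float(np.sum(w * mu_i))
    d = mu_i - mean
    c2 = float(np.sum(w * (sd_i**2 + d**2)))
    c3 = float(np.sum(w * (d**3 + 3.0 * d * sd_i**2)))
    c4 = float(np.sum(w * (d**4 + 6.0 * d**2 * sd_i**2 + 3.0 * sd_i**4)))
    return MixtureMoments(
        mean=mean,
        sd=float(np.sqrt(c2)),
        skewness=float(c3 / c2**1.5),
        excess_kurtosis=float(c4 / c2**2 - 3.0),
    )
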