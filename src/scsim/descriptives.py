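"""Per-sample descriptive statistic battery.

Every simulated or observed sample is summarised by the same battery:
n, mean, median, min, max, range, SD (n-1 denominator), skewness, excess
kurtosis, and — when a reference maximum is supplied — the percentage of
values strictly exceeding it (the "exceedance" of an adult sample over the
largest juvenile observed).

Skewness and kurtosis use the bias-corrected G1/G2 estimators (the common
spreadsheet convention): G1 = [n/((n-1)(n-2))] * sum(z^3) and
G2 = {n(n+1)/[(n-1)(n-2)(n-3)]} * sum(z^4) - 3(n-1)^2/[(n-2)(n-3)], which
scipy exposes as ``skew(..., bias=False)`` / ``kurtosis(..., bias=False)``.
"Kurtosis" always means excess kurtosis (normal = 0). Uncorrected g1/g2
are available via ``bias_corrected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SampleStats:
    """The descriptive battery for one sample.

    ``skewness`` and ``excess_kurtosis`` are NaN ("undefined") for n < 4;
    ``pct_exceeding`` is None when no reference maximum was supplied.
    """

    n: int
    mean: float
    median: float
    min: float
    max: float
    range: float
    sd: float
    skewness: float
    excess_kurtosis: float
    pct_exceeding: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


STAT_COLUMNS = [
    "n", "mean", "median", "min", "max", "range",
    "sd", "skewness", "excess_kurtosis", "pct_exceeding",
]


def sample_descriptives(values, reference_max: float | None = None,
                        bias_corrected: bool = True) -> SampleStats:
    """Compute the battery for a single sample of SCSI values.

    Parameters
    ----------
    values : array-like
        The sample; must be non-empty.
    reference_max : float, optional
        Largest value of the paired juvenile sample;
        ``pct_exceeding = 100 * #{v > reference_max} / n``
        (strict inequality).
    bias_corrected : bool
        Use G1/G2 (default) or the uncorrected moment ratios g1/g2.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    n = values.size
    vmin = float(values.min())
    vmax = float(values.max())
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    if n >= 4 and sd > 0:
        skew = float(stats.skew(values, bias=not bias_corrected))
        kurt = float(stats.kurtosis(values, bias=not bias_corrected, fisher=True))
    else:
        skew = float("nan")
        kurt = float("nan")
    pct = None
    if reference_max is not None:
        pct = float(100.0 * np.count_nonzero(values > reference_max) / n)
    return SampleStats(
        n=n,
        mean=float(values.mean()),
        median=float(np.median(values)),
        min=vmin,
        max=vmax,
        range=vmax - vmin,
        sd=sd,
        skewness=skew,
        excess_kurtosis=kurt,
        pct_exceeding=pct,
    )


def batch_descriptives(values: np.ndarray, reference_max=None,
                       bias_corrected: bool = True) -> pd.DataFrame:
    """Vectorised battery over a (replicates, n) matrix of samples.

    One row per replicate, columns as in :class:`SampleStats`.
    ``reference_max`` may be a scalar or a per-replicate vector.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("expected a non-empty (replicates, n) matrix")
    r, n = values.shape
    out = pd.DataFrame(index=np.arange(r))
    out["n"] = n
    out["mean"] = values.mean(axis=1)
    out["median"] = np.median(values, axis=1)
    out["min"] = values.min(axis=1)
    out["max"] = values.max(axis=1)
    out["range"] = out["max"] - out["min"]
    out["sd"] = values.std(axis=1, ddof=1) if n > 1 else np.nan
    if n >= 4:
        out["skewness"] = stats.skew(values, axis=1, bias=not bias_corrected)
        out["excess_kurtosis"] = stats.kurtosis(
            values, axis=1, bias=not bias_corrected, fisher=True
        )
    else:
        out["skewness"] = np.nan
        out["excess_kurtosis"] = np.nan
    if reference_max is not None:
        ref = np.asarray(reference_max, dtype=float).reshape(-1, 1)
        out["pct_exceeding"] = 100.0 * (values > ref).mean(axis=1)
    else:
        out["pct_exceeding"] = np.nan
    return out
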