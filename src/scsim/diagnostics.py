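"""Decision framework for observed juvenile/adult SCSI sample pairs.

A knife-edge critical size limit acting on a single population predicts a
conjunction of changes from the juvenile to the adult sample: mean up, SD
down, range down, skewness up, kurtosis up, and almost no adults beyond
the largest juvenile observed. An unsampled second population of larger
individuals predicts the mean shift *without* the variance compression —
SD and range grow, and many adults exceed the juvenile maximum. The
diagnostics here evaluate that checklist, compare observed exceedance
against its Monte-Carlo null band, provide the 1-df chi-square
goodness-of-fit test on exceedance counts, and project a juvenile
histogram through a hypothesised knife-edge cut for visual comparison
with the observed adult histogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from scsim.descriptives import SampleStats, batch_descriptives
from scsim.mortality import MortalityScenario
from scsim.populations import PopulationSpec
from scsim.replicates import SampleDesign, run_knife_edge_scenario

VERDICT_KNIFE_EDGE = "consistent-with-knife-edge-mortality"
VERDICT_SECOND_POPULATION = "consistent-with-second-population"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class EmpiricalHistogram:
    """Binned SCSI measurements: B+1 ascending edges and B counts."""

    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("need B+1 bin edges for B counts")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class NullExceedance:
    """Monte-Carlo null distribution summary of the exceedance percentage."""

    median: float
    lower: float      # 2.5th percentile
    upper: float      # 97.5th percentile
    mean: float
    replicates: int
    warning: str | None = None


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    pvalue: float
    small_expected_cell: bool = False
    tiny_expected_cell: bool = False


@dataclass
class DiagnosticReport:
    """Checklist outcome for one juvenile/adult pair.

    ``directions`` maps each statistic to "increased" / "decreased" /
    "unchanged" / "unavailable" (juvenile -> adult).
    """

    directions: dict
    observed_pct_exceeding: float | None
    null_exceedance: NullExceedance | None
    chisq: ChisqResult | None
    verdict: str
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "verdict": self.verdict,
            "observed_pct_exceeding": self.observed_pct_exceeding,
            "notes": list(self.notes),
        }
        for stat, direction in self.directions.items():
            out[f"direction_{stat}"] = direction
        if self.null_exceedance is not None:
            out["null_exceedance_median"] = self.null_exceedance.median
            out["null_exceedance_lower"] = self.null_exceedance.lower
            out["null_exceedance_upper"] = self.null_exceedance.upper
        if self.chisq is not None:
            out["chisq_statistic"] = self.chisq.statistic
            out["chisq_df"] = self.chisq.df
            out["chisq_pvalue"] = self.chisq.pvalue
        return out

    def to_text(self) -> str:
        lines = ["Juvenile vs adult SCSI diagnostic", "=" * 34]
        for stat, direction in self.directions.items():
            lines.append(f"{stat:>16s}: {direction}")
        if self.observed_pct_exceeding is not None:
            lines.append(f"observed exceedance: {self.observed_pct_exceeding:.2f}%")
        if self.null_exceedance is not None:
            ne = self.null_exceedance
            lines.append(
                f"null exceedance: median {ne.median:.2f}% "
                f"(95% band {ne.lower:.2f}-{ne.upper:.2f}%)"
            )
        if self.chisq is not None:
            lines.append(
                f"chi-square: {self.chisq.statistic:.2f} "
                f"(df={self.chisq.df}, p={self.chisq.pvalue:.3g})"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _direction(j: float, a: float) -> str:
    if j is None or a is None or np.isnan(j) or np.isnan(a):
        return "unavailable"
    if a > j:
        return "increased"
    if a < j:
        return "decreased"
    return "unchanged"


def diagnose_pair(
    juvenile: SampleStats,
    adult: SampleStats,
    null_exceedance: NullExceedance | tuple | None = None,
    chisq: ChisqResult | None = None,
) -> DiagnosticReport:
    """Apply the decision checklist to a juvenile/adult battery pair.

    The knife-edge verdict requires *all* of: mean increased, SD
    decreased, range decreased, skewness increased, kurtosis increased,
    and observed exceedance within the null band's upper bound. The
    second-population verdict fires when the mean increased but the SD or
    range increased — or the exceedance breaks the null bound. Anything
    else is indeterminate.
    """
    if isinstance(null_exceedance, tuple):
        med, lo, hi = null_exceedance
        null_exceedance = NullExceedance(
            median=med, lower=lo, upper=hi, mean=float("nan"), replicates=0
        )

    directions = {
        "mean": _direction(juvenile.mean, adult.mean),
        "sd": _direction(juvenile.sd, adult.sd),
        "range": _direction(juvenile.range, adult.range),
        "skewness": _direction(juvenile.skewness, adult.skewness),
        "kurtosis": _direction(juvenile.excess_kurtosis, adult.excess_kurtosis),
    }
    notes = []
    unavailable = [k for k, v in directions.items() if v == "unavailable"]
    if unavailable:
        notes.append(f"unavailable checklist statistics: {', '.join(unavailable)}")

    observed_pct = adult.pct_exceeding
    exceed_ok = None  # None: cannot evaluate
    if observed_pct is not None and null_exceedance is not None:
        exceed_ok = observed_pct <= null_exceedance.upper

    knife_edge = (
        directions["mean"] == "increased"
        and directions["sd"] == "decreased"
        and directions["range"] == "decreased"
        and directions["skewness"] == "increased"
        and directions["kurtosis"] == "increased"
        and exceed_ok is True
    )
    second_population = directions["mean"] == "increased" and (
        directions["sd"] == "increased"
        or directions["range"] == "increased"
        or exceed_ok is False
    )

    if knife_edge:
        verdict = VERDICT_KNIFE_EDGE
    elif second_population:
        verdict = VERDICT_SECOND_POPULATION
    else:
        verdict = VERDICT_INDETERMINATE
        if exceed_ok is None:
            notes.append("exceedance comparison unavailable")

    return DiagnosticReport(
        directions=directions,
        observed_pct_exceeding=observed_pct,
        null_exceedance=null_exceedance,
        chisq=chisq,
        verdict=verdict,
        notes=notes,
    )


def expected_null_exceedance(
    juvenile_n: int,
    adult_n: int,
    spec: PopulationSpec,
    scenario: MortalityScenario,
    replicates: int = 2_000,
    seed: int = 0,
    population_mode: str = "fresh-draws",
) -> NullExceedance:
    """Null distribution of the exceedance percentage under knife-edge truncation.

    Simulates the single-population null — juvenile sample of
    ``juvenile_n``, knife-edge cut at the scenario limit, adult sample of
    ``adult_n`` — and returns the median, central 95% band, and mean of
    the per-replicate exceedance percentage. With rate 0 the mean
    proportion is the exchangeability value 1/(juvenile_n + 1).
    """
    warning = None
    if replicates < 100:
        warning = f"only {replicates} replicates; null band is unreliable"
        warnings.warn(warning, stacklevel=2)
    design = SampleDesign(
        juvenile_n=juvenile_n,
        adult_n=adult_n,
        replicates=replicates,
        seed=seed,
        population_mode=population_mode,
    )
    res = run_knife_edge_scenario(spec, scenario, design, keep_replicates=True)
    pct = res.per_replicate["pct_exceeding"].to_numpy()
    return NullExceedance(
        median=float(np.median(pct)),
        lower=float(np.percentile(pct, 2.5)),
        upper=float(np.percentile(pct, 97.5)),
        mean=float(pct.mean()),
        replicates=replicates,
        warning=warning,
    )


def chisq_exceedance(observed_exceeding: int, adult_n: int,
                     expected_proportion: float) -> ChisqResult:
    """1-df goodness-of-fit chi-square on the {exceeding, not exceeding} table."""
    if not 0 < expected_proportion < 1:
        raise ValueError("expected_proportion must lie strictly between 0 and 1")
    if not 0 <= observed_exceeding <= adult_n:
        raise ValueError("observed_exceeding must lie in [0, adult_n]")
    exp = np.array([expected_proportion, 1.0 - expected_proportion]) * adult_n
    obs = np.array([observed_exceeding, adult_n - observed_exceeding], dtype=float)
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    pvalue = float(sps.chi2.sf(statistic, df=1))
    tiny = bool((exp < 1).any())
    small = bool((exp < 5).any())
    if tiny:
        warnings.warn("an expected cell count is below 1; chi-square is unreliable",
                      stacklevel=2)
    return ChisqResult(statistic=statistic, df=1, pvalue=pvalue,
                       small_expected_cell=small, tiny_expected_cell=tiny)


def project_adult_histogram(
    juvenile: EmpiricalHistogram,
    mortality_rate: float,
    adult_total: float,
) -> EmpiricalHistogram:
    """Project a juvenile histogram through a hypothesised knife-edge cut.

    The cut point is the empirical ``mortality_rate`` quantile of the
    histogram under within-bin uniform interpolation; all mass below it is
    removed (the cut bin is retained pro-rata) and the surviving mass is
    rescaled to ``adult_total``. Counts are returned as real numbers so
    conservation is exact.
    """
    if not 0 <= mortality_rate < 1:
        raise ValueError(f"mortality_rate must lie in [0, 1), got {mortality_rate}")
    total = juvenile.total
    if total <= 0:
        raise ValueError("juvenile histogram has no mass")
    cut_mass = mortality_rate * total
    cum = np.concatenate([[0.0], np.cumsum(juvenile.counts)])
    surviving = juvenile.counts.astype(float).copy()
    # remove mass bin by bin up to the interpolated cut point
    for b in range(len(surviving)):
        if cum[b + 1] <= cut_mass:
            surviving[b] = 0.0
        elif cum[b] < cut_mass:
            surviving[b] = cum[b + 1] - cut_mass
        else:
            break
    scale = adult_total / surviving.sum()
    return EmpiricalHistogram(
        bin_edges=juvenile.bin_edges,
        counts=surviving * scale,
        label=f"{juvenile.label} projected at {mortality_rate:.0%} mortality".strip(),
    )
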