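"""Configuration, CSV interfaces, and the two end-to-end table experiments.

``run_table1`` reproduces the full knife-edge factorial (juvenile n in
{50, 200, 1000} x adult n in {50, 200, 600, 1000} x mortality rate in
{20, 40, 60, 80}%, 48 scenarios) and ``run_table2`` the two-population
mixture factorial (adult n in {50, 200} x second component mean in
{35, 40} x second-component contribution 10-60%, 24 scenarios). Display
files mimic the layout of the deposited simulation outputs
("SimulatedStatistics-KnifeEdgeMortality.csv" and
"SimulatedStatistics-TwoSamples.csv"); full-precision companions carry
every battery statistic. Every output embeds the seed, the config hash
and the package version as comment-header lines, so a persisted config
re-run with the same seed reproduces the files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from scsim.mortality import MortalityScenario
from scsim.populations import MixtureDesign, PopulationSpec
from scsim.replicates import (
    FIXED_POPULATION,
    SampleDesign,
    run_knife_edge_scenario,
    run_mixture_scenario,
)

logger = logging.getLogger("scsim")

KNIFE_EDGE_FILENAME = "SimulatedStatistics-KnifeEdgeMortality.csv"
TWO_SAMPLES_FILENAME = "SimulatedStatistics-TwoSamples.csv"

TABLE1_COLUMNS = ["Juvenile", "Adult", "Mortality", "Median", "Range",
                  "Min", "Max", "SD", "Kurtosis", "Skew", "%"]
TABLE2_COLUMNS = ["Pop 1", "Pop 2", "Pop 3", "Mean", "Range",
                  "Min", "Max", "SD", "Kurtosis", "Skew", "%"]


@dataclass
class RunConfig:
    """Serializable description of one experiment run.

    Defaults are the study conditions: a Normal(30, 5) population of one
    million, 10,000 replicates, and the full factorial grids. ``fast``
    lowers the replicate count to 2,000 for quick turnaround runs.
    """

    experiment: str = "knife-edge"  # knife-edge | mixture | diagnose | project
    population_mean: float = 30.0
    population_sd: float = 5.0
    population_size: int = 1_000_000
    juvenile_sizes: tuple = (50, 200, 1000)
    adult_sizes: tuple = (50, 200, 600, 1000)
    mortality_rates: tuple = (0.2, 0.4, 0.6, 0.8)
    second_means: tuple = (35.0, 40.0)
    second_sd: float = 5.0
    contributions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    mixture_adult_sizes: tuple = (50, 200)
    replicates: int = 10_000
    seed: int = 1
    population_mode: str = FIXED_POPULATION
    display_decimals: int = 1
    fast: bool = False

    @property
    def effective_replicates(self) -> int:
        return 2_000 if self.fast else self.replicates

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(getattr(cls, k, None), tuple) else v
            for k, v in d.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def sha256(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _header_lines(config: RunConfig) -> list[str]:
    from scsim import __version__

    return [
        f"# scsim version={__version__}",
        f"# seed={config.seed}",
        f"# replicates={config.effective_replicates}",
        f"# config_sha256={config.sha256()}",
    ]


def write_table_csv(path, df: pd.DataFrame, config: RunConfig,
                    float_format: str | None = None) -> None:
    """Write a table with the provenance comment header."""
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=float_format)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(_header_lines(config)) + "\n")
        fh.write(buf.getvalue())


def read_table_csv(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table_csv` (comments skipped)."""
    return pd.read_csv(path, comment="#")


def _cell_seed(master_seed: int, cell_index: int):
    # independent, order-invariant stream per factorial cell
    return (int(master_seed), int(cell_index))


def run_table1(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the knife-edge mortality factorial; optionally write CSVs.

    Returns the display table (one row per scenario, statistics rounded
    to ``display_decimals``); when ``out_dir`` is given, writes the
    display file under the deposited-layout name plus a full-precision
    ``*-raw.csv`` companion with every battery statistic.
    """
    spec = PopulationSpec(config.population_mean, config.population_sd,
                          config.population_size)
    rows, raw_rows = [], []
    cell = 0
    for jn in config.juvenile_sizes:
        for an in config.adult_sizes:
            for rate in config.mortality_rates:
                scenario = MortalityScenario.from_rate(rate, spec=spec)
                design = SampleDesign(
                    juvenile_n=jn, adult_n=an,
                    replicates=config.effective_replicates,
                    seed=_cell_seed(config.seed, cell),
                    population_mode=config.population_mode,
                )
                t0 = time.perf_counter()
                res = run_knife_edge_scenario(spec, scenario, design)
                logger.info(
                    "knife-edge cell %d (juvenile=%d adult=%d rate=%.0f%%): "
                    "%d replicates in %.2fs",
                    cell, jn, an, 100 * rate, res.replicates,
                    time.perf_counter() - t0,
                )
                s = res.stats
                d = config.display_decimals
                rows.append({
                    "Juvenile": jn, "Adult": an, "Mortality": int(round(100 * rate)),
                    "Median": round(s["median"], d), "Range": round(s["range"], d),
                    "Min": round(s["min"], d), "Max": round(s["max"], d),
                    "SD": round(s["sd"], d), "Kurtosis": round(s["excess_kurtosis"], d),
                    "Skew": round(s["skewness"], d), "%": round(s["pct_exceeding"], d),
                })
                raw_rows.append({**res.scenario, **{f"stat_{k}": v for k, v in s.items()}})
                cell += 1
    display = pd.DataFrame(rows, columns=TABLE1_COLUMNS)
    raw = pd.DataFrame(raw_rows)
    if out_dir is not None:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table_csv(out_dir / KNIFE_EDGE_FILENAME, display, config)
        write_table_csv(
            out_dir / KNIFE_EDGE_FILENAME.replace(".csv", "-raw.csv"), raw, config
        )
    return display


def run_table2(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Run the two-population mixture factorial; optionally write CSVs.

    The second component plays the role of "population 2" (mean 35) or
    "population 3" (mean 40); its contribution column is left blank in
    the display table when unused, mirroring the deposited layout.
    """
    pop1 = PopulationSpec(config.population_mean, config.population_sd,
                          config.population_size, label="population 1")
    rows, raw_rows = [], []
    cell = 0
    for an in config.mixture_adult_sizes:
        for second_mean in config.second_means:
            pop2 = PopulationSpec(second_mean, config.second_sd,
                                  config.population_size, label="population 2")
            for contrib in config.contributions:
                design = MixtureDesign(
                    components=[(pop1, 1.0 - contrib), (pop2, contrib)],
                    adult_n=an,
                )
                sample_design = SampleDesign(
                    juvenile_n=design.reference_n, adult_n=an,
                    replicates=config.effective_replicates,
                    seed=_cell_seed(config.seed, 10_000 + cell),
                )
                t0 = time.perf_counter()
                res = run_mixture_scenario(design, sample_design)
                logger.info(
                    "mixture cell %d (adult=%d second_mean=%.0f contribution=%.0f%%): "
                    "%d replicates in %.2fs",
                    cell, an, second_mean, 100 * contrib, res.replicates,
                    time.perf_counter() - t0,
                )
                s = res.stats
                d = config.display_decimals
                pct1 = int(round(100 * (1.0 - contrib)))
                pct2 = int(round(100 * contrib))
                rows.append({
                    "Pop 1": pct1,
                    "Pop 2": pct2 if second_mean == config.second_means[0] else "",
                    "Pop 3": pct2 if second_mean != config.second_means[0] else "",
                    "Mean": round(s["mean"], d), "Range": round(s["range"], d),
                    "Min": round(s["min"], d), "Max": round(s["max"], d),
                    "SD": round(s["sd"], d), "Kurtosis": round(s["excess_kurtosis"], d),
                    "Skew": round(s["skewness"], d), "%": round(s["pct_exceeding"], d),
                })
                raw_rows.append({
                    "adult_n": an, "second_mean": second_mean,
                    "second_contribution": contrib,
                    **{f"stat_{k}": v for k, v in s.items()},
                })
                cell += 1
    display = pd.DataFrame(rows, columns=TABLE2_COLUMNS)
    raw = pd.DataFrame(raw_rows)
    if out_dir is not None:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table_csv(out_dir / TWO_SAMPLES_FILENAME, display, config)
        write_table_csv(
            out_dir / TWO_SAMPLES_FILENAME.replace(".csv", "-raw.csv"), raw, config
        )
    return display


def read_observations(path) -> dict:
    """Read user-supplied juvenile/adult SCSI measurements.

    Two layouts are accepted (comment lines starting with ``#`` ignored):

    * per-individual values — columns ``stage, scsi``;
    * binned histograms — columns ``stage, bin_low, bin_high, count``.

    Returns a mapping of stage name to a float array of values or an
    :class:`~scsim.diagnostics.EmpiricalHistogram`.
    """
    from scsim.diagnostics import EmpiricalHistogram

    df = pd.read_csv(path, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    out = {}
    if "scsi" in cols:
        for stage, grp in df.groupby(cols["stage"]):
            out[str(stage)] = grp[cols["scsi"]].to_numpy(dtype=float)
    elif {"bin_low", "bin_high", "count"} <= set(cols):
        for stage, grp in df.groupby(cols["stage"]):
            grp = grp.sort_values(cols["bin_low"])
            lows = grp[cols["bin_low"]].to_numpy(dtype=float)
            highs = grp[cols["bin_high"]].to_numpy(dtype=float)
            if not np.allclose(lows[1:], highs[:-1]):
                raise ValueError(f"bins for stage {stage!r} are not contiguous")
            edges = np.concatenate([lows, highs[-1:]])
            out[str(stage)] = EmpiricalHistogram(
                bin_edges=edges,
                counts=grp[cols["count"]].to_numpy(dtype=float),
                label=str(stage),
            )
    else:
        raise ValueError(
            "expected columns (stage, scsi) or (stage, bin_low, bin_high, count); "
            f"got {list(df.columns)}"
        )
    return out


def write_histogram_csv(path, hist, config: RunConfig | None = None) -> None:
    """Write an :class:`EmpiricalHistogram` in the binned input layout."""
    df = pd.DataFrame({
        "stage": hist.label or "projected",
        "bin_low": hist.bin_edges[:-1],
        "bin_high": hist.bin_edges[1:],
        "count": hist.counts,
    })
    header = _header_lines(config) if config is not None else []
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)
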