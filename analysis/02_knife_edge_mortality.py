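"""Simulated adult samples under knife-edge size-selective mortality.

Runs the full factorial — juvenile sample size {50, 200, 1000} x adult
sample size {50, 200, 600, 1000} x mortality rate {20, 40, 60, 80}% —
over a Normal(30, 5) population of one million, 10,000 replicates per
scenario, and summarises every descriptive statistic of the adult sample
at its 50th percentile across replicates.

Writes results/SimulatedStatistics-KnifeEdgeMortality.csv (display) and
a full-precision -raw companion. Run with --fast for 2,000 replicates.
"""

import argparse
import logging
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from scsim.io import RunConfig, run_table1

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=10_000)
parser.add_argument("--fast", action="store_true", help="2,000 replicates per scenario")
args = parser.parse_args()

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
out = pathlib.Path(__file__).resolve().parents[1] / "results"

cfg = RunConfig(experiment="knife-edge", seed=args.seed,
                replicates=args.replicates, fast=args.fast)
df = run_table1(cfg, out_dir=out)
print(df.to_string(index=False))
print()
print("Reading: with rising mortality the adult median and minimum climb, the")
print("range and SD shrink, skewness and kurtosis rise. The % column — adults")
print("beyond the largest juvenile sampled — is driven almost entirely by the")
print("juvenile sample size: with 1,000 juveniles it stays at or below ~1%,")
print("with only 50 juveniles it can approach 18%.")
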