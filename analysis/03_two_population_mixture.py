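"""Simulated adult samples assembled from two juvenile populations.

Runs the mixture factorial — adult sample size {50, 200} x second
component Normal(35, 5) or Normal(40, 5) x second-component contribution
10-60% — with no mortality, 10,000 replicates per scenario, juvenile
reference samples drawn from population 1 only (the population that
juvenile sampling would actually have covered).

Writes results/SimulatedStatistics-TwoSamples.csv (display) and a
full-precision -raw companion. Run with --fast for 2,000 replicates.
"""

import argparse
import logging
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from scsim.io import RunConfig, run_table2

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=10_000)
parser.add_argument("--fast", action="store_true", help="2,000 replicates per scenario")
args = parser.parse_args()

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
out = pathlib.Path(__file__).resolve().parents[1] / "results"

cfg = RunConfig(experiment="mixture", seed=args.seed,
                replicates=args.replicates, fast=args.fast)
df = run_table2(cfg, out_dir=out)
print(df.to_string(index=False))
print()
print("Reading: as the second population's contribution grows the adult mean")
print("climbs — but so do the SD and the share of adults beyond the largest")
print("juvenile sampled from population 1 (up to ~34% at 60% contribution).")
print("Mean-shift plus variance expansion is the mixture signature, cleanly")
print("opposed to the truncation signature of knife-edge mortality.")
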