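"""Diagnosing an observed juvenile/adult pair: the coho salmon case study.

Applies the decision checklist to the published descriptive statistics of
Strait of Georgia coho salmon mean intercirculus distance (first 10
marine circuli): ocean age-0 juveniles sampled in 2000 versus age-1
immatures sampled in 2001. Then projects a synthetic stand-in for the
juvenile histogram through the 90% knife-edge mortality that was claimed
for this stock, to show what the adult distribution *should* have looked
like under that hypothesis.

Writes results/case_study_report.txt / .json and
results/case_study_projection.csv.
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from scsim import SampleStats, diagnose_pair, project_adult_histogram
from scsim.diagnostics import EmpiricalHistogram
from scsim.io import write_histogram_csv

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# Published summary statistics (mean intercirculus distance, mm):
# age-0 juveniles (2000) vs age-1 immatures (2001).
juvenile = SampleStats(n=87, mean=0.038, median=float("nan"), min=0.031,
                       max=0.049, range=0.018, sd=0.004, skewness=0.40,
                       excess_kurtosis=-0.43)
adult = SampleStats(n=248, mean=0.043, median=float("nan"), min=0.031,
                    max=0.058, range=0.027, sd=0.004, skewness=0.04,
                    excess_kurtosis=0.15)

report = diagnose_pair(juvenile, adult)
print(report.to_text())
(OUT / "case_study_report.txt").write_text(report.to_text() + "\n")
report.to_json(OUT / "case_study_report.json")

print()
print("Reading: the adult range grew, the SD did not shrink and skewness fell")
print("— each the opposite of what left-truncation of a single population")
print("predicts. The pattern instead matches an unsampled second population")
print("of larger individuals contributing to the adult sample.")
print()

# Synthetic juvenile histogram (labelled synthetic: a normal fit to the
# published age-0 summaries, binned at 0.002 mm — not digitised data).
edges = np.arange(0.030, 0.052, 0.002)
centers = (edges[:-1] + edges[1:]) / 2
density = np.exp(-0.5 * ((centers - juvenile.mean) / juvenile.sd) ** 2)
counts = np.round(juvenile.n * density / density.sum(), 0)
synthetic = EmpiricalHistogram(edges, counts, label="synthetic age-0 juveniles")

projected = project_adult_histogram(synthetic, mortality_rate=0.9,
                                    adult_total=adult.n)
write_histogram_csv(OUT / "case_study_projection.csv", projected)

print("Projection of the synthetic juvenile histogram through a 90% knife-edge cut")
for lo, hi, c in zip(projected.bin_edges[:-1], projected.bin_edges[1:], projected.counts):
    bar = "#" * int(round(c / 5))
    print(f"  [{lo:.3f}, {hi:.3f}): {c:7.1f} {bar}")
print()
print("Under 90% knife-edge mortality nearly all adult mass should sit in the")
print(f"top bins above ~{projected.bin_edges[np.argmax(projected.counts > 0)]:.3f} mm, "
      "with zero mass below the cut — unlike the")
print("observed adult distribution, which spans the full juvenile range down")
print(f"to {adult.min:.3f} mm.")
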