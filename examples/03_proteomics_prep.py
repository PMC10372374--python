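"""Precursor report -> protein matrix: filter, aggregate, MaxLFQ, impute.

Builds a small synthetic precursor-level DIA report (two proteins, two
peptides each, charge states +2/+3 across six runs, one contaminant row),
then runs the fixed post-processing chain and prints what each step kept.
"""

import numpy as np
import pandas as pd

from liveromics import proteomics as pp

rng = np.random.default_rng(0)
runs = [f"run{i + 1}" for i in range(6)]
rows = []
for prot, level in [("ALB", 5e5), ("FASN", 2e5)]:
    for pep in ("A", "B"):
        for charge in (2, 3):
            for j, run in enumerate(runs):
                inten = level * (1 + 0.1 * j) * (2 if pep == "B" else 1)
                inten *= rng.lognormal(0, 0.02)
                rows.append([run, f"{prot}_{pep}_{charge}", f"{prot}_{pep}",
                             charge, prot, True, False, 0.001, 0.001, 0.001,
                             inten])
rows.append(["run1", "krt", "KRT_pep", 2, "KRT10", True, True,
             0.0, 0.0, 0.0, 9e9])  # contaminant
report = pd.DataFrame(rows, columns=list(pp.REQUIRED_COLUMNS))

matrix, info = pp.prepare_proteins(report, seed=0)
print(f"precursor rows in/out:  {info['filter']['n_in']} -> "
      f"{info['filter']['n_out']} (removed: {info['filter']['removed']})")
print(f"peptides aggregated:    {info['n_peptides']}")
print(f"proteins quantified:    {info['n_proteins_kept']}")
print("\nMaxLFQ protein profiles (linear intensities):")
print(matrix.round(0).to_string())
# Profiles follow the planted 10%-per-run trend; the contaminant never
# reaches quantification.
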