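"""One-configuration end-to-end synthetic run.

Runs every stage (differential abundance, lipid QC, multivariate, network)
from a single seeded configuration and prints the consolidated report. The
output directory gains per-stage TSV/JSON files plus a manifest of
parameters, sub-seeds and file hashes sufficient to re-execute the run.
"""

import json

from liveromics import pipeline

config = pipeline.RunConfig(
    seed=11,
    out_dir="scratch/example_run",
    n_features=150,
    lipid_species=200,
    lipid_planted=(20, 3, 5, 8),
    ppi_nodes=600,
    n_random_network=200,
)
report = pipeline.run_all(config)
print(json.dumps(report["stages"], indent=2, default=str))
# proteome.summary counts the features flagged per effect; network.lcc.z is
# the connectivity z-score of the differentially abundant proteins, which
# is large because the planted module genes carry planted group effects.
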