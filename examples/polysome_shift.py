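"""Detect planted translational shifts in a simulated polysome experiment.

Simulates a fraction-resolved RNA-seq count table (two genotypes, three
replicates, 10% of genes shifted out of polysomes by one log2 unit in the
mutant), runs the polysome-shift pipeline, and compares the estimates with
the planted truth.
"""

import numpy as np

from ciliashift.polysome import run_psr
from ciliashift.simulate import PolysomeSimConfig, generate_polysome_experiment

config = PolysomeSimConfig(
    n_genes=2000,
    shifted_fraction=0.1,
    true_delta_psr=-1.0,
    total_reads_per_sample=1_000_000,
    n_replicates=3,
    dispersion=0.05,
    seed=11,
)
table, truth = generate_polysome_experiment(config)
result = run_psr(table, wt="WT", mut="NRS", alpha=0.05)

est = result["psr"].to_numpy()
print(f"genes simulated:            {config.n_genes}")
print(f"planted shifted genes:      {int(truth.shifted.sum())} at PSR = {config.true_delta_psr}")
print(f"mean estimated PSR (shifted): {np.nanmean(est[truth.shifted]):+.3f}")
print(f"mean estimated PSR (null):    {np.nanmean(est[~truth.shifted]):+.3f}")
counts = result["class"].value_counts().to_dict()
print(f"classification (p < 0.05):  {counts}")
hit = (result['class'][truth.shifted] == 'down').mean()
print(f"shifted genes called down:  {100 * hit:.1f}%")
# A mean estimated PSR near -1 for the planted set and near 0 for null genes
# means the pipeline recovers the planted translational depletion unbiasedly;
# the 'down' percentage is its detection power at these depths.
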