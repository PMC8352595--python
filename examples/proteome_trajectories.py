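"""Trajectory profiling of cilium-annotated proteins across differentiation.

Simulates an LFQ intensity time course (two genotypes, five stages, three
replicates, 10% missing values), imputes the missing entries from a
left-shifted normal, keeps proteins annotated with 'cilia', Z-normalizes
each protein's profile and scores how closely it follows the group mean
trajectory.
"""

import numpy as np

from ciliashift.proteome import go_subset, impute_missing, trajectory_match, z_normalize
from ciliashift.simulate import generate_lfq_timecourse

matrix, truth = generate_lfq_timecourse(
    n_proteins=400, n_replicates=3, missing_rate=0.1, group_effect=1.0, seed=5
)
print(f"proteins x samples:   {matrix.shape[0]} x {matrix.shape[1]}")
print(f"missing entries:      {int(matrix.isna().sum().sum())}")

imputed = impute_missing(matrix, width=0.3, downshift=1.8, seed=5)
subset = go_subset(imputed, truth.annotations, term="cilia")
print(f"'cilia'-annotated:    {len(subset)} proteins retained")

for genotype in ("WT", "NRS"):
    cols = [c for c in subset.columns if c.startswith(genotype)]
    z, constant = z_normalize(np.log2(subset[cols]))
    scored = trajectory_match(z, r_threshold=0.8)
    n_match = int((scored["label"] == "match").sum())
    print(
        f"{genotype}: {n_match}/{len(scored)} proteins match the group mean "
        f"trajectory (r >= 0.8); mean r = {scored['r'].mean():.3f}"
    )
# A higher match fraction and mean r in WT reflects the coordinated induction
# of the ciliary program; the mutant's attenuated ramp loosens the bundle.
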