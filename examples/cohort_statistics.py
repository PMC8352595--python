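"""Small-cohort tests on genotype and ultrastructure count tables.

Runs the chi-square goodness of fit of litter genotype counts against the
1:2:1 Mendelian expectation, and a 2x2 chi-square on pooled axoneme-defect
counts (13 defective of 81 mutant cross-sections vs 1 of 94 control).
"""

from ciliashift.stats import fisher_exact_2x2, mendelian_chisq, pearson_chisq_2x2

litter = mendelian_chisq([7, 11, 4], expected_ratio=(1, 2, 1))
print(f"litter (7, 11, 4) vs 1:2:1:  chi2 = {litter.chi2:.3f}, df = {litter.df}, p = {litter.p:.2f}")

tem = pearson_chisq_2x2([[13, 68], [1, 93]])
print(f"axoneme defects 13/81 vs 1/94: chi2 = {tem.chi2:.2f}, p = {tem.p:.1e}")

motility = fisher_exact_2x2([[40, 60], [75, 25]])
print(f"motile bundles 40/100 vs 75/100: Fisher two-sided p = {motility:.2e}")
# p = 0.66 for the litter means the genotypes fit Mendelian segregation; the
# tiny chi-square and Fisher p-values flag genotype-dependent defect and
# motility proportions.
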