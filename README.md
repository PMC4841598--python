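# ripenet

Transcriptome analysis toolkit for two-genotype, multi-stage RNA-seq
designs without biological replicates — the setting of a late-ripening
citrus bud mutant (MT) profiled against its wild type (WT) at three fruit
ripening stages (170, 190 and 210 days after flowering), one sequencing
library per genotype x stage. The package covers the full downstream
chain: exact Poisson differential expression on raw counts, transcription
factor (TF) family assignment from DNA-binding-domain hits, unsigned
weighted coexpression network analysis with permutation validation, and
set/cluster/enrichment summaries — plus a seeded synthetic-data generator
so every stage can be exercised and verified offline.

## The statistics at the core

**Exact Poisson test for two libraries.** Reads for a gene are modelled as
Poisson; with `x` reads in a library of `N1` total reads and `y` in a
library of `N2`, the probability of observing `y` given `x` under equal
expression is

    P(y|x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

and the two-sided p-value is `2*C` for the cumulative
`C = sum_{i<=y} P(i|x)`, or `2*(1-C)` when `C > 0.5`. Everything is
evaluated in log space (log-gamma + log-sum-exp) so counts at the 10^6
scale stay finite and deep tails keep precision. Expression is normalised
as RPKM = 10^9 x / (N L); a gene is differentially expressed (DEG) when
Benjamini–Hochberg FDR <= 0.001 and |log2 ratio| >= 1.

**Coexpression networks.** On RPKM-filtered genes (> 0.3 in at least one
sample), the unsigned adjacency is `a_ij = |cor(g_i, g_j)|^beta`
(default beta = 6), converted to topological overlap (TOM); modules come
from average-linkage clustering of 1 − TOM with a minimum module size of
30 and eigengene merging below dissimilarity 0.25. Modules are validated
by permutation: mean intramodular TOM against random gene sets of equal
size. Module eigengenes (first principal component of the standardized
module), kME (gene–eigengene correlation), GS (gene–trait correlation)
and module–trait correlations use Pearson r with Student-t p-values;
|r| > 0.8 with p < 0.05 flags significant module–trait links, and
|GS| >= 0.8 plus |MM| >= 0.8 (both p < 0.05) screens hub genes.

**TF annotation and downstream summaries.** Genes are assigned to TF
families by required/forbidden domain-model rules at e-value <= 1e-10;
DEG/TF sets are intersected into Venn regions; per-stage log2 fold-change
profiles are clustered Eisen-style (uncentered correlation, average
linkage); term over-representation uses the one-sided hypergeometric test
with BH correction at corrected p < 0.01.

## Worked example

```python
import ripenet as rn

# counts with 200 planted 4-fold DE genes (2 genotypes x 3 stages)
cm, truth = rn.generate_counts(n_genes=2000, de_fraction=0.1,
                               effect_log2=2.0, seed=1)
comp = rn.de_test(cm, "MT170", "WT170")
print(f"{comp.name}: {len(comp.degs)} DEGs of {len(comp.table)} genes")
# MT170_vs_WT170: 102 DEGs of 2000 genes

print(f"{rn.ac_test_pvalue(41, 131, 1_000_000, 1_000_000):.3e}")
# 2.370e-12  (41 vs 131 reads in equal-size libraries)
print(f"{rn.log2_ratio(33.37, 14.32):.2f}")
# 1.22  (MT vs WT RPKM fold change)

# latent-factor expression with 5 planted 50-gene modules + linked traits
expr, traits, net = rn.generate_coexpression(
    n_samples=20, trait_links={"citric_acid": 0, "ABA": 2}, seed=1)
model = rn.WGCNA(power=6, min_module_size=30).fit(expr.T)
print(model.partition_.sizes.to_dict())
# {'turquoise': 51, 'blue': 50, 'brown': 50, 'yellow': 50, 'green': 50}
mt = rn.module_trait_correlation(model.eigengenes_, traits)
print(mt[mt.significant])
#       module        trait      r    p  significant
#    turquoise          ABA  0.957  0.0         True
#         blue  citric_acid  0.957  0.0         True
```

The DE comparison finds 102 of the 200 planted genes at the strict
FDR <= 0.001 / 2-fold threshold (low-expression genes lack power at these
library depths); the network run recovers the five planted modules almost
exactly and flags each trait as significantly correlated with the module
carrying its latent factor.

The same stages are available from the shell: `ripenet simulate`, `de`,
`tf`, `sets`, `cluster`, `network`, `validate`, `traits`, `enrich`, and
`ripenet run-all` for the whole chain with a JSON run manifest.

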