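# genepip

Post-GWAS fine-mapping and risk-gene nomination with functional priors, for
statistical geneticists working from summary statistics and single-cell
epigenomic annotations. The package implements, end to end on plain-text
inputs:

- **single-effect Bayesian fine-mapping** of approximately independent LD
  blocks from z-scores (L = 1 SER; posterior inclusion probabilities and
  credible sets with optional LD-purity filtering);
- **functional enrichment priors**: an EM-fit logistic model tying each
  SNP's prior causal probability to binary annotations (open-chromatin
  classes, coding, conserved), reported as log2 fold enrichment with
  BH-adjusted Wald tests;
- **gene-level PIP aggregation**: SNP-to-gene weights from exons, active
  promoters, enhancer loops (ABC ≥ 0.015, promoter-capture Hi-C, OCRs within
  20 kb of an active promoter), UTRs, and an exponential distance decay
  `w = exp(-d / 5·10^4)` as fallback; gene PIPs, credible gene sets, and a
  nearest-gene benchmarking baseline;
- **PIP partitioning** into disjoint functional categories (summed PIP =
  expected causal variants per category) and locus-level cell-type
  attribution;
- **eQTL tissue-sharing decomposition** `p = Σ_c p_c w_c` over functional
  categories, enrichment versus matched controls, and a power simulation
  quantifying bulk-tissue dilution of cell-type-specific eQTLs;
- a **synthetic-data generator** reproducing every input with ground truth
  (AR1 LD, annotation-enriched causal placement, gene landscapes with
  loops, eQTL cell-type mixtures).

## Model sketch

Within a block with z-scores `z_j`, the single-effect posterior is

    PIP_j = pi_j BF(z_j) / Σ_k pi_k BF(z_k),
    log BF(z) = ½ log(1/(1+σ₀²)) + (z²/2) σ₀²/(1+σ₀²),

with priors `pi_j = logistic(α₀ + Σ_k α_k A_jk)` renormalized per block; σ₀²
is profiled on a log-spaced grid. Enrichment coefficients α are estimated by
EM over blocks under a single-causal-or-none model (the marginal likelihood
per block is `Π_j(1-π_j)(1 + Σ_j odds_j BF_j)`). A gene's PIP is
`Σ_i PIP_i · w̃_ig` with `w̃_ig = w_ig / Σ_g w_ig`, so each SNP distributes
its causal evidence across its linked genes; the 80% credible gene set is
the smallest set of genes capturing 80% of a locus's gene-mapped PIP.

## Worked example

```python
import pandas as pd
from genepip import genemap as gm
from genepip.io import GeneModel, LinkRecord, VariantRecord

g1 = GeneModel("g1", "chr1", "+", 10_001, exons=((10_000, 10_400),))
g2 = GeneModel("g2", "chr1", "+", 60_001, exons=((60_000, 60_400),))
links = [LinkRecord("chr1", 29_900, 30_100, "g1", "ABC", 0.5),
         LinkRecord("chr1", 29_900, 30_100, "g2", "ABC", 0.5)]
variants = [VariantRecord("s1", "chr1", 10_200, 4.0, "b1"),
            VariantRecord("s2", "chr1", 30_000, 3.0, "b1")]

weights = gm.normalize_weights(gm.SnpGeneLinker([g1, g2], links=links).link_all(variants))
pips = pd.DataFrame({"variant_id": ["s1", "s2"], "block_id": "b1", "pip": [0.6, 0.4]})
gene_tab, support, locus = gm.compute_gene_pips(pips, weights)
print(gene_tab[["gene_id", "gene_pip"]])
print(gm.credible_gene_set(locus, coverage=0.8)[["gene_id", "contribution"]])
```

prints

```
  gene_id  gene_pip
0      g1       0.8
1      g2       0.2
  gene_id  contribution
0      g1           0.8
```

SNP `s1` (PIP 0.6) sits in an exon of `g1` and supports only that gene; SNP
`s2` (PIP 0.4) loops to both genes, so its evidence splits 0.2/0.2. The 80%
credible gene set is `{g1}`.

The same pipeline is scriptable from the shell:

```
genepip simulate --kind genome --seed 1 --out-dir sim/
genepip enrich   --sumstats sim/sumstats.tsv --blocks sim/blocks.bed \
                 --annotations sim/annotations.tsv --out-dir enr/
genepip finemap  --sumstats sim/sumstats.tsv --blocks sim/blocks.bed \
                 --priors enr/priors.tsv --out-dir fm/
```

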