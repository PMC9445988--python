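# tissuemod

Integrative tissue-specificity analysis for multi-cohort case/control
transcriptomics, aimed at mood-disorder-style study designs where many
small microarray datasets from different tissues (prefrontal cortex,
cerebellum, blood compartments, …) must be combined before any
tissue-level signal becomes visible.

The pipeline chains:

1. **Differential expression** per dataset — OLS of log2 expression on
   case/control status (+ covariates); loose DEG pre-filter at p < 0.05;
   demographic-confounder screen (age, sex, …).
2. **Integration** — same-tissue datasets merged and batch-adjusted with
   the parametric empirical-Bayes location/scale model (shrunken per-batch
   location γ\* and scale δ\*).
3. **Weighted co-expression network** — unsigned adjacency
   a_ij = |cor(x_i, x_j)|^β with the soft power β picked by scale-free
   fit; topological overlap T_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij);
   average-linkage modules on 1 − T; module eigengenes (first principal
   component), kME and GS; a module is **tissue-specific** iff its
   eigengene satisfies |r| > 0.6 and p < 0.05 against the tissue
   indicator, and its hub genes are screened at |GS| > 0.6, |kME| > 0.8.
4. **Cross-disease consensus** — the two TOMs are scaled to a common 98th
   percentile (target^(log q_ref / log q_tgt)), the consensus TOM is their
   elementwise minimum, and the per-disease module–tissue correlations are
   merged under the sign-consistency rule (smaller |r| kept, p = max,
   inconsistent cells = NA).
5. **Robust rank aggregation** — per tissue, each dataset's DEGs ranked by
   logFC; a gene's sorted normalised ranks are scored with beta order
   statistics, ρ = min_k BetaCDF(r_(k); k, n−k+1), corrected p = min(1, ρ·n).
6. **GWAS windows** — variants deduplicated by rsID and mapped to genes
   within ±20 kb of the locus.
7. **Tissue-specific genes** — screened hub genes of flagged modules that
   also carry RRA or GWAS evidence, minus confounder-driven genes; shared
   calls across the two diseases; hypergeometric ORA against GMT sets.

A seeded synthetic-data generator (`tissuemod.simulate`) stands in for the
public cohorts: it plants tissue-restricted correlated gene blocks, DE
genes, batch effects, confounder genes and a toy GWAS fixture, and
returns the full ground truth, so every stage is verifiable at desk
scale.  See `docs/methods.md` for the models and the design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
simulated two-disease cohorts and write their tables under `results/`:

```bash
cd analysis
python 01_simulate_study.py
python 04_coexpression_network.py
python 08_tissue_specific_genes.py
```

prints (fixed root seed):

```
MDD: 8 datasets x 450 genes, 250 module genes in 5 planted modules, 60 DE genes, 10 GWAS-proximal genes -> results/bundles/MDD
MDD: scan recommends beta=8 (analysis uses beta=8); 5 modules, ARI vs planted = 0.93; 4 tissue-specific module-tissue pairs; 164 screened hub genes
BP: scan recommends beta=12 (analysis uses beta=8); 4 modules, ARI vs planted = 0.85; 4 tissue-specific module-tissue pairs; 158 screened hub genes
MDD: 8 tissue-specific genes across 4 tissues; precision vs truth 7/8
BP: 9 tissue-specific genes across 3 tissues; precision vs truth 8/9
```

The detected modules track the planted ones (adjusted Rand index 0.93 for
the MDD cohort) and each tissue-differential module is flagged for
exactly its home tissue, e.g. for MDD (`results/network/MDD/
module_tissue_cor.tsv`, cells with |r| > 0.6):

```
module tissue      r        p
     1   PBMC  0.826  4.2e-21
     2     WB -0.857  4.1e-24
     3    PFC  0.774  3.6e-17
     4    CRE  0.749  1.3e-15
```

and the final calls join those modules' hub genes with rank-aggregation
and GWAS-window evidence (`results/specificity/MDD/
tissue_specific_genes.tsv`):

```
gene   module tissue   GS    kME   module_r  evidence
G0120  1      PBMC    0.64  0.82   0.83     GWAS
G0153  2      WB     -0.76  0.89  -0.86     RRA
G0157  2      WB     -0.69  0.90  -0.86     both
G0024  3      PFC     0.71  0.89   0.77     RRA
```

Seven of the eight MDD calls are planted-module members of the flagged
tissue with planted DE or GWAS support.  The same stages are available as
a CLI (`tissuemod simulate|deg|integrate|network|consensus|rra|gwas-map|
specific-genes|enrich|all`); `tissuemod all --seed N --out DIR` runs the
whole pipeline end to end and writes a provenance JSON with per-file
checksums (identical across reruns with the same seed).

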