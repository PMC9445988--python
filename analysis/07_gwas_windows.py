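"""Map the toy GWAS variant tables to genes within +/-20 kb of each locus
after merging recurring variants; check recovery against the planted
GWAS-proximal gene set.
"""

import warnings

from common import CONFIG, DISEASES, disease_study, outdir
from tissuemod import gwas, io

warnings.filterwarnings("ignore")

for disease in DISEASES:
    _, truth, variants, bed = disease_study(disease)
    out = outdir(f"gwas/{disease}")
    deduped = gwas.dedupe_variants(variants)
    mapped, hits = gwas.map_variants_to_genes(deduped, bed,
                                              window=CONFIG.gwas_window)
    io.write_table(gwas.gene_summary(hits), out / "gwas_genes.tsv", index=False)
    recovered = len(mapped & truth.gwas_genes)
    print(f"{disease}: {len(variants)} raw variants -> {len(deduped)} after "
          f"dedupe; {len(mapped)} genes within {CONFIG.gwas_window//1000} kb "
          f"({recovered}/{len(truth.gwas_genes)} planted recovered, "
          f"{len(mapped - truth.gwas_genes)} spurious)")
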