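"""Generate the two simulated disease cohorts (stand-ins for the MDD and BP
GEO collections) with planted tissue-specific modules, DE genes, batch
effects, confounder genes and a toy GWAS fixture; write the full bundles.
"""

import warnings

from common import DISEASES, disease_study, outdir
from tissuemod.simulate import write_fixture_bundle

warnings.filterwarnings("ignore")

for disease in DISEASES:
    datasets, truth, variants, bed = disease_study(disease)
    out = outdir(f"bundles/{disease}")
    manifest = write_fixture_bundle(datasets, truth, out,
                                    variants=variants, bed=bed)
    n_mod = int((truth.modules > 0).sum())
    print(f"{disease}: {len(datasets)} datasets x {datasets[0].n_genes} genes, "
          f"{n_mod} module genes in {truth.modules.max()} planted modules, "
          f"{len(truth.de_genes)} DE genes, {len(truth.gwas_genes)} GWAS-proximal "
          f"genes -> {out}")
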