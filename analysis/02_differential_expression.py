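"""Per-dataset differential expression (case vs control, p < 0.05, no FDR)
and the demographic-confounder screen; write one DEG table per dataset and
a summary of counts against the planted truth.
"""

import warnings

import pandas as pd

from common import CONFIG, DISEASES, disease_study, outdir
from tissuemod import deg, io

warnings.filterwarnings("ignore")

for disease in DISEASES:
    datasets, truth, _, _ = disease_study(disease)
    out = outdir(f"deg/{disease}")
    rows = []
    for ds in datasets:
        normalised = deg.log2_normalise(ds)
        table = deg.differential_expression(normalised,
                                            covariates=CONFIG.covariates)
        report = deg.confounder_screen(normalised, CONFIG.confounders,
                                       alpha=CONFIG.confounder_alpha)
        selected = deg.select_degs(table, report, alpha=CONFIG.deg_alpha)
        table["excluded_by_confounder"] = report.excluded
        io.write_table(table, out / f"deg_{ds.name}.tsv")
        hit_de = len(selected & truth.de_genes)
        rows.append({"dataset": ds.name, "n_deg": len(selected),
                     "n_excluded": int(report.excluded.sum()),
                     "planted_de_recovered": hit_de,
                     "planted_de_total": len(truth.de_genes)})
    summary = pd.DataFrame(rows)
    io.write_table(summary, out / "summary.tsv", index=False)
    print(f"{disease}: DEG counts per dataset "
          f"{summary['n_deg'].min()}-{summary['n_deg'].max()}; "
          f"planted DE recovered per dataset "
          f"{summary['planted_de_recovered'].min()}-"
          f"{summary['planted_de_recovered'].max()} of "
          f"{summary['planted_de_total'].iloc[0]}")
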