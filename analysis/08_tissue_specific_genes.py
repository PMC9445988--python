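"""The headline join: hub genes of tissue-specific modules that also carry
RRA or GWAS evidence, minus confounder-driven genes; per-disease calls,
the shared (both-disease) calls, and ORA of the called genes against the
planted-module GMT.
"""

import warnings

from common import BUNDLE_POWER, CONFIG, DISEASES, disease_study, outdir
from tissuemod import deg, gwas, io, network, rra, specificity
from tissuemod.pipeline import network_matrix_from_bundle

warnings.filterwarnings("ignore")

calls = {}
for disease in DISEASES:
    datasets, truth, variants, bed = disease_study(disease)
    out = outdir(f"specificity/{disease}")

    matrix = network_matrix_from_bundle(datasets)
    net = network.build_network(matrix.expr, BUNDLE_POWER)
    modules = network.detect_modules(net, cut_height=CONFIG.cut_height,
                                     min_module_size=CONFIG.min_module_size)
    modules = network.merge_similar_modules(matrix.expr, modules,
                                            merge_cut=CONFIG.merge_cut)
    modules = network.module_tissue_correlation(matrix.expr, modules,
                                                matrix.tissue_labels)
    screened = network.screen_module_genes(modules)

    excluded = set()
    by_tissue = {}
    for d in datasets:
        normalised = deg.log2_normalise(d)
        table = deg.differential_expression(normalised)
        excluded |= deg.confounder_screen(
            normalised, CONFIG.confounders,
            alpha=CONFIG.confounder_alpha).excluded_genes
        degs = table[table["p"] < CONFIG.deg_alpha]
        if len(degs):
            by_tissue.setdefault(d.tissue, {})[d.name] = degs
    robust = set()
    for tissue in sorted(by_tissue):
        robust |= rra.significant_genes(
            rra.aggregate_directions(by_tissue[tissue], alpha=CONFIG.rra_alpha))
    mapped, _ = gwas.map_variants_to_genes(gwas.dedupe_variants(variants), bed,
                                           window=CONFIG.gwas_window)

    table = specificity.call_tissue_specific_genes(screened, robust, mapped,
                                                   excluded)
    calls[disease] = table
    io.write_table(table, out / "tissue_specific_genes.tsv", index=False)
    io.write_table(specificity.summarise_calls(table),
                   out / "call_summary.tsv", index=False)

    # precision vs the planted truth
    good = sum(
        truth.modules[row["gene"]] != 0
        and row["tissue"] in truth.module_homes[truth.modules[row["gene"]]]
        and (row["gene"] in truth.de_genes or row["gene"] in truth.gwas_genes)
        for _, row in table.iterrows())
    universe = set(matrix.expr.index)
    gmt = {f"module_{m}": set(truth.modules.index[truth.modules == m])
           for m in sorted(set(truth.modules) - {0})}
    called = set(table["gene"]) & universe
    if called:
        io.write_table(specificity.over_representation(called, gmt, universe),
                       out / "ora.tsv", index=False)
    print(f"{disease}: {table['gene'].nunique()} tissue-specific genes "
          f"across {table['tissue'].nunique()} tissues; precision vs truth "
          f"{good}/{len(table)}")

shared = specificity.shared_genes(calls[DISEASES[0]], calls[DISEASES[1]])
io.write_table(shared, outdir("specificity") / "shared_genes.tsv", index=False)
print(f"shared in both diseases: {shared['gene'].nunique()} gene-tissue calls")
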