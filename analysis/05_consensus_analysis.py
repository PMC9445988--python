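"""Cross-disease consensus: scale the two TOMs to a common 98th percentile,
take the elementwise minimum, detect consensus modules, and merge the two
module-tissue correlation tables under the sign-consistency rule.
"""

import warnings

import numpy as np
import pandas as pd

from common import BUNDLE_POWER, CONFIG, DISEASES, disease_study, outdir
from tissuemod import consensus, io, network
from tissuemod.consensus import _offdiag_quantile
from tissuemod.pipeline import network_matrix_from_bundle

warnings.filterwarnings("ignore")

matrices = {}
for disease in DISEASES:
    datasets, truth, _, _ = disease_study(disease)
    matrices[disease] = network_matrix_from_bundle(datasets)

shared = sorted(set(matrices[DISEASES[0]].expr.index)
                & set(matrices[DISEASES[1]].expr.index))
nets = {d: network.build_network(m.expr.loc[shared], BUNDLE_POWER)
        for d, m in matrices.items()}

qa = _offdiag_quantile(nets[DISEASES[0]].tom, CONFIG.quantile)
qb = _offdiag_quantile(nets[DISEASES[1]].tom, CONFIG.quantile)
ref_d, tgt_d = (DISEASES[0], DISEASES[1]) if qa >= qb else (DISEASES[1], DISEASES[0])
pair = consensus.scale_tom(nets[ref_d].tom, nets[tgt_d].tom, q=CONFIG.quantile)
ctom = consensus.consensus_tom(pair)

cnet = network.CoexpressionNetwork(genes=pd.Index(shared, name="gene"),
                                   beta=BUNDLE_POWER,
                                   adjacency=np.minimum(*[n.adjacency
                                                          for n in nets.values()]),
                                   tom=ctom)
cmods = network.detect_modules(cnet, cut_height=CONFIG.cut_height,
                               min_module_size=CONFIG.min_module_size)

out = outdir("consensus")
tables = {}
for disease, m in matrices.items():
    ms = network.module_tissue_correlation(
        m.expr.loc[shared], network.ModuleSet(labels=cmods.labels),
        m.tissue_labels, r_min=CONFIG.module_r, alpha=CONFIG.module_alpha)
    tables[disease] = consensus.correlation_long_table(ms)
merged = consensus.merge_correlation_tables(tables[DISEASES[0]],
                                            tables[DISEASES[1]],
                                            r_min=CONFIG.module_r,
                                            alpha=CONFIG.module_alpha)
io.write_table(cmods.labels.to_frame(), out / "consensus_modules.tsv")
io.write_table(merged, out / "consensus_cor.tsv", index=False)
io.write_json({"reference": ref_d, "target": tgt_d,
               "exponent": pair.exponent, "quantile": CONFIG.quantile,
               "q_reference": pair.quantile_reference,
               "q_target_before": pair.quantile_target_before},
              out / "scaling_report.json")

n_cons = int(merged["consistent"].sum())
n_flag = int(merged["flagged"].sum())
print(f"shared genes: {len(shared)}; scaling {tgt_d} TOM to {ref_d} with "
      f"exponent {pair.exponent:.3f}; consensus modules: "
      f"{len(cmods.module_ids)}; consistent module-tissue cells: {n_cons} "
      f"of {len(merged)}, flagged: {n_flag}")
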