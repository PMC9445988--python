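"""Final evidence join: tissue-specific gene calls and generic ORA.

A gene is called tissue-specific when it (1) survives the hub-gene screen
(|GS| > 0.6, |kME| > 0.8 inside a tissue-specific module), (2) carries
independent evidence from robust rank aggregation or GWAS proximity, and
(3) is not confounder-excluded.  Over-representation analysis is a plain
upper-tail hypergeometric test against user-supplied GMT gene sets with
Benjamini-Hochberg correction; no term database semantics are implied.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import DataError


def call_tissue_specific_genes(
    screened: pd.DataFrame,
    rra_genes: set,
    gwas_genes: set,
    confounder_excluded: set = frozenset(),
    require_both: bool = False,
) -> pd.DataFrame:
    """screened ∩ (RRA ∪ GWAS) − excluded, annotated with the evidence label.

    ``screened`` is the table from ``network.screen_module_genes``.  With
    ``require_both`` the evidence rule becomes RRA ∧ GWAS (stricter AND
    mode).  Returns the screened columns plus ``evidence`` in
    {"RRA", "GWAS", "both"}.
    """
    if not len(screened):
        return screened.assign(evidence=pd.Series(dtype=str))
    out = screened.copy()
    in_rra = out["gene"].isin(rra_genes)
    in_gwas = out["gene"].isin(gwas_genes)
    keep = (in_rra & in_gwas) if require_both else (in_rra | in_gwas)
    keep &= ~out["gene"].isin(confounder_excluded)
    out = out[keep].copy()
    evidence = pd.Series("RRA", index=out.index)
    evidence[out["gene"].isin(gwas_genes) & ~out["gene"].isin(rra_genes)] = "GWAS"
    evidence[out["gene"].isin(gwas_genes) & out["gene"].isin(rra_genes)] = "both"
    out["evidence"] = evidence
    return out.reset_index(drop=True)


def shared_genes(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Rows whose (gene, tissue) pair is called in both diseases."""
    if not len(calls_a) or not len(calls_b):
        return calls_a.iloc[0:0].assign(context=pd.Series(dtype=str))
    key_b = set(zip(calls_b["gene"], calls_b["tissue"]))
    mask = [pair in key_b for pair in zip(calls_a["gene"], calls_a["tissue"])]
    out = calls_a[mask].copy()
    out["context"] = "shared"
    return out.reset_index(drop=True)


def summarise_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts per tissue plus the pooled (unique-gene) total, since a gene
    can be called in several tissues."""
    per_tissue = (
        calls.groupby("tissue")["gene"].nunique().rename("n_genes").reset_index()
        if len(calls)
        else pd.DataFrame(columns=["tissue", "n_genes"])
    )
    pooled = pd.DataFrame({"tissue": ["ALL"], "n_genes": [calls["gene"].nunique()
                                                          if len(calls) else 0]})
    return pd.concat([per_tissue, pooled], ignore_index=True)


def over_representation(gene_list: set, gene_sets: dict, universe: set) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of ``gene_list`` against each GMT set.

    Every set is intersected with the universe before testing; the list
    must be a subset of the universe.  p = P[X >= overlap] for X ~
    Hypergeom(N=|universe|, K=|set|, L=|list|); q is the BH adjustment
    across sets.
    """
    if not universe:
        raise DataError("ORA universe is empty")
    gene_list = set(gene_list)
    if not gene_list <= set(universe):
        stray = sorted(gene_list - set(universe))[:5]
        raise DataError(f"gene list is not a subset of the universe (e.g. {stray})")
    N, L = len(universe), len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & set(universe))
        k = len(set(members) & gene_list)
        p = float(stats.hypergeom.sf(k - 1, N, K, L)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "list_size": L, "universe_size": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
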