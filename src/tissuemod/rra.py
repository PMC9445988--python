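"""Robust rank aggregation over per-dataset DEG rankings.

Each dataset contributes an ordered gene list (by logFC); a gene's
normalised ranks r_(1) <= ... <= r_(n) over the n lists containing it are
scored with beta order-statistic CDFs, rho = min_k BetaCDF(r_(k); k,
n-k+1), and the minimum is Bonferroni-corrected over the n list positions:
p = min(1, rho * n).  Genes with p < 0.05 are called robustly ranked.
Up- and down-regulated lists are aggregated separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ConfigError, DataError


def normalise_ranks(deg_tables: dict, direction: str = "up",
                    by_abs: bool = False) -> pd.DataFrame:
    """Per-dataset normalised ranks, genes x lists, NaN where absent.

    ``deg_tables`` maps list name -> DegTable (needs a finite ``logFC``
    column, unique gene index).  ``direction="up"`` ranks by descending
    logFC, ``"down"`` ascending; ``by_abs`` ranks by descending |logFC|.
    Ties are broken by gene id (lexicographically smaller first).
    """
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    cols = {}
    for name, table in deg_tables.items():
        if table.index.has_duplicates:
            dupes = table.index[table.index.duplicated()].unique().tolist()
            raise DataError(f"list {name!r}: duplicate gene(s) {dupes[:5]}")
        if not len(table):
            raise DataError(f"list {name!r} is empty")
        lfc = table["logFC"]
        if not np.isfinite(lfc.to_numpy(float)).all():
            raise DataError(f"list {name!r}: non-finite logFC")
        key = lfc.abs() if by_abs else (lfc if direction == "down" else -lfc)
        order = pd.DataFrame(
            {"key": key.to_numpy(), "gene": list(table.index)}
        ).sort_values(["key", "gene"], kind="mergesort")
        n = len(order)
        cols[name] = pd.Series(np.arange(1, n + 1) / n,
                               index=pd.Index(order["gene"], name="gene"))
    return pd.DataFrame(cols)


def beta_scores(r_sorted, n: int) -> np.ndarray:
    """BetaCDF(r_(k); k, n-k+1) for k = 1..n; input must be sorted ascending."""
    r = np.asarray(r_sorted, float)
    if r.ndim != 1 or r.size != n:
        raise DataError("beta_scores: need a length-n vector")
    if np.any(np.diff(r) < 0):
        raise DataError("beta_scores: ranks must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise DataError("beta_scores: normalised ranks must lie in (0, 1]")
    k = np.arange(1, n + 1)
    return stats.beta.cdf(r, k, n - k + 1)


def aggregate(ranks: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """RRA result per gene: rho, n_lists, p_corrected, significant.

    rho is the minimum beta order-statistic score over the gene's sorted
    normalised ranks; the correction factor is the number of lists
    containing the gene.  Genes present in no list are dropped with a
    warning.
    """
    R = ranks.to_numpy(float)
    n_lists = (~np.isnan(R)).sum(axis=1)
    empty = n_lists == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} gene(s) present in no list; dropped",
                      stacklevel=2)
    rows = []
    for gene, row, n in zip(ranks.index, R, n_lists):
        if n == 0:
            continue
        r = np.sort(row[~np.isnan(row)])
        rho = float(np.min(beta_scores(r, int(n))))
        p = min(1.0, rho * int(n))
        rows.append((gene, int(n), rho, p, p < alpha))
    out = pd.DataFrame(rows, columns=["gene", "n_lists", "rho", "p_corrected",
                                      "significant"]).set_index("gene")
    return out


def aggregate_directions(deg_tables: dict, alpha: float = 0.05,
                         by_abs: bool = False) -> pd.DataFrame:
    """Aggregate the up- and down-ranked lists separately and stack the
    results with a ``direction`` column; the robust DEG set is the union of
    significant genes over both directions."""
    parts = []
    for direction in ("up", "down"):
        ranks = normalise_ranks(deg_tables, direction=direction, by_abs=by_abs)
        res = aggregate(ranks, alpha=alpha)
        res["direction"] = direction
        parts.append(res.reset_index())
    return pd.concat(parts, ignore_index=True)


def significant_genes(result: pd.DataFrame) -> set:
    return set(result.loc[result["significant"], "gene"])


def calibrate_null(n_lists: int, n_genes: int, reps: int, seed: int,
                   alphas=(0.01, 0.05)) -> pd.DataFrame:
    """Empirical type-I table under independent uniform permutations.

    Each replicate draws ``n_lists`` independent permutations of
    ``n_genes`` ranks, aggregates, and counts the fraction of genes called
    at each alpha.  The Bonferroni-style correction makes the procedure
    conservative, so the fractions sit at or below alpha.
    """
    if reps < 100:
        raise ConfigError("calibrate_null needs reps >= 100")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n_lists + 1)
    a_params, b_params = k, n_lists - k + 1
    counts = {a: 0 for a in alphas}
    for _ in range(reps):
        R = np.column_stack(
            [rng.permutation(n_genes) + 1 for _ in range(n_lists)]
        ) / n_genes
        R.sort(axis=1)
        scores = stats.beta.cdf(R, a_params[None, :], b_params[None, :])
        p = np.minimum(1.0, scores.min(axis=1) * n_lists)
        for a in alphas:
            counts[a] += int((p < a).sum())
    total = reps * n_genes
    return pd.DataFrame(
        {"alpha": list(alphas),
         "fraction_significant": [counts[a] / total for a in alphas],
         "n_lists": n_lists, "n_genes": n_genes, "reps": reps}
    )
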