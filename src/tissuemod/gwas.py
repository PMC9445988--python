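"""Window-based variant-to-gene mapping.

Variants (1-based loci) are deduplicated by rsID, then mapped to every
gene whose BED interval (0-based half-open) lies within ``window`` bp of
the locus: the 0-based point p-1 hits gene [s, e) iff
max(0, s - (p-1), (p-1) - (e-1)) <= window.  The window is anchored on the
variant and measured to the gene interval (not the TSS); strand is ignored
and the distance is unsigned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import io
from .dataset import DataError

DEFAULT_WINDOW = 20_000


def dedupe_variants(raw: pd.DataFrame) -> pd.DataFrame:
    """One record per rsID (first occurrence kept).

    rsIDs recurring at a different position keep the first position with a
    warning; distinct rsIDs at the same (chrom, pos) are all kept.
    """
    if not len(raw):
        return raw.copy()
    conflicts = (
        raw.groupby("rsID")[["chrom", "pos_1based"]].nunique().max(axis=1) > 1
    )
    n_conflicts = int(conflicts.sum())
    if n_conflicts:
        warnings.warn(
            f"{n_conflicts} rsID(s) recur at conflicting positions; kept the first",
            stacklevel=2,
        )
    return raw.drop_duplicates(subset="rsID", keep="first").reset_index(drop=True)


def map_variants_to_genes(
    variants: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
):
    """Return (gene set, hits DataFrame with gene/rsID/distance).

    ``genes`` is a BED-style frame (chrom, start, end, name).  Variants on
    chromosomes absent from the BED are skipped with a warning.
    """
    if window < 0:
        raise DataError("window must be >= 0")
    hits = []
    bed_chroms = set(genes["chrom"])
    unknown = sorted(set(variants["chrom"]) - bed_chroms)
    if unknown:
        warnings.warn(f"variant chromosome(s) {unknown} absent from BED; skipped",
                      stacklevel=2)
    for chrom, vgrp in variants.groupby("chrom", sort=False):
        if chrom not in bed_chroms:
            continue
        g = genes[genes["chrom"] == chrom]
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        names = g["name"].to_numpy()
        for rsid, pos1 in zip(vgrp["rsID"], vgrp["pos_1based"]):
            q = int(pos1) - 1  # 0-based point
            dist = np.maximum(0, np.maximum(starts - q, q - (ends - 1)))
            sel = dist <= window
            for name, d in zip(names[sel], dist[sel]):
                hits.append((name, rsid, int(d)))
    hits_df = pd.DataFrame(hits, columns=["gene", "rsID", "distance"])
    return set(hits_df["gene"]), hits_df


def gene_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-gene variant count and minimum distance."""
    if not len(hits):
        return pd.DataFrame(columns=["gene", "n_variants", "min_distance"])
    return (
        hits.groupby("gene")
        .agg(n_variants=("rsID", "nunique"), min_distance=("distance", "min"))
        .reset_index()
    )


def load_gwas_catalog_extract(path, traits=None) -> pd.DataFrame:
    """Load a curated variant TSV (rsID, chrom, pos_1based, trait) and keep
    rows whose trait is in ``traits`` (all rows if ``traits`` is None)."""
    table = io.read_variants_tsv(path)
    if traits is not None:
        table = table[table["trait"].isin(set(traits))].reset_index(drop=True)
    return table
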