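"""Cross-disease consensus: TOM quantile scaling, consensus TOM, and the
sign-consistency merge of two module-tissue correlation tables.

Two TOMs computed on different cohorts have different value distributions;
raising the target TOM elementwise to log(q_ref)/log(q_tgt) equalises the
chosen off-diagonal quantile (default the 98th percentile) exactly, after
which the consensus TOM is the elementwise minimum.  Correlation tables are
merged only where the two diseases agree in sign; the combined r is the
smaller magnitude, the combined p the larger of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ConfigError, DataError


def _offdiag_quantile(tom: np.ndarray, q: float) -> float:
    """Order-statistic quantile (numpy method='lower') of the strict upper
    triangle.  An order statistic, not an interpolated value, so that a
    monotone power transform commutes with it exactly."""
    vals = tom[np.triu_indices_from(tom, k=1)]
    return float(np.quantile(vals, q, method="lower"))


@dataclass
class ScaledTomPair:
    reference: np.ndarray
    target: np.ndarray  # scaled
    exponent: float
    q: float
    quantile_reference: float
    quantile_target_before: float


def scale_tom(reference: np.ndarray, target: np.ndarray, q: float = 0.98) -> ScaledTomPair:
    """Raise ``target`` elementwise to log(q_ref)/log(q_tgt).

    Both TOMs must share shape; the q-quantiles must lie strictly in (0, 1)
    (log of 0 or 1 is undefined/degenerate).  The diagonal stays 1 because
    1**e == 1.
    """
    if reference.shape != target.shape:
        raise DataError("scale_tom: TOM shapes differ")
    if not (0.0 < q < 1.0):
        raise ConfigError("quantile level q must lie in (0, 1)")
    q_ref = _offdiag_quantile(reference, q)
    q_tgt = _offdiag_quantile(target, q)
    for name, val in (("reference", q_ref), ("target", q_tgt)):
        if not (0.0 < val < 1.0):
            raise DataError(f"{name} {q:.0%} TOM quantile is {val}; scaling undefined")
    exponent = np.log(q_ref) / np.log(q_tgt)
    scaled = np.power(target, exponent)
    np.fill_diagonal(scaled, 1.0)
    return ScaledTomPair(
        reference=reference, target=scaled, exponent=float(exponent), q=q,
        quantile_reference=q_ref, quantile_target_before=q_tgt,
    )


def consensus_tom(pair: ScaledTomPair) -> np.ndarray:
    """Elementwise minimum of the scaled pair (symmetric, unit diagonal)."""
    if pair.reference.shape != pair.target.shape:
        raise DataError("consensus_tom: gene sets differ")
    return np.minimum(pair.reference, pair.target)


def merge_correlation_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                             r_min: float = 0.6, alpha: float = 0.05) -> pd.DataFrame:
    """Merge two long-format module-tissue correlation tables.

    Inputs need columns module, tissue, r, p with identical (module, tissue)
    index sets.  A cell is consistent iff r_A * r_B > 0 (strictly: r = 0
    carries no sign).  Consistent cells get combined_r = the smaller-
    magnitude r (sign preserved) and combined_p = max(p_A, p_B); the
    ``flagged`` column applies |combined_r| > r_min and combined_p < alpha.
    Inconsistent cells carry NaN (written as the literal "NA").
    """
    key = ["module", "tissue"]
    out_cols = ["module", "tissue", "r_A", "p_A", "r_B", "p_B", "consistent",
                "combined_r", "combined_p", "flagged"]
    if not len(table_a) and not len(table_b):
        return pd.DataFrame(columns=out_cols)
    a = table_a.set_index(key).sort_index()
    b = table_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise DataError(
            f"correlation tables index mismatch; only in A: {only_a[:5]}, "
            f"only in B: {only_b[:5]}"
        )
    out = pd.DataFrame(index=a.index)
    out["r_A"], out["p_A"] = a["r"], a["p"]
    out["r_B"], out["p_B"] = b["r"], b["p"]
    consistent = (out["r_A"] * out["r_B"]) > 0
    out["consistent"] = consistent
    mag = np.minimum(out["r_A"].abs(), out["r_B"].abs())
    out["combined_r"] = np.where(consistent, np.sign(out["r_A"]) * mag, np.nan)
    out["combined_p"] = np.where(consistent, np.maximum(out["p_A"], out["p_B"]), np.nan)
    out["flagged"] = consistent & (out["combined_r"].abs() > r_min) & (
        out["combined_p"] < alpha)
    return out.reset_index()


def correlation_long_table(moduleset) -> pd.DataFrame:
    """Flatten a ModuleSet's module-tissue r/p matrices to long format."""
    rows = []
    for me_name in moduleset.module_tissue_r.index:
        for tissue in moduleset.module_tissue_r.columns:
            rows.append(
                {
                    "module": int(me_name.removeprefix("ME")),
                    "tissue": tissue,
                    "r": moduleset.module_tissue_r.loc[me_name, tissue],
                    "p": moduleset.module_tissue_p.loc[me_name, tissue],
                }
            )
    return pd.DataFrame(rows, columns=["module", "tissue", "r", "p"])
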