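"""Per-dataset normalisation, differential expression and confounder screen.

Differential expression is an ordinary least-squares fit of log2 expression
on case/control status plus optional covariates; with no covariates the
status t statistic reduces exactly to the pooled two-sample t-test.  Genes
pass at p < deg_alpha (default 0.05, deliberately loose, uncorrected).  The
confounder screen flags genes whose expression tracks a demographic
covariate (two-sample t-test for binary, Pearson correlation for
continuous); flagged genes are excluded from the final tissue-specific
calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DataError, ExpressionDataset

#: Matrices whose maximum value is below this are taken to be log2 already.
LOG_SCALE_MAX = 30.0


@dataclass
class ConfounderReport:
    """Long-format per-gene x per-confounder test results plus the
    per-gene exclusion flag (any confounder p < alpha)."""

    tests: pd.DataFrame  # columns: gene, confounder, statistic, p
    excluded: pd.Series  # bool, indexed by gene
    alpha: float

    @property
    def excluded_genes(self) -> set:
        return set(self.excluded.index[self.excluded])


def log2_normalise(raw: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """log2(x + pseudocount); skips (with a warning) matrices that already
    look log-scaled (max < 30).  Negative input values are a data error."""
    values = raw.expr.to_numpy()
    if (values < 0).any():
        raise DataError(
            f"dataset {raw.name!r}: negative expression values cannot be log2-normalised"
        )
    if np.nanmax(values) < LOG_SCALE_MAX:
        warnings.warn(
            f"dataset {raw.name!r}: max value {np.nanmax(values):.3g} < {LOG_SCALE_MAX:g}; "
            "matrix looks log2-scaled already, skipping transform",
            stacklevel=2,
        )
        return raw
    expr = np.log2(raw.expr + pseudocount)
    return ExpressionDataset(expr, raw.meta, name=raw.name)


def _design_matrix(meta: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(meta)), (meta["status"] == "case").to_numpy(float)]
    names = ["intercept", "status"]
    for c in covariates:
        if c not in meta.columns:
            raise DataError(f"covariate {c!r} not in metadata")
        cols.append(meta[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise DataError(f"rank-deficient design; collinear columns: {collinear}")
    return X


def differential_expression(ds: ExpressionDataset, covariates=()) -> pd.DataFrame:
    """OLS of expression on status (+ covariates); returns a DegTable.

    Columns: logFC (case minus control status coefficient, log2 units),
    t, p (two-sided), significant (p < 0.05 by default; callers re-threshold
    via :func:`select_degs`).  Zero-variance genes get p = 1.
    """
    status = ds.meta["status"]
    if (status == "case").sum() < 2 or (status == "control").sum() < 2:
        raise DataError(f"dataset {ds.name!r}: need >=2 case and >=2 control samples")
    X = _design_matrix(ds.meta, covariates)
    Y = ds.expr.to_numpy(float)
    n, p = X.shape
    XtXi = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtXi  # genes x p
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtXi[1, 1])
    logfc = B[:, 1]
    # zero-variance rows: relative to the gene's own scale, not absolute
    scale2 = (Y**2).mean(axis=1) + 1.0
    flat = sigma2 <= 1e-20 * scale2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    small_fc = np.abs(logfc) <= 1e-10 * np.sqrt(scale2)
    t = np.where(flat, 0.0, t)
    pvals = np.where(flat & small_fc, 1.0, pvals)
    pvals = np.where(flat & ~small_fc, 0.0, pvals)
    out = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": pvals}, index=ds.expr.index
    )
    out["significant"] = out["p"] < 0.05
    return out


def confounder_screen(
    ds: ExpressionDataset, confounders, alpha: float = 0.05
) -> ConfounderReport:
    """Test every gene against each confounder.

    ``confounders`` is an iterable of (name, kind) with kind in
    {"binary", "continuous"}; binary uses the equal-variance two-sample
    t-test between levels, continuous uses Pearson correlation with a
    t-distributed p on n-2 df.  Constant confounder columns are skipped
    with a warning.
    """
    Y = ds.expr.to_numpy(float)
    n = Y.shape[1]
    records = []
    for name, kind in confounders:
        if name not in ds.meta.columns:
            raise DataError(f"confounder {name!r} not in metadata")
        cov = ds.meta[name].to_numpy(float)
        if np.ptp(cov) == 0:
            warnings.warn(f"confounder {name!r} is constant; skipped", stacklevel=2)
            continue
        if kind == "binary":
            levels = np.unique(cov)
            if levels.size != 2:
                raise DataError(
                    f"binary confounder {name!r} has {levels.size} level(s)"
                )
            a, b = Y[:, cov == levels[0]], Y[:, cov == levels[1]]
            stat, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
            stat = np.nan_to_num(stat, nan=0.0)
            p = np.nan_to_num(p, nan=1.0)  # zero-variance genes
        elif kind == "continuous":
            z = (cov - cov.mean()) / cov.std()
            ysd = Y.std(axis=1)
            yc = Y - Y.mean(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (yc @ z) / (n * ysd)
            r = np.nan_to_num(r, nan=0.0)
            r = np.clip(r, -1.0, 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
            stat = r
            p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
            p = np.where(np.abs(r) >= 1.0, 0.0, p)
            p = np.where(ysd == 0, 1.0, p)
        else:
            raise DataError(f"unknown confounder kind {kind!r}")
        records.append(
            pd.DataFrame(
                {
                    "gene": ds.expr.index,
                    "confounder": name,
                    "statistic": stat,
                    "p": p,
                }
            )
        )
    tests = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["gene", "confounder", "statistic", "p"])
    )
    if len(tests):
        excluded = tests.groupby("gene")["p"].min().reindex(ds.expr.index, fill_value=1.0) < alpha
    else:
        excluded = pd.Series(False, index=ds.expr.index)
    excluded.name = "excluded"
    return ConfounderReport(tests=tests, excluded=excluded, alpha=alpha)


def select_degs(
    deg: pd.DataFrame, report: ConfounderReport | None = None, alpha: float = 0.05
) -> set:
    """Genes with p < alpha (strict) and not confounder-excluded."""
    selected = set(deg.index[deg["p"] < alpha])
    if report is not None:
        selected -= report.excluded_genes
    return selected
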