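"""Same-tissue merging and parametric empirical-Bayes batch adjustment.

The batch model is the classic location/scale formulation: after per-gene
standardisation against the grand mean and pooled variance, each batch's
additive effect gamma_gb is shrunk toward a normal prior and its scale
delta_gb toward an inverse-gamma prior, both with moment-matched
hyperparameters, by the closed-form iteration (relative tolerance 1e-4,
max 100 rounds).  With a single batch the adjustment is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DataError, ExpressionDataset, MergedTissueMatrix

_EPS = 1e-12


def merge_tissue(datasets, deg_sets, case_only: bool = True) -> MergedTissueMatrix:
    """Concatenate same-tissue datasets over the DEG-defined gene space.

    Rows are the union of the per-dataset DEG sets restricted to genes
    present in every member dataset; columns are the (case-only, unless
    ``case_only=False``) samples of all members, batch-labelled by dataset.
    """
    tissues = {ds.tissue for ds in datasets}
    if len(tissues) != 1:
        raise DataError(f"merge_tissue: datasets span several tissues: {sorted(tissues)}")
    tissue = tissues.pop()

    deg_union: set = set()
    for s in deg_sets:
        deg_union |= set(s)
    present = set(datasets[0].expr.index)
    for ds in datasets[1:]:
        present &= set(ds.expr.index)
    rows = sorted(deg_union & present)
    if not rows:
        counts = {ds.name: ds.n_genes for ds in datasets}
        raise DataError(
            f"merge_tissue: empty gene intersection; per-dataset gene counts: {counts}"
        )

    blocks, batch = [], []
    for ds in datasets:
        use = ds
        if case_only:
            keep = ds.meta.index[ds.meta["status"] == "case"]
            use = ds.subset_samples(keep)
        blocks.append(use.expr.loc[rows])
        batch.extend([ds.name] * use.n_samples)
    expr = pd.concat(blocks, axis=1)
    return MergedTissueMatrix(
        expr=expr,
        batch=pd.Series(batch, index=expr.columns, name="batch"),
        tissue=tissue,
        deg_genes=tuple(rows),
    )


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch parameters.

    ``gamma_star``/``delta_star`` are per-gene x per-batch shrunken
    location (standardised units) and scale (SD ratio); ``alpha`` is the
    per-gene grand mean, ``pooled_sd`` the per-gene pooled residual SD.
    ``priors`` records the normal / inverse-gamma hyperparameters.
    """

    batches: tuple
    alpha: pd.Series
    pooled_sd: pd.Series
    gamma_star: pd.DataFrame  # genes x batches
    delta_star: pd.DataFrame  # genes x batches (SD scale, >0)
    priors: dict
    n_iter: dict
    converged: bool = True

    @property
    def genes(self) -> pd.Index:
        return self.alpha.index


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1) if delta_hat.size > 1 else 0.0
    if s2 < _EPS:
        return np.inf
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1) if delta_hat.size > 1 else 0.0
    if s2 < _EPS:
        return np.inf
    return (m * s2 + m**3) / s2


def fit_empirical_bayes_batch(
    m: MergedTissueMatrix, tol: float = 1e-4, max_iter: int = 100
) -> BatchModel:
    """Fit the parametric location/scale batch model on a merged matrix.

    Requires >=2 samples per batch.  Degenerate priors (all genes showing
    identical batch effects, e.g. noise-free fixtures) fall back to the
    unshrunk estimates, which is the correct no-information limit.
    """
    batches = tuple(dict.fromkeys(m.batch))
    sizes = {b: int((m.batch == b).sum()) for b in batches}
    singles = [b for b, k in sizes.items() if k < 2]
    if singles:
        raise DataError(
            f"batch(es) {singles} have a single sample; pool them covariate-free "
            "or drop them before fitting"
        )
    Y = m.expr.to_numpy(float)
    genes = m.expr.index
    n_total = Y.shape[1]
    masks = {b: (m.batch == b).to_numpy() for b in batches}

    # Grand mean weighted by batch size, pooled residual variance about the
    # per-batch means (the standardisation the location/scale model assumes).
    batch_means = np.column_stack([Y[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([sizes[b] / n_total for b in batches])
    alpha = batch_means @ weights
    fitted = np.empty_like(Y)
    for j, b in enumerate(batches):
        fitted[:, masks[b]] = batch_means[:, [j]]
    var_pooled = ((Y - fitted) ** 2).mean(axis=1)
    pooled_sd = np.sqrt(np.maximum(var_pooled, _EPS))

    if len(batches) == 1:
        return BatchModel(
            batches=batches,
            alpha=pd.Series(alpha, index=genes, name="alpha"),
            pooled_sd=pd.Series(pooled_sd, index=genes, name="pooled_sd"),
            gamma_star=pd.DataFrame(0.0, index=genes, columns=list(batches)),
            delta_star=pd.DataFrame(1.0, index=genes, columns=list(batches)),
            priors={}, n_iter={},
        )

    Z = (Y - alpha[:, None]) / pooled_sd[:, None]

    gamma_star = np.empty((len(genes), len(batches)))
    delta_star = np.empty_like(gamma_star)
    priors, n_iters = {}, {}
    converged = True
    for j, b in enumerate(batches):
        Zb = Z[:, masks[b]]
        nb = sizes[b]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), max(g_hat.var(ddof=1), _EPS)
        a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)
        priors[b] = {"gamma_bar": float(g_bar), "tau2": float(t2),
                     "a_prior": float(a_pr), "b_prior": float(b_pr)}
        if not np.isfinite(a_pr):
            # no across-gene spread in the scale estimates -> no shrinkage
            gamma_star[:, j] = g_hat if t2 <= _EPS else (
                (t2 * nb * g_hat + d_hat * g_bar) / (t2 * nb + d_hat))
            delta_star[:, j] = np.sqrt(np.maximum(d_hat, _EPS))
            n_iters[b] = 0
            continue
        g_old, d_old = g_hat.copy(), np.maximum(d_hat.copy(), _EPS)
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (t2 * nb * g_hat + d_old * g_bar) / (t2 * nb + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_pr) / (nb / 2.0 + a_pr - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), _EPS)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), _EPS)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        else:
            converged = False
            warnings.warn(
                f"batch {b!r}: EB iteration did not converge in {max_iter} rounds; "
                "using the last iterate",
                stacklevel=2,
            )
        n_iters[b] = it
        gamma_star[:, j] = g_old
        delta_star[:, j] = np.sqrt(np.maximum(d_old, _EPS))

    return BatchModel(
        batches=batches,
        alpha=pd.Series(alpha, index=genes, name="alpha"),
        pooled_sd=pd.Series(pooled_sd, index=genes, name="pooled_sd"),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=list(batches)),
        delta_star=pd.DataFrame(delta_star, index=genes, columns=list(batches)),
        priors=priors, n_iter=n_iters, converged=converged,
    )


def apply_batch_adjustment(m: MergedTissueMatrix, model: BatchModel) -> MergedTissueMatrix:
    """x* = (x - alpha - gamma* . pooled_sd) / delta* + alpha, per batch.

    Equivalent to standardise, subtract gamma*, divide by delta*, then
    restore the gene's pooled scale and grand mean.  Output shape equals
    input shape; gene and sample order are preserved.
    """
    unknown = sorted(set(m.batch) - set(model.batches))
    if unknown:
        raise DataError(f"batch label(s) {unknown} absent from the fitted model")
    if not m.expr.index.equals(model.genes):
        raise DataError("model was fitted on a different gene space")
    Y = m.expr.to_numpy(float)
    alpha = model.alpha.to_numpy()
    sd = model.pooled_sd.to_numpy()
    Z = (Y - alpha[:, None]) / sd[:, None]
    out = np.empty_like(Z)
    for b in dict.fromkeys(m.batch):
        mask = (m.batch == b).to_numpy()
        g = model.gamma_star[b].to_numpy()
        d = model.delta_star[b].to_numpy()
        out[:, mask] = (Z[:, mask] - g[:, None]) / d[:, None]
    adjusted = out * sd[:, None] + alpha[:, None]
    return MergedTissueMatrix(
        expr=pd.DataFrame(adjusted, index=m.expr.index, columns=m.expr.columns),
        batch=m.batch.copy(),
        tissue=m.tissue,
        deg_genes=m.deg_genes,
    )


def batch_f_statistics(m: MergedTissueMatrix) -> pd.Series:
    """Per-gene one-way ANOVA F across batches (batch-effect size proxy)."""
    groups = [m.expr.loc[:, (m.batch == b).to_numpy()].to_numpy() for b in
              dict.fromkeys(m.batch)]
    if len(groups) < 2:
        return pd.Series(0.0, index=m.expr.index, name="F")
    f, _ = stats.f_oneway(*groups, axis=1)
    return pd.Series(np.nan_to_num(f, nan=0.0), index=m.expr.index, name="F")


def batch_diagnostics(before: MergedTissueMatrix, after: MergedTissueMatrix) -> pd.DataFrame:
    """Per-sample median/IQR and per-gene batch-F summaries, before vs after.

    Rows: one per sample plus ``gene_F_median`` and ``gene_F_mean``;
    columns: median_before, iqr_before, median_after, iqr_after (for the F
    rows the median/iqr columns carry the F summary before/after).
    """
    if before.expr.shape != after.expr.shape:
        raise DataError("batch_diagnostics: shapes differ")

    def per_sample(m):
        q1, med, q3 = np.percentile(m.expr.to_numpy(), [25, 50, 75], axis=0)
        return med, q3 - q1

    med_b, iqr_b = per_sample(before)
    med_a, iqr_a = per_sample(after)
    table = pd.DataFrame(
        {
            "median_before": med_b,
            "iqr_before": iqr_b,
            "median_after": med_a,
            "iqr_after": iqr_a,
        },
        index=before.expr.columns,
    )
    fb, fa = batch_f_statistics(before), batch_f_statistics(after)
    table.loc["gene_F_median"] = [fb.median(), np.nan, fa.median(), np.nan]
    table.loc["gene_F_mean"] = [fb.mean(), np.nan, fa.mean(), np.nan]
    return table


def batch_mean_rmse(m: MergedTissueMatrix, clean: pd.DataFrame) -> float:
    """RMSE of batch-centred gene means against a batch-free reference.

    For each (gene, batch): the batch mean minus the gene's grand mean,
    compared with the same quantity in ``clean``.  Centring is deliberate:
    a location/scale adjustment preserves each gene's grand mean, so the
    absolute offset is unidentifiable from the batches alone; what the
    adjustment can and should remove is the between-batch spread.
    """
    if not m.expr.index.equals(clean.index):
        clean = clean.loc[m.expr.index]

    def centred(df):
        grand = df.mean(axis=1)
        return np.concatenate(
            [df.loc[:, (m.batch == b).to_numpy()].mean(axis=1) - grand
             for b in dict.fromkeys(m.batch)]
        )

    return float(np.sqrt(((centred(m.expr) - centred(clean)) ** 2).mean()))


def combine_tissues(matrices, mode: str = "union") -> MergedTissueMatrix:
    """Stack per-tissue adjusted matrices into the cross-tissue network input.

    ``mode="union"``: gene space is the union of per-tissue rows and every
    tissue must carry every union gene (missing genes are an error, never
    imputed).  ``mode="intersect"``: gene space is the intersection.
    """
    if not matrices:
        raise DataError("combine_tissues: no matrices given")
    spaces = [set(m.expr.index) for m in matrices]
    if mode == "union":
        genes = set().union(*spaces)
        for m, s in zip(matrices, spaces):
            missing = genes - s
            if missing:
                raise DataError(
                    f"tissue {m.tissue}: {len(missing)} union gene(s) missing "
                    f"(e.g. {sorted(missing)[:5]}); use mode='intersect' or fix inputs"
                )
    elif mode == "intersect":
        genes = set.intersection(*spaces)
        if not genes:
            raise DataError("combine_tissues: empty gene intersection")
    else:
        raise DataError(f"combine_tissues: unknown mode {mode!r}")
    rows = sorted(genes)
    expr = pd.concat([m.expr.loc[rows] for m in matrices], axis=1)
    batch = pd.concat([m.batch for m in matrices])
    batch.index = expr.columns
    out = MergedTissueMatrix(expr=expr, batch=batch, tissue="ALL",
                             deg_genes=tuple(rows))
    out.tissue_labels = pd.Series(
        np.concatenate([[m.tissue] * m.expr.shape[1] for m in matrices]),
        index=expr.columns, name="tissue",
    )
    return out
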