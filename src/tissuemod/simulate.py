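"""Seeded multi-dataset, multi-tissue expression simulator.

The generator emulates the study design the pipeline is built for: several
case/control microarray datasets per tissue, merged downstream into one
matrix per disease.  Expression follows a latent-factor model

    x_gs = baseline_g + loading_g * f_m(s) [module genes, factor active in
           the module's home tissue] + DE shift [case samples]
           + confounder effect + batch shift_g + batch scale_g * noise,

on log2 scale; exported values are ``2**x`` so the pipeline's log2 step is
exercised.  The latent factor has a nonzero mean in the home tissue, which
is the single mechanism that produces both within-module correlation and a
module-eigengene/tissue correlation (a zero-mean factor would shift
variances, not means, and no module could ever reach |r| > 0.6 against a
tissue indicator).

Every planted feature is recorded in :class:`GroundTruth` so downstream
stages have an exact acceptance surface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import TISSUES, ConfigError, ExpressionDataset
from . import io


@dataclass(frozen=True)
class PlantedModule:
    """A correlated gene block whose latent factor is active in ``home_tissue``.

    ``factor_mean`` may be negative (module suppressed in its home tissue);
    ``home_tissue`` may be a tuple of tissues sharing the factor.
    """

    module_id: int
    size: int
    home_tissue: str | tuple
    factor_mean: float = 2.75
    factor_sd: float = 2.0
    loading_range: tuple = (1.0, 1.3)

    @property
    def homes(self) -> tuple:
        if isinstance(self.home_tissue, str):
            return (self.home_tissue,)
        return tuple(self.home_tissue)


@dataclass(frozen=True)
class Confounder:
    """A demographic covariate driving a block of genes.

    binary: affected genes shift by ``effect * noise_sd`` between levels;
    continuous: affected genes gain ``effect * noise_sd`` per covariate SD.
    """

    name: str
    kind: str  # "binary" | "continuous"
    n_affected: int
    effect: float


def _default_modules() -> tuple:
    # Modules 1-4: tissue-differential blocks, one per tissue (module 4 is
    # suppressed in its home tissue).  Module 5 is a second PFC block with a
    # zero-mean factor: co-expressed within PFC but not tissue-differential,
    # so the unsigned network can keep it apart from module 1.
    return (
        PlantedModule(1, 50, "PFC", factor_mean=2.75),
        PlantedModule(2, 50, "CRE", factor_mean=2.75),
        PlantedModule(3, 50, "PBMC", factor_mean=2.75),
        PlantedModule(4, 50, "WB", factor_mean=-2.75),
        PlantedModule(5, 50, "PFC", factor_mean=0.0, factor_sd=2.5),
    )


def _default_confounders() -> tuple:
    return (
        Confounder("age", "continuous", 15, 1.0),
        Confounder("sex", "binary", 15, 1.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated disease cohort.

    Defaults give the standard desk-scale bundle: 4 tissues x 2 datasets x
    20 samples (10 case / 10 control), 450 genes of which 5 x 50 form
    planted modules and 200 are background.
    """

    n_tissues: int = 4
    datasets_per_tissue: int = 2
    samples_per_dataset: int = 20
    n_genes: int = 450
    planted_modules: tuple = field(default_factory=_default_modules)
    n_de_genes: int = 60
    de_effect: float = 1.0
    batch_shift_sd: float = 0.6
    batch_scale_sd: float = 0.3
    confounders: tuple = field(default_factory=_default_confounders)
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    @property
    def tissues(self) -> tuple:
        return TISSUES[: self.n_tissues]

    def validate(self) -> None:
        for name in ("n_tissues", "datasets_per_tissue", "samples_per_dataset", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        module_total = sum(m.size for m in self.planted_modules)
        if module_total > self.n_genes:
            raise ConfigError(
                f"planted module sizes sum to {module_total} > n_genes={self.n_genes}"
            )
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        ids = [m.module_id for m in self.planted_modules]
        if len(set(ids)) != len(ids):
            raise ConfigError("module ids must be unique")
        for m in self.planted_modules:
            for t in m.homes:
                if t not in self.tissues:
                    raise ConfigError(
                        f"module {m.module_id} home tissue {t!r} not among {self.tissues}"
                    )
        for c in self.confounders:
            if c.kind not in ("binary", "continuous"):
                raise ConfigError(f"confounder {c.name!r}: unknown kind {c.kind!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by gene id.

    ``modules`` maps every gene to its planted module (0 = background);
    ``clean`` holds the log2 expression each dataset would have shown with
    no batch shift and unit batch scale (the oracle for batch correction).
    ``gwas_genes`` is filled by :func:`simulate_gwas_fixture`.
    """

    modules: pd.Series
    module_homes: dict
    loadings: pd.Series
    de: pd.DataFrame  # index gene, column "sign"
    confounder_genes: dict
    clean: dict  # dataset name -> log2 DataFrame
    gwas_genes: set = field(default_factory=set)

    @property
    def de_genes(self) -> set:
        return set(self.de.index)

    @property
    def all_confounded(self) -> set:
        out: set = set()
        for genes in self.confounder_genes.values():
            out |= set(genes)
        return out


def simulate_study(config: SimulationConfig):
    """Generate one cohort: a list of :class:`ExpressionDataset` (linear scale)
    plus the matching :class:`GroundTruth`.

    One dataset per (tissue, replicate) pair; identical seeds give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = pd.Index([f"G{i:04d}" for i in range(config.n_genes)], name="gene")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    # Planted module membership: contiguous blocks from the front.
    labels = np.zeros(config.n_genes, dtype=int)
    loadings = np.zeros(config.n_genes)
    pos = 0
    module_homes = {}
    for m in config.planted_modules:
        labels[pos : pos + m.size] = m.module_id
        lo, hi = m.loading_range
        loadings[pos : pos + m.size] = rng.uniform(lo, hi, m.size)
        module_homes[m.module_id] = m.homes
        pos += m.size
    background = np.flatnonzero(labels == 0)

    # DE genes: anywhere in the panel, sign +/- chosen per gene and shared
    # across tissues so cross-dataset rank signal is consistent.
    de_idx = rng.choice(config.n_genes, size=min(config.n_de_genes, config.n_genes),
                        replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=de_idx.size)
    de_vec = np.zeros(config.n_genes)
    de_vec[de_idx] = de_sign * config.de_effect * config.noise_sd

    # Confounder-driven genes: background only, disjoint across confounders,
    # so module recovery truth stays unambiguous.
    conf_effect = {}
    confounder_genes = {}
    pool = rng.permutation(background)
    taken = 0
    for c in config.confounders:
        n = min(c.n_affected, pool.size - taken)
        idx = pool[taken : taken + n]
        taken += n
        vec = np.zeros(config.n_genes)
        vec[idx] = c.effect * config.noise_sd
        conf_effect[c.name] = vec
        confounder_genes[c.name] = set(genes[idx])

    datasets = []
    clean = {}
    n = config.samples_per_dataset
    n_case = (n + 1) // 2
    for tissue in config.tissues:
        for rep in range(1, config.datasets_per_tissue + 1):
            dname = f"{tissue}_d{rep}"
            samples = [f"{dname}_s{i:02d}" for i in range(n)]
            status = np.array(["case"] * n_case + ["control"] * (n - n_case))
            age = rng.normal(50.0, 10.0, n)
            sex = rng.integers(0, 2, n).astype(float)
            ph = rng.normal(6.5, 0.25, n)

            x = np.tile(baseline[:, None], (1, n))
            for m in config.planted_modules:
                if tissue in m.homes:
                    f = rng.normal(m.factor_mean, m.factor_sd, n)
                else:
                    f = np.zeros(n)
                member = labels == m.module_id
                x[member] += loadings[member, None] * f[None, :]
            x += de_vec[:, None] * (status == "case")[None, :]
            for c in config.confounders:
                cov = sex if c.name == "sex" else (
                    age if c.name == "age" else ph)
                if c.kind == "binary":
                    z = (cov > np.median(cov)).astype(float) if c.name not in ("sex",) else cov
                else:
                    z = (cov - cov.mean()) / (cov.std() or 1.0)
                x += conf_effect[c.name][:, None] * z[None, :]

            noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n))
            clean_x = x + noise
            shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
            scale = np.exp(rng.normal(0.0, config.batch_scale_sd, config.n_genes))
            dirty = x + shift[:, None] + scale[:, None] * noise

            meta = pd.DataFrame(
                {
                    "tissue": tissue,
                    "status": status,
                    "batch": dname,
                    "age": age,
                    "sex": sex,
                    "ph": ph,
                },
                index=pd.Index(samples, name="sample_id"),
            )
            expr = pd.DataFrame(np.exp2(dirty), index=genes, columns=samples)
            datasets.append(ExpressionDataset(expr, meta, name=dname))
            clean[dname] = pd.DataFrame(clean_x, index=genes, columns=samples)

    truth = GroundTruth(
        modules=pd.Series(labels, index=genes, name="module"),
        module_homes=module_homes,
        loadings=pd.Series(loadings, index=genes, name="loading"),
        de=pd.DataFrame({"sign": de_sign}, index=genes[de_idx]).sort_index(),
        confounder_genes=confounder_genes,
        clean=clean,
    )
    return datasets, truth


def simulate_gwas_fixture(
    truth: GroundTruth,
    window_hits: int,
    decoys: int,
    seed: int,
    window: int = 20_000,
    spacing: int = 100_000,
    gene_length: int = 10_000,
    chrom: str = "chr1",
    chrom_length: int = 250_000_000,
):
    """Emit a toy gene BED and variant table exercising the +/-20 kb window.

    Exactly ``window_hits`` variants fall inside truth-selected genes
    (planted-module members preferred) and ``decoys`` land mid-gap, farther
    than ``window`` from every gene.  The first hit variant is emitted twice
    (same rsID and position) to exercise recurring-variant merging.
    Updates ``truth.gwas_genes`` with the intended hit genes.
    """
    genes = list(truth.modules.index)
    if window_hits > len(genes):
        raise ConfigError("window_hits exceeds the number of genes")
    if decoys > max(0, len(genes) - 1):
        raise ConfigError("decoys exceed the number of inter-gene gaps")
    if (len(genes) - 1) * spacing + gene_length > chrom_length:
        raise ConfigError("too many genes for the toy chromosome length")
    if (spacing - gene_length) // 2 <= window:
        raise ConfigError("gene spacing too tight for decoys outside the window")

    rng = np.random.default_rng(seed)
    starts = np.arange(len(genes), dtype=np.int64) * spacing
    bed = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + gene_length, "name": genes}
    )

    module_members = np.flatnonzero(truth.modules.to_numpy() > 0)
    pool = module_members if module_members.size >= window_hits else np.arange(len(genes))
    hit_idx = np.sort(rng.choice(pool, size=window_hits, replace=False))

    rows = []
    for j, gi in enumerate(hit_idx):
        pos1 = int(starts[gi]) + gene_length // 2 + 1  # inside the gene, 1-based
        rows.append((f"rs{gi:06d}", chrom, pos1, "MDD"))
        if j == 0:  # recurring risk variant
            rows.append((f"rs{gi:06d}", chrom, pos1, "MDD"))
    gap_choices = rng.choice(len(genes) - 1, size=decoys, replace=False) if decoys else []
    for gi in gap_choices:
        mid = int(starts[gi]) + gene_length + (spacing - gene_length) // 2
        rows.append((f"rs9{gi:05d}", chrom, mid + 1, "MDD"))
    variants = pd.DataFrame(rows, columns=list(io.VARIANT_COLUMNS))

    truth.gwas_genes = {genes[i] for i in hit_idx}
    return variants, bed


def write_fixture_bundle(datasets, truth: GroundTruth, out_dir,
                         variants=None, bed=None, seed=None) -> dict:
    """Write the full bundle (expression/metadata TSVs, truth tables, GMT,
    optional BED + variants) plus a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for ds in datasets:
        expr_path, meta_path = out / f"expr_{ds.name}.tsv", out / f"meta_{ds.name}.tsv"
        io.write_expression_tsv(ds.expr, expr_path)
        io.write_metadata_tsv(ds.meta, meta_path)
        files[f"expr_{ds.name}"] = expr_path.name
        files[f"meta_{ds.name}"] = meta_path.name

    io.write_table(truth.modules.to_frame(), out / "truth_modules.tsv")
    io.write_table(truth.de, out / "truth_de.tsv")
    conf = pd.DataFrame(
        [(name, g) for name, gs in truth.confounder_genes.items() for g in sorted(gs)],
        columns=["confounder", "gene"],
    )
    io.write_table(conf, out / "truth_confounders.tsv", index=False)
    gmt = {
        f"module_{mid}": set(truth.modules.index[truth.modules == mid])
        for mid in sorted(set(truth.modules) - {0})
    }
    io.write_gmt(gmt, out / "planted_modules.gmt")
    files.update(
        truth_modules="truth_modules.tsv",
        truth_de="truth_de.tsv",
        truth_confounders="truth_confounders.tsv",
        planted_modules="planted_modules.gmt",
    )
    if variants is not None:
        io.write_variants_tsv(variants, out / "variants.tsv")
        files["variants"] = "variants.tsv"
    if bed is not None:
        io.write_bed(bed, out / "genes.bed")
        files["genes_bed"] = "genes.bed"

    manifest = {
        "seed": seed,
        "n_datasets": len(datasets),
        "files": files,
        "checksums": {
            name: hashlib.sha256((out / fname).read_bytes()).hexdigest()
            for name, fname in sorted(files.items())
        },
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Return a copy of ``config`` with fields replaced (convenience)."""
    return replace(config, **kwargs)
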