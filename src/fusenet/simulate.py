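"""Synthetic paired normal/cancer expression data with planted structure.

The generator emulates FPKM-scale RNA-Seq/miRNA-Seq matrices: log2
expression of an active gene is Gaussian around a gene-specific mean,
exponentiated back to the FPKM scale.  On top of that baseline the
generator plants

* co-expression modules — groups of genes whose log2 profiles share a
  target within-module Pearson correlation, optionally active in only one
  condition or rewired (same genes, different correlation pattern) in the
  cancer condition;
* fold-change genes — mean log2 shift between conditions;
* a noise floor — a fraction of genes drawn far below the activity
  threshold so that the zFPKM filter should remove them.

Survival times follow an exponential proportional-hazards model driven by
standardized expression of chosen driver genes, and boolean knowledge
annotations follow a two-rate Bernoulli model with configurable
enrichment odds inside a chosen gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .matrix import ExpressionMatrix

# log2-scale constants of the generative model (config-exposed knobs are in
# SimulationConfig; these are the fixed baseline shape)
ACTIVE_MEAN_LOG2 = 5.0
ACTIVE_MEAN_SD = 1.5
WITHIN_SD_LOG2 = 1.0
NOISE_MEAN_LOG2 = -9.0
NOISE_MEAN_SD = 0.5
LNCRNA_FRACTION = 0.2


@dataclass
class PlantedModule:
    """A planted co-expression module.

    ``within_correlation`` is the target pairwise Pearson correlation of the
    member genes in the conditions where the module is active.
    ``rewired_in_cancer`` keeps the same genes co-expressed in both
    conditions but mixes the cancer-side correlation structure through an
    independent random orthogonal rotation, creating a different pairwise
    pattern.
    """

    member_genes: list[str]
    within_correlation: float = 0.9
    active_in: str = "both"  # normal | cancer | both
    rewired_in_cancer: bool = False
    # constant shift of the members' base mean log2 expression (both
    # conditions); lets planted modules occupy distinct expression strata
    mean_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_correlation <= 1.0:
            raise ValueError("within_correlation must be in [0, 1]")
        if self.active_in not in {"normal", "cancer", "both"}:
            raise ValueError(f"bad active_in: {self.active_in!r}")


@dataclass
class SimulationConfig:
    n_rna: int = 250
    n_mirna: int = 50
    n_samples_normal: int = 60
    n_samples_cancer: int = 60
    modules: list[PlantedModule] = field(default_factory=list)
    n_de_genes: int = 0
    de_log2fc: float = 2.0
    noise_floor_fraction: float = 0.0
    seed: int = 0
    # when True, fold-change genes are drawn from module members first
    # (models modules whose expression level also shifts with condition)
    de_overlap_modules: bool = False
    # dispersion of per-gene baseline log2 means; small values produce a
    # flat expression landscape where distance ranking is noise-driven
    base_mean_sd: float = ACTIVE_MEAN_SD

    def __post_init__(self) -> None:
        for name in ("n_rna", "n_mirna", "n_samples_normal", "n_samples_cancer", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        if not 0.0 <= self.noise_floor_fraction < 1.0:
            raise ValueError("noise_floor_fraction must be in [0, 1)")
        n_genes = self.n_rna + self.n_mirna
        module_genes: set[str] = set()
        total = 0
        for m in self.modules:
            members = set(m.member_genes)
            if members & module_genes:
                raise ValueError("module member lists must be disjoint")
            module_genes |= members
            total += len(m.member_genes)
        if total > n_genes:
            raise ValueError("sum of module sizes exceeds the gene universe")
        unknown = module_genes - set(self.gene_ids())
        if unknown:
            raise ValueError(f"module genes outside the universe: {sorted(unknown)[:5]}")

    def gene_ids(self) -> list[str]:
        rna = [f"RNA{i:05d}" for i in range(self.n_rna)]
        mir = [f"MIR{i:05d}" for i in range(self.n_mirna)]
        return rna + mir

    def biotypes(self) -> pd.Series:
        """Deterministic biotype assignment: a fixed fraction of RNA genes
        are labeled lncRNA, the rest protein_coding; MIR genes are miRNA."""
        labels = {}
        n_lnc = int(round(self.n_rna * LNCRNA_FRACTION))
        for i in range(self.n_rna):
            labels[f"RNA{i:05d}"] = "lncRNA" if i < n_lnc else "protein_coding"
        for i in range(self.n_mirna):
            labels[f"MIR{i:05d}"] = "miRNA"
        ids = self.gene_ids()
        return pd.Series([labels[g] for g in ids], index=ids, name="biotype")


@dataclass
class GeneRoles:
    """Ground-truth role assignment derived deterministically from a config."""

    module_genes: list[str]
    de_genes: list[str]
    noise_genes: list[str]


def plan_roles(config: SimulationConfig) -> GeneRoles:
    """Assign DE and noise-floor roles deterministically from the seed.

    Module membership comes from the config itself.  Noise-floor genes are
    drawn from genes that are neither module members nor DE.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = config.gene_ids()
    module_genes = [g for m in config.modules for g in m.member_genes]
    module_set = set(module_genes)

    free = [g for g in genes if g not in module_set]
    if config.de_overlap_modules:
        pool = module_genes + free
    else:
        pool = free
    if config.n_de_genes > len(pool):
        raise ValueError("n_de_genes exceeds the eligible gene pool")
    de = list(rng.choice(pool, size=config.n_de_genes, replace=False)) if config.n_de_genes else []

    n_noise = int(round(config.noise_floor_fraction * len(genes)))
    noise_pool = [g for g in free if g not in set(de)]
    if n_noise > len(noise_pool):
        raise ValueError("noise_floor_fraction too large for the non-module gene pool")
    noise = list(rng.choice(noise_pool, size=n_noise, replace=False)) if n_noise else []
    return GeneRoles(module_genes=module_genes, de_genes=de, noise_genes=noise)


def _module_chol(module: PlantedModule, condition: str, rng: np.random.Generator) -> np.ndarray | None:
    """Cholesky factor of the module's signal correlation in one condition.

    Returns None when the module is inactive in the condition (independent
    genes).  The base structure is equicorrelation at the target rho; a
    rewired cancer side rotates it with a random orthogonal matrix and
    renormalizes the diagonal, which preserves strong co-expression but
    changes which pairs are strongly correlated.
    """
    active = module.active_in in (condition, "both")
    if not active:
        return None
    m = len(module.member_genes)
    rho = module.within_correlation
    corr = np.full((m, m), rho)
    np.fill_diagonal(corr, 1.0)
    if condition == "cancer" and module.rewired_in_cancer and m > 1:
        q = ortho_group.rvs(m, random_state=rng)
        cov = q @ corr @ q.T
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
    # jitter for numerical PSD safety
    return np.linalg.cholesky(corr + 1e-10 * np.eye(m))


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate paired (normal, cancer) FPKM matrices over one gene universe."""
    roles = plan_roles(config)
    genes = config.gene_ids()
    biotypes = config.biotypes()
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_genes = len(genes)
    base_mean = rng.normal(ACTIVE_MEAN_LOG2, config.base_mean_sd, size=n_genes)
    noise_idx = [gene_pos[g] for g in roles.noise_genes]
    base_mean[noise_idx] = rng.normal(NOISE_MEAN_LOG2, NOISE_MEAN_SD, size=len(noise_idx))
    for module in config.modules:
        if module.mean_offset:
            for g in module.member_genes:
                base_mean[gene_pos[g]] += module.mean_offset

    mats = {}
    for condition, n_samples in (
        ("normal", config.n_samples_normal),
        ("cancer", config.n_samples_cancer),
    ):
        mean = base_mean.copy()
        if condition == "cancer":
            for g in roles.de_genes:
                mean[gene_pos[g]] += config.de_log2fc
        signal = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
        for module in config.modules:
            chol = _module_chol(module, condition, rng)
            if chol is None:
                continue
            idx = [gene_pos[g] for g in module.member_genes]
            z = rng.normal(0.0, 1.0, size=(len(idx), n_samples))
            signal[idx, :] = chol @ z
        log2x = mean[:, None] + WITHIN_SD_LOG2 * signal
        fpkm = np.exp2(log2x)
        sample_ids = [f"{condition[0].upper()}{j:04d}" for j in range(n_samples)]
        mats[condition] = ExpressionMatrix(
            values=pd.DataFrame(fpkm, index=genes, columns=sample_ids),
            biotypes=biotypes,
            condition=condition,
        )
    return mats["normal"], mats["cancer"]


def generate_survival(
    cancer: ExpressionMatrix,
    driver_genes: list[str],
    betas: list[float],
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_median_days: float = 730.0,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival table for the cancer samples.

    The linear predictor is sum(beta_i * z_i) over standardized driver
    expression; censoring times are exponential with a rate chosen so the
    expected censored fraction is ``censor_rate``.
    """
    if len(driver_genes) != len(betas):
        raise ValueError("driver_genes and betas must have equal length")
    missing = [g for g in driver_genes if g not in set(cancer.genes)]
    if missing:
        raise ValueError(f"unknown driver gene ids: {missing}")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    log2x = np.log2(cancer.values.loc[driver_genes].to_numpy() + 1.0)
    if len(driver_genes):
        mu = log2x.mean(axis=1, keepdims=True)
        sd = log2x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (log2x - mu) / sd
        eta = np.asarray(betas) @ z
    else:
        eta = np.zeros(cancer.n_samples)

    base_rate = np.log(2.0) / baseline_median_days
    rate = base_rate * np.exp(eta)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_lambda = censor_rate / (1.0 - censor_rate) * rate.mean()
        censor_time = rng.exponential(1.0 / censor_lambda, size=len(event_time))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(len(event_time), dtype=int)
    time = np.maximum(time, 1e-8)

    table = pd.DataFrame({"event": event, "time": time}, index=cancer.samples)
    table.index.name = "sample_id"
    for g, row in zip(driver_genes, log2x):
        table[g] = row
    return table


def generate_annotations(
    gene_universe: list[str],
    positive_fraction: float,
    enriched_set: list[str],
    enrichment_odds: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Boolean knowledge flags with enrichment inside ``enriched_set``.

    Base positive odds are multiplied by ``enrichment_odds`` for genes in
    the enriched set.
    """
    universe = list(gene_universe)
    enriched = set(enriched_set)
    unknown = enriched - set(universe)
    if unknown:
        raise ValueError(f"enriched genes outside the universe: {sorted(unknown)[:5]}")
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must be in (0, 1)")
    if enrichment_odds < 1.0:
        raise ValueError("enrichment_odds must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    base_odds = positive_fraction / (1.0 - positive_fraction)
    enriched_odds = base_odds * enrichment_odds
    p_enriched = enriched_odds / (1.0 + enriched_odds)
    probs = np.where(
        np.isin(universe, list(enriched)), p_enriched, positive_fraction
    )
    flags = rng.random(len(universe)) < probs
    return pd.Series(flags.astype(int), index=universe, name="flag")


def benchmark_config(
    seed: int = 0,
    n_modules: int = 18,
    module_size: int = 6,
    within_correlation: float = 0.9,
    n_samples: int = 60,
    noise_floor_fraction: float = 0.0,
) -> SimulationConfig:
    """Canonical recovery benchmark: ~300 genes, many small planted modules.

    Modules are small and tight so their fused-network edge weights are
    strongly concentrated per node (which the disparity filter rewards),
    every fourth module is rewired in the cancer condition, fold-change
    genes sit inside modules, and the baseline mean dispersion is kept low
    so the thresholded distance network forms a broad connective mesh
    rather than a few extreme-expression hubs.
    """
    gene_ids = [f"RNA{i:05d}" for i in range(250)] + [f"MIR{i:05d}" for i in range(50)]
    modules, pos = [], 0
    for m in range(n_modules):
        members = gene_ids[pos : pos + module_size]
        pos += module_size
        modules.append(
            PlantedModule(
                member_genes=members,
                within_correlation=within_correlation,
                active_in="both",
                rewired_in_cancer=(m % 4 == 1),
            )
        )
    return SimulationConfig(
        n_rna=250,
        n_mirna=50,
        n_samples_normal=n_samples,
        n_samples_cancer=n_samples,
        modules=modules,
        n_de_genes=20,
        de_log2fc=1.0,
        noise_floor_fraction=noise_floor_fraction,
        seed=seed,
        de_overlap_modules=True,
        base_mean_sd=0.5,
    )


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
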