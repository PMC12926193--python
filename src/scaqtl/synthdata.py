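"""Synthetic multi-donor, multi-library scATAC-like datasets with planted truth.

The generator emulates the count structure that every downstream stage of the
pipeline assumes: sparse Poisson fragment counts per cell and peak, donor and
library random intercepts on the log scale, donor genotype effects (caQTLs),
genotype-by-cell-state interaction effects (dynamic caQTLs), grade-of-
membership topic structure over cells, LD-correlated SNP blocks around each
peak, and QC covariates correlated with sequencing depth.

The generative model for cell i, peak c is

    y_ic ~ Poisson(mu_ic)
    log mu_ic = log(s_i * 1e-4 * base_c) + log m_ic
                + beta_c g_{d(i)} + delta_c g_{d(i)} t_i + a_{d(i)} + b_{l(i)}

where s_i is the cell's library size (lognormal), base_c the peak's baseline
accessibility in mean fragments per peak per 10^4 library size, m_ic the
topic modulation sum_k l_ik phi_ck normalized to mean 1 over cells within the
peak, t_i the loading of the designated dynamic topic, a_d ~ N(0, sigma_donor^2),
b_l ~ N(0, sigma_library^2). Genotype dosages follow per-SNP binomial(2, maf)
marginals coupled by an AR(1) Gaussian copula on the haplotype scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_cell_states",
    "simulate_counts",
    "simulate_summary_stats",
    "simulate_dataset",
]

# fixed offsets used to derive independent sub-streams from the global seed
_SEED_GENO = 11
_SEED_STATES = 23
_SEED_COUNTS = 37
_SEED_TRUTH = 53


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults are chosen to mirror a desk-scale version of a multi-study
    PBMC scATAC caQTL design: 40 donors at ~100 cells each, 600 peaks of
    which half carry a planted caQTL (the "cPeak" set; the other half are
    null peaks usable as matched controls), ~10 SNPs in LD around each
    peak, and log-scale effect sizes of SD 0.5.
    """

    n_donors: int = 40
    n_studies: int = 1
    n_libraries_per_study: int = 4
    cells_per_donor: tuple[int, int] = (80, 120)
    n_peaks: int = 600
    snps_per_peak: int = 10
    n_topics: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    frac_caqtl_peaks: float = 0.5
    beta_sd: float = 0.5
    frac_dynamic: float = 0.2
    delta_sd: float = 0.5
    sigma_donor: float = 0.25
    sigma_library: float = 0.15
    # (mu, sigma) of log total fragments per cell; exp(9.2) ~ 1e4
    depth_lognormal_params: tuple[float, float] = (9.2, 0.5)
    # mean fragments per peak per 1e4 library size, uniform over peaks
    baseline_rate_range: tuple[float, float] = (0.1, 1.0)
    topic_concentration: float = 0.5
    repeated_visits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_caqtl_peaks", "frac_dynamic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("beta_sd", "delta_sd", "sigma_donor", "sigma_library"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.cells_per_donor[0] > self.cells_per_donor[1]:
            raise ValueError("cells_per_donor min must be <= max")
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated dataset."""

    causal_snp_per_peak: np.ndarray  # global SNP index, -1 for null peaks
    beta_true: np.ndarray  # per-peak log-rate per alt allele
    delta_true: np.ndarray  # per-peak interaction per unit loading
    topic_loadings_true: np.ndarray  # cells x K, rows sum to 1
    topic_profiles_true: np.ndarray  # peaks x K, columns sum to 1
    donor_effects: np.ndarray
    library_effects: np.ndarray
    dynamic_topic: int = 0

    def __post_init__(self) -> None:
        rows = self.topic_loadings_true.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            raise ValueError("topic loading rows must sum to 1")


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    adata: AnnData  # cells x peaks counts + obs metadata
    peaks: pd.DataFrame  # chrom, start, end, peak_id
    snps: pd.DataFrame  # snp, chrom, pos, ea, oa, maf, peak_index
    dosages: np.ndarray  # donors x SNPs in {0,1,2}
    truth: GroundTruth
    caqtl_peaks: np.ndarray = field(default_factory=lambda: np.array([], int))
    null_peaks: np.ndarray = field(default_factory=lambda: np.array([], int))


def _copula_haplotypes(rng, n_ind, mafs, ld_rho):
    """Two latent AR(1) Gaussian haplotypes thresholded to alleles."""
    n_snps = mafs.size
    thresh = stats.norm.ppf(mafs)
    dosage = np.zeros((n_ind, n_snps), dtype=np.int64)
    for _ in range(2):
        z = rng.standard_normal((n_ind, n_snps))
        for j in range(1, n_snps):
            z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1.0 - ld_rho**2) * z[:, j]
        dosage += (z < thresh).astype(np.int64)
    return dosage


def simulate_genotypes(
    n_donors: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.9,
    seed: int = 0,
    start_pos: int = 1_000_000,
    mean_spacing: int = 2_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate donor x SNP dosages with AR(1) Gaussian-copula LD.

    Returns (dosages in {0,1,2}, strictly increasing positions).
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    dosage = _copula_haplotypes(rng, n_donors, mafs, ld_rho)
    gaps = rng.integers(max(1, mean_spacing // 2), mean_spacing * 3 // 2 + 1, size=n_snps)
    positions = start_pos + np.cumsum(gaps)
    return dosage, positions


def simulate_cell_states(
    n_cells: int,
    K: int,
    concentration: float = 0.5,
    seed: int = 0,
    n_peaks: int = 600,
    frac_topic_peaks: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet topic loadings per cell and sparse per-topic peak profiles.

    Loadings rows sum to 1; profile columns sum to 1. Each topic elevates a
    random subset of ``frac_topic_peaks`` peaks by gamma-distributed factors
    over a small uniform background.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    loadings = rng.dirichlet(np.full(K, concentration), size=n_cells)
    profiles = np.full((n_peaks, K), 0.2)
    n_sig = max(1, int(round(frac_topic_peaks * n_peaks)))
    for k in range(K):
        idx = rng.choice(n_peaks, size=n_sig, replace=False)
        profiles[idx, k] += rng.gamma(shape=2.0, scale=2.0, size=n_sig)
    profiles /= profiles.sum(axis=0, keepdims=True)
    return loadings, profiles


def _cell_metadata(rng, config: SimConfig) -> pd.DataFrame:
    """Assign cells to donors, studies, libraries, visits; draw depths and QC."""
    lo, hi = config.cells_per_donor
    donor_study = np.arange(config.n_donors) % config.n_studies
    rows = []
    for d in range(config.n_donors):
        n_cells_d = int(rng.integers(lo, hi + 1))
        study = donor_study[d]
        if config.repeated_visits and d % 2 == 0:
            # even-indexed donors contribute a second, smaller visit
            n_v2 = max(2, n_cells_d // 3)
            visits = np.r_[np.ones(n_cells_d, int), np.full(n_v2, 2, int)]
        else:
            visits = np.ones(n_cells_d, int)
        libs = rng.integers(0, config.n_libraries_per_study, size=visits.size)
        for v, lib in zip(visits, libs):
            rows.append((d, study, study * config.n_libraries_per_study + lib, v))
    meta = pd.DataFrame(rows, columns=["donor", "study", "library", "visit"])
    n = len(meta)
    mu, sg = config.depth_lognormal_params
    z_depth = rng.standard_normal(n)
    depth = np.exp(mu + sg * z_depth)
    # QC covariates jointly normal with log-depth at correlation 0.5
    def corr_noise():
        return 0.5 * z_depth + np.sqrt(1 - 0.25) * rng.standard_normal(n)

    meta["cell_id"] = [f"cell{i:06d}" for i in range(n)]
    meta["depth"] = depth
    meta["TSSEnrichment"] = 8.0 + 2.0 * corr_noise()
    meta["MTratio"] = 1.0 / (1.0 + np.exp(-(-3.0 + 0.5 * corr_noise())))
    meta["log10nFrags"] = np.log10(depth) + 0.05 * rng.standard_normal(n)
    return meta


def simulate_counts(
    config: SimConfig,
    genotypes: np.ndarray,
    truth: GroundTruth,
) -> AnnData:
    """Draw the sparse Poisson count matrix given genotypes and ground truth.

    ``genotypes`` is donors x SNPs; ``truth.causal_snp_per_peak`` indexes its
    columns. Returns an AnnData with obs columns (cell_id, donor, library,
    study, visit, TSSEnrichment, MTratio, log10nFrags).
    """
    n_peaks = truth.beta_true.size
    if genotypes.shape[0] != config.n_donors:
        raise ValueError("genotype rows must equal n_donors")
    if truth.topic_profiles_true.shape[0] != n_peaks:
        raise ValueError("topic profile rows must equal number of peaks")
    rng = np.random.default_rng(config.seed + _SEED_COUNTS)
    meta = _cell_metadata(rng, config)
    n_cells = len(meta)
    if truth.topic_loadings_true.shape[0] != n_cells:
        raise ValueError(
            f"truth has loadings for {truth.topic_loadings_true.shape[0]} cells "
            f"but the design yields {n_cells} cells"
        )
    L = truth.topic_loadings_true
    Phi = truth.topic_profiles_true
    donor = meta["donor"].to_numpy()
    lib = meta["library"].to_numpy()
    t = L[:, truth.dynamic_topic]

    base = np.empty(n_peaks)
    rng_truth = np.random.default_rng(config.seed + _SEED_TRUTH + 1)
    base[:] = rng_truth.uniform(*config.baseline_rate_range, size=n_peaks)

    # topic modulation, normalized per peak to mean 1 across cells
    mod = L @ Phi.T  # cells x peaks
    mod /= mod.mean(axis=0, keepdims=True)

    depth_term = meta["depth"].to_numpy()[:, None] * 1e-4 * base[None, :]
    log_mu = np.log(depth_term) + np.log(np.maximum(mod, 1e-300))
    has_qtl = truth.causal_snp_per_peak >= 0
    if np.any(has_qtl):
        g_cols = genotypes[:, truth.causal_snp_per_peak[has_qtl]][donor]
        log_mu[:, has_qtl] += truth.beta_true[has_qtl][None, :] * g_cols
        log_mu[:, has_qtl] += (
            truth.delta_true[has_qtl][None, :] * g_cols * t[:, None]
        )
    log_mu += truth.donor_effects[donor][:, None]
    log_mu += truth.library_effects[lib][:, None]

    counts = rng.poisson(np.exp(log_mu))
    X = sparse.csr_matrix(counts)
    obs = meta.set_index("cell_id")[
        ["donor", "library", "study", "visit", "TSSEnrichment", "MTratio", "log10nFrags"]
    ].copy()
    obs.index.name = "cell_id"
    var = pd.DataFrame(index=[f"peak{c}" for c in range(n_peaks)])
    adata = AnnData(X=X, obs=obs, var=var)
    adata.obs["depth"] = meta["depth"].to_numpy()
    return adata


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """End-to-end simulation: genotypes, topic structure, truth, counts.

    Peaks are laid out every 300 kb on one chromosome (so the 250 kb mapping
    windows of neighboring peaks do not overlap) with ``snps_per_peak`` SNPs
    in an independent AR(1) LD block within +-10 kb of each peak center.
    """
    cfg = config
    rng_truth = np.random.default_rng(cfg.seed + _SEED_TRUTH)

    # --- peaks ---
    spacing = 300_000
    centers = 1_000_000 + spacing * np.arange(cfg.n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": centers - 250,
            "end": centers + 250,
            "peak_id": [f"peak{c}" for c in range(cfg.n_peaks)],
        }
    )

    # --- genotypes: independent LD block per peak ---
    blocks = []
    positions = []
    mafs_all = []
    for c in range(cfg.n_peaks):
        dos, pos = simulate_genotypes(
            cfg.n_donors,
            cfg.snps_per_peak,
            cfg.maf_range,
            cfg.ld_rho,
            seed=cfg.seed + _SEED_GENO + 1000 + c,
            start_pos=int(centers[c]) - 10_000,
            mean_spacing=max(1, 20_000 // max(1, cfg.snps_per_peak)),
        )
        blocks.append(dos)
        positions.append(pos)
        mafs_all.append(dos.mean(axis=0) / 2.0)
    dosages = np.concatenate(blocks, axis=1)
    snp_pos = np.concatenate(positions)
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i:06d}" for i in range(dosages.shape[1])],
            "chrom": "chr1",
            "pos": snp_pos,
            "ea": "A",
            "oa": "G",
            "maf": np.concatenate(mafs_all),
            "peak_index": np.repeat(np.arange(cfg.n_peaks), cfg.snps_per_peak),
        }
    )

    # --- planted effects ---
    n_caqtl = int(round(cfg.frac_caqtl_peaks * cfg.n_peaks))
    caqtl_peaks = np.sort(rng_truth.choice(cfg.n_peaks, size=n_caqtl, replace=False))
    null_peaks = np.setdiff1d(np.arange(cfg.n_peaks), caqtl_peaks)
    causal = np.full(cfg.n_peaks, -1, dtype=int)
    beta = np.zeros(cfg.n_peaks)
    delta = np.zeros(cfg.n_peaks)
    if n_caqtl:
        within = rng_truth.integers(0, cfg.snps_per_peak, size=n_caqtl)
        causal[caqtl_peaks] = caqtl_peaks * cfg.snps_per_peak + within
        beta[caqtl_peaks] = rng_truth.normal(0.0, cfg.beta_sd, size=n_caqtl)
        n_dyn = int(round(cfg.frac_dynamic * n_caqtl))
        dyn = rng_truth.choice(caqtl_peaks, size=n_dyn, replace=False)
        delta[dyn] = rng_truth.normal(0.0, cfg.delta_sd, size=n_dyn)

    # --- cell states (needs the realized number of cells) ---
    rng_cells = np.random.default_rng(cfg.seed + _SEED_COUNTS)
    n_cells = len(_cell_metadata(rng_cells, cfg))
    loadings, profiles = simulate_cell_states(
        n_cells,
        cfg.n_topics,
        concentration=cfg.topic_concentration,
        seed=cfg.seed + _SEED_STATES,
        n_peaks=cfg.n_peaks,
    )
    truth = GroundTruth(
        causal_snp_per_peak=causal,
        beta_true=beta,
        delta_true=delta,
        topic_loadings_true=loadings,
        topic_profiles_true=profiles,
        donor_effects=rng_truth.normal(0.0, cfg.sigma_donor, size=cfg.n_donors),
        library_effects=rng_truth.normal(
            0.0, cfg.sigma_library, size=cfg.n_studies * cfg.n_libraries_per_study
        ),
        dynamic_topic=cfg.n_topics - 1,
    )
    adata = simulate_counts(cfg, dosages, truth)
    return SimulatedDataset(
        config=cfg,
        adata=adata,
        peaks=peaks,
        snps=snps,
        dosages=dosages,
        truth=truth,
        caqtl_peaks=caqtl_peaks,
        null_peaks=null_peaks,
    )


def simulate_summary_stats(
    genotypes: np.ndarray,
    causal_config: str,
    n1: int,
    n2: int,
    h2: float = 0.2,
    seed: int = 0,
    ld_rho: float = 0.9,
    snp_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP marginal summary statistics for a pair of quantitative traits.

    ``genotypes`` (individuals x SNPs) defines the SNP panel; fresh genotype
    draws of sizes n1 and n2 are simulated from the same allele frequencies
    and AR(1) copula. ``causal_config`` is one of:

    - "shared": one causal SNP common to both traits
    - "distinct": two different causal SNPs, drawn far apart in the block
    - "single": trait 1 has a causal SNP, trait 2 is null
    - "null": both traits null

    Each trait's per-SNP beta/se come from simple marginal OLS regressions.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if causal_config not in {"shared", "distinct", "single", "null"}:
        raise ValueError(f"unknown causal_config {causal_config!r}")
    rng = np.random.default_rng(seed)
    mafs = np.clip(genotypes.mean(axis=0) / 2.0, 0.01, 0.5)
    n_snps = mafs.size
    if causal_config == "distinct" and n_snps < 4:
        raise ValueError("need >= 4 SNPs for distinct causal variants")

    if causal_config == "null":
        c1 = c2 = -1
    else:
        c1 = int(rng.integers(0, n_snps))
        if causal_config == "shared":
            c2 = c1
        elif causal_config == "single":
            c2 = -1
        else:  # distinct: maximize separation in the LD chain
            c1 = n_snps // 4
            c2 = 3 * n_snps // 4

    tables = []
    for n, causal in ((n1, c1), (n2, c2)):
        g = _copula_haplotypes(rng, n, mafs, ld_rho).astype(float)
        y = rng.standard_normal(n) * np.sqrt(max(1.0 - h2, 1e-12))
        if causal >= 0:
            p_c = mafs[causal]
            b = np.sqrt(h2 / (2.0 * p_c * (1.0 - p_c)))
            y = y + b * (g[:, causal] - 2 * p_c)
        gc = g - g.mean(axis=0, keepdims=True)
        yc = y - y.mean()
        var_g = (gc**2).sum(axis=0)
        var_g = np.maximum(var_g, 1e-12)
        beta = gc.T @ yc / var_g
        # residual variance of the marginal fit per SNP
        rss = (yc**2).sum() - beta**2 * var_g
        se = np.sqrt(np.maximum(rss, 1e-12) / (n - 2) / var_g)
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        ids = snp_ids if snp_ids is not None else [f"rs{i:06d}" for i in range(n_snps)]
        pos = positions if positions is not None else 1_000_000 + 2_000 * np.arange(n_snps)
        tables.append(
            pd.DataFrame(
                {
                    "snp": ids,
                    "chrom": "chr1",
                    "pos": pos,
                    "ea": "A",
                    "oa": "G",
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "maf": mafs,
                    "n": n,
                }
            )
        )
    return tables[0], tables[1]
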