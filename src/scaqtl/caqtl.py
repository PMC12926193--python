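"""Single-cell Poisson mixed-effects (sc-PME) caQTL mapping.

Per-cell fragment counts in one peak are modeled as

    y_i ~ Poisson(mu_i),
    log mu_i = log s_i + beta g_{d(i)} + x_i' gamma + a_{d(i)} + b_{l(i)}

with the cell's log library size s_i as offset, donor genotype dosage g,
z-scaled fixed QC/latent covariates x_i, and donor/library random
intercepts. The module provides the windowed scan (SNPs within +-125 kb of
the peak center, minor-allele-count filter >= 4), lead-SNP extraction with
per-peak Bonferroni correction, Storey q-values over lead SNPs (significant
at q < 0.1), dynamic genotype-by-loading interaction LRTs with per-topic
q-values Bonferroni-adjusted over topics (significant at adjusted q < 0.01),
donor-genotype permutation calibration with sparsity/mean-matched control
peaks, RASQUAL-style empirical significance from pooled permuted statistics,
and effect-size concordance metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .glmm import GlmmResult, fit_glmm
from .qvalue import storey_qvalue

__all__ = [
    "CellDesign",
    "ScpmeFit",
    "CalibrationReport",
    "DEFAULT_TOPIC_MAP",
    "make_cell_design",
    "compute_genotype_pcs",
    "compute_lsi",
    "aggregate_pseudobulk",
    "snp_window",
    "filter_snps",
    "fit_scpme",
    "scan_peak",
    "scan_dataset",
    "call_caqtls",
    "dynamic_lrt",
    "dynamic_scan",
    "adjust_dynamic",
    "permute_genotypes",
    "permute_and_calibrate",
    "peak_features",
    "match_control_peaks",
    "empirical_significance",
    "effect_concordance",
]

# Cell-type -> trajectory-topic map used for dynamic caQTL adjustment
# (topics present in each common immune cell type).
DEFAULT_TOPIC_MAP: dict[str, tuple[str, ...]] = {
    "B": ("k1", "k11"),
    "CD4 T": ("k6", "k7", "k17"),
    "CD8 T": ("k3", "k6", "k7", "k14", "k17", "k18", "k19"),
    "NK": ("k3", "k17"),
    "monocyte": ("k10", "k12", "k15"),
    "DC": ("k4", "k10", "k12", "k15"),
    "other T": ("k3", "k6", "k8", "k14", "k17", "k18", "k19"),
}

QTL_COLUMNS = [
    "peak_id",
    "snp_id",
    "chrom",
    "pos",
    "distance",
    "beta",
    "se",
    "z",
    "p",
    "p_bonf",
    "q",
    "is_lead",
]


@dataclass
class CellDesign:
    """Per-cell fixed design for sc-PME fits.

    ``X`` holds the z-scaled fixed covariates (no intercept column; one is
    added internally), ``offset`` the per-cell log library size, ``donor``
    and ``library`` integer-coded grouping factors.
    """

    X: np.ndarray
    offset: np.ndarray
    donor: np.ndarray
    library: np.ndarray
    columns: list[str] = field(default_factory=list)
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offsets must be finite")
        if self.X.shape[1]:
            means = self.X.mean(axis=0)
            sds = self.X.std(axis=0)
            if np.any(np.abs(means) > 1e-6) or np.any(np.abs(sds - 1.0) > 1e-4):
                raise ValueError("design columns must be z-scaled (mean 0, SD 1)")
        if self.g is not None and (np.min(self.g) < 0 or np.max(self.g) > 2):
            raise ValueError("genotype dosages must lie in [0, 2]")

    @property
    def n_cells(self) -> int:
        return self.offset.size


@dataclass
class ScpmeFit:
    """One peak-SNP sc-PME association."""

    beta: float
    se: float
    z: float
    p_wald: float
    sigma_donor: float
    sigma_library: float
    loglik: float
    converged: bool
    flags: dict = field(default_factory=dict)


@dataclass
class CalibrationReport:
    """Outcome of a donor-genotype permutation calibration run."""

    fraction_q_below: dict[str, float]
    n_peaks: dict[str, int]
    fdr: float
    leads: dict[str, pd.DataFrame]
    permutation: np.ndarray


def _zscale(a: np.ndarray, name: str) -> np.ndarray:
    sd = a.std()
    if sd < 1e-12:
        raise ValueError(f"covariate {name!r} is constant and cannot be z-scaled")
    return (a - a.mean()) / sd


def make_cell_design(
    obs: pd.DataFrame,
    covariates: tuple[str, ...] = ("TSSEnrichment", "MTratio", "log10nFrags"),
    extra: np.ndarray | None = None,
    extra_names: list[str] | None = None,
    depth: np.ndarray | None = None,
) -> CellDesign:
    """Build a :class:`CellDesign` from cell metadata.

    ``extra`` may carry additional z-scalable columns such as genotype PCs
    or latent-embedding (LSI) dimensions. ``depth`` defaults to the ``depth``
    metadata column (per-cell library size).
    """
    cols = [_zscale(obs[c].to_numpy(float), c) for c in covariates]
    names = list(covariates)
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != len(obs):
            extra = extra.T
        for j in range(extra.shape[1]):
            nm = extra_names[j] if extra_names else f"extra{j}"
            cols.append(_zscale(extra[:, j], nm))
            names.append(nm)
    X = np.column_stack(cols) if cols else np.empty((len(obs), 0))
    if depth is None:
        depth = obs["depth"].to_numpy(float)
    donor = pd.Categorical(obs["donor"]).codes.astype(np.int64)
    library = pd.Categorical(obs["library"]).codes.astype(np.int64)
    return CellDesign(
        X=X, offset=np.log(depth), donor=donor, library=library, columns=names
    )


def compute_genotype_pcs(dosages: np.ndarray, n_pcs: int = 5) -> np.ndarray:
    """Top principal components of the centered donor x SNP dosage matrix."""
    d = dosages - dosages.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    k = min(n_pcs, s.size)
    return u[:, :k] * s[:k]


def compute_lsi(counts: sparse.spmatrix, n_dims: int = 5, drop_first: bool = True):
    """TF-IDF + truncated SVD latent embedding of the cell x peak matrix."""
    from sklearn.decomposition import TruncatedSVD

    X = sparse.csr_matrix(counts, dtype=float)
    tf = X.multiply(1.0 / np.maximum(X.sum(axis=1), 1))
    idf = np.log1p(X.shape[0] / np.maximum((X > 0).sum(axis=0).A1, 1))
    mat = sparse.csr_matrix(tf.multiply(idf))
    svd = TruncatedSVD(n_components=n_dims + int(drop_first), random_state=0)
    emb = svd.fit_transform(mat)
    return emb[:, 1:] if drop_first else emb[:, :n_dims]


def aggregate_pseudobulk(
    counts: sparse.spmatrix,
    cell_groups: np.ndarray,
    donor: np.ndarray | None = None,
    visit: np.ndarray | None = None,
    dedup_by_visit: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sum single-cell counts within groups; optionally keep one visit per donor.

    With ``dedup_by_visit``, for each donor only cells from the visit with
    the most cells are retained (ties broken toward the earlier visit)
    before aggregation, avoiding repeated-measurement donors.
    """
    counts = sparse.csr_matrix(counts)
    keep = np.ones(counts.shape[0], dtype=bool)
    if dedup_by_visit:
        if donor is None or visit is None:
            raise ValueError("dedup_by_visit requires donor and visit arrays")
        df = pd.DataFrame({"donor": donor, "visit": visit})
        sizes = df.groupby(["donor", "visit"]).size().reset_index(name="n")
        best = (
            sizes.sort_values(["donor", "n", "visit"], ascending=[True, False, True])
            .drop_duplicates("donor")
            .set_index("donor")["visit"]
        )
        keep = visit == best.loc[pd.Series(donor)].to_numpy()
    groups = pd.Categorical(np.asarray(cell_groups)[keep])
    ind = sparse.csr_matrix(
        (np.ones(keep.sum()), (groups.codes, np.arange(keep.sum()))),
        shape=(len(groups.categories), int(keep.sum())),
    )
    pb = np.asarray((ind @ counts[keep]).todense())
    meta = pd.DataFrame({"group": list(groups.categories)})
    return pb, meta


def snp_window(
    peak: tuple[int, int], positions: np.ndarray, half_width: int = 125_000
) -> np.ndarray:
    """Indices of SNPs within +-half_width of the peak center (closed)."""
    center = (int(peak[0]) + int(peak[1])) // 2
    positions = np.asarray(positions)
    return np.flatnonzero(
        (positions >= center - half_width) & (positions <= center + half_width)
    )


def filter_snps(dosages: np.ndarray, min_mac: int = 4) -> np.ndarray:
    """Keep SNPs with minor-allele dosage sum >= min_mac (and polymorphic)."""
    dosages = np.asarray(dosages)
    ac = dosages.sum(axis=0)
    mac = np.minimum(ac, 2 * dosages.shape[0] - ac)
    return np.flatnonzero(mac >= min_mac)


def fit_scpme(
    y: np.ndarray,
    design: CellDesign,
    g: np.ndarray | None = None,
    method: str = "laplace",
    sigma_fixed: np.ndarray | None = None,
    eta_start: np.ndarray | None = None,
    extra_cols: np.ndarray | None = None,
) -> ScpmeFit:
    """Fit the sc-PME model for one peak and one SNP.

    ``g`` (per-cell dosage) overrides ``design.g``. ``extra_cols`` appends
    unscaled columns (used internally for interaction terms).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    if g is None:
        g = design.g
    if g is None:
        raise ValueError("a genotype vector is required")
    cols = [np.ones(design.n_cells), np.asarray(g, float), design.X]
    if extra_cols is not None:
        cols.append(np.atleast_2d(extra_cols.T).T)
    X = np.column_stack(cols)
    res = fit_glmm(
        y,
        X,
        [design.donor, design.library],
        family="poisson",
        offset=design.offset,
        method=method,
        sigma_fixed=sigma_fixed,
        eta_start=eta_start,
    )
    return _to_scpme(res)


def _to_scpme(res: GlmmResult, coef: int = 1) -> ScpmeFit:
    beta = float(res.beta[coef])
    se = float(res.se[coef])
    if res.converged and se > 0:
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z, p = np.nan, np.nan
    return ScpmeFit(
        beta=beta,
        se=se,
        z=z,
        p_wald=p,
        sigma_donor=float(res.sigma[0]) if res.sigma.size > 0 else np.nan,
        sigma_library=float(res.sigma[1]) if res.sigma.size > 1 else np.nan,
        loglik=res.loglik,
        converged=res.converged,
        flags=res.flags,
    )


def _base_fit(y, design, method="pql"):
    """Genotype-free fit of a peak: variance components + warm start."""
    X = np.column_stack([np.ones(design.n_cells), design.X])
    return fit_glmm(
        y,
        X,
        [design.donor, design.library],
        family="poisson",
        offset=design.offset,
        method=method,
    )


def scan_peak(
    y: np.ndarray,
    dosages: np.ndarray,
    design: CellDesign,
    snp_ids: list[str],
    positions: np.ndarray,
    peak: tuple[int, int],
    peak_id: str = "peak",
    chrom: str = "chr1",
    method: str = "pql",
    refit_components_per_snp: bool = False,
) -> pd.DataFrame:
    """sc-PME scan of one peak over pre-filtered window SNPs.

    ``dosages`` is donors x SNPs for the SNPs to test. Variance components
    are estimated once on the genotype-free base model and held fixed per
    SNP unless ``refit_components_per_snp``. The lead SNP has the smallest
    Wald p; ties break by distance to the peak center, then by snp_id.
    """
    m = dosages.shape[1]
    center = (int(peak[0]) + int(peak[1])) // 2
    base = _base_fit(y, design, method=method)
    rows = []
    for j in range(m):
        g = dosages[design.donor, j].astype(float)
        fit = fit_scpme(
            y,
            design,
            g,
            method=method,
            sigma_fixed=None if refit_components_per_snp else base.sigma,
            eta_start=base.eta,
        )
        rows.append(
            {
                "peak_id": peak_id,
                "snp_id": snp_ids[j],
                "chrom": chrom,
                "pos": int(positions[j]),
                "distance": abs(int(positions[j]) - center),
                "beta": fit.beta,
                "se": fit.se,
                "z": fit.z,
                "p": fit.p_wald,
                "converged": fit.converged,
            }
        )
    rec = pd.DataFrame(rows)
    n_tested = int(rec["p"].notna().sum())
    rec["p_bonf"] = np.minimum(1.0, rec["p"] * max(n_tested, 1))
    order = rec.sort_values(["p", "distance", "snp_id"], kind="stable")
    rec["is_lead"] = False
    if n_tested:
        rec.loc[order.index[0], "is_lead"] = True
    return rec


def scan_dataset(
    counts: sparse.spmatrix,
    peaks: pd.DataFrame,
    snps: pd.DataFrame,
    dosages: np.ndarray,
    design: CellDesign,
    peak_indices: np.ndarray | None = None,
    window: int = 125_000,
    min_mac: int = 4,
    method: str = "pql",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Scan many peaks; returns (all records, lead records, untested peaks)."""
    counts = sparse.csc_matrix(counts)
    positions = snps["pos"].to_numpy()
    snp_ids = snps["snp"].to_numpy()
    keep_mac = np.zeros(dosages.shape[1], dtype=bool)
    keep_mac[filter_snps(dosages, min_mac=min_mac)] = True
    if peak_indices is None:
        peak_indices = np.arange(len(peaks))
    all_records = []
    untested = []
    for c in peak_indices:
        row = peaks.iloc[int(c)]
        win = snp_window((row["start"], row["end"]), positions, half_width=window)
        win = win[keep_mac[win]]
        if win.size == 0:
            untested.append(row["peak_id"])
            continue
        y = np.asarray(counts[:, int(c)].todense()).ravel()
        rec = scan_peak(
            y,
            dosages[:, win],
            design,
            list(snp_ids[win]),
            positions[win],
            (row["start"], row["end"]),
            peak_id=row["peak_id"],
            chrom=str(row.get("chrom", "chr1")),
            method=method,
        )
        all_records.append(rec)
    if untested:
        warnings.warn(
            f"{len(untested)} peak(s) had no eligible SNP and were skipped",
            UserWarning,
            stacklevel=2,
        )
    if not all_records:
        empty = pd.DataFrame(columns=QTL_COLUMNS)
        return empty, empty, untested
    records = pd.concat(all_records, ignore_index=True)
    leads = records[records["is_lead"]].reset_index(drop=True)
    return records, leads, untested


def call_caqtls(
    leads: pd.DataFrame, fdr: float = 0.10, min_peaks: int = 50
) -> pd.DataFrame:
    """Storey q-values over per-peak lead Bonferroni p; significant at q < fdr."""
    if len(leads) < min_peaks:
        raise ValueError(
            f"only {len(leads)} lead records; q-value estimation needs >= "
            f"{min_peaks} peaks — pass min_peaks explicitly to lower the guard"
        )
    out = leads.copy()
    _, q = storey_qvalue(out["p_bonf"].to_numpy())
    out["q"] = q
    out["significant"] = out["q"] < fdr
    return out


def dynamic_lrt(
    y: np.ndarray,
    design: CellDesign,
    g: np.ndarray,
    t: np.ndarray,
    method: str = "pql",
) -> dict:
    """Genotype-by-loading interaction LRT for one peak-SNP pair.

    Full model adds theta*t + delta*g*t to the sc-PME mean; the reduced
    model keeps theta*t only. Returns a record with delta_hat, lrt_stat and
    the chi-square(1) p-value. A constant loading makes the interaction
    unidentifiable and is reported as stat 0 with a flag.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    g = np.asarray(g, float)
    if np.std(t) < 1e-12:
        return {
            "delta_hat": 0.0,
            "lrt_stat": 0.0,
            "p_lrt": 1.0,
            "converged": False,
            "flag": "constant_loading",
        }
    ones = np.ones(design.n_cells)
    X_red = np.column_stack([ones, g, design.X, t])
    X_full = np.column_stack([ones, g, design.X, t, g * t])
    groups = [design.donor, design.library]
    reduced = fit_glmm(
        y, X_red, groups, family="poisson", offset=design.offset, method=method
    )
    full = fit_glmm(
        y, X_full, groups, family="poisson", offset=design.offset, method=method
    )
    if not (reduced.converged and full.converged):
        return {
            "delta_hat": np.nan,
            "lrt_stat": np.nan,
            "p_lrt": np.nan,
            "converged": False,
            "flag": "not_converged",
        }
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return {
        "delta_hat": float(full.beta[-1]),
        "lrt_stat": stat,
        "p_lrt": float(stats.chi2.sf(stat, df=1)),
        "converged": True,
        "flag": "",
    }


def dynamic_scan(
    counts: sparse.spmatrix,
    leads: pd.DataFrame,
    snps: pd.DataFrame,
    dosages: np.ndarray,
    design: CellDesign,
    loadings: np.ndarray,
    topics: list[str],
    cell_type: str = "all",
    method: str = "pql",
) -> pd.DataFrame:
    """Interaction LRT of each lead caQTL SNP against each topic loading.

    ``leads`` must carry a ``peak_index`` column addressing count-matrix
    columns; ``loadings`` is cells x len(topics).
    """
    counts = sparse.csc_matrix(counts)
    snp_index = pd.Index(snps["snp"])
    rows = []
    for _, lead in leads.iterrows():
        j = snp_index.get_loc(lead["snp_id"])
        y = np.asarray(counts[:, int(lead["peak_index"])].todense()).ravel()
        g = dosages[design.donor, j].astype(float)
        for k, topic in enumerate(topics):
            res = dynamic_lrt(y, design, g, loadings[:, k], method=method)
            rows.append(
                {
                    "peak_id": lead["peak_id"],
                    "snp_id": lead["snp_id"],
                    "topic": topic,
                    "cell_type": cell_type,
                    **res,
                }
            )
    return pd.DataFrame(rows)


def adjust_dynamic(
    records: pd.DataFrame,
    topics_per_snp: dict | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-topic Storey q-values, Bonferroni-multiplied by topics tested per SNP.

    ``topics_per_snp`` maps (cell_type, snp_id) or snp_id to the number of
    topics the SNP was tested in; by default it is counted from the records.
    """
    out = records.copy()
    out["q_topic"] = np.nan
    for (_, _), idx in out.groupby(["cell_type", "topic"]).groups.items():
        p = out.loc[idx, "p_lrt"].to_numpy(float)
        ok = np.isfinite(p)
        if ok.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, q = storey_qvalue(p[ok])
        vals = np.full(p.size, np.nan)
        vals[ok] = q
        out.loc[idx, "q_topic"] = vals
    if topics_per_snp is None:
        counts = out.groupby(["cell_type", "snp_id"])["topic"].nunique()
        n_topics = [
            counts.loc[(ct, s)] for ct, s in zip(out["cell_type"], out["snp_id"])
        ]
    else:
        n_topics = [
            topics_per_snp.get((ct, s), topics_per_snp.get(s, 1))
            for ct, s in zip(out["cell_type"], out["snp_id"])
        ]
    out["n_topics_tested"] = n_topics
    out = out[out["n_topics_tested"] > 0].copy()
    out["q_adj"] = np.minimum(1.0, out["q_topic"] * out["n_topics_tested"])
    out["significant"] = out["q_adj"] < alpha
    return out


def permute_genotypes(dosages: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle genotype vectors across donors, preserving within-donor LD."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dosages.shape[0])
    return dosages[perm], perm


def permute_and_calibrate(
    counts: sparse.spmatrix,
    peaks: pd.DataFrame,
    snps: pd.DataFrame,
    dosages: np.ndarray,
    design: CellDesign,
    peak_sets: dict[str, np.ndarray],
    seed: int = 0,
    fdr: float = 0.10,
    window: int = 125_000,
    method: str = "pql",
    min_peaks: int = 50,
) -> CalibrationReport:
    """Permute donor-genotype assignment, rerun the scan, report q < fdr rates.

    q-values are computed within each named peak set (e.g. "cpeaks",
    "controls"), mirroring separate calibration analyses of QTL-bearing
    peaks and matched null controls.
    """
    perm_dos, perm = permute_genotypes(dosages, seed)
    fractions, leads_by_set, n_by_set = {}, {}, {}
    for name, idx in peak_sets.items():
        _, leads, _ = scan_dataset(
            counts,
            peaks,
            snps,
            perm_dos,
            design,
            peak_indices=np.asarray(idx),
            window=window,
            method=method,
        )
        called = call_caqtls(leads, fdr=fdr, min_peaks=min(min_peaks, len(leads)))
        fractions[name] = float(called["significant"].mean())
        leads_by_set[name] = called
        n_by_set[name] = int(len(called))
    return CalibrationReport(
        fraction_q_below=fractions,
        n_peaks=n_by_set,
        fdr=fdr,
        leads=leads_by_set,
        permutation=perm,
    )


def peak_features(counts: sparse.spmatrix) -> pd.DataFrame:
    """Per-peak sparsity (fraction of zero cells) and mean count."""
    counts = sparse.csc_matrix(counts)
    n = counts.shape[0]
    nnz = counts.getnnz(axis=0)
    return pd.DataFrame(
        {
            "sparsity": 1.0 - nnz / n,
            "mean_count": np.asarray(counts.sum(axis=0)).ravel() / n,
        }
    )


def match_control_peaks(
    target_features: pd.DataFrame,
    candidate_features: pd.DataFrame,
    k: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Nearest-neighbor control matching without replacement.

    Features are z-scaled jointly; each target greedily takes its nearest
    unused candidate (Euclidean). Returns positional indices into the
    candidate table and a covariate-balance report with standardized mean
    differences before and after matching.
    """
    if k != 1:
        raise NotImplementedError("only 1:1 matching is supported")
    nt, nc = len(target_features), len(candidate_features)
    if nt > nc:
        raise ValueError(f"more targets ({nt}) than candidates ({nc})")
    cols = list(target_features.columns)
    both = np.vstack([target_features[cols].to_numpy(float),
                      candidate_features[cols].to_numpy(float)])
    mu, sd = both.mean(axis=0), both.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    tz = (target_features[cols].to_numpy(float) - mu) / sd
    cz = (candidate_features[cols].to_numpy(float) - mu) / sd
    used = np.zeros(nc, dtype=bool)
    chosen = np.empty(nt, dtype=int)
    for i in range(nt):
        d2 = ((cz - tz[i]) ** 2).sum(axis=1)
        d2[used] = np.inf
        j = int(np.argmin(d2))
        used[j] = True
        chosen[i] = j

    def smd(a, b):
        pooled = np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2.0)
        pooled = np.where(pooled < 1e-12, 1.0, pooled)
        return (a.mean(axis=0) - b.mean(axis=0)) / pooled

    t_raw = target_features[cols].to_numpy(float)
    c_raw = candidate_features[cols].to_numpy(float)
    balance = pd.DataFrame(
        {
            "feature": cols,
            "smd_pre": smd(t_raw, c_raw),
            "smd_post": smd(t_raw, c_raw[chosen]),
        }
    )
    return chosen, balance


def empirical_significance(
    nominal_stat: np.ndarray, permuted_stat: np.ndarray, fdr: float = 0.10
) -> pd.DataFrame:
    """Empirical p from pooled permutation nulls, plus Storey q.

    Larger statistic = more significant (pass -log10-transformed values).
    p_emp = (1 + #{null >= observed}) / (1 + N_null).
    """
    null = np.sort(np.asarray(permuted_stat, float))
    if null.size == 0:
        raise ValueError("the permuted null set is empty")
    obs = np.asarray(nominal_stat, float)
    n_ge = null.size - np.searchsorted(null, obs, side="left")
    p_emp = (1.0 + n_ge) / (1.0 + null.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        _, q = storey_qvalue(p_emp)
    return pd.DataFrame(
        {"stat": obs, "p_emp": p_emp, "q": q, "significant": q < fdr}
    )


def effect_concordance(beta_a: np.ndarray, beta_b: np.ndarray) -> dict:
    """Sign-agreement fraction and Pearson correlation of paired effects."""
    a = np.asarray(beta_a, float)
    b = np.asarray(beta_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    nonzero = (a != 0) & (b != 0)
    n_zero = int((~nonzero).sum())
    if nonzero.sum() == 0:
        return {
            "sign_agreement": np.nan,
            "correlation": np.nan,
            "n_pairs": int(a.size),
            "n_zero_excluded": n_zero,
            "flag": "all_pairs_zero",
        }
    agree = float(np.mean(a[nonzero] * b[nonzero] > 0))
    corr = float(np.corrcoef(a, b)[0, 1]) if a.size > 1 else np.nan
    return {
        "sign_agreement": agree,
        "correlation": corr,
        "n_pairs": int(a.size),
        "n_zero_excluded": n_zero,
    }
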