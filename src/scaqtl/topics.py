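"""Grade-of-membership topic modeling of scATAC counts via Poisson NMF.

The cell x peak count matrix is factorized as X ~ Poisson(L F') with
nonnegative loadings L (cells x K) and factors F (peaks x K), maximizing

    sum_ij [ x_ij log (L F')_ij - (L F')_ij ]   (constants dropped).

Fitting uses multiplicative EM updates for a main phase followed by cyclic
coordinate-descent (single-column Newton) refinement, mirroring the
main/refine schedule of incremental topic-model fitting: models with more
topics are obtained by appending uniform columns (1/K for loadings,
1/n_peaks for factors) to a smaller fit and refitting, which keeps topic
identities stable across the K ladder. The Poisson fit converts to a
multinomial topic model (per-cell topic proportions Q, per-topic peak
probabilities Phi) for downstream trajectory and peak-score analyses.
Peak-level scores propagate to gene level by summing scores of peaks in the
gene body plus distance-decayed scores of peaks upstream of the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import spearmanr

__all__ = [
    "PoissonNmfFit",
    "TopicModel",
    "GeneScoreTable",
    "downsample_for_fit",
    "fit_poisson_nmf",
    "expand_and_refit",
    "project_loadings",
    "to_multinomial",
    "select_top_peaks",
    "gene_scores",
    "flag_technical_topics",
]

_EPS = 1e-15


@dataclass
class PoissonNmfFit:
    L: np.ndarray
    F: np.ndarray
    objective_trace: np.ndarray
    K: int


@dataclass
class TopicModel:
    Q: np.ndarray  # cells x K, rows sum to 1
    Phi: np.ndarray  # peaks x K, columns sum to 1
    K: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.Q.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("Q rows must sum to 1")
        if np.any(np.abs(self.Phi.sum(axis=0) - 1.0) > 1e-8):
            raise ValueError("Phi columns must sum to 1")


@dataclass
class GeneScoreTable:
    scores: pd.DataFrame  # gene x topic
    zscores: pd.DataFrame  # standardized across topics per gene


def _check_counts(X) -> sparse.csr_matrix:
    X = sparse.csr_matrix(X)
    if X.data.size and (np.any(X.data < 0) or np.any(X.data != np.floor(X.data))):
        raise ValueError("counts must be nonnegative integers")
    return X.astype(float)


def downsample_for_fit(
    counts, n_cells: int, seed: int = 0
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Random cell subset for model fitting, rescuing all-zero peaks.

    Peaks with zero counts among the sampled cells get one extra cell in
    which they are nonzero appended (so the fitted factors cover every peak
    and the model can be projected back to the full matrix). A peak with no
    nonzero cell anywhere is an error.
    """
    X = _check_counts(counts)
    n_total, n_peaks = X.shape
    if n_cells > n_total:
        raise ValueError("n_cells exceeds the number of cells")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(n_total, size=n_cells, replace=False))
    in_set = np.zeros(n_total, dtype=bool)
    in_set[chosen] = True
    Xc = sparse.csc_matrix(X)
    covered = np.asarray(X[chosen].sum(axis=0)).ravel() > 0
    for j in np.flatnonzero(~covered):
        cells_j = Xc.indices[Xc.indptr[j] : Xc.indptr[j + 1]]
        if cells_j.size == 0:
            raise ValueError(f"peak {j} has zero counts in all cells")
        if np.any(in_set[cells_j]):
            continue  # rescued already by a previous append
        rescue = int(cells_j[0])
        chosen.append(rescue)
        in_set[rescue] = True
    idx = np.asarray(chosen)
    return X[idx], idx


def _objective(x, e, Lsum, Fsum) -> float:
    return float(np.sum(x * np.log(np.maximum(e, _EPS))) - Lsum @ Fsum)


def _em_iteration(X, R, rows, L, F):
    """One full multiplicative EM iteration (L update, then F update)."""
    R.data = X.data / np.maximum(_nz_mu(X, rows, L, F), _EPS)
    L = L * np.maximum(R @ F, 0.0) / np.maximum(F.sum(axis=0), _EPS)
    L = np.maximum(L, _EPS)
    R.data = X.data / np.maximum(_nz_mu(X, rows, L, F), _EPS)
    F = F * np.maximum(R.T @ L, 0.0) / np.maximum(L.sum(axis=0), _EPS)
    F = np.maximum(F, _EPS)
    return L, F


def _nz_mu(X, rows, L, F):
    return np.einsum("ij,ij->i", L[rows], F[X.indices])


def _row_indices(X) -> np.ndarray:
    return np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))


def _cd_sweep(x, rows, cols, e, L, F, n_cells, n_peaks):
    """One cyclic coordinate-descent sweep (Newton per topic column).

    Updates L and F in place; maintains e = mu at the nonzero entries.
    """
    K = L.shape[1]
    Fsum = F.sum(axis=0)
    for k in range(K):
        w = F[cols, k]
        ratio = x * w / np.maximum(e, _EPS)
        grad = np.bincount(rows, weights=ratio, minlength=n_cells) - Fsum[k]
        hess = -np.bincount(
            rows, weights=ratio * w / np.maximum(e, _EPS), minlength=n_cells
        )
        old = L[:, k].copy()
        new = np.where(hess < -1e-300, old - grad / hess, np.where(grad < 0, _EPS, old))
        new = np.maximum(new, _EPS)
        L[:, k] = new
        e += (new - old)[rows] * w
    Lsum = L.sum(axis=0)
    for k in range(K):
        w = L[rows, k]
        ratio = x * w / np.maximum(e, _EPS)
        grad = np.bincount(cols, weights=ratio, minlength=n_peaks) - Lsum[k]
        hess = -np.bincount(
            cols, weights=ratio * w / np.maximum(e, _EPS), minlength=n_peaks
        )
        old = F[:, k].copy()
        new = np.where(hess < -1e-300, old - grad / hess, np.where(grad < 0, _EPS, old))
        new = np.maximum(new, _EPS)
        F[:, k] = new
        e += (new - old)[cols] * w


def _run_schedule(X, L, F, n_main, n_refine, tol=1e-10, trace=None):
    """EM main phase followed by coordinate-descent refinement."""
    rows = _row_indices(X)
    cols = X.indices
    x = X.data
    R = sparse.csr_matrix((np.ones_like(x), cols, X.indptr), shape=X.shape)
    trace = [] if trace is None else trace
    prev = -np.inf
    for _ in range(n_main):
        L, F = _em_iteration(X, R, rows, L, F)
        obj = _objective(x, _nz_mu(X, rows, L, F), L.sum(axis=0), F.sum(axis=0))
        trace.append(obj)
        if np.isfinite(prev) and abs(obj - prev) < tol * max(1.0, abs(obj)):
            break
        prev = obj
    e = _nz_mu(X, rows, L, F)
    obj = _objective(x, e, L.sum(axis=0), F.sum(axis=0))
    for _ in range(n_refine):
        L_old, F_old, e_old = L.copy(), F.copy(), e.copy()
        _cd_sweep(x, rows, cols, e, L, F, X.shape[0], X.shape[1])
        new_obj = _objective(x, e, L.sum(axis=0), F.sum(axis=0))
        if new_obj < obj - 1e-9 * max(1.0, abs(obj)):
            # Newton sweep overshot: revert and take a safe EM step instead
            L, F, e = L_old, F_old, e_old
            L, F = _em_iteration(X, R, rows, L, F)
            e = _nz_mu(X, rows, L, F)
            new_obj = _objective(x, e, L.sum(axis=0), F.sum(axis=0))
        trace.append(new_obj)
        if abs(new_obj - obj) < tol * max(1.0, abs(new_obj)):
            obj = new_obj
            break
        obj = new_obj
    return L, F, trace


def fit_poisson_nmf(
    counts,
    K: int,
    n_main: int = 100,
    n_refine: int = 200,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> PoissonNmfFit:
    """Fit a K-topic Poisson NMF with the main/refine schedule."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X = _check_counts(counts)
    n_cells, n_peaks = X.shape
    if init is None:
        rng = np.random.default_rng(seed)
        L = rng.uniform(0.5, 1.5, size=(n_cells, K))
        F = rng.uniform(0.5, 1.5, size=(n_peaks, K))
        scale = X.sum() / float(L.sum(axis=0) @ F.sum(axis=0))
        F *= scale
    else:
        L, F = (np.array(init[0], float), np.array(init[1], float))
    L, F, trace = _run_schedule(X, L, F, n_main, n_refine)
    return PoissonNmfFit(L=L, F=F, objective_trace=np.asarray(trace), K=K)


def expand_and_refit(
    fit: PoissonNmfFit,
    K_new: int,
    counts,
    n_main: int = 100,
    n_refine: int = 200,
    n_refine_runs: int = 2,
) -> PoissonNmfFit:
    """Grow a fit to K_new topics, keeping existing topic columns in place.

    New loading columns start at 1/K_new and new factor columns at
    1/n_peaks; the expanded model is refit with ``n_main`` EM iterations
    followed by ``n_refine_runs`` consecutive runs of ``n_refine``
    coordinate-descent sweeps. Topic i of the old fit stays topic i.
    """
    if K_new <= fit.K:
        raise ValueError(f"K_new ({K_new}) must exceed current K ({fit.K})")
    X = _check_counts(counts)
    n_cells, n_peaks = X.shape
    add = K_new - fit.K
    L = np.hstack([fit.L, np.full((n_cells, add), 1.0 / K_new)])
    F = np.hstack([fit.F, np.full((n_peaks, add), 1.0 / n_peaks)])
    trace: list[float] = []
    L, F, trace = _run_schedule(X, L, F, n_main, n_refine, trace=trace)
    for _ in range(n_refine_runs - 1):
        L, F, trace = _run_schedule(X, L, F, 0, n_refine, trace=trace)
    return PoissonNmfFit(L=L, F=F, objective_trace=np.asarray(trace), K=K_new)


def project_loadings(
    F: np.ndarray, counts_new, max_iter: int = 500, tol: float = 1e-12
) -> np.ndarray:
    """Multinomial topic proportions for new cells with factors held fixed.

    Each cell's Poisson loadings solve an independent convex maximum-
    likelihood problem (EM on L only); the result is converted to topic
    proportions (rows sum to 1). All-zero cells get uniform 1/K proportions
    with a warning.
    """
    X = _check_counts(counts_new)
    n_cells = X.shape[0]
    K = F.shape[1]
    if np.any(F < 0):
        raise ValueError("F must be nonnegative")
    Fsum = np.maximum(F.sum(axis=0), _EPS)
    L = np.full((n_cells, K), 1.0, dtype=float)
    R = sparse.csr_matrix(
        (np.ones_like(X.data), X.indices, X.indptr), shape=X.shape
    )
    rows = _row_indices(X)
    prev = None
    for _ in range(max_iter):
        mu = _nz_mu(X, rows, L, F)
        R.data = X.data / np.maximum(mu, _EPS)
        L_new = L * np.maximum(R @ F, 0.0) / Fsum
        if prev is not None and np.max(np.abs(L_new - L)) < tol * (1.0 + L.max()):
            L = L_new
            break
        prev = L
        L = np.maximum(L_new, 0.0)
    scaled = L * Fsum
    totals = scaled.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero cell(s); assigning uniform loadings",
            UserWarning,
            stacklevel=2,
        )
        scaled[zero] = 1.0
        totals[zero] = K
    return scaled / totals[:, None]


def to_multinomial(fit: PoissonNmfFit) -> TopicModel:
    """Convert a Poisson NMF fit to the multinomial topic model.

    u_k = sum_j F_jk; Phi = F / u; Q_ik proportional to L_ik u_k.
    """
    u = fit.F.sum(axis=0)
    if np.any(u <= 0):
        raise ValueError("a topic has zero total factor mass")
    Phi = fit.F / u
    scaled = fit.L * u
    totals = scaled.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("a cell has zero total loading mass")
    Q = scaled / totals[:, None]
    return TopicModel(Q=Q, Phi=Phi, K=fit.K)


def select_top_peaks(
    Phi: np.ndarray, topic: int, frac: float = 0.10
) -> np.ndarray:
    """Indices of the ceil(frac * n_peaks) highest-scoring peaks of a topic.

    Ties at the selection boundary break toward the lower genomic order
    (row index); the returned set size is invariant to ties.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    scores = np.asarray(Phi)[:, topic]
    n = scores.size
    n_top = int(np.ceil(frac * n))
    order = np.lexsort((np.arange(n), -scores))
    return np.sort(order[:n_top])


def gene_scores(
    peak_scores: np.ndarray,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_bp: int = 5_000,
    decay_bp: int = 5_000,
    kernel: str = "exp",
) -> GeneScoreTable:
    """Propagate per-peak scores to genes.

    Scores of peaks overlapping the gene body are summed directly; a peak
    whose center lies within ``upstream_bp`` upstream of the TSS
    (strand-aware) contributes its score weighted by w(d) = exp(-d /
    decay_bp) (or the power-law kernel (1 + d / decay_bp)^-1), with d the
    center-to-TSS distance. Genes with no contributing peak score 0.
    Z-scores standardize each gene's scores across topics (sample SD).
    """
    if kernel not in {"exp", "power"}:
        raise ValueError("kernel must be 'exp' or 'power'")
    S = np.atleast_2d(np.asarray(peak_scores, float).T).T  # peaks x K
    n_topics = S.shape[1]
    centers = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    p_chrom = peaks["chrom"].to_numpy()
    p_start = peaks["start"].to_numpy()
    p_end = peaks["end"].to_numpy()
    out = np.zeros((len(genes), n_topics))
    for gi, gene in genes.reset_index(drop=True).iterrows():
        on_chrom = p_chrom == gene["chrom"]
        body = on_chrom & (p_start < gene["end"]) & (p_end > gene["start"])
        if gene["strand"] == "-":
            d = centers - gene["tss"]
        else:
            d = gene["tss"] - centers
        upstream = on_chrom & ~body & (d >= 0) & (d <= upstream_bp)
        if kernel == "exp":
            w = np.exp(-d / decay_bp)
        else:
            w = 1.0 / (1.0 + d / decay_bp)
        out[gi] = S[body].sum(axis=0) + (w[upstream, None] * S[upstream]).sum(axis=0)
    scores = pd.DataFrame(
        out,
        index=genes["gene"].to_numpy(),
        columns=[f"k{k + 1}" for k in range(n_topics)],
    )
    mean = out.mean(axis=1, keepdims=True)
    if n_topics > 1:
        sd = out.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (out - mean) / sd, 0.0)
    zscores = pd.DataFrame(z, index=scores.index, columns=scores.columns)
    return GeneScoreTable(scores=scores, zscores=zscores)


def flag_technical_topics(
    Q: np.ndarray, qc: pd.DataFrame, threshold: float = 0.3
) -> pd.DataFrame:
    """Flag topics whose loadings track QC covariates.

    A topic is technical if |Spearman rho| with any QC covariate exceeds
    the threshold. Returns a topic x covariate correlation table with a
    ``technical`` column.
    """
    K = Q.shape[1]
    rows = []
    for k in range(K):
        rhos = {c: float(spearmanr(Q[:, k], qc[c]).statistic) for c in qc.columns}
        rows.append({"topic": k, **rhos})
    table = pd.DataFrame(rows).set_index("topic")
    table["technical"] = (table.abs() > threshold).any(axis=1)
    return table
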