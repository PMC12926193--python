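"""Post-mapping integration: GWAS loci, ABF colocalization, sharing, enrichment.

Colocalization follows the single-causal-variant approximate-Bayes-factor
framework: per SNP j and trait, the Wakefield log-ABF is

    labf_j = 1/2 [ log(1 - r) + r z_j^2 ],   r = W / (W + se_j^2)

with prior effect variance W (0.15^2 for quantitative traits, 0.2^2 for
case-control). The five hypothesis sums (H0 no association; H1/H2 one
trait only; H3 two distinct causal SNPs; H4 one shared causal SNP) are
accumulated in log space with priors p1, p2, p12 and normalized into
posterior probabilities PP0..PP4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import logsumexp

from .qvalue import storey_pi1

__all__ = [
    "SummaryStats",
    "ColocResult",
    "GwasLocus",
    "define_gwas_loci",
    "coloc_eligible",
    "wakefield_labf",
    "coloc_abf",
    "sharing_contexts",
    "secondary_sharing_threshold",
    "pairwise_pi1",
    "coaccessible_peaks",
    "distal_coacc_test",
    "fisher_enrichment",
    "categorize_coloc_contexts",
]

W_QUANT = 0.15**2
W_CC = 0.20**2


@dataclass
class SummaryStats:
    """Per-SNP association summary statistics for one trait."""

    table: pd.DataFrame  # snp, chrom, pos, beta, se, p, maf, n
    trait: str = "trait"
    trait_type: str = "quantitative"  # or "case-control"

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp", "beta", "se", "p"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"summary statistics lack columns {sorted(missing)}")
        if np.any(t["se"].to_numpy(float) <= 0):
            raise ValueError("standard errors must be positive")
        z = np.abs(t["beta"].to_numpy(float) / t["se"].to_numpy(float))
        p_implied = 2.0 * stats.norm.sf(z)
        p = t["p"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(p - p_implied) / np.maximum(p_implied, 1e-300)
        if np.nanmedian(rel[p_implied > 1e-10]) > 0.10:
            warnings.warn(
                f"trait {self.trait!r}: p-values deviate from the normal "
                "approximation implied by beta/se by >10%",
                UserWarning,
                stacklevel=2,
            )

    @property
    def prior_w(self) -> float:
        return W_CC if self.trait_type == "case-control" else W_QUANT


@dataclass
class GwasLocus:
    lead_snp: str
    lead_pos: int
    chrom: str
    lead_p: float
    window: tuple[int, int]
    members: list[str] = field(default_factory=list)


@dataclass
class ColocResult:
    n_overlap_snps: int
    pp: np.ndarray  # PP0..PP4
    priors: tuple[float, float, float]
    eligible: bool

    def __post_init__(self) -> None:
        if self.pp.size != 5 or np.any(self.pp < 0):
            raise ValueError("pp must be a nonnegative 5-vector")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")


def define_gwas_loci(
    ss: pd.DataFrame,
    p_thresh: float = 1e-7,
    window_bp: int = 1_000_000,
    removal_bp: int | None = None,
) -> list[GwasLocus]:
    """Greedy GWAS locus definition.

    Starting from the smallest-p SNP below ``p_thresh``, a locus window of
    ``window_bp`` is centered on the lead, all SNPs within ``removal_bp``
    (default: ``window_bp``) of the lead on its chromosome are removed, and
    the procedure repeats until no qualifying SNP remains.
    """
    removal_bp = window_bp if removal_bp is None else removal_bp
    t = ss[["snp", "chrom", "pos", "p"]].copy()
    loci: list[GwasLocus] = []
    while True:
        cand = t[t["p"] < p_thresh]
        if cand.empty:
            break
        lead = cand.loc[cand["p"].idxmin()]
        half = window_bp // 2
        in_window = (
            (t["chrom"] == lead["chrom"])
            & (t["pos"] >= lead["pos"] - half)
            & (t["pos"] <= lead["pos"] + half)
        )
        loci.append(
            GwasLocus(
                lead_snp=str(lead["snp"]),
                lead_pos=int(lead["pos"]),
                chrom=str(lead["chrom"]),
                lead_p=float(lead["p"]),
                window=(int(lead["pos"]) - half, int(lead["pos"]) + half),
                members=list(t.loc[in_window, "snp"]),
            )
        )
        remove = (
            (t["chrom"] == lead["chrom"])
            & (t["pos"] >= lead["pos"] - removal_bp)
            & (t["pos"] <= lead["pos"] + removal_bp)
        )
        t = t[~remove]
    return loci


def coloc_eligible(
    ss1: pd.DataFrame, ss2: pd.DataFrame, min_overlap: int = 150
) -> tuple[bool, pd.Index]:
    """Eligibility: > min_overlap shared SNPs and both leads in the overlap."""
    overlap = pd.Index(ss1["snp"]).intersection(pd.Index(ss2["snp"]))
    lead1 = ss1.loc[ss1["p"].idxmin(), "snp"]
    lead2 = ss2.loc[ss2["p"].idxmin(), "snp"]
    ok = (len(overlap) > min_overlap) and (lead1 in overlap) and (lead2 in overlap)
    return bool(ok), overlap


def wakefield_labf(
    beta: np.ndarray, se: np.ndarray, W: float = W_QUANT
) -> np.ndarray:
    """Wakefield log approximate Bayes factor per SNP."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if W < 0:
        raise ValueError("W must be >= 0")
    V = se**2
    r = W / (W + V)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_abf(
    ss1,
    ss2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    require_eligible: bool = True,
) -> ColocResult:
    """Single-causal-variant ABF colocalization of two traits over one region.

    Accepts :class:`SummaryStats` or plain tables. All hypothesis sums are
    accumulated in log space; a (numerically) negative H3 mass after the
    distinct-pair subtraction is clipped with a warning.
    """
    t1, w1 = _as_table(ss1)
    t2, w2 = _as_table(ss2)
    eligible, overlap = coloc_eligible(t1, t2)
    if require_eligible and not eligible:
        raise ValueError(
            "trait pair fails eligibility (>150 shared SNPs incl. both leads); "
            "pass require_eligible=False to override"
        )
    m1 = t1.set_index("snp").loc[overlap]
    m2 = t2.set_index("snp").loc[overlap]
    l1 = wakefield_labf(m1["beta"].to_numpy(), m1["se"].to_numpy(), w1)
    l2 = wakefield_labf(m2["beta"].to_numpy(), m2["se"].to_numpy(), w2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    # sum over ordered distinct pairs: sum_i sum_j BF1_i BF2_j - sum_j BF1_j BF2_j
    both = lsum1 + lsum2
    if both <= lsum12 + 1e-12:
        warnings.warn(
            "H3 mass numerically non-positive after distinct-pair subtraction; "
            "clipping",
            UserWarning,
            stacklevel=2,
        )
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(lsum12 - both))
    lh4 = np.log(p12) + lsum12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(
        n_overlap_snps=len(overlap), pp=pp, priors=(p1, p2, p12), eligible=eligible
    )


def _as_table(ss) -> tuple[pd.DataFrame, float]:
    if isinstance(ss, SummaryStats):
        return ss.table, ss.prior_w
    return ss, W_QUANT


def secondary_sharing_threshold(primary: float = 0.10, n_cell_types: int = 5) -> float:
    """Bonferroni-adjusted q threshold for calling a caQTL shared.

    Significance in the focal type uses ``primary``; sharing with another
    type requires q below primary / (n_cell_types - 1).
    """
    if n_cell_types < 2:
        raise ValueError("need at least two cell types")
    return primary / (n_cell_types - 1)


def sharing_contexts(
    q_matrix: pd.DataFrame,
    primary: float = 0.10,
    secondary: float = 0.025,
) -> pd.DataFrame:
    """Cross-cell-type sharing from a peak x cell-type q-value matrix.

    A peak significant in a focal type (q < primary) is shared with another
    type iff that type's q < secondary; context count = 1 + number of other
    types passing secondary; "specific" iff the count is 1. Returns one row
    per (peak, focal type) with q < primary.
    """
    q = q_matrix.to_numpy(float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q-values must lie in [0, 1]")
    rows = []
    types = list(q_matrix.columns)
    for i, peak in enumerate(q_matrix.index):
        for j, focal in enumerate(types):
            if q[i, j] >= primary:
                continue
            others = [t for k, t in enumerate(types) if k != j and q[i, k] < secondary]
            rows.append(
                {
                    "peak": peak,
                    "cell_type": focal,
                    "q": q[i, j],
                    "context_count": 1 + len(others),
                    "specific": len(others) == 0,
                    "shared_with": ",".join(others),
                }
            )
    return pd.DataFrame(rows)


def pairwise_pi1(lead_p_in_other: np.ndarray) -> float:
    """pi1 sharing estimate: Storey pi1 of cell-type-B p-values at
    peaks significant in cell type A."""
    return storey_pi1(np.asarray(lead_p_in_other, float))


def coaccessible_peaks(
    counts: sparse.spmatrix,
    reference_peak: int,
    peak_positions: np.ndarray,
    window_bp: int = 125_000,
    r_min: float = 0.5,
    control_band: tuple[float, float] = (0.05, 0.10),
    n_aggregates: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Co-accessible (and control) peaks for a reference peak.

    Cells are partitioned into ``n_aggregates`` random pseudo-replicates;
    per-aggregate mean accessibility is correlated (Pearson) between the
    reference peak and every candidate whose center lies within
    ``window_bp``. Candidates with r > r_min are co-accessible; controls are
    drawn distance-matched from the band control_band of correlations.
    """
    counts = sparse.csc_matrix(counts, dtype=float)
    n_cells, n_peaks = counts.shape
    if n_cells < n_aggregates:
        raise ValueError("need at least n_aggregates cells")
    rng = np.random.default_rng(seed)
    assign = rng.permutation(n_cells) % n_aggregates
    ind = sparse.csr_matrix(
        (np.ones(n_cells), (assign, np.arange(n_cells))), shape=(n_aggregates, n_cells)
    )
    group_sizes = np.bincount(assign, minlength=n_aggregates)[:, None]
    agg = np.asarray((ind @ counts).todense()) / group_sizes

    pos = np.asarray(peak_positions)
    ref_pos = pos[reference_peak]
    cand = np.flatnonzero(
        (np.abs(pos - ref_pos) <= window_bp) & (np.arange(n_peaks) != reference_peak)
    )
    if cand.size == 0:
        empty = np.array([], dtype=int)
        return empty, empty, pd.DataFrame(columns=["peak", "r", "distance"])
    ref = agg[:, reference_peak]
    rc = ref - ref.mean()
    denom_ref = np.sqrt((rc**2).sum())
    x = agg[:, cand] - agg[:, cand].mean(axis=0, keepdims=True)
    denom = np.sqrt((x**2).sum(axis=0)) * denom_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rc @ x / np.maximum(denom, 1e-300), 0.0)
    dist = np.abs(pos[cand] - ref_pos)
    table = pd.DataFrame({"peak": cand, "r": r, "distance": dist})

    coacc = cand[r > r_min]
    in_band = (r > control_band[0]) & (r < control_band[1])
    band_peaks = cand[in_band]
    band_dist = dist[in_band]
    controls = []
    used = np.zeros(band_peaks.size, dtype=bool)
    for d in np.sort(dist[r > r_min]):
        if band_peaks.size == 0:
            break
        dd = np.abs(band_dist - d).astype(float)
        dd[used] = np.inf
        j = int(np.argmin(dd))
        if np.isinf(dd[j]):
            break
        used[j] = True
        controls.append(band_peaks[j])
    return coacc, np.asarray(controls, dtype=int), table


def distal_coacc_test(
    counts: sparse.spmatrix,
    lead_g: np.ndarray,
    coacc_peaks: np.ndarray,
    design,
    fdr: float = 0.10,
    method: str = "pql",
) -> pd.DataFrame:
    """Test a reference peak's lead SNP against each co-accessible peak.

    ``lead_g`` is the per-cell dosage of the reference lead SNP. Storey
    q-values are computed across all tested pairs; significant at q < fdr.
    """
    from .caqtl import fit_scpme
    from .qvalue import storey_qvalue

    counts = sparse.csc_matrix(counts)
    rows = []
    for c in np.asarray(coacc_peaks, int):
        y = np.asarray(counts[:, c].todense()).ravel()
        fit = fit_scpme(y, design, lead_g, method=method)
        rows.append(
            {
                "peak_index": c,
                "beta": fit.beta,
                "se": fit.se,
                "p": fit.p_wald,
                "converged": fit.converged,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, q_ok = storey_qvalue(out.loc[ok, "p"].to_numpy())
        q[np.flatnonzero(ok)] = q_ok
        out["q"] = q
        out["significant"] = out["q"] < fdr
    return out


def fisher_enrichment(
    hits_in: int, set_size: int, hits_out: int, bg_size: int
) -> dict:
    """Two-sided Fisher exact test on [[hits_in, miss_in], [hits_out, miss_out]].

    Returns the conditional-MLE odds ratio, p-value, 95% CI and log2(OR).
    """
    miss_in = set_size - hits_in
    miss_out = bg_size - hits_out
    if min(hits_in, miss_in, hits_out, miss_out) < 0:
        raise ValueError("negative contingency cell; check counts")
    table = np.array([[hits_in, miss_in], [hits_out, miss_out]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    orr = float(res.statistic)
    return {
        "odds_ratio": orr,
        "log2_or": float(np.log2(orr)) if orr > 0 else -np.inf,
        "p": float(p),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
    }


def categorize_coloc_contexts(
    results: pd.DataFrame,
    context_map: pd.DataFrame | None = None,
    pp4_threshold: float = 0.75,
) -> pd.DataFrame:
    """Categorize loci by caQTL/eQTL colocalization context overlap.

    ``results`` rows: locus, modality ("caQTL"/"eQTL"), context, pp4.
    ``context_map`` (optional) maps eQTL-panel contexts onto caQTL contexts
    (columns: from, to). Categories: caQTL-only, eQTL-only,
    both-same-context, both-different-context.
    """
    t = results.copy()
    if context_map is not None:
        m = dict(zip(context_map["from"], context_map["to"]))
        t["context"] = [m.get(c, c) for c in t["context"]]
    rows = []
    for locus, grp in t.groupby("locus"):
        hit = grp[grp["pp4"] >= pp4_threshold]
        ca = set(hit.loc[hit["modality"] == "caQTL", "context"])
        eq = set(hit.loc[hit["modality"] == "eQTL", "context"])
        if not ca and not eq:
            category = "uncolocalized"
        elif ca and not eq:
            category = "caQTL-only"
        elif eq and not ca:
            category = "eQTL-only"
        elif ca & eq:
            category = "both-same-context"
        else:
            category = "both-different-context"
        rows.append(
            {
                "locus": locus,
                "category": category,
                "n_caqtl_contexts": len(ca),
                "n_eqtl_contexts": len(eq),
            }
        )
    return pd.DataFrame(rows)
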