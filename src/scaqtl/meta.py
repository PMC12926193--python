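"""Cross-study meta-analysis of per-SNP caQTL effects.

Combines per-study effect sizes and standard errors with inverse-variance
fixed effects (FE) and the Han-Eskin RE2 random-effects model. RE2 jointly
tests the mean effect mu and between-study heterogeneity tau^2: the profile
log-likelihood

    l(mu, tau^2) = sum_s [ -1/2 log(2 pi (se_s^2 + tau^2))
                           - (beta_s - mu)^2 / (2 (se_s^2 + tau^2)) ]

is maximized over mu in R, tau^2 >= 0, and S_RE2 = 2 (l_max - l(0, 0)) is
referred to the asymptotic mixture 1/2 chi2_1 + 1/2 chi2_2. The asymptotic
p-value is anti-conservative for very small study counts (the original tool
tabulates small-sample nulls); calibration-style tests in this package rely
on simulation, not on exact small-sample p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaRecord", "harmonize_effects", "fe_meta", "re2_meta"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MetaRecord:
    beta_fe: float
    se_fe: float
    z_fe: float
    p_fe: float
    tau2_hat: float
    mu_hat: float
    S_re2: float
    p_re2: float
    n_studies: int


def harmonize_effects(
    records: list[pd.DataFrame], reference: int = 0
) -> tuple[list[pd.DataFrame], dict]:
    """Align effect alleles across per-study tables (snp, ea, oa, beta, se).

    Effects are sign-flipped where a study's effect allele is the reference
    study's other allele; strand-ambiguous (A/T, C/G) mismatches and
    irreconcilable allele pairs are dropped. Returns the aligned tables
    restricted to shared SNPs plus a log of dropped counts.
    """
    ref = records[reference].set_index("snp")
    shared = ref.index
    for r in records:
        shared = shared.intersection(pd.Index(r["snp"]))
    dropped_ambiguous: set[str] = set()
    dropped_mismatch: set[str] = set()
    aligned = []
    for r in records:
        t = r.set_index("snp").loc[shared].copy()
        same = (t["ea"] == ref.loc[shared, "ea"]) & (t["oa"] == ref.loc[shared, "oa"])
        swapped = (t["ea"] == ref.loc[shared, "oa"]) & (t["oa"] == ref.loc[shared, "ea"])
        ambiguous = [
            s
            for s in shared
            if (str(t.loc[s, "ea"]), str(t.loc[s, "oa"])) in _AMBIGUOUS
            and not same.loc[s]
        ]
        t.loc[swapped, "beta"] = -t.loc[swapped, "beta"]
        ea = t.loc[swapped, "ea"].copy()
        t.loc[swapped, "ea"] = t.loc[swapped, "oa"]
        t.loc[swapped, "oa"] = ea
        bad = shared[~(same | swapped)]
        dropped_mismatch.update(bad)
        dropped_ambiguous.update(ambiguous)
        aligned.append(t)
    drop = dropped_mismatch | dropped_ambiguous
    keep = [s for s in shared if s not in drop]
    aligned = [t.loc[keep].reset_index() for t in aligned]
    log = {
        "n_shared": len(shared),
        "n_dropped_mismatch": len(dropped_mismatch),
        "n_dropped_ambiguous": len(dropped_ambiguous),
        "n_kept": len(keep),
    }
    return aligned, log


def fe_meta(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Inverse-variance fixed-effects combination -> (beta, se, p)."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if b.size < 1:
        raise ValueError("need at least one study")
    if np.any(s <= 0) or not np.all(np.isfinite(b)) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def _re2_loglik(b, v, mu, tau2):
    tot = v + tau2
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * tot) - (b - mu) ** 2 / (2.0 * tot)))


def _profile_mu(b, v, tau2):
    w = 1.0 / (v + tau2)
    return float((w * b).sum() / w.sum())


def re2_meta(betas: np.ndarray, ses: np.ndarray, n_grid: int = 50) -> MetaRecord:
    """Han-Eskin RE2 meta-analysis of one SNP across >= 2 studies.

    tau^2 is maximized over a log-spaced profile grid spanning
    [1e-8, 100 * max(se^2)] followed by 1-D Newton refinement; the null is
    (mu=0, tau^2=0) and p = 1/2 P(chi2_1 > S) + 1/2 P(chi2_2 > S).
    """
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if b.size < 2:
        raise ValueError("RE2 needs at least two studies")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(s)) and np.all(s > 0)):
        raise ValueError("effects and standard errors must be finite, se > 0")
    v = s**2

    beta_fe, se_fe, p_fe = fe_meta(b, s)
    z_fe = beta_fe / se_fe

    grid = np.concatenate([[0.0], np.geomspace(1e-8, 100.0 * v.max(), n_grid)])
    lls = np.array([_re2_loglik(b, v, _profile_mu(b, v, t2), t2) for t2 in grid])
    i = int(np.argmax(lls))
    tau2 = float(grid[i])

    # Newton refinement on tau^2 (profile over mu each step)
    for _ in range(25):
        mu = _profile_mu(b, v, tau2)
        tot = v + tau2
        g = float(np.sum(((b - mu) ** 2 - tot) / (2.0 * tot**2)))
        h = float(np.sum((tot - 2.0 * (b - mu) ** 2) / (2.0 * tot**3)))
        if abs(h) < 1e-300:
            break
        step = -g / h if h < 0 else np.sign(g) * 0.1 * max(tau2, v.min())
        new = max(0.0, tau2 + step)
        if _re2_loglik(b, v, _profile_mu(b, v, new), new) < _re2_loglik(b, v, mu, tau2):
            # fall back to halved steps; stop when no improvement
            improved = False
            for _ in range(20):
                step *= 0.5
                cand = max(0.0, tau2 + step)
                if _re2_loglik(b, v, _profile_mu(b, v, cand), cand) > _re2_loglik(
                    b, v, mu, tau2
                ):
                    new, improved = cand, True
                    break
            if not improved:
                break
        if abs(new - tau2) < 1e-12 * (1.0 + tau2):
            tau2 = new
            break
        tau2 = new

    mu = _profile_mu(b, v, tau2)
    l_max = _re2_loglik(b, v, mu, tau2)
    l_null = _re2_loglik(b, v, 0.0, 0.0)
    S = max(0.0, 2.0 * (l_max - l_null))
    p = float(0.5 * stats.chi2.sf(S, 1) + 0.5 * stats.chi2.sf(S, 2))
    return MetaRecord(
        beta_fe=beta_fe,
        se_fe=se_fe,
        z_fe=z_fe,
        p_fe=p_fe,
        tau2_hat=tau2,
        mu_hat=mu,
        S_re2=S,
        p_re2=p,
        n_studies=int(b.size),
    )
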