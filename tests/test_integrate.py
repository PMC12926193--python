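import numpy as np
import pandas as pd
import pytest
from scipy import integrate as sint
from scipy import sparse, stats

from scaqtl.integrate import (
    coaccessible_peaks,
    coloc_abf,
    coloc_eligible,
    categorize_coloc_contexts,
    define_gwas_loci,
    distal_coacc_test,
    fisher_enrichment,
    pairwise_pi1,
    secondary_sharing_threshold,
    sharing_contexts,
    wakefield_labf,
)


def ss_from_z(z, se=0.05, pos_step=1_000, ids=None):
    z = np.asarray(z, float)
    n = z.size
    return pd.DataFrame({
        "snp": ids if ids is not None else [f"s{i}" for i in range(n)],
        "chrom": "chr1",
        "pos": 1_000_000 + pos_step * np.arange(n),
        "beta": z * se,
        "se": se,
        "p": 2 * stats.norm.sf(np.abs(z)),
    })


def coloc_enumeration_oracle(b1, se1, b2, se2, p1=1e-4, p2=1e-4, p12=1e-5,
                             W=0.15**2):
    """Direct linear-space enumeration of the five hypothesis sums."""
    def bf(b, s):
        V = np.asarray(s, float) ** 2
        r = W / (W + V)
        return np.sqrt(1 - r) * np.exp(r * (np.asarray(b) / np.asarray(s)) ** 2 / 2)

    bf1, bf2 = bf(b1, se1), bf(b2, se2)
    h0 = 1.0
    h1 = p1 * bf1.sum()
    h2 = p2 * bf2.sum()
    h3 = p1 * p2 * (bf1.sum() * bf2.sum() - (bf1 * bf2).sum())
    h4 = p12 * (bf1 * bf2).sum()
    tot = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / tot


class TestLoci:
    def test_single_significant_snp(self):
        ss = ss_from_z([1.0, 6.0, 0.5])
        loci = define_gwas_loci(ss)
        assert len(loci) == 1
        assert loci[0].lead_snp == "s1"

    def test_nearby_snps_form_one_locus(self):
        ss = pd.DataFrame({
            "snp": ["a", "b"], "chrom": "chr1", "pos": [1_000_000, 1_400_000],
            "p": [1e-9, 1e-8],
        })
        loci = define_gwas_loci(ss)
        assert len(loci) == 1 and loci[0].lead_snp == "a"

    def test_distant_snps_form_two_loci(self):
        ss = pd.DataFrame({
            "snp": ["a", "b"], "chrom": "chr1", "pos": [1_000_000, 3_000_000],
            "p": [1e-9, 1e-8],
        })
        assert len(define_gwas_loci(ss)) == 2

    def test_no_two_leads_within_removal_radius_and_idempotent(self, rng):
        n = 400
        ss = pd.DataFrame({
            "snp": [f"s{i}" for i in range(n)], "chrom": "chr1",
            "pos": np.sort(rng.integers(0, 50_000_000, n)),
            "p": rng.uniform(1e-12, 1.0, n) ** 3,
        })
        loci = define_gwas_loci(ss)
        pos = np.sort([lc.lead_pos for lc in loci])
        assert np.all(np.diff(pos) > 1_000_000)
        leftovers = ss[~ss["snp"].isin(
            [s for lc in loci for s in
             ss.loc[(ss["chrom"] == lc.chrom)
                    & (np.abs(ss["pos"] - lc.lead_pos) <= 1_000_000), "snp"]]
        )]
        assert len(define_gwas_loci(leftovers)) == 0


class TestEligibility:
    def test_exactly_150_overlap_ineligible(self, rng):
        z = rng.standard_normal(150)
        ok, _ = coloc_eligible(ss_from_z(z), ss_from_z(rng.standard_normal(150)))
        assert not ok

    def test_151_overlap_with_leads_eligible(self, rng):
        z = rng.standard_normal(151)
        ok, _ = coloc_eligible(ss_from_z(z), ss_from_z(rng.standard_normal(151)))
        assert ok

    def test_missing_lead_blocks_eligibility(self, rng):
        z1 = rng.standard_normal(300)
        z1[7] = 9.0
        ss1 = ss_from_z(z1)
        ss2 = ss_from_z(rng.standard_normal(299),
                        ids=[f"s{i}" for i in range(1, 300)])
        ss2b = ss2[ss2["snp"] != "s7"]  # drop trait-1's lead from the overlap
        ok, _ = coloc_eligible(ss1, ss2b)
        assert not ok


class TestWakefield:
    def test_null_z_shrinks(self):
        labf = wakefield_labf(np.array([0.0]), np.array([0.1]))
        assert labf[0] < 0

    def test_against_quadrature_oracle(self):
        beta, se, W = 0.1, 0.02, 0.0225
        labf = wakefield_labf(np.array([beta]), np.array([se]), W=W)[0]
        V = se**2

        def integrand(b):
            return stats.norm.pdf(beta, b, np.sqrt(V)) * stats.norm.pdf(b, 0, np.sqrt(W))

        num, _ = sint.quad(integrand, -1.5, 1.5, limit=400)
        oracle = np.log(num / stats.norm.pdf(beta, 0, np.sqrt(V)))
        assert labf == pytest.approx(oracle, abs=1e-6)

    def test_prior_collapse(self):
        labf = wakefield_labf(np.array([0.3]), np.array([0.1]), W=0.0)
        assert labf[0] == pytest.approx(0.0, abs=1e-12)


class TestColoc:
    def test_flat_traits_favor_h0(self):
        # precise studies (se = 0.005) shrink every per-SNP ABF hard
        z = np.zeros(1_000)
        res = coloc_abf(ss_from_z(z, se=0.005), ss_from_z(z, se=0.005))
        assert res.pp[0] > 0.99

    def test_matches_enumeration_oracle_on_three_snp_toys(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            z1 = r.normal(0, 3, 3)
            z2 = r.normal(0, 3, 3)
            t1, t2 = ss_from_z(z1), ss_from_z(z2)
            res = coloc_abf(t1, t2, require_eligible=False)
            oracle = coloc_enumeration_oracle(
                t1["beta"], t1["se"], t2["beta"], t2["se"]
            )
            assert np.max(np.abs(res.pp - oracle)) < 1e-9

    def test_shared_causal_gives_pp4(self, rng):
        z1 = rng.normal(0, 1, 500)
        z2 = rng.normal(0, 1, 500)
        z1[100] = z2[100] = 8.0
        res = coloc_abf(ss_from_z(z1), ss_from_z(z2))
        assert res.pp[4] > 0.95

    def test_distinct_causals_give_pp3(self, rng):
        z1 = rng.normal(0, 1, 500)
        z2 = rng.normal(0, 1, 500)
        z1[100] = 8.0
        z2[400] = 8.0
        res = coloc_abf(ss_from_z(z1), ss_from_z(z2))
        assert res.pp[3] > res.pp[4]

    def test_invariances(self, rng):
        z1 = rng.normal(0, 2, 300)
        z2 = rng.normal(0, 2, 300)
        t1, t2 = ss_from_z(z1), ss_from_z(z2)
        base = coloc_abf(t1, t2)
        flipped = t1.copy()
        flipped["beta"] = -flipped["beta"]
        assert np.allclose(coloc_abf(flipped, t2).pp, base.pp, atol=1e-12)
        shuffled = t1.sample(frac=1.0, random_state=1)
        assert np.allclose(coloc_abf(shuffled, t2).pp, base.pp, atol=1e-12)
        assert base.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ineligible_pair_raises_unless_overridden(self, rng):
        t1 = ss_from_z(rng.standard_normal(50))
        t2 = ss_from_z(rng.standard_normal(50))
        with pytest.raises(ValueError, match="eligibility"):
            coloc_abf(t1, t2)
        res = coloc_abf(t1, t2, require_eligible=False)
        assert not res.eligible


class TestSharing:
    def test_secondary_threshold_value(self):
        assert secondary_sharing_threshold(0.10, 5) == pytest.approx(0.025)

    def test_specific_peak(self):
        q = pd.DataFrame([[0.05, 0.5, 0.5, 0.5, 0.5]], index=["p1"],
                         columns=list("ABCDE"))
        out = sharing_contexts(q)
        assert len(out) == 1
        assert bool(out["specific"].iloc[0]) and out["context_count"].iloc[0] == 1

    def test_shared_peak_and_boundary(self):
        q = pd.DataFrame([[0.05, 0.024, 0.5, 0.5, 0.5],
                          [0.05, 0.026, 0.5, 0.5, 0.5]],
                         index=["shared", "boundary"], columns=list("ABCDE"))
        out = sharing_contexts(q)
        focal_a = out[out["cell_type"] == "A"].set_index("peak")
        assert focal_a.loc["shared", "context_count"] == 2
        assert focal_a.loc["boundary", "context_count"] == 1

    def test_monotonicity_in_secondary_threshold(self, rng):
        q = pd.DataFrame(rng.uniform(size=(50, 5)), columns=list("ABCDE"))
        loose = sharing_contexts(q, secondary=0.05)
        tight = sharing_contexts(q, secondary=0.01)
        merged = loose.merge(tight, on=["peak", "cell_type"], suffixes=("_l", "_t"))
        assert np.all(merged["context_count_t"] <= merged["context_count_l"])


class TestPi1:
    def test_identical_sets(self, rng):
        p = np.full(200, 1e-6)
        assert pairwise_pi1(p) > 0.9

    def test_independent_null(self, rng):
        assert pairwise_pi1(rng.uniform(size=2_000)) == pytest.approx(0.0, abs=0.05)

    def test_planted_half_sharing(self, rng):
        shared = 2 * stats.norm.sf(np.abs(rng.normal(4, 1, 1_000)))
        null = rng.uniform(size=1_000)
        p = np.concatenate([shared, null])
        assert pairwise_pi1(p) == pytest.approx(0.5, abs=0.1)


class TestCoaccessibility:
    def _counts(self, rng, n_cells=2_000, n_peaks=30, shared_pairs=((0, 3),)):
        lam = rng.uniform(2.0, 5.0, n_peaks)
        latent = rng.gamma(1.0, 1.0, n_cells)  # shared per-cell activity
        mu = np.tile(lam, (n_cells, 1))
        for a, b in shared_pairs:
            mu[:, a] = lam[a] * latent
            mu[:, b] = lam[b] * latent
        return sparse.csr_matrix(rng.poisson(mu))

    def test_duplicate_peak_is_coaccessible(self, rng):
        X = np.asarray(self._counts(rng).todense())
        X[:, 5] = X[:, 0]
        pos = 1_000_000 + 10_000 * np.arange(30)
        coacc, _, table = coaccessible_peaks(sparse.csr_matrix(X), 0, pos, seed=1)
        assert 5 in coacc
        assert table.set_index("peak").loc[5, "r"] > 0.99

    def test_independent_peaks_uncorrelated(self, rng):
        # null r over 100 aggregates has SE ~ 0.1: 95% lie within ~2 SE
        X = self._counts(rng, shared_pairs=())
        pos = 1_000_000 + 10_000 * np.arange(30)
        _, _, table = coaccessible_peaks(X, 0, pos, seed=2)
        assert (np.abs(table["r"]) < 0.2).mean() >= 0.9

    def test_planted_coregulated_pair_recovered(self, rng):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            X = self._counts(r)
            pos = 1_000_000 + 10_000 * np.arange(30)
            coacc, _, _ = coaccessible_peaks(X, 0, pos, seed=s)
            hits += int(3 in coacc)
        assert hits >= 9

    def test_window_limits_candidates(self, rng):
        X = self._counts(rng)
        pos = 1_000_000 + 200_000 * np.arange(30)  # all outside 125 kb
        coacc, controls, table = coaccessible_peaks(X, 0, pos, seed=3)
        assert coacc.size == 0 and controls.size == 0 and table.empty


class TestDistal:
    def test_planted_distal_effect_detected_with_concordant_sign(self):
        from conftest import make_poisson_glmm_data
        from scaqtl.caqtl import make_cell_design
        import pandas as pd

        r = np.random.default_rng(8)
        n_d, m = 40, 60
        donor = np.repeat(np.arange(n_d), m)
        g_d = r.binomial(2, 0.3, n_d).astype(float)
        depth = r.lognormal(5.5, 0.3, donor.size)
        obs = pd.DataFrame({
            "donor": donor, "library": r.integers(0, 4, donor.size),
            "TSSEnrichment": r.normal(8, 2, donor.size),
            "MTratio": r.uniform(0.01, 0.1, donor.size),
            "log10nFrags": np.log10(depth), "depth": depth,
        })
        design = make_cell_design(obs)
        # 1 co-regulated peak (positive effect), 5 null peaks
        etas = [np.log(depth * 5e-3) + 0.6 * g_d[donor]] + [
            np.log(depth * 5e-3) for _ in range(5)
        ]
        counts = sparse.csr_matrix(np.column_stack([r.poisson(np.exp(e)) for e in etas]))
        out = distal_coacc_test(counts, g_d[donor], np.arange(6), design)
        assert bool(out.loc[0, "significant"])
        assert out.loc[0, "beta"] > 0
        assert out.loc[1:, "significant"].sum() <= 1


class TestFisher:
    def test_balanced_table(self):
        res = fisher_enrichment(10, 100, 10, 100)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_against_hypergeometric_enumeration(self):
        """Exact enumeration of the conditional (hypergeometric) null."""
        a, n1, c, n2 = 20, 100, 5, 100
        res = fisher_enrichment(a, n1, c, n2)
        # two-sided p: sum of hypergeometric pmfs <= pmf(observed)
        M, K, N = n1 + n2, a + c, n1
        support = np.arange(max(0, K - (M - N)), min(K, N) + 1)
        pmf = stats.hypergeom.pmf(support, M, K, N)
        p_oracle = pmf[pmf <= pmf[support == a] * (1 + 1e-7)].sum()
        assert res["p"] == pytest.approx(p_oracle, abs=1e-10)
        assert res["ci_low"] < res["odds_ratio"] < res["ci_high"]

    def test_empty_hit_row(self):
        res = fisher_enrichment(0, 50, 10, 100)
        assert res["odds_ratio"] == 0.0
        assert 0 < res["p"] <= 1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_enrichment(10, 5, 0, 10)


class TestCategorize:
    results = pd.DataFrame({
        "locus": ["l1", "l2", "l2", "l3", "l3", "l4"],
        "modality": ["caQTL", "caQTL", "eQTL", "caQTL", "eQTL", "eQTL"],
        "context": ["monocyte", "monocyte", "monocyte", "CD4 T", "monocyte", "B"],
        "pp4": [0.9, 0.9, 0.85, 0.8, 0.95, 0.6],
    })

    def test_categories(self):
        out = categorize_coloc_contexts(self.results).set_index("locus")
        assert out.loc["l1", "category"] == "caQTL-only"
        assert out.loc["l2", "category"] == "both-same-context"
        assert out.loc["l3", "category"] == "both-different-context"
        assert out.loc["l4", "category"] == "uncolocalized"

    def test_context_mapping_applied(self):
        cmap = pd.DataFrame({"from": ["classical monocyte"], "to": ["monocyte"]})
        res = self.results.copy()
        res.loc[res["locus"] == "l3", "context"] = ["CD4 T", "classical monocyte"]
        res.loc[(res["locus"] == "l3") & (res["modality"] == "caQTL"),
                "context"] = "monocyte"
        out = categorize_coloc_contexts(res, context_map=cmap).set_index("locus")
        assert out.loc["l3", "category"] == "both-same-context"
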