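"""Scoring-engine checks against independent oracles.

The clumping oracle is a from-scratch greedy reimplementation on dense
matrices; the LDpred-inf oracle is a dense whole-matrix solve; the
residualization oracle is the normal-equations closed form.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from sklearn.metrics import roc_auc_score

from pgs_spectrum import pgs_engine as eng
from pgs_spectrum.io_formats import GenotypeMatrix, SummaryStats
from pgs_spectrum.synthdata import SimulationConfig, simulate_genotypes

from conftest import small_config


def weights_from(df: pd.DataFrame) -> eng.HarmonizedWeights:
    return eng.HarmonizedWeights(df.reset_index(drop=True))


def make_stats(variants, a1, a2, beta, p=None):
    t = pd.DataFrame({
        "SNP": variants["id"], "A1": a1, "A2": a2, "BETA": beta,
        "SE": 0.05, "P": p if p is not None else 0.5})
    return SummaryStats("t", t)


class TestHarmonize:
    def test_matching_and_swapped_alleles(self, toy_variants):
        v = toy_variants.iloc[:1]          # target A/G
        same = make_stats(v, ["A"], ["G"], [0.2])
        assert eng.harmonize(same, toy_variants).table["beta"].iloc[0] == 0.2
        swapped = make_stats(v, ["G"], ["A"], [0.2])
        assert eng.harmonize(swapped, toy_variants).table["beta"].iloc[0] == -0.2

    def test_strand_flip_resolved(self, toy_variants):
        v = toy_variants.iloc[:1]          # target A/G; complement T/C
        flipped = make_stats(v, ["T"], ["C"], [0.3])
        assert eng.harmonize(flipped, toy_variants).table["beta"].iloc[0] == 0.3
        flipped_swapped = make_stats(v, ["C"], ["T"], [0.3])
        assert eng.harmonize(flipped_swapped, toy_variants
                             ).table["beta"].iloc[0] == -0.3

    def test_ambiguous_dropped_by_default(self, toy_variants):
        v = toy_variants.iloc[8:9]         # target A/T: strand-ambiguous
        st = make_stats(v, ["A"], ["T"], [0.1])
        res = eng.harmonize(st, toy_variants)
        assert res.n_variants == 0
        assert res.exclusions["v8"] == "strand-ambiguous"
        kept = eng.harmonize(st, toy_variants, policy="keep_ambiguous")
        assert kept.n_variants == 1

    def test_mixed_fixture_retention_count(self, toy_variants):
        """10 variants: 2 swapped, 1 flipped, 1 ambiguous, 1 absent -> 8 kept
        under the drop policy (hand-enumerated)."""
        a1 = list(toy_variants["a1"])
        a2 = list(toy_variants["a2"])
        a1[0], a2[0] = a2[0], a1[0]                      # swap v0
        a1[1], a2[1] = a2[1], a1[1]                      # swap v1
        comp = eng.COMPLEMENT
        a1[2], a2[2] = comp[a1[2]], comp[a2[2]]          # flip v2
        st = make_stats(toy_variants, a1, a2, beta=np.full(10, 0.1))
        st.table.loc[3, "SNP"] = "not_in_target"         # absent
        res = eng.harmonize(st, toy_variants)            # v8 is A/T ambiguous
        assert res.n_variants == 8
        assert res.exclusions == {"not_in_target": "absent-from-target",
                                  "v8": "strand-ambiguous"}
        assert res.table.set_index("id").loc["v0", "beta"] == -0.1
        assert res.table.set_index("id").loc["v2", "beta"] == 0.1


def brute_force_clump(pvals, pos, chrom, R, r2_max, window):
    """Independent greedy clumping oracle on a dense correlation matrix."""
    order = sorted(range(len(pvals)), key=lambda i: (pvals[i], chrom[i], pos[i]))
    claimed = [False] * len(pvals)
    index = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        index.append(i)
        for j in range(len(pvals)):
            if not claimed[j] and chrom[j] == chrom[i] \
                    and abs(pos[j] - pos[i]) <= window \
                    and R[i, j] ** 2 >= r2_max:
                claimed[j] = True
    return set(index)


class TestClump:
    def _panel(self, seed, n=200, m=50):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n, 5))
        load = rng.uniform(-1, 1, (5, m))
        D = np.clip(np.round(Z @ load + rng.standard_normal((n, m)) + 1), 0, 2)
        return D

    def test_correlated_triple_keeps_smallest_p(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(500)
        D = np.column_stack([base + 0.9 * rng.standard_normal(500)
                             for _ in range(3)])
        ld = eng.LDMatrixView(D, radius=10)
        tab = pd.DataFrame({"id": ["a", "b", "c"], "chrom": "1",
                            "pos": [100, 200, 300], "vindex": [0, 1, 2],
                            "beta": 0.1, "p": [1e-8, 1e-6, 1e-4]})
        kept = eng.ld_clump(weights_from(tab), ld, r2_max=0.1, window_kb=500)
        assert kept == {"a"}

    def test_independent_variants_all_kept(self, rng):
        D = rng.integers(0, 3, size=(2000, 8)).astype(float)
        ld = eng.LDMatrixView(D, radius=10)
        tab = pd.DataFrame({"id": [f"v{i}" for i in range(8)], "chrom": "1",
                            "pos": np.arange(8) * 1000, "vindex": np.arange(8),
                            "beta": 0.1, "p": rng.uniform(size=8)})
        kept = eng.ld_clump(weights_from(tab), ld, r2_max=0.1, window_kb=500)
        assert kept == set(tab["id"])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = 50
        D = self._panel(seed, m=m)
        ld = eng.LDMatrixView(D, radius=m)
        pvals = rng.uniform(size=m)
        pos = np.sort(rng.choice(np.arange(1, 10_000) * 100, m, replace=False))
        tab = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": "1",
                            "pos": pos, "vindex": np.arange(m), "beta": 0.1,
                            "p": pvals})
        R = np.corrcoef(D, rowvar=False)
        expect = brute_force_clump(pvals, pos, ["1"] * m, R, 0.2, 300_000)
        got = eng.ld_clump(weights_from(tab), ld, r2_max=0.2, window_kb=300)
        assert got == {f"v{i}" for i in expect}

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        D = self._panel(5, m=30)
        ld = eng.LDMatrixView(D, radius=30)
        tab = pd.DataFrame({"id": [f"v{i}" for i in range(30)], "chrom": "1",
                            "pos": np.arange(30) * 1000, "vindex": np.arange(30),
                            "beta": 0.1,
                            "p": np.repeat(rng.uniform(size=10), 3)})
        a = eng.ld_clump(weights_from(tab), ld, 0.2, 500)
        b = eng.ld_clump(weights_from(tab.sample(frac=1, random_state=1)),
                         ld, 0.2, 500)
        assert a == b

    def test_empty_input(self):
        ld = eng.LDMatrixView(np.zeros((10, 2)), radius=1)
        assert eng.ld_clump(weights_from(pd.DataFrame(
            columns=["id", "chrom", "pos", "vindex", "beta", "p"])), ld) == set()


class TestThreshold:
    def test_strict_boundary(self):
        tab = pd.DataFrame({"id": list("abc"), "chrom": "1",
                            "pos": [1, 2, 3], "vindex": [0, 1, 2],
                            "beta": 0.1, "p": [0.049, 0.05, 0.051]})
        out = eng.threshold(weights_from(tab), p_max=0.05)
        assert list(out.table["id"]) == ["a"]

    def test_pmax_one_keeps_all(self):
        tab = pd.DataFrame({"id": list("abc"), "chrom": "1", "pos": [1, 2, 3],
                            "vindex": [0, 1, 2], "beta": 0.1,
                            "p": [0.2, 0.9, 0.999]})
        assert eng.threshold(weights_from(tab), p_max=1.0).n_variants == 3

    def test_null_retention_fraction(self, rng):
        p = rng.uniform(size=10000)
        tab = pd.DataFrame({"id": [f"v{i}" for i in range(10000)], "chrom": "1",
                            "pos": np.arange(10000), "vindex": np.arange(10000),
                            "beta": 0.0, "p": p})
        frac = eng.threshold(weights_from(tab), 0.05).n_variants / 10000
        assert frac == pytest.approx(0.05, abs=0.01)


class TestScore:
    def _geno(self, D):
        D = np.asarray(D, float)
        n = D.shape[0]
        return GenotypeMatrix(np.asarray(D, float),
                              np.array([f"s{i}" for i in range(n)]),
                              np.array(["EA"] * n))

    def test_arithmetic(self):
        g = self._geno([[0, 2], [1, 1], [2, 0]])
        tab = pd.DataFrame({"id": ["a", "b"], "chrom": "1", "pos": [1, 2],
                            "vindex": [0, 1], "beta": [0.1, -0.2], "p": 0.5})
        assert np.allclose(eng.score(g, weights_from(tab)), [-0.4, -0.1, 0.2])

    def test_zero_weights_zero_scores(self):
        g = self._geno(np.random.default_rng(0).integers(0, 3, (5, 3)))
        tab = pd.DataFrame({"id": list("abc"), "chrom": "1", "pos": [1, 2, 3],
                            "vindex": [0, 1, 2], "beta": 0.0, "p": 0.5})
        assert np.allclose(eng.score(g, weights_from(tab)), 0.0)

    def test_linearity(self, rng):
        g = self._geno(rng.integers(0, 3, (20, 6)))
        mk = lambda b: weights_from(pd.DataFrame(
            {"id": [f"v{i}" for i in range(6)], "chrom": "1",
             "pos": np.arange(6), "vindex": np.arange(6), "beta": b, "p": 0.5}))
        b1, b2 = rng.normal(size=6), rng.normal(size=6)
        assert np.allclose(eng.score(g, mk(b1)) + eng.score(g, mk(b2)),
                           eng.score(g, mk(b1 + b2)))

    def test_allele_flip_shifts_by_constant(self, rng):
        """Swapping effect/other allele and negating beta maps dosage to
        2-dosage: raw scores shift by a constant, corrected scores match."""
        D = rng.integers(0, 3, (50, 8)).astype(float)
        g = self._geno(D)
        beta = rng.normal(size=8)
        mk = lambda b: weights_from(pd.DataFrame(
            {"id": [f"v{i}" for i in range(8)], "chrom": "1",
             "pos": np.arange(8), "vindex": np.arange(8), "beta": b, "p": 0.5}))
        s1 = eng.score(g, mk(beta))
        g_flip = self._geno(2.0 - D)
        s2 = eng.score(g_flip, mk(-beta))
        assert np.allclose(s2 - s1, (s2 - s1)[0])
        c1 = eng.residualize_standardize(s1, None)
        c2 = eng.residualize_standardize(s2, None)
        assert np.allclose(c1, c2, atol=1e-10)

    def test_missing_dosage_mean_imputed_within_group(self):
        D = np.array([[0.0], [2.0], [np.nan], [2.0]])
        g = GenotypeMatrix(D, np.array(["a", "b", "c", "d"]),
                           np.array(["EA", "EA", "EA", "AA"]))
        tab = pd.DataFrame({"id": ["v"], "chrom": "1", "pos": [1],
                            "vindex": [0], "beta": [1.0], "p": 0.5})
        s = eng.score(g, weights_from(tab))
        assert s[2] == pytest.approx(1.0)    # EA mean of (0,2)

    def test_no_overlap_errors(self):
        g = self._geno([[0], [1]])
        empty = weights_from(pd.DataFrame(
            columns=["id", "chrom", "pos", "vindex", "beta", "p"]))
        with pytest.raises(eng.ScoringError, match="no scoring variants"):
            eng.score(g, empty)


class TestLdpredInf:
    def _weights(self, beta, p=None):
        m = len(beta)
        return weights_from(pd.DataFrame(
            {"id": [f"v{i}" for i in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1), "vindex": np.arange(m),
             "beta": beta, "p": 0.5 if p is None else p}))

    def test_identity_ld_closed_form(self, rng):
        m, n, h2 = 5000, 10_000, 0.5
        # independent variants: large panel, radius spans everything
        D = rng.integers(0, 3, size=(4000, 60)).astype(float)
        ld = eng.LDMatrixView(D, radius=60)
        # overwrite with exactly-identity LD via orthogonal columns
        ld._X = np.linalg.qr(rng.standard_normal((4000, 60)))[0] * np.sqrt(4000)
        beta = rng.normal(size=60)
        out = eng.ldpred_inf(self._weights(beta), ld, h2=h2, n=n, m=m)
        shrink = (n * h2) / (n * h2 + m)
        assert np.allclose(out.table["beta"], beta * shrink, atol=1e-10)
        assert shrink == pytest.approx(0.5)

    def test_shrinkage_monotone_to_one(self, rng):
        D = rng.integers(0, 3, size=(500, 10)).astype(float)
        ld = eng.LDMatrixView(D, radius=10)
        ld._X = np.linalg.qr(rng.standard_normal((500, 10)))[0] * np.sqrt(500)
        beta = np.ones(10)
        prev = 0.0
        for nh2 in [1e3, 1e4, 1e5, 1e6]:
            out = eng.ldpred_inf(self._weights(beta), ld, h2=1.0,
                                 n=int(nh2), m=5000)
            val = out.table["beta"].iloc[0]
            assert val > prev
            prev = val
        assert prev == pytest.approx(1.0, abs=1e-2)

    def test_matches_dense_solver_oracle(self):
        """Banded 200-variant panel, radius covering the band: the windowed
        solve equals the dense whole-matrix solve."""
        cfg = SimulationConfig(n_subjects_per_ancestry={"EA": 800},
                               n_variants=200, n_blocks=10, block_rho=0.6,
                               trait_specs=[], target_or_per_sd={},
                               ps_prevalence={"EA": 0.15}, seed=31)
        _, geno = simulate_genotypes(cfg)
        ld = eng.LDMatrixView(geno, radius=100)
        rng = np.random.default_rng(1)
        beta = rng.normal(size=200) * 0.01
        h2, n, m = 0.3, 50_000, 200
        out = eng.ldpred_inf(self._weights(beta), ld, h2=h2, n=n, m=m)
        Dfull = ld.block(0, 200)
        dense = linalg.solve(Dfull + (m / (n * h2)) * np.eye(200), beta)
        assert np.allclose(out.table["beta"], dense, atol=1e-6)


class TestPCs:
    def test_duplicated_subjects_share_pcs(self, rng):
        D = rng.integers(0, 3, (30, 40)).astype(float)
        dup = np.vstack([D, D])
        g = GenotypeMatrix(dup, np.array([f"s{i}" for i in range(60)]),
                           np.array(["EA"] * 60))
        pcs = eng.compute_pcs(g, None, k=3)
        assert np.allclose(pcs[:30], pcs[30:], atol=1e-8)

    def test_orthonormal_columns(self, rng):
        D = rng.integers(0, 3, (80, 120)).astype(float)
        g = GenotypeMatrix(D, np.array([f"s{i}" for i in range(80)]),
                           np.array(["EA"] * 80))
        pcs = eng.compute_pcs(g, None, k=5)
        assert np.allclose(pcs.T @ pcs, np.eye(5), atol=1e-8)

    def test_pc1_separates_ancestry(self):
        cfg = SimulationConfig(n_subjects_per_ancestry={"EA": 300, "AA": 300},
                               n_variants=1000, n_blocks=100, fst=0.1,
                               trait_specs=[], target_or_per_sd={}, seed=41)
        _, geno = simulate_genotypes(cfg)
        pc1 = eng.compute_pcs(geno, None, k=1)[:, 0]
        labels = (geno.ancestry == "EA").astype(int)
        auc = roc_auc_score(labels, pc1)
        assert max(auc, 1 - auc) > 0.99

    def test_k_too_large_errors(self, rng):
        D = rng.integers(0, 3, (5, 10)).astype(float)
        g = GenotypeMatrix(D, np.array(list("abcde")), np.array(["EA"] * 5))
        with pytest.raises(ValueError):
            eng.compute_pcs(g, None, k=5)


class TestResidualize:
    def test_orthogonal_pcs_reduce_to_zscore(self, rng):
        y = rng.normal(size=400)
        pcs = np.linalg.qr(rng.standard_normal((400, 3)))[0]
        Z = np.column_stack([np.ones(400), pcs])
        y_orth = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        out = eng.residualize_standardize(y_orth, pcs)
        assert np.allclose(out, y_orth / y_orth.std(), atol=1e-8)

    def test_score_equal_to_pc_errors(self, rng):
        pcs = np.linalg.qr(rng.standard_normal((50, 2)))[0]
        with pytest.raises(eng.DegenerateScoreError):
            eng.residualize_standardize(pcs[:, 0], pcs)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=200)
        pcs = rng.standard_normal((200, 4))
        out = eng.residualize_standardize(y, pcs)
        Z = np.column_stack([np.ones(200), pcs])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        resid = y - Z @ beta
        assert np.allclose(out, resid / resid.std(), atol=1e-10)

    def test_corrected_scores_are_standard_within_group(self, small_study):
        ss = small_study
        w = eng.harmonize(ss.sumstats["ADHD"], ss.variants)
        cs = eng.corrected_scores(ss.genotypes, w, k_pcs=5)
        for anc in ("EA", "AA"):
            m = ss.genotypes.ancestry == anc
            assert abs(cs[m].mean()) < 1e-8
            assert abs(cs[m].std() - 1) < 1e-8


class TestEndToEnd:
    def test_correlated_trait_detected_null_trait_not(self, small_study):
        """A trait sharing architecture with the outcome scores positively;
        an unrelated trait does not."""
        ss = small_study
        ld = eng.build_ld_view(ss.genotypes, radius=50)
        pcs = eng.group_pcs(ss.genotypes, k=5)
        cors = {}
        for name in ("ADHD", "SCZ"):
            w = eng.clump_and_threshold(
                eng.harmonize(ss.sumstats[name], ss.variants), ld)
            cs = eng.corrected_scores(ss.genotypes, w, pcs=pcs)
            g_true = ss.genetic_score("ADHD")
            cors[name] = np.corrcoef(cs, g_true)[0, 1]
        # null-score correlation noise scales with 1/sqrt(n_variants) on a
        # 300-variant panel, so the bound is loose; the contrast is the point
        assert cors["ADHD"] > 0.3
        assert abs(cors["SCZ"]) < 0.25
        assert cors["ADHD"] > 2 * abs(cors["SCZ"])
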