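"""Clumping, scoring, LOCO assembly and the weight-method registry."""

import numpy as np
import pandas as pd
import pytest

from locopgs import (
    LocoScoreSet,
    PGSConfig,
    clump,
    loco_pgs,
    register_weight_method,
    score,
)
from locopgs.pgs import get_weight_method

from conftest import make_matrix


def stats_frame(G, p, beta=None):
    v = G.variants
    return pd.DataFrame(
        {
            "SNP": v["id"],
            "CHR": v["chrom"],
            "BP": v["pos"],
            "A1": v["a1"],
            "A2": v["a2"],
            "FREQ": v["freq_a1"],
            "N": G.n_samples,
            "BETA": np.ones(len(v)) if beta is None else np.asarray(beta),
            "SE": 0.1,
            "P": np.asarray(p, dtype=float),
        }
    )


class TestClump:
    def test_perfect_ld_keeps_single_index(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=(100, 1)).astype(np.int8)
        G = make_matrix(np.repeat(col, 3, axis=1))
        stats_df = stats_frame(G, [1e-10, 1e-9, 1e-8])
        out = clump(stats_df, G, 1e-4, 0.1, 250_000)
        assert list(out["SNP"]) == ["v0"]

    def test_different_chromosomes_never_clumped(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=(100, 1)).astype(np.int8)
        G = make_matrix(np.repeat(col, 2, axis=1), chrom=[1, 2])
        out = clump(stats_frame(G, [1e-10, 1e-9]), G, 1e-4, 0.1, 10**9)
        assert len(out) == 2

    def test_toy_panel_matches_brute_force_greedy(self):
        # five fixed dosage columns with hand-checkable pairwise r^2
        d = np.array(
            [
                [0, 0, 2, 0, 1],
                [1, 1, 1, 0, 2],
                [2, 2, 0, 1, 0],
                [0, 0, 2, 1, 1],
                [1, 1, 1, 2, 2],
                [2, 2, 0, 2, 0],
                [0, 1, 2, 0, 1],
                [2, 1, 0, 2, 1],
            ],
            dtype=np.int8,
        )
        G = make_matrix(d)
        p = np.array([1e-9, 1e-8, 1e-7, 1e-6, 1e-5])
        out = clump(stats_frame(G, p), G, 1e-4, 0.2, 10**9)

        # brute-force re-execution of the greedy rule
        z = (d - d.mean(0)) / d.std(0)
        r2 = np.corrcoef(d.T) ** 2
        order = np.argsort(p)
        claimed = np.zeros(5, dtype=bool)
        expect = []
        for i in order:
            if claimed[i]:
                continue
            claimed[i] = True
            expect.append(f"v{i}")
            for j in range(5):
                if not claimed[j] and r2[i, j] > 0.2:
                    claimed[j] = True
        assert sorted(out["SNP"]) == sorted(expect)

    def test_retained_pairs_below_r2(self, geno_medium):
        rng = np.random.default_rng(2)
        p = 10 ** -rng.uniform(3, 12, geno_medium.n_variants)
        out = clump(stats_frame(geno_medium, p), geno_medium, 1e-3, 0.1,
                    250_000)
        assert (out.merge(stats_frame(geno_medium, p), on="SNP")["P"] <=
                1e-3).all()
        idx = geno_medium.variant_indexer()[out["SNP"]].to_numpy()
        Z = geno_medium.standardized(idx)
        for a in range(len(out)):
            for b in range(a + 1, len(out)):
                if out.loc[a, "CHR"] != out.loc[b, "CHR"]:
                    continue
                if abs(out.loc[a, "BP"] - out.loc[b, "BP"]) > 250_000:
                    continue
                r = np.corrcoef(Z[:, a], Z[:, b])[0, 1]
                assert r**2 <= 0.1 + 1e-9

    def test_threshold_monotonicity(self, geno_medium):
        rng = np.random.default_rng(3)
        p = 10 ** -rng.uniform(1, 10, geno_medium.n_variants)
        sizes = [
            len(clump(stats_frame(geno_medium, p), geno_medium, thr, 0.1,
                      250_000))
            for thr in (1e-6, 1e-4, 1e-2)
        ]
        assert sizes == sorted(sizes)


class TestScore:
    def test_single_variant_effect_allele_a1(self):
        G = make_matrix(np.array([[2]], dtype=np.int8))
        W = pd.DataFrame(
            {"SNP": ["v0"], "CHR": [1], "BP": [1], "A1": ["A"], "WEIGHT": [0.5]}
        )
        assert score(G, W)[0] == pytest.approx(1.0)

    def test_effect_allele_flip(self):
        G = make_matrix(np.array([[2]], dtype=np.int8))  # a1=A, a2=G
        W = pd.DataFrame(
            {"SNP": ["v0"], "CHR": [1], "BP": [1], "A1": ["G"], "WEIGHT": [0.5]}
        )
        assert score(G, W)[0] == pytest.approx(0.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        G = make_matrix(d)
        w = rng.standard_normal(10)
        W = pd.DataFrame(
            {
                "SNP": G.variants["id"],
                "CHR": G.variants["chrom"],
                "BP": G.variants["pos"],
                "A1": "A",
                "WEIGHT": w,
            }
        )
        got = score(G, W)
        expect = np.zeros(30)
        for i in range(30):
            for j in range(10):
                expect[i] += w[j] * d[i, j]
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_zero_overlap_raises(self):
        G = make_matrix(np.array([[1]], dtype=np.int8))
        W = pd.DataFrame(
            {"SNP": ["zz"], "CHR": [1], "BP": [1], "A1": ["A"], "WEIGHT": [1.0]}
        )
        with pytest.raises(ValueError, match="overlap"):
            score(G, W)


class TestLocoPgs:
    def test_all_weights_on_one_chromosome(self, geno_small):
        p = np.ones(geno_small.n_variants)
        chrom1 = geno_small.variants["chrom"].to_numpy() == 1
        p[np.flatnonzero(chrom1)[:5]] = 1e-9
        scores = loco_pgs(stats_frame(geno_small, p), geno_small, PGSConfig())
        np.testing.assert_allclose(scores.column(1), 0.0)
        total = score(geno_small, scores.weight_table)
        for c in (2, 3, 4):
            np.testing.assert_allclose(scores.column(c), total, atol=1e-12)

    def test_subtraction_decomposition_identity(self, geno_medium):
        rng = np.random.default_rng(5)
        p = 10 ** -rng.uniform(2, 10, geno_medium.n_variants)
        scores = loco_pgs(stats_frame(geno_medium, p), geno_medium, PGSConfig())
        total = score(geno_medium, scores.weight_table)
        for c in scores.chromosomes:
            wc = scores.weight_table[scores.weight_table["CHR"] == c]
            contrib = (
                score(geno_medium, wc) if len(wc) else np.zeros(len(total))
            )
            np.testing.assert_allclose(
                total - scores.column(c), contrib, atol=1e-12
            )

    def test_per_exclusion_mode_agrees_without_cross_chromosome_ld(
        self, geno_medium
    ):
        rng = np.random.default_rng(6)
        p = 10 ** -rng.uniform(2, 8, geno_medium.n_variants)
        sdf = stats_frame(geno_medium, p)
        sub = loco_pgs(sdf, geno_medium, PGSConfig())
        per = loco_pgs(sdf, geno_medium, PGSConfig(per_exclusion=True))
        np.testing.assert_allclose(sub.scores, per.scores, atol=1e-10)

    def test_loco_uncorrelated_with_own_chromosome(self):
        from locopgs import (GenotypeSimSpec, PhenoSimSpec, gwas_scan,
                             simulate_genotypes, simulate_quantitative)

        spec = GenotypeSimSpec(n_samples=2_000, variants_per_chromosome=200,
                               n_chromosomes=6, ld_block_size=10, ld_rho=0.5,
                               seed=30)
        G = simulate_genotypes(spec)
        pheno, _ = simulate_quantitative(
            G, PhenoSimSpec(n_causal=40, h2=0.5, seed=31)
        )
        sdf = gwas_scan(G, pheno)
        scores = loco_pgs(sdf, G, PGSConfig())
        n = G.n_samples
        chrom = G.variants["chrom"].to_numpy()
        cors = []
        for c in scores.chromosomes:
            s = scores.column(c)
            if s.std() == 0:
                continue
            Z = G.standardized(np.flatnonzero(chrom == c))
            sc = (s - s.mean()) / s.std()
            cors.extend(np.abs(Z.T @ sc / n))
        assert np.mean(cors) < 3 / np.sqrt(n)

    def test_determinism(self, geno_small):
        rng = np.random.default_rng(7)
        p = 10 ** -rng.uniform(2, 8, geno_small.n_variants)
        sdf = stats_frame(geno_small, p)
        a = loco_pgs(sdf, geno_small, PGSConfig())
        b = loco_pgs(sdf, geno_small, PGSConfig())
        np.testing.assert_array_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.weight_table, b.weight_table)

    def test_single_chromosome_rejected(self):
        G = make_matrix(np.zeros((4, 2), dtype=np.int8), chrom=[1, 1])
        with pytest.raises(ValueError, match="chromosome"):
            loco_pgs(stats_frame(G, [0.5, 0.5]), G, PGSConfig())

    def test_tsv_round_trip(self, geno_small, tmp_path):
        rng = np.random.default_rng(8)
        p = 10 ** -rng.uniform(2, 8, geno_small.n_variants)
        scores = loco_pgs(stats_frame(geno_small, p), geno_small, PGSConfig())
        scores.to_tsv(tmp_path / "s.tsv")
        back = LocoScoreSet.from_tsv(tmp_path / "s.tsv")
        np.testing.assert_allclose(back.scores, scores.scores, rtol=1e-12)
        np.testing.assert_array_equal(back.chromosomes, scores.chromosomes)


class TestConfigGuard:
    def test_high_threshold_refused_without_override(self):
        with pytest.raises(ValueError, match="high"):
            PGSConfig(p_threshold=0.05)
        cfg = PGSConfig(p_threshold=0.05, allow_high_threshold=True)
        assert cfg.p_threshold == 0.05


class TestWeightMethodRegistry:
    def test_alias_of_builtin_is_identical(self, geno_small):
        register_weight_method("pt_alias", get_weight_method("pt"))
        rng = np.random.default_rng(9)
        p = 10 ** -rng.uniform(2, 8, geno_small.n_variants)
        sdf = stats_frame(geno_small, p)
        a = loco_pgs(sdf, geno_small, PGSConfig(weight_method="pt"))
        b = loco_pgs(sdf, geno_small, PGSConfig(weight_method="pt_alias"))
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_top1_method(self, geno_small):
        def top1(stats_df, G_ref, cfg):
            best = stats_df.loc[[stats_df["P"].idxmin()]]
            return pd.DataFrame(
                {
                    "SNP": best["SNP"].to_numpy(),
                    "CHR": best["CHR"].to_numpy(),
                    "BP": best["BP"].to_numpy(),
                    "A1": best["A1"].to_numpy(),
                    "WEIGHT": best["BETA"].to_numpy(),
                }
            )

        register_weight_method("top1", top1)
        rng = np.random.default_rng(10)
        p = 10 ** -rng.uniform(2, 8, geno_small.n_variants)
        out = loco_pgs(
            stats_frame(geno_small, p), geno_small,
            PGSConfig(weight_method="top1"),
        )
        assert len(out.weight_table) == 1

    def test_unit_weights_reproduce_allele_counts(self, geno_small):
        def unit(stats_df, G_ref, cfg):
            sub = stats_df.head(3)
            return pd.DataFrame(
                {
                    "SNP": sub["SNP"].to_numpy(),
                    "CHR": sub["CHR"].to_numpy(),
                    "BP": sub["BP"].to_numpy(),
                    "A1": sub["A1"].to_numpy(),
                    "WEIGHT": 1.0,
                }
            )

        register_weight_method("unit3", unit)
        p = np.full(geno_small.n_variants, 1e-6)
        sdf = stats_frame(geno_small, p)
        scores = loco_pgs(sdf, geno_small, PGSConfig(weight_method="unit3"))
        # the three weighted variants all sit on chromosome 1, so every other
        # chromosome's LOCO column equals their raw allele-count sum
        counts = geno_small.imputed(np.arange(3)).sum(axis=1)
        np.testing.assert_allclose(scores.column(2), counts, atol=1e-12)

    def test_unknown_method_raises(self, geno_small):
        with pytest.raises(KeyError, match="unknown"):
            loco_pgs(
                stats_frame(geno_small, np.ones(geno_small.n_variants)),
                geno_small,
                PGSConfig(weight_method="nope"),
            )
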