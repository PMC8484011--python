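"""Normalization, filtering, homeolog logFC, DE, PCA and clustering."""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from polyhomeo import homeolog_expr as hx
from polyhomeo import synthdata


def small_matrix(counts, species, gene_subgenome=None, lengths=None):
    """Build an ExpressionMatrix from a counts DataFrame and species list."""
    samples = pd.DataFrame(
        {
            "species": species,
            "accession": [f"a{i}" for i in range(len(species))],
            "replicate": 1,
            "tissue": "rosette",
        },
        index=counts.columns,
    )
    if gene_subgenome is None:
        gene_subgenome = pd.Series(
            ["TH" if g.startswith("TH") else "AR" for g in counts.index],
            index=counts.index,
        )
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    return hx.ExpressionMatrix(counts, lengths, samples, gene_subgenome)


class TestCrossMapperFilter:
    def make(self, th_mean, ar_mean, subgenome="TH"):
        counts = pd.DataFrame(
            {
                "s_th": [th_mean, 50],
                "s_ar": [ar_mean, 50],
            },
            index=[f"{subgenome}g0", "ARg9" if subgenome == "TH" else "THg9"],
        )
        return small_matrix(counts, ["thaliana", "arenosa"])

    def test_right_species_dominates_kept(self):
        kept = hx.filter_cross_mappers(self.make(100, 0))
        assert "THg0" in kept

    def test_wrong_species_dominates_removed(self):
        kept = hx.filter_cross_mappers(self.make(10, 100))
        assert "THg0" not in kept

    def test_equal_means_kept(self):
        kept = hx.filter_cross_mappers(self.make(50, 50))
        assert "THg0" in kept

    def test_mirrored_rule_for_ar_genes(self):
        kept = hx.filter_cross_mappers(self.make(100, 10, subgenome="AR"))
        assert "ARg0" not in kept

    def test_requires_both_ancestor_panels(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["THg0"])
        m = small_matrix(counts, ["thaliana", "thaliana"])
        with pytest.raises(ValueError, match="pure samples"):
            hx.filter_cross_mappers(m)


class TestTPM:
    def test_single_gene_sample_is_1e6(self):
        tpm = hx.compute_tpm(
            pd.DataFrame({"s": [7]}, index=["g"]), pd.Series({"g": 500})
        )
        assert tpm.loc["g", "s"] == pytest.approx(1e6)

    def test_length_halving_doubles_share(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        tpm = hx.compute_tpm(counts, lengths)
        assert tpm.loc["a", "s"] == pytest.approx(2e6 / 3)
        assert tpm.loc["b", "s"] == pytest.approx(1e6 / 3)

    def test_scale_invariance_and_unit_sum(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 5000, size=30),
                            index=counts.index)
        tpm = hx.compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)
        tpm2 = hx.compute_tpm(counts * 2, lengths)
        pd.testing.assert_frame_equal(tpm, tpm2)

    def test_all_zero_sample_flagged(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero counts"):
            hx.compute_tpm(counts, pd.Series({"a": 100, "b": 100}))


class TestTMM:
    def fixture_counts(self, rng, n=100, samples=4):
        mu = rng.lognormal(4, 1.5, size=n)
        scale = np.array([1.0, 1.7, 0.6, 1.2])[:samples]
        counts = rng.poisson(np.outer(mu, scale))
        return pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(samples)],
        )

    def test_duplicated_sample_gets_factor_one(self, rng):
        counts = self.fixture_counts(rng)
        counts["s3"] = counts["s0"]
        f = hx.tmm_factors(counts[["s0", "s3"]])
        assert f["s0"] == pytest.approx(1.0)
        assert f["s3"] == pytest.approx(1.0)

    def test_pure_library_size_shift_absorbed(self, rng):
        counts = self.fixture_counts(rng, samples=2)
        counts["s1"] = counts["s0"] * 2  # exact doubling: no composition change
        f = hx.tmm_factors(counts[["s0", "s1"]])
        assert f["s0"] == pytest.approx(1.0, abs=1e-9)
        assert f["s1"] == pytest.approx(1.0, abs=1e-9)

    def test_geometric_mean_is_one(self, rng):
        f = hx.tmm_factors(self.fixture_counts(rng))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    @pytest.mark.skipif(
        shutil.which("Rscript") is None, reason="Rscript not available"
    )
    def test_matches_reference_edger_implementation(self, rng, tmp_path):
        # independent oracle: edgeR's calcNormFactors on the same fixture
        counts = self.fixture_counts(rng)
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.delim('{path}', row.names=1));"
            "f <- calcNormFactors(x, method='TMM', refColumn=1);"
            "cat(sprintf('%.10f', f), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        ref = np.array([float(v) for v in out.stdout.split()])
        mine = hx.tmm_factors(counts, reference_sample="s0").to_numpy()
        np.testing.assert_allclose(mine, ref, rtol=1e-6)


class TestEffectiveSizesAndCPM:
    def test_allopolyploid_size_is_mean_of_subgenome_totals(self):
        tpm = pd.DataFrame(
            {"sue1": [1e6, 3e6], "sue2": [1e6, 3e6]},
            index=["THg0", "ARg0"],
        )
        samples = pd.DataFrame(
            {
                "species": ["suecica_natural", "suecica_natural"],
                "accession": ["x", "y"],
                "replicate": 1,
            },
            index=["sue1", "sue2"],
        )
        subg = pd.Series({"THg0": "TH", "ARg0": "AR"})
        sizes, factors = hx.effective_library_sizes(tpm, samples, subg)
        assert sizes["sue1"] == pytest.approx(2e6)
        # identical samples: all TMM factors 1
        assert np.allclose(factors.to_numpy(), 1.0)

    def test_ancestor_ignores_other_subgenome_rows(self):
        tpm = pd.DataFrame(
            {"th1": [9e5, 1e5], "th2": [9e5, 1e5]},
            index=["THg0", "ARg0"],
        )
        samples = pd.DataFrame(
            {
                "species": ["thaliana", "thaliana"],
                "accession": ["x", "y"],
                "replicate": 1,
            },
            index=["th1", "th2"],
        )
        subg = pd.Series({"THg0": "TH", "ARg0": "AR"})
        sizes, _ = hx.effective_library_sizes(tpm, samples, subg)
        # AR rows (cross-mapping noise) are excluded from a thaliana size
        assert sizes["th1"] == pytest.approx(9e5)

    def test_equal_totals_give_that_total(self):
        tpm = pd.DataFrame(
            {"s1": [5e5, 5e5], "s2": [5e5, 5e5]}, index=["THg0", "ARg0"]
        )
        samples = pd.DataFrame(
            {
                "species": ["suecica_natural"] * 2,
                "accession": ["x", "y"],
                "replicate": 1,
            },
            index=["s1", "s2"],
        )
        subg = pd.Series({"THg0": "TH", "ARg0": "AR"})
        sizes, _ = hx.effective_library_sizes(tpm, samples, subg)
        assert sizes["s1"] == pytest.approx(5e5)

    def test_log_cpm_values(self):
        counts = pd.DataFrame({"s": [0, 1023]}, index=["a", "b"])
        sizes = pd.Series({"s": 1e6})
        lcpm = hx.log_cpm(counts, sizes, prior=1.0)
        assert lcpm.loc["a", "s"] == pytest.approx(0.0)
        assert lcpm.loc["b", "s"] == pytest.approx(10.0)

    def test_pipeline_invariant_to_rescaling_one_sample(self, expression):
        # sequencing a library deeper must not move its normalized values
        matrix, _ = expression
        norm = hx.normalize(matrix)
        scaled_counts = matrix.counts.copy()
        scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 10
        scaled = hx.ExpressionMatrix(
            scaled_counts, matrix.lengths, matrix.samples,
            matrix.gene_subgenome,
        )
        norm2 = hx.normalize(scaled)
        # identical up to TMM trimming discreteness: float rounding can flip
        # ranks exactly at the trim boundary, moving factors by < 0.01 log2
        np.testing.assert_allclose(
            norm.log2_cpm.to_numpy(), norm2.log2_cpm.to_numpy(), atol=0.01
        )

    def test_log_cpm_monotone_in_count(self):
        counts = pd.DataFrame({"s": np.arange(50)}, index=range(50))
        lcpm = hx.log_cpm(counts, pd.Series({"s": 1e6}))
        assert (np.diff(lcpm["s"]) > 0).all()


class TestExpressionFilterAndLogFC:
    def test_filter_thresholds(self, expression, hmap):
        matrix, _ = expression
        norm = hx.normalize(matrix)
        kept = hx.expression_filter(norm, matrix.samples, hmap.pairs)
        # default simulation expresses every pair everywhere
        assert len(kept) == len(hmap.pairs)

    def test_underexpressed_pair_dropped(self, expression, hmap):
        matrix, _ = expression
        norm = hx.normalize(matrix)
        # silence one pair's TH member everywhere: fails thaliana >= 3
        lcpm = norm.log2_cpm.copy()
        lcpm.loc[hmap.pairs["th_gene"].iloc[0]] = -10.0
        norm2 = hx.NormalizedExpression(
            lcpm, norm.effective_sizes, norm.tmm_factors, norm.prior
        )
        kept = hx.expression_filter(norm2, matrix.samples, hmap.pairs)
        assert hmap.pairs["pair_id"].iloc[0] not in set(kept["pair_id"])

    def test_equal_homeologs_give_zero_logfc(self):
        lcpm = pd.DataFrame(
            {"sue_r1": [5.0, 5.0, 3.0, 5.0]},
            index=["THg0", "ARg0", "THg1", "ARg1"],
        )
        samples = pd.DataFrame(
            {
                "species": ["suecica_natural"],
                "accession": ["x"],
                "replicate": 1,
            },
            index=["sue_r1"],
        )
        norm = hx.NormalizedExpression(
            lcpm, pd.Series({"sue_r1": 1e6}),
            pd.DataFrame(1.0, index=["TH", "AR"], columns=["sue_r1"]),
        )
        pairs = pd.DataFrame(
            {
                "pair_id": ["p0", "p1"],
                "th_gene": ["THg0", "THg1"],
                "ar_gene": ["ARg0", "ARg1"],
            }
        )
        stats = hx.homeolog_logfc(norm, samples, pairs)
        assert stats.per_accession.loc[0, "x"] == pytest.approx(0.0)
        # AR at 4x TH (2 log2 units) -> +2
        assert stats.per_accession.loc[1, "x"] == pytest.approx(2.0)

    def test_logfc_antisymmetric_under_subgenome_swap(self, expression, hmap):
        matrix, _ = expression
        norm = hx.normalize(matrix)
        fwd = hx.homeolog_logfc(norm, matrix.samples, hmap.pairs)
        swapped = hmap.pairs.rename(
            columns={"th_gene": "ar_gene", "ar_gene": "th_gene"}
        )
        rev = hx.homeolog_logfc(norm, matrix.samples, swapped)
        np.testing.assert_allclose(
            fwd.per_accession.to_numpy(), -rev.per_accession.to_numpy()
        )


class TestTissueSpecific:
    def build(self, delta):
        samples = pd.DataFrame(
            {
                "species": ["suecica_natural"] * 2,
                "accession": ["x", "x"],
                "replicate": 1,
                "tissue": ["rosette", "flower"],
            },
            index=["s_ros", "s_flo"],
        )
        lcpm = pd.DataFrame(
            {"s_ros": [5.0 + delta, 5.0], "s_flo": [5.0, 5.0]},
            index=["THg0", "ARg0"],
        )
        norm = hx.NormalizedExpression(
            lcpm, pd.Series({"s_ros": 1e6, "s_flo": 1e6}),
            pd.DataFrame(1.0, index=["TH", "AR"], columns=["s_ros", "s_flo"]),
        )
        pairs = pd.DataFrame(
            {"pair_id": ["p0"], "th_gene": ["THg0"], "ar_gene": ["ARg0"]}
        )
        return hx.tissue_specific_pairs(
            norm, samples, pairs, tissues=("rosette", "flower")
        )

    def test_eightfold_difference_flagged(self):
        out = self.build(3.0)
        assert bool(out.loc[0, "th_flagged"])
        assert bool(out.loc[0, "analysed"])

    def test_small_difference_not_flagged(self):
        out = self.build(1.5)
        assert not bool(out.loc[0, "analysed"])

    def test_boundary_two_is_inclusive(self):
        out = self.build(2.0)
        assert bool(out.loc[0, "th_flagged"])


class TestWilcoxonDE:
    def brute_force_two_sided_p(self, a, b):
        """Oracle: enumerate all rank assignments of the pooled sample."""
        pooled = np.concatenate([a, b])
        n_a = len(a)
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        obs = ranks[:n_a].sum()
        null = [
            sum(ranks[list(idx)])
            for idx in combinations(range(len(pooled)), n_a)
        ]
        null = np.array(null)
        mean = null.mean()
        extreme = np.sum(np.abs(null - mean) >= abs(obs - mean) - 1e-9)
        return extreme / len(null)

    def test_fully_separated_small_groups_match_enumeration(self):
        a = np.array([10.0, 11.0, 12.0, 13.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        values = pd.DataFrame(
            [np.concatenate([a, b])],
            index=["g"],
            columns=[f"x{i}" for i in range(8)],
        )
        res = hx.differential_expression(
            values, [f"x{i}" for i in range(4)], [f"x{i}" for i in range(4, 8)]
        )
        # all 70 assignments enumerated: the observed split is one of 2
        assert res.loc["g", "p"] == pytest.approx(
            self.brute_force_two_sided_p(a, b), rel=1e-12
        )
        assert res.loc["g", "p"] == pytest.approx(2 / 70, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_groups_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=5)
        b = rng.normal(0.5, 1, size=6)
        values = pd.DataFrame(
            [np.concatenate([a, b])], index=["g"],
            columns=[f"x{i}" for i in range(11)],
        )
        res = hx.differential_expression(
            values, [f"x{i}" for i in range(5)],
            [f"x{i}" for i in range(5, 11)],
        )
        assert res.loc["g", "p"] == pytest.approx(
            self.brute_force_two_sided_p(a, b), rel=1e-9
        )

    def test_identical_groups_give_p_one(self):
        values = pd.DataFrame(
            [[3.0, 3.0, 3.0, 3.0]], index=["g"], columns=list("wxyz")
        )
        res = hx.differential_expression(values, ["w", "x"], ["y", "z"])
        assert res.loc["g", "p"] == 1.0
        assert res.loc["g", "q"] == 1.0

    def test_bh_fixed_point_for_equal_pvalues(self):
        # many genes with identical data: all p equal -> all q equal p
        row = [1.0, 2.0, 10.0, 11.0]
        values = pd.DataFrame(
            [row] * 5, index=[f"g{i}" for i in range(5)], columns=list("wxyz")
        )
        res = hx.differential_expression(values, ["w", "x"], ["y", "z"])
        np.testing.assert_allclose(res["q"], res["p"])

    def test_groups_of_one_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            hx.differential_expression(values, ["a"], ["b"])


class TestPCA:
    def test_properties(self, expression):
        matrix, _ = expression
        norm = hx.normalize(matrix)
        res = hx.pca_by_subgenome(
            norm, matrix.samples, matrix.gene_subgenome, n_components=3
        )
        for sub in ("TH", "AR"):
            evr = res[sub]["explained_variance_ratio"]
            assert (np.diff(evr) <= 1e-12).all()
            scores = res[sub]["scores"].to_numpy()
            cov = np.cov(scores.T)
            off = cov - np.diag(np.diag(cov))
            assert np.allclose(off, 0.0, atol=1e-8)

    def test_duplicated_sample_identical_scores(self, expression):
        matrix, _ = expression
        norm = hx.normalize(matrix)
        dup = norm.log2_cpm.copy()
        dup["copycat"] = dup.iloc[:, 0]
        samples = matrix.samples.copy()
        samples.loc["copycat"] = samples.iloc[0]
        norm2 = hx.NormalizedExpression(
            dup,
            pd.concat(
                [norm.effective_sizes,
                 pd.Series({"copycat": norm.effective_sizes.iloc[0]})]
            ),
            pd.concat(
                [norm.tmm_factors,
                 norm.tmm_factors.iloc[:, [0]].rename(
                     columns={norm.tmm_factors.columns[0]: "copycat"})],
                axis=1,
            ),
        )
        res = hx.pca_by_subgenome(norm2, samples, matrix.gene_subgenome)
        scores = res["TH"]["scores"]
        np.testing.assert_allclose(
            scores.iloc[0].to_numpy(), scores.loc["copycat"].to_numpy(),
            atol=1e-8,
        )


class TestClusterDEGs:
    def planted(self, rng, k=2, n_per=20, n_samples=12):
        base = []
        for c in range(k):
            pattern = np.zeros(n_samples)
            pattern[c::k] = 5.0
            for _ in range(n_per):
                base.append(pattern + rng.normal(0, 0.2, n_samples))
        return pd.DataFrame(
            base, index=[f"g{i}" for i in range(k * n_per)]
        )

    def test_two_orthogonal_patterns_separate_perfectly(self, rng):
        values = self.planted(rng, k=2)
        labels = hx.cluster_degs(values, k=2)
        first = labels.iloc[:20]
        second = labels.iloc[20:]
        assert first.nunique() == 1
        assert second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_partition_stable_under_row_permutation(self, rng):
        values = self.planted(rng, k=2)
        labels = hx.cluster_degs(values, k=2)
        perm = values.sample(frac=1.0, random_state=7)
        labels_perm = hx.cluster_degs(perm, k=2)
        pd.testing.assert_series_equal(
            labels.sort_index(), labels_perm.sort_index()
        )

    def test_k_one_single_cluster(self, rng):
        values = self.planted(rng, k=2)
        assert hx.cluster_degs(values, k=1).nunique() == 1

    def test_zero_variance_gene_assigned_to_nearest_centroid(self, rng):
        values = self.planted(rng, k=2)
        values.loc["flatline"] = 0.0
        labels = hx.cluster_degs(values, k=2)
        assert labels["flatline"] in {1, 2}


class TestCrossMappingRate:
    def test_zero_leak_recovered_as_zero(self, annotation, hmap):
        p = synthdata.SynthParams(
            n_genes_per_subgenome=200, leak_th=0.0, leak_ar=0.0, seed=3
        )
        matrix, _ = synthdata.simulate_expression(annotation, hmap, None, p)
        est = hx.cross_mapping_rate(matrix)
        assert est["into_th"] == 0.0
        assert est["into_ar"] == 0.0
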