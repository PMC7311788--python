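"""Stage-1 / stage-2 PCA: oracle equivalence, sign canon, variance bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from nichespace.ordination import (
    OrdinationError,
    dimension_pca,
    fix_sign,
    niche_space,
    pca,
    pca_of_pcas,
    summarize_space,
)
from nichespace.simulate import PRIMARY_LATENT
from nichespace.traits import log10_transform

GRADIENT_NAMES = [
    "pc1.leaf_economy", "pc2.leaf_economy",
    "pc1.mechanical_support", "pc2.mechanical_support",
    "pc1.reproductive_phenology", "pc2.reproductive_phenology",
]


def random_frame(rng, n, p):
    return pd.DataFrame(
        rng.normal(size=(n, p)) * rng.uniform(0.5, 3, size=p)
        + rng.uniform(-5, 5, size=p),
        columns=[f"v{j}" for j in range(p)],
    )


def assert_equal_up_to_sign(a, b, atol=1e-8):
    """Columns agree up to the (arbitrary) per-axis orientation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    assert a.shape == b.shape
    for j in range(a.shape[1]):
        assert np.allclose(a[:, j], b[:, j], atol=atol) or np.allclose(
            a[:, j], -b[:, j], atol=atol
        ), f"column {j} differs beyond sign"


class TestPca:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("standardize", [True, False])
    def test_matches_sklearn_oracle(self, seed, standardize):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 31), rng.integers(2, 7)
        data = random_frame(rng, n, p)
        res = pca(data, standardize=standardize)
        X = data.to_numpy()
        if standardize:
            X = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = SkPCA(n_components=min(n, p)).fit(X)
        k = min(n - 1, p)
        assert np.allclose(res.eigenvalues[:k], oracle.explained_variance_[:k], atol=1e-8)
        assert_equal_up_to_sign(res.eigenvectors[:, :k], oracle.components_.T[:, :k])
        assert_equal_up_to_sign(res.scores.to_numpy()[:, :k], oracle.transform(X)[:, :k])

    def test_rank_one_two_correlated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        res = pca(pd.DataFrame({"a": x, "b": 3 * x + 1}), standardize=True)
        assert np.allclose(res.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_variance_conservation_standardized(self):
        rng = np.random.default_rng(3)
        res = pca(random_frame(rng, 40, 5), standardize=True)
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)

    def test_eigenvector_orthonormality_and_score_projection(self):
        rng = np.random.default_rng(4)
        res = pca(random_frame(rng, 25, 4), standardize=True)
        V = res.eigenvectors
        assert np.allclose(V.T @ V, np.eye(4), atol=1e-8)

    def test_more_columns_than_rows_reports_zero_tail(self):
        rng = np.random.default_rng(5)
        res = pca(random_frame(rng, 4, 6), standardize=True)
        assert len(res.eigenvalues) == 6
        assert np.all(res.eigenvalues[3:] == 0.0)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_zero_variance_column_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [2.0, 2, 2, 2]})
        with pytest.raises(OrdinationError, match="flat"):
            pca(df, standardize=True)

    def test_row_permutation_leaves_percent_variance(self):
        rng = np.random.default_rng(6)
        data = random_frame(rng, 30, 4)
        res = pca(data, standardize=True)
        shuffled = data.sample(frac=1, random_state=1)
        res2 = pca(shuffled, standardize=True)
        assert np.allclose(res.percent_variance, res2.percent_variance, atol=1e-10)


class TestFixSign:
    def test_flips_and_preserves_decomposition(self):
        rng = np.random.default_rng(7)
        res = pca(random_frame(rng, 20, 3), standardize=True)
        for j in range(3):
            col = res.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        res = pca(random_frame(rng, 20, 3), standardize=True)
        res2 = fix_sign(res)
        assert np.array_equal(res.eigenvectors, res2.eigenvectors)
        assert res.scores.equals(res2.scores)


class TestDimensionPca:
    def test_mechanical_block_pattern(self):
        # MPH and MDBH nearly collinear ("plant size"), STD independent:
        # PC1 must be a size axis, PC2 a density axis
        rng = np.random.default_rng(9)
        size = rng.normal(size=50)
        block = pd.DataFrame(
            {
                "STD": 10 ** (0.05 * rng.normal(size=50) - 0.25),
                "MPH": 10 ** (0.25 * size + 0.06 * rng.normal(size=50) + 1.0),
                "MDBH": 10 ** (0.30 * size + 0.07 * rng.normal(size=50) + 1.1),
            },
            index=pd.MultiIndex.from_tuples(
                [(f"S{i}", "TF") for i in range(50)], names=["species_id", "biome"]
            ),
        )
        full = pd.concat(
            {
                "LA": block["MPH"] * 0 + 10, "LDMC": block["MPH"] * 0 + 0.4,
                "SLA": pd.Series(10 ** rng.normal(2, 0.1, 50), index=block.index),
                "LNC": pd.Series(10 ** rng.normal(1.3, 0.1, 50), index=block.index),
                "STD": block["STD"], "MPH": block["MPH"], "MDBH": block["MDBH"],
                "FLT": block["MPH"] * 0 + 180, "FRT": block["MPH"] * 0 + 220,
                "FLD": pd.Series(10 ** rng.normal(1.9, 0.2, 50), index=block.index),
                "FRD": pd.Series(10 ** rng.normal(1.9, 0.2, 50), index=block.index),
            },
            axis=1,
        )
        # LA/LDMC/FLT/FRT constant -> standardize only mechanical block here
        res = pca(np.log10(full[["STD", "MPH", "MDBH"]]), standardize=True)
        assert set(res.dominant_variables(0)) <= {"MPH", "MDBH"}
        assert res.dominant_variables(1) == ["STD"]
        assert res.percent_variance[0] >= res.percent_variance[1]

    def test_gradients_shape_and_centering(self, community):
        logged = log10_transform(community.trait_table)
        results, gradients = dimension_pca(logged)
        assert list(gradients.scores.columns) == GRADIENT_NAMES
        assert np.allclose(gradients.scores.mean(), 0.0, atol=1e-10)
        assert len(results) == 3
        for name, dom in gradients.dominant.items():
            dim = name.split(".", 1)[1]
            assert all(t in logged.columns for t in dom.split("+"))
            assert results[dim] is not None

    def test_planted_latents_recovered(self, community):
        logged = log10_transform(community.trait_table)
        results, _ = dimension_pca(logged)
        for dim, res in results.items():
            truth = community.latents[PRIMARY_LATENT[dim]]
            r = np.corrcoef(res.scores["PC1"], truth)[0, 1]
            assert abs(r) >= 0.9, f"{dim}: |r|={abs(r):.3f}"


class TestPcaOfPcas:
    def test_isotropic_gradients(self):
        rng = np.random.default_rng(10)
        from nichespace.ordination import DimensionGradients

        scores = pd.DataFrame(rng.normal(size=(4000, 6)), columns=GRADIENT_NAMES)
        space = pca_of_pcas(DimensionGradients(scores=scores, dominant={}))
        assert np.allclose(space.eigenvalues, 1.0, atol=0.15)
        assert np.allclose(space.percent_variance, 100 / 6, atol=2.0)

    def test_variance_bookkeeping(self, pooled_analysis):
        _, space = pooled_analysis
        assert np.allclose(
            space.percent_variance, space.eigenvalues / 6 * 100, atol=1e-8
        )
        assert np.allclose(space.scores.mean(), 0.0, atol=1e-10)

    def test_planted_correlated_pair_dominates_pc1(self):
        # pc1.leaf_economy and pc2.mechanical_support correlated at r = -0.8,
        # the rest independent noise: those two carry the largest-magnitude
        # PC1 loadings with opposite signs
        rng = np.random.default_rng(11)
        from nichespace.ordination import DimensionGradients

        n = 400
        z = rng.normal(size=n)
        scores = pd.DataFrame(rng.normal(size=(n, 6)), columns=GRADIENT_NAMES)
        scores["pc1.leaf_economy"] = z + 0.5 * rng.normal(size=n)
        scores["pc2.mechanical_support"] = -z + 0.5 * rng.normal(size=n)
        space = pca_of_pcas(DimensionGradients(scores=scores, dominant={}))
        load = space.loadings["PC1"]
        top2 = load.abs().nlargest(2).index.tolist()
        assert set(top2) == {"pc1.leaf_economy", "pc2.mechanical_support"}
        assert load[top2[0]] * load[top2[1]] < 0

    def test_misaligned_gradient_rows_rejected(self):
        from nichespace.ordination import DimensionGradients

        scores = pd.DataFrame(np.ones((5, 6)), columns=GRADIENT_NAMES)
        scores.iloc[2, 0] = np.nan
        with pytest.raises(OrdinationError, match="missing"):
            pca_of_pcas(DimensionGradients(scores=scores, dominant={}))

    def test_small_biome_warns_and_pads_eigenvalues(self, community):
        cf = community.trait_table.subset("CF")
        with pytest.warns(UserWarning, match="only 6 species"):
            _, space = niche_space(cf)
        assert len(space.eigenvalues) == 6
        assert space.eigenvalues[-1] == 0.0  # rank deficit from n <= p
        assert space.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)


class TestSummaries:
    def test_report_schema(self, pooled_analysis):
        dim_results, space = pooled_analysis
        summary = summarize_space(space, dim_results)
        grads = [g.replace("_", " ") for g in GRADIENT_NAMES]
        assert list(summary.niche.index) == ["eigenvalue", "percent_variance"] + grads
        assert {"pc1_loading", "pc1_scaled", "pc1_dominant"} <= set(summary.niche.columns)
        assert len(summary.dimensions) == 6  # 3 dimensions x 2 axes
        by_dim = summary.dimensions.groupby("dimension")["percent"].sum()
        assert (by_dim <= 100 + 1e-9).all()

    def test_scaled_loadings_are_sqrt_eigenvalue_multiples(self, pooled_analysis):
        dim_results, space = pooled_analysis
        summary = summarize_space(space, dim_results)
        body = summary.niche.iloc[2:]
        ratio = body["pc1_scaled"] / body["pc1_loading"]
        assert np.allclose(ratio, np.sqrt(space.eigenvalues[0]), atol=1e-10)
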