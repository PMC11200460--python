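"""Supervised multiview CCA: block assembly, eigensolve, cross-loadings."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from presympto.errors import ConfigurationError, DataError
from presympto.smvcca import (
    MVCCASolution, ProjectedFeatures, ViewSet, build_block_matrices,
    build_label_view, cross_loading, cross_loading_report, make_viewset,
    pearson, project_views, rank_regions, solve_smvcca,
)


def two_view_cca_oracle(X, Y, eta):
    """Independent regularized two-view CCA via whitening + SVD.

    Views are column-centered and scaled by 1/sqrt(N-1) to match the block
    construction; returns (leading correlation, direction_x, direction_y).
    """
    n = X.shape[0]
    Xc = (X - X.mean(axis=0)) / np.sqrt(n - 1)
    Yc = (Y - Y.mean(axis=0)) / np.sqrt(n - 1)
    Cxx = Xc.T @ Xc + eta * np.eye(X.shape[1])
    Cyy = Yc.T @ Yc + eta * np.eye(Y.shape[1])
    Cxy = Xc.T @ Yc

    def inv_sqrt(A):
        w, V = np.linalg.eigh(A)
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Wx, Wy = inv_sqrt(Cxx), inv_sqrt(Cyy)
    U, S, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    return S[0], Wx @ U[:, 0], Wy @ Vt[0]


def random_viewset(seed, n=50, d=4, m=1, label_effect=1.0):
    rng = np.random.default_rng(seed)
    labels = ["diseased"] * (n // 2) + ["wild"] * (n - n // 2)
    shift = np.array([label_effect * (lab == "diseased") for lab in labels])
    views = []
    for _ in range(m):
        V = rng.standard_normal((n, d))
        V[:, 0] += shift
        views.append(V)
    label_view, _ = build_label_view(labels)
    return ViewSet(views=views, label_view=label_view,
                   region_names=tuple(f"R{i}" for i in range(m))), labels


class TestBuildLabelView:
    def test_study_class_counts(self):
        labels = ["diseased"] * 15 + ["wild"] * 10
        Z_l, order = build_label_view(labels)
        assert order == ("wild", "diseased")
        np.testing.assert_array_equal(Z_l.sum(axis=0), [10.0, 15.0])

    def test_rows_one_hot(self):
        Z_l, _ = build_label_view(["wild", "diseased", "wild"])
        np.testing.assert_array_equal(Z_l.sum(axis=1), np.ones(3))

    def test_consistent_relabeling_permutes_columns(self):
        a, order_a = build_label_view(["wild", "diseased", "diseased"])
        b, order_b = build_label_view(["x", "y", "y"])
        perm = [order_b.index(s) for s in ("x", "y")]
        np.testing.assert_array_equal(
            a[:, [order_a.index("wild"), order_a.index("diseased")]],
            b[:, perm],
        )

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="2 classes"):
            build_label_view(["wild", "wild"])


class TestBuildBlockMatrices:
    def test_study_dimension(self, rng):
        n = 30
        views = [rng.standard_normal((n, 6)) for _ in range(9)]
        labels = ["diseased"] * 18 + ["wild"] * 12
        label_view, _ = build_label_view(labels)
        vs = ViewSet(views=views, label_view=label_view,
                     region_names=tuple(str(i) for i in range(9)))
        blocks = build_block_matrices(vs, eta=0.01)
        assert blocks.C_bar.shape == (56, 56)  # 9*6 + 2
        np.testing.assert_array_equal(blocks.C_bar, blocks.C_bar.T)

    def test_identical_views_share_blocks(self, rng):
        V = rng.standard_normal((20, 3))
        labels = ["diseased"] * 10 + ["wild"] * 10
        label_view, _ = build_label_view(labels)
        vs = ViewSet(views=[V, V.copy()], label_view=label_view,
                     region_names=("a", "b"))
        blocks = build_block_matrices(vs, eta=0.0)
        off = blocks.C_bar[blocks.block_slices[0], blocks.block_slices[1]]
        diag = blocks.C_under[blocks.block_slices[0], blocks.block_slices[0]]
        np.testing.assert_allclose(off, diag, atol=1e-12)

    def test_against_brute_force_assembly(self, rng):
        vs, _ = random_viewset(3, n=15, d=2, m=3)
        blocks = build_block_matrices(vs, eta=0.01)
        processed = []
        for V in [*vs.views, vs.label_view]:
            Vc = V - V.mean(axis=0)
            processed.append(Vc / np.sqrt(vs.n - 1))
        for a, sa in enumerate(blocks.block_slices):
            for b, sb in enumerate(blocks.block_slices):
                expected = processed[a].T @ processed[b]
                if a == b:
                    np.testing.assert_allclose(
                        blocks.C_under[sa, sb], expected, atol=1e-12)
                    np.testing.assert_allclose(
                        blocks.C_bar[sa, sb], 0.0, atol=1e-12)
                else:
                    np.testing.assert_allclose(
                        blocks.C_bar[sa, sb], expected, atol=1e-12)
                    np.testing.assert_allclose(
                        blocks.C_under[sa, sb], 0.0, atol=1e-12)


class TestSolveSmvcca:
    @pytest.mark.parametrize("seed", range(20))
    def test_single_view_matches_two_view_cca_oracle(self, seed):
        vs, _ = random_viewset(seed, n=50, d=4, m=1)
        blocks = build_block_matrices(vs, eta=0.01)
        sol = solve_smvcca(blocks, d_p=2)
        s1, wx, wy = two_view_cca_oracle(vs.views[0], vs.label_view, 0.01)
        assert sol.eigenvalues[0] == pytest.approx(s1, abs=1e-8)
        # leading direction per view, up to sign and the 1/sqrt(2) stacking
        for block, oracle_dir in ((sol.V_blocks[0][:, 0], wx),
                                  (sol.V_blocks[1][:, 0], wy)):
            u = block / np.linalg.norm(block)
            v = oracle_dir / np.linalg.norm(oracle_dir)
            assert min(np.linalg.norm(u - v), np.linalg.norm(u + v)) < 1e-8

    def test_self_correlation_limit(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 1))
        vs = ViewSet(views=[x], label_view=x.copy(), region_names=("r",))
        blocks = build_block_matrices(vs, eta=1e-10)
        sol = solve_smvcca(blocks, d_p=1)
        assert sol.eigenvalues[0] == pytest.approx(1.0, abs=1e-6)

    def test_eta_recorded_and_residual_enforced(self):
        vs, _ = random_viewset(7, m=3)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        assert sol.eta == 0.01
        assert sol.residual < 1e-8

    def test_label_sign_convention(self):
        vs, _ = random_viewset(11, m=2)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        for c in range(sol.d_p):
            col = sol.V_blocks[-1][:, c]
            nz = col[np.abs(col) > 1e-12]
            if nz.size:
                assert nz[0] > 0

    def test_dp_out_of_range(self):
        vs, _ = random_viewset(1, m=2)
        with pytest.raises(ConfigurationError, match="d_p"):
            solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=3)

    def test_positive_scaling_invariance(self):
        # with per-view normalization (block diagonal) and negligible eta,
        # rescaling any single view leaves the canonical correlations alone
        vs, labels = random_viewset(5, m=3)
        sol = solve_smvcca(build_block_matrices(vs, eta=1e-10), d_p=2)
        scaled_views = [V.copy() for V in vs.views]
        scaled_views[1] *= 7.5
        scaled = ViewSet(views=scaled_views, label_view=vs.label_view,
                         region_names=vs.region_names)
        sol_scaled = solve_smvcca(build_block_matrices(scaled, eta=1e-10),
                                  d_p=2)
        np.testing.assert_allclose(
            sol.eigenvalues, sol_scaled.eigenvalues, atol=1e-6)


class TestProjectViews:
    def test_concatenated_width(self):
        vs, _ = random_viewset(2, m=9, d=6)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        proj = project_views(sol, vs)
        assert proj.concatenated.shape == (vs.n, 18)

    def test_projection_deterministic(self):
        vs, _ = random_viewset(4, m=2)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        a = project_views(sol, vs).concatenated
        b = project_views(sol, vs).concatenated
        np.testing.assert_array_equal(a, b)

    def test_identity_projection(self):
        vs, _ = random_viewset(6, m=1, d=4)
        blocks = build_block_matrices(vs, eta=0.01)
        sol = MVCCASolution(
            V_blocks=[np.eye(4)[:, :2], np.eye(2)],
            eigenvalues=np.array([1.0, 0.5]), d_p=2, eta=0.01,
            residual=0.0, block_slices=blocks.block_slices,
            means=[np.zeros(4), np.zeros(2)], centering=False,
        )
        proj = project_views(sol, vs)
        np.testing.assert_array_equal(proj.per_view[0], vs.views[0][:, :2])


class TestCrossLoading:
    def test_self_copy_gives_unit_loading(self, rng):
        z = rng.standard_normal(30)
        view = np.column_stack([z, z, z])
        _, cl = cross_loading(view, z)
        assert cl == pytest.approx(1.0)

    def test_sign_flip_invariant_under_absolute_aggregation(self, rng):
        z = rng.standard_normal(30)
        view = np.column_stack([-z, -z])
        corrs, cl = cross_loading(view, z)
        np.testing.assert_allclose(corrs, -1.0)
        assert cl == pytest.approx(1.0)
        _, cl_signed = cross_loading(view, z, aggregation="signed_mean")
        assert cl_signed == pytest.approx(-1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_direct_pearson_formula(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((10, 3))
        h = rng.standard_normal(10)
        corrs, cl = cross_loading(g, h)
        for d in range(3):
            gc = g[:, d] - g[:, d].mean()
            hc = h - h.mean()
            direct = (gc @ hc) / np.sqrt((gc @ gc) * (hc @ hc))
            assert corrs[d] == pytest.approx(direct, abs=1e-12)
        assert cl == pytest.approx(np.abs(corrs).mean(), abs=1e-12)

    def test_constant_column_contributes_zero_with_warning(self, rng):
        view = np.column_stack([np.full(10, 2.0), rng.standard_normal(10)])
        with pytest.warns(UserWarning, match="constant"):
            corrs, _ = cross_loading(view, rng.standard_normal(10))
        assert corrs[0] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError, match="N >= 3"):
            cross_loading(np.zeros((2, 2)), np.zeros(2))

    def test_joint_sample_permutation_invariance(self, rng):
        vs, _ = random_viewset(8, m=3)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        proj = project_views(sol, vs)
        report = cross_loading_report(vs, proj)
        perm = rng.permutation(vs.n)
        vs_p = ViewSet(views=[V[perm] for V in vs.views],
                       label_view=vs.label_view[perm],
                       region_names=vs.region_names)
        proj_p = ProjectedFeatures(
            per_view=[V[perm] for V in proj.per_view],
            label_projection=proj.label_projection[perm],
            region_names=proj.region_names, d_p=proj.d_p)
        report_p = cross_loading_report(vs_p, proj_p)
        np.testing.assert_allclose(report["CL"], report_p["CL"], atol=1e-12)


class TestRankRegions:
    def test_descending_with_canonical_tie_break(self):
        import pandas as pd
        report = pd.DataFrame({
            "region": ["A", "B", "C", "D"],
            "CL": [0.4, 0.7, 0.4, 0.9],
        })
        assert rank_regions(report) == ["D", "B", "A", "C"]

    def test_all_equal_returns_canonical_order(self):
        import pandas as pd
        report = pd.DataFrame({"region": list("wxyz"), "CL": [0.5] * 4})
        assert rank_regions(report) == list("wxyz")

    def test_informative_regions_outrank_noise(self, small_cohort,
                                               small_observed):
        from presympto.features import FEATURE_NAMES, standardize_columns
        obs, _, _ = standardize_columns(small_observed)
        row_labels = [small_cohort.labels[m] for m in obs.row_meta["mouse"]]
        vs = make_viewset(obs.X, obs.regions, obs.d, row_labels)
        sol = solve_smvcca(build_block_matrices(vs, eta=0.01), d_p=2)
        proj = project_views(sol, vs)
        report = cross_loading_report(vs, proj, feature_names=FEATURE_NAMES)
        assert set(rank_regions(report)[:2]) == {"A", "B"}
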