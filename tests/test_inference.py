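"""Spin tests, FDR, age maps, axis correlations, GLM, TFCE, permutation FWER."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thalagrad import inference, synthetic
from thalagrad.core import ConnectivityMatrix
from thalagrad.inference import (
    DesignMatrix,
    SpinPermutationSet,
    axis_correlation,
    fdr_bh,
    glm_tmap,
    group_scalar_ancova,
    make_spins,
    permutation_fwer,
    spin_test,
    tfce_enhance,
    vertex_totals,
)


def moran_lag1(mesh, full_map):
    """Edge-level lag-1 spatial autocorrelation over the cortex."""
    e = mesh.edges()
    ok = mesh.cortex_mask[e].all(axis=1)
    z = full_map - full_map[mesh.cortex_mask].mean()
    return (z[e[ok, 0]] * z[e[ok, 1]]).mean() / z[mesh.cortex_mask].var()


class TestMakeSpins:
    def test_identity_rotation_gives_identity_map(self, mesh2):
        from scipy.spatial import cKDTree

        sphere = mesh2.sphere_coords[mesh2.cortex_indices]
        idx = inference._spin_indices(sphere, cKDTree(sphere), np.eye(3))
        assert np.array_equal(idx, np.arange(len(sphere)))

    def test_indices_valid_and_reproducible(self, mesh2):
        spins = make_spins(mesh2, 10, rng_seed=4)
        n = len(spins.cortex_indices)
        assert spins.indices.shape == (10, n)
        assert spins.indices.min() >= 0 and spins.indices.max() < n
        again = make_spins(mesh2, 10, rng_seed=4)
        assert np.array_equal(spins.indices, again.indices)

    def test_spins_preserve_spatial_autocorrelation(self, mesh3):
        """Spun smooth maps keep the original's lag-1 autocorrelation within 25%."""
        smooth = synthetic.random_smooth_maps(mesh3, 1, fwhm=20.0, rng_seed=0)[0]
        original = moran_lag1(mesh3, smooth)
        spins = make_spins(mesh3, 2, rng_seed=1)
        for p in range(2):
            spun = np.zeros_like(smooth)
            spun[spins.cortex_indices] = smooth[spins.cortex_indices][spins.indices[p]]
            assert abs(moran_lag1(mesh3, spun) - original) <= 0.25 * abs(original)


class TestSpinTest:
    def test_self_correlation_is_one(self, mesh2):
        m = synthetic.random_smooth_maps(mesh2, 1, fwhm=25.0, rng_seed=2)[0]
        spins = make_spins(mesh2, 20, rng_seed=0)
        r, p = spin_test(m, m, spins)
        assert r == pytest.approx(1.0)

    def test_add_one_formula_single_permutation(self, mesh2):
        """With one spin whose null |r| < |r_obs|, each directional p is 1/2."""
        cortex = mesh2.cortex_indices
        n = len(cortex)
        rng = np.random.default_rng(3)
        a = rng.normal(size=n)
        # a permutation chosen so the spun correlation is (almost surely) weaker
        idx = rng.permutation(n)[np.newaxis, :]
        spins = SpinPermutationSet(idx, cortex, rng_seed=0)
        r, p = spin_test(a, a, spins)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.5)

    def test_constant_map_rejected(self, mesh2):
        spins = make_spins(mesh2, 5, rng_seed=0)
        with pytest.raises(ValueError, match="constant"):
            spin_test(np.ones(mesh2.n_vertices), np.ones(mesh2.n_vertices), spins)


def brute_force_bh(p, q):
    """Textbook step-up rule: reject the i smallest iff max{i: p_(i) <= iq/m}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    return reject


class TestFdrBH:
    def test_hand_executed_example(self):
        p = np.array([0.001, 0.4, 0.9])
        adj, reject = fdr_bh(p, q=0.05)
        assert reject.tolist() == [True, False, False]
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)

    def test_all_ones_rejects_nothing_and_empty_input(self):
        _, reject = fdr_bh(np.ones(6), q=0.05)
        assert not reject.any()
        adj, reject = fdr_bh(np.array([]))
        assert adj.size == 0 and reject.size == 0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10**6), m=st.integers(1, 40),
           q=st.sampled_from([0.01, 0.05, 0.1, 0.2]))
    def test_matches_brute_force_step_up(self, seed, m, q):
        p = np.random.default_rng(seed).random(m)
        _, reject = fdr_bh(p, q=q)
        assert np.array_equal(reject, brute_force_bh(p, q))


class TestAgeCorrelationMap:
    def test_perfect_linear_relationship(self):
        ages = np.linspace(30, 44, 12)
        values = np.outer(2 * ages, np.ones(5))
        sm = inference.age_correlation_map(values, ages, domain="thalamus")
        assert np.allclose(sm.values, 1.0)
        assert sm.mask.all()

    def test_constant_element_excluded_from_family(self):
        rng = np.random.default_rng(1)
        ages = np.linspace(30, 44, 10)
        values = rng.normal(size=(10, 4))
        values[:, 2] = 7.0
        sm = inference.age_correlation_map(values, ages, domain="cortex")
        assert np.isnan(sm.values[2]) and np.isnan(sm.p_adjusted[2])
        assert not sm.mask[2]

    def test_null_calibration_fdr(self):
        """Permuted ages: average FDR-masked discovery proportion stays near zero."""
        rng = np.random.default_rng(2)
        props = []
        for _ in range(100):
            values = rng.normal(size=(20, 30))
            ages = rng.permutation(np.linspace(29, 45, 20))
            sm = inference.age_correlation_map(values, ages, domain="cortex")
            props.append(sm.mask.mean())
        assert np.mean(props) <= 0.05

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            inference.age_correlation_map(np.ones((2, 3)), np.array([30.0, 40.0]),
                                          domain="cortex")


class TestAxisCorrelation:
    def test_coordinate_itself_correlates_perfectly(self, grid_small):
        r, p = axis_correlation(grid_small.coordinates[:, 1], grid_small, "y")
        assert r == pytest.approx(1.0)

    def test_residualized_values_uncorrelated(self, grid_small):
        rng = np.random.default_rng(3)
        v = rng.normal(size=grid_small.n_seeds)
        x = np.column_stack([np.ones(grid_small.n_seeds), grid_small.coordinates])
        v = v - x @ np.linalg.lstsq(x, v, rcond=None)[0]
        for axis in "xyz":
            r, _ = axis_correlation(v, grid_small, axis)
            assert abs(r) < 0.05

    def test_planted_component1_follows_xy_axes(self, grid_small, planted_small):
        s1 = planted_small.true_scores[:, 0]
        rx, _ = axis_correlation(s1, grid_small, "x")
        ry, _ = axis_correlation(s1, grid_small, "y")
        assert abs(rx) >= 0.5 and abs(ry) >= 0.5

    def test_invalid_axis(self, grid_small):
        with pytest.raises(ValueError):
            axis_correlation(np.zeros(grid_small.n_seeds), grid_small, "w")


class TestVertexTotals:
    def test_matches_brute_force_and_trivial_cases(self):
        single = ConnectivityMatrix(np.array([[1.0, 2.0, 0.5]]), [0], np.arange(3),
                                    state="smoothed")
        assert np.allclose(vertex_totals(single), [1.0, 2.0, 0.5])
        ones = ConnectivityMatrix(np.ones((3, 4)), np.arange(3), np.arange(4),
                                  state="filtered")
        assert np.allclose(vertex_totals(ones), 3.0)
        rng = np.random.default_rng(4)
        v = rng.random((6, 9))
        mat = ConnectivityMatrix(v, np.arange(6), np.arange(9), state="smoothed")
        expected = [sum(v[i][j] for i in range(6)) for j in range(9)]
        assert np.allclose(vertex_totals(mat), expected)

    def test_proportion_mode_sums_to_one(self):
        rng = np.random.default_rng(5)
        mat = ConnectivityMatrix(rng.random((5, 8)), np.arange(5), np.arange(8),
                                 state="filtered")
        prop = vertex_totals(mat, proportion=True)
        assert prop.sum() == pytest.approx(1.0)
        assert np.allclose(prop, vertex_totals(mat) / vertex_totals(mat).sum())

    def test_rejects_normalized_state(self):
        mat = ConnectivityMatrix(np.ones((3, 4)), np.arange(3), np.arange(4),
                                 state="normalized")
        with pytest.raises(ValueError):
            vertex_totals(mat)


def two_group_design(n_per_group):
    g = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    x = np.column_stack([np.ones(2 * n_per_group), g])
    return DesignMatrix(x, np.array([0.0, 1.0]), ["intercept", "group"])


class TestGlmTmap:
    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(30, 25))
        design = two_group_design(15)
        sm = glm_tmap(y, design)
        t_ref = stats.ttest_ind(y[15:], y[:15], equal_var=True)
        assert np.allclose(sm.values, t_ref.statistic, atol=1e-10)
        assert np.allclose(sm.p, t_ref.pvalue, atol=1e-10)

    def test_zero_residual_degenerate_fit_warns(self):
        design = two_group_design(4)
        y = np.repeat([[0.0], [1.0]], 4, axis=0)  # exact group effect, no noise
        with pytest.warns(UserWarning, match="zero-residual"):
            sm = glm_tmap(y, design)
        assert np.isinf(sm.values[0]) and sm.values[0] > 0

    def test_permuting_group_leaves_reduced_fit_unchanged(self):
        """The covariates-only fit is invariant to the group labels."""
        rng = np.random.default_rng(6)
        n = 20
        y = rng.normal(size=(n, 8))
        age = np.linspace(29, 45, n)
        z = np.column_stack([np.ones(n), age])
        fit = z @ np.linalg.lstsq(z, y, rcond=None)[0]
        for _ in range(3):
            order = rng.permutation(n)  # permuted labels never enter z
            fit2 = z @ np.linalg.lstsq(z, y, rcond=None)[0]
            assert np.array_equal(fit, fit2)

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(x, np.array([0.0, 1.0]))


class TestTfce:
    def test_single_vertex_closed_form(self, mesh1):
        """Isolated peak: enhanced value equals sum over h of h^H * area^E * dh."""
        v = int(mesh1.cortex_indices[0])
        t = np.zeros(mesh1.n_vertices)
        h0 = 3.0
        t[v] = h0
        enhanced = tfce_enhance(t, mesh1, H=2.0, E=0.5)
        area = mesh1.vertex_areas()[v]
        dh = h0 / 100
        hs = np.arange(dh, h0 + 1e-9, dh)
        expected = np.sum(hs**2 * area**0.5 * dh)
        assert enhanced[v] == pytest.approx(expected, rel=0.01)
        assert np.all(enhanced[np.arange(len(t)) != v] == 0)

    def test_all_zero_map(self, mesh1):
        assert np.all(tfce_enhance(np.zeros(mesh1.n_vertices), mesh1) == 0)

    def test_disjoint_clusters_are_local(self, mesh2):
        """Deleting one cluster leaves the other cluster's enhancement unchanged."""
        sphere = mesh2.sphere_coords
        cap_a = (sphere @ np.array([1.0, 0, 0]) > 0.9) & mesh2.cortex_mask
        cap_b = (sphere @ np.array([-1.0, 0, 0]) > 0.9) & mesh2.cortex_mask
        both = np.zeros(mesh2.n_vertices)
        both[cap_a] = 2.0
        both[cap_b] = 3.0
        only_a = np.where(cap_a, both, 0.0)
        dh = 3.0 / 100  # common threshold ladder for comparability
        e_both = tfce_enhance(both, mesh2, dh=dh)
        e_a = tfce_enhance(only_a, mesh2, dh=dh)
        assert np.allclose(e_both[cap_a], e_a[cap_a])

    def test_negative_values_enhanced_symmetrically(self, mesh2):
        m = synthetic.random_smooth_maps(mesh2, 1, fwhm=25.0, rng_seed=7)[0]
        assert np.allclose(tfce_enhance(-m, mesh2), -tfce_enhance(m, mesh2))

    def test_pointwise_monotonicity(self, mesh1):
        rng = np.random.default_rng(8)
        dh = 0.05
        for _ in range(5):
            lo = rng.random(mesh1.n_vertices)
            hi = lo + rng.random(mesh1.n_vertices)
            lo[mesh1.medial_mask] = hi[mesh1.medial_mask] = 0.0
            assert np.all(tfce_enhance(hi, mesh1, dh=dh) >=
                          tfce_enhance(lo, mesh1, dh=dh) - 1e-12)

    def test_non_finite_rejected(self, mesh1):
        bad = np.zeros(mesh1.n_vertices)
        bad[0] = np.inf
        with pytest.raises(ValueError):
            tfce_enhance(bad, mesh1)


class TestPermutationFwer:
    def design(self, n, rng):
        g = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        age = rng.uniform(29, 45, n)
        x = np.column_stack([np.ones(n), g, age])
        return DesignMatrix(x, np.array([0.0, 1.0, 0.0]))

    def test_overwhelming_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(9)
        n, m = 24, 15
        design = self.design(n, rng)
        y = rng.normal(size=(n, m))
        y[design.matrix[:, 1] == 1, 0] += 50.0
        sm = permutation_fwer(y, design, n_perm=99, rng_seed=0)
        assert sm.p[0] == pytest.approx(1.0 / 100.0)
        assert sm.mask[0]

    def test_p_monotone_in_observed_statistic(self):
        rng = np.random.default_rng(10)
        design = self.design(30, rng)
        y = rng.normal(size=(30, 40))
        sm = permutation_fwer(y, design, n_perm=60, rng_seed=1)
        order = np.argsort(np.abs(sm.values))
        assert np.all(np.diff(sm.p[order]) <= 1e-12)

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(11)
        design = self.design(12, rng)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_fwer(rng.normal(size=(12, 5)), design, n_perm=10, rng_seed=0)


class TestGroupScalarAncova:
    def design(self, n, rng, group=None):
        g = group if group is not None else np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        age = rng.uniform(29, 45, n)
        sex = rng.integers(0, 2, n).astype(float)
        x = np.column_stack([np.ones(n), g, age, sex])
        return DesignMatrix(x, np.array([0.0, 1.0, 0.0, 0.0]))

    def test_orthogonal_group_gives_near_zero_f(self):
        rng = np.random.default_rng(12)
        n = 40
        design = self.design(n, rng)
        v = rng.normal(size=n)
        x = design.matrix
        # residualize values against the group column (and intercept)
        zg = np.column_stack([x[:, 0], x[:, 1]])
        v = v - zg @ np.linalg.lstsq(zg, v, rcond=None)[0]
        # remove covariate columns' overlap too, keeping exact orthogonality to group
        f, p = group_scalar_ancova(v, self.design(n, np.random.default_rng(12)))
        assert p > 0.05

    def test_exact_group_difference_degenerate(self):
        rng = np.random.default_rng(13)
        g = np.r_[np.zeros(10), np.ones(10)]
        design = DesignMatrix(np.column_stack([np.ones(20), g]), np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="zero-residual"):
            f, p = group_scalar_ancova(g * 2.0, design)
        assert np.isinf(f)

    def test_power_matches_noncentral_f(self):
        """Empirical power at a known group shift tracks the noncentral-F curve."""
        rng = np.random.default_rng(14)
        n, delta, n_rep = 100, 0.6, 500
        g = np.r_[np.zeros(50), np.ones(50)]
        rejections = 0
        for _ in range(n_rep):
            design = self.design(n, rng, group=g)
            v = rng.normal(size=n) + delta * g
            _, p = group_scalar_ancova(v, design)
            rejections += p < 0.05
        # noncentrality for a balanced two-group contrast: n/4 * delta^2
        lam = n / 4 * delta**2
        df2 = n - 4
        crit = stats.f.isf(0.05, 1, df2)
        power = stats.ncf.sf(crit, 1, df2, lam)
        assert rejections / n_rep == pytest.approx(power, abs=0.05)
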