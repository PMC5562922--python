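"""Connectivity matrices, density thresholding, and sweep endpoint rules."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import cm_from_r
from fcnet.cohort import CohortSpec, generate_cohort
from fcnet.connectivity import (
    DensitySweep,
    build_sweep_networks,
    edge_budget,
    find_max_density_fdr,
    find_min_connected_density,
    pearson_connectivity,
    threshold_by_density,
)


class TestPearsonConnectivity:
    def test_hand_computed_correlation_and_p(self):
        """r from the raw covariance formula and p from t = r sqrt((n-2)/(1-r^2))."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        cm = pearson_connectivity(np.vstack([x, y]))
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        t_oracle = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), 3)
        assert cm.r[0, 1] == pytest.approx(r_oracle, abs=1e-12)
        assert cm.p[0, 1] == pytest.approx(p_oracle, rel=1e-10)
        assert cm.r[0, 0] == 0.0  # diagonal rule

    def test_copy_and_negation_extremes(self, rng):
        base = rng.standard_normal(30)
        ts = np.vstack([base, base, -base, rng.standard_normal(30)])
        cm = pearson_connectivity(ts)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)
        assert cm.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_region_named(self):
        ts = np.ones((3, 10))
        ts[0] = np.arange(10)
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            pearson_connectivity(ts)

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValueError, match="3 timepoints"):
            pearson_connectivity(rng.standard_normal((4, 2)))

    def test_symmetry_and_bounds(self, rng):
        cm = pearson_connectivity(rng.standard_normal((15, 40)))
        assert np.allclose(cm.r, cm.r.T)
        assert np.all(np.abs(cm.r) <= 1)
        off = ~np.eye(15, dtype=bool)
        assert np.all((cm.p[off] >= 0) & (cm.p[off] <= 1))


class TestThresholding:
    def test_edge_budget_default_sweep_n90(self):
        """Edge budgets over the default grid for 90 nodes, frozen from the
        round-half-away rule on 4005 possible edges."""
        sweep = DensitySweep()
        expected = [981, 1001, 1021, 1041, 1061, 1081,
                    1101, 1121, 1141, 1161, 1181, 1202]
        assert [edge_budget(float(d), 90) for d in sweep.densities] == expected

    def test_top_edges_against_sort_oracle(self, rng):
        r = np.array([
            [0.0, 0.9, 0.1, 0.5],
            [0.9, 0.0, 0.7, 0.2],
            [0.1, 0.7, 0.0, 0.8],
            [0.5, 0.2, 0.8, 0.0],
        ])
        net = threshold_by_density(cm_from_r(r), 0.5)  # budget = 3 of 6
        # oracle: exhaustive sort of the 6 pairs
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        top = sorted(pairs, key=lambda ij: -r[ij])[:3]
        assert net.n_edges == 3
        for i, j in top:
            assert net.adjacency[i, j] == 1

    def test_full_density_gives_complete_graph(self, rng):
        cm = pearson_connectivity(rng.standard_normal((6, 30)))
        net = threshold_by_density(cm, 0.999)
        assert net.n_edges == 15

    def test_zero_budget_density_errors(self, rng):
        cm = pearson_connectivity(rng.standard_normal((6, 30)))
        with pytest.raises(ValueError, match="empty edge budget"):
            threshold_by_density(cm, 0.01)

    def test_absolute_ranking_variant(self):
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = -0.9
        r[1, 2] = r[2, 1] = 0.4
        r[0, 2] = r[2, 0] = 0.1
        signed = threshold_by_density(cm_from_r(r), 0.34)  # 1 edge
        absolute = threshold_by_density(cm_from_r(r), 0.34, ranking="absolute")
        assert signed.adjacency[1, 2] == 1
        assert absolute.adjacency[0, 1] == 1

    def test_permutation_equivariance(self, rng):
        cm = pearson_connectivity(rng.standard_normal((10, 60)))
        perm = rng.permutation(10)
        r_p = cm.r[np.ix_(perm, perm)]
        p_p = cm.p[np.ix_(perm, perm)]
        net = threshold_by_density(cm, 0.3)
        net_p = threshold_by_density(cm_from_r(r_p, p_p), 0.3)
        np.testing.assert_array_equal(
            net.adjacency[np.ix_(perm, perm)], net_p.adjacency
        )


class TestDensitySweep:
    def test_default_grid_has_12_points(self):
        sweep = DensitySweep()
        assert len(sweep) == 12
        assert sweep.densities[0] == pytest.approx(0.245)
        assert sweep.densities[-1] == pytest.approx(0.300)
        assert np.allclose(np.diff(sweep.densities), 0.005)

    def test_sweep_networks_nested_and_counted(self, rng):
        cm = pearson_connectivity(rng.standard_normal((90, 100)))
        nets = build_sweep_networks(cm, DensitySweep())
        assert len(nets) == 12
        counts = [n.n_edges for n in nets]
        assert counts == [981, 1001, 1021, 1041, 1061, 1081,
                          1101, 1121, 1141, 1161, 1181, 1202]
        for lo, hi in zip(nets, nets[1:]):
            assert np.all(hi.adjacency >= lo.adjacency)  # edge-set inclusion


class TestMinConnectedDensity:
    def test_matches_grid_scan_oracle(self, rng):
        """Independent oracle: check all-subject connectivity at every grid
        density with networkx and take the smallest."""
        import networkx as nx

        cms = [pearson_connectivity(rng.standard_normal((20, 30)))
               for _ in range(4)]
        step = 0.02
        result = find_min_connected_density(cms, step)
        oracle = None
        for k in range(1, 50):
            d = k * step
            if edge_budget(d, 20) == 0:
                continue
            ok = all(
                nx.is_connected(nx.from_numpy_array(
                    threshold_by_density(cm, d).adjacency))
                for cm in cms
            )
            if ok:
                oracle = round(d, 10)
                break
        assert result == oracle

    def test_star_dominant_matrix_connects_at_first_grid_point(self):
        n = 8
        r = np.full((n, n), 0.01)
        for i in range(1, n):
            r[0, i] = r[i, 0] = 0.9 - 0.01 * i  # hub edges dominate
        cm = cm_from_r(r)
        # first grid point with budget >= n-1 hub edges
        assert find_min_connected_density([cm], 0.25) == 0.25

    def test_monotone_in_cohort_inclusion(self, rng):
        cms = [pearson_connectivity(rng.standard_normal((15, 40)))
               for _ in range(3)]
        d_small = find_min_connected_density(cms[:1], 0.01)
        d_full = find_min_connected_density(cms, 0.01)
        assert d_full >= d_small


class TestMaxDensityFdr:
    def _cm_with_p(self, pvals):
        """5-node matrix whose 10 unique pairs carry the given p-values."""
        n = 5
        r = np.zeros((n, n))
        p = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        r[iu] = np.linspace(0.9, 0.1, 10)
        p[iu] = pvals
        r += r.T
        p += p.T
        return cm_from_r(r, p)

    def test_extreme_p_values(self):
        assert find_max_density_fdr([self._cm_with_p(np.zeros(10))]) == 1.0
        assert find_max_density_fdr([self._cm_with_p(np.ones(10))]) == 0.0

    def test_step_up_hand_oracle(self):
        """BH at q=0.05 on (.001...005, .2..(6)) keeps exactly the first 5 of
        10 pairs: p_(5)=.005 <= 5*.05/10 and p_(6)=.2 > 6*.05/10."""
        p = [0.001, 0.002, 0.003, 0.004, 0.005, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert find_max_density_fdr([self._cm_with_p(p)], q=0.05) == 0.5

    def test_minimum_over_subjects(self):
        loose = self._cm_with_p(np.zeros(10))
        tight = self._cm_with_p([0.001] * 5 + [0.9] * 5)
        assert find_max_density_fdr([loose, tight]) == 0.5

    def test_monotone_in_q(self, rng):
        cm = pearson_connectivity(rng.standard_normal((12, 50)))
        fracs = [find_max_density_fdr([cm], q) for q in (0.01, 0.05, 0.2)]
        assert fracs == sorted(fracs)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            find_max_density_fdr([])


class TestEndpointRulesOnSyntheticCohort:
    def test_rules_produce_usable_sweep(self):
        """On a small strongly-correlated cohort the derived endpoints bracket
        a nonempty grid."""
        spec = CohortSpec(n_regions=15, n_per_group=3, n_timepoints=150,
                          rho_within=0.5, rho_between=0.15, delta=0.1,
                          delta_sd=0.0, behavior_coupling=0.0, seed=3)
        records, _ = generate_cohort(spec)
        cms = [pearson_connectivity(r) for r in records]
        d_min = find_min_connected_density(cms, 0.005)
        frac = find_max_density_fdr(cms, 0.05)
        assert 0 < d_min < 1
        assert d_min <= frac
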