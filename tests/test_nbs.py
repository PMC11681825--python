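"""NBS engine: edge-wise ANCOVA, effect sizes, components, permutation null."""

import numpy as np
import pytest
from scipy import stats as ss

from connstat.connectivity import BandDefinition
from connstat.io import FCBundle
from connstat.nbs import (
    DesignSpec,
    EdgewiseStats,
    NetworkBasedStatistic,
    ThresholdPolicy,
    edgewise_ancova,
    fwer_pvalue,
    omega_squared,
    permutation_null,
    run_nbs,
    suprathreshold_components,
)
from connstat.simulate import PlantedEffect, SimulationConfig, simulate_fc_directly

ALPHA = BandDefinition("alpha", 8.0, 13.0)


def _bundle_from_edge_values(values_per_subject, r, band="alpha"):
    """Build a bundle whose single-band matrices carry given edge vectors."""
    iu = np.triu_indices(r, 1)
    subjects = [f"S{i}" for i in range(len(values_per_subject))]
    matrices = {}
    for s, vals in zip(subjects, values_per_subject):
        m = np.zeros((r, r))
        m[iu] = vals
        m += m.T
        matrices[(s, band)] = m
    return FCBundle(subjects=subjects, bands=[band], matrices=matrices)


class TestEdgewiseAncova:
    def test_hand_anova_f_three_groups(self):
        # groups [1,2,3],[2,3,4],[3,4,5]: SSB=6 (df 2), SSW=6 (df 6) -> F=3
        y = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        bundle = _bundle_from_edge_values([[v] for v in y], r=2)
        design = DesignSpec(group=np.repeat(["a", "b", "c"], 3),
                            group_levels=["a", "b", "c"])
        stats = edgewise_ancova(bundle, "alpha", design)
        assert stats.F[0] == pytest.approx(3.0, abs=1e-10)
        assert stats.df_between == 2
        assert stats.df_error == 6

    def test_constant_edge_gives_zero_f(self):
        bundle = _bundle_from_edge_values([[0.4]] * 8, r=2)
        design = DesignSpec(group=np.repeat(["a", "b"], 4),
                            group_levels=["a", "b"])
        stats = edgewise_ancova(bundle, "alpha", design)
        assert stats.F[0] == 0.0

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(0)
        bundle = _bundle_from_edge_values(rng.uniform(0, 1, (8, 1)), r=2)
        group = np.repeat(["a", "b"], 4)
        cov = (group == "b").astype(float)  # identical to the dummy
        design = DesignSpec(group=group, group_levels=["a", "b"],
                            covariates=cov)
        with pytest.raises(ValueError, match="rank"):
            edgewise_ancova(bundle, "alpha", design)

    def test_two_group_f_equals_t_squared(self, rng):
        y = rng.uniform(0, 1, (20, 6))
        bundle = _bundle_from_edge_values(y, r=4)
        group = np.repeat(["a", "b"], 10)
        design = DesignSpec(group=group, group_levels=["a", "b"])
        stats = edgewise_ancova(bundle, "alpha", design)
        t = ss.ttest_ind(y[:10], y[10:]).statistic
        assert np.allclose(stats.F, t**2, atol=1e-10)

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            DesignSpec(group=np.array(["a", "b", "b"]),
                       group_levels=["a", "b"])


class TestOmegaSquared:
    def test_f_of_one_gives_zero(self):
        assert omega_squared(1.0, 3, 138) == 0.0

    def test_study_scale_value(self):
        # 3*(4.2-1) / (3*(4.2-1) + 138) = 9.6 / 147.6
        assert omega_squared(4.2, 3, 138) == pytest.approx(9.6 / 147.6, abs=1e-12)

    def test_sub_unity_f_floored(self):
        assert omega_squared(0.5, 3, 138) == 0.0

    def test_starting_threshold_from_medium_bound(self):
        pol = ThresholdPolicy()
        f0 = pol.starting_f(df_between=3, n=138)
        # smallest grid F whose omega-squared reaches 0.06
        assert omega_squared(f0, 3, 138) >= 0.06
        assert omega_squared(round(f0 - 0.1, 10), 3, 138) < 0.06
        assert ThresholdPolicy(f_initial=4.2).starting_f(3, 138) == 4.2


def _stats_from_f(f_edges, r):
    return EdgewiseStats(F=np.asarray(f_edges, dtype=float),
                         omega2=np.zeros(len(f_edges)),
                         df_between=3, df_error=40, n=48, n_regions=r)


def _bfs_components(edges, n):
    """Brute-force BFS oracle for connected components of an edge list."""
    adj = {v: set() for v in range(n)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), []
    nodes_with_edges = {v for e in edges for v in e}
    for start in sorted(nodes_with_edges):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset((min(i, j), max(i, j))
                               for i, j in edges if i in comp))
    return comps


class TestComponents:
    def test_toy_graph_two_components(self):
        r = 8
        iu = np.triu_indices(r, 1)
        f = np.zeros(len(iu[0]))
        lookup = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(*iu))}
        for e in [(0, 1), (1, 2), (5, 6)]:
            f[lookup[e]] = 10.0
        comps = suprathreshold_components(_stats_from_f(f, r), 5.0)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == [0, 1, 2]
        assert comps[1].edges == [(5, 6)]

    def test_no_edge_above_threshold(self):
        r = 5
        f = np.zeros(10)
        assert suprathreshold_components(_stats_from_f(f, r), 0.5) == []

    def test_complete_graph_component_size(self):
        r = 68
        e = r * (r - 1) // 2
        comps = suprathreshold_components(_stats_from_f(np.full(e, 9.0), r), 1.0)
        assert len(comps) == 1
        assert comps[0].size == 2278

    def test_strict_inequality_at_threshold(self):
        r = 3
        comps = suprathreshold_components(_stats_from_f([4.2, 0, 0], r), 4.2)
        assert comps == []

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        r = 12
        iu = np.triu_indices(r, 1)
        for _ in range(100):
            f = rng.uniform(0, 1, len(iu[0]))
            thr = rng.uniform(0.2, 0.9)
            comps = suprathreshold_components(_stats_from_f(f, r), thr)
            edges = [(int(i), int(j)) for i, j, v in zip(*iu, f) if v > thr]
            oracle = _bfs_components(edges, r)
            assert {frozenset(c.edges) for c in comps} == set(oracle)

    def test_max_size_monotone_in_threshold(self, rng):
        r = 10
        f = rng.uniform(0, 5, 45)
        sizes = []
        for thr in np.linspace(0, 5, 21):
            comps = suprathreshold_components(_stats_from_f(f, r), thr)
            sizes.append(comps[0].size if comps else 0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestFwerPvalue:
    def test_count_convention(self):
        assert fwer_pvalue(5, [1, 2, 5, 7, 9]) == pytest.approx(0.6)

    def test_extremes(self):
        assert fwer_pvalue(10, [1, 2, 3]) == 0.0
        assert fwer_pvalue(1, [1, 2, 3]) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            fwer_pvalue(3, [])


class TestPermutationNull:
    def test_deterministic_given_seed(self, small_null_cohort):
        bundle, cohort = small_null_cohort
        design = DesignSpec.from_cohort(cohort, ["age", "side"])
        a = permutation_null(bundle, "alpha", design, 2.1, n_perm=10, seed=5)
        b = permutation_null(bundle, "alpha", design, 2.1, n_perm=10, seed=5)
        assert np.array_equal(a, b)

    def test_degenerate_duplicated_subjects(self):
        # two identical subjects per group, zero noise: every relabelling
        # yields the same F map, so all null max sizes equal the observed
        base = np.array([0.2, 0.5, 0.8])
        vals = [base, base, base + 0.1, base + 0.1]
        bundle = _bundle_from_edge_values(vals, r=3)
        design = DesignSpec(group=np.array(["a", "a", "b", "b"]),
                            group_levels=["a", "b"])
        stats = edgewise_ancova(bundle, "alpha", design)
        comps = suprathreshold_components(stats, 1.0)
        null = permutation_null(bundle, "alpha", design, 1.0, n_perm=20, seed=0)
        # permutations either reproduce the observed grouping or a mixed one
        # with F=0; the maximum over sizes can never exceed the observed
        assert null.max() <= (comps[0].size if comps else 0)


class TestRunNBS:
    def test_scan_starts_at_f_initial_and_steps(self, small_null_cohort):
        bundle, cohort = small_null_cohort
        design = DesignSpec.from_cohort(cohort, ["age"])
        res = run_nbs(bundle, "alpha", design,
                      ThresholdPolicy(f_initial=4.2, alpha=1e-9),
                      n_perm=20, seed=0)
        fs = [t["f"] for t in res.scan_trace]
        assert fs[0] == pytest.approx(4.2)
        if len(fs) > 1:
            assert fs[1] == pytest.approx(4.3)
        steps = np.diff(fs)
        assert np.allclose(steps, 0.1)

    def test_planted_component_recovered(self):
        planted = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5),
                   (5, 6), (6, 7), (7, 8), (8, 9), (0, 9)]
        hits = 0
        for seed in range(1, 11):
            cfg = SimulationConfig(
                group_sizes={"A": 15, "B": 15, "C": 15, "D": 15},
                n_regions=20, seed=seed, bands=(ALPHA,))
            eff = PlantedEffect(band="alpha", edges=planted,
                                group_deltas={"A": 0.2})
            bundle, cohort = simulate_fc_directly(cfg, [eff])
            design = DesignSpec.from_cohort(cohort,
                                            ["age", "duration", "ledd", "side"])
            res = run_nbs(bundle, "alpha", design,
                          ThresholdPolicy(f_initial=6.0),
                          n_perm=100, seed=seed, scan=False)
            if res.significant:
                det, pl = set(res.component.edges), set(planted)
                if len(det & pl) / len(det | pl) >= 0.5:
                    hits += 1
        assert hits >= 8

    def test_null_bundle_usually_not_significant(self, small_null_cohort):
        bundle, cohort = small_null_cohort
        design = DesignSpec.from_cohort(cohort, ["age", "duration"])
        res = run_nbs(bundle, "alpha", design, ThresholdPolicy(),
                      n_perm=100, seed=3, scan=False)
        assert res.p_fwer is None or res.p_fwer > 0.05 or not res.significant

    def test_no_network_result_carries_trace(self, small_null_cohort):
        bundle, cohort = small_null_cohort
        design = DesignSpec.from_cohort(cohort, [])
        res = run_nbs(bundle, "alpha", design,
                      ThresholdPolicy(f_initial=1e6), n_perm=5, seed=0)
        assert not res.significant
        assert res.component is None
        assert res.scan_trace[-1]["max_size"] == 0

    def test_estimator_api_matches_wrapper(self, small_null_cohort):
        bundle, cohort = small_null_cohort
        design = DesignSpec.from_cohort(cohort, ["age"])
        res = run_nbs(bundle, "alpha", design, ThresholdPolicy(),
                      n_perm=20, seed=7, scan=False)
        est = NetworkBasedStatistic(policy=ThresholdPolicy(), n_perm=20,
                                    scan=False, seed=7)
        est.fit(bundle.edge_matrix("alpha"), cohort.groups().to_numpy(),
                covariates=cohort.covariate_matrix(["age"]),
                group_levels=cohort.group_levels)
        assert np.allclose(est.f_, res.edgewise.F)
        assert est.result_.f_threshold == res.f_threshold
        assert est.result_.p_fwer == res.p_fwer
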