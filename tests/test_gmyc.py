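"""GMYC likelihood, threshold scan and support statistics.

The reference oracle below recomputes the mixed-likelihood by explicit
interval enumeration with per-interval branch counting (no shared code with
the implementation's per-process sufficient statistics).
"""

import numpy as np
import pytest

import gmycdelim as g
from gmycdelim.gmyc import GmycConfig, single_process_loglik

from .conftest import random_ultrametric_tree


def _crossings(tree, t):
    return [
        n
        for n in tree.nodes
        if n.parent is not None and n.age <= t < n.parent.age
    ]


def _subtree_labels(tree, node):
    return set(tree.clade_tips(node))


def oracle_loglik(tree, T, lam_spec, lam_coal, p_spec=1.0, p_coal=1.0):
    """Brute-force mixed log-likelihood by interval sweep.

    Events at age >= T are speciation, younger events coalescences inside
    the entity subtended by the branch crossing T above them.  Each event's
    waiting-time factor uses its process rate (rootward lineage count for
    speciation, tipward count for coalescence) and its ranked-topology
    factor 1/C(k_tipward, 2); exposure integrates the per-interval rates.
    """
    ages = sorted({n.age for n in tree.internal_nodes})
    breaks = sorted(set([0.0, T, tree.root_age] + ages))
    entity_roots = [
        n for n in tree.nodes
        if n.parent is not None and n.age < T <= n.parent.age
    ]
    clusters = []
    for r in entity_roots:
        members = {r} | {
            n for n in tree.nodes if n.parent is not None and _is_descendant(n, r)
        }
        clusters.append(members)

    def cluster_count(members, t):
        return sum(
            1 for n in members if n.parent is not None and n.age <= t < n.parent.age
        )

    eps_base = min(b - a for a, b in zip(breaks, breaks[1:]) if b > a) / 10.0

    ll = 0.0
    # exposure by midpoint counting
    for lo, hi in zip(breaks, breaks[1:]):
        if hi <= lo:
            continue
        mid = 0.5 * (lo + hi)
        dt = hi - lo
        if mid >= T:
            k = len(_crossings(tree, mid))
            ll -= lam_spec * (k ** p_spec) * dt
        else:
            for members in clusters:
                n = cluster_count(members, mid)
                if n >= 2:
                    ll -= lam_coal * ((n * (n - 1.0)) ** p_coal) * dt

    # event factors
    for node in tree.internal_nodes:
        a = node.age
        if a >= T:
            if node.parent is None:
                k_root = 1
            else:
                k_root = len(_crossings(tree, a + eps_base))
            k_tip = k_root + 1
            ll += np.log(lam_spec) + p_spec * np.log(max(k_root, 1))
            ll -= np.log(k_tip * (k_tip - 1) / 2.0)
        else:
            members = next(m for m in clusters if node in m)
            n = cluster_count(members, a - eps_base)
            ll += np.log(lam_coal) + p_coal * np.log(n * (n - 1.0))
            ll -= np.log(n * (n - 1) / 2.0)
    return ll


def _is_descendant(node, ancestor):
    p = node.parent
    while p is not None:
        if p is ancestor:
            return True
        p = p.parent
    return False


class TestLoglik:
    def test_hand_computed_four_tip_value(self, four_tip_tree):
        """Frozen value from an explicit hand interval decomposition:
        one speciation factor lam_s*1/C(2,2), two coalescence factors
        2*lam_c, speciation exposure 2*1.5, coalescent exposure 5*0.6."""
        ll = g.gmyc_loglik(four_tip_tree, 0.5, 1.0, 5.0)
        assert ll == pytest.approx(2 * np.log(10.0) - 6.0, abs=1e-12)

    def test_matches_oracle_on_four_tip_tree(self, four_tip_tree):
        got = g.gmyc_loglik(four_tip_tree, 0.5, 1.0, 5.0)
        want = oracle_loglik(four_tip_tree, 0.5, 1.0, 5.0)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle_on_random_small_trees(self, seed):
        """Exhaustive agreement with the interval-sweep oracle on <=5-tip
        trees over random age configurations, thresholds and rates."""
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree(rng, int(rng.integers(4, 6)))
        T = float(rng.uniform(0.05, 0.95)) * tree.root_age
        ls = float(rng.uniform(0.1, 5.0))
        lc = float(rng.uniform(0.1, 20.0))
        ps = float(rng.choice([1.0, 1.0, 1.5]))
        pc = float(rng.choice([1.0, 1.0, 0.8]))
        cfg = GmycConfig(p_spec=ps, p_coal=pc)
        got = g.gmyc_loglik(tree, T, ls, lc, cfg)
        want = oracle_loglik(tree, T, ls, lc, ps, pc)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_invariant_under_tip_relabeling(self, seed=3):
        rng = np.random.default_rng(seed)
        tree = random_ultrametric_tree(rng, 8)
        ll1 = g.gmyc_loglik(tree, 0.4 * tree.root_age, 1.0, 3.0)
        labels = tree.tip_labels
        perm = list(rng.permutation(labels))
        newick = tree.to_newick()
        for old, new in zip(labels, [f"tmp{i}" for i in range(len(labels))]):
            newick = newick.replace(old, new)
        for tmp, new in zip([f"tmp{i}" for i in range(len(labels))], perm):
            newick = newick.replace(tmp, new)
        tree2 = g.read_newick(newick)
        ll2 = g.gmyc_loglik(tree2, 0.4 * tree.root_age, 1.0, 3.0)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 2.0, 7.5])
    def test_rescaling_shifts_by_event_count_log_c(self, four_tip_tree, c):
        """Change of time units: ages and T scaled by c, rates by 1/c,
        shifts the log-likelihood by -(n_tips - 1) * ln c."""
        base = g.gmyc_loglik(four_tip_tree, 0.5, 1.0, 5.0)
        newick = "((A:{a},B:{a}):{b},(C:{c2},D:{c2}):{d});".format(
            a=0.1 * c, b=1.9 * c, c2=0.2 * c, d=1.8 * c
        )
        scaled_tree = g.read_newick(newick)
        scaled = g.gmyc_loglik(scaled_tree, 0.5 * c, 1.0 / c, 5.0 / c)
        n_events = four_tip_tree.n_tips - 1
        assert scaled == pytest.approx(base - n_events * np.log(c), rel=1e-9)

    def test_threshold_and_rate_domains(self, four_tip_tree):
        with pytest.raises(ValueError):
            g.gmyc_loglik(four_tip_tree, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            g.gmyc_loglik(four_tip_tree, 2.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            g.gmyc_loglik(four_tip_tree, 0.5, -1.0, 1.0)


class TestFit:
    def test_rate_grid_oracle(self, four_tip_tree):
        """The per-threshold closed-form rate MLE matches a 50x50 log-spaced
        grid search of gmyc_loglik (grid centred on events/exposure
        estimates computed independently)."""
        fit = g.fit_gmyc(four_tip_tree)
        assert len(fit.thresholds) == 1
        T = fit.threshold
        # independent moment estimates: events and exposures by sweep
        ls0 = fit.lam_spec[0]
        lc0 = fit.lam_coal[0]
        grid_s = np.logspace(np.log10(ls0) - 0.3, np.log10(ls0) + 0.3, 50)
        grid_c = np.logspace(np.log10(lc0) - 0.3, np.log10(lc0) + 0.3, 50)
        best = max(
            g.gmyc_loglik(four_tip_tree, T, a, b) for a in grid_s for b in grid_c
        )
        assert fit.max_loglik == pytest.approx(best, abs=1e-3)
        assert fit.max_loglik >= best - 1e-12

    def test_fit_reports_consistent_partition(self, four_tip_tree):
        fit = g.fit_gmyc(four_tip_tree)
        assert fit.n_entities_best == fit.partition.n_entities
        assert fit.n_entities_best == len(
            set(fit.partition.tip_to_entity.values())
        )
        assert set(fit.partition.tip_to_entity) == set(four_tip_tree.tip_labels)

    def test_weights_normalize(self):
        rng = np.random.default_rng(5)
        tree = random_ultrametric_tree(rng, 15)
        fit = g.fit_gmyc(tree)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fit.lam_spec > 0) and np.all(fit.lam_coal > 0)
        assert fit.aic == pytest.approx(6.0 - 2.0 * fit.loglik)

    def test_needs_four_tips(self, three_tip_tree):
        with pytest.raises(ValueError):
            g.fit_gmyc(three_tip_tree)

    def test_midpoint_rule_runs(self):
        rng = np.random.default_rng(7)
        tree = random_ultrametric_tree(rng, 10)
        fit = g.fit_gmyc(tree, GmycConfig(threshold_rule="midpoints"))
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cumulative_weight_ci_rule(self):
        rng = np.random.default_rng(8)
        tree = random_ultrametric_tree(rng, 10)
        fit = g.fit_gmyc(tree, GmycConfig(ci_rule="cumulative-weight-0.95"))
        lo, hi = fit.entity_count_range
        assert lo <= fit.n_entities_best <= hi

    def test_clear_separation_recovers_species_count(self):
        """Simulated trees with coalescent depths far below the speciation
        threshold: the scan finds the true entity count and the true
        threshold falls inside the reported range."""
        cfg = g.SimConfig(n_species=20, seed=42)
        tree, truth = g.sim_full_tree(cfg)
        fit = g.fit_gmyc(tree)
        assert fit.n_entities_best == 20
        assert fit.threshold_range[0] <= cfg.threshold <= fit.threshold_range[1]
        assert fit.max_loglik >= fit.null_loglik
        # entities correspond to the true species partition
        ent = fit.partition.tip_to_entity
        species = dict(zip(truth.tip_id, truth.species))
        mapping = {}
        for tip, e in ent.items():
            mapping.setdefault(e, set()).add(species[tip])
        assert all(len(v) == 1 for v in mapping.values())

    def test_single_population_tree_gives_weak_structure_signal(self):
        """On a pure-coalescent (one species) tree the LRT is far below the
        structured-data LRT and the entity-count confidence range is wide."""
        rng = np.random.default_rng(9)
        tree = random_ultrametric_tree(rng, 20)
        fit_null = g.fit_gmyc(tree)
        cfg = g.SimConfig(n_species=20, seed=9)
        tree_s, _ = g.sim_full_tree(cfg)
        fit_s = g.fit_gmyc(tree_s)
        assert fit_null.lrt < 0.2 * fit_s.lrt
        lo, hi = fit_null.entity_count_range
        assert hi - lo >= 1  # no single sharp partition


class TestNull:
    def test_null_loglik_matches_direct_formula(self, four_tip_tree):
        ll, lam = single_process_loglik(four_tip_tree)
        # independent: events at 0.1, 0.2, 2.0 with tipward counts 4, 3, 2
        exposure = 12 * 0.1 + 6 * 0.1 + 2 * 1.8
        lam_hat = 3 / exposure
        want = 3 * (np.log(lam_hat) - 1.0) + 3 * np.log(2.0)
        assert ll == pytest.approx(want, rel=1e-12)
        assert lam == pytest.approx(lam_hat, rel=1e-12)


class TestSupports:
    def test_supports_partition_unity(self):
        rng = np.random.default_rng(4)
        tree = random_ultrametric_tree(rng, 12)
        fit = g.fit_gmyc(tree)
        sup = g.split_supports(fit)
        total = sup.coalescence_support + sup.speciation_support
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_root_has_full_speciation_support(self):
        rng = np.random.default_rng(6)
        tree = random_ultrametric_tree(rng, 12)
        fit = g.fit_gmyc(tree)
        sup = g.split_supports(fit).set_index("node_id")
        root = tree.root.label
        assert sup.loc[root, "speciation_support"] == pytest.approx(1.0)
        assert sup.loc[root, "coalescence_support"] == pytest.approx(0.0)

    def test_node_younger_than_all_candidates_full_coalescence(self):
        cfg = g.SimConfig(n_species=10, seed=2)
        tree, _ = g.sim_full_tree(cfg)
        fit = g.fit_gmyc(tree)
        youngest = min(tree.internal_nodes, key=lambda n: n.age)
        sup = g.split_supports(fit).set_index("node_id")
        assert sup.loc[youngest.label, "coalescence_support"] == pytest.approx(1.0)

    def test_raising_cutoff_never_adds_strong_splits(self):
        rng = np.random.default_rng(10)
        tree = random_ultrametric_tree(rng, 15)
        fit = g.fit_gmyc(tree)
        counts = [
            int(g.split_supports(fit, strong_cutoff=c).strong.sum())
            for c in (0.80, 0.90, 0.95, 0.99)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
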