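import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import expm

import sexlinkage as sl
from sexlinkage.io_prep import SexlinkageError
from sexlinkage.phylo_turnover import (
    IndexedTree,
    _q_from_params,
    branch_posteriors,
    mk_loglik,
    state_probability_matrix,
)
from sexlinkage.synthetic_data import simulate_trait_history

from conftest import balanced_newick


def enumeration_loglik(tt, spm, q, prior):
    """Brute-force likelihood: sum over all internal-node state assignments."""
    it = IndexedTree.build(tt)
    k = spm.shape[1]
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    trans = {i: expm(q * it.blen[i]) for i in range(it.n_nodes) if it.parent[i] >= 0}
    tip_p = {nid: spm.loc[lab].to_numpy() for lab, nid in it.tip_ids.items()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = prior[st[0]]
        for i in range(it.n_nodes):
            if it.parent[i] < 0:
                continue
            ps = st[it.parent[i]]
            if i in st:
                pr *= trans[i][ps, st[i]]
            else:
                pr *= float(trans[i][ps] @ tip_p[i])
        total += pr
    return math.log(total)


class TestMkLikelihood:
    def test_two_tip_er_matches_transition_matrix_oracle(self):
        q_rate = 0.35
        t = 1.4
        tt = sl.timetree_from_string(f"(A:{t},B:{t});")
        spm = state_probability_matrix({"A": "s0", "B": "s1"}, ["s0", "s1"], ["A", "B"])
        q = _q_from_params(np.array([q_rate]), 2, "ER")
        it = IndexedTree.build(tt)
        ll = mk_loglik(it, spm, q, np.array([0.5, 0.5]))
        p = expm(q * t)
        lik = 0.5 * (p[0, 0] * p[0, 1] + p[1, 0] * p[1, 1])
        assert ll == pytest.approx(math.log(lik), abs=1e-10)

    @pytest.mark.parametrize("newick,k", [
        ("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", 3),
        ("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);", 3),
        ("((A:0.5,B:0.5):0.5,C:1);", 2),
    ])
    def test_pruning_equals_enumeration(self, newick, k):
        rng = np.random.default_rng(k)
        tt = sl.timetree_from_string(newick)
        tips = tt.tip_labels
        states = [f"s{i}" for i in range(k)]
        tip_states = {t: states[rng.integers(k)] for t in tips[:-1]}  # last tip soft
        spm = state_probability_matrix(tip_states, states, tips)
        q = _q_from_params(rng.random(k * (k - 1)) * 0.5, k, "ARD")
        prior = np.full(k, 1.0 / k)
        it = IndexedTree.build(tt)
        ll = mk_loglik(it, spm, q, prior)
        assert ll == pytest.approx(enumeration_loglik(tt, spm, q, prior), abs=1e-8)

    def test_uniform_tips_rates_collapse_to_zero(self):
        tt = sl.timetree_from_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        spm = state_probability_matrix(
            {t: "s0" for t in tt.tip_labels}, ["s0", "s1"], tt.tip_labels
        )
        fit = sl.fit_mk(tt, spm, "ER")
        assert fit.q[0, 1] < 1e-4
        assert fit.log_lik == pytest.approx(math.log(0.5), abs=1e-4)

    def test_aic_ordering_respects_nesting(self, balanced_tree16):
        rng = np.random.default_rng(2)
        states = ["s0", "s1", "s2"]
        tip_states = {t: states[rng.integers(3)] for t in balanced_tree16.tip_labels}
        spm = state_probability_matrix(tip_states, states, balanced_tree16.tip_labels)
        best, fits = sl.fit_mk_auto(balanced_tree16, spm)
        assert fits["ARD"].log_lik >= fits["SYM"].log_lik - 1e-9
        assert fits["SYM"].log_lik >= fits["ER"].log_lik - 1e-9
        assert best.aic == min(f.aic for f in fits.values())


class TestStochasticMaps:
    def setup_fit(self):
        tt = sl.timetree_from_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        spm = state_probability_matrix(
            {"A": "s0", "B": "s0", "C": "s1", "D": "s1"}, ["s0", "s1"], tt.tip_labels
        )
        fit = sl.fit_mk(tt, spm, "ER")
        return tt, spm, fit

    def test_same_seed_identical_maps(self):
        tt, spm, fit = self.setup_fit()
        a = sl.stochastic_maps(tt, fit, spm, n=10, seed=5)
        b = sl.stochastic_maps(tt, fit, spm, n=10, seed=5)
        assert all(
            x.events == y.events and (x.node_state == y.node_state).all()
            for x, y in zip(a, b)
        )

    def test_near_zero_rates_give_changeless_maps(self):
        tt = sl.timetree_from_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        spm = state_probability_matrix(
            {t: "s0" for t in tt.tip_labels}, ["s0", "s1"], tt.tip_labels
        )
        fit = sl.MkFit("ER", _q_from_params(np.array([1e-12]), 2, "ER"),
                       0.0, 0.0, 1, ["s0", "s1"])
        maps = sl.stochastic_maps(tt, fit, spm, n=50, seed=1)
        assert all(m.n_changes() == 0 for m in maps)

    def test_node_frequencies_match_marginal_posteriors(self):
        tt, spm, fit = self.setup_fit()
        maps = sl.stochastic_maps(tt, fit, spm, n=4000, seed=3)
        it = IndexedTree.build(tt)
        # marginal posterior of the root by enumeration over root states
        k = 2
        prior = np.full(k, 0.5)
        lik = np.zeros(k)
        for s in range(k):
            spm_root = spm.copy()
            num = enumeration_loglik_root_state(tt, spm, fit.q, prior, s)
            lik[s] = num
        post = lik / lik.sum()
        freq = np.mean([m.node_state[0] == 1 for m in maps])
        assert abs(freq - post[1]) < 0.02

    def test_mean_change_count_matches_analytic_expectation(self):
        """Uninformative tips: maps are prior draws, E[changes] = (k-1) q L."""
        tt = sl.timetree_from_string(balanced_newick(6, 6.0))
        states = ["s0", "s1"]
        spm = state_probability_matrix({}, states, tt.tip_labels)
        q_rate = 0.08
        fit = sl.MkFit("ER", _q_from_params(np.array([q_rate]), 2, "ER"),
                       0.0, 0.0, 1, states)
        maps = sl.stochastic_maps(tt, fit, spm, n=4000, seed=9)
        total_len = tt.total_branch_length()
        expected = q_rate * total_len
        mean = np.mean([m.n_changes() for m in maps])
        assert abs(mean - expected) / expected < 0.10


def enumeration_loglik_root_state(tt, spm, q, prior, root_state):
    it = IndexedTree.build(tt)
    k = spm.shape[1]
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    trans = {i: expm(q * it.blen[i]) for i in range(it.n_nodes) if it.parent[i] >= 0}
    tip_p = {nid: spm.loc[lab].to_numpy() for lab, nid in it.tip_ids.items()}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal) - 1):
        st = dict(zip(internal[1:], assign))
        st[0] = root_state
        pr = prior[root_state]
        for i in range(it.n_nodes):
            if it.parent[i] < 0:
                continue
            ps = st[it.parent[i]]
            pr *= trans[i][ps, st[i]] if i in st else float(trans[i][ps] @ tip_p[i])
        total += pr
    return total


class TestTurnoverDetection:
    def test_true_history_yields_exact_gain_count(self, balanced_tree16):
        """Fed its own planted history, detection returns the planted gains."""
        q = np.array([[-0.03, 0.03], [0.0, 0.0]])  # irreversible gain
        for seed in range(30):
            tips, hist = simulate_trait_history(
                balanced_tree16, ["no", "yes"], q, "no", seed=seed
            )
            gains = [e for e in hist.events if e[3] == 1]
            if not gains:
                continue
            spm = state_probability_matrix(tips, ["no", "yes"],
                                           balanced_tree16.tip_labels)
            events = sl.detect_turnovers([hist], balanced_tree16, spm, "yes")
            assert len(events) == len(gains)
            assert {e.branch for e in events} == {g[0] for g in gains}

    def test_matching_root_state_gives_no_events(self, balanced_tree16):
        spm = state_probability_matrix(
            {t: "yes" for t in balanced_tree16.tip_labels}, ["no", "yes"],
            balanced_tree16.tip_labels,
        )
        q = np.array([[0.0, 0.0], [0.0, 0.0]])
        node_state = np.ones(IndexedTree.build(balanced_tree16).n_nodes, dtype=int)
        hist = sl.CharacterHistory(node_state, [])
        events = sl.detect_turnovers([hist], balanced_tree16, spm, "yes")
        assert [e for e in events if not e.root_or_earlier] == []

    def test_sister_tips_share_one_stem_event(self, balanced_tree16):
        it = IndexedTree.build(balanced_tree16)
        # find a cherry: internal node whose children are both tips
        cherry = next(
            i for i in range(it.n_nodes)
            if it.children[i] and all(not it.children[c] for c in it.children[i])
        )
        node_state = np.zeros(it.n_nodes, dtype=int)
        node_state[cherry] = 1
        for c in it.children[cherry]:
            node_state[c] = 1
        t_mid = it.depth[it.parent[cherry]] + it.blen[cherry] / 2
        hist = sl.CharacterHistory(node_state, [(cherry, t_mid, 0, 1)])
        tips = {lab: ("yes" if node_state[nid] else "no")
                for lab, nid in it.tip_ids.items()}
        spm = state_probability_matrix(tips, ["no", "yes"], balanced_tree16.tip_labels)
        events = sl.detect_turnovers([hist] * 5, balanced_tree16, spm, "yes")
        assert len(events) == 1 and events[0].branch == cherry


class TestRates:
    def test_rate_arithmetic(self):
        tt = sl.timetree_from_string(balanced_newick(16, 10.0))
        # scale: construct a tree with total length 30 by using events only
        r = sl.estimate_rate([0] * 3, tt)
        assert r.rate_per_my == pytest.approx(3 / tt.total_branch_length())

    def test_published_rate_implies_divergence_time(self):
        """Rate 0.186/My predicts one turnover between species ~2.7 My apart."""
        star = "(" + ",".join(f"t{i}:5.0" for i in range(100)) + ");"
        tt = sl.timetree_from_string(star)  # total branch length 500 My
        r = sl.estimate_rate(list(range(93)), tt)  # 93/500 = 0.186 per My
        assert r.rate_per_my == pytest.approx(0.186)
        assert r.expected_divergence_my == pytest.approx(1 / (2 * 0.186))
        assert r.expected_divergence_my == pytest.approx(2.7, abs=0.02)

    def test_zero_length_tree_rejected(self):
        tt = sl.timetree_from_string("(A:0,B:0);")
        with pytest.raises(SexlinkageError, match="zero"):
            sl.estimate_rate([1], tt)


class TestTransitionAges:
    def test_exact_u_distribution(self):
        from sexlinkage.phylo_turnover import HeterogametyTransition as HT

        trans = [HT(1, a, "XY", "ZW") for a in (1.0, 2.0, 3.0)] + [
            HT(2, a, "ZW", "XY") for a in (10.0, 11.0, 12.0)
        ]
        res = sl.compare_transition_ages(trans)
        # exact two-sided p for complete separation at n=3,3: 2 * 1/C(6,3)
        assert res["p_value"] == pytest.approx(2 / 20)

    def test_identical_age_sets_p_one(self):
        from sexlinkage.phylo_turnover import HeterogametyTransition as HT

        trans = [HT(1, a, "XY", "ZW") for a in (1.0, 2.0)] + [
            HT(2, a, "ZW", "XY") for a in (1.0, 2.0)
        ]
        assert sl.compare_transition_ages(trans)["p_value"] == pytest.approx(1.0)

    def test_empty_direction_returns_none(self):
        from sexlinkage.phylo_turnover import HeterogametyTransition as HT

        assert sl.compare_transition_ages([HT(1, 1.0, "XY", "ZW")]) is None


class TestRecruitment:
    def test_expected_never_recruited_matches_binomial(self):
        lgs = sl.default_lg_table(23, 1_000_000)
        rt = sl.random_recruitment_test(30, lgs, n_sim=10_000, observed_never=10,
                                        seed=4)
        expected = 23 * (22 / 23) ** 30
        se = rt.never_counts.std(ddof=1) / np.sqrt(len(rt.never_counts))
        assert abs(rt.never_counts.mean() - expected) < 3 * se

    def test_per_lg_mean_proportional_to_length(self):
        lgs = pd.DataFrame(
            {"lg_id": ["a", "b"], "length_bp": [3_000_000, 1_000_000]}
        )
        rt = sl.random_recruitment_test(40, lgs, n_sim=20_000, observed_never=1, seed=2)
        assert rt.per_lg_mean["a"] == pytest.approx(30, rel=0.05)
        assert rt.per_lg_mean["b"] == pytest.approx(10, rel=0.05)

    def test_single_lg_never_unrecruited(self):
        lgs = sl.default_lg_table(1, 1_000_000)
        rt = sl.random_recruitment_test(5, lgs, n_sim=1000, observed_never=1, seed=1)
        assert rt.fraction_ge_observed == 0.0

    def test_deterministic_under_seed(self):
        lgs = sl.default_lg_table(23, 1_000_000)
        a = sl.random_recruitment_test(30, lgs, n_sim=2000, observed_never=9, seed=7)
        b = sl.random_recruitment_test(30, lgs, n_sim=2000, observed_never=9, seed=7)
        assert a.fraction_ge_observed == b.fraction_ge_observed

    def test_zero_events_rejected(self):
        lgs = sl.default_lg_table(3, 1_000)
        with pytest.raises(SexlinkageError, match="n_events"):
            sl.random_recruitment_test(0, lgs, 100, 1, seed=1)


class TestPgls:
    def test_star_phylogeny_equals_ols(self):
        star = sl.timetree_from_string("(A:1,B:1,C:1,D:1,E:1,F:1);")
        labels = ["A", "B", "C", "D", "E", "F"]
        rng = np.random.default_rng(8)
        x = rng.random(6)
        y = 1.5 * x + rng.normal(0, 0.2, 6)
        fit = sl.pgls_fit(y, x, star, labels)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.coefficient == pytest.approx(slope, abs=1e-8)
        # OLS t-test oracle
        ols = stats.linregress(x, y)
        assert fit.p_value == pytest.approx(ols.pvalue, abs=1e-8)

    def test_exact_linear_relation(self, balanced_tree16):
        labels = balanced_tree16.tip_labels
        x = np.arange(len(labels), dtype=float)
        y = 2.0 * x
        fit = sl.pgls_fit(y, x, balanced_tree16, labels)
        assert fit.coefficient == pytest.approx(2.0, abs=1e-8)
        assert fit.p_value < 1e-12

    def test_type_i_error_calibrated(self, balanced_tree16):
        """BM-simulated y independent of x: rejection rate near nominal 5%."""
        from sexlinkage.phylo_turnover import bm_covariance

        labels = balanced_tree16.tip_labels
        c = bm_covariance(balanced_tree16, labels)
        chol = np.linalg.cholesky(c)
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = chol @ rng.standard_normal(len(labels))
            x = chol @ rng.standard_normal(len(labels))
            if sl.pgls_fit(y, x, balanced_tree16, labels).p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.12

    def test_too_few_observations(self):
        star = sl.timetree_from_string("(A:1,B:1);")
        with pytest.raises(SexlinkageError, match="3"):
            sl.pgls_fit([1, 2], [1, 2], star, ["A", "B"])
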