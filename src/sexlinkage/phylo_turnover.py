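"""Phylogenetic analysis of sex-chromosome evolution.

Ancestral-state reconstruction of sex-linked linkage groups and heterogamety
under Mk models (equal rates, symmetric rates, all-rates-different), sampled
character histories ("stochastic maps") via endpoint-conditioned CTMC
simulation with uniformization, detection of sex-chromosome turnover points
as the tip-to-root 0.5-crossings of per-state posteriors, turnover and
heterogamety transition rates, a randomization test for biased recruitment of
chromosomes as sex chromosomes, and phylogenetic generalized least squares
with a Brownian-motion covariance.

Rates are per million years; event times are reported as ages (My before
present) on an ultrametric time tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import minimize

from .io_prep import SexlinkageError, TimeTree

MK_MODELS = ("ER", "SYM", "ARD")

#: along-branch posterior grid density for turnover detection
BRANCH_GRID_POINTS = 100

#: uniformization rate safety factor
UNIFORMIZATION_FACTOR = 1.05


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------


@dataclass
class IndexedTree:
    """A TimeTree with stable integer node ids and cached geometry.

    Node 0 is the root; nodes are numbered in preorder. ``parent[i]`` is -1
    for the root; ``blen[i]`` is the branch length subtending node i;
    ``depth[i]`` the distance from the root; tips carry taxon labels.
    """

    timetree: TimeTree
    nodes: list = field(repr=False, default_factory=list)
    parent: np.ndarray = None
    blen: np.ndarray = None
    depth: np.ndarray = None
    tip_ids: dict = None  # label -> node id
    children: list = None

    @classmethod
    def build(cls, timetree: TimeTree) -> "IndexedTree":
        nodes = list(timetree.tree.preorder_node_iter())
        nid = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        blen = np.zeros(len(nodes))
        depth = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        tip_ids = {}
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = nid[id(n.parent_node)]
                parent[i] = p
                blen[i] = n.edge.length or 0.0
                depth[i] = depth[p] + blen[i]
                children[p].append(i)
            if n.is_leaf():
                tip_ids[n.taxon.label] = i
        return cls(timetree, nodes, parent, blen, depth, tip_ids, children)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def height(self) -> float:
        return float(self.depth.max())

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def postorder(self):
        return reversed(range(self.n_nodes))

    def age(self, dist_from_root: float) -> float:
        return self.height - dist_from_root


# ---------------------------------------------------------------------------
# state probability matrix
# ---------------------------------------------------------------------------


def state_probability_matrix(
    tip_states: dict, states: list[str], all_tips: list[str]
) -> pd.DataFrame:
    """Code tip data as a probability matrix over states.

    Tips present in ``tip_states`` get probability 1 on their state; tips
    without information are attributed equal probability for all states.
    """
    mat = pd.DataFrame(
        np.full((len(all_tips), len(states)), 1.0 / len(states)),
        index=all_tips,
        columns=states,
    )
    for tip, st in tip_states.items():
        if st is None:
            continue
        if st not in states:
            raise SexlinkageError(f"state {st!r} not in state list")
        mat.loc[tip] = 0.0
        mat.loc[tip, st] = 1.0
    return mat


def validate_spm(spm: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    rows = spm.to_numpy().sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol):
        raise SexlinkageError("state probability rows must sum to 1")
    return spm


# ---------------------------------------------------------------------------
# Mk model fitting
# ---------------------------------------------------------------------------


@dataclass
class MkFit:
    model: str
    q: np.ndarray  # rate matrix, rows sum to 0
    log_lik: float
    aic: float
    n_params: int
    states: list[str]
    converged: bool = True


def _q_from_params(params: np.ndarray, k: int, model: str) -> np.ndarray:
    q = np.zeros((k, k))
    if model == "ER":
        q[:] = params[0]
    elif model == "SYM":
        it = iter(params)
        for i in range(k):
            for j in range(i + 1, k):
                r = next(it)
                q[i, j] = q[j, i] = r
    elif model == "ARD":
        it = iter(params)
        for i in range(k):
            for j in range(k):
                if i != j:
                    q[i, j] = next(it)
    else:
        raise SexlinkageError(f"unknown Mk model {model!r}")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _n_free_rates(k: int, model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def _tip_partials(it: IndexedTree, spm: pd.DataFrame) -> np.ndarray:
    k = spm.shape[1]
    partial = np.ones((it.n_nodes, k))
    for label, nid in it.tip_ids.items():
        if label not in spm.index:
            raise SexlinkageError(f"tree tip {label!r} missing from state matrix")
        partial[nid] = spm.loc[label].to_numpy()
    return partial


def mk_loglik(
    it: IndexedTree, spm: pd.DataFrame, q: np.ndarray, root_prior: np.ndarray
) -> float:
    """Felsenstein pruning log-likelihood with soft tip priors."""
    partial = _tip_partials(it, spm)
    logscale = 0.0
    trans = {}
    for i in it.postorder():
        for c in it.children[i]:
            t = it.blen[c]
            if t not in trans:
                trans[t] = expm(q * t)
            partial[i] = partial[i] * (trans[t] @ partial[c])
        s = partial[i].sum()
        if not np.isfinite(s) or s <= 0:
            raise SexlinkageError(f"non-finite likelihood at node {i}")
        partial[i] /= s
        logscale += math.log(s)
    lik = float(root_prior @ partial[0])
    # the per-node normalization already absorbed the root sum once
    return logscale + math.log(lik) - math.log(partial[0].sum())


def fit_mk(
    tree: TimeTree,
    spm: pd.DataFrame,
    model: str = "ER",
    root_prior: str = "uniform",
    init_q: np.ndarray | None = None,
) -> MkFit:
    """Maximum-likelihood Mk fit by bounded quasi-Newton optimization.

    Tip data are soft priors (probability rows); the root prior is uniform by
    default ("stationary" uses the chain's stationary distribution of the
    candidate Q at each evaluation).
    """
    spm = validate_spm(spm)
    if spm.shape[1] < 2:
        raise SexlinkageError("need at least 2 states")
    it = IndexedTree.build(tree)
    k = spm.shape[1]
    n_par = _n_free_rates(k, model)
    height = max(it.height, 1e-9)

    def prior_for(q):
        if root_prior == "uniform":
            return np.full(k, 1.0 / k)
        w = _stationary(q)
        return w

    def nll(log_rates):
        q = _q_from_params(np.exp(log_rates), k, model)
        try:
            return -mk_loglik(it, spm, q, prior_for(q))
        except (SexlinkageError, ValueError, OverflowError):
            return 1e12

    if init_q is not None:
        x0 = np.log(np.clip(_params_from_q(init_q, model), 1e-10, None))
    else:
        x0 = np.full(n_par, math.log(0.5 / height))
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(math.log(1e-10), math.log(1e4))] * n_par,
        options={"maxiter": 500},
    )
    q = _q_from_params(np.exp(res.x), k, model)
    ll = -res.fun
    if not np.isfinite(ll):
        raise SexlinkageError("Mk optimizer did not reach a finite likelihood")
    return MkFit(
        model=model,
        q=q,
        log_lik=float(ll),
        aic=2.0 * n_par - 2.0 * float(ll),
        n_params=n_par,
        states=list(spm.columns),
        converged=bool(res.success),
    )


def _params_from_q(q: np.ndarray, model: str) -> np.ndarray:
    k = q.shape[0]
    if model == "ER":
        off = q[~np.eye(k, dtype=bool)]
        return np.array([off.mean()])
    if model == "SYM":
        return np.array([(q[i, j] + q[j, i]) / 2 for i in range(k) for j in range(i + 1, k)])
    return np.array([q[i, j] for i in range(k) for j in range(k) if i != j])


def _stationary(q: np.ndarray) -> np.ndarray:
    k = q.shape[0]
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    w, *_ = np.linalg.lstsq(a, b, rcond=None)
    w = np.clip(w, 1e-12, None)
    return w / w.sum()


def fit_mk_auto(
    tree: TimeTree, spm: pd.DataFrame, root_prior: str = "uniform"
) -> tuple[MkFit, dict[str, MkFit]]:
    """Fit ER, SYM and ARD and select the minimum-AIC model.

    Each richer model is initialized from the simpler fit so that the nested
    log-likelihood ordering (ARD >= SYM >= ER) holds. AIC ties (< 1e-6) go to
    the simpler model.
    """
    fits: dict[str, MkFit] = {}
    fits["ER"] = fit_mk(tree, spm, "ER", root_prior)
    fits["SYM"] = fit_mk(tree, spm, "SYM", root_prior, init_q=fits["ER"].q)
    if fits["SYM"].log_lik < fits["ER"].log_lik:
        fits["SYM"] = _clone_as(fits["ER"], "SYM", spm.shape[1])
    fits["ARD"] = fit_mk(tree, spm, "ARD", root_prior, init_q=fits["SYM"].q)
    if fits["ARD"].log_lik < fits["SYM"].log_lik:
        fits["ARD"] = _clone_as(fits["SYM"], "ARD", spm.shape[1])
    best = min(MK_MODELS, key=lambda m: (round(fits[m].aic / 1e-6), _n_free_rates(spm.shape[1], m)))
    return fits[best], fits


def _clone_as(fit: MkFit, model: str, k: int) -> MkFit:
    n_par = _n_free_rates(k, model)
    return MkFit(model, fit.q.copy(), fit.log_lik, 2 * n_par - 2 * fit.log_lik,
                 n_par, list(fit.states), fit.converged)


# ---------------------------------------------------------------------------
# stochastic character maps
# ---------------------------------------------------------------------------


@dataclass
class CharacterHistory:
    """One sampled state history along the tree.

    ``node_state[i]`` is the state index at node i; ``events`` holds
    (node_id, dist_from_root, from_state, to_state) for every change on the
    branch subtending node_id, ordered along the branch.
    """

    node_state: np.ndarray
    events: list[tuple[int, float, int, int]]

    def n_changes(self) -> int:
        return len(self.events)

    def state_at(self, it: IndexedTree, nid: int, dist_from_root: float) -> int:
        """State on the branch subtending ``nid`` at a distance from root."""
        p = it.parent[nid]
        st = self.node_state[p] if p >= 0 else self.node_state[nid]
        for b, t, s_from, s_to in self.events:
            if b == nid and t <= dist_from_root:
                st = s_to
        return int(st)


def _conditional_partials(it: IndexedTree, spm: pd.DataFrame, q: np.ndarray):
    k = spm.shape[1]
    partial = _tip_partials(it, spm)
    trans = np.zeros((it.n_nodes, k, k))
    for i in it.postorder():
        if it.parent[i] >= 0:
            trans[i] = expm(q * it.blen[i])
        for c in it.children[i]:
            partial[i] = partial[i] * (trans[c] @ partial[c])
        s = partial[i].sum()
        partial[i] /= s
    return partial, trans


def _sample_path(
    q: np.ndarray, a: int, b: int, t: float, rng: np.random.Generator,
    max_jumps: int = 10_000,
) -> list[tuple[float, int, int]]:
    """Endpoint-conditioned CTMC path from state a to b over time t.

    Uniformization with rate 1.05 * max |Q_ii|; returns (time_in_branch,
    from, to) for each real (non-virtual) jump.
    """
    k = q.shape[0]
    omega = UNIFORMIZATION_FACTOR * float(np.max(-np.diag(q)))
    if omega <= 0 or t <= 0:
        return []
    r = np.eye(k) + q / omega
    p_t = expm(q * t)
    target = p_t[a, b]
    if target <= 0:
        raise SexlinkageError("impossible endpoint combination in path sampling")
    # sample number of uniformized jumps
    u = rng.random() * target
    acc = 0.0
    log_pois = -omega * t
    r_pow = np.eye(k)
    powers = [r_pow]
    n = 0
    while True:
        acc += math.exp(log_pois) * powers[n][a, b]
        if acc >= u or n >= max_jumps:
            break
        n += 1
        log_pois += math.log(omega * t) - math.log(n)
        powers.append(powers[-1] @ r)
    # jump chain conditioned on endpoints
    states = [a]
    for m in range(1, n + 1):
        prev = states[-1]
        w = r[prev, :] * powers[n - m][:, b]
        w = np.clip(w, 0, None)
        if w.sum() <= 0:
            w = np.ones(k)
        states.append(int(rng.choice(k, p=w / w.sum())))
    times = np.sort(rng.random(n)) * t
    path = []
    for m in range(1, n + 1):
        if states[m] != states[m - 1]:
            path.append((float(times[m - 1]), states[m - 1], states[m]))
    return path


def stochastic_maps(
    tree: TimeTree,
    fit: MkFit,
    spm: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    root_prior: str = "uniform",
) -> list[CharacterHistory]:
    """Sample character histories conditional on tip data and a fitted Q.

    Node states are drawn from conditional posteriors (pruning partials),
    branch histories from the endpoint-conditioned CTMC via uniformization.
    """
    spm = validate_spm(spm)
    it = IndexedTree.build(tree)
    k = spm.shape[1]
    q = fit.q
    partial, trans = _conditional_partials(it, spm, q)
    prior = np.full(k, 1.0 / k) if root_prior == "uniform" else _stationary(q)
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n):
        node_state = np.zeros(it.n_nodes, dtype=int)
        w = prior * partial[0]
        node_state[0] = rng.choice(k, p=w / w.sum())
        events: list[tuple[int, float, int, int]] = []
        for i in range(1, it.n_nodes):
            p = it.parent[i]
            w = trans[i][node_state[p], :] * partial[i]
            node_state[i] = rng.choice(k, p=w / w.sum())
            start = it.depth[p]
            for dt, s_from, s_to in _sample_path(
                q, node_state[p], node_state[i], it.blen[i], rng
            ):
                events.append((i, start + dt, s_from, s_to))
        maps.append(CharacterHistory(node_state, events))
    return maps


def branch_posteriors(
    it: IndexedTree, maps: list[CharacterHistory], n_states: int,
    grid: int = BRANCH_GRID_POINTS,
) -> dict[int, np.ndarray]:
    """Per-branch along-branch posterior state frequencies.

    For branch subtending node i returns an (grid, n_states) array of the
    fraction of maps in each state at evenly spaced points (parent -> node).
    """
    out = {}
    # collect events per (map, branch)
    ev: dict[tuple[int, int], list[tuple[float, int]]] = {}
    for m_idx, m in enumerate(maps):
        for b, t, s_from, s_to in m.events:
            ev.setdefault((m_idx, b), []).append((t, s_to))
    for i in range(1, it.n_nodes):
        p = it.parent[i]
        pts = it.depth[p] + np.linspace(0.0, it.blen[i], grid)
        counts = np.zeros((grid, n_states))
        for m_idx, m in enumerate(maps):
            changes = ev.get((m_idx, i), [])
            st = np.full(grid, m.node_state[p], dtype=int)
            for t, s_to in sorted(changes):
                st[pts >= t] = s_to
            counts[np.arange(grid), st] += 1
        out[i] = counts / len(maps)
    return out


# ---------------------------------------------------------------------------
# turnover detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverEvent:
    branch: int  # node id subtended by the branch carrying the event
    age: float  # My before present
    state: str  # gained state label
    root_or_earlier: bool = False


def detect_turnovers(
    maps: list[CharacterHistory],
    tree: TimeTree,
    spm: pd.DataFrame,
    state: str,
    threshold: float = 0.5,
    grid: int = BRANCH_GRID_POINTS,
) -> list[TurnoverEvent]:
    """Gain points of one state, read from the mapped posterior.

    For every tip carrying the state, walk the tip-to-root path; the first
    point where the along-branch posterior of the state drops below the
    threshold is the turnover (gain) point. Events on the same branch are
    deduplicated. Paths on which the posterior never drops yield a single
    root-edge event flagged ``root_or_earlier``.
    """
    if not maps:
        raise SexlinkageError("no maps supplied")
    it = IndexedTree.build(tree)
    states = list(spm.columns)
    s_idx = states.index(state)
    post = branch_posteriors(it, maps, len(states), grid)
    events: dict[int, TurnoverEvent] = {}
    root_event = None
    for label, tip in it.tip_ids.items():
        if spm.loc[label, state] < threshold:
            continue
        nid = tip
        found = False
        while it.parent[nid] >= 0:
            p = post[nid][:, s_idx]
            pts = it.depth[it.parent[nid]] + np.linspace(0.0, it.blen[nid], grid)
            below = np.flatnonzero(p < threshold)
            if below.size:
                j = below[-1]  # last grid point below threshold, walking tipward
                # posterior crosses upward between j and j+1
                if j + 1 < grid:
                    f = (threshold - p[j]) / max(p[j + 1] - p[j], 1e-12)
                    t_cross = pts[j] + f * (pts[j + 1] - pts[j])
                else:
                    t_cross = pts[j]
                if nid not in events:
                    events[nid] = TurnoverEvent(
                        branch=nid, age=float(it.age(t_cross)), state=state
                    )
                found = True
                break
            nid = it.parent[nid]
        if not found and root_event is None:
            root_event = TurnoverEvent(
                branch=0, age=float(it.height), state=state, root_or_earlier=True
            )
    out = sorted(events.values(), key=lambda e: -e.age)
    if root_event is not None:
        out.insert(0, root_event)
    return out


def detect_turnovers_binary_per_lg(
    tree: TimeTree,
    lg_calls: dict[str, list[str]],
    all_tips: list[str],
    n_maps: int = 1000,
    seed: int = 0,
    uninformative_tips: list[str] | None = None,
) -> tuple[list[TurnoverEvent], dict[str, list[CharacterHistory]]]:
    """Per-LG binary (yes/no) reconstruction and gain detection.

    ``lg_calls`` maps lg_id -> species using that LG as sex chromosome. Each
    LG is reconstructed as an independent binary trait so that tips with
    multi-LG (fusion) signals can be "yes" for several LGs. Tips listed in
    ``uninformative_tips`` get 50/50 priors.
    """
    events: list[TurnoverEvent] = []
    maps_by_lg: dict[str, list[CharacterHistory]] = {}
    unknown = set(uninformative_tips or [])
    for j, (lg, species) in enumerate(sorted(lg_calls.items())):
        tip_states = {
            t: ("yes" if t in species else "no") for t in all_tips if t not in unknown
        }
        spm = state_probability_matrix(tip_states, ["no", "yes"], all_tips)
        fit, _ = fit_mk_auto(tree, spm)
        maps = stochastic_maps(tree, fit, spm, n=n_maps, seed=seed + 7919 * (j + 1))
        maps_by_lg[lg] = maps
        for ev in detect_turnovers(maps, tree, spm, "yes"):
            events.append(TurnoverEvent(ev.branch, ev.age, lg, ev.root_or_earlier))
    return events, maps_by_lg


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverRate:
    n_events: int
    total_branch_length_my: float
    rate_per_my: float
    expected_divergence_my: float  # expected divergence time for one event


def estimate_rate(events: list, tree: TimeTree) -> TurnoverRate:
    """Events per lineage-million-years, over the tree's total branch length.

    Also reports the divergence time at which one event is expected between
    two species: t = 1 / (2 * rate) (two lineages accumulate 2*rate*t events
    since their split).
    """
    total = tree.total_branch_length()
    if total <= 0:
        raise SexlinkageError("tree has zero total branch length")
    rate = len(events) / total
    return TurnoverRate(
        n_events=len(events),
        total_branch_length_my=total,
        rate_per_my=rate,
        expected_divergence_my=math.inf if rate == 0 else 1.0 / (2.0 * rate),
    )


# ---------------------------------------------------------------------------
# heterogamety transitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeterogametyTransition:
    branch: int
    age: float
    from_state: str
    to_state: str
    injected: bool = False


@dataclass
class HeterogametyAnalysis:
    transitions: list
    rate_per_my: float
    counts: dict  # (from, to) -> n
    fit: MkFit


def heterogamety_transitions(
    tree: TimeTree,
    spm: pd.DataFrame,
    n_maps: int = 1000,
    seed: int = 0,
    extra_transitions: list | None = None,
) -> HeterogametyAnalysis:
    """Reconstruct heterogamety (XY/ZW, optionally NonGSD) transitions.

    Runs the Mk/stochastic-mapping machinery over heterogamety states and
    reads directed transitions as per-state gain points, taking the
    rootward-side majority state as the origin. Literature-driven transitions
    can be injected via ``extra_transitions`` and enter counts and rate.
    """
    spm = validate_spm(spm)
    fit, _ = fit_mk_auto(tree, spm)
    maps = stochastic_maps(tree, fit, spm, n=n_maps, seed=seed)
    it = IndexedTree.build(tree)
    states = list(spm.columns)
    post = branch_posteriors(it, maps, len(states))
    transitions: list[HeterogametyTransition] = []
    for st in states:
        for ev in detect_turnovers(maps, tree, spm, st):
            if ev.root_or_earlier:
                continue
            # origin = majority state at the rootward end of the event branch
            p_parent = post[ev.branch][0]
            order = np.argsort(-p_parent)
            from_idx = next(
                (int(o) for o in order if states[o] != st), int(order[0])
            )
            transitions.append(
                HeterogametyTransition(ev.branch, ev.age, states[from_idx], st)
            )
    for t in extra_transitions or []:
        transitions.append(t)
    counts: dict[tuple[str, str], int] = {}
    for t in transitions:
        counts[(t.from_state, t.to_state)] = counts.get((t.from_state, t.to_state), 0) + 1
    rate = estimate_rate(transitions, tree).rate_per_my
    return HeterogametyAnalysis(transitions, rate, counts, fit)


def crosstab_turnovers(
    lg_events: list[TurnoverEvent],
    het: HeterogametyAnalysis,
    tree: TimeTree,
    het_maps: list[CharacterHistory],
    het_states: list[str],
) -> pd.DataFrame:
    """Label each LG turnover as heterogamety-preserving or -changing.

    The heterogamety state just rootward and just tipward of each LG turnover
    point is read from the heterogamety maps; a change labels the turnover
    heterogamety-changing. Heterogamety transitions on branches with no LG
    event are the uncoupled changes.
    """
    it = IndexedTree.build(tree)
    post = branch_posteriors(it, het_maps, len(het_states))
    rows = []
    lg_branches = set()
    for ev in lg_events:
        if ev.branch == 0 and ev.root_or_earlier:
            rows.append((ev.state, ev.age, None, None, "root_or_earlier"))
            continue
        lg_branches.add(ev.branch)
        p = post[ev.branch]
        t_ev = it.height - ev.age
        pts = it.depth[it.parent[ev.branch]] + np.linspace(
            0.0, it.blen[ev.branch], p.shape[0]
        )
        j = int(np.clip(np.searchsorted(pts, t_ev), 1, p.shape[0] - 1))
        before = het_states[int(np.argmax(p[j - 1]))]
        after = het_states[int(np.argmax(p[-1]))]
        rows.append(
            (ev.state, ev.age, before, after,
             "preserving" if before == after else "changing")
        )
    df = pd.DataFrame(
        rows, columns=["lg", "age", "het_before", "het_after", "label"]
    )
    df.attrs["uncoupled_heterogamety_changes"] = [
        t for t in het.transitions if t.branch not in lg_branches
    ]
    return df


def compare_transition_ages(
    transitions: list[HeterogametyTransition],
    direction_a: tuple[str, str] = ("XY", "ZW"),
    direction_b: tuple[str, str] = ("ZW", "XY"),
):
    """Two-sided Mann-Whitney U test on transition ages by direction."""
    ages_a = [t.age for t in transitions if (t.from_state, t.to_state) == direction_a]
    ages_b = [t.age for t in transitions if (t.from_state, t.to_state) == direction_b]
    if not ages_a or not ages_b:
        return None
    method = "exact" if max(len(ages_a), len(ages_b)) <= 20 else "auto"
    res = stats.mannwhitneyu(ages_a, ages_b, alternative="two-sided", method=method)
    return {"u": float(res.statistic), "p_value": float(res.pvalue),
            "n_a": len(ages_a), "n_b": len(ages_b)}


# ---------------------------------------------------------------------------
# recruitment randomization test
# ---------------------------------------------------------------------------


@dataclass
class RecruitmentTest:
    fraction_ge_observed: float
    observed_never: int
    per_lg_mean: pd.Series
    never_counts: np.ndarray  # per-simulation number of never-recruited LGs
    per_lg_counts: np.ndarray  # (n_sim, n_lg)


def random_recruitment_test(
    n_events: int,
    lgs: pd.DataFrame,
    n_sim: int = 10_000,
    observed_never: int = 10,
    seed: int = 0,
    window: int = 10_000,
) -> RecruitmentTest:
    """Randomization test for biased chromosome recruitment.

    Each simulation drops ``n_events`` 10-kb windows uniformly on the genome
    (an LG receives a window with probability proportional to its length) and
    records the containing LG as a recruited sex chromosome. Reports the
    fraction of simulations with at least ``observed_never`` never-recruited
    LGs and the per-LG recruitment distribution.
    """
    if n_events <= 0:
        raise SexlinkageError("n_events must be > 0")
    lengths = lgs["length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise SexlinkageError("LG lengths must be > 0")
    p = lengths / lengths.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, p, size=n_sim)
    never = (counts == 0).sum(axis=1)
    frac = float((never >= observed_never).mean())
    return RecruitmentTest(
        fraction_ge_observed=frac,
        observed_never=observed_never,
        per_lg_mean=pd.Series(counts.mean(axis=0), index=lgs["lg_id"].tolist()),
        never_counts=never,
        per_lg_counts=counts,
    )


# ---------------------------------------------------------------------------
# pGLS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PglsFit:
    coefficient: float
    p_value: float
    intercept: float
    model: str = "BM"


def bm_covariance(tree: TimeTree, labels: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-MRCA path length."""
    it = IndexedTree.build(tree)
    n = len(labels)
    # ancestor sets with depths
    anc: dict[str, list[tuple[int, float]]] = {}
    for lab in labels:
        if lab not in it.tip_ids:
            raise SexlinkageError(f"tip {lab!r} not in tree")
        path = []
        nid = it.tip_ids[lab]
        while nid >= 0:
            path.append((nid, it.depth[nid]))
            nid = it.parent[nid]
        anc[lab] = path
    c = np.zeros((n, n))
    for i in range(n):
        set_i = dict(anc[labels[i]])
        c[i, i] = it.depth[it.tip_ids[labels[i]]]
        for j in range(i + 1, n):
            shared = max(d for nid, d in anc[labels[j]] if nid in set_i)
            c[i, j] = c[j, i] = shared
    return c


def pgls_fit(y, x, tree: TimeTree, labels: list[str] | None = None) -> PglsFit:
    """GLS regression of y on x with Brownian phylogenetic covariance."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if labels is None:
        labels = tree.tip_labels
    if len(y) != len(labels) or len(x) != len(labels):
        raise SexlinkageError("y/x lengths must match tree tips")
    if len(y) < 3:
        raise SexlinkageError("pGLS needs at least 3 observations")
    c = bm_covariance(tree, labels)
    # star phylogenies give diagonal C; degenerate C is an error
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise SexlinkageError("singular phylogenetic covariance") from exc
    design = np.column_stack([np.ones_like(x), x])
    xtci = design.T @ cinv
    fisher = xtci @ design
    try:
        beta = np.linalg.solve(fisher, xtci @ y)
    except np.linalg.LinAlgError as exc:
        raise SexlinkageError("singular design in pGLS") from exc
    resid = y - design @ beta
    dof = len(y) - 2
    sigma2 = float(resid @ cinv @ resid) / dof
    cov_beta = sigma2 * np.linalg.inv(fisher)
    se = math.sqrt(max(cov_beta[1, 1], 0.0))
    if se == 0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t = beta[1] / se
        p = float(2 * stats.t.sf(abs(t), dof))
    return PglsFit(coefficient=float(beta[1]), p_value=p, intercept=float(beta[0]))
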