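"""SI simulator: single steps, ensembles, oracles and reproducibility."""

from itertools import product

import networkx as nx
import numpy as np
import pytest

from seednet import (
    ProbabilityMatrix, SimulationConfig, arrivals_at, run_ensemble, step,
)


def _pm(nodes, entries):
    n = len(nodes)
    P = np.zeros((n, n))
    for (i, j), p in entries.items():
        P[i, j] = p
    return ProbabilityMatrix(nodes=tuple(nodes), P=P)


# ----------------------------------------------------------------- step

def test_certain_edge_transmits(rng):
    pm = _pm(["A", "B"], {(0, 1): 1.0})
    state = np.array([1, 0])
    new, events = step(state, pm, rng)
    assert new.tolist() == [1, 1]
    assert events.tolist() == [[0, 1]]


def test_zero_matrix_changes_nothing(rng):
    pm = _pm(["A", "B"], {})
    new, events = step(np.array([1, 0]), pm, rng)
    assert new.tolist() == [1, 0]
    assert events.size == 0


def test_step_rejects_mismatched_state(rng):
    pm = _pm(["A", "B"], {(0, 1): 0.5})
    with pytest.raises(ValueError):
        step(np.array([1, 0, 0]), pm, rng)


def test_single_step_event_rate_matches_binomial(rng):
    # two-node edge with p = 0.3: event fraction over many single steps
    p = 0.3
    pm = _pm(["A", "B"], {(0, 1): p})
    n = 10_000
    hits = sum(step(np.array([1, 0]), pm, rng)[1].size > 0
               for _ in range(n))
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 3 * se


def test_nonpersistent_update_can_revert():
    # literal update 1(s A > 0): with no incoming edge the start reverts
    pm = _pm(["A", "B"], {(0, 1): 1.0})
    rng = np.random.default_rng(0)
    new, _ = step(np.array([1, 0]), pm, rng, persistence=False)
    assert new.tolist() == [0, 1]


# ------------------------------------------------------------- ensembles

def test_deterministic_chain_infects_downstream():
    pm = _pm(["A", "B", "C"], {(0, 1): 1.0, (1, 2): 1.0})
    cfg = SimulationConfig(start_node="A", n_steps=2, n_reps=20, rng_seed=1)
    tr = run_ensemble(pm, cfg)
    assert (tr.contaminated == 2).all()           # B and C beyond the start
    assert (tr.contaminated_incl_start == 3).all()
    assert tr.n_success == 20


def test_isolated_start_never_succeeds():
    pm = _pm(["A", "B"], {(1, 0): 0.9})   # A has no outgoing edges
    cfg = SimulationConfig(start_node="A", n_steps=10, n_reps=50, rng_seed=1)
    tr = run_ensemble(pm, cfg)
    assert tr.n_success == 0
    assert (tr.contaminated == 0).all()


def test_unknown_start_node_is_an_error():
    pm = _pm(["A", "B"], {(0, 1): 0.5})
    with pytest.raises(ValueError):
        run_ensemble(pm, SimulationConfig(start_node="Z"))


def test_same_seed_gives_identical_event_logs():
    pm = _pm(["A", "B", "C"], {(0, 1): 0.4, (1, 2): 0.6, (0, 2): 0.2})
    cfg = SimulationConfig(start_node="A", n_steps=5, n_reps=40, rng_seed=99)
    a, b = run_ensemble(pm, cfg), run_ensemble(pm, cfg)
    assert np.array_equal(a.events, b.events)
    assert np.array_equal(a.contaminated, b.contaminated)
    c = run_ensemble(pm, SimulationConfig(start_node="A", n_steps=5,
                                          n_reps=40, rng_seed=100))
    assert not np.array_equal(a.events, c.events)


def test_expected_first_step_events_match_row_sum():
    probs = {(0, 1): 0.3, (0, 2): 0.5, (0, 3): 0.1}
    pm = _pm(["A", "B", "C", "D"], probs)
    n_reps = 4000
    tr = run_ensemble(pm, SimulationConfig(start_node="A", n_steps=1,
                                           n_reps=n_reps, rng_seed=3))
    mean_events = tr.events.shape[0] / n_reps
    expect = sum(probs.values())
    se = np.sqrt(sum(p * (1 - p) for p in probs.values()) / n_reps)
    assert abs(mean_events - expect) < 3 * se


def test_infected_count_monotone_under_persistence(rng):
    n = 8
    P = (rng.random((n, n)) < 0.4) * rng.random((n, n)) * 0.5
    np.fill_diagonal(P, 0.0)
    pm = ProbabilityMatrix(nodes=tuple(f"N{i}" for i in range(n)), P=P)
    for _ in range(20):
        state = np.zeros(n, dtype=np.int8)
        state[0] = 1
        prev = 1
        for _ in range(6):
            state, _ = step(state, pm, rng, persistence=True)
            assert state.sum() >= prev
            prev = state.sum()


def test_certain_spread_equals_graph_reachability(rng):
    # with all p = 1 the ever-infected set is the forward-reachable set
    for seed in range(4):
        g_rng = np.random.default_rng(seed)
        n = 9
        adj = (g_rng.random((n, n)) < 0.2) & ~np.eye(n, dtype=bool)
        nodes = [f"N{i}" for i in range(n)]
        pm = ProbabilityMatrix(nodes=tuple(nodes), P=adj.astype(float))
        g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        tr = run_ensemble(pm, SimulationConfig(start_node="N0", n_steps=n,
                                               n_reps=3, rng_seed=seed))
        reachable = nx.descendants(g, 0)
        assert (tr.contaminated == len(reachable)).all()


# -------------------------------------------------- enumeration oracle

def exact_ever_infected_distribution(P, start, n_steps, persistence=True):
    """Exhaustive enumeration over all per-step edge outcomes."""
    n = P.shape[0]
    edges = [(i, j) for i in range(n) for j in range(n) if P[i, j] > 0]
    dist: dict[frozenset, float] = {}

    def rec(state, ever, t, prob):
        if t == n_steps:
            dist[ever] = dist.get(ever, 0.0) + prob
            return
        active = [e for e in edges if e[0] in state]
        for outcome in product((0, 1), repeat=len(active)):
            p = prob
            received = set()
            for bit, (i, j) in zip(outcome, active):
                p *= P[i, j] if bit else (1.0 - P[i, j])
                if bit:
                    received.add(j)
            if p == 0.0:
                continue
            new = (state | received) if persistence else frozenset(received)
            rec(frozenset(new), ever | frozenset(received), t + 1, p)

    rec(frozenset({start}), frozenset({start}), 0, 1.0)
    return dist


def test_ensemble_matches_exhaustive_enumeration():
    nodes = ("A", "B", "C", "D")
    P = np.zeros((4, 4))
    P[0, 1], P[1, 2], P[0, 2], P[2, 3] = 0.6, 0.5, 0.25, 0.4
    pm = ProbabilityMatrix(nodes=nodes, P=P)
    n_steps, n_reps = 2, 6000
    exact = exact_ever_infected_distribution(P, 0, n_steps)
    assert sum(exact.values()) == pytest.approx(1.0)

    tr = run_ensemble(pm, SimulationConfig(start_node="A", n_steps=n_steps,
                                           n_reps=n_reps, rng_seed=11))
    # reconstruct the ever-infected set of each replicate from its events
    observed: dict[frozenset, int] = {}
    for rep in range(n_reps):
        dests = tr.events[tr.events[:, 0] == rep][:, 3]
        key = frozenset({0}) | frozenset(int(d) for d in dests)
        observed[key] = observed.get(key, 0) + 1

    for key, p in exact.items():
        freq = observed.get(key, 0) / n_reps
        se = np.sqrt(p * (1 - p) / n_reps)
        assert abs(freq - p) < 4 * se + 1e-9, (set(key), freq, p)
    assert set(observed) <= set(exact)


# --------------------------------------------------------------- arrivals

def test_star_network_arrivals_all_direct():
    pm = _pm(["S", "F", "X"], {(0, 1): 1.0, (0, 2): 0.5})
    tr = run_ensemble(pm, SimulationConfig(start_node="S", n_steps=3,
                                           n_reps=10, rng_seed=5))
    arr = arrivals_at(tr, focal="F")
    assert arr.indirect_total == 0
    assert arr.direct_per_rep == pytest.approx(3.0)   # fires every step


def test_two_hop_path_arrivals_all_indirect():
    # start -> X -> focal with certain edges: once X is infected (step 1),
    # it delivers one indirect arrival in every later step
    pm = _pm(["S", "X", "F"], {(0, 1): 1.0, (1, 2): 1.0})
    n_steps = 10
    tr = run_ensemble(pm, SimulationConfig(start_node="S", n_steps=n_steps,
                                           n_reps=8, rng_seed=5))
    arr = arrivals_at(tr, focal="F")
    assert arr.direct_total == 0
    assert (arr.indirect_by_rep == n_steps - 1).all()


def test_no_path_to_focal_no_arrivals():
    pm = _pm(["S", "F", "X"], {(0, 2): 1.0})
    tr = run_ensemble(pm, SimulationConfig(start_node="S", n_steps=5,
                                           n_reps=10, rng_seed=5))
    arr = arrivals_at(tr, focal="F")
    assert arr.direct_total == 0 and arr.indirect_total == 0
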