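"""Stochastic-time susceptible-infected spread over the trade network.

The model is a discrete-time Markov chain on infection state vectors.  At
each time-step a uniform draw per edge realises a random adjacency matrix
A_t (edge (i, j) present iff U_ij < p_ij); every realised edge out of an
infected node is a *dispersal event*, recorded even when the destination is
already infected (repeated arrivals are meaningful for focal-country risk).
The next state infects every node that received an event; with persistence
on (the default, matching SI semantics where establishment is permanent)
the previous state is OR-ed in, so infection never reverts.  The literal
non-persistent update s_{t+1} = 1(s_t A_t > 0) is available for comparison.

An ensemble runs ``n_reps`` independent replicates of ``n_steps`` from a
single start country.  Replicate random streams are spawned from one seed
sequence, so ensembles are reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dispersal import ProbabilityMatrix

__all__ = ["SimulationConfig", "SimulationTrace", "ArrivalSummary",
           "step", "run_ensemble", "arrivals_at"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble parameters.

    Defaults follow the study design: 200 replicates of 10 time-steps, one
    nominal year of trade per step, permanent establishment.
    """

    start_node: str
    n_steps: int = 10
    n_reps: int = 200
    rng_seed: int = 0
    persistence: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_reps < 1:
            raise ValueError("n_steps and n_reps must be >= 1")


def step(state: np.ndarray, P: ProbabilityMatrix | np.ndarray,
         rng: np.random.Generator,
         persistence: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Advance the infection state one time-step.

    Parameters
    ----------
    state:
        0/1 vector over the matrix's node ordering.
    P:
        Per-edge transmission probabilities.
    rng:
        Source of the per-edge uniform draws.  Draws are made only for rows
        of currently infected nodes (other rows cannot fire); this does not
        change the law of the chain, only the stream consumption.
    persistence:
        OR the previous state into the next (SI semantics).  When off, the
        literal update 1(s_t A_t > 0) is used and an infected node with no
        incoming event reverts to susceptible.

    Returns
    -------
    (new_state, events):
        ``events`` is an (E, 2) integer array of (origin, destination) node
        indices, one row per realised edge out of an infected node —
        including transmissions to already-infected destinations.
    """
    mat = P.P if isinstance(P, ProbabilityMatrix) else np.asarray(P)
    state = np.asarray(state)
    if state.shape != (mat.shape[0],):
        raise ValueError(f"state has shape {state.shape}, expected "
                         f"({mat.shape[0]},)")
    infected = np.flatnonzero(state)
    if infected.size == 0:
        return state.astype(np.int8), np.empty((0, 2), dtype=np.int64)

    draws = rng.random((infected.size, mat.shape[1]))
    fired = draws < mat[infected, :]          # p=0 edges can never fire
    rows, cols = np.nonzero(fired)
    events = np.column_stack((infected[rows], cols))

    received = fired.any(axis=0)
    if persistence:
        new_state = (state.astype(bool) | received)
    else:
        new_state = received
    return new_state.astype(np.int8), events


@dataclass
class SimulationTrace:
    """Ensemble output: per-replicate summaries plus the full event log.

    ``events`` has columns (replicate, time-step, origin, destination) as
    node indices into ``nodes``; ``contaminated`` counts ever-infected nodes
    per replicate excluding the start (the start is infected by
    construction; the inclusive count is ``contaminated_incl_start``).
    """

    nodes: tuple[str, ...]
    start_node: str
    n_steps: int
    n_reps: int
    persistence: bool
    rng_seed: int
    events: np.ndarray                 # (E, 4) int64
    contaminated: np.ndarray           # (n_reps,) ever-infected excl. start
    contaminated_incl_start: np.ndarray
    success: np.ndarray                # (n_reps,) bool: >=1 dispersal event
    edge_counts: np.ndarray            # (n, n) total events per edge

    @property
    def n_success(self) -> int:
        return int(self.success.sum())

    def events_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "replicate": self.events[:, 0],
            "step": self.events[:, 1],
            "origin": [self.nodes[i] for i in self.events[:, 2]],
            "destination": [self.nodes[j] for j in self.events[:, 3]],
        })


def run_ensemble(P: ProbabilityMatrix, config: SimulationConfig,
                 ) -> SimulationTrace:
    """Run ``config.n_reps`` independent replicates from one start country.

    Each replicate starts with only the start node infected and advances
    ``config.n_steps`` steps.  A replicate is *successful* if it produced at
    least one dispersal event.  Replicate RNG substreams are spawned from
    ``config.rng_seed``, so results are reproducible and independent of how
    replicates might be scheduled.
    """
    nodes = P.nodes
    if config.start_node not in nodes:
        raise ValueError(f"start node {config.start_node!r} not in network")
    n = len(nodes)
    start_idx = nodes.index(config.start_node)

    seq = np.random.SeedSequence(config.rng_seed)
    children = seq.spawn(config.n_reps)

    all_events = []
    contaminated = np.zeros(config.n_reps, dtype=np.int64)
    contaminated_incl = np.zeros(config.n_reps, dtype=np.int64)
    success = np.zeros(config.n_reps, dtype=bool)
    edge_counts = np.zeros((n, n), dtype=np.int64)

    for rep in range(config.n_reps):
        rng = np.random.default_rng(children[rep])
        state = np.zeros(n, dtype=np.int8)
        state[start_idx] = 1
        ever = state.astype(bool)
        for t in range(config.n_steps):
            state, events = step(state, P, rng,
                                 persistence=config.persistence)
            ever |= state.astype(bool)
            if events.size:
                success[rep] = True
                np.add.at(edge_counts, (events[:, 0], events[:, 1]), 1)
                rep_step = np.full((events.shape[0], 2), (rep, t + 1),
                                   dtype=np.int64)
                all_events.append(np.hstack((rep_step, events)))
        contaminated_incl[rep] = int(ever.sum())
        contaminated[rep] = int(ever.sum()) - int(ever[start_idx])

    events_arr = (np.vstack(all_events) if all_events
                  else np.empty((0, 4), dtype=np.int64))
    return SimulationTrace(
        nodes=nodes, start_node=config.start_node, n_steps=config.n_steps,
        n_reps=config.n_reps, persistence=config.persistence,
        rng_seed=config.rng_seed, events=events_arr,
        contaminated=contaminated, contaminated_incl_start=contaminated_incl,
        success=success, edge_counts=edge_counts)


@dataclass(frozen=True)
class ArrivalSummary:
    """Direct versus indirect contaminant arrivals at a focal country."""

    focal: str
    start: str
    direct_total: int
    indirect_total: int
    direct_per_rep: float        # mean events per replicate
    indirect_per_rep: float
    direct_by_rep: np.ndarray = field(repr=False, default=None)
    indirect_by_rep: np.ndarray = field(repr=False, default=None)


def arrivals_at(trace: SimulationTrace, focal: str,
                start: Optional[str] = None) -> ArrivalSummary:
    """Count dispersal events into ``focal``, split direct vs indirect.

    An event (i, focal) is *direct* when i is the simulation's start country
    and *indirect* when i is any other (secondarily infected) country.
    Counts are aggregated per replicate and averaged over replicates.
    """
    if focal not in trace.nodes:
        raise ValueError(f"focal country {focal!r} not in node set")
    start = trace.start_node if start is None else start
    focal_idx = trace.nodes.index(focal)
    start_idx = trace.nodes.index(start)

    direct_by_rep = np.zeros(trace.n_reps, dtype=np.int64)
    indirect_by_rep = np.zeros(trace.n_reps, dtype=np.int64)
    ev = trace.events
    into_focal = ev[ev[:, 3] == focal_idx]
    for rep, _, origin, _ in into_focal:
        if origin == start_idx:
            direct_by_rep[rep] += 1
        else:
            indirect_by_rep[rep] += 1

    return ArrivalSummary(
        focal=focal, start=start,
        direct_total=int(direct_by_rep.sum()),
        indirect_total=int(indirect_by_rep.sum()),
        direct_per_rep=float(direct_by_rep.mean()),
        indirect_per_rep=float(indirect_by_rep.mean()),
        direct_by_rep=direct_by_rep, indirect_by_rep=indirect_by_rep)
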