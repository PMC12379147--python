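"""Monte-Carlo SIR spreading simulator: the ground truth for spreading ability.

Synchronous discrete-time dynamics on the graph: each step, every infected
node independently infects each susceptible neighbor with probability beta,
then recovers with probability lam (lam = 1 means every node transmits for
exactly one step — infections are always computed from the start-of-step
infected set, before recoveries are applied).  A node's spreading ability is
the mean final outbreak size (|R| at absorption) over many runs seeded at it.
"""
from __future__ import annotations

import math
from collections.abc import Callable, Hashable
from dataclasses import dataclass, field

import numpy as np

from .centrality import ScoreTable
from .graph import Graph

__all__ = ["SIRConfig", "simulate_once", "spreading_ability", "epidemic_threshold"]


@dataclass(frozen=True)
class SIRConfig:
    """Simulation parameters.

    beta: per-contact, per-step infection probability.
    lam:  per-step recovery probability (default 1, as in the reference setup).
    runs: Monte-Carlo repetitions per seed node (default 1000).
    rng_seed: master seed; each node gets its own substream so adding nodes
        does not perturb the streams of existing ones.
    """

    beta: float
    lam: float = 1.0
    runs: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must be in (0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def simulate_once(
    g: Graph,
    seed: Hashable,
    beta: float,
    lam: float = 1.0,
    rng: np.random.Generator | None = None,
    edge_uniforms: Callable[[int, int], float] | None = None,
) -> int:
    """One SIR outbreak seeded at ``seed``; returns the final recovered count.

    ``edge_uniforms(u, v)`` optionally supplies the uniform variate deciding
    the infection attempt along directed edge (u, v) (internal indices); with
    lam = 1 each directed edge is attempted at most once, so a memoized source
    couples runs across beta values for monotonicity checks.  Default draws
    come from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    indptr, indices = g.csr()
    status = np.zeros(g.N, dtype=np.uint8)  # 0=S, 1=I, 2=R
    s = g.index(seed)
    status[s] = 1
    infected = np.array([s], dtype=np.int64)
    while infected.size:
        counts = indptr[infected + 1] - indptr[infected]
        targets = np.concatenate(
            [indices[indptr[u] : indptr[u + 1]] for u in infected]
        )
        sus_mask = status[targets] == 0
        if edge_uniforms is None:
            hit = targets[sus_mask & (rng.random(targets.size) < beta)]
        else:
            sources = np.repeat(infected, counts)
            hit = np.array(
                [
                    v
                    for u, v, ok in zip(sources, targets, sus_mask)
                    if ok and edge_uniforms(int(u), int(v)) < beta
                ],
                dtype=np.int64,
            )
        status[hit] = 1
        newly = np.unique(hit)
        if lam >= 1.0:
            status[infected] = 2
            infected = newly
        else:
            rec = rng.random(infected.size) < lam
            status[infected[rec]] = 2
            infected = np.concatenate([infected[~rec], newly])
    return int((status != 0).sum())


def _node_rng(master_seed: int, node_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(node_index,))
    )


def spreading_ability(
    g: Graph, cfg: SIRConfig, keep_runs: bool = False
) -> ScoreTable | tuple[ScoreTable, dict[Hashable, np.ndarray]]:
    """Mean outbreak size per seed node over ``cfg.runs`` simulations.

    Deterministic given ``cfg.rng_seed``: node i's runs are drawn from the
    substream ``SeedSequence(rng_seed, spawn_key=(i,))``.
    """
    scores: dict[Hashable, float] = {}
    all_sizes: dict[Hashable, np.ndarray] = {}
    for i, v in enumerate(g.nodes):
        rng = _node_rng(cfg.rng_seed, i)
        sizes = np.array(
            [simulate_once(g, v, cfg.beta, cfg.lam, rng) for _ in range(cfg.runs)],
            dtype=float,
        )
        scores[v] = float(sizes.mean())
        if keep_runs:
            all_sizes[v] = sizes
    table = ScoreTable(
        "sir",
        scores,
        params={"beta": cfg.beta, "lam": cfg.lam, "runs": cfg.runs, "rng_seed": cfg.rng_seed},
    )
    return (table, all_sizes) if keep_runs else table


def epidemic_threshold(g: Graph) -> float:
    """Heterogeneous mean-field epidemic threshold <k> / (<k^2> - <k>)."""
    if g.E < 1:
        raise ValueError("epidemic threshold needs at least one edge")
    deg = g.degree_array().astype(float)
    k1 = deg.mean()
    k2 = (deg**2).mean()
    denom = k2 - k1
    if denom <= 0:
        raise ValueError(
            f"<k^2> - <k> = {denom:g} <= 0 (e.g. a perfect matching); "
            "threshold undefined, supply beta explicitly"
        )
    return k1 / denom
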