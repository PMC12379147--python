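"""Ranking-quality metrics against the SIR ground truth.

Kendall tau-a between score vectors, its mean over a beta grid, the
monotonicity index (how uniquely a method scores nodes), the eta% performance
gain of one method over another, and top-k comparison tables.
"""
from __future__ import annotations

import json
from collections.abc import Hashable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import (
    METHODS,
    SCORE_DECIMALS,
    RankList,
    ScoreTable,
    compute_method,
    rank_nodes,
)
from .graph import Graph
from .sir import SIRConfig, epidemic_threshold, spreading_ability

__all__ = [
    "kendall_tau",
    "sigma_tau",
    "monotonicity",
    "performance_gain",
    "top_k",
    "overlap",
    "beta_grid",
    "EvalReport",
    "evaluate_methods",
    "plot_tau_curves",
]


def kendall_tau(x: Sequence[float], y: Sequence[float], variant: str = "a") -> float:
    """Kendall rank correlation between two equal-length score sequences.

    The default is the untied tau-a form, (N_c - N_d) / (n(n-1)/2): pairs tied
    in either sequence count in neither N_c nor N_d but stay in the
    denominator.  ``variant="b"`` switches to the tie-corrected tau-b
    (delegated to scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"sequences must be 1-d and equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if variant == "b":
        return float(stats.kendalltau(x, y).statistic)
    if variant != "a":
        raise ValueError(f"unknown variant {variant!r}")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    nc_minus_nd = float((sx[iu] * sy[iu]).sum())
    return nc_minus_nd / (0.5 * n * (n - 1))


def sigma_tau(taus: Sequence[float]) -> float:
    """Arithmetic mean of Kendall tau values over the beta grid."""
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise ValueError("empty tau grid")
    return float(taus.mean())


def monotonicity(scores: ScoreTable | Sequence[float], decimals: int = SCORE_DECIMALS) -> float:
    """M = (1 - sum_i N_i(N_i - 1) / (N(N - 1)))^2 over tied-score groups.

    N_i counts nodes sharing a score value (after rounding to ``decimals``
    places); 1 means every node is scored uniquely, 0 means one giant tie.
    """
    vals = (
        np.array(list(scores.scores.values()), dtype=float)
        if isinstance(scores, ScoreTable)
        else np.asarray(scores, dtype=float)
    )
    n = vals.size
    if n < 2:
        raise ValueError("monotonicity needs at least 2 nodes")
    _, counts = np.unique(np.round(vals, decimals), return_counts=True)
    tied = float((counts * (counts - 1)).sum())
    return (1.0 - tied / (n * (n - 1))) ** 2


def performance_gain(tau_c: float, tau_phi: float) -> float:
    """eta% = (tau_c - tau_phi) / |tau_phi| * 100; defined as 0 when tau_phi = 0."""
    if tau_phi == 0:
        return 0.0
    return (tau_c - tau_phi) / abs(tau_phi) * 100.0


def top_k(ranks: RankList, k: int) -> list[Hashable]:
    """First k nodes of a rank list."""
    if not 1 <= k <= len(ranks.nodes):
        raise ValueError(f"k must be in [1, {len(ranks.nodes)}], got {k}")
    return list(ranks.nodes[:k])


def overlap(a: Sequence[Hashable], b: Sequence[Hashable]) -> int:
    """Size of the set intersection of two node lists."""
    return len(set(a) & set(b))


def beta_grid(g: Graph, n_steps: int = 15, step: float = 0.01) -> list[float]:
    """beta_th + step*i for i = 1..n_steps (the grid used for sigma(tau))."""
    bth = epidemic_threshold(g)
    return [bth + step * i for i in range(1, n_steps + 1)]


@dataclass
class EvalReport:
    """Per-method evaluation against SIR ground truth across a beta grid."""

    grid: list[float]
    taus: dict[str, list[float]]  # method -> tau at each beta
    sigma: dict[str, float]  # method -> mean tau over the grid
    monotonicity: dict[str, float]
    eta: dict[str, list[float]]  # baseline -> eta% of candidate per beta
    eta_sigma: dict[str, float]  # baseline -> eta% on sigma(tau)
    top: dict[str, list[Hashable]]  # method -> top-k node labels
    candidate: str
    provenance: dict = field(default_factory=dict)

    def tau_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.taus)
        df.insert(0, "beta", self.grid)
        return df

    def summary_frame(self) -> pd.DataFrame:
        methods = list(self.taus)
        return pd.DataFrame(
            {
                "method": methods,
                "sigma_tau": [self.sigma[m] for m in methods],
                "monotonicity": [self.monotonicity[m] for m in methods],
                "eta_pct_vs_candidate": [self.eta_sigma.get(m, 0.0) for m in methods],
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "grid": self.grid,
            "taus": self.taus,
            "sigma_tau": self.sigma,
            "monotonicity": self.monotonicity,
            "eta_pct": self.eta,
            "eta_pct_sigma": self.eta_sigma,
            "top_k": {m: [str(v) for v in nodes] for m, nodes in self.top.items()},
            "candidate": self.candidate,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_methods(
    g: Graph,
    methods: Sequence[str],
    cfg: SIRConfig,
    grid: Sequence[float],
    candidate: str = "eddc",
    k: int = 10,
    method_params: dict[str, dict] | None = None,
) -> EvalReport:
    """Score each method's ranking against SIR spreading ability.

    For every beta in ``grid`` the SIR mean outbreak sizes are recomputed
    (runs/lam/seed from ``cfg``) and Kendall tau-a is taken between each
    method's score vector and the SIR score vector, aligned on node identity.
    Also reports sigma(tau), the monotonicity of each method's scores, the
    eta% gain of ``candidate`` over each baseline, and top-k node lists.
    Fully determined by ``cfg.rng_seed``.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    if not grid:
        raise ValueError("beta grid must be non-empty")
    method_params = method_params or {}
    tables = {m: compute_method(g, m, **method_params.get(m, {})) for m in methods}
    order = g.nodes
    vectors = {m: t.array(order) for m, t in tables.items()}

    taus: dict[str, list[float]] = {m: [] for m in methods}
    for beta in grid:
        sir_scores = spreading_ability(
            g, SIRConfig(beta=beta, lam=cfg.lam, runs=cfg.runs, rng_seed=cfg.rng_seed)
        ).array(order)
        for m in methods:
            taus[m].append(kendall_tau(vectors[m], sir_scores))

    sigma = {m: sigma_tau(taus[m]) for m in methods}
    mono = {m: monotonicity(tables[m]) for m in methods}
    eta: dict[str, list[float]] = {}
    eta_sig: dict[str, float] = {}
    if candidate in taus:
        for m in methods:
            if m == candidate:
                continue
            eta[m] = [
                performance_gain(tc, tp) for tc, tp in zip(taus[candidate], taus[m])
            ]
            eta_sig[m] = performance_gain(sigma[candidate], sigma[m])
    kk = min(k, g.N)
    top = {m: top_k(rank_nodes(tables[m]), kk) for m in methods}
    return EvalReport(
        grid=list(grid),
        taus=taus,
        sigma=sigma,
        monotonicity=mono,
        eta=eta,
        eta_sigma=eta_sig,
        top=top,
        candidate=candidate,
        provenance={
            "N": g.N,
            "E": g.E,
            "lam": cfg.lam,
            "runs": cfg.runs,
            "rng_seed": cfg.rng_seed,
            "k": kk,
        },
    )


def plot_tau_curves(report: EvalReport, path: str | Path) -> None:
    """Minimal tau-vs-beta line plot, one curve per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for m, vals in report.taus.items():
        ax.plot(report.grid, vals, marker="o", label=m)
    ax.set_xlabel(r"infection probability $\beta$")
    ax.set_ylabel(r"Kendall $\tau$ vs SIR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
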