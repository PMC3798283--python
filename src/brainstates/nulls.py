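"""Degree-matched random networks and null-normalized metrics.

Null graphs are built by repeated double-edge swaps: (a-b, c-d) becomes
(a-d, c-b), rejecting self-loops and multi-edges, with each weight
traveling with its original edge. This preserves the exact degree sequence
and the exact weight multiset while randomizing topology. Raw metrics are
divided by the mean over ``n_null`` such graphs; small-worldness is
``sigma = nC / nL``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .atlas import ValidationError
from .metrics import MetricRecord, compute_metrics
from .thresholding import BrainGraph


@njit(cache=True)
def _swap_kernel(edge_i, edge_j, adj, n_target, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_edges = edge_i.shape[0]
    done = 0
    attempts = 0
    while done < n_target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edge_i[e1], edge_j[e1]
        c, d = edge_i[e2], edge_j[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edge_i[e1], edge_j[e1] = a, d
        edge_i[e2], edge_j[e2] = c, b
        done += 1
    return done


def rewire(graph: BrainGraph, swaps_per_edge: int = 10, seed: int = 0) -> BrainGraph:
    """Degree-preserving randomization; weights stay on their original edges."""
    i, j, w = graph.edge_list()
    if i.size < 2:
        raise ValidationError("need at least 2 edges to rewire")
    if swaps_per_edge == 0:
        return BrainGraph(graph.weights.copy(), graph.density, graph.subject,
                          graph.condition, provenance="rewire(0 swaps)")
    adj = graph.weights > 0
    ei, ej = i.astype(np.int64).copy(), j.astype(np.int64).copy()
    n_target = int(swaps_per_edge * i.size)
    achieved = _swap_kernel(ei, ej, adj.copy(), n_target, 10 * n_target,
                            int(np.uint32(seed)))
    if achieved < n_target:
        warnings.warn(
            f"rewiring achieved {achieved}/{n_target} swaps within attempt budget",
            RuntimeWarning, stacklevel=2,
        )
    out = np.zeros_like(graph.weights)
    out[ei, ej] = w
    out[ej, ei] = w
    return BrainGraph(out, graph.density, graph.subject, graph.condition,
                      provenance=f"rewire({swaps_per_edge} swaps/edge, seed={seed})")


@dataclass
class NormalizedMetrics:
    """Raw metrics together with null means and normalized ratios."""

    raw: MetricRecord
    null_means: dict[str, float]
    nC: float
    nL: float
    nE: float
    nQ: float
    sigma: float
    n_null: int
    seed: int
    provenance: str = field(default="double-edge-swap nulls, weights travel with edges")


def normalize_metrics(
    graph: BrainGraph,
    n_null: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    n_restarts: int = 50,
    null_restarts: int = 10,
    include_modularity: bool = True,
    raw: MetricRecord | None = None,
) -> NormalizedMetrics:
    """Normalize C, L, E, Q by their means over a matched null ensemble.

    ``raw`` may carry precomputed metrics of the real graph; otherwise they
    are computed here with ``n_restarts`` modularity restarts. Null graphs
    use ``null_restarts`` restarts (the ensemble mean needs less precision
    per draw).
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    if raw is None:
        raw = compute_metrics(graph, n_restarts=n_restarts, seed=seed,
                              include_local=False,
                              include_modularity=include_modularity)
    if swaps_per_edge == 0:
        # degenerate ensemble: every null equals the graph itself
        means = {"C": raw.C, "L": raw.L, "E": raw.E, "Q": raw.Q}
        return NormalizedMetrics(
            raw=raw, null_means=means, nC=1.0, nL=1.0, nE=1.0,
            nQ=1.0 if include_modularity else float("nan"),
            sigma=1.0, n_null=n_null, seed=seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(np.uint32(seed)), 0x17]))
    null_vals = {"C": [], "L": [], "E": [], "Q": []}
    for _ in range(n_null):
        null_seed = int(rng.integers(0, 2**31 - 1))
        null = rewire(graph, swaps_per_edge=swaps_per_edge, seed=null_seed)
        rec = compute_metrics(null, n_restarts=null_restarts, seed=null_seed,
                              include_local=False,
                              include_modularity=include_modularity)
        null_vals["C"].append(rec.C)
        null_vals["L"].append(rec.L)
        null_vals["E"].append(rec.E)
        null_vals["Q"].append(rec.Q)
    means = {k: float(np.mean(v)) for k, v in null_vals.items()}
    for k in ("C", "L", "E") + (("Q",) if include_modularity else ()):
        if means[k] == 0:
            raise ValidationError(f"null mean of {k} is zero; cannot normalize")
    nc = raw.C / means["C"]
    nl = raw.L / means["L"]
    ne = raw.E / means["E"]
    nq = raw.Q / means["Q"] if include_modularity else float("nan")
    return NormalizedMetrics(
        raw=raw, null_means=means, nC=nc, nL=nl, nE=ne, nQ=nq,
        sigma=nc / nl, n_null=n_null, seed=seed,
    )


def threshold_constraint_table(
    matrices_by_condition: dict[str, list],
    densities: list[float],
    n_null: int = 20,
    seed: int = 0,
) -> "pd.DataFrame":
    """Per-density, per-condition mean degree and small-worldness.

    Feeds :func:`brainstates.thresholding.select_threshold_range`:
    ``matrices_by_condition`` maps condition labels to lists of
    ConnectivityMatrix; each matrix is thresholded at each candidate
    density and sigma is estimated against ``n_null`` rewired nulls.
    """
    import pandas as pd

    from .thresholding import proportional_threshold

    rng = np.random.default_rng(np.random.SeedSequence([int(np.uint32(seed)), 0x7B]))
    rows = []
    for cond, mats in matrices_by_condition.items():
        for dens in densities:
            degrees, sigmas = [], []
            for m in mats:
                g = proportional_threshold(m, dens)
                degrees.append(float(g.degrees().mean()))
                nm = normalize_metrics(g, n_null=n_null,
                                       seed=int(rng.integers(0, 2**31 - 1)),
                                       include_modularity=False)
                sigmas.append(nm.sigma)
            rows.append((dens, cond, float(np.mean(degrees)),
                         float(np.mean(sigmas)), mats[0].n))
    return pd.DataFrame(rows, columns=["density", "condition", "mean_degree",
                                       "sigma", "n_nodes"])
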