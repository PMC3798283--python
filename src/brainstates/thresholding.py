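"""Proportional density thresholding of connectivity matrices.

A graph at density ``t`` keeps the strongest ``t``% of the N(N-1)/2
possible edges by signed correlation — negative correlations never enter a
graph — with the original weights preserved on the retained edges. The
analysis density range is bounded below by mean degree >= 2*ln(N) (network
estimability) and above by mean small-worldness >= 1 in every condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ConnectivityMatrix, ValidationError


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class BrainGraph:
    """Symmetric non-negative weighted adjacency at a stated edge density."""

    weights: np.ndarray
    density: float
    subject: str = ""
    condition: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("adjacency must be symmetric")
        if np.diag(w).any():
            raise ValidationError("adjacency diagonal must be zero")
        if (w < 0).any():
            raise ValidationError("retained weights must be positive")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def degrees(self) -> np.ndarray:
        return (np.triu(self.weights, k=1) > 0).sum(axis=0) + \
               (np.triu(self.weights, k=1) > 0).sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays over retained edges with i < j."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.weights[iu, ju] > 0
        return iu[keep], ju[keep], self.weights[iu[keep], ju[keep]]


def proportional_threshold(matrix: ConnectivityMatrix, density: float) -> BrainGraph:
    """Keep the strongest ``round(density * M)`` positive edges, weights intact.

    Ranking is by signed correlation, descending; ties at the cutoff are
    broken by (lower i, lower j) order, which makes the retained edge set
    at a lower density a subset of that at any higher density.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must be in (0, 1]")
    n = matrix.n
    m = n * (n - 1) // 2
    k = _round_half_up(density * m)
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.values[iu, ju]
    n_pos = int((vals > 0).sum())
    if k > n_pos:
        raise ValidationError(
            f"requested {k} edges but only {n_pos} positive correlations exist "
            f"(maximum achievable density {n_pos / m:.4f})"
        )
    # stable sort on descending value; row-major (i, j) order breaks ties
    order = np.argsort(-vals, kind="stable")[:k]
    w = np.zeros((n, n))
    w[iu[order], ju[order]] = vals[order]
    w += w.T
    return BrainGraph(
        w, density=density, subject=matrix.subject, condition=matrix.condition,
        provenance=f"proportional_threshold(density={density})",
    )


def select_threshold_range(
    constraint_table: pd.DataFrame,
    step: float = 0.05,
    degree_factor: float = 2.0,
) -> list[float]:
    """Pick the admissible density grid from per-density condition summaries.

    ``constraint_table`` has one row per (density, condition) with columns
    ``density``, ``condition``, ``mean_degree``, ``sigma`` (mean
    small-worldness) and ``n_nodes``. The lower bound is the smallest
    density whose mean degree is >= ``degree_factor * ln(N)`` in every
    condition; the upper bound is the largest density with sigma >= 1 in
    every condition. The returned grid runs lower..upper in ``step``
    increments.
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    t = constraint_table
    densities = np.array(sorted(t["density"].unique()))
    deg_ok, sig_ok = [], []
    for d in densities:
        sub = t[t["density"] == d]
        thresh = degree_factor * np.log(sub["n_nodes"].to_numpy(float))
        deg_ok.append(bool((sub["mean_degree"].to_numpy(float) >= thresh).all()))
        sig_ok.append(bool((sub["sigma"].to_numpy(float) >= 1.0).all()))
    deg_ok, sig_ok = np.array(deg_ok), np.array(sig_ok)
    if not deg_ok.any() or not sig_ok.any():
        raise ValidationError(
            "empty admissible density range: "
            f"degree constraint satisfied at {densities[deg_ok].tolist()}, "
            f"small-worldness constraint satisfied at {densities[sig_ok].tolist()}"
        )
    lower = densities[deg_ok].min()
    upper = densities[sig_ok].max()
    if lower > upper:
        raise ValidationError(
            f"empty admissible density range: lower bound {lower} exceeds upper {upper}"
        )
    grid = []
    d = lower
    while d <= upper + 1e-9:
        grid.append(round(float(d), 10))
        d += step
    return grid
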