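"""Temporal cleaning of ROI time series and Pearson connectivity construction.

Cleaning order is fixed: trim initial volumes, remove per-ROI linear and
quadratic trends, partial out nuisance regressors, zero-phase band-pass.
Global-signal regression is deliberately not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .atlas import ConnectivityMatrix, TimeSeriesPanel, ValidationError


def detrend_quadratic(x: np.ndarray) -> np.ndarray:
    """Remove per-column constant, linear and quadratic trends (least squares)."""
    t = x.shape[0]
    tt = np.linspace(-1, 1, t)
    basis = np.column_stack([np.ones(t), tt, tt**2])
    return x - basis @ np.linalg.lstsq(basis, x, rcond=None)[0]


def clean_timeseries(
    panel: TimeSeriesPanel,
    band: tuple[float, float] = (0.01, 0.1),
    nuisance: np.ndarray | None = None,
    trim: int = 4,
) -> TimeSeriesPanel:
    """Trim, detrend (linear+quadratic), regress nuisance, band-pass.

    ``band`` is (low, high) in Hz and must sit inside (0, Nyquist) for the
    panel's TR. ``nuisance`` is a T x m regressor matrix aligned with the
    *un-trimmed* panel; it is trimmed along with the data. The band-pass is
    a zero-phase (forward-backward) Butterworth filter, so correlations are
    not distorted by phase shifts.
    """
    if trim >= panel.n_timepoints:
        raise ValidationError("trim must be smaller than the panel length")
    nyq = 1.0 / (2.0 * panel.tr)
    low, high = band
    if not (0 < low < high < nyq):
        raise ValidationError(f"band {band} outside (0, {nyq:.4g}) Hz")

    x = detrend_quadratic(panel.data[trim:])
    t = x.shape[0]

    if nuisance is not None:
        nuis = np.asarray(nuisance, float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] == panel.n_timepoints:
            nuis = nuis[trim:]
        elif nuis.shape[0] != t:
            raise ValidationError("nuisance regressors do not match panel length")
        nuis = np.column_stack([np.ones(t), nuis])
        if np.linalg.matrix_rank(nuis) < nuis.shape[1]:
            warnings.warn("rank-deficient nuisance matrix; using pseudo-inverse",
                          RuntimeWarning, stacklevel=2)
        x -= nuis @ np.linalg.lstsq(nuis, x, rcond=None)[0]

    b, a = signal.butter(2, [low / nyq, high / nyq], btype="bandpass")
    x = signal.filtfilt(b, a, x, axis=0)
    return TimeSeriesPanel(panel.subject, panel.condition, x, tr=panel.tr)


def correlation_matrix(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI time courses; diagonal set to 1."""
    if panel.n_timepoints < 3:
        raise ValidationError("need at least 3 timepoints for correlation")
    sd = panel.data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValidationError(f"constant-valued ROI column(s): {constant.tolist()}")
    r = np.corrcoef(panel.data, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, subject=panel.subject, condition=panel.condition)


@dataclass(frozen=True)
class CorrelationSummary:
    median: float
    prop_negative: float
    prop_above_04: float
    prop_0_to_04: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "prop_negative": self.prop_negative,
            "prop_above_04": self.prop_above_04,
            "prop_0_to_04": self.prop_0_to_04,
            "hist_counts": self.hist_counts.tolist(),
            "hist_edges": self.hist_edges.tolist(),
        }


def correlation_summary(matrices: list[ConnectivityMatrix],
                        n_hist_bins: int = 40) -> CorrelationSummary:
    """Descriptives of the condition-mean matrix's upper triangle.

    Reports the median correlation, the proportion of negative values,
    the proportion above 0.4 and the proportion in [0, 0.4].
    """
    if not matrices:
        raise ValidationError("need at least one matrix")
    mean = np.mean([m.values for m in matrices], axis=0)
    r = ConnectivityMatrix(mean).upper_triangle()
    counts, edges = np.histogram(r, bins=n_hist_bins, range=(-1, 1))
    return CorrelationSummary(
        median=float(np.median(r)),
        prop_negative=float(np.mean(r < 0)),
        prop_above_04=float(np.mean(r > 0.4)),
        prop_0_to_04=float(np.mean((r >= 0) & (r <= 0.4))),
        hist_counts=counts,
        hist_edges=edges,
    )


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bin_by_distance(
    matrix: ConnectivityMatrix,
    dist: np.ndarray,
    bin_width: float = 9.0,
    n_bins: int = 15,
) -> "pd.DataFrame":
    """Mean upper-triangle correlation per inter-ROI distance bin.

    Bins are half-open [k*w, (k+1)*w); the last bin absorbs all larger
    distances. Returns a DataFrame (bin, center_mm, mean_r, n_pairs).
    """
    import pandas as pd

    if bin_width <= 0 or n_bins < 1:
        raise ValidationError("bin_width must be > 0 and n_bins >= 1")
    iu = np.triu_indices(matrix.n, k=1)
    r = matrix.values[iu]
    d = np.asarray(dist, float)[iu]
    idx = np.minimum((d // bin_width).astype(int), n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        rows.append((
            k,
            (k + 0.5) * bin_width,
            float(r[sel].mean()) if sel.any() else np.nan,
            int(sel.sum()),
        ))
    out = pd.DataFrame(rows, columns=["bin", "center_mm", "mean_r", "n_pairs"])
    if (out["n_pairs"] > 0).sum() == 1:
        warnings.warn("all ROI pairs fall in a single distance bin",
                      RuntimeWarning, stacklevel=2)
    return out
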