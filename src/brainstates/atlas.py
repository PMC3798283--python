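"""ROI atlas, time-series panels and connectivity matrices: containers and TSV I/O.

The atlas defines the canonical node order for every matrix in a study:
``roi_id`` is remapped to contiguous 0..N-1 on load, preserving file order.
All delimited formats are plain TSV so they stay diff-able and human
readable; floats are written at 10 significant digits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

#: anatomical subdivisions, in display order
SUBDIVISIONS = ("Fcx", "Tcx", "Pcx", "Ocx", "BG", "Thl", "BS", "Crbl")

#: cortical subdivisions (lobe-level); used by the edge taxonomy
CORTICAL = frozenset({"Fcx", "Tcx", "Pcx", "Ocx"})

#: study conditions in protocol order: wakefulness, sedation,
#: loss of consciousness, recovery
CONDITIONS = ("W", "S", "LOC", "R")

FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """A file does not match the expected delimited layout."""


class ValidationError(ValueError):
    """Contents parsed but violate a study invariant."""


@dataclass(frozen=True)
class ROIAtlas:
    """Node table: id, name, 8-way subdivision and barycenter coordinates (mm)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["roi_id", "name", "subdivision", "x", "y", "z"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"atlas missing columns: {missing}")
        if t["roi_id"].duplicated().any():
            raise ValidationError("duplicate roi_id in atlas")
        bad = set(t["subdivision"]) - set(SUBDIVISIONS)
        if bad:
            raise ValidationError(f"unknown subdivision labels: {sorted(bad)}")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy(float)).all():
            raise ValidationError("non-finite atlas coordinate")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def subdivision(self) -> np.ndarray:
        return self.table["subdivision"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """N x 3 array of barycenter coordinates in mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_atlas(path: str | os.PathLike) -> ROIAtlas:
    """Read an atlas TSV; roi_id is remapped to 0..N-1 in file order."""
    table = pd.read_csv(path, sep="\t")
    if "roi_id" not in table.columns:
        raise FormatError("atlas file lacks a roi_id column")
    if table["roi_id"].duplicated().any():
        raise ValidationError("duplicate roi_id in atlas file")
    table = table.copy()
    table["roi_id"] = np.arange(len(table))
    return ROIAtlas(table.reset_index(drop=True))


@dataclass
class TimeSeriesPanel:
    """One scan: T x N matrix of ROI signals for one subject in one condition."""

    subject: str
    condition: str
    data: np.ndarray
    tr: float = 2.46

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValidationError("time series must be T x N with T >= 2")
        if not np.isfinite(self.data).all():
            raise ValidationError("non-finite value in time series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson-r matrix with unit diagonal."""

    values: np.ndarray
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("connectivity matrix must be symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValidationError("correlations outside [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Vector of the N(N-1)/2 unique off-diagonal entries, row-major i<j."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class StudyDataset:
    """Balanced panel of scans: every subject present in every condition."""

    atlas: ROIAtlas
    panels: dict[tuple[str, str], TimeSeriesPanel]

    def __post_init__(self) -> None:
        ns = {p.n_roi for p in self.panels.values()}
        if len(ns) > 1:
            raise ValidationError(f"inconsistent ROI counts across panels: {sorted(ns)}")
        if ns and ns.pop() != self.atlas.n:
            raise ValidationError("panel ROI count does not match atlas size")
        for s in self.subjects:
            missing = [c for c in CONDITIONS if (s, c) not in self.panels]
            if missing:
                raise ValidationError(
                    f"subject {s!r} missing conditions {missing}: paired design requires "
                    "all four conditions per subject"
                )

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.panels})

    def panel(self, subject: str, condition: str) -> TimeSeriesPanel:
        return self.panels[(subject, condition)]

    def drop_subjects(self, subjects: set[str]) -> "StudyDataset":
        kept = {k: v for k, v in self.panels.items() if k[0] not in subjects}
        return StudyDataset(self.atlas, kept)


# ---------------------------------------------------------------------------
# matrix / panel TSV round trip

def write_matrix(values: np.ndarray, names: list[str], path: str | os.PathLike) -> None:
    """Write a square matrix as TSV with a header row of ROI names."""
    pd.DataFrame(values, columns=names).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    v = df.to_numpy(float)
    if v.shape[0] != v.shape[1]:
        raise FormatError(f"matrix file {path} is not square: {v.shape}")
    return v, list(df.columns)


def write_timeseries(panel: TimeSeriesPanel, names: list[str], path: str | os.PathLike) -> None:
    pd.DataFrame(panel.data, columns=names).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def load_study(manifest: str | os.PathLike, atlas: ROIAtlas, *, t_max: int = 196,
               tr: float = 2.46) -> StudyDataset:
    """Load a study from a manifest TSV (subject, condition, timeseries_path).

    Panels longer than ``t_max`` timepoints are truncated to the first
    ``t_max`` rows so all scans enter the analysis with equal length.
    Relative paths are resolved against the manifest's directory.
    """
    man = pd.read_csv(manifest, sep="\t")
    required = ["subject", "condition", "timeseries_path"]
    missing = [c for c in required if c not in man.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    base = os.path.dirname(os.fspath(manifest))
    panels: dict[tuple[str, str], TimeSeriesPanel] = {}
    for row in man.itertuples(index=False):
        p = row.timeseries_path
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        data = pd.read_csv(p, sep="\t").to_numpy(float)
        if data.shape[0] > t_max:
            data = data[:t_max]
        panels[(str(row.subject), row.condition)] = TimeSeriesPanel(
            str(row.subject), row.condition, data, tr=tr
        )
    return StudyDataset(atlas, panels)


def euclidean_distances(atlas: ROIAtlas) -> np.ndarray:
    """N x N matrix of 3-D Euclidean distances (mm) between ROI barycenters."""
    coords = atlas.coords
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinate in atlas")
    return squareform(pdist(coords))
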