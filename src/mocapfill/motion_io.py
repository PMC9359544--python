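"""Data model and file I/O for marker-trajectory matrices.

A motion sample is an ``m_frames x 3*n_markers`` matrix whose columns are
ordered x, y, z per marker, together with a 0/1 observation mask of the same
shape.  Gaps — contiguous frame intervals during which one marker (or every
marker) is unobserved — are represented explicitly so they can be transplanted
onto training data.  A skeleton connectivity graph provides shortest-path
distances between markers, used by the locally weighted taper masks.

Missing values are stored as 0 internally (after de-meaning this coincides
with mean imputation); NaN appears only at the file boundary (CSV/TRC).
Gap granularity is the whole marker: a NaN in any one coordinate marks all
three coordinates of that marker missing at that frame.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MotionSample",
    "GapSpec",
    "FrameGapSpec",
    "SkeletonModel",
    "read_motion",
    "write_motion",
    "apply_gaps",
    "apply_frame_gaps",
    "gaps_from_mask",
    "skeleton_distance",
]


class MotionFormatError(ValueError):
    """Raised when a motion file cannot be parsed as the named format."""


@dataclass
class GapSpec:
    """A missing-marker interval: ``marker`` unobserved on frames [start, end)."""

    marker: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap interval [{self.start}, {self.end})")
        if self.marker < 0:
            raise ValueError(f"negative marker index {self.marker}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FrameGapSpec:
    """A run of wholly missing frames [start, end): every marker unobserved."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid frame-gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def frames(self) -> range:
        return range(self.start, self.end)


@dataclass
class MotionSample:
    """A frames x (3*markers) trajectory matrix with an observation mask.

    Parameters
    ----------
    values
        Real matrix of shape ``(m_frames, 3*n_markers)``; columns ordered
        x, y, z per marker, in dataset length units.
    marker_names
        One name per marker.
    mask
        0/1 matrix of the same shape; 1 = observed.  Defaults to all-ones.
    frame_rate
        Frames per second, if known.
    """

    values: np.ndarray
    marker_names: list[str]
    mask: np.ndarray | None = None
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, c = self.values.shape
        if m < 1:
            raise ValueError("need at least one frame")
        if c % 3 != 0:
            raise ValueError(f"column count {c} not divisible by 3")
        if len(self.marker_names) != c // 3:
            raise ValueError("marker_names length does not match column count / 3")
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=np.uint8)
        else:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask entries must be 0 or 1")
            self.mask = self.mask.astype(np.uint8)
        if not np.isfinite(self.values[self.mask == 1]).all():
            raise ValueError("observed entries (mask=1) must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1] // 3

    def marker_columns(self, marker: int) -> slice:
        """Column slice holding the x, y, z coordinates of ``marker``."""
        if not 0 <= marker < self.n_markers:
            raise IndexError(f"marker {marker} out of range [0, {self.n_markers})")
        return slice(3 * marker, 3 * marker + 3)

    def copy(self) -> "MotionSample":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class SkeletonModel:
    """Marker connectivity graph; edge weights default to 1 per bone."""

    n_markers: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        n_markers: int,
        edges: list[tuple[int, int]] | list[tuple[int, int, float]],
    ) -> "SkeletonModel":
        g = nx.Graph()
        g.add_nodes_from(range(n_markers))
        for e in edges:
            i, j = int(e[0]), int(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if i == j:
                raise ValueError(f"self-loop on marker {i}")
            if w < 0:
                raise ValueError(f"negative edge weight {w}")
            if not (0 <= i < n_markers and 0 <= j < n_markers):
                raise ValueError(f"edge ({i}, {j}) outside marker range")
            g.add_edge(i, j, weight=w)
        return cls(n_markers=n_markers, graph=g)

    @classmethod
    def from_file(cls, path: str, marker_names: list[str] | None = None) -> "SkeletonModel":
        """Load a skeleton from a 2-column edge-list text file or a YAML file.

        YAML files carry ``edges: [[a, b], ...]`` with integer indices or
        marker names (names require ``marker_names``).
        """
        def resolve(tok: str) -> int:
            tok = str(tok)
            if re.fullmatch(r"\d+", tok):
                return int(tok)
            if marker_names is None or tok not in marker_names:
                raise ValueError(f"unknown marker name {tok!r} in skeleton file")
            return marker_names.index(tok)

        edges: list[tuple[int, int, float]] = []
        if path.endswith((".yml", ".yaml")):
            with open(path) as fh:
                doc = yaml.safe_load(fh)
            for e in doc["edges"]:
                w = float(e[2]) if len(e) > 2 else 1.0
                edges.append((resolve(e[0]), resolve(e[1]), w))
        else:
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    toks = line.split()
                    w = float(toks[2]) if len(toks) > 2 else 1.0
                    edges.append((resolve(toks[0]), resolve(toks[1]), w))
        n = (
            len(marker_names)
            if marker_names is not None
            else 1 + max(max(i, j) for i, j, _ in edges)
        )
        return cls.from_edges(n, edges)

    def distance(self, j1: int, j2: int) -> float:
        return skeleton_distance(self, j1, j2)


def skeleton_distance(skeleton: SkeletonModel, j1: int, j2: int) -> float:
    """Shortest-path distance between two markers on the skeleton graph.

    Symmetric, zero iff ``j1 == j2`` (on simple graphs), and satisfies the
    triangle inequality; raises if the two markers are disconnected, since a
    taper mask cannot be built for unreachable markers.
    """
    g = skeleton.graph
    for j in (j1, j2):
        if j not in g:
            raise KeyError(f"marker {j} not in skeleton graph")
    if j1 == j2:
        return 0.0
    try:
        return float(nx.shortest_path_length(g, j1, j2, weight="weight"))
    except nx.NetworkXNoPath:
        raise ValueError(f"markers {j1} and {j2} are disconnected in the skeleton") from None


# ---------------------------------------------------------------------------
# gap application


def _check_gap(gap: GapSpec, m: int, n: int) -> None:
    if gap.marker >= n:
        raise IndexError(f"gap marker {gap.marker} out of range [0, {n})")
    if gap.end > m:
        raise IndexError(f"gap interval [{gap.start}, {gap.end}) exceeds {m} frames")


def apply_gaps(sample: MotionSample, gaps: list[GapSpec]) -> MotionSample:
    """Return a copy of ``sample`` with each gap's block masked and zeroed.

    Each gap zeroes mask and values over its marker's three coordinate
    columns and its frame interval; the input sample is untouched.
    Idempotent: applying the same gap list twice equals applying it once.
    """
    out = sample.copy()
    for gap in gaps:
        _check_gap(gap, out.n_frames, out.n_markers)
        cols = out.marker_columns(gap.marker)
        out.values[gap.start : gap.end, cols] = 0.0
        out.mask[gap.start : gap.end, cols] = 0
    return out


def apply_frame_gaps(sample: MotionSample, frame_gaps: list[FrameGapSpec]) -> MotionSample:
    """Return a copy with whole frames masked and zeroed (all markers)."""
    out = sample.copy()
    for fg in frame_gaps:
        if fg.end > out.n_frames:
            raise IndexError(f"frame gap [{fg.start}, {fg.end}) exceeds {out.n_frames} frames")
        out.values[fg.start : fg.end, :] = 0.0
        out.mask[fg.start : fg.end, :] = 0
    return out


def gaps_from_mask(mask: np.ndarray) -> list[GapSpec]:
    """Recover per-marker GapSpecs from an observation mask.

    Assumes marker granularity (all three coordinates share the same mask);
    overlapping/adjacent missing runs per marker are merged.
    """
    mask = np.asarray(mask)
    m, c = mask.shape
    gaps: list[GapSpec] = []
    for j in range(c // 3):
        missing = (mask[:, 3 * j : 3 * j + 3] == 0).any(axis=1)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            gaps.append(GapSpec(marker=j, start=int(s), end=int(e)))
    return gaps


# ---------------------------------------------------------------------------
# readers / writers


def _marker_granularity(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NaN in any coordinate of a marker masks all three; values zeroed."""
    m, c = values.shape
    mask = np.ones((m, c), dtype=np.uint8)
    for j in range(c // 3):
        cols = slice(3 * j, 3 * j + 3)
        bad = ~np.isfinite(values[:, cols]).all(axis=1)
        mask[bad, cols] = 0
    values = np.where(mask == 1, values, 0.0)
    return values, mask


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("c3d", "trc", "csv"):
        return ext
    raise MotionFormatError(f"cannot infer motion format from {path!r}")


def read_motion(path: str, format: str | None = None) -> MotionSample:
    """Read a motion sample from a C3D, TRC, or CSV file.

    Missing observations (NaN in CSV/TRC, empty TRC fields, negative residual
    in C3D) yield mask=0 and value 0.  Columns are ordered x, y, z per marker
    in file marker order.
    """
    fmt = (format or _infer_format(path)).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "trc":
        return _read_trc(path)
    if fmt == "c3d":
        return _read_c3d(path)
    raise MotionFormatError(f"unknown motion format {format!r}")


def write_motion(sample: MotionSample, path: str, format: str | None = None) -> None:
    """Write a motion sample to TRC or CSV; mask=0 entries are encoded as NaN."""
    fmt = (format or _infer_format(path)).lower()
    if fmt == "csv":
        _write_csv(sample, path)
    elif fmt == "trc":
        _write_trc(sample, path)
    else:
        raise MotionFormatError(f"unsupported output format {format!r}")


def _read_csv(path: str) -> MotionSample:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise MotionFormatError(f"cannot parse {path!r} as CSV: {exc}") from exc
    if df.shape[1] % 3 != 0:
        raise MotionFormatError(
            f"{path!r}: {df.shape[1]} columns is not divisible by 3"
        )
    names = []
    for c in range(0, df.shape[1], 3):
        col = str(df.columns[c])
        names.append(col[:-2] if col.endswith(("_x", "_X")) else f"M{c // 3}")
    values = df.to_numpy(dtype=float)
    values, mask = _marker_granularity(values)
    return MotionSample(values=values, marker_names=names, mask=mask)


def _write_csv(sample: MotionSample, path: str) -> None:
    cols = [f"{nm}_{ax}" for nm in sample.marker_names for ax in "xyz"]
    out = np.where(sample.mask == 1, sample.values, np.nan)
    pd.DataFrame(out, columns=cols).to_csv(path, index=False)


def _read_trc(path: str) -> MotionSample:
    """Parse a TRC file (tab-separated; headers on lines 1-5, data from line 7).

    TRC frame numbers are 1-based; they are discarded on read, and internal
    frame indexing is 0-based.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise MotionFormatError(f"{path!r}: missing TRC PathFileType header (line 1)")
    meta = dict(zip(lines[1].split("\t"), lines[2].split("\t")))
    try:
        rate = float(meta.get("DataRate", "nan"))
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise MotionFormatError(f"{path!r}: bad TRC header record (line 3)") from exc
    names = [t for t in lines[3].split("\t")[2:] if t][:n_markers]
    if len(names) != n_markers:
        raise MotionFormatError(f"{path!r}: marker-name row lists {len(names)} of {n_markers} markers")
    rows = []
    for ln_no, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        toks = line.split("\t")
        coords = toks[2 : 2 + 3 * n_markers]
        coords += [""] * (3 * n_markers - len(coords))
        try:
            rows.append([float(t) if t.strip() else np.nan for t in coords])
        except ValueError as exc:
            raise MotionFormatError(f"{path!r}: bad data record on line {ln_no}") from exc
    if not rows:
        raise MotionFormatError(f"{path!r}: no data rows")
    values, mask = _marker_granularity(np.asarray(rows, dtype=float))
    return MotionSample(
        values=values,
        marker_names=names,
        mask=mask,
        frame_rate=rate if np.isfinite(rate) else None,
    )


def _write_trc(sample: MotionSample, path: str) -> None:
    rate = sample.frame_rate or 120.0
    m, n = sample.n_frames, sample.n_markers
    out = np.where(sample.mask == 1, sample.values, np.nan)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{os.path.basename(path)}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{m}\t{n}\tmm\t{rate:g}\t1\t{m}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(sample.marker_names) + "\t\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{j + 1}\tY{j + 1}\tZ{j + 1}" for j in range(n))
            + "\n"
        )
        for i in range(m):
            cells = ["" if np.isnan(v) else f"{v:.8f}" for v in out[i]]
            fh.write(f"{i + 1}\t{i / rate:.6f}\t" + "\t".join(cells) + "\n")


def _read_c3d(path: str) -> MotionSample:
    """Read marker trajectories from a binary C3D file via ``ezc3d``.

    Points flagged invalid (negative residual) or non-finite are treated as
    missing.  Analog channels are ignored.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package "
            "(pip install ezc3d); TRC and CSV need no extra dependency"
        ) from exc
    c = ezc3d.c3d(path)
    pts = c["data"]["points"]  # (4, n_markers, n_frames)
    n_markers, m = pts.shape[1], pts.shape[2]
    values = np.transpose(pts[:3], (2, 1, 0)).reshape(m, 3 * n_markers)
    resid = c["data"]["meta_points"]["residuals"][0]  # (n_markers, n_frames)
    invalid = (resid < 0).T  # (m, n_markers)
    values = values.copy()
    for j in range(n_markers):
        values[invalid[:, j], 3 * j : 3 * j + 3] = np.nan
    values, mask = _marker_granularity(values)
    names = [str(s).strip() for s in c["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c["parameters"]["POINT"]["RATE"]["value"][0])
    return MotionSample(values=values, marker_names=names, mask=mask, frame_rate=rate or None)
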