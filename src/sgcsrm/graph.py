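"""Electrode graph construction.

The electrode montage is modelled as points on a sphere.  The initial
adjacency follows an inverse-square distance law, A_ij = min(1, delta/d_ij^2),
reflecting the observation that inter-regional brain correlations decay
roughly with the inverse square of Euclidean distance.  Selected homologous
left-right electrode pairs ("global connections") are re-initialized to a
negative weight so the network can express hemispheric asymmetry from the
start.  The propagation operator is the symmetrically normalized graph
S = D^{-1/2} (A + I) D^{-1/2}; degrees use absolute values so that negative
(asymmetry) edges keep the operator real.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ElectrodeLayout",
    "AdjacencyMatrix",
    "NormalizedGraph",
    "GLOBAL_CONNECTION_PAIRS",
    "load_layout_csv",
    "seed62_layout",
    "pairwise_distances",
    "init_adjacency",
    "apply_global_connections",
    "normalize_adjacency",
]

#: Homologous left-right electrode pairs given a special initial weight.
GLOBAL_CONNECTION_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"),
    ("AF3", "AF4"),
    ("F5", "F6"),
    ("FC5", "FC6"),
    ("C5", "C6"),
    ("CP5", "CP6"),
    ("P5", "P6"),
    ("PO5", "PO6"),
    ("O1", "O2"),
)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Named electrodes with 3-D scalp coordinates (cm)."""

    names: tuple[str, ...]
    coords: np.ndarray  # (C, 3)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.names) != len(set(self.names)):
            raise ValueError("electrode names must be unique")
        if coords.shape != (len(self.names), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.names)}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("electrode coordinates must be finite")
        if len(self.names) < 2:
            raise ValueError("a layout needs at least 2 electrodes")

    def subset(self, names: list[str] | tuple[str, ...]) -> "ElectrodeLayout":
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"electrodes not in layout: {missing}")
        rows = [index[n] for n in names]
        return ElectrodeLayout(tuple(names), self.coords[rows])


@dataclass
class AdjacencyMatrix:
    """A (possibly learnable) electrode graph, one per frequency band."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    delta: float = 5.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        c = len(self.channel_names)
        if self.values.shape != (c, c):
            raise ValueError(f"adjacency shape {self.values.shape} != ({c}, {c})")

    def copy(self) -> "AdjacencyMatrix":
        return AdjacencyMatrix(self.values.copy(), self.channel_names, self.delta)


@dataclass
class NormalizedGraph:
    """The symmetric normalization S of an adjacency matrix."""

    values: np.ndarray


def load_layout_csv(path_or_buffer) -> ElectrodeLayout:
    """Read an electrode layout from CSV with columns ``name,x,y,z``."""
    df = pd.read_csv(path_or_buffer)
    expected = ["name", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"layout CSV must have columns {expected}, got {list(df.columns)}")
    return ElectrodeLayout(tuple(df["name"].astype(str)), df[["x", "y", "z"]].to_numpy(float))


def seed62_layout() -> ElectrodeLayout:
    """The bundled 62-electrode 10-10 montage on a spherical scalp model.

    Coordinates are pre-scaled so that with the default ``delta = 5`` about
    20% of inter-electrode relationships saturate at full weight.
    """
    text = resources.files("sgcsrm.data").joinpath("seed62.csv").read_text()
    return load_layout_csv(io.StringIO(text))


def pairwise_distances(layout: ElectrodeLayout) -> np.ndarray:
    """Euclidean distance matrix between electrodes."""
    diff = layout.coords[:, None, :] - layout.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    c = len(layout.names)
    off = ~np.eye(c, dtype=bool)
    if np.any(dist[off] == 0):
        warnings.warn("duplicate electrode coordinates: zero off-diagonal distance")
    return dist


def init_adjacency(dist: np.ndarray, delta: float = 5.0, channel_names=None) -> AdjacencyMatrix:
    """Initial adjacency A_ij = min(1, delta / d_ij^2), with unit diagonal.

    Coincident electrodes (d_ij = 0 off-diagonal) get the saturated weight 1,
    the limit of the rule as distance shrinks.
    """
    dist = np.asarray(dist, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    c = dist.shape[0]
    with np.errstate(divide="ignore"):
        a = np.minimum(1.0, delta / dist**2)
    np.fill_diagonal(a, 1.0)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(c))
    return AdjacencyMatrix(a, tuple(channel_names), delta)


def apply_global_connections(
    adjacency: AdjacencyMatrix,
    pairs: tuple[tuple[str, str], ...] = GLOBAL_CONNECTION_PAIRS,
    value: float = -1.0,
) -> tuple[AdjacencyMatrix, list[tuple[str, str]]]:
    """Set symmetric left-right pairs to ``value``; absent pairs are skipped.

    Returns the updated adjacency and the list of pairs actually applied.
    """
    out = adjacency.copy()
    index = {n: i for i, n in enumerate(out.channel_names)}
    applied: list[tuple[str, str]] = []
    for left, right in pairs:
        if left in index and right in index:
            i, j = index[left], index[right]
            out.values[i, j] = value
            out.values[j, i] = value
            applied.append((left, right))
        else:
            logger.debug("global connection (%s, %s) absent from layout; skipped", left, right)
    return out, applied


def normalize_adjacency(adjacency: AdjacencyMatrix | np.ndarray) -> NormalizedGraph:
    """S = D^{-1/2} (A + I) D^{-1/2} with absolute-value degrees.

    Self-loops are added on top of the unit diagonal the initial adjacency
    already carries; the propagation rule is applied literally.
    """
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a_tilde = a + np.eye(a.shape[0])
    degree = np.abs(a_tilde).sum(axis=1)
    if np.any(degree == 0):
        raise ValueError("isolated node: zero absolute degree in A + I")
    inv_sqrt = 1.0 / np.sqrt(degree)
    return NormalizedGraph(inv_sqrt[:, None] * a_tilde * inv_sqrt[None, :])


# ---------------------------------------------------------------------------
# Montage generation (used once to produce the bundled seed62.csv; kept so
# the layout is reproducible from code and usable for other channel counts).
# ---------------------------------------------------------------------------

_ROWS: dict[str, float] = {
    # row prefix -> polar angle of the midline electrode from the vertex (deg);
    # positive toward the nasion, negative toward the inion
    "FP": 72.0,
    "AF": 54.0,
    "F": 36.0,
    "FC": 18.0,
    "C": 0.0,
    "CP": -18.0,
    "P": -36.0,
    "PO": -54.0,
    "O": -72.0,
}

SEED62_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)


def _sph(polar_deg: float, azimuth_deg: float, radius: float = 10.0) -> np.ndarray:
    """Point on a sphere: polar angle from vertex, azimuth from the +x (nasion) axis."""
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return radius * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp(p: np.ndarray, q: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between two points on the same sphere."""
    r = np.linalg.norm(p)
    u, v = p / r, q / r
    omega = np.arccos(np.clip(u @ v, -1.0, 1.0))
    if omega < 1e-12:
        return p.copy()
    w = (np.sin((1 - t) * omega) * u + np.sin(t * omega) * v) / np.sin(omega)
    return r * w


def build_seed62_layout(radius: float = 10.0) -> ElectrodeLayout:
    """Construct an idealized 62-channel 10-10 montage on a sphere.

    Midline electrodes sit on the sagittal great circle at 18-degree steps;
    the temporal ring lies 72 degrees from the vertex; lateral electrodes are
    placed by great-circle interpolation along each coronal arc, mirroring
    standard 10-10 proportional spacing.  CB1/CB2 sit below the occipital
    ring.  Distances are then rescaled so that, with the inverse-square rule
    at delta = 5, the 0.2 quantile of squared inter-electrode distances
    equals delta — i.e. roughly 20% of channel relationships saturate.
    """
    pos: dict[str, np.ndarray] = {}
    # midline
    for row, polar in _ROWS.items():
        name = row + "Z"
        pos[name] = _sph(abs(polar), 0.0 if polar >= 0 else 180.0, radius)
    # outer (temporal) ring at 72 degrees from the vertex; azimuth measured
    # from the nasion direction (+x), counter-clockwise, in 18-degree steps:
    # left hemisphere positive, right hemisphere the mirror image
    outer_left = {
        "FP1": 18.0, "AF7": 36.0, "F7": 54.0, "FT7": 72.0, "T7": 90.0,
        "TP7": 108.0, "P7": 126.0, "PO7": 144.0, "O1": 162.0,
    }
    mirror_name = {"FP1": "FP2", "AF7": "AF8", "F7": "F8", "FT7": "FT8",
                   "T7": "T8", "TP7": "TP8", "P7": "P8", "PO7": "PO8", "O1": "O2"}
    for name, az in outer_left.items():
        p = _sph(72.0, az, radius)
        pos[name] = p
        pos[mirror_name[name]] = p * np.array([1.0, -1.0, 1.0])
    # lateral electrodes: interpolate along the coronal arc between the
    # midline electrode of the row and the outer-ring electrode of the row
    arcs = {
        "F": ("FZ", "F7", ("F1", "F3", "F5")),
        "FC": ("FCZ", "FT7", ("FC1", "FC3", "FC5")),
        "C": ("CZ", "T7", ("C1", "C3", "C5")),
        "CP": ("CPZ", "TP7", ("CP1", "CP3", "CP5")),
        "P": ("PZ", "P7", ("P1", "P3", "P5")),
        "PO": ("POZ", "PO7", ("PO3", "PO5")),
        "AF": ("AFZ", "AF7", ("AF3",)),
    }
    mirror = {"1": "2", "3": "4", "5": "6", "7": "8"}
    for _row, (mid, end, inner) in arcs.items():
        n_seg = len(inner) + 1
        for k, name in enumerate(inner, start=1):
            left = _slerp(pos[mid], pos[end], k / n_seg)
            pos[name] = left
            rname = name[:-1] + mirror[name[-1]]
            pos[rname] = left * np.array([1.0, -1.0, 1.0])
    # cerebellar electrodes below the parieto-occipital ring
    pos["CB1"] = _sph(86.0, 153.0, radius)
    pos["CB2"] = pos["CB1"] * np.array([1.0, -1.0, 1.0])

    coords = np.array([pos[name] for name in SEED62_CHANNELS])
    # calibrate scale: 0.2 quantile of off-diagonal squared distance -> delta=5
    layout = ElectrodeLayout(SEED62_CHANNELS, coords)
    d = pairwise_distances(layout)
    off = d[~np.eye(len(SEED62_CHANNELS), dtype=bool)]
    q = np.quantile(off**2, 0.2)
    coords = coords * np.sqrt(5.0 / q)
    return ElectrodeLayout(SEED62_CHANNELS, coords)
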