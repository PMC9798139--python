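"""Distance-matrix and class-type encoding of a trajectory.

Each frame is encoded as a fixed-length vector over the binding-site
backbone atoms: for every atom, the minimum Euclidean distance from that
atom to any site-associated TWN centroid in the frame.  A ring is
site-associated when its centroid lies within ``site_radius`` of at least
one site atom.  Frames without any retained ring carry the sentinel
``NO_TWN`` (infinity) in every entry.

Distances are then binned into four hydration-shell classes:

    A: d < 5 A      B: 5 <= d < 7.5 A      C: 7.5 <= d < 10 A      D: d >= 10 A

``NO_TWN`` maps to class D (farther than the last shell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .models import BindingSite, WaterFrame
from .twn import Tip3pParams, TwnRing, detect_twns

__all__ = [
    "NO_TWN",
    "CLASS_LABELS",
    "CLASS_EDGES",
    "DEFAULT_SITE_RADIUS",
    "EncodedTrajectory",
    "frame_distance_vector",
    "classify",
    "classify_array",
    "encode_trajectory",
]

#: Sentinel distance for frames containing no site-associated TWN.
NO_TWN = float("inf")

#: Shell labels in increasing-distance order.
CLASS_LABELS = ("A", "B", "C", "D")

#: Upper bin edges (A); bins are left-closed: [0,5), [5,7.5), [7.5,10), [10,inf).
CLASS_EDGES = (5.0, 7.5, 10.0)

#: Default TWN inclusion radius around the site (A); matches the outermost
#: informative class boundary.
DEFAULT_SITE_RADIUS = 10.0


def classify(d: float) -> str:
    """Map one distance (A) or the NO_TWN sentinel to its shell class."""
    if d != d:  # NaN
        raise ValidationError("distance is NaN")
    if d == NO_TWN:
        return "D"
    if d < 0:
        raise ValidationError(f"negative distance {d:g}")
    for label, edge in zip(CLASS_LABELS, CLASS_EDGES):
        if d < edge:
            return label
    return "D"


def classify_array(distances: np.ndarray) -> np.ndarray:
    """Elementwise `classify` over an array; returns dtype '<U1'."""
    d = np.asarray(distances, dtype=float)
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    if (d[np.isfinite(d)] < 0).any():
        raise ValidationError("distance matrix contains negative entries")
    idx = np.searchsorted(CLASS_EDGES, d, side="right")
    return np.array(CLASS_LABELS, dtype="U1")[idx]


def frame_distance_vector(
    rings: Sequence[TwnRing],
    site: BindingSite,
    site_radius: float = DEFAULT_SITE_RADIUS,
) -> np.ndarray:
    """Per-atom minimum centroid distance for one frame.

    Rings whose centroid is farther than ``site_radius`` from every site
    atom are discarded; each entry of the returned ``(n_atoms,)`` vector is
    the minimum distance from that atom to any retained centroid, or
    ``NO_TWN`` when no ring is retained.
    """
    frames = {r.frame_index for r in rings}
    if len(frames) > 1:
        raise ValidationError(f"rings span multiple frames: {sorted(frames)}")
    atoms = site.atom_coords
    if not rings:
        return np.full(atoms.shape[0], NO_TWN)
    centroids = np.stack([r.centroid for r in rings])
    table = cdist(centroids, atoms)  # (n_rings, n_atoms)
    retained = table.min(axis=1) <= site_radius
    if not retained.any():
        return np.full(atoms.shape[0], NO_TWN)
    return table[retained].min(axis=0)


@dataclass
class EncodedTrajectory:
    """Per-frame distance vectors and class labels for one protein.

    ``distance_matrix`` is ``(n_frames, 4 * n_residues)`` in A with
    ``NO_TWN`` sentinels; ``class_matrix`` holds the shell label of every
    entry.  Columns are residue-major in N, CA, C, O order.
    """

    protein_label: str
    frame_order: list[int]
    distance_matrix: np.ndarray
    class_matrix: np.ndarray
    site: BindingSite
    site_radius: float = DEFAULT_SITE_RADIUS

    def __post_init__(self) -> None:
        self.distance_matrix = np.asarray(self.distance_matrix, dtype=float)
        self.class_matrix = np.asarray(self.class_matrix, dtype="U1")
        if self.distance_matrix.shape != self.class_matrix.shape:
            raise ValidationError(
                f"distance matrix {self.distance_matrix.shape} and class matrix "
                f"{self.class_matrix.shape} shapes differ"
            )
        if self.distance_matrix.ndim != 2 or self.distance_matrix.shape[1] != self.site.n_atoms:
            raise ValidationError(
                f"matrix has {self.distance_matrix.shape[-1]} columns; site "
                f"{self.site.protein_label!r} has {self.site.n_atoms} atoms"
            )
        if len(self.frame_order) != self.distance_matrix.shape[0]:
            raise ValidationError("frame_order length does not match matrix rows")

    @property
    def n_frames(self) -> int:
        return self.distance_matrix.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.distance_matrix.shape[1]


def encode_trajectory(
    frames: Iterable[WaterFrame],
    site: BindingSite,
    params: Tip3pParams = Tip3pParams(),
    site_radius: float = DEFAULT_SITE_RADIUS,
) -> EncodedTrajectory:
    """Detect TWNs in every frame and stack the per-frame encodings.

    Deterministic for fixed inputs; rows follow the input frame order.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("cannot encode an empty trajectory")
    rows = []
    order = []
    for frame in frames:
        rings = detect_twns(frame, params)
        rows.append(frame_distance_vector(rings, site, site_radius))
        order.append(frame.frame_index)
    distance_matrix = np.stack(rows)
    return EncodedTrajectory(
        protein_label=site.protein_label,
        frame_order=order,
        distance_matrix=distance_matrix,
        class_matrix=classify_array(distance_matrix),
        site=site,
        site_radius=site_radius,
    )
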