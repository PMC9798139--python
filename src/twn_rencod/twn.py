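"""Topological water network (TWN) detection.

A water pair is hydrogen bonded when its TIP3P interaction energy is at or
below an energy criterion (default -2.25 kcal/mol).  The pair energy is the
full 3x3 site Coulomb sum plus a single oxygen-oxygen Lennard-Jones term:

    v(a, b) = k_e * sum_i sum_j q_i q_j / r_ij  +  A / r_oo^12  -  C / r_oo^6

with k_e the electrostatic conversion constant in kcal*A/(e^2*mol).  A TWN
here is a 3-membered ring: three waters whose three pair energies all meet
the criterion.  Its centroid is the arithmetic mean of the three oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import ValidationError
from .models import WaterFrame

__all__ = [
    "Tip3pParams",
    "TwnRing",
    "pair_interaction_energy",
    "hbond_graph",
    "find_three_rings",
    "detect_twns",
]


@dataclass(frozen=True)
class Tip3pParams:
    """TIP3P interaction parameters and hydrogen-bond criterion.

    Attributes
    ----------
    q_o, q_h:
        Partial charges (e) on the oxygen and each hydrogen site.  The
        molecule must be neutral: ``q_o + 2 q_h = 0``.
    lj_a, lj_c:
        Lennard-Jones repulsive (kcal*A^12/mol) and attractive
        (kcal*A^6/mol) coefficients, applied on the O-O distance only.
    coulomb_constant:
        Electrostatic conversion constant (kcal*A/(e^2*mol)).  The standard
        CHARMM/TIP3P value 332.0636 is the default; it is exposed here
        because conventions differ slightly between codes.
    hbond_criterion:
        Pair energy at or below this value (kcal/mol) counts as a hydrogen
        bond.
    oo_prescreen_cutoff:
        O-O distance (A) beyond which pairs are skipped without evaluating
        the energy.  At 4.5 A no orientation of a TIP3P pair reaches the
        default criterion, so the prescreen does not change results; set a
        non-positive value to disable it.
    """

    q_o: float = -0.834
    q_h: float = 0.417
    lj_a: float = 582000.0
    lj_c: float = 595.0
    coulomb_constant: float = 332.0636
    hbond_criterion: float = -2.25
    oo_prescreen_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if abs(self.q_o + 2.0 * self.q_h) > 1e-9:
            raise ValidationError(
                f"water not neutral: q_o + 2*q_h = {self.q_o + 2 * self.q_h:g} e"
            )
        if self.lj_a <= 0 or self.lj_c <= 0:
            raise ValidationError("Lennard-Jones coefficients must be positive")
        if self.hbond_criterion >= 0:
            raise ValidationError("hydrogen-bond criterion must be negative")

    @property
    def site_charges(self) -> np.ndarray:
        """Charges of the (O, H, H) sites in e."""
        return np.array([self.q_o, self.q_h, self.q_h])

    def without_prescreen(self) -> "Tip3pParams":
        return replace(self, oo_prescreen_cutoff=0.0)


@dataclass(frozen=True)
class TwnRing:
    """One detected 3-membered water ring.

    ``water_indices`` is the ascending triple of frame-local water indices;
    ``pair_energies`` stores (e_ij, e_jk, e_ik) in kcal/mol for the triple
    (i, j, k); ``centroid`` is the mean of the three oxygen positions (A).
    """

    frame_index: int
    water_indices: tuple[int, int, int]
    pair_energies: tuple[float, float, float]
    centroid: np.ndarray

    def __post_init__(self) -> None:
        i, j, k = self.water_indices
        if not (i < j < k):
            raise ValidationError(f"ring indices not ascending: {self.water_indices}")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float).reshape(3))


def _min_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def pair_interaction_energy(
    water_a: np.ndarray,
    water_b: np.ndarray,
    params: Tip3pParams = Tip3pParams(),
    box: np.ndarray | None = None,
) -> float:
    """TIP3P interaction energy (kcal/mol) between two waters.

    Each water is a ``(3, 3)`` array of sites in the order O, H1, H2.  The
    result is symmetric in its arguments; with ``box`` given, every
    site-site distance uses the minimum-image convention.
    """
    a = np.asarray(water_a, dtype=float).reshape(3, 3)
    b = np.asarray(water_b, dtype=float).reshape(3, 3)
    disp = _min_image(a[:, None, :] - b[None, :, :], None if box is None else np.asarray(box, float))
    r = np.linalg.norm(disp, axis=-1)
    r_oo = r[0, 0]
    if r_oo < 1e-6:
        raise ValidationError(f"coincident oxygens (r_oo = {r_oo:g} A)")
    q = params.site_charges
    coulomb = params.coulomb_constant * float(np.sum(q[:, None] * q[None, :] / r))
    lj = params.lj_a / r_oo**12 - params.lj_c / r_oo**6
    return coulomb + lj


def _pair_energies_vectorized(
    sites: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    params: Tip3pParams,
    box: np.ndarray | None,
) -> np.ndarray:
    """Energies for many water pairs at once; ``sites`` is (n, 3, 3)."""
    disp = sites[idx_a][:, :, None, :] - sites[idx_b][:, None, :, :]
    disp = _min_image(disp, box)
    r = np.linalg.norm(disp, axis=-1)  # (m, 3, 3)
    r_oo = r[:, 0, 0]
    if (r_oo < 1e-6).any():
        bad = int(np.argmax(r_oo < 1e-6))
        raise ValidationError(
            f"coincident oxygens for waters {int(idx_a[bad])} and {int(idx_b[bad])}"
        )
    q = params.site_charges
    coulomb = params.coulomb_constant * np.sum(q[:, None] * q[None, :] / r, axis=(1, 2))
    lj = params.lj_a / r_oo**12 - params.lj_c / r_oo**6
    return coulomb + lj


def hbond_graph(frame: WaterFrame, params: Tip3pParams = Tip3pParams()) -> nx.Graph:
    """Hydrogen-bond graph of a frame under the energy criterion.

    Nodes are frame-local water indices; an edge (a, b) carries its pair
    energy in the ``energy`` attribute and is present iff that energy is at
    or below ``params.hbond_criterion``.
    """
    g = nx.Graph()
    g.add_nodes_from(range(frame.n_waters))
    if frame.n_waters < 2:
        return g
    box = frame.box
    oo = _min_image(frame.oxygens[:, None, :] - frame.oxygens[None, :, :], box)
    dist = np.linalg.norm(oo, axis=-1)
    ia, ib = np.triu_indices(frame.n_waters, k=1)
    if params.oo_prescreen_cutoff > 0:
        keep = dist[ia, ib] <= params.oo_prescreen_cutoff
        ia, ib = ia[keep], ib[keep]
    if ia.size == 0:
        return g
    energies = _pair_energies_vectorized(frame.all_sites(), ia, ib, params, box)
    bonded = energies <= params.hbond_criterion
    g.add_weighted_edges_from(
        zip(ia[bonded].tolist(), ib[bonded].tolist(), energies[bonded].tolist()),
        weight="energy",
    )
    return g


def find_three_rings(graph: nx.Graph) -> list[tuple[int, int, int]]:
    """Enumerate every triangle of a simple undirected graph once.

    Returns ascending triples in lexicographic order.
    """
    adjacency = {u: set(graph[u]) for u in graph}
    triangles: list[tuple[int, int, int]] = []
    for u in sorted(adjacency):
        higher = sorted(v for v in adjacency[u] if v > u)
        for v, w in combinations(higher, 2):
            if w in adjacency[v]:
                triangles.append((u, v, w))
    return triangles


def detect_twns(frame: WaterFrame, params: Tip3pParams = Tip3pParams()) -> list[TwnRing]:
    """Detect all 3-membered ring TWNs in one frame.

    Builds the hydrogen-bond graph, enumerates triangles, and fills in the
    three pair energies and the oxygen centroid of each ring.  Rings are
    returned sorted by their ascending water triple.
    """
    graph = hbond_graph(frame, params)
    rings = []
    for i, j, k in find_three_rings(graph):
        rings.append(
            TwnRing(
                frame_index=frame.frame_index,
                water_indices=(i, j, k),
                pair_energies=(
                    graph.edges[i, j]["energy"],
                    graph.edges[j, k]["energy"],
                    graph.edges[i, k]["energy"],
                ),
                centroid=frame.oxygens[[i, j, k]].mean(axis=0),
            )
        )
    return rings
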