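"""Synthetic water trajectories with planted, known TWN structure.

The generator stands in for restrained-solvent MD output: every frame
contains zero or more planted water triangles (three TIP3P waters on an
equilateral triangle of side 2.8 A, each donating an O-H to the next oxygen
around the cycle, so all three pair energies clear the -2.25 kcal/mol
criterion at zero jitter) plus background waters placed by rejection
sampling at a minimum mutual separation that keeps them hydrogen-bond free.

Frames are reproducible from the seed alone; each frame draws from its own
substream so regenerating frame k never depends on how many random numbers
earlier frames consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .models import BindingSite, ResidueID, WaterFrame

__all__ = [
    "TRIANGLE_SIDE",
    "TIP3P_OH",
    "TIP3P_HOH_DEG",
    "PlantedSite",
    "SyntheticSpec",
    "planted_triangle",
    "generate_trajectory",
    "synthetic_binding_site",
]

#: O-O side of the planted triangle (A); a typical water-water H-bond distance.
TRIANGLE_SIDE = 2.8
#: TIP3P rigid internal geometry.
TIP3P_OH = 0.9572
TIP3P_HOH_DEG = 104.52

_MAX_REJECTION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class PlantedSite:
    """A planted TWN location with its per-frame presence probability."""

    center: tuple[float, float, float]
    presence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence <= 1.0:
            raise ValidationError(f"presence probability {self.presence} outside [0, 1]")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic trajectory.

    ``jitter_sigma`` is the scale (A) of isotropic Gaussian noise rigidly
    displacing each planted water; background waters are uniform in
    ``noise_box`` subject to ``min_noise_separation`` from each other and
    from the planted oxygens.
    """

    n_frames: int
    planted_sites: list[PlantedSite] = field(default_factory=list)
    jitter_sigma: float = 0.0
    n_noise_waters: int = 0
    noise_box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    min_noise_separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_sites = [
            s if isinstance(s, PlantedSite) else PlantedSite(**s) for s in self.planted_sites
        ]
        if self.n_frames <= 0:
            raise ValidationError("n_frames must be positive")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be non-negative")
        if self.n_noise_waters < 0:
            raise ValidationError("n_noise_waters must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = [
            PlantedSite(center=tuple(s["center"]), presence=float(s.get("presence", 1.0)))
            for s in raw.pop("planted_sites", [])
        ]
        if "noise_box" in raw:
            raw["noise_box"] = tuple(raw["noise_box"])
        return cls(planted_sites=sites, **raw)


def _water_from_directions(oxygen: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """(3, 3) site array O, H1, H2 from an oxygen and two O-H unit directions."""
    return np.vstack([oxygen, oxygen + TIP3P_OH * d1, oxygen + TIP3P_OH * d2])


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def planted_triangle(
    center: Sequence[float],
    jitter_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Three TIP3P waters forming a hydrogen-bonded ring, as ``(3, 3, 3)``.

    Oxygens sit on an equilateral triangle of side `TRIANGLE_SIDE` centred
    at ``center``; each water's first hydrogen points at the next oxygen in
    the cycle (donor -> acceptor) and the second hydrogen lies in the
    triangle plane, rotated away from the interior by the TIP3P HOH angle.
    Isotropic Gaussian jitter of scale ``jitter_sigma`` displaces each
    water rigidly (one offset per molecule), so the rigid TIP3P internal
    geometry survives arbitrarily large jitter while the hydrogen-bond
    geometry between waters degrades.
    """
    if jitter_sigma < 0:
        raise ValidationError("jitter_sigma must be non-negative")
    center = np.asarray(center, dtype=float).reshape(3)
    circum = TRIANGLE_SIDE / math.sqrt(3.0)
    vertices = center + circum * np.array(
        [[math.cos(a), math.sin(a), 0.0] for a in 2 * math.pi * np.arange(3) / 3]
    )
    hoh = math.radians(TIP3P_HOH_DEG)
    normal = np.array([0.0, 0.0, 1.0])
    waters = []
    for k in range(3):
        oxygen = vertices[k]
        donor = vertices[(k + 1) % 3] - oxygen
        donor = donor / np.linalg.norm(donor)
        outward = oxygen - center
        cand1 = _rotation(normal, hoh) @ donor
        cand2 = _rotation(normal, -hoh) @ donor
        second = cand1 if cand1 @ outward > cand2 @ outward else cand2
        waters.append(_water_from_directions(oxygen, donor, second))
    sites = np.stack(waters)
    if jitter_sigma > 0:
        if rng is None:
            raise ValidationError("jitter_sigma > 0 requires an rng")
        sites = sites + rng.normal(scale=jitter_sigma, size=(3, 1, 3))
    return sites


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_water(oxygen: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d1 = _random_unit(rng)
    perp = rng.normal(size=3)
    perp -= (perp @ d1) * d1
    perp /= np.linalg.norm(perp)
    hoh = math.radians(TIP3P_HOH_DEG)
    d2 = math.cos(hoh) * d1 + math.sin(hoh) * perp
    return _water_from_directions(oxygen, d1, d2)


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, frame_index]))


def generate_trajectory(
    spec: SyntheticSpec,
    out: str | Path | None = None,
    return_ground_truth: bool = False,
) -> list[WaterFrame] | tuple[list[WaterFrame], list[list[int]]]:
    """Realise a synthetic trajectory; optionally write a multi-model PDB.

    Per frame, each planted site is independently present with its
    probability; background waters are rejection-sampled uniformly in the
    noise box at least ``min_noise_separation`` from every already placed
    oxygen, with random orientations.  With ``return_ground_truth`` the
    per-frame lists of realised planted-site indices are returned as well.
    """
    frames: list[WaterFrame] = []
    ground_truth: list[list[int]] = []
    box = np.asarray(spec.noise_box, dtype=float)
    for t in range(spec.n_frames):
        rng = _frame_rng(spec.seed, t)
        waters: list[np.ndarray] = []
        oxygens: list[np.ndarray] = []
        realized: list[int] = []
        for s_idx, site in enumerate(spec.planted_sites):
            if rng.random() <= site.presence:
                realized.append(s_idx)
                tri = planted_triangle(site.center, spec.jitter_sigma, rng)
                waters.extend(tri)
                oxygens.extend(tri[:, 0])
        for _ in range(spec.n_noise_waters):
            for _attempt in range(_MAX_REJECTION_ATTEMPTS):
                pos = rng.uniform(low=0.0, high=box)
                if not oxygens or np.linalg.norm(
                    np.stack(oxygens) - pos, axis=1
                ).min() >= spec.min_noise_separation:
                    break
            else:
                raise ValidationError(
                    f"could not place noise water {len(oxygens)} after "
                    f"{_MAX_REJECTION_ATTEMPTS} attempts; enlarge noise_box or "
                    f"reduce n_noise_waters / min_noise_separation"
                )
            waters.append(_random_water(pos, rng))
            oxygens.append(pos)
        if waters:
            sites = np.stack(waters)
            frame = WaterFrame(
                frame_index=t,
                time_ps=float(t),
                oxygens=sites[:, 0],
                hydrogens=sites[:, 1:],
            )
        else:
            frame = WaterFrame(
                frame_index=t,
                time_ps=float(t),
                oxygens=np.empty((0, 3)),
                hydrogens=np.empty((0, 2, 3)),
            )
        frames.append(frame)
        ground_truth.append(realized)
    if out is not None:
        from .io import write_frames_pdb

        write_frames_pdb(frames, out)
    if return_ground_truth:
        return frames, ground_truth
    return frames


def synthetic_binding_site(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    n_residues: int = 16,
    label: str = "synthetic",
) -> BindingSite:
    """A synthetic binding site ringing ``center`` for encoding tests.

    Residues are laid out on a spiral of increasing radius (3.5 to 11 A)
    around the pocket centre so that planted TWN centroids near the centre
    populate all four distance classes.  This is a geometric stand-in for a
    real KLIFS-style pocket, not derived from any protein structure.
    """
    residues = []
    coords = np.empty((n_residues, 4, 3))
    # small rigid backbone footprint reused for every residue
    footprint = np.array(
        [[0.0, 0.0, 0.0], [1.46, 0.0, 0.0], [2.02, 1.42, 0.0], [1.45, 2.44, 0.6]]
    )
    center = np.asarray(center, dtype=float).reshape(3)
    for k in range(n_residues):
        frac = k / max(n_residues - 1, 1)
        radius = 3.5 + 7.5 * frac
        angle = 2 * math.pi * (k * 0.618034 % 1.0)
        z = 3.0 * math.sin(2 * math.pi * frac)
        base = center + np.array(
            [radius * math.cos(angle), radius * math.sin(angle), z]
        )
        rot = _rotation(np.array([0.0, 0.0, 1.0]), angle)
        coords[k] = base + footprint @ rot.T
        residues.append(ResidueID("A", k + 1, "GLY"))
    return BindingSite(protein_label=label, residues=residues, coords=coords)
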