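"""Core domain containers: water frames, binding sites, site pairings.

Coordinates are Cartesian angstroms throughout; no unit conversion happens
anywhere in the package. A water molecule is a rigid 3-site object (one
oxygen, two hydrogens); a binding site is an ordered list of residues each
contributing exactly the four backbone atoms N, CA, C, O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ValidationError

#: Fixed backbone-atom order within each binding-site residue.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: O-H bond-length sanity window (angstrom) for rigid 3-site waters.
OH_DISTANCE_RANGE = (0.5, 1.5)


class ResidueID(NamedTuple):
    """Identity of a binding-site residue."""

    chain: str
    resnum: int
    resname: str

    def __str__(self) -> str:  # e.g. "A:123:GLY"
        return f"{self.chain}:{self.resnum}:{self.resname}"


@dataclass
class WaterFrame:
    """One trajectory snapshot of water molecules.

    Parameters
    ----------
    frame_index:
        Non-negative index of the frame within its trajectory.
    oxygens:
        ``(n_waters, 3)`` oxygen coordinates in angstrom.
    hydrogens:
        ``(n_waters, 2, 3)`` hydrogen coordinates in angstrom.
    time_ps:
        Optional simulation time of the frame in picoseconds.
    box:
        Optional orthorhombic box lengths ``(3,)`` in angstrom; when present,
        site-site distances are computed under the minimum-image convention.
    """

    frame_index: int
    oxygens: np.ndarray
    hydrogens: np.ndarray
    time_ps: float | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.oxygens = np.asarray(self.oxygens, dtype=float).reshape(-1, 3)
        self.hydrogens = np.asarray(self.hydrogens, dtype=float).reshape(-1, 2, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.validate()

    @property
    def n_waters(self) -> int:
        return self.oxygens.shape[0]

    def water_sites(self, index: int) -> np.ndarray:
        """Return the ``(3, 3)`` site array (O, H1, H2) of one water."""
        return np.vstack([self.oxygens[index], self.hydrogens[index]])

    def all_sites(self) -> np.ndarray:
        """Return all waters as an ``(n_waters, 3, 3)`` site array."""
        return np.concatenate(
            [self.oxygens[:, None, :], self.hydrogens], axis=1
        )

    def validate(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame index {self.frame_index}")
        if self.hydrogens.shape[0] != self.oxygens.shape[0]:
            raise ValidationError(
                f"frame {self.frame_index}: {self.oxygens.shape[0]} oxygens but "
                f"{self.hydrogens.shape[0]} hydrogen pairs"
            )
        if not (np.isfinite(self.oxygens).all() and np.isfinite(self.hydrogens).all()):
            raise ValidationError(f"frame {self.frame_index}: non-finite coordinates")
        if self.n_waters:
            d = np.linalg.norm(self.hydrogens - self.oxygens[:, None, :], axis=-1)
            lo, hi = OH_DISTANCE_RANGE
            bad = np.nonzero((d <= lo) | (d >= hi))[0]
            if bad.size:
                raise ValidationError(
                    f"frame {self.frame_index}: water {bad[0]} has O-H distance "
                    f"{d[bad[0]].min():.3f} A outside ({lo}, {hi})"
                )
        if self.box is not None and (self.box <= 0).any():
            raise ValidationError(f"frame {self.frame_index}: non-positive box length")


@dataclass
class BindingSite:
    """An ordered binding-site residue list with static backbone coordinates.

    The protein is restrained during production MD, so a single set of
    backbone coordinates per protein describes the site in every frame.

    ``coords`` has shape ``(n_residues, 4, 3)`` with the atom axis in the
    fixed order N, CA, C, O.
    """

    protein_label: str
    residues: list[ResidueID]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.residues = [ResidueID(*r) for r in self.residues]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residues), 4, 3):
            raise ValidationError(
                f"site {self.protein_label!r}: coords shape {self.coords.shape} "
                f"!= ({len(self.residues)}, 4, 3)"
            )
        if not np.isfinite(self.coords).all():
            raise ValidationError(f"site {self.protein_label!r}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return 4 * len(self.residues)

    @property
    def atom_coords(self) -> np.ndarray:
        """Flat ``(4 * n_residues, 3)`` coordinates, residue-major, N/CA/C/O."""
        return self.coords.reshape(-1, 3)

    @property
    def atom_labels(self) -> list[str]:
        """Column labels, e.g. ``A:123:GLY.CA``, matching ``atom_coords`` order."""
        return [
            f"{res}.{atom}" for res in self.residues for atom in BACKBONE_ATOMS
        ]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None) -> "BindingSite":
        """Return a rigidly transformed copy (used for invariance checks)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, float).T
        if translation is not None:
            coords = coords + np.asarray(translation, float)
        return BindingSite(self.protein_label, list(self.residues), coords)


@dataclass
class SitePairing:
    """Index-aligned residue correspondence between two binding sites.

    Residue ``k`` of the reference corresponds to residue ``k`` of the query
    (KLIFS-style positional alignment); both sites must therefore have the
    same residue count.
    """

    reference_site: BindingSite
    query_site: BindingSite

    def __post_init__(self) -> None:
        nr = self.reference_site.n_residues
        nq = self.query_site.n_residues
        if nr != nq:
            raise ValidationError(
                f"site residue counts differ: {self.reference_site.protein_label!r} "
                f"has {nr}, {self.query_site.protein_label!r} has {nq}"
            )

    @property
    def n_residues(self) -> int:
        return self.reference_site.n_residues
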