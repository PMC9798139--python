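"""File input/output: trajectories, binding-site configs, ring tables, matrices.

The mandatory trajectory dialect is multi-model PDB (MODEL/ENDMDL delimited,
one model per frame); waters are recognised by residue name against a
configurable whitelist.  GRO input is available as an optional adapter when
MDAnalysis is installed.  Binding sites are read from a small YAML/JSON
config that either inlines backbone coordinates or points at a reference
PDB to extract them from.
"""

from __future__ import annotations

import glob as _glob
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .encoding import EncodedTrajectory
from .errors import InputFormatError, ValidationError
from .models import BACKBONE_ATOMS, BindingSite, ResidueID, WaterFrame
from .twn import TwnRing

__all__ = [
    "DEFAULT_WATER_RESNAMES",
    "read_water_frames",
    "read_binding_site",
    "write_rings",
    "read_rings",
    "write_frames_pdb",
    "write_distance_matrix",
    "write_class_matrix",
]

#: Residue names recognised as water (case-insensitive).
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3"})

_RING_COLUMNS = [
    "frame_index", "water_i", "water_j", "water_k",
    "e_ij", "e_jk", "e_ik", "centroid_x", "centroid_y", "centroid_z",
]


def _parse_cryst1(path: Path) -> np.ndarray | None:
    """Box lengths from the first CRYST1 record, orthorhombic only."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha, beta, gamma = (
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except ValueError as exc:
                    raise InputFormatError(f"{path}: malformed CRYST1 record") from exc
                if max(abs(alpha - 90), abs(beta - 90), abs(gamma - 90)) > 1e-2:
                    warnings.warn(
                        f"{path}: non-orthorhombic cell ignored "
                        f"(angles {alpha}, {beta}, {gamma})"
                    )
                    return None
                if min(a, b, c) <= 1.0:
                    return None  # placeholder cell
                return np.array([a, b, c])
    return None


def _waters_from_residues(residues, frame_index: int, path) -> tuple[np.ndarray, np.ndarray]:
    oxygens, hydrogens = [], []
    for res in residues:
        o_atoms = [a for a in res if a.element == "O"]
        h_atoms = [a for a in res if a.element == "H"]
        if len(o_atoms) != 1 or len(h_atoms) != 2:
            chain = res.get_parent().id
            raise InputFormatError(
                f"{path}: water {chain}:{res.id[1]}:{res.get_resname().strip()} in "
                f"frame {frame_index} has {len(o_atoms)} oxygen(s) and "
                f"{len(h_atoms)} hydrogen(s); expected 1 and 2"
            )
        oxygens.append(o_atoms[0].coord)
        hydrogens.append([h_atoms[0].coord, h_atoms[1].coord])
    if not oxygens:
        return np.empty((0, 3)), np.empty((0, 2, 3))
    return np.asarray(oxygens, float), np.asarray(hydrogens, float)


def read_water_frames(
    path: str | Path,
    format: str = "pdb",
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> list[WaterFrame]:
    """Read per-frame water coordinates from a trajectory file.

    ``format`` is ``"pdb"`` (multi-model PDB, the mandatory dialect) or
    ``"gro"`` (a GRO file or glob of GRO files, one frame each; requires
    MDAnalysis).  Non-water records are ignored; frame order follows file
    order.  Raises `InputFormatError` on malformed records, waters with a
    wrong atom count, or zero frames.
    """
    whitelist = {name.upper() for name in water_resnames}
    if format == "gro":
        return _read_gro_series(path, whitelist)
    if format != "pdb":
        raise ValidationError(f"unknown trajectory format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"trajectory file not found: {path}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except PDBConstructionException as exc:
        raise InputFormatError(f"{path}: {exc}") from exc
    box = _parse_cryst1(path)
    frames = []
    for i, model in enumerate(structure):
        waters = [
            res for res in model.get_residues()
            if res.get_resname().strip().upper() in whitelist
        ]
        oxygens, hydrogens = _waters_from_residues(waters, i, path)
        frames.append(
            WaterFrame(frame_index=i, oxygens=oxygens, hydrogens=hydrogens, box=box)
        )
    if not frames:
        raise InputFormatError(f"{path}: no frames (no MODEL records or atoms)")
    return frames


def _read_gro_series(path, whitelist) -> list[WaterFrame]:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise InputFormatError(
            "GRO input requires the optional MDAnalysis dependency"
        ) from exc
    paths = sorted(_glob.glob(str(path))) if any(c in str(path) for c in "*?[") else [str(path)]
    if not paths:
        raise InputFormatError(f"no GRO files match {path}")
    frames = []
    for i, p in enumerate(paths):
        u = mda.Universe(p)
        sel = u.select_atoms(
            "resname " + " ".join(sorted(whitelist))
        )
        oxygens, hydrogens = [], []
        for res in sel.residues:
            o = res.atoms.select_atoms("element O or name O OW")
            h = res.atoms.select_atoms("element H or name H1 H2 HW1 HW2")
            if len(o) != 1 or len(h) != 2:
                raise InputFormatError(
                    f"{p}: water {res.resid} has {len(o)} oxygen(s) and "
                    f"{len(h)} hydrogen(s); expected 1 and 2"
                )
            oxygens.append(o.positions[0])
            hydrogens.append(h.positions[:2])
        frames.append(
            WaterFrame(
                frame_index=i,
                oxygens=np.asarray(oxygens, float).reshape(-1, 3),
                hydrogens=np.asarray(hydrogens, float).reshape(-1, 2, 3),
            )
        )
    return frames


def read_binding_site(path: str | Path) -> BindingSite:
    """Read a binding-site definition from a YAML/JSON config.

    Schema::

        protein_label: KIT
        reference_pdb: kit.pdb        # optional; resolved relative to config
        expected_residues: 16         # optional declared count
        residues:
          - {chain: A, resnum: 673, resname: GLY,
             atoms: {N: [x,y,z], CA: [...], C: [...], O: [...]}}  # atoms optional

    Residues without inline ``atoms`` take their backbone coordinates from
    the first model of ``reference_pdb``.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"binding-site config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "residues" not in raw:
        raise InputFormatError(f"{path}: config must be a mapping with a 'residues' list")
    label = str(raw.get("protein_label", path.stem))
    entries = raw["residues"]
    if not entries:
        raise InputFormatError(f"{path}: empty residue list")
    declared = raw.get("expected_residues")
    if declared is not None and int(declared) != len(entries):
        raise ValidationError(
            f"{path}: {len(entries)} residues listed but expected_residues={declared}"
        )

    ref_model = None
    if raw.get("reference_pdb"):
        ref_path = Path(raw["reference_pdb"])
        if not ref_path.is_absolute():
            ref_path = path.parent / ref_path
        if not ref_path.exists():
            raise InputFormatError(f"reference PDB not found: {ref_path}")
        parser = PDBParser(PERMISSIVE=False, QUIET=True)
        ref_model = next(iter(parser.get_structure("ref", str(ref_path))))

    residues: list[ResidueID] = []
    coords = np.empty((len(entries), 4, 3))
    for k, entry in enumerate(entries):
        rid = ResidueID(str(entry["chain"]), int(entry["resnum"]), str(entry["resname"]))
        residues.append(rid)
        atoms = entry.get("atoms")
        if atoms is not None:
            missing = [a for a in BACKBONE_ATOMS if a not in atoms]
            if missing:
                raise ValidationError(f"{path}: residue {rid} lacks inline atoms {missing}")
            coords[k] = [np.asarray(atoms[a], float) for a in BACKBONE_ATOMS]
            continue
        if ref_model is None:
            raise ValidationError(
                f"{path}: residue {rid} has no inline atoms and no reference_pdb is given"
            )
        try:
            chain = ref_model[rid.chain]
            res = chain[(" ", rid.resnum, " ")]
        except KeyError as exc:
            raise ValidationError(
                f"reference PDB lacks residue {rid}"
            ) from exc
        if res.get_resname().strip().upper() != rid.resname.upper():
            warnings.warn(
                f"residue {rid}: reference PDB names it {res.get_resname().strip()}"
            )
        for a_idx, name in enumerate(BACKBONE_ATOMS):
            if name not in res:
                raise ValidationError(
                    f"reference PDB residue {rid} lacks backbone atom {name}"
                )
            coords[k, a_idx] = res[name].coord
    return BindingSite(protein_label=label, residues=residues, coords=coords)


def write_rings(rings: Sequence[TwnRing], path: str | Path) -> None:
    """Write detected rings as a TSV, one row per ring.

    Columns: frame_index, water_i/j/k (ascending), the three pair energies
    (kcal/mol) and the centroid coordinates (A).
    """
    rows = [
        (
            r.frame_index, *r.water_indices, *r.pair_energies,
            r.centroid[0], r.centroid[1], r.centroid[2],
        )
        for r in rings
    ]
    df = pd.DataFrame(rows, columns=_RING_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_rings(path: str | Path) -> list[TwnRing]:
    """Read a ring TSV written by `write_rings`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RING_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: ring table lacks columns {missing}")
    return [
        TwnRing(
            frame_index=int(row.frame_index),
            water_indices=(int(row.water_i), int(row.water_j), int(row.water_k)),
            pair_energies=(row.e_ij, row.e_jk, row.e_ik),
            centroid=np.array([row.centroid_x, row.centroid_y, row.centroid_z]),
        )
        for row in df.itertuples()
    ]


def write_frames_pdb(frames: Sequence[WaterFrame], path: str | Path) -> None:
    """Write water frames as a multi-model PDB (one MODEL per frame)."""
    frames = list(frames)
    if not frames:
        raise ValidationError("no frames to write")
    lines: list[str] = []
    box = frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for frame in frames:
        lines.append(f"MODEL     {frame.frame_index + 1:4d}")
        serial = 1
        for w in range(frame.n_waters):
            resseq = w % 9999 + 1
            for name, xyz, element in (
                ("O", frame.oxygens[w], "O"),
                ("H1", frame.hydrogens[w, 0], "H"),
                ("H2", frame.hydrogens[w, 1], "H"),
            ):
                # PDB fixed columns: name 13-16, resname 18-20, chain 22,
                # resseq 23-26, coordinates 31-54, element 77-78
                lines.append(
                    f"HETATM{serial % 99999:5d} {' ' + name:<4s} HOH A{resseq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _matrix_header(encoded: EncodedTrajectory) -> str:
    return (
        f"# protein_label={encoded.protein_label}\n"
        f"# site_radius_A={encoded.site_radius:g}\n"
    )


def write_distance_matrix(encoded: EncodedTrajectory, path: str | Path) -> None:
    """TSV of the distance matrix; NO_TWN sentinels are written as ``inf``."""
    _write_matrix(encoded, encoded.distance_matrix, path, fmt=lambda v: f"{v:.4f}" if np.isfinite(v) else "inf")


def write_class_matrix(encoded: EncodedTrajectory, path: str | Path) -> None:
    """TSV of the class-type matrix with single-letter shell labels."""
    _write_matrix(encoded, encoded.class_matrix, path, fmt=str)


def _write_matrix(encoded: EncodedTrajectory, matrix, path, fmt) -> None:
    labels = encoded.site.atom_labels
    with open(path, "w") as fh:
        fh.write(_matrix_header(encoded))
        fh.write("frame\t" + "\t".join(labels) + "\n")
        for fi, row in zip(encoded.frame_order, matrix):
            fh.write(str(fi) + "\t" + "\t".join(fmt(v) for v in row) + "\n")
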