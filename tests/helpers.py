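"""Shared construction helpers for test inputs (not oracles)."""

from __future__ import annotations

import math

import numpy as np

from twn_rencod.models import WaterFrame

TIP3P_OH = 0.9572
TIP3P_HOH = math.radians(104.52)


def make_water(oxygen, d1, d2) -> np.ndarray:
    """(3, 3) water sites from an oxygen position and two O-H directions."""
    oxygen = np.asarray(oxygen, float)
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    return np.vstack([oxygen, oxygen + TIP3P_OH * d1, oxygen + TIP3P_OH * d2])


def random_water(rng: np.random.Generator, oxygen=None) -> np.ndarray:
    """A TIP3P water with random orientation (rigid internal geometry)."""
    if oxygen is None:
        oxygen = rng.uniform(-10, 10, size=3)
    d1 = rng.normal(size=3)
    d1 /= np.linalg.norm(d1)
    perp = rng.normal(size=3)
    perp -= (perp @ d1) * d1
    perp /= np.linalg.norm(perp)
    d2 = math.cos(TIP3P_HOH) * d1 + math.sin(TIP3P_HOH) * perp
    return make_water(oxygen, d1, d2)


def ideal_hbond_pair(r_oo: float = 2.8) -> tuple[np.ndarray, np.ndarray]:
    """Near-linear hydrogen-bond dimer: donor O-H pointing at the acceptor O.

    The acceptor's HOH bisector points away from the donor, in-plane.
    """
    half = TIP3P_HOH / 2
    donor = make_water(
        (0, 0, 0),
        (1, 0, 0),
        (math.cos(TIP3P_HOH), math.sin(TIP3P_HOH), 0),
    )
    acceptor = make_water(
        (r_oo, 0, 0),
        (math.cos(half), math.sin(half), 0),
        (math.cos(half), -math.sin(half), 0),
    )
    return donor, acceptor


def random_frame(rng: np.random.Generator, n_waters: int, box_edge: float,
                 frame_index: int = 0, periodic: bool = False) -> WaterFrame:
    """Frame of randomly placed, randomly oriented waters in a cubic box.

    The box edge controls contact density and hence the hydrogen-bond graph.
    """
    waters = [
        random_water(rng, oxygen=rng.uniform(0, box_edge, size=3))
        for _ in range(n_waters)
    ]
    sites = (
        np.stack(waters) if waters else np.empty((0, 3, 3))
    )
    return WaterFrame(
        frame_index=frame_index,
        oxygens=sites[:, 0] if n_waters else np.empty((0, 3)),
        hydrogens=sites[:, 1:] if n_waters else np.empty((0, 2, 3)),
        box=np.full(3, box_edge) if periodic else None,
    )
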