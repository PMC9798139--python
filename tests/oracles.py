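"""Independent reference implementations used only to check the package.

Everything here is written as plainly as possible (explicit loops, textbook
formulas) and stays independent of the code paths it verifies.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

COULOMB_CONSTANT = 332.0636
Q_O, Q_H = -0.834, 0.417
LJ_A, LJ_C = 582000.0, 595.0


def tip3p_reference_energy(water_a, water_b, box=None,
                           coulomb_constant=COULOMB_CONSTANT,
                           q_o=Q_O, q_h=Q_H, lj_a=LJ_A, lj_c=LJ_C) -> float:
    """Term-by-term TIP3P pair energy: 9 Coulomb terms + 1 O-O LJ term."""
    charges = [q_o, q_h, q_h]
    total = 0.0
    for i in range(3):
        for j in range(3):
            dx = water_a[i][0] - water_b[j][0]
            dy = water_a[i][1] - water_b[j][1]
            dz = water_a[i][2] - water_b[j][2]
            if box is not None:
                dx -= box[0] * round(dx / box[0])
                dy -= box[1] * round(dy / box[1])
                dz -= box[2] * round(dz / box[2])
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            total += coulomb_constant * charges[i] * charges[j] / r
    ox = water_a[0][0] - water_b[0][0]
    oy = water_a[0][1] - water_b[0][1]
    oz = water_a[0][2] - water_b[0][2]
    if box is not None:
        ox -= box[0] * round(ox / box[0])
        oy -= box[1] * round(oy / box[1])
        oz -= box[2] * round(oz / box[2])
    r_oo = math.sqrt(ox * ox + oy * oy + oz * oz)
    return total + lj_a / r_oo**12 - lj_c / r_oo**6


def brute_force_triangles(n_vertices: int, edges: set[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """All triangles by scanning every C(n, 3) triple against an edge set."""
    normalized = {tuple(sorted(e)) for e in edges}
    out = []
    for a, b, c in combinations(range(n_vertices), 3):
        if (a, b) in normalized and (b, c) in normalized and (a, c) in normalized:
            out.append((a, b, c))
    return out


def brute_force_frame_triangles(frame_sites, criterion=-2.25, box=None):
    """Triangles of a frame straight from oracle pair energies (no graph)."""
    n = len(frame_sites)
    edges = set()
    for a, b in combinations(range(n), 2):
        if tip3p_reference_energy(frame_sites[a], frame_sites[b], box=box) <= criterion:
            edges.add((a, b))
    return brute_force_triangles(n, edges)


def brute_force_distance_vector(centroids, atoms, site_radius):
    """Per-atom minimum centroid distance via the full pairwise table."""
    atoms = np.asarray(atoms, float)
    if len(centroids) == 0:
        return np.full(len(atoms), np.inf)
    table = np.empty((len(centroids), len(atoms)))
    for i, c in enumerate(centroids):
        for j, a in enumerate(atoms):
            table[i, j] = math.dist(tuple(c), tuple(a))
    retained = [i for i in range(len(centroids)) if table[i].min() <= site_radius]
    if not retained:
        return np.full(len(atoms), np.inf)
    return table[retained].min(axis=0)


def greedy_assignment_reference(cost_matrix):
    """Greedy sequential assignment from a fully materialised cost matrix.

    Row t takes the cheapest remaining column; ties go to the lowest column
    index.  Returns (permutation, costs).
    """
    n = len(cost_matrix)
    remaining = list(range(n))
    perm, costs = [], []
    for t in range(n):
        best = min(remaining, key=lambda j: (cost_matrix[t][j], j))
        perm.append(best)
        costs.append(cost_matrix[t][best])
        remaining.remove(best)
    return perm, costs


def pearson_formula(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def kendall_formula(x, y) -> float:
    """Kendall tau-b by explicit pair counting."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / math.sqrt((n0 - ties_x) * (n0 - ties_y))


def _ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_formula(x, y) -> float:
    return pearson_formula(_ranks(list(x)), _ranks(list(y)))
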