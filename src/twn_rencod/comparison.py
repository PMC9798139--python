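"""Frame reordering and binding-site similarity scoring.

The query trajectory's frames are reordered against the reference by greedy
sequential assignment: reference frames are visited in order and each takes
the not-yet-assigned query frame with the smallest difference in distance
values (L1 over the per-atom entries by default).  Similarity is then the
fraction of (frame, atom) cells whose shell classes agree after reordering.

The comparison is anchored on the reference, so compare(P1, P2) and
compare(P2, P1) may differ; callers wanting a symmetric number average the
two directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import EncodedTrajectory, NO_TWN
from .errors import ValidationError

__all__ = [
    "DEFAULT_SENTINEL_CAP",
    "ComparisonResult",
    "frame_difference",
    "reorder_frames",
    "similarity_score",
    "compare",
]

#: Distance (A) substituted for the NO_TWN sentinel in frame differences;
#: beyond the last finite class boundary so absent TWNs behave as "far".
DEFAULT_SENTINEL_CAP = 12.0


def _capped(row: np.ndarray, cap: float) -> np.ndarray:
    return np.where(np.isinf(row), cap, row)


def frame_difference(
    ref_row: np.ndarray,
    query_row: np.ndarray,
    cap: float = DEFAULT_SENTINEL_CAP,
    metric: str = "l1",
) -> float:
    """Difference in distance values between two frame vectors.

    NO_TWN sentinels are valued at ``cap`` before the norm is taken.
    """
    a = np.asarray(ref_row, dtype=float)
    b = np.asarray(query_row, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"row lengths differ: {a.shape} vs {b.shape}")
    diff = _capped(a, cap) - _capped(b, cap)
    if metric == "l1":
        return float(np.abs(diff).sum())
    if metric == "l2":
        return float(np.sqrt((diff**2).sum()))
    raise ValidationError(f"unknown metric {metric!r}")


def _check_compatible(reference: EncodedTrajectory, query: EncodedTrajectory) -> None:
    if reference.n_frames != query.n_frames:
        raise ValidationError(
            f"frame counts differ: {reference.protein_label!r} has "
            f"{reference.n_frames}, {query.protein_label!r} has {query.n_frames}"
        )
    if reference.n_atoms != query.n_atoms:
        raise ValidationError(
            f"atom counts differ: {reference.protein_label!r} has "
            f"{reference.n_atoms}, {query.protein_label!r} has {query.n_atoms}"
        )


def reorder_frames(
    reference: EncodedTrajectory,
    query: EncodedTrajectory,
    cap: float = DEFAULT_SENTINEL_CAP,
    metric: str = "l1",
) -> tuple[list[int], list[float]]:
    """Greedy sequential assignment of query frames to reference frames.

    Reference frames are processed in order; step ``t`` picks, among the
    query frames not yet assigned, the one minimising `frame_difference` to
    reference frame ``t`` (ties broken by lowest query frame index).
    Returns the permutation (reference position -> query row index) and the
    per-step costs.
    """
    _check_compatible(reference, query)
    ref = _capped(reference.distance_matrix, cap)
    qry = _capped(query.distance_matrix, cap)
    n = ref.shape[0]
    available = np.ones(n, dtype=bool)
    permutation: list[int] = []
    costs: list[float] = []
    for t in range(n):
        if metric == "l1":
            c = np.abs(qry - ref[t]).sum(axis=1)
        elif metric == "l2":
            c = np.sqrt(((qry - ref[t]) ** 2).sum(axis=1))
        else:
            raise ValidationError(f"unknown metric {metric!r}")
        c[~available] = np.inf
        choice = int(np.argmin(c))  # argmin takes the first minimum: lowest index
        permutation.append(choice)
        costs.append(float(c[choice]))
        available[choice] = False
    return permutation, costs


@dataclass
class ComparisonResult:
    """Outcome of one directed binding-site comparison."""

    reference_label: str
    query_label: str
    permutation: list[int]
    frame_costs: list[float]
    matched_pairs: int
    total_pairs: int
    similarity: float

    def __post_init__(self) -> None:
        if self.total_pairs <= 0:
            raise ValidationError("total_pairs must be positive")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValidationError(f"similarity {self.similarity} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_label,
            "query": self.query_label,
            "permutation": list(self.permutation),
            "frame_costs": list(self.frame_costs),
            "matched_pairs": self.matched_pairs,
            "total_pairs": self.total_pairs,
            "similarity": self.similarity,
        }


def _validate_permutation(permutation: Sequence[int], n: int) -> np.ndarray:
    perm = np.asarray(permutation, dtype=int)
    if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
        raise ValidationError(
            f"permutation is not a bijection on {n} frame positions: {permutation!r}"
        )
    return perm


def similarity_score(
    reference: EncodedTrajectory,
    query: EncodedTrajectory,
    permutation: Sequence[int],
    frame_costs: Sequence[float] | None = None,
) -> ComparisonResult:
    """Fraction of matched class pairs after reordering the query frames."""
    _check_compatible(reference, query)
    perm = _validate_permutation(permutation, query.n_frames)
    reordered = query.class_matrix[perm]
    matched = int((reference.class_matrix == reordered).sum())
    total = reference.n_frames * reference.n_atoms
    return ComparisonResult(
        reference_label=reference.protein_label,
        query_label=query.protein_label,
        permutation=[int(p) for p in perm],
        frame_costs=list(frame_costs) if frame_costs is not None else [],
        matched_pairs=matched,
        total_pairs=total,
        similarity=matched / total,
    )


def compare(
    reference: EncodedTrajectory,
    query: EncodedTrajectory,
    cap: float = DEFAULT_SENTINEL_CAP,
    metric: str = "l1",
) -> ComparisonResult:
    """Full directed comparison: reorder the query frames, then score."""
    permutation, costs = reorder_frames(reference, query, cap=cap, metric=metric)
    return similarity_score(reference, query, permutation, frame_costs=costs)
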