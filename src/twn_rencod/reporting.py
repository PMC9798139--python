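"""Activity tables, correlation utilities and run provenance.

Binding-site similarity values are evaluated against inhibitor potency by
correlating, over protein pairs, the similarity score with the absolute
log10 difference in dissociation constants |log10(Kd_i) - log10(Kd_j)|.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputFormatError, ValidationError

__all__ = ["ActivityTable", "correlate", "pair_key", "provenance"]

_METHODS = ("pearson", "kendall", "spearman")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered key for a protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ActivityTable:
    """Per-protein inhibitor potency (Kd, nM) with unique labels.

    Censored entries written as e.g. ``">10000"`` are taken at the bound
    with a warning; there is no principled desk-scale alternative.
    """

    kd_nm: dict[str, float]

    def __post_init__(self) -> None:
        for label, kd in self.kd_nm.items():
            if not kd > 0:
                raise ValidationError(f"Kd for {label!r} must be positive, got {kd}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityTable":
        """Read a two-column TSV: protein_label, kd_nM."""
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        if "protein_label" not in cols or "kd_nm" not in cols:
            raise InputFormatError(
                f"{path}: expected columns protein_label and kd_nM, got {list(df.columns)}"
            )
        kd: dict[str, float] = {}
        for _, row in df.iterrows():
            label = str(row[cols["protein_label"]])
            if label in kd:
                raise ValidationError(f"{path}: duplicate protein label {label!r}")
            raw = str(row[cols["kd_nm"]]).strip().replace(",", "")
            if raw.startswith(">") or raw.startswith("<"):
                warnings.warn(
                    f"censored Kd {raw!r} for {label!r} taken at its bound"
                )
                raw = raw[1:].strip()
            kd[label] = float(raw)
        return cls(kd)

    def activity_difference(self, a: str, b: str) -> float:
        """|log10(Kd_a) - log10(Kd_b)|."""
        return abs(np.log10(self.kd_nm[a]) - np.log10(self.kd_nm[b]))


def correlate(
    similarities: dict[tuple[str, str], float] | pd.DataFrame,
    activities: ActivityTable,
    method: str = "pearson",
) -> float:
    """Correlation between pairwise similarities and activity differences.

    ``similarities`` maps protein pairs to similarity scores (or is a
    DataFrame with columns protein_a, protein_b, similarity).  Requires at
    least 3 pairs, all present in the activity table; constant vectors are
    rejected because the coefficient is undefined.
    """
    if method not in _METHODS:
        raise ValidationError(f"method must be one of {_METHODS}, got {method!r}")
    if isinstance(similarities, pd.DataFrame):
        similarities = {
            pair_key(str(r.protein_a), str(r.protein_b)): float(r.similarity)
            for r in similarities.itertuples()
        }
    if len(similarities) < 3:
        raise ValidationError(f"need at least 3 protein pairs, got {len(similarities)}")
    sims, diffs = [], []
    for (a, b), s in sorted(similarities.items()):
        for label in (a, b):
            if label not in activities.kd_nm:
                raise ValidationError(f"protein {label!r} missing from activity table")
        sims.append(s)
        diffs.append(activities.activity_difference(a, b))
    x = np.asarray(sims)
    y = np.asarray(diffs)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant input vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def provenance(inputs: dict[str, str | Path] | None = None, **params) -> dict:
    """Provenance block for machine outputs: version, parameters, digests."""
    from . import __version__

    block = {"package": "twn-rencod", "version": __version__, "parameters": params}
    if inputs:
        digests = {}
        for name, p in inputs.items():
            p = Path(p)
            if p.exists():
                digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        block["input_sha256"] = digests
    return block
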