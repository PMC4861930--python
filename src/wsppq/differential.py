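"""Differentially abundant protein (DAP) calling and overlap analysis.

A protein is a DAP when |Zq| >= threshold (default 2, i.e. p < 0.05 under
the standard-normal null); the comparison is inclusive. Excluded
(contaminant) proteins are never flagged. Overlaps among the DAP sets of
several comparisons are reported as exact intersection counts plus pairwise
percentages normalized by the smaller set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import ComparisonResult

__all__ = ["call_daps", "dap_ids", "overlap_analysis", "OverlapSummary"]


def call_daps(result: ComparisonResult, threshold: float = 2.0) -> pd.DataFrame:
    """Flag DAPs in one comparison.

    Returns one row per protein: protein_id, Zq, is_dap, direction
    (up/down/none). ``is_dap`` iff the protein is not excluded and
    |Zq| >= threshold; direction follows the sign of Zq.
    """
    if not threshold > 0:
        raise ConfigError("DAP threshold must be > 0")
    df = result.proteins[["protein_id", "Zq", "excluded_flag"]].copy()
    is_dap = (~df["excluded_flag"]) & (df["Zq"].abs() >= threshold)
    df["is_dap"] = is_dap
    df["direction"] = np.where(is_dap & (df["Zq"] > 0), "up",
                               np.where(is_dap, "down", "none"))
    return df[["protein_id", "Zq", "is_dap", "direction"]]


def dap_ids(result: ComparisonResult, threshold: float = 2.0,
            direction: str | None = None) -> set[str]:
    """Convenience: the set of DAP accessions, optionally one direction."""
    calls = call_daps(result, threshold)
    mask = calls["is_dap"]
    if direction is not None:
        mask &= calls["direction"] == direction
    return set(calls.loc[mask, "protein_id"])


@dataclass
class OverlapSummary:
    """Set arithmetic over the DAP sets of >= 2 comparisons.

    ``intersections`` maps every combination of comparison labels (as a
    sorted tuple, size >= 2) to its exact intersection count;
    ``pairwise_percent`` expresses each pairwise intersection relative to
    the smaller of the two sets, in percent.
    """

    sizes: dict[str, int]
    intersections: dict[tuple[str, ...], int]
    pairwise_percent: dict[tuple[str, str], float]
    union_size: int = 0
    unique_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "union_size": self.union_size,
            "unique_counts": self.unique_counts,
            "intersections": {"&".join(k): v for k, v in self.intersections.items()},
            "pairwise_percent": {"&".join(k): v
                                 for k, v in self.pairwise_percent.items()},
        }


def overlap_analysis(dap_sets: Mapping[str, set[str]]) -> OverlapSummary:
    """Count intersections among DAP sets and their relative overlaps.

    The pairwise overlap percentage is |A & B| / min(|A|, |B|) * 100 — the
    shared fraction of the smaller set. Rounding is left to report time.
    """
    if len(dap_sets) < 2:
        raise ConfigError("overlap analysis needs >= 2 comparisons")
    labels = sorted(dap_sets)
    sizes = {lab: len(dap_sets[lab]) for lab in labels}
    inter: dict[tuple[str, ...], int] = {}
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            s = set.intersection(*(set(dap_sets[lab]) for lab in combo))
            inter[combo] = len(s)
    pct: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        smaller = min(sizes[a], sizes[b])
        pct[(a, b)] = 100.0 * inter[(a, b)] / smaller if smaller else 0.0
    union = set().union(*(dap_sets[lab] for lab in labels))
    others = {lab: set().union(*(dap_sets[o] for o in labels if o != lab))
              for lab in labels}
    unique = {lab: len(set(dap_sets[lab]) - others[lab]) for lab in labels}
    return OverlapSummary(sizes, inter, pct, len(union), unique)
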