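"""Functional-category statistics: enrichment of DAP sets and threshold-free
proteome-wide category regulation.

Two complementary views of the same annotation database:

* :func:`enrich_daps` — classical over-representation of a DAP set against
  the quantified background, exact hypergeometric upper tail, significant
  at p < alpha.  Depends on the DAP threshold.

* :func:`test_category_regulation` — threshold-free: under the null every
  protein's Zq is standard normal, so for a category C with n quantified
  members the standardized sum

      Zc = sum_{q in C} Zq / sqrt(n)

  is itself standard normal.  A coherent shift of the members moves Zc by
  sqrt(n) times the mean member shift, which is what makes small but
  coordinated changes detectable without any per-protein cutoff.  Two-sided
  normal p-values are Benjamini-Hochberg adjusted across all tested
  categories; a category is called regulated (up if Zc > 0, down otherwise)
  at q <= fdr.

:func:`build_cumulative_curves` exports the cumulative frequency of member
Zq values together with the standard-normal and all-protein reference
curves, ready for plotting; the core produces no graphics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, EmptyInputError
from .io import CategoryDB
from .model import ComparisonResult

__all__ = [
    "enrich_daps",
    "test_category_regulation",
    "CumulativeCurve",
    "build_cumulative_curves",
]


def enrich_daps(dap_ids: set[str], background_ids: set[str], db: CategoryDB,
                direction: str = "up", alpha: float = 0.05,
                min_category_size: int = 5) -> pd.DataFrame:
    """Hypergeometric over-representation of a DAP set per category.

    The population is the quantified, non-excluded background; draws are the
    DAPs (of one direction); successes are the category members present in
    the background.  p = P(X >= n_overlap), the exact upper tail.
    Categories with fewer than ``min_category_size`` members in the
    background are skipped.  Rows sorted by ascending p.
    """
    if not background_ids:
        raise EmptyInputError("empty background")
    if not dap_ids <= background_ids:
        raise ConfigError("dap_ids must be a subset of background_ids")
    m_pop = len(background_ids)
    n_draw = len(dap_ids)
    rows = []
    for cid in db.ids():
        in_bg = db.members(cid) & background_ids
        k_cat = len(in_bg)
        if k_cat < min_category_size:
            continue
        n_overlap = len(in_bg & dap_ids)
        # P(X >= n_overlap) for X ~ Hypergeom(m_pop, k_cat, n_draw)
        p = float(stats.hypergeom.sf(n_overlap - 1, m_pop, k_cat, n_draw))
        rows.append({
            "category_id": cid, "direction": direction,
            "n_background": m_pop, "n_dap": n_draw,
            "n_category_in_background": k_cat, "n_overlap": n_overlap,
            "p_value": min(p, 1.0), "significant": p < alpha,
        })
    out = pd.DataFrame(rows, columns=[
        "category_id", "direction", "n_background", "n_dap",
        "n_category_in_background", "n_overlap", "p_value", "significant"])
    return out.sort_values(["p_value", "category_id"],
                           kind="mergesort", ignore_index=True)


def test_category_regulation(result: ComparisonResult, db: CategoryDB,
                             fdr: float = 0.05,
                             min_size: int = 5) -> pd.DataFrame:
    """Threshold-free category regulation via the standardized Zq sum.

    For each category with >= ``min_size`` quantified (non-excluded)
    members: Zc = sum(Zq)/sqrt(n), two-sided normal p, BH q across all
    tested categories; regulated iff q <= fdr, direction by sign of Zc.
    Returns an empty frame (with a warning) when no category qualifies.
    """
    if not 0 < fdr < 1:
        raise ConfigError("fdr must lie in (0, 1)")
    zq = result.zq_map()
    rows = []
    for cid in db.ids():
        member_z = [zq[m] for m in db.members(cid) if m in zq]
        n = len(member_z)
        if n < min_size:
            continue
        zc = float(np.sum(member_z)) / np.sqrt(n)
        rows.append({"category_id": cid, "n": n, "Zc": zc,
                     "p_value": float(2.0 * stats.norm.sf(abs(zc)))})
    cols = ["category_id", "n", "Zc", "p_value", "q_value",
            "direction", "regulated"]
    if not rows:
        import warnings
        warnings.warn("no category meets min_size; empty regulation table")
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["direction"] = np.where(out["Zc"] > 0, "up", "down")
    out["regulated"] = out["q_value"] <= fdr
    return out[cols].sort_values(["q_value", "p_value", "category_id"],
                                 kind="mergesort", ignore_index=True)


# the name starts with "test_" for API reasons; keep pytest from collecting it
test_category_regulation.__test__ = False  # type: ignore[attr-defined]


@dataclass
class CumulativeCurve:
    """Plot-ready cumulative frequency of member Zq for one category.

    ``category`` holds the members' sorted Zq with cumulative frequencies
    1/n .. 1; ``normal`` the standard-normal CDF and ``all_proteins`` the
    empirical CDF of the whole included proteome, both evaluated on a
    common grid, as reference series.
    """

    category_id: str
    category: pd.DataFrame
    normal: pd.DataFrame
    all_proteins: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        frames = []
        for series, df in (("category", self.category),
                           ("normal", self.normal),
                           ("all_proteins", self.all_proteins)):
            frames.append(df.assign(series=series, category_id=self.category_id))
        return pd.concat(frames, ignore_index=True)[
            ["category_id", "series", "Zq", "cumulative_freq"]]


def build_cumulative_curves(result: ComparisonResult, db: CategoryDB,
                            category_ids: list[str]) -> list[CumulativeCurve]:
    """Cumulative-frequency curves of Zq for chosen categories.

    Each curve carries the category's member ECDF plus two references: the
    theoretical N(0,1) CDF and the ECDF of all included proteins, so a
    coherent shift of the category appears as a horizontal translation away
    from both references.
    """
    zq = result.zq_map()
    all_z = np.sort(np.fromiter(zq.values(), dtype=float))
    n_all = all_z.size
    all_curve = pd.DataFrame({
        "Zq": all_z,
        "cumulative_freq": np.arange(1, n_all + 1) / n_all,
    })
    normal_curve = pd.DataFrame({
        "Zq": all_z, "cumulative_freq": stats.norm.cdf(all_z),
    })
    curves = []
    for cid in category_ids:
        if cid not in db:
            raise KeyError(f"unknown category id {cid!r}")
        member_z = np.sort(np.array(
            [zq[m] for m in db.members(cid) if m in zq], dtype=float))
        if member_z.size == 0:
            raise EmptyInputError(f"category {cid!r} has no quantified members")
        cat_curve = pd.DataFrame({
            "Zq": member_z,
            "cumulative_freq": np.arange(1, member_z.size + 1) / member_z.size,
        })
        curves.append(CumulativeCurve(cid, cat_curve, normal_curve, all_curve))
    return curves
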