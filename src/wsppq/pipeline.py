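"""End-to-end study runner: every configured comparison, reports, manifest.

Thin deterministic composition over the library modules; re-running with the
same inputs and configuration yields byte-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import categories as _categories
from . import cluster as _cluster
from .differential import dap_ids, overlap_analysis, OverlapSummary
from .io import (CategoryDB, DesignConfig, ExclusionList, QuantTable,
                 write_category_report, write_cluster_report,
                 write_protein_report, write_run_manifest)
from .model import ComparisonResult, run_wspp

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """All per-comparison results plus cross-comparison summaries."""

    comparisons: dict[str, ComparisonResult]
    overlap: OverlapSummary | None = None
    regulation: dict[str, object] = field(default_factory=dict)


def _label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def run_study(table: QuantTable, design: DesignConfig,
              exclusions: ExclusionList | None = None,
              category_db: CategoryDB | None = None,
              outdir: str | Path | None = None) -> StudyResult:
    """Quantify every configured comparison and, when a category database is
    given, run the threshold-free regulation test per comparison.

    With ``outdir`` set, writes one protein report per comparison (and a
    category report when applicable) plus a JSON run manifest.
    """
    results: dict[str, ComparisonResult] = {}
    regulation: dict[str, object] = {}
    for comparison in design.comparisons:
        res = run_wspp(table, design, comparison, exclusions)
        results[_label(comparison)] = res
        if category_db is not None and len(category_db):
            regulation[_label(comparison)] = _categories.test_category_regulation(
                res, category_db, fdr=design.category_fdr,
                min_size=design.min_category_size)

    overlap = None
    if len(results) >= 2:
        overlap = overlap_analysis({
            lab: dap_ids(res, design.dap_threshold)
            for lab, res in results.items()
        })

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts = {}
        for lab, res in results.items():
            write_protein_report(res, outdir / f"proteins_{lab}.tsv",
                                 design.dap_threshold)
            counts[lab] = {
                "n_proteins": int(len(res.proteins)),
                "n_excluded": int(res.proteins["excluded_flag"].sum()),
                "n_daps": int(len(dap_ids(res, design.dap_threshold))),
                "n_dropped_spectra": res.n_dropped_spectra,
                "k": res.variance.k,
                "sigma2_P": res.variance.sigma2_P,
                "sigma2_Q": res.variance.sigma2_Q,
            }
            if lab in regulation:
                write_category_report(regulation[lab],
                                      outdir / f"categories_{lab}.tsv")
        extra = {"comparisons": counts}
        if overlap is not None:
            extra["overlap"] = overlap.to_json_dict()
        write_run_manifest(outdir / "manifest.json", design, extra)
    return StudyResult(results, overlap, regulation)
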