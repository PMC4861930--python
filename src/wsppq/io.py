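"""Readers, writers and run configuration for the quantification pipeline.

External formats
----------------
* PSM table: UTF-8 TSV with a mandatory header naming ``spectrum_id``,
  ``peptide_key``, ``protein_id`` and one column per reporter channel.
  Intensities are non-negative reals in arbitrary units (dot decimal).
* Category database: standard GMT (``id<TAB>description<TAB>member...``).
* Exclusion lists: plain text, one accession per line, ``#`` comments.
* Reports: TSV with fixed column order and 6-significant-digit floats;
  every run is accompanied by a JSON manifest echoing the configuration.

All identifiers are case-sensitive exact strings; no accession-version
stripping is performed — callers pre-normalize.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .model import ComparisonResult

PSM_KEY_COLUMNS = ("spectrum_id", "peptide_key", "protein_id")

__all__ = [
    "QuantTable",
    "DesignConfig",
    "CategoryDB",
    "ExclusionList",
    "read_psm_table",
    "write_psm_table",
    "read_gmt",
    "write_gmt",
    "read_exclusion_list",
    "write_exclusion_list",
    "write_protein_report",
    "write_category_report",
    "write_cluster_report",
    "write_run_manifest",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """PSM-level reporter-intensity records, the pipeline's raw input.

    ``data`` holds one row per peptide-spectrum match with the key columns
    ``spectrum_id`` (unique), ``peptide_key`` (sequence+charge) and
    ``protein_id``, plus one float column per reporter channel.
    """

    data: pd.DataFrame
    channel_ids: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in (*PSM_KEY_COLUMNS, *self.channel_ids)
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"QuantTable missing columns: {missing}")
        dup = self.data["spectrum_id"].duplicated()
        if dup.any():
            raise ValidationError(
                "duplicate spectrum_id values: "
                f"{sorted(self.data.loc[dup, 'spectrum_id'].unique()[:5])}"
            )
        inten = self.data[self.channel_ids].to_numpy(dtype=float)
        if not np.isfinite(inten).all():
            raise ValidationError("non-finite reporter intensity")
        if (inten < 0).any():
            raise ValidationError("negative reporter intensity")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DesignConfig:
    """Experimental design: channel-to-cohort map, comparisons, thresholds.

    ``comparisons`` is an ordered list of ``(test_cohort, reference_cohort)``
    pairs; each cohort must own at least one channel in ``channel_map``.
    """

    channel_map: dict[str, str]
    comparisons: list[tuple[str, str]]
    dap_threshold: float = 2.0
    enrichment_alpha: float = 0.05
    category_fdr: float = 0.05
    min_category_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.comparisons = [tuple(c) for c in self.comparisons]
        cohorts = set(self.channel_map.values())
        for test, ref in self.comparisons:
            for cohort in (test, ref):
                if cohort not in cohorts:
                    raise ConfigError(
                        f"comparison cohort {cohort!r} not in channel_map"
                    )
        if not self.dap_threshold > 0:
            raise ConfigError("dap_threshold must be > 0")
        for name in ("enrichment_alpha", "category_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")

    @property
    def channel_ids(self) -> list[str]:
        return list(self.channel_map)

    def channels_for(self, cohort: str) -> list[str]:
        chans = [ch for ch, co in self.channel_map.items() if co == cohort]
        if not chans:
            raise ConfigError(f"cohort {cohort!r} has no channels")
        return chans

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["comparisons"] = [list(c) for c in self.comparisons]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class CategoryDB:
    """Functional-category annotation: id -> (name, member accessions)."""

    categories: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, (_, members) in self.categories.items():
            if not members:
                raise ValidationError(f"category {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.categories)

    def __contains__(self, cid: str) -> bool:
        return cid in self.categories

    def name(self, cid: str) -> str:
        return self.categories[cid][0]

    def members(self, cid: str) -> frozenset[str]:
        return self.categories[cid][1]

    def ids(self) -> list[str]:
        return list(self.categories)


@dataclass
class ExclusionList:
    """Accessions removed before grand-mean estimation (e.g. plasma, keratin)."""

    accessions: set[str] = field(default_factory=set)
    label: str = ""

    def __post_init__(self) -> None:
        if any((not a) or a != a.strip() for a in self.accessions):
            raise ValidationError("exclusion list contains blank/padded ids")

    def __or__(self, other: "ExclusionList") -> "ExclusionList":
        label = "+".join(x for x in (self.label, other.label) if x)
        return ExclusionList(self.accessions | other.accessions, label)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def read_psm_table(path: str | Path, channel_ids: Sequence[str]) -> QuantTable:
    """Read a PSM TSV, validating header, intensities and id uniqueness.

    Raises :class:`FormatError` naming any missing column, and
    :class:`ValidationError` with 1-based file line numbers for rows whose
    intensities are negative or non-numeric. Row order is preserved.
    """
    channel_ids = list(channel_ids)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (*PSM_KEY_COLUMNS, *channel_ids):
        if col not in df.columns:
            raise FormatError(f"{path}: header lacks required column {col!r}")

    bad_lines: list[int] = []
    numeric = {}
    for ch in channel_ids:
        vals = pd.to_numeric(df[ch], errors="coerce")
        bad = vals.isna() | (vals < 0) | ~np.isfinite(vals)
        if bad.any():
            # +2: header line plus 1-based indexing
            bad_lines.extend((df.index[bad] + 2).tolist())
        numeric[ch] = vals
    if bad_lines:
        raise ValidationError(
            f"{path}: negative or non-numeric intensity on line(s) "
            f"{sorted(set(bad_lines))[:10]}"
        )
    out = df[list(PSM_KEY_COLUMNS)].copy()
    for ch in channel_ids:
        out[ch] = numeric[ch].astype(float)
    return QuantTable(out, channel_ids)


def write_psm_table(table: QuantTable, path: str | Path) -> None:
    """Write a PSM TSV that :func:`read_psm_table` round-trips byte-exactly."""
    cols = [*PSM_KEY_COLUMNS, *table.channel_ids]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in table.data[cols].itertuples(index=False):
            fields = [str(v) if isinstance(v, str) else repr(float(v))
                      for v in row]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GMT category databases
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> CategoryDB:
    """Parse a GMT file into a :class:`CategoryDB`.

    Each non-empty line needs >= 3 tab-separated fields (id, description,
    members...). Member lists are de-duplicated; blank tokens are dropped.
    """
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            cid, desc = fields[0], fields[1]
            if cid in categories:
                raise ValidationError(f"{path}:{lineno}: duplicate category id {cid!r}")
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ValidationError(f"{path}:{lineno}: category {cid!r} has no members")
            categories[cid] = (desc, members)
    return CategoryDB(categories)


def write_gmt(db: CategoryDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cid, (desc, members) in db.categories.items():
            fh.write("\t".join([cid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# exclusion lists
# ---------------------------------------------------------------------------

def read_exclusion_list(path: str | Path, label: str = "") -> ExclusionList:
    """Read one accession per line; ``#`` starts a comment; blanks ignored."""
    accessions: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                accessions.add(token)
    return ExclusionList(accessions, label)


def write_exclusion_list(excl: ExclusionList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for acc in sorted(excl.accessions):
            fh.write(acc + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(v: object) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".6g")
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    return str(v)


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_protein_report(result: "ComparisonResult", path: str | Path,
                         dap_threshold: float = 2.0) -> None:
    """Write the per-protein quantification report.

    Columns: protein_id, n_peptides, n_spectra, x_q, Xprime_q, Wq, Zq,
    dap_flag, direction. Rows sorted by descending \\|Zq\\|, ties broken
    lexicographically by accession; floats carry 6 significant digits.
    Excluded proteins are reported but never flagged as DAPs.
    """
    df = result.proteins.copy()
    dap = (~df["excluded_flag"]) & (df["Zq"].abs() >= dap_threshold)
    df["dap_flag"] = dap
    df["direction"] = np.where(
        dap & (df["Zq"] > 0), "up", np.where(dap, "down", "none")
    )
    df = df.sort_values(
        ["Zq", "protein_id"], key=lambda s: -s.abs() if s.name == "Zq" else s,
        kind="mergesort",
    )
    cols = ["protein_id", "n_peptides", "n_spectra", "x_q", "Xprime_q",
            "Wq", "Zq", "dap_flag", "direction"]
    _write_tsv(df[cols], path)


def write_category_report(regulation: pd.DataFrame, path: str | Path) -> None:
    """Write the category-regulation table (category, n, Zc, p, q, direction)."""
    cols = ["category_id", "n", "Zc", "p_value", "q_value", "direction", "regulated"]
    df = regulation.sort_values(
        ["q_value", "p_value", "category_id"], kind="mergesort"
    )
    _write_tsv(df[cols], path)


def write_cluster_report(assignment, regulation: pd.DataFrame | None,
                         path: str | Path) -> None:
    """Write cluster membership: cluster_id, category_id, representative flag,
    plus Zc/direction when a regulation table is supplied."""
    rows = []
    zc = {}
    direction = {}
    if regulation is not None:
        zc = dict(zip(regulation["category_id"], regulation["Zc"]))
        direction = dict(zip(regulation["category_id"], regulation["direction"]))
    for cluster_id in sorted(assignment.clusters):
        rep = assignment.representatives[cluster_id]
        for cid in sorted(assignment.clusters[cluster_id]):
            rows.append({
                "cluster_id": cluster_id,
                "category_id": cid,
                "representative": cid == rep,
                "Zc": zc.get(cid, float("nan")),
                "direction": direction.get(cid, "none"),
            })
    _write_tsv(pd.DataFrame(rows), path)


def write_run_manifest(path: str | Path, design: DesignConfig,
                       extra: Mapping[str, object] | None = None) -> None:
    """JSON sidecar echoing the configuration, seeds and per-stage counts."""
    from . import __version__

    payload: dict[str, object] = {
        "wsppq_version": __version__,
        "design": {
            **dataclasses.asdict(design),
            "comparisons": [list(c) for c in design.comparisons],
        },
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
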