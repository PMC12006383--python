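"""Reading, validating and writing annotated IGH repertoire tables.

The on-disk format is the AIRR Rearrangement TSV dialect: one row per
observed sequence (UMI-collapsed), tab-separated, with a header row.
Community column names are accepted as aliases for the internal field
names (``junction`` for the nucleotide junction, ``c_call`` for the
constant-region call, ``duplicate_count`` for the UMI abundance,
``sequence_alignment``/``germline_alignment`` for the V-region pair).

Rows violating the data-model invariants are dropped at load and
tallied in a :class:`LoadReport`; nothing is dropped silently.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("repconv")

#: Recognised isotype labels (sub-isotype resolution where the constant
#: region distinguishes subclasses).
ISOTYPES = (
    "IGHM",
    "IGHD",
    "IGHA1",
    "IGHA2",
    "IGHG1",
    "IGHG2",
    "IGHG3",
    "IGHG4",
    "IGHE",
)

#: Tissue vocabulary used for sample metadata.
TISSUES = ("LN", "PBMC", "plasmablast", "gut_inflamed", "gut_uninflamed", "other")

#: Minimum retained CDR-H3 (junction) amino-acid length.  Mirrors the
#: shortest word context the greedy clustering stage can handle
#: (CD-HIT-style ``-l 4``): shorter junctions are rejected at load.
MIN_JUNCTION_AA_LEN = 4

#: Aliases: internal field name -> accepted column names, in priority order.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "sequence_id": ("sequence_id",),
    "v_call": ("v_call",),
    "d_call": ("d_call",),
    "j_call": ("j_call",),
    "junction_aa": ("junction_aa",),
    "junction_nt": ("junction_nt", "junction"),
    "isotype": ("isotype", "c_call"),
    "umi_count": ("umi_count", "duplicate_count"),
    "v_sequence_alignment": ("v_sequence_alignment", "sequence_alignment"),
    "v_germline_alignment": ("v_germline_alignment", "germline_alignment"),
}

MANDATORY_FIELDS = (
    "sequence_id",
    "v_call",
    "j_call",
    "junction_aa",
    "junction_nt",
    "isotype",
    "umi_count",
)


class RepertoireError(ValueError):
    """Raised for malformed repertoire files or metadata."""


def normalize_gene_call(raw_call: str) -> str:
    """Collapse an annotation gene call to a gene-level name.

    Strips the allele suffix (``*NN``) and, when several comma-separated
    calls are present, keeps the first (annotation tools order calls by
    score).  Deterministic.

    >>> normalize_gene_call("IGHV4-39*01")
    'IGHV4-39'
    >>> normalize_gene_call("IGHJ4*02,IGHJ5*01")
    'IGHJ4'
    """
    if raw_call is None:
        raise RepertoireError("empty gene call")
    first = str(raw_call).split(",")[0].strip()
    gene = first.split("*")[0].strip()
    if not gene:
        raise RepertoireError(f"unparsable gene call: {raw_call!r}")
    return gene


def parse_isotype(c_call: str | None) -> str:
    """Map a constant-region call to an isotype label.

    The longest recognised isotype that prefixes the call wins
    (``IGHA1P`` -> ``IGHA1``).  Calls lacking subclass resolution
    (bare ``IGHA``/``IGHG``) or unrecognised calls map to ``unknown``;
    such rows are retained but excluded from isotype-stratified
    statistics downstream.
    """
    if c_call is None:
        return "unknown"
    call = str(c_call).strip().upper()
    for iso in sorted(ISOTYPES, key=len, reverse=True):
        if call.startswith(iso):
            return iso
    return "unknown"


@dataclass
class Rearrangement:
    """One annotated IGH sequence observation (UMI-collapsed row).

    ``v_call``/``j_call`` keep the annotation as given; the gene-level
    names used for clone matching are derived at construction into
    ``v_gene``/``j_gene``.  ``v_sequence_alignment`` and
    ``v_germline_alignment`` are an equal-length aligned pair covering
    the V region (CDR1/2 + framework) used for mutation counting.
    """

    sequence_id: str
    v_call: str
    j_call: str
    junction_aa: str
    junction_nt: str
    isotype: str = "unknown"
    umi_count: int = 1
    d_call: str | None = None
    v_sequence_alignment: str | None = None
    v_germline_alignment: str | None = None
    v_gene: str = field(init=False)
    j_gene: str = field(init=False)

    def __post_init__(self) -> None:
        self.v_gene = normalize_gene_call(self.v_call)
        self.j_gene = normalize_gene_call(self.j_call)


@dataclass
class RepertoireSample:
    """A set of rearrangements plus subject/tissue/group metadata."""

    sample_id: str
    subject_id: str
    tissue: str = "other"
    group: str = ""
    rearrangements: list[Rearrangement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rearrangements)


@dataclass
class LoadReport:
    """Row-level accounting for one load: kept vs dropped, with reasons."""

    n_rows: int = 0
    n_kept: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return self.n_rows - self.n_kept

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_kept": self.n_kept,
                "n_dropped": self.n_dropped,
                "drop_reasons": dict(self.drop_reasons),
            }
        )


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map internal field names to the columns present in the file."""
    resolved: dict[str, str] = {}
    for internal, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in columns:
                resolved[internal] = alias
                break
    missing = [f for f in MANDATORY_FIELDS if f not in resolved]
    if missing:
        raise RepertoireError(
            "missing mandatory column(s): "
            + ", ".join(f"{m} (aliases: {'/'.join(COLUMN_ALIASES[m])})" for m in missing)
        )
    return resolved


def _row_to_rearrangement(row: Mapping[str, object]) -> tuple[Rearrangement | None, str | None]:
    """Validate one row; return (rearrangement, None) or (None, drop reason)."""

    def _get(name: str) -> str | None:
        val = row.get(name)
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return None
        s = str(val).strip()
        return s or None

    junction_aa = _get("junction_aa")
    junction_nt = _get("junction_nt")
    if not junction_aa or not junction_nt:
        return None, "missing_junction"
    if len(junction_aa) < MIN_JUNCTION_AA_LEN:
        return None, "junction_aa_too_short"
    try:
        umi = int(float(row.get("umi_count", 1)))
    except (TypeError, ValueError):
        return None, "bad_umi_count"
    if umi < 1:
        return None, "bad_umi_count"
    seq_aln = _get("v_sequence_alignment")
    germ_aln = _get("v_germline_alignment")
    if (seq_aln is None) != (germ_aln is None):
        return None, "unpaired_alignment"
    if seq_aln is not None and germ_aln is not None and len(seq_aln) != len(germ_aln):
        return None, "alignment_length_mismatch"
    v_call, j_call = _get("v_call"), _get("j_call")
    if not v_call or not j_call:
        return None, "unparsable_gene_call"
    try:
        r = Rearrangement(
            sequence_id=_get("sequence_id") or "",
            v_call=v_call,
            j_call=j_call,
            junction_aa=junction_aa,
            junction_nt=junction_nt,
            isotype=parse_isotype(_get("isotype")),
            umi_count=umi,
            d_call=_get("d_call"),
            v_sequence_alignment=seq_aln,
            v_germline_alignment=germ_aln,
        )
    except RepertoireError:
        return None, "unparsable_gene_call"
    if not r.sequence_id:
        return None, "missing_sequence_id"
    return r, None


def read_repertoire(
    path: str | Path,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[list[RepertoireSample], LoadReport]:
    """Read an AIRR Rearrangement TSV into validated samples.

    Parameters
    ----------
    path
        Tab-separated file with a header row.  If a ``sample_id`` column
        is present, rows are grouped by it; otherwise all rows form a
        single sample (whose id comes from *metadata* or the file stem).
    metadata
        Mapping ``sample_id -> {subject_id, tissue, group}``.  Samples
        without an entry default subject_id to the sample_id.

    Returns
    -------
    (samples, report)
        Samples sorted by sample_id, and the row-level load report.
        Invalid rows are dropped and counted; zero surviving rows is a
        hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    resolved = _resolve_columns(list(df.columns))
    metadata = dict(metadata or {})

    report = LoadReport(n_rows=len(df))
    by_sample: dict[str, list[Rearrangement]] = {}
    has_sample_col = "sample_id" in df.columns
    default_sample = next(iter(metadata), path.stem)

    for rec in df.to_dict("records"):
        row = {internal: rec.get(col) for internal, col in resolved.items()}
        r, reason = _row_to_rearrangement(row)
        if r is None:
            report.drop_reasons[reason] += 1
            continue
        sid = str(rec["sample_id"]) if has_sample_col else default_sample
        by_sample.setdefault(sid, []).append(r)
        report.n_kept += 1

    if report.n_kept == 0:
        raise RepertoireError(f"no valid rows survived loading {path}")
    if report.n_dropped:
        logger.warning(
            "load %s: dropped %d/%d rows (%s)",
            path.name,
            report.n_dropped,
            report.n_rows,
            dict(report.drop_reasons),
        )

    samples = []
    for sid in sorted(by_sample):
        meta = metadata.get(sid, {})
        samples.append(
            RepertoireSample(
                sample_id=sid,
                subject_id=str(meta.get("subject_id", sid)),
                tissue=str(meta.get("tissue", "other")),
                group=str(meta.get("group", "")),
                rearrangements=by_sample[sid],
            )
        )
    return samples, report


def write_repertoire(samples: Iterable[RepertoireSample], path: str | Path) -> None:
    """Write samples to one AIRR Rearrangement TSV (with a sample_id column)."""
    rows = []
    for s in samples:
        for r in s.rearrangements:
            rows.append(
                {
                    "sequence_id": r.sequence_id,
                    "sample_id": s.sample_id,
                    "v_call": r.v_call,
                    "d_call": r.d_call or "",
                    "j_call": r.j_call,
                    "junction": r.junction_nt,
                    "junction_aa": r.junction_aa,
                    "c_call": r.isotype,
                    "duplicate_count": r.umi_count,
                    "sequence_alignment": r.v_sequence_alignment or "",
                    "germline_alignment": r.v_germline_alignment or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read sample metadata from TSV or YAML into sample_id -> descriptor."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise RepertoireError(f"metadata YAML must map sample_id to fields: {path}")
        return {str(k): dict(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise RepertoireError("metadata TSV requires a sample_id column")
    return {
        str(rec["sample_id"]): {k: v for k, v in rec.items() if k != "sample_id"}
        for rec in df.to_dict("records")
    }


def write_metadata(samples: Iterable[RepertoireSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "tissue": s.tissue,
            "group": s.group,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
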