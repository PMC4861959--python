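"""Readers and writers for every external file the pipeline touches.

All genomic intervals are held internally as 0-based, half-open
``[start, end)`` — BED's native convention.  GTF input (1-based, inclusive)
is converted at the boundary so that downstream window arithmetic never has
to reason about coordinate dialects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "TranscriptRecord",
    "ExpressionMatrix",
    "FormatError",
    "read_peaks",
    "read_annotation",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_network",
    "read_network",
    "write_classification",
    "read_classification",
    "write_feature_table",
    "read_feature_table",
]


class FormatError(ValueError):
    """Raised for malformed records in an input file; carries line context."""


@dataclass(frozen=True)
class Peak:
    """A single CLIP binding site of one RBP.

    ``binding_p`` is the per-peak binding p-value reported by the peak
    caller (smaller = stronger binding signal), constrained to (0, 1].
    """

    rbp_id: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str = "."
    binding_p: float = 1.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("peak chrom must be non-empty")
        if self.start >= self.end:
            raise FormatError(
                f"peak start must be < end, got [{self.start}, {self.end})"
            )
        if not (0.0 < self.binding_p <= 1.0):
            raise FormatError(
                f"binding p-value must be in (0, 1], got {self.binding_p}"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript: exon structure, parent gene and biotype.

    Exons are 0-based half-open, sorted by start, non-overlapping.
    ``length`` is the spliced length, i.e. the sum of exon lengths.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: transcript needs >=1 exon")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"{self.transcript_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        expected = sum(e - s for s, e in self.exons)
        if self.length == 0:
            object.__setattr__(self, "length", expected)
        elif self.length != expected:
            raise FormatError(
                f"{self.transcript_id}: length {self.length} != exon sum {expected}"
            )

    @property
    def genomic_start(self) -> int:
        return self.exons[0][0]

    @property
    def genomic_end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ExpressionMatrix:
    """Expression values (TPM-like or protein abundance), rows x tissues."""

    data: pd.DataFrame  # index: row ids, columns: tissue ids
    level: str = "transcript"  # or "protein"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate row ids: {dups}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate tissue ids")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# peaks (BED-like)


def read_peaks(
    path: str | Path,
    rbp_id: str | None = None,
    p_value_column: int = 4,
    log10_p: bool = False,
) -> list[Peak]:
    """Read CLIP peaks from a tab-separated BED-like file.

    Parameters
    ----------
    path
        BED file with at least 5 columns (chrom, start, end, name, score);
        strand is taken from column 6 when present.
    rbp_id
        RBP these peaks belong to; defaults to the file stem.
    p_value_column
        0-based index of the column carrying the per-peak binding p-value.
        CLIP peak exports differ in where (and how) they store it.
    log10_p
        If True the column holds -log10(p) and is converted back to raw p.

    Raises
    ------
    FormatError
        listing the offending line numbers, if any record fails validation.
    """
    path = Path(path)
    if rbp_id is None:
        rbp_id = path.stem
    peaks: list[Peak] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= max(p_value_column, 2):
                errors.append(f"line {lineno}: expected >={p_value_column + 1} columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                p = float(fields[p_value_column])
                if log10_p:
                    p = 10.0 ** (-p)
                strand = fields[5] if len(fields) > 5 else "."
                peaks.append(
                    Peak(rbp_id, fields[0], start, end, strand, binding_p=p)
                )
            except (ValueError, FormatError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    return peaks


# ---------------------------------------------------------------------------
# annotation (GTF)

_BIOTYPE_KEYS = ("transcript_biotype", "gene_biotype", "biotype", "transcript_type", "gene_type")


def read_annotation(path: str | Path) -> list[TranscriptRecord]:
    """Read exon features from a GTF file into per-transcript records.

    GTF coordinates (1-based, inclusive) are converted to internal 0-based
    half-open intervals: exon (a, b) becomes [a-1, b), preserving length.
    Transcripts whose exons overlap raise; non-exon features are ignored.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        info = grouped.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", ["?"])[0],
                "biotype": _extract_biotype(feat.attributes),
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
            },
        )
        info["exons"].append((feat.start - 1, feat.end))
    records = []
    for tid, info in grouped.items():
        exons = tuple(sorted(info.pop("exons")))
        records.append(TranscriptRecord(transcript_id=tid, exons=exons, **info))
    return records


def _extract_biotype(attrs) -> str:
    for key in _BIOTYPE_KEYS:
        if key in attrs:
            return attrs[key][0]
    return "unknown"


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, level: str = "transcript") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = tissue ids, index = row ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(df, level=level)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


# ---------------------------------------------------------------------------
# edge lists (undirected PPI)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected edge list; dedupes and drops self-loops."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            edges.append(key)
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# tabular pipeline outputs


def write_network(net, path: str | Path) -> None:
    """Write a TargetNetwork as TSV (rbp_id, transcript_id, n_supporting_peaks)."""
    rows = []
    for rbp, targets in sorted(net.targets.items()):
        for tid in sorted(targets):
            rows.append((rbp, tid, len(net.supporting_peaks.get((rbp, tid), []))))
    pd.DataFrame(rows, columns=["rbp_id", "transcript_id", "n_supporting_peaks"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path: str | Path):
    from .network import TargetNetwork

    df = pd.read_csv(path, sep="\t", dtype={"rbp_id": str, "transcript_id": str})
    net = TargetNetwork()
    for row in df.itertuples(index=False):
        net.targets.setdefault(row.rbp_id, set()).add(row.transcript_id)
    return net


def write_classification(records: Sequence, path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in records]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_classification(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"rbp_id": str})


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
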