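"""Build the RBP -> target-transcript network from CLIP peaks.

A transcript is a target of an RBP when at least one of the RBP's peaks
overlaps (shares >=1 base with) a window of +/- ``flank`` bp around any of
the transcript's exon start or end coordinates.  The default flank of
300 bp reflects the empirical footprint of RBP binding around splice
sites.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats import Peak, TranscriptRecord

__all__ = ["BoundaryWindow", "TargetNetwork", "boundary_windows", "map_targets", "network_summary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundaryWindow:
    """Window of +/- flank bp around one exon boundary (0-based half-open)."""

    chrom: str
    start: int
    end: int
    transcript_id: str
    boundary_kind: str  # "exon_start" | "exon_end"


@dataclass
class TargetNetwork:
    """Map RBP -> set of target transcript ids, with supporting peaks."""

    targets: dict[str, set[str]] = field(default_factory=dict)
    supporting_peaks: dict[tuple[str, str], list[Peak]] = field(default_factory=dict)

    def add(self, rbp_id: str, transcript_id: str, peak: Peak | None = None) -> None:
        self.targets.setdefault(rbp_id, set()).add(transcript_id)
        if peak is not None:
            self.supporting_peaks.setdefault((rbp_id, transcript_id), []).append(peak)

    def rbps(self) -> list[str]:
        return sorted(self.targets)

    def n_targets(self, rbp_id: str) -> int:
        return len(self.targets.get(rbp_id, set()))

    def union_targets(self) -> set[str]:
        out: set[str] = set()
        for t in self.targets.values():
            out |= t
        return out


def boundary_windows(
    transcript: TranscriptRecord, flank: int = 300
) -> list[BoundaryWindow]:
    """Windows around each exon's first and last base.

    For an exon [s, e) the start window is [s - flank, s + flank + 1) and
    the end window is [(e-1) - flank, (e-1) + flank + 1): each covers the
    boundary base itself plus ``flank`` bp on both sides, clipped at the
    chromosome origin.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for s, e in transcript.exons:
        out.append(
            BoundaryWindow(
                transcript.chrom,
                max(0, s - flank),
                s + flank + 1,
                transcript.transcript_id,
                "exon_start",
            )
        )
        out.append(
            BoundaryWindow(
                transcript.chrom,
                max(0, e - 1 - flank),
                e + flank,
                transcript.transcript_id,
                "exon_end",
            )
        )
    return out


def map_targets(
    peaks: Iterable[Peak],
    transcripts: Sequence[TranscriptRecord],
    flank: int = 300,
    respect_strand: bool = False,
    exclude_self: dict[str, str] | None = None,
) -> TargetNetwork:
    """Overlap peaks with exon-boundary windows to derive the target network.

    Parameters
    ----------
    peaks, transcripts
        Must share a chromosome naming scheme; peaks on chromosomes absent
        from the annotation are counted and ignored with a warning.
    flank
        Half-width of the boundary window in bp.
    respect_strand
        Require peak and transcript strand to agree ('.' peaks never match).
    exclude_self
        Optional map rbp_id -> gene_id; targets of that gene are dropped
        for that RBP (an RBP's own transcripts count as targets otherwise).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    for tx in transcripts:
        for w in boundary_windows(tx, flank):
            trees[tx.chrom].addi(w.start, w.end, tx.transcript_id)

    net = TargetNetwork()
    missing_chroms: dict[str, int] = defaultdict(int)
    for peak in peaks:
        net.targets.setdefault(peak.rbp_id, set())
        if peak.chrom not in trees:
            missing_chroms[peak.chrom] += 1
            continue
        for iv in trees[peak.chrom].overlap(peak.start, peak.end):
            tx = tx_by_id[iv.data]
            if respect_strand and peak.strand != tx.strand:
                continue
            if exclude_self and exclude_self.get(peak.rbp_id) == tx.gene_id:
                continue
            net.add(peak.rbp_id, tx.transcript_id, peak)
    if missing_chroms:
        total = sum(missing_chroms.values())
        warnings.warn(
            f"{total} peaks on chromosomes absent from the annotation "
            f"({sorted(missing_chroms)}) were ignored",
            stacklevel=2,
        )
    return net


def network_summary(net: TargetNetwork) -> tuple[pd.DataFrame, int]:
    """Per-RBP target counts and the size of the union of all target sets."""
    table = pd.DataFrame(
        {
            "rbp_id": net.rbps(),
            "n_targets": [net.n_targets(r) for r in net.rbps()],
        }
    )
    return table, len(net.union_targets())
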