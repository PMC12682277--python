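"""Structural-variant breakpoint parsing, fragile-region clustering, and
RSS annotation of clusters.

A "fragile region" here is a group of patient breakpoints on one chromosome
in which consecutive breakpoints lie at most ``max_gap`` (default 100 bp)
apart — the single-linkage reading of the published selection rule.  A
``--diameter`` mode bounding the maximum pairwise distance instead is kept
for sensitivity analysis; for clusters spanning < max_gap the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .rss_scanner import RSSConsensus, RSSHit, ScanParams, scan_rss
from .seqcore import DnaSequence

SV_TYPES = {
    "deletion",
    "insertion",
    "inversion",
    "inter_translocation",
    "intra_translocation",
    "unknown",
}


class TableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class BreakpointRecord:
    """One breakpoint; genomic position stored 0-based (converted from the
    1-based database export convention on input)."""

    sample_id: str
    chrom: str
    pos: int
    sv_type: str = "unknown"
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")


@dataclass(frozen=True)
class BreakpointCluster:
    chrom: str
    members: tuple[BreakpointRecord, ...]

    @property
    def start(self) -> int:
        return min(m.pos for m in self.members)

    @property
    def end(self) -> int:  # half-open
        return max(m.pos for m in self.members) + 1

    @property
    def span(self) -> int:
        return max(m.pos for m in self.members) - self.start

    @property
    def n_breakpoints(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 100
    min_breakpoints: int = 2
    flank: int = 0
    method: str = "gap"  # "gap" (adjacent distance) or "diameter" (max pairwise)

    def __post_init__(self) -> None:
        if self.max_gap < 0 or self.min_breakpoints < 0 or self.flank < 0:
            raise ValueError("ClusterParams fields must be non-negative")
        if self.method not in ("gap", "diameter"):
            raise ValueError("method must be 'gap' or 'diameter'")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample_id", "chrom", "pos", "sv_type")


def parse_breakpoint_table(source: str | Path | TextIO) -> list[BreakpointRecord]:
    """Read a tab-delimited breakpoint export (1-based positions).

    Requires columns sample_id, chrom, pos, sv_type; optional mate_chrom and
    mate_pos.  Unknown sv_type values are mapped to ``unknown`` with a
    warning; a non-integer position is an error naming the offending line.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[BreakpointRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            pos = int(row["pos"])
        except (TypeError, ValueError):
            raise TableFormatError(
                f"line {line_no}: non-integer pos {row['pos']!r}"
            ) from None
        sv = str(row["sv_type"]).strip()
        if sv not in SV_TYPES:
            warnings.warn(f"line {line_no}: unknown sv_type {sv!r}, recorded as 'unknown'")
            sv = "unknown"
        mate_chrom = row.get("mate_chrom")
        mate_pos = row.get("mate_pos")
        has_mate = pd.notna(mate_chrom) and pd.notna(mate_pos)
        records.append(
            BreakpointRecord(
                sample_id=str(row["sample_id"]),
                chrom=str(row["chrom"]),
                pos=pos - 1,
                sv_type=sv,
                mate_chrom=str(mate_chrom) if has_mate else None,
                mate_pos=int(mate_pos) - 1 if has_mate else None,
            )
        )
    return records


def parse_bedpe(source: str | Path | TextIO) -> list[BreakpointRecord]:
    """Read BEDPE (0-based half-open): each line yields one record per side."""
    df = pd.read_csv(source, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise TableFormatError("BEDPE needs at least 6 columns")
    records: list[BreakpointRecord] = []
    for idx, row in df.iterrows():
        name = str(row[6]) if df.shape[1] > 6 and pd.notna(row[6]) else f"bedpe_{idx}"
        try:
            p1, p2 = int(row[1]), int(row[4])
        except ValueError:
            raise TableFormatError(f"BEDPE line {idx + 1}: non-integer start") from None
        c1, c2 = str(row[0]), str(row[3])
        sv = "inter_translocation" if c1 != c2 else "unknown"
        records.append(BreakpointRecord(name, c1, p1, sv, c2, p2))
        records.append(BreakpointRecord(name, c2, p2, sv, c1, p1))
    return records


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def expand_mates(records: Iterable[BreakpointRecord]) -> list[BreakpointRecord]:
    """Add a standalone record for each mate side of translocation records,
    so both sides participate in clustering on their own chromosomes."""
    out: list[BreakpointRecord] = []
    for r in records:
        out.append(r)
        if r.mate_chrom is not None and r.mate_pos is not None:
            out.append(
                BreakpointRecord(r.sample_id, r.mate_chrom, r.mate_pos, r.sv_type)
            )
    return out


def cluster_breakpoints(
    records: Sequence[BreakpointRecord],
    params: ClusterParams | None = None,
    include_mates: bool = False,
) -> list[BreakpointCluster]:
    """Group breakpoints into fragile-region clusters.

    Per chromosome, positions are sorted and chained: a new cluster starts
    whenever the distance to the previous breakpoint (``gap`` method) or to
    the cluster's first breakpoint (``diameter`` method) exceeds ``max_gap``.
    Clusters with fewer than ``min_breakpoints`` members are dropped.  The
    result is invariant to input order and partitions the retained records.
    """
    params = params or ClusterParams()
    recs = expand_mates(records) if include_mates else list(records)

    by_chrom: dict[str, list[BreakpointRecord]] = {}
    for r in recs:
        by_chrom.setdefault(r.chrom, []).append(r)

    clusters: list[BreakpointCluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.sample_id))
        current: list[BreakpointRecord] = []
        for r in members:
            if not current:
                current = [r]
                continue
            ref = current[-1].pos if params.method == "gap" else current[0].pos
            if r.pos - ref <= params.max_gap:
                current.append(r)
            else:
                clusters.append(BreakpointCluster(chrom, tuple(current)))
                current = [r]
        if current:
            clusters.append(BreakpointCluster(chrom, tuple(current)))
    return [c for c in clusters if c.n_breakpoints >= params.min_breakpoints]


# ---------------------------------------------------------------------------
# RSS annotation
# ---------------------------------------------------------------------------

class CoverageError(ValueError):
    pass


def annotate_cluster_rss(
    cluster: BreakpointCluster,
    window_sequence: DnaSequence,
    window_start: int,
    consensus: RSSConsensus | None = None,
    scan_params: ScanParams | None = None,
) -> list[tuple[RSSHit, int]]:
    """Scan the genomic window over a cluster and attach, per hit, the
    unsigned distance (nt) from the hit's heptamer to the nearest member
    breakpoint (0 when a breakpoint falls inside the heptamer).

    Hits are sorted by (distance, mismatch_score).
    """
    window_end = window_start + len(window_sequence)
    if window_start > cluster.start or window_end < cluster.end:
        raise CoverageError(
            f"window [{window_start}, {window_end}) does not cover cluster "
            f"[{cluster.start}, {cluster.end})"
        )
    hits = scan_rss(window_sequence, consensus, scan_params)
    annotated: list[tuple[RSSHit, int]] = []
    for hit in hits:
        h0, h1 = hit.heptamer_interval_top()
        g0, g1 = window_start + h0, window_start + h1  # genomic, half-open
        dist = min(
            0 if g0 <= m.pos < g1 else min(abs(m.pos - g0), abs(m.pos - (g1 - 1)))
            for m in cluster.members
        )
        annotated.append((hit, dist))
    annotated.sort(key=lambda t: (t[1], t[0].mismatch_score, t[0].heptamer_start))
    return annotated


def clusters_to_table(clusters: Sequence[BreakpointCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.chrom, c.start, c.end, c.n_breakpoints, c.span) for c in clusters],
        columns=["chrom", "start0", "end0", "n_breakpoints", "span"],
    )
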