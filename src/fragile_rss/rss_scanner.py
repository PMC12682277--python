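"""Cryptic and canonical 12/23-RSS detection, scoring, and nick-site prediction.

A recombination signal sequence (RSS) is a conserved heptamer (consensus
CACAGTG) and nonamer (consensus ACAAAAACC) separated by a poorly conserved
spacer of 12 or 23 nt.  The RAG endonuclease nicks immediately 5' of the
heptamer.  Cryptic RSSs deviate from the consensus at a few positions; this
module enumerates every heptamer/spacer/nonamer arrangement within stated
mismatch budgets, ranks the candidates, and optionally attaches a
position-weight-matrix log-odds score.

Coordinate convention: every hit carries coordinates on the strand it was
found on (for bottom-strand hits, offsets into the reverse complement of the
scanned sequence), so that ``nonamer_start = heptamer_start + 7 + spacer``
always holds.  ``heptamer_interval_top`` maps a hit back onto the top strand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqcore import DnaSequence, hamming, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class RSSConsensus:
    heptamer: str = "CACAGTG"
    nonamer: str = "ACAAAAACC"
    spacer_lengths: frozenset[int] = frozenset({12, 23})

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7 or len(self.nonamer) != 9:
            raise ValueError("heptamer must be 7 nt and nonamer 9 nt")
        if any(s <= 0 for s in self.spacer_lengths):
            raise ValueError("spacer lengths must be positive")
        object.__setattr__(self, "spacer_lengths", frozenset(self.spacer_lengths))

    @property
    def min_footprint(self) -> int:
        return 7 + min(self.spacer_lengths) + 9


@dataclass(frozen=True)
class ScanParams:
    """Mismatch budgets and scan options.

    Defaults (3 heptamer / 4 nonamer mismatches) are the loosest deviations
    described for the glioblastoma fragile-region substrates; ``anchor_cac``
    requires the first three heptamer bases (CAC, essential for RAG
    recognition) to match exactly.
    """

    max_heptamer_mismatch: int = 3
    max_nonamer_mismatch: int = 4
    spacer_tolerance: int = 0
    anchor_cac: bool = True
    strands: str = "both"  # top | bottom | both

    def __post_init__(self) -> None:
        if not 0 <= self.max_heptamer_mismatch <= 7:
            raise ValueError("max_heptamer_mismatch must be in [0, 7]")
        if not 0 <= self.max_nonamer_mismatch <= 9:
            raise ValueError("max_nonamer_mismatch must be in [0, 9]")
        if self.spacer_tolerance < 0:
            raise ValueError("spacer_tolerance must be >= 0")
        if self.strands not in ("top", "bottom", "both"):
            raise ValueError("strands must be top, bottom or both")


@dataclass(frozen=True)
class RSSHit:
    """One candidate RSS arrangement.

    Offsets are 0-based on the hit's own strand; ``mismatch_score`` is the
    weighted mismatch total (lower is better), ``model_score`` a log-odds
    scalar (higher is better) when a model was supplied.
    """

    sequence_id: str
    strand: str  # "+" or "-"
    heptamer_start: int
    spacer_length: int
    nonamer_start: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    heptamer_seq: str
    nonamer_seq: str
    mismatch_score: float
    model_score: float | None = None
    sequence_length: int = 0  # length of the scanned sequence, for mapping

    def __post_init__(self) -> None:
        if self.nonamer_start != self.heptamer_start + 7 + self.spacer_length:
            raise ValueError("nonamer_start must equal heptamer_start + 7 + spacer")

    def heptamer_interval_top(self) -> tuple[int, int]:
        """Half-open top-strand interval occupied by the heptamer."""
        if self.strand == "+":
            return (self.heptamer_start, self.heptamer_start + 7)
        end = self.sequence_length - self.heptamer_start
        return (end - 7, end)


class RSSModel:
    """Per-position base-frequency model for heptamer + nonamer windows.

    ``score = sum log((f + pc) / (bg + pc)) - spacer_penalty * |s - s*|``
    where *f* is the position frequency of the observed base, *bg* the
    background frequency, *pc* a pseudocount and *s** the nearest admissible
    spacer length.  A uniform model equal to background scores 0 everywhere.

    The shipped default (``RSSModel.default()``) concentrates 0.91 on the
    consensus base at the three CAC heptamer positions and the first nonamer
    position, 0.70 elsewhere, with the remainder spread uniformly.  It is a
    package default for ranking, not a published parameterisation; trained
    models can be loaded from JSON.
    """

    def __init__(
        self,
        heptamer_freqs: np.ndarray,
        nonamer_freqs: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 1e-3,
        spacer_penalty: float = 1.0,
        spacer_lengths: frozenset[int] = frozenset({12, 23}),
    ) -> None:
        self.heptamer_freqs = np.asarray(heptamer_freqs, dtype=float)
        self.nonamer_freqs = np.asarray(nonamer_freqs, dtype=float)
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.pseudocount = float(pseudocount)
        self.spacer_penalty = float(spacer_penalty)
        self.spacer_lengths = frozenset(spacer_lengths)
        for name, table, n in (
            ("heptamer", self.heptamer_freqs, 7),
            ("nonamer", self.nonamer_freqs, 9),
        ):
            if table.shape != (n, 4):
                raise ValueError(f"{name} table must be {n}x4")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} frequencies must sum to 1 per position")

    @classmethod
    def default(cls, consensus: RSSConsensus | None = None) -> "RSSModel":
        consensus = consensus or RSSConsensus()

        def table(motif: str, strong: set[int]) -> np.ndarray:
            t = np.empty((len(motif), 4))
            for i, base in enumerate(motif):
                p = 0.91 if i in strong else 0.70
                t[i] = (1.0 - p) / 3.0
                t[i, _BASE_INDEX[base]] = p
            return t

        return cls(
            table(consensus.heptamer, {0, 1, 2}),
            table(consensus.nonamer, {0}),
            spacer_lengths=consensus.spacer_lengths,
        )

    def _positional(self, table: np.ndarray, seq: str) -> float:
        pc, bg = self.pseudocount, self.background
        total = 0.0
        for i, base in enumerate(seq):
            j = _BASE_INDEX.get(base)
            if j is None:  # N: uninformative position
                continue
            total += math.log((table[i, j] + pc) / (bg[j] + pc))
        return total

    def score(self, heptamer_seq: str, nonamer_seq: str, spacer_length: int) -> float:
        dev = min(abs(spacer_length - s) for s in self.spacer_lengths)
        return (
            self._positional(self.heptamer_freqs, heptamer_seq)
            + self._positional(self.nonamer_freqs, nonamer_seq)
            - self.spacer_penalty * dev
        )

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "heptamer_freqs": self.heptamer_freqs.tolist(),
            "nonamer_freqs": self.nonamer_freqs.tolist(),
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "spacer_penalty": self.spacer_penalty,
            "spacer_lengths": sorted(self.spacer_lengths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSSModel":
        return cls(
            np.array(d["heptamer_freqs"]),
            np.array(d["nonamer_freqs"]),
            np.array(d["background"]),
            d["pseudocount"],
            d["spacer_penalty"],
            frozenset(d["spacer_lengths"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RSSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_WEIGHTS = (2.0, 1.0, 1.0)


def mismatch_score(
    heptamer_mismatches: "int | RSSHit",
    nonamer_mismatches: int | None = None,
    spacer_length: int | None = None,
    spacer_lengths: frozenset[int] = frozenset({12, 23}),
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted mismatch total ``w_h*m_h + w_n*m_n + w_s*|s - nearest spacer|``.

    Zero iff a perfect consensus at an admissible spacer.  Heptamer
    mismatches weigh double by default because heptamer integrity dominates
    RAG recognition.  Accepts either an :class:`RSSHit` or the three raw
    counts.
    """
    if isinstance(heptamer_mismatches, RSSHit):
        hit = heptamer_mismatches
        heptamer_mismatches = hit.heptamer_mismatches
        nonamer_mismatches = hit.nonamer_mismatches
        spacer_length = hit.spacer_length
    w_h, w_n, w_s = weights
    if w_h < 0 or w_n < 0 or w_s < 0:
        raise ValueError("weights must be non-negative")
    dev = min(abs(spacer_length - s) for s in spacer_lengths)
    return w_h * heptamer_mismatches + w_n * nonamer_mismatches + w_s * dev


def scan_rss(
    seq: DnaSequence,
    consensus: RSSConsensus | None = None,
    params: ScanParams | None = None,
    model: RSSModel | None = None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> list[RSSHit]:
    """Enumerate every qualifying heptamer/spacer/nonamer arrangement.

    All overlapping hits are reported (a region can present both a 12- and a
    23-type arrangement); output is sorted by (mismatch_score, heptamer_start,
    strand) with top before bottom, fully deterministic.  A sequence shorter
    than the minimal footprint yields an empty list.
    """
    consensus = consensus or RSSConsensus()
    params = params or ScanParams()

    spacers = sorted(
        {
            s + d
            for s in consensus.spacer_lengths
            for d in range(-params.spacer_tolerance, params.spacer_tolerance + 1)
            if s + d > 0
        }
    )

    strands: list[tuple[str, str]] = []
    if params.strands in ("top", "both"):
        strands.append(("+", seq.bases))
    if params.strands in ("bottom", "both"):
        strands.append(("-", revcomp(seq.bases)))

    hits: list[RSSHit] = []
    for strand, s in strands:
        n = len(s)
        for i in range(n - 6):
            hept = s[i : i + 7]
            if params.anchor_cac and hept[:3] != "CAC":
                continue
            m_h = hamming(hept, consensus.heptamer)
            if m_h > params.max_heptamer_mismatch:
                continue
            for sp in spacers:
                j = i + 7 + sp
                if j + 9 > n:
                    continue
                nona = s[j : j + 9]
                m_n = hamming(nona, consensus.nonamer)
                if m_n > params.max_nonamer_mismatch:
                    continue
                hits.append(
                    RSSHit(
                        sequence_id=seq.id,
                        strand=strand,
                        heptamer_start=i,
                        spacer_length=sp,
                        nonamer_start=j,
                        heptamer_mismatches=m_h,
                        nonamer_mismatches=m_n,
                        heptamer_seq=hept,
                        nonamer_seq=nona,
                        mismatch_score=mismatch_score(
                            m_h, m_n, sp, consensus.spacer_lengths, weights
                        ),
                        model_score=(model.score(hept, nona, sp) if model else None),
                        sequence_length=n,
                    )
                )
    hits.sort(key=lambda h: (h.mismatch_score, h.heptamer_start, h.strand != "+"))
    return hits


def model_score(hit: RSSHit, model: RSSModel) -> float:
    """Log-odds score of a hit's heptamer + nonamer windows under ``model``."""
    return model.score(hit.heptamer_seq, hit.nonamer_seq, hit.spacer_length)


def nick_site(hit: RSSHit) -> int:
    """0-based cut coordinate on the hit's strand: RAG nicks 5' of the
    heptamer, so the cut falls at ``heptamer_start`` and the 5'-labelled
    fragment of a top-strand hit is exactly that many nucleotides long."""
    return hit.heptamer_start


HIT_TSV_COLUMNS = [
    "seq_id",
    "strand",
    "hept_start0",
    "hept_seq",
    "hept_mm",
    "spacer_len",
    "nona_start0",
    "nona_seq",
    "nona_mm",
    "mismatch_score",
    "model_score",
    "nick_site0",
]


def hits_to_table(hits: list[RSSHit]):
    """Hit list as a pandas DataFrame with the standard column set."""
    import pandas as pd

    rows = [
        (
            h.sequence_id,
            h.strand,
            h.heptamer_start,
            h.heptamer_seq,
            h.heptamer_mismatches,
            h.spacer_length,
            h.nonamer_start,
            h.nonamer_seq,
            h.nonamer_mismatches,
            h.mismatch_score,
            h.model_score if h.model_score is not None else float("nan"),
            nick_site(h),
        )
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_TSV_COLUMNS)
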