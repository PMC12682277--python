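"""Map recombinant junction sequences onto their two parental sequences.

A junction read is assumed anchored: its first base aligns to position 0 of
the left parent and its last base to the end of the right parent (primer
trimming is the caller's job).  The call reports

* ``p`` — longest common prefix with the left parent,
* ``q`` — longest common suffix with the right parent,
* microhomology ``mu = max(0, p + q - len(junction))`` — bases shared by both
  parents at the transition, leaving the true breakpoint ambiguous within an
  interval of that length (the hallmark of microhomology-mediated end
  joining),
* inserted bases when ``p + q < len(junction)``.

Exactly one of microhomology and insertion can be positive; a blunt join has
both zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .rss_scanner import RSSHit
from .seqcore import DnaSequence


class NoAnchorError(ValueError):
    """Junction shares no prefix with the left parent nor suffix with the right."""


class ReferenceError_(ValueError):
    """An RSS hit does not lie on the parent it is being compared against."""


@dataclass(frozen=True)
class JunctionCall:
    junction_id: str
    left_parent_id: str
    right_parent_id: str
    left_match_len: int      # p
    right_match_len: int     # q
    microhomology_len: int   # mu
    inserted_bases: str
    breakpoint_interval_left: tuple[int, int]   # half-open on left parent
    breakpoint_interval_right: tuple[int, int]  # half-open on right parent

    def __post_init__(self) -> None:
        if self.microhomology_len > 0 and self.inserted_bases:
            raise ValueError("microhomology and insertion cannot both be positive")
        for iv in (self.breakpoint_interval_left, self.breakpoint_interval_right):
            if iv[1] - iv[0] != self.microhomology_len:
                raise ValueError("breakpoint interval length must equal microhomology")

    @property
    def kind(self) -> str:
        if self.microhomology_len > 0:
            return "microhomology"
        return "insertion" if self.inserted_bases else "blunt"

    @property
    def left_breakpoint(self) -> int:
        """Canonical (leftmost) point breakpoint on the left parent."""
        return self.breakpoint_interval_left[0]


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def map_junction(
    junction: DnaSequence,
    left_parent: DnaSequence,
    right_parent: DnaSequence,
) -> JunctionCall:
    """Decompose an anchored junction into (p, q, microhomology, insert).

    Deterministic exact matching; raises :class:`NoAnchorError` when the
    junction matches neither parent at its anchored ends.  Inverted-
    orientation rearrangements are handled by the caller supplying
    reverse-complemented parents.
    """
    j, l, r = junction.bases, left_parent.bases, right_parent.bases
    p = _lcp(j, l)
    q = _lcs(j, r)
    if p == 0 and q == 0:
        raise NoAnchorError(
            f"junction {junction.id!r} shares no sequence with its parents"
        )
    mu = max(0, p + q - len(j))
    insert = j[p : len(j) - q] if len(j) - p - q > 0 else ""
    right_start = len(r) - q
    return JunctionCall(
        junction_id=junction.id,
        left_parent_id=left_parent.id,
        right_parent_id=right_parent.id,
        left_match_len=p,
        right_match_len=q,
        microhomology_len=mu,
        inserted_bases=insert,
        breakpoint_interval_left=(p - mu, p),
        breakpoint_interval_right=(right_start, right_start + mu),
    )


def breakpoint_offset_from_heptamer(call: JunctionCall, hit: RSSHit) -> int:
    """Signed distance (nt) from a heptamer to the junction's transition on
    the parent carrying the hit.

    0 means the junction transitions exactly at the heptamer's 5' edge;
    negative means 5' of the heptamer — where breakpoints cluster when RAG
    nicking initiated the break.  Uses the canonical leftmost transition
    point of the (possibly ambiguous) breakpoint interval.
    """
    if hit.sequence_id == call.left_parent_id:
        bp = call.breakpoint_interval_left[0]
    elif hit.sequence_id == call.right_parent_id:
        bp = call.breakpoint_interval_right[0]
    else:
        raise ReferenceError_(
            f"hit on {hit.sequence_id!r} matches neither parent of {call.junction_id!r}"
        )
    return bp - hit.heptamer_start


def junction_histogram(offsets: Iterable[int]) -> dict[int, int]:
    """Exact-integer histogram of breakpoint offsets; counts sum to the
    number of inputs."""
    return dict(sorted(Counter(offsets).items()))


def calls_to_table(calls: Sequence[JunctionCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            (
                c.junction_id,
                c.left_match_len,
                c.right_match_len,
                c.microhomology_len,
                c.inserted_bases,
                c.breakpoint_interval_left[0],
                c.breakpoint_interval_right[0],
                c.kind,
            )
            for c in calls
        ],
        columns=["junction_id", "p", "q", "mu", "insert_seq", "left_bp0", "right_bp0", "kind"],
    )
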