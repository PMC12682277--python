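"""Sequence primitives: validated DNA sequences, duplex substrates, FASTA I/O.

Coordinates are 0-based, half-open throughout the package.  Reports that
need the bench convention ("N nt away from the 5' end" = number of bases
preceding a feature) can use the 0-based start directly, since both count
the bases 5' of the feature.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class LengthError(ValueError):
    """Raised when an operation requires equal-length sequences."""


@dataclass(frozen=True)
class DnaSequence:
    """An uppercase DNA sequence over {A,C,G,T,N} with a text id.

    Lowercase input is uppercased; IUPAC ambiguity codes other than N are
    rejected because every substrate handled here is unambiguous.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(bases) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, key) -> str:
        return self.bases[key]

    def revcomp(self, id: str | None = None) -> "DnaSequence":
        return DnaSequence(id or f"{self.id}_rc", self.bases.translate(_COMPLEMENT)[::-1])


def revcomp(seq: DnaSequence | str) -> DnaSequence | str:
    """Reverse complement (A<->T, C<->G, N<->N); an involution."""
    if isinstance(seq, DnaSequence):
        return seq.revcomp()
    return DnaSequence("x", seq).bases.translate(_COMPLEMENT)[::-1]


def hamming(a: DnaSequence | str, b: DnaSequence | str) -> int:
    """Number of mismatched positions between two equal-length sequences."""
    sa = a.bases if isinstance(a, DnaSequence) else a.upper()
    sb = b.bases if isinstance(b, DnaSequence) else b.upper()
    if len(sa) != len(sb):
        raise LengthError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


@dataclass(frozen=True)
class DuplexSubstrate:
    """Two annealed strands with (possibly zero) single-stranded overhangs.

    After trimming the stated 5' and 3' overhangs from each strand, the
    bottom strand must be the exact reverse complement of the top strand.
    Overhangs at the 3' ends occur in practice (poly-T tailed substrates),
    so both ends are modelled.
    """

    top: DnaSequence
    bottom: DnaSequence
    five_prime_overhang_top: int = 0
    five_prime_overhang_bottom: int = 0
    three_prime_overhang_top: int = 0
    three_prime_overhang_bottom: int = 0

    def __post_init__(self) -> None:
        t = self._trim(self.top.bases, self.five_prime_overhang_top, self.three_prime_overhang_top)
        b = self._trim(
            self.bottom.bases, self.five_prime_overhang_bottom, self.three_prime_overhang_bottom
        )
        if b != revcomp(t):
            raise ValueError(
                f"duplex {self.top.id}/{self.bottom.id}: trimmed strands are not "
                "reverse complements"
            )

    @staticmethod
    def _trim(s: str, five: int, three: int) -> str:
        return s[five : len(s) - three] if three else s[five:]

    @property
    def paired_region(self) -> str:
        """Double-stranded core in top-strand orientation."""
        return self._trim(
            self.top.bases, self.five_prime_overhang_top, self.three_prime_overhang_top
        )


def find_overhangs(top: DnaSequence, bottom: DnaSequence) -> tuple[int, int, int, int]:
    """Minimal-total trims (top5', top3', bottom5', bottom3') that make the
    strands exact reverse complements.

    Raises ValueError if no trimming yields a complementary core.
    """
    t, b = top.bases, bottom.bases
    best: tuple[int, int, int, int, int] | None = None
    for t5 in range(len(t)):
        for t3 in range(len(t) - t5):
            core = t[t5 : len(t) - t3] if t3 else t[t5:]
            m = len(core)
            rc_core = revcomp(core)
            for b5 in range(len(b) - m + 1):
                b3 = len(b) - m - b5
                if b[b5 : b5 + m] == rc_core:
                    cand = (t5 + t3 + b5 + b3, t5, t3, b5, b3)
                    if best is None or cand < best:
                        best = cand
        if best is not None and best[0] == 0:
            break
    if best is None:
        raise ValueError(f"{top.id}/{bottom.id}: no annealing register found")
    return best[1:]


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[DnaSequence]:
    return [DnaSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Oligonucleotide fixtures (bench substrates, transcribed from the published
# reagent table; hyphens in the printed sequences are line breaks, removed)
# ---------------------------------------------------------------------------

#: top-strand / bottom-strand oligo names and the locus each duplex derives from
OLIGO_PAIRS: dict[str, tuple[str, str]] = {
    "AKN1/AKN2": ("AKN1", "AKN2"),        # canonical 12RSS control
    "AP92/AP93": ("AP92", "AP93"),        # CAMK2D fragile region
    "AP94/AP95": ("AP94", "AP95"),        # RNF38-MELK fragile region
    "AP96/AP97": ("AP96", "AP97"),        # AMY1B fragile region
    "AP98/AP99": ("AP98", "AP99"),        # DIPK1A fragile region
    "AP100/AP101": ("AP100", "AP101"),    # RN7SKP123-MTF2 fragile region
    "DG13/DG14": ("DG13", "DG14"),        # RSS-free control
    "DG27/DG28": ("DG27", "DG28"),        # RSS-free control
    "MS20/MS21": ("MS20", "MS21"),        # heptamer/nonamer-free pulldown control
}


def _fixture_fasta_path() -> Path:
    return Path(resources.files("fragile_rss").joinpath("fixtures/oligos.fasta"))


@functools.cache
def load_fixture_sequences() -> dict[str, DnaSequence]:
    """All shipped oligos keyed by name (AKN1, AP92, ...)."""
    return {s.id: s for s in read_fasta(_fixture_fasta_path())}


def load_fixture_oligos() -> dict[str, DuplexSubstrate]:
    """Annealed duplex substrates keyed by pair name, e.g. ``"AKN1/AKN2"``.

    Overhang lengths are computed (minimal trims giving exact reverse
    complementarity), never hard-coded, so the duplex invariant is verified
    for every shipped pair at load time.
    """
    seqs = load_fixture_sequences()
    out: dict[str, DuplexSubstrate] = {}
    for pair, (top_name, bot_name) in OLIGO_PAIRS.items():
        top, bottom = seqs[top_name], seqs[bot_name]
        t5, t3, b5, b3 = find_overhangs(top, bottom)
        out[pair] = DuplexSubstrate(top, bottom, t5, b5, t3, b3)
    return out
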