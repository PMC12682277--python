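"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the implementation modules' internals: reverse
complementation goes through Biopython and every search is an exhaustive
enumeration over all windows / transition points.
"""

from Bio.Seq import Seq

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"


def bio_revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_scan(
    seq: str,
    spacers=(12, 23),
    max_hept_mm: int = 3,
    max_nona_mm: int = 4,
    anchor_cac: bool = True,
    strands: str = "both",
):
    """Triple loop over (strand, heptamer position, spacer).  Returns the set
    of (strand, heptamer_start, spacer, m_h, m_n) tuples, coordinates on the
    scanned strand."""
    todo = []
    if strands in ("top", "both"):
        todo.append(("+", seq))
    if strands in ("bottom", "both"):
        todo.append(("-", bio_revcomp(seq)))
    found = set()
    for strand, s in todo:
        for i in range(len(s)):
            for spacer in spacers:
                j = i + 7 + spacer
                if j + 9 > len(s):
                    continue
                hept, nona = s[i : i + 7], s[j : j + 9]
                if anchor_cac and not hept.startswith("CAC"):
                    continue
                m_h = mismatches(hept, HEPTAMER)
                m_n = mismatches(nona, NONAMER)
                if m_h <= max_hept_mm and m_n <= max_nona_mm:
                    found.add((strand, i, spacer, m_h, m_n))
    return found


def exhaustive_junction_decomposition(junction: str, left: str, right: str):
    """Enumerate every transition point to recover (p, q, mu, insert).

    A blunt transition at t requires junction[:t] to be a prefix of the left
    parent and junction[t:] a suffix of the right parent; the spread of valid
    t values is the microhomology.  If no blunt transition exists, the
    maximal prefix/suffix matches delimit the inserted bases.
    """
    n = len(junction)
    prefix_ok = [junction[:t] == left[:t] for t in range(n + 1)]
    suffix_ok = [
        len(right) >= n - t and (n == t or junction[t:] == right[len(right) - (n - t):])
        for t in range(n + 1)
    ]
    p = max(t for t in range(n + 1) if prefix_ok[t])
    q = max(n - t for t in range(n + 1) if suffix_ok[t])
    blunt = [t for t in range(n + 1) if prefix_ok[t] and suffix_ok[t]]
    if blunt:
        return p, q, max(blunt) - min(blunt), ""
    return p, q, 0, junction[p : n - q]
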