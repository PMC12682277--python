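"""Seeded generators for every input the pipeline consumes, with planted
ground truth, standing in for database exports that cannot be redistributed.

Every generator is a pure function of its parameters and an explicit integer
seed (numpy ``default_rng``; no global state): rerunning with the same seed
is byte-identical.  Ground truth is returned as a :class:`PlantedTruth` that
serialises to JSON next to the generated files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .breakpoint_cluster import BreakpointRecord
from .seqcore import DnaSequence

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedTruth:
    kind: str
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"kind": self.kind, "seed": self.seed, "params": self.params}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["kind"], d["seed"], d["params"])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _mutate(rng: np.random.Generator, motif: str, n_mut: int, allowed: list[int]) -> str:
    """Substitute exactly ``n_mut`` positions (chosen from ``allowed``) with
    a different random base."""
    if n_mut > len(allowed):
        raise ValueError(f"cannot place {n_mut} mismatches in {len(allowed)} positions")
    out = list(motif)
    for i in rng.choice(allowed, size=n_mut, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != motif[i]])
    return "".join(out)


def gen_rss_sequence(
    length: int,
    heptamer_offset: int,
    m_h: int,
    spacer: int,
    m_n: int,
    background_gc: float = 0.5,
    seed: int = 0,
    anchor_cac: bool = True,
    heptamer: str = "CACAGTG",
    nonamer: str = "ACAAAAACC",
    seq_id: str | None = None,
) -> tuple[DnaSequence, PlantedTruth]:
    """Random background with a planted heptamer/spacer/nonamer arrangement.

    Mismatches are placed uniformly at random; the CAC anchor positions of
    the heptamer are preserved when ``anchor_cac`` is set.  Mirrors the bench
    substrate design, where the cryptic heptamer sat ~20 nt from the 5' end.
    """
    footprint = 7 + spacer + 9
    if heptamer_offset < 0 or heptamer_offset + footprint > length:
        raise ValueError("planted RSS footprint does not fit in the sequence")
    rng = np.random.default_rng(seed)
    bases = _random_bases(rng, length, background_gc)
    hept_positions = list(range(3, 7)) if anchor_cac else list(range(7))
    hept = _mutate(rng, heptamer, m_h, hept_positions)
    nona = _mutate(rng, nonamer, m_n, list(range(9)))
    bases[heptamer_offset : heptamer_offset + 7] = list(hept)
    nona_start = heptamer_offset + 7 + spacer
    bases[nona_start : nona_start + 9] = list(nona)
    seq = DnaSequence(seq_id or f"rss_sim_seed{seed}", "".join(bases))
    truth = PlantedTruth(
        "rss_sequence",
        seed,
        {
            "heptamer_offset": heptamer_offset,
            "spacer": spacer,
            "nonamer_offset": nona_start,
            "m_h": m_h,
            "m_n": m_n,
            "heptamer_seq": hept,
            "nonamer_seq": nona,
            "length": length,
            "background_gc": background_gc,
            "anchor_cac": anchor_cac,
        },
    )
    return seq, truth


def gen_breakpoint_records(
    n_clusters: int,
    breakpoints_per_cluster: int,
    cluster_span: int = 60,
    intercluster_gap: int = 10_000,
    chrom: str = "chr1",
    seed: int = 0,
    start: int = 1_000_000,
) -> tuple[list[BreakpointRecord], PlantedTruth]:
    """Clustered breakpoints mimicking a database structural-variant export.

    Each cluster occupies at most ``cluster_span`` nt (its extremes pinned to
    the span so the geometry is exact); clusters are separated by more than
    ``intercluster_gap``.  When ``cluster_span <= 100`` and the gap exceeds
    100, clustering at max_gap=100 provably recovers the planted memberships.
    """
    if intercluster_gap <= cluster_span or intercluster_gap <= 100:
        raise ValueError("intercluster_gap must exceed cluster_span and 100")
    if breakpoints_per_cluster < 1:
        raise ValueError("need at least one breakpoint per cluster")
    rng = np.random.default_rng(seed)
    sv_types = ["deletion", "inversion", "inter_translocation", "intra_translocation"]
    records: list[BreakpointRecord] = []
    memberships: list[list[int]] = []
    origin = start
    for c in range(n_clusters):
        if breakpoints_per_cluster == 1 or cluster_span == 0:
            offsets = np.zeros(breakpoints_per_cluster, dtype=int)
        else:
            inner = rng.integers(0, cluster_span + 1, size=breakpoints_per_cluster - 2)
            offsets = np.sort(np.concatenate([[0, cluster_span], inner]))
        positions = origin + offsets
        memberships.append([int(p) for p in positions])
        for k, pos in enumerate(positions):
            records.append(
                BreakpointRecord(
                    sample_id=f"S{c}_{k}",
                    chrom=chrom,
                    pos=int(pos),
                    sv_type=str(rng.choice(sv_types)),
                )
            )
        origin = int(positions.max()) + intercluster_gap + int(rng.integers(0, 1000))
    truth = PlantedTruth(
        "breakpoints",
        seed,
        {
            "chrom": chrom,
            "n_clusters": n_clusters,
            "breakpoints_per_cluster": breakpoints_per_cluster,
            "cluster_span": cluster_span,
            "cluster_positions": memberships,
        },
    )
    return records, truth


def gen_junction_reads(
    left_parent: DnaSequence,
    right_parent: DnaSequence,
    cut_left: int,
    cut_right: int,
    microhomology: int = 0,
    insert: str = "",
    n: int = 1,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[DnaSequence], PlantedTruth]:
    """Recombinant junction reads joining ``left_parent[:cut_left]`` to
    ``right_parent[cut_right:]`` with optional inserted bases.

    ``microhomology`` asserts the intended ambiguity: the generator verifies
    that the exact-matching decomposition of the error-free junction equals
    the requested (mu, insert) — i.e. the requested cut sites really do sit
    inside a shared ``mu``-mer and no accidental homology extends it —
    raising ``ValueError`` otherwise.  With ``error_rate`` > 0, each base is
    substituted independently with that probability.
    """
    if microhomology > 0 and insert:
        raise ValueError("microhomology and insert cannot both be positive")
    if not (0 <= cut_left <= len(left_parent)) or not (0 <= cut_right <= len(right_parent)):
        raise ValueError("cut sites must lie within the parents")
    l, r = left_parent.bases, right_parent.bases
    junction = l[:cut_left] + insert + r[cut_right:]

    # verify plantedness against the exact decomposition
    n_j = len(junction)
    p = 0
    while p < min(n_j, len(l)) and junction[p] == l[p]:
        p += 1
    q = 0
    while q < min(n_j, len(r)) and junction[n_j - 1 - q] == r[len(r) - 1 - q]:
        q += 1
    mu_real = max(0, p + q - n_j)
    ins_real = junction[p : n_j - q] if n_j - p - q > 0 else ""
    if mu_real != microhomology or ins_real != insert:
        raise ValueError(
            f"construction is not uniquely decodable: realised (mu={mu_real}, "
            f"insert={ins_real!r}) != requested (mu={microhomology}, insert={insert!r})"
        )

    rng = np.random.default_rng(seed)
    reads: list[DnaSequence] = []
    for i in range(n):
        bases = list(junction)
        if error_rate > 0:
            hits = rng.random(len(bases)) < error_rate
            for k in np.flatnonzero(hits):
                bases[k] = rng.choice([b for b in "ACGT" if b != bases[k]])
        reads.append(DnaSequence(f"junction_{i}", "".join(bases)))
    truth = PlantedTruth(
        "junctions",
        seed,
        {
            "left_parent": left_parent.id,
            "right_parent": right_parent.id,
            "cut_left": cut_left,
            "cut_right": cut_right,
            "p": p,
            "q": q,
            "microhomology": microhomology,
            "insert": insert,
            "n": n,
            "error_rate": error_rate,
        },
    )
    return reads, truth


def gen_colony_counts(
    a: int,
    p: float,
    n_replicates: int,
    seed: int = 0,
    condition: str = "sim",
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Binomial colony counts: CA ~ Binomial(A, p) per replicate.

    ``p`` on the order of 1e-5 to 1e-4 matches the episomal-assay scale
    (frequencies of 0.0002%–0.0128%).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if a <= 0:
        raise ValueError("A must be positive")
    rng = np.random.default_rng(seed)
    ca = rng.binomial(a, p, size=n_replicates)
    df = pd.DataFrame(
        {
            "condition": condition,
            "replicate": np.arange(1, n_replicates + 1),
            "CA": ca,
            "A": a,
        }
    )
    truth = PlantedTruth("colony_counts", seed, {"A": a, "p": p, "n_replicates": n_replicates})
    return df, truth


def gen_expression_matrix(
    n_samples: int,
    class_proportions: tuple[float, float, float] = (0.25, 0.5, 0.25),
    separation: float = 3.0,
    seed: int = 0,
    genes: tuple[str, str] = ("RAG1", "RAG2"),
    base_log2: float = 1.0,
    sd_log2: float = 0.25,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Cohort FPKM matrix for two genes from a three-component mixture.

    Per gene, latent classes (L/M/H) are assigned with *exact* counts
    (largest-remainder rounding of the proportions, order shuffled) so that
    with default quartile proportions the empirical 25th/75th percentiles
    fall between the class components and stratification provably recovers
    the planted classes when ``separation`` is well above ``sd_log2``.
    Values are drawn on the log2 scale from normals ``separation`` apart per
    class; FPKM = 2**x - 1 so the standard log2(x+1) transform returns the
    latent scale.
    """
    props = np.asarray(class_proportions, float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if separation == 0:
        import warnings

        warnings.warn("separation 0: planted classes are unrecoverable")
    rng = np.random.default_rng(seed)
    sample_ids = [f"P{i:04d}" for i in range(n_samples)]

    # exact class counts by largest remainder
    raw = props * n_samples
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_samples - counts.sum()]:
        counts[i] += 1

    data = {}
    classes = {}
    for gene in genes:
        lab = rng.permutation(np.repeat(np.array(["L", "M", "H"]), counts))
        mu = base_log2 + np.select(
            [lab == "L", lab == "M", lab == "H"], [0.0, separation, 2 * separation]
        )
        x = rng.normal(mu, sd_log2)
        data[gene] = np.maximum(2.0**x - 1.0, 0.0)
        classes[gene] = lab.tolist()
    matrix = pd.DataFrame(data, index=sample_ids).T
    truth = PlantedTruth(
        "expression",
        seed,
        {
            "n_samples": n_samples,
            "class_proportions": props.tolist(),
            "separation": separation,
            "classes": classes,
            "genes": list(genes),
        },
    )
    return matrix, truth
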