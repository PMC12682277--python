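# Methods

## Scope and model

The package formalises an in-silico pipeline linking cancer structural-variant
breakpoints to cryptic V(D)J recombination signals:

1. cluster patient breakpoints into fragile regions,
2. scan those regions (and bench substrates) for cryptic 12/23-RSSs,
3. predict where RAG would nick,
4. decompose sequenced recombinant junctions into breakpoint, microhomology
   and insertions,
5. quantify recombination frequencies from the episomal colony assay, and
6. stratify an expression cohort by RAG1/RAG2 levels.

All coordinates are 0-based, half-open. Where bench work counts "N nt away
from the 5′ end", that number equals the 0-based start offset (both count
the bases preceding the feature), so no separate convention is needed in
reports. One published description places a cryptic heptamer "21 nt" from
the 5′ end of its substrate where the printed oligo puts the best
CAC-anchored heptamer after 20 bases; the package reports the computed
0-based offset (20) and treats the one-off counting as a convention
difference, not a data conflict.

## RSS scanning

The scanner enumerates every (strand, heptamer position, spacer) triple and
keeps those whose heptamer is within `max_heptamer_mismatch` (default 3) of
`CACAGTG`, whose nonamer is within `max_nonamer_mismatch` (default 4) of
`ACAAAAACC`, and whose spacer is within `spacer_tolerance` (default 0) of an
admissible length (default {12, 23}). The defaults are the loosest
deviations described for the five glioblastoma fragile-region substrates;
they are parameters, not truths — stated per-region mismatch counts are
never hard-coded, because they depend on where the original analysis
anchored its windows. `anchor_cac` (default on) demands an exact CAC at
heptamer positions 1–3, reflecting the near-absolute requirement of that
trinucleotide for RAG recognition; unanchored scanning is available for
sensitivity analyses. All overlapping hits are reported — the AMY1B-derived
substrate genuinely presents both a 12- and a 23-spacer arrangement on the
same heptamer — and ranking is left to scores.

Bottom-strand hits carry coordinates on the reverse complement (so the
invariant `nonamer_start = heptamer_start + 7 + spacer` always holds) and
map back to top-strand intervals via `heptamer_interval_top()`. Output
order is deterministic: (mismatch score, heptamer start, strand).

Two scores are attached. The *mismatch score*
`w_h·m_h + w_n·m_n + w_s·|s − s*|` (default weights 2, 1, 1 — heptamer
integrity dominates RAG recognition, so its mismatches weigh double) is a
transparent ranking heuristic, zero only for a perfect consensus at an
admissible spacer. The *model score* is a standard log-odds sum
`Σ log((f + pc)/(bg + pc))` over heptamer and nonamer positions minus a
per-nt spacer-deviation penalty. The shipped default model (0.91 on the
consensus base at the CAC positions and the first nonamer base, 0.70
elsewhere, uniform background, pseudocount 1e-3, spacer penalty 1/nt) is a
package default chosen to make the consensus the unique maximum and to
penalise CAC-adjacent substitutions hardest; it is **not** a published,
trained parameterisation, and externally trained models (e.g. recombination
information content matrices) can be supplied as JSON in its place.
Published RIC values are therefore not reproduced here; only orderings that
follow from consistency (canonical above cryptic) are asserted.

The nick site is `heptamer_start`: RAG nicks immediately 5′ of the
heptamer, so a top-strand 5′-labelled fragment has exactly that length.

## Breakpoint clustering

The published selection rule — "distance between 2 breakpoints ≤ 100 bp" —
is read as the adjacent-pair gap, implemented as single-linkage chaining on
sorted per-chromosome positions; a `diameter` mode bounding the maximum
pairwise distance is provided because the two readings diverge for regions
wider than the gap (for the five published intervals, all spanning ≤ 59 nt,
they coincide). Clusters need `min_breakpoints` (default 2) members; the
publication does not state its qualifying count, so 2 (the minimum that
makes "cluster" meaningful) is the package's choice. Inter-chromosomal
records contribute one breakpoint per side, clustered independently.
Database-style TSV input is 1-based inclusive; BEDPE is 0-based half-open;
both normalise to the internal convention.

Cluster annotation scans the covering genomic window and reports, per hit,
the unsigned distance from the heptamer to the nearest member breakpoint
(0 if a breakpoint falls inside the heptamer), sorted by distance then
mismatch score.

## Junction mapping

Junctions are anchored (first base at left-parent position 0, last base at
the right parent's end). With `p` the longest common prefix against the
left parent and `q` the longest common suffix against the right,
`μ = max(0, p + q − |J|)` is the microhomology — the overlap makes the true
transition ambiguous within intervals of length μ on both parents (the
signature of microhomology-mediated end joining) — and when `p + q < |J|`
the middle bases are an untemplated insertion. The two are mutually
exclusive by construction. For histograms a canonical leftmost transition
point is used, a documented convention. Matching is exact and
deterministic; tolerant matching of isolated substitutions inside the
matched regions was considered and deliberately left out of the default
path to keep the decomposition unique. Orientation is the caller's job
(supply reverse-complemented parents for inverted rearrangements).

## Recombination statistics

The assay readout is `f = CA/A × 100` percent, where CA counts
double-resistant (recombined) colonies and A total recovered colonies.
Because CA is tiny (0–5 in several experiments), intervals are exact
binomial Clopper–Pearson at 95% (via the beta quantile), valid at zero
counts where Wald intervals collapse. Fold changes are plain ratios; a
zero-denominator comparison (a condition with no recombinants) is reported
as infinite with a warning rather than an error. Replicate comparisons use
the classic pooled-variance Student's *t* (matching the stated analysis;
Welch via flag) with stars at p < 0.05 / 0.005 / 0.0001 and the convention
p = 1 for identical constant groups. Frequencies are carried in percent
end-to-end.

## Expression stratification

Values are transformed log2(x+1); per-gene 25th/75th percentiles (numpy's
linear interpolation between order statistics, the "type 7" convention —
the source analysis does not state one) define Low (< q25), High (> q75)
and Medium (boundaries inclusive, per the strict inequalities in the
published definition). Labels combine to nine groups `R1{L,M,H}/R2{L,M,H}`.
Because classification depends only on ranks, any strictly increasing
rescaling (including an RPKM↔FPKM change of units) yields identical labels;
this is property-tested.

## Synthetic data

Generators emulate the statistical structure each stage assumes, not the
biology of a genome:

- `gen_rss_sequence` — i.i.d. background at a stated GC content with a
  planted heptamer/nonamer carrying exactly the requested mismatch counts
  (CAC preserved when anchored). Real genomic background has dinucleotide
  structure that inflates motif false positives; an i.i.d. background is
  the documented default, so passing planted-recovery tests demonstrates
  correctness of the search, not genomic specificity.
- `gen_breakpoint_records` — clusters whose extreme positions are pinned to
  the requested span (≤ 60 nt by default, the scale of the published
  regions) and separated by > max(100, span), which makes planted
  membership recovery a construction guarantee rather than a statistical
  event.
- `gen_junction_reads` — joins `L[:cut_left]` to `R[cut_right:]` (plus
  optional insert) and *verifies decodability*: if accidental homology at
  the cut sites would change the exact decomposition away from the
  requested (μ, insert), the construction is rejected. Sequencing noise is
  i.i.d. substitution only.
- `gen_colony_counts` — CA ~ Binomial(A, p); defaults A = 10⁶,
  p = 3.2×10⁻⁵ match the published assay scale (0.0032%).
- `gen_expression_matrix` — per gene, latent L/M/H classes at exact
  largest-remainder counts of the requested proportions (default quartile
  shape 0.25/0.5/0.25), then log2-scale normals `separation` apart
  (default 3, sd 0.25); FPKM = 2^x − 1 keeps values non-negative and makes
  the standard transform recover the latent scale. Exact counts are what
  make quartile thresholds fall between components, so planted classes are
  provably recoverable at large separation; real cohorts have continuous,
  overlapping expression, which is why the published "~350 medium / ~180
  high" patient counts are not regression targets.

All generators take explicit integer seeds (numpy `default_rng`, no global
state) and return serialisable `PlantedTruth` records; reruns are
byte-identical.

## Oligonucleotide fixtures

The bench substrates are transcribed from the published reagent table
(hyphens, which are print line breaks, removed). Duplex overhangs are
computed as the minimal end-trims making the strands exact reverse
complements, never hard-coded. Two findings from that computation: the
canonical-control pair anneals with 1-nt 5′ overhangs on both strands (the
printed strands are 50-mers offset by one), and the poly(T)-tailed pulldown
control needs 3′ as well as 5′ overhang trimming, which is why the duplex
type models both ends.

## Numerical and testing choices

Problem sizes in the test and acceptance suites — 100 random 200-nt
sequences for scanner/oracle equality, 300 random junctions ≤ 30 nt against
exhaustive transition-point enumeration, 1,000 binomial replicates at
A = 10⁶ for estimator calibration, cohorts of 100–400 samples — are chosen
so each suite completes in seconds while leaving the statistical assertions
well-powered (the calibration bound is 3 standard errors of the mean at
n = 1,000). Oracles used in tests (brute-force triple-loop scan, exhaustive
junction enumeration, Biopython reverse complement) are independent
implementations, not calls into the package.

## Known limitations

- No modelling of hairpin formation, 12/23 synapsis pairing, or non-B DNA
  structures; the scanner treats each arrangement independently.
- The default RSS model is a ranking default, not trained; absolute model
  scores are not comparable to published information-content values.
- Junction mapping assumes anchored, primer-trimmed reads and exact
  matching; heavily mutated recombinants need preprocessing.
- Genome-scale scanning is linear-time per window but pure Python; it is
  intended for fragile-region windows, not whole chromosomes.
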