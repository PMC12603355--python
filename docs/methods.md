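# Methods

## Scope and model

`refkit` prepares amplicon reference databases for taxonomic classification
and benchmarks classifier accuracy in silico. The processing model is the
one used by modern 16S workflows: a reference database is a set of
full-length sequences joined to lineages over a fixed, ordered rank schema
(domain → species by default); before training a classifier the taxonomy is
curated, the primer-targeted subregion is extracted from each sequence, and
sequences that become identical within that region are collapsed into one
record carrying a *merged taxonomy*, because the target region simply cannot
tell the member taxa apart.

## Taxonomy curation

Three source-database anomalies are handled, in a fixed order:

1. **Convergence detection.** A label at any rank below the first conflicts
   when its set of ancestor-label tuples (all shallower ranks) has size ≥ 2.
   This generalizes the motivating case (a species epithet under two genera)
   to every rank: the failure mode is any child with two parents, which a
   single-parent classifier training tree cannot represent. Convergence is a
   *source* defect, so the pipeline reports it and aborts by default;
   opt-in auto-resolution renames offenders by suffixing the nearest
   ancestor label.
2. **Duplicate-name resolution.** A label repeated at two ranks of one
   lineage (family and genus both `Clostridium`) makes rank-labelled output
   ambiguous. The deeper occurrence is rewritten to `<label>_<rank initial>`
   (`Clostridium_g`), or treated as fatal under the `error` policy. Records
   are never deleted: deleting would silently shrink the database.
   Only labels read from the source are eligible.
3. **Rank propagation.** Every empty rank is filled with its nearest
   non-empty shallower label, verbatim, with per-rank provenance set to
   `propagated`. Propagation runs after duplicate resolution and its
   artifacts are exempt from it — a propagated genus that now equals its
   family label is expected, not an anomaly. The operation is idempotent and
   requires a non-empty first rank.

Provenance flags (`source` / `propagated` / `merged`) travel with every
label in memory; they are not persisted in the on-disk taxonomy table,
which stays plain two-column QIIME dialect.

## In-silico PCR

Primer matching uses IUPAC *compatible-set* semantics: a position counts as
a mismatch only when the base sets of the primer letter and the template
letter are disjoint, so degeneracy on either side (including N) never
inflates the count. The mismatch model is a per-primer maximum substitution
count (default 2) with no indels; indel-tolerant alignment was deliberately
excluded to keep the search exact and verifiable against a brute-force
enumeration of all substring pairs.

A product requires a forward-primer site and a reverse-complemented
reverse-primer site on the same strand, non-overlapping, with the full
primer-to-primer span inside the product window (default 50–2000 nt; the
window is applied to the span with primers included, and the
`include_primers` flag controls only whether the primer intervals are kept
in the emitted amplicon). Both orientations are searched; hits found on the
reverse complement are mapped back to plus-strand coordinates (0-based,
half-open) and reported with strand `-`. Overlapping and nested site pairs
each yield a hit — sites are not consumed — which is what locus counting on
multi-copy rRNA operons needs. Reference extraction, by contrast, keeps a
single amplicon per record: fewest total mismatches, then leftmost, then
shortest, then plus strand, a deterministic tie-break chosen because operon
copies are expected and an error would be wrong.

The site scan is a vectorized bitmask comparison (4-bit base masks;
compatibility is a non-zero AND), exactly equivalent to the per-letter set
test.

## Dereplication and merged taxonomies

Dereplication is exact full-length identity after case/U→T normalization —
the behaviour of VSEARCH's full-length dereplication, not similarity
clustering (OTU clustering belongs to read pipelines, not database
preprocessing). Each cluster gets a synthetic id `drv_<first 8 hex of the
representative's SHA-256>`, stable across runs and input orders.

Merged labels join the distinct member names per rank with `/` in order of
first appearance, after factoring the longest shared leading word sequence:
`Staphylococcus aureus` + `S. schweitzeri` + `S. argenteus` print as
`Staphylococcus aureus/schweitzeri/argenteus`. The shared prefix is capped
below the shortest name's word count so every remainder is non-empty. Labels
with more than 6 names print the first 5 plus `+K`. Expansion (used by
group-aware scoring) inverts the factoring with the convention that each
later part replaces the trailing `len(part)` words of the first, fully
printed, name; this is exact whenever member names share the same word
count (the typical binomial case) and is documented as a convention rather
than a guarantee for ragged name lengths.

## Reference classifier

The built-in classifier is the classical word-presence naive Bayes method:
k = 8, each sequence reduced to its set of distinct unambiguous 8-mers, one
class per distinct full lineage. Priors and conditionals use

    P(w)   = (n(w) + 0.5) / (N + 1)
    P(w|c) = (m(w, c) + P(w)) / (M(c) + 1)

(presence/absence, not multiplicity). Queries score classes by summed log
conditionals over their distinct words; ties break to the lexicographically
smallest lineage, which makes results order-independent. Bootstrap
confidence resamples ⌈V/8⌉ of the query's V words with replacement, 100
times; the per-rank confidence is the fraction of draws whose winner agrees
with the full-query winner on the whole label prefix down to that rank —
prefix agreement makes confidence monotone non-increasing with depth by
construction. Ranks below the deepest one meeting the cutoff (default 0.8)
are blanked in the reported lineage. All of k, the subsample fraction, the
draw count and the cutoff are exposed; the defaults are the field-standard
parameterization. Words absent from the training corpus share one prior
(0.5/(N+1)) and are handled through a dedicated model column, so scores are
always finite. The model persists as a single JSON file embedding the
SHA-256 of its training database when supplied.

## Evaluation

Scoring is per rank. An empty predicted label is *unassigned*: it costs
recall but never precision (open-set convention). In group-aware mode a
merged label on either side matches when one side's expanded name set
contains the other's; strict mode requires string equality. Per expected
taxon t: TP = matching queries expected t; FN = expected-t queries that
mismatch or are unassigned; FP = non-matching queries whose prediction
names t (exactly or via a merged group). Matched merged predictions
generate no false positives for their other members — a merged group
counted as correct for one member must not simultaneously be punished for
the rest. The headline figure is macro F1 (unweighted mean over taxa with
≥ 1 expected query); micro F1 is computed alongside. Queries whose expected
label is empty at a rank are excluded at that rank.

## Synthetic fixtures

The generator emulates a 16S-style reference set: a balanced seven-rank
taxonomy (3 species/genus, 2 genera/family, doubling upward), and
sequences laid out as 60 nt flank | forward-primer site | 140 nt core
(80 nt conserved split around a 60 nt species-specific variable window) |
reverse-primer site | 60 nt flank. The primer sites are one concrete
instantiation of the degenerate V3–V4 primers 341F/805R, so unmutated
references amplify with zero mismatches. Identical-amplicon group members
share the whole inter-primer core but differ in flanks, so merging appears
only after extraction — the property the merged-taxonomy machinery exists
for. Anomalies are planted in disjoint species so each is recovered by
exactly one detection; empty cells are planted as deep-rank suffixes
(species, then genus), the pattern real exports show, because blanking a
mid-lineage rank would manufacture convergence conflicts underneath it.
Genomes embed each species' locus 1–5 times (uniform; real rRNA operon copy
numbers span roughly this range) in uniform-composition background with
spacers longer than the product window, so neighbouring loci can never pair
into an extra in-range product and locus counts are exact by construction.
Query noise is i.i.d. per-base substitution to one of the three other
bases.

Randomness flows from one seed through per-component substreams
(taxonomy/sequences/genomes/queries), so outputs are byte-identical for a
given spec + seed and adding one anomaly type does not perturb the others.

What the fixtures do **not** emulate: rRNA secondary structure and
GC skew, sequencing error profiles and chimeras, length variation of the
target region across taxa, intragenomic operon polymorphism, and the scale
and label noise of real SILVA/Greengenes2-sized databases. Perfect scores
on the noiseless fixture therefore validate the machinery (curation,
extraction, merging, scoring and the classifier's self-consistency), not
classifier accuracy on real communities.

## Problem sizes and numerical choices

The standard study fixture is 50 species (seeded), with 2 planted
cross-rank duplicates, 3 empty cells and identical-amplicon groups of sizes
3 and 2; oracle cross-checks run 500 random PCR instances (sequences
≤ 200 nt, degenerate primers 4–12 nt, mismatch budgets 0–2) and 200 random
label-pair sets. These sizes give exact oracle comparisons in seconds while
covering every code path. Hashing is SHA-256 throughout (manifests, cluster
ids); database writing is canonical (id-sorted records, LF endings,
prefixes re-applied) so identical inputs give byte-identical files.
Floating-point comparisons in scoring are exact fractions of integer
counts; the only tolerance used internally is 1e-12 when asserting
group-aware dominance, to absorb summation order.

## Known limitations

- No indel tolerance in primer matching; a primer-site indel in a genome
  hides the locus.
- Merged-label expansion is convention-exact only for equal word counts.
- The classifier is a clear, oracle-checkable reference implementation, not
  a speed-optimized one; training databases beyond ~10⁵ sequences would
  want a sparse or memory-mapped conditional matrix.
- Provenance flags are an in-memory annotation and are lost on write/read
  round-trips of the two-column taxonomy format.
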