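# Methods

## Scope and model

The package chains four evidence streams over an annotated fungal genome
into per-gene activity calls for core (backbone) biosynthetic genes, and a
metabolomics wing linking genomic potential to secreted compounds. It
consumes only *downstream* artifacts — gene models (GFF3), per-base RNA-seq
coverage (bedGraph), 6mA methylated-adenine-cluster (MAC) positions (BED),
tabular homology results (outfmt-6-like TSV), trees (newick), MS/MS spectra
(MGF), feature tables (TSV). Read alignment, gene prediction, sequence
search, alignment/trimming/tree inference, peak finding and
peptide-spectrum matching are upstream tools' jobs and out of scope.

## Genomic evidence calls

Coordinates are 1-based inclusive internally (GFF3 convention); bedGraph
and BED are converted from 0-based half-open on read.

**Transcription.** `gene_coverage_fraction` counts bases of [start, end]
with depth ≥ `min_depth` (default 5). `is_transcribed` requires that
fraction to exceed `min_fraction` (default 0.95). The threshold is stated
both as "more than 95%" and "at least 95%" in common usage; the predicate
defaults to the strict `>` reading with a `strict=False` switch, and the
delineation stage uses the same default. Coverage counts every base of the
single-interval gene model; no exon awareness is attempted.

**Cluster delineation.** From each core gene, extension is greedy and
bidirectional: the next gene joins iff its intergenic distance to the
current outermost member (`next.start − prev.end − 1`) is ≤ `max_gap_bp`
(default 10,000, inclusive) *and* it passes `is_transcribed`; the first
failure stops that direction permanently, so a transcribed gene past a
silent neighbor never joins. The core seeds its cluster even when itself
poorly covered — the delineation is anchored on the prediction, and the
core's own transcription flag is still reported. Backbones are `clustered`
(≥ 2 members) or `isolated`.

**Promoter methylation.** TSS = `start` on `+`, `end` on `−`. A promoter
is methylated iff some MAC position is within `window_bp` (default 500,
inclusive) of the TSS.

**Transcript matching.** A gene is eligible iff it has ≥ 3 catalytic
domains and ≥ 100 aa; ineligible genes return `None` and are excluded from
denominators rather than counted silent. An eligible gene matches iff some
hit has E ≤ 10⁻³, similarity > 95% and HSP/query length ratio > 0.95
(HSP length over *query* length; the alternative denominator is not
represented in the input format).

**Integration.** `active_any` is the disjunction of the three flags;
summaries report fractions per strain and overall. Protein detection is an
input flag (≥ k distinct peptides, default k = 1).

**Region agreement.** Two prediction tools are compared as the fraction of
one tool's genes overlapping (≥ 1 shared base, same scaffold) any of the
other's regions — the weakest defensible overlap notion.

## Homology families and taxonomy

BBH pairs require mutual best bitscore at E ≤ 10⁻⁵, ties broken by lower
E-value then lexicographic subject id for determinism. Families are
connected components of the BBH graph (single linkage); genes without
pairs are singleton families. This is a deliberate stand-in for full
orthogroup inference (score normalization + MCL): families here serve only
as a grouping, and the stand-in is validated by exact recovery of planted
families. Top-hit taxonomy uses strict comparisons (E < 10⁻⁸,
identity > 30%, qcovhsp > 25%), takes the largest-bitscore survivor per
query, and counts each distinct phylum once per cluster; kingdom fractions
aggregate over counted results, with unknown taxonomy binned separately,
never dropped. Excluding the query's own clade from the hit table is the
caller's responsibility.

## HGT placement

Trees are read as rooted as written (no rerooting); internal node labels
are bootstrap supports in [0, 100]. With Q the query leaf and P its
parent: *sister(G)* iff the union of P's non-query subtrees is non-empty
and homogeneous for one foreign group G (prokaryote or non-fungal
eukaryote); *nested(G)* iff additionally the extra leaves under P's parent
are all G. Multifurcations are handled by taking unions over sibling
subtrees. The support gate defaults to the literal whole-tree reading —
every labeled internal branch ≥ `min_support` (default 70) — with a
`path_only` alternative checking just the branches defining the
classification; branches without a label (e.g., the root edge, which
FastTree/RAxML leave unlabeled) are skipped rather than failed. A failed
gate downgrades the verdict to `none`. Homolog selection takes up to 10
best hits per group (prokaryotes, non-fungal eukaryotes, other fungi) with
the query capping tree size at 31 leaves.

## Molecular networking

Preprocessing removes fragment peaks within ±17 Da of the precursor
(inclusive) and then keeps a peak only if it ranks in the top 6 by
intensity within its own ±50 Da window (ties rank lower m/z first).

**Modified cosine.** Intensities are square-rooted and each spectrum
scaled to unit Euclidean norm; peak pairs are candidates when aligned
directly (|Δm/z| ≤ 0.5 Da) or shifted by the precursor mass difference;
the one-to-one matching is greedy by descending intensity product, with
the score the sum of matched products clipped to [0, 1]. Greedy matching
is checked against the exhaustive optimal assignment (Hungarian algorithm)
and against an independent reference implementation in the test suite.

**Consensus clustering.** Single-pass greedy centroid clustering stands in
for multi-round MS-Cluster: spectra in descending total-intensity order
join the best-scoring existing consensus with |Δprecursor| ≤ 2.0 Da and
cosine ≥ 0.7, else seed a new one; consensus peaks are members' peaks
merged in 0.5 Da bins (summed intensity, intensity-weighted bin m/z) and
the consensus precursor is the intensity-weighted mean. Consensi with
fewer than 2 members are eliminated. The stand-in is validated by exact
planted-family recovery and consensus purity on synthetic data.

**Edges.** Candidate edges need cosine > 0.7 and ≥ 6 matched peaks
("greater than six" is read as ≥ 6 for internal consistency with the
library-matching rule "at least six"; the strictness is configurable), and
survive only when each endpoint is in the other's top-10 most similar
nodes (ties to lower node id). Self-loops are excluded. Library matching
applies the same two thresholds and keeps the best-scoring annotation.
Nodes are labeled by member conditions: single strain, shared fungal,
control only, or fungal + control.

**Feature filtering.** A feature passes at sample/control ≥ 4 (≥ 10 for
the high-confidence variant); a zero control with positive sample counts
as infinite ratio and passes.

## Mass arithmetic

Monoisotopic masses use C = 12 exactly, H 1.00782503, N 14.00307401,
O 15.99491462, P 30.97376200, S 31.97207117; adducts add/subtract the
proton mass 1.00727646 Da (electron accounted for; |z| = 1 only). Errors
are always reported in both mDa and ppm with explicit labels: for the
package's worked example (observed 523.1232 vs C27H22O11 [M+H]⁺ =
523.12349) the absolute error is −0.288 mDa while the relative error is
−0.55 ppm, and reporting both prevents the classic unit mix-up between
numerically similar values. `find_formulas` enumerates exhaustively over
finite per-element bounds (heaviest element first, pruned on the remaining
lower mass bound), sorted by |error|; an RDBE ≥ 0 plausibility filter is
available but off by default so the enumeration stays complete.

## Synthetic data and what passing tests show

Generators are pure functions of (seed, spec); each draws from its own
named substream of a single integer seed, so outputs are byte-identical
across reruns and unaffected by other generators. Planted layouts use
intra-cluster gaps of 1.2–8 kbp (always joinable), flanks > 10 kbp,
transcribed-gene coverage 97–100% vs silent 40–48%, blocked-decoy genes at
near-threshold 90–94% coverage, MACs within 500 bp of methylated TSSs and
nothing within 600 bp otherwise, bootstrap supports ≥ 70 for positive
placements and one 50–69 branch for support-broken negatives, and
compound families as CH₂ homolog series (14.0157 Da offsets) sharing an
8-fragment scaffold with ≥ 2 replicates per compound.

The generators emulate the *decision structure* of real data, not its
physics: no read-level noise, chimeric spectra, isotope envelopes,
retention-time drift, or annotation error. Exact planted-truth recovery
therefore demonstrates that the rules are implemented correctly and their
boundaries behave as specified — not that the pipeline is robust to messy
real inputs.

Default problem sizes for the shipped end-to-end runs — ~200 genes in 10
clusters, 6 families over 4 genomes, 50 trees, 60 family spectra plus 20
decoy compounds, 131 cores with 69 active (52.7%) for the evidence
summary — were chosen as the smallest scales at which every rule,
boundary and negative control is exercised with planted structure.

## Numerical choices and degenerate inputs

All tolerance boundaries are inclusive; ranking ties break toward lower
m/z, lower node id, or lexicographic id throughout, making every stage
deterministic under input permutation. Empty inputs yield empty outputs
(no division by zero in summaries); an empty spectrum scores 0 with 0
matches; zero-intensity peak sets normalize to zero vectors. Manifests
record parameters and SHA-256 input/output hashes and contain no
timestamps, so byte-identical reruns are verifiable by hash comparison.

## Known limitations

Single-interval gene models only (no exon-aware coverage); no rerooting or
outgroup logic in placement calls; single-pass clustering can split a
compound across consensi if replicate intensities straddle a join-score
boundary (not observed at the shipped noise levels); formula enumeration
is exponential in the number of unbounded-ish elements and is meant for
small CHNOPS bounds; only singly charged adducts are supported.
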