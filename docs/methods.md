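# Methods

## Target selection model

A spliced transcript with *n* exons carries *n−1* introns, each bounded by
the near-invariant donor GT and acceptor AG dinucleotides read on the
transcript sense strand. A transition edit at any of these four bases
abolishes recognition by the spliceosome. The editable base for each editor
× site-kind combination is fixed by the chemistry:

| combination | edited base | strand relative to transcript | forced neighbour |
|---|---|---|---|
| CBE × donor | C complementary to the donor G | antisense | preceded by A |
| CBE × acceptor | C complementary to the acceptor G | antisense | followed by T |
| ABE × donor | A complementary to the donor T | antisense | followed by C |
| ABE × acceptor | the acceptor A itself | sense | followed by G |

The "forced neighbour" column is a structural invariant — the complementary
strand of GT reads AC, of AG reads CT — and the test suite asserts it for
100% of designed guides; the pentanucleotide motif matrix reports frequency
1.0 at the forced offset by construction.

Guide enumeration slides the protospacer so the target base occupies every
position k = 1..L (L = 20 by default) and keeps placements whose immediately
3' PAM matches the configured IUPAC pattern. Window membership (default
positions 4–8) is recorded, never used as an enumeration filter: window
position is a scoring input, and placements outside it are legitimate
(weakly active) candidates. Genomic N bases match no PAM character and
placements containing N are dropped. Identical placements shared between
transcripts of a gene are merged with transcript ids accumulated; cross-gene
(paralog) deduplication is deliberately not attempted. Only Cas9-family
3'-PAM geometry is supported.

Correctness is established against a brute-force oracle
(`guide_design.brute_force_scan`): a naive sweep of every (L+|PAM|)-mer on
both strands of the whole contig, with the PAM tested by explicit expansion
of the IUPAC pattern into its string set. The oracle shares only the
low-level candidate constructor with the production path; its enumeration
and PAM logic are independent.

## Coordinates and conventions

Internal coordinates are 0-based half-open; all user-facing output (TSV,
predicted edits, reports) is 1-based inclusive, matching GFF3. BED output is
0-based half-open per that format. Protospacer positions are counted 1..L
from the 5' (PAM-distal) end. "Sense" always means the transcript strand;
minus-strand genes are handled by reverse-complementing genome slices before
any motif logic, which makes the plus- and minus-strand constructions exact
mirror images (a tested property).

A donor maps to the last exonic base of its upstream exon in spliced-mRNA
coordinates; an acceptor to the first base of its downstream exon. The
"percent through the mRNA" statistic uses the spliced transcript length,
not pre-mRNA. Exon bins are assigned with terminal labels dominating:
last > first > second_to_last > second > middle, so a 2-exon gene yields
"first" and "last". Introns shorter than 4 nt (donor and acceptor
dinucleotides would overlap) are skipped with a warning. Non-canonical
sites (GC-AG, AT-AC, …) are extracted and flagged but excluded from design
unless explicitly included — the editing logic targets the canonical GT/AG
bases.

## Meta-analysis pipeline

Editing efficiencies collected from heterogeneous studies are made
comparable in three steps:

1. **Normalization.** Each value is divided by the maximum observed in its
   (study, cell type) group and scaled to percent, so every surviving group
   has an exact maximum of 100. Groups that are entirely zero carry no scale
   information and are dropped with a warning. The operation is idempotent.
2. **Duplicate collapsing.** The same guide assayed by several studies is
   reduced to one record per (editor, guide, protospacer position) by
   arithmetic mean; the result is invariant to input order.
3. **Context aggregation.** Records are grouped by the base preceding (or
   following) the target; the context mean pools all positions, and the
   fold-change between contexts c1, c2 is mean(c1)/mean(c2).

Smoothing uses classical LOESS: for each integer query position 1..20, a
weighted least-squares polynomial of degree 2 over the ceil(span·n) nearest
points with tricube weights, ties in neighbour selection broken toward lower
x. Spans follow the editor-specific values used for the published activity
curves: 0.5 for the cytidine editor (BE4), 0.45 for the adenosine editor
(ABE7.10). Degree and kernel are the classical defaults; the sources for
the curves name only the span. Two degenerate-input safeguards: if every
selected neighbour sits exactly at the bandwidth edge (all tricube weights
zero) the weights fall back to uniform, and if the positively-weighted
neighbours span fewer distinct abscissae than the polynomial needs, the
local degree is reduced accordingly. Fitted values are clamped to [0, 100].
Curves are fit to collapsed records and evaluated only at integer positions.

## Scoring (activity-profile lookup)

A guide's score is `curve[preceding_base](target_position)` — the smoothed
normalized efficiency for its dinucleotide context at its protospacer
position. This is the minimal model consistent with what is known: the
preceding base and the window position are the two dominant predictors,
while the following base has a much smaller effect and is therefore
recorded but not scored. Contexts with fewer than 10 collapsed records fall
back to the pooled curve rescaled by (context mean / overall mean), noted in
the profile provenance. A guide whose target sits at position 1 takes its
preceding base from the genomic base 5' of the protospacer. The default
selection threshold is a score ≥ 20 (percent of the per-dataset maximum);
filtering is a flag on the output, never a deletion. Ranking is total and
deterministic: score descending, then earlier spliced-mRNA offset (earlier
and inner exons disrupt more reliably), donors before acceptors, then
protospacer lexicographically.

## Targetability survey

A gene is *spliced* iff any transcript has ≥ 2 exons and *targetable* iff at
least one guide exists under the supplied editor/PAM list. Guides are
deduplicated within a gene across transcripts and editor specs on (edited
base, strand, span, target coordinate) — PAM identity is excluded from the
key so nested PAM sets (NGG within NG) cannot double-count a placement,
which also makes guide counts monotone under added PAMs (a tested
invariant). Quantiles use linear interpolation (type 7). Published
genome-wide figures for the human annotation depend on the annotation
release and a full genome download; this package reproduces the survey
logic at fixture scale with exact planted counts instead.

## Synthetic data generators

**Genes** (`fixtures.make_fixture_gene`): exons and introns of configurable
lengths (defaults 30–80 nt exons, 24–60 nt introns, 4 exons — compact but
realistic architecture for exhaustive oracle scans), every intron opening
with GT (GTAAGT consensus when it fits) and closing with AG. Per splice site
and editor, a Poisson(`pam_density`) number of PAM-enabling dinucleotides is
written at admissible offsets, never overwriting splice motifs or earlier
plants. With `pam_density=0` the contig is sampled with no GG or CC
dinucleotide anywhere, which provably admits no NGG placement on either
strand — the planted-untargetable construction used in survey tests. Ground
truth always comes from the brute-force oracle. All draws derive from one
integer seed; the same (config, seed) reproduces byte-identical output. The
hand-built 60-nt worked-example gene ships as a static constant.

**Meta tables** (`fixtures.make_fixture_meta`): raw values are
`amplitude(study) × multiplier(editor, preceding base) × shape(position) +
N(0, σ²)`, clamped to [0, 100], with a Gaussian window shape centred at
position 6 (sd 2.4 for the CBE, 1.6 for the narrower ABE window), per-study
amplitudes uniform on 40–95%, and a 15% chance a guide is entered by a
second study (exercising duplicate collapsing). Defaults mirror the scale of
the published cross-study dataset: 6 studies, 102 guides, ~4.4 edits per
guide (~447 records). The planted T/G multiplier ratios equal the published
context-mean ratios (28.7/6.9 for the CBE, 24.5/6.3 for the ABE). Each
guide's positions are sampled without replacement (a real protospacer has
one context per position).

Because additive noise is clamped at zero, contexts whose expected signal is
near zero are biased upward; the generator therefore also returns the
analytic expectation of each context mean under the clamped model
(E[max(0, N(μ, σ²))] averaged over drawn amplitudes and uniform positions),
and recovery tests compare the pipeline's fold-changes to these clamp-aware
planted values, averaged over 20 seeds (a single ~450-record table has
~10% sampling error on a fold-change, so per-seed agreement is not a
meaningful criterion). What these fixtures do *not* emulate: real position
distributions of editable bases, correlated bystander measurements,
between-lab protocol effects beyond a scale factor, or figure-extraction
error in the curated literature values — so passing recovery tests
demonstrate the pipeline's statistical correctness, not the accuracy of any
specific published estimate.

## Problem sizes and determinism

The default verification scale is 50 seeded genes (≈ 1900 oracle-verified
guides across editors and PAMs NGG/NG), 200 genes for motif re-reading, 20
seeds × ~450 records for fold-change recovery — sizes at which the
brute-force oracle remains exhaustive while the whole suite runs in
seconds. No design or scoring path uses randomness; repeated runs are
byte-identical. `scripts/acceptance.py` derives all generator seeds from a
single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Only 3'-PAM (Cas9-family) geometry; Cas12a-style 5' PAMs are out of scope.
- No off-target search, no editing-outcome genotype modelling, no
  bystander-aware protein-consequence scoring.
- The score is a context × position lookup; it does not model saturation,
  chromatin, or sgRNA secondary structure.
- Branch-point and polypyrimidine-tract targeting are not supported; only
  the two invariant GT/AG bases are targets.
- The optional Ensembl REST adapter is a convenience for interactive use
  and is never exercised by tests.
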