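# Methods

## Coordinates and containers

All internal coordinates are 0-based, half-open; the GTF reader/writer
converts to and from the 1-based inclusive GTF dialect at the boundary.
A `TranscriptModel` stores sorted, disjoint exons on one contig and
strand, an optional CDS (each CDS segment contained in an exon; the
stop codon lies inside the CDS — no separate stop_codon feature is
emitted), and free-form attributes holding expression (`fpkm`), read
depth (`cov`, fold units) and supporting sample labels. Introns and
UTRs are never stored: introns are the gaps between consecutive exons,
and UTRs are the interval difference between the exonic and the CDS
region, split at the CDS bounds into 5' and 3' parts by transcript
orientation. Strand "." transcripts are accepted throughout but
excluded from orientation-dependent answers (UTR sides, run-on calls,
donor/acceptor naming); requesting UTRs on "." raises.

Coverage is treated as a supplied per-transcript attribute. How an
assembler derives "coverage of uniquely mapped reads" from alignments
varies by tool and is upstream of this package.

## Class codes

`classify_transcript` is total and evaluates six rules in fixed
priority order:

1. `=` — identical intron chain (multi-exon) or, for two single-exon
   transcripts, reciprocal exonic overlap ≥ `single_exon_overlap_fraction`
   (default 0.5; single-exon matching conventions vary between tools,
   so the fraction is exposed and logged);
2. `j` — shares ≥ 1 junction with a span-overlapping reference
   transcript;
3. `o` — exonic overlap with no shared junction;
4. `i` — span contained in one intron of a reference transcript;
5. `p` — no reference-exon overlap and the span begins within
   `run_on_window` bp (default 2000) downstream of a reference 3' end
   on the same strand;
6. `u` — otherwise.

Strand "." is a wildcard for rules 1–3; rule 4 is strand-agnostic
(containment in an intron is a positional statement); rule 5 requires
an explicit strand. Antisense overlap (query exons over reference
exons on the opposite explicit strand) deliberately falls through to
`u`: the six-code alphabet has no antisense class, and `p` excludes any
reference-exon overlap. Ties among qualifying reference transcripts
are broken by most shared junctions, then largest exonic overlap, then
smallest transcript_id, making reports deterministic. `o` transcripts
exist only to keep classification total; they are dropped (with a
logged count) before any downstream category set.

`cluster_genes` performs single-linkage clustering; two transcripts
are linked iff they share exonic bases ≥ `min_overlap` (default 0.1)
times the exonic length of the shorter one, on the same contig and a
compatible strand.

## Consolidation pipeline

`refine_annotation` runs merge → support/coverage filter →
categorization → fusion removal → new-gene overlap filtering.

* **Merge.** Isoform identity across samples is the `=` criterion.
  The merged representative takes the widest termini over its members
  (the junction chain is invariant, so only the terminal exons widen),
  the union of supporting samples, and the maximum coverage and FPKM.
* **Filter.** `|samples| ≥ min_samples` (default 2) and
  `coverage > min_coverage` (default 2, strictly greater). The strict
  inequality is intentional and tested; both thresholds are exposed in
  `RefineConfig`.
* **Fusions.** A transcript whose exons overlap exons of ≥ 2 distinct
  reference genes with the same explicit strand is removed from the
  extended and novel isoform sets (only those sets — intergenic
  transcripts are handled by clustering instead).
* **New-gene cleanup.** A single-sample transcript is *tainted* if it
  overlaps reference exons directly or via a transitive chain of
  exon-overlapping single-sample transcripts (unbounded depth; the
  closure depth is logged). New-gene candidates overlapping the
  reference or any tainted transcript are removed, and removal acts on
  whole clusters: one tainted member removes its cluster.
* **Boundary extensions** are measured per reference gene against the
  gene-span envelope (min start / max end over its transcripts), not
  per isoform, and oriented by the gene strand; the per-gene value is
  the maximum over surviving `=`/`j` transcripts.
* **ORFs.** Novel isoforms and new genes get the longest complete ORF
  of their spliced sequence as CDS (none attached when no complete ORF
  exists); extended isoforms inherit the matched reference CDS when it
  fits inside their exons.

Sample specificity reports fractions of retained transcripts whose
support is all-male, all-female, or confined to one strain, plus the
chance baseline: records supported by exactly two samples discordant in
both sex and strain.

## Splicing events and frame impact

Events are extracted pairwise. Within the shared genomic span, introns
present in exactly one transcript are clustered by closed-interval
contact; each cluster is one event:

* one intron, strictly inside an exon of the other isoform →
  **intron retention** (region = the intron);
* two introns vs one fused intron with agreeing outer boundaries and
  the enclosed exon present exactly → **exon skipping** (region = the
  skipped exon);
* two introns sharing one boundary → **alt donor** or **alt acceptor**
  (donor = 5' intron end in transcript orientation; region = the
  stretch between the two alternative sites);
* anything else, including any cluster touching an intron that crosses
  the shared-span boundary (terminal variation: no common flanking
  splice site exists) → **complex**, delimited by the shared-span
  boundary. On "." strand pairs the donor/acceptor naming falls back
  to '+' orientation.

Per-gene counts deduplicate events by (mode, region) across all
isoform pairs; raw pair counts are reported alongside.

`find_orf` scans the three forward frames of the oriented transcript
sequence for the longest ATG→stop frame (stops = TAA/TAG/TGA; a codon
containing N is never a start or stop); ties go 5'-most. Similarity-
guided ORF choice (using homology evidence) is out of scope.
`map_orf_to_genome` projects transcript coordinates through the exon
chain (right-to-left on '-') and preserves total length exactly.

`assess_impact` computes the net CDS-overlapping exonic length change
over the event region between the inclusion and exclusion isoform: not
divisible by 3 → frameshift; otherwise the inclusion isoform's
annotated CDS is translated codon-by-codon and a stop codon overlapping
the event region before the annotated stop → premature_stop; else
frame-preserving (events outside both CDSs are frame-preserving with a
`utr_only` flag). The premature-stop search uses the annotated reading
frame only. Note the inclusion CDS must be supplied (for planted
events: the reference CDS extended through the event region) — a
de-novo ORF scan of the inclusion isoform would terminate *at* the
premature stop and hide it.

## Evaluation

Base-level sensitivity counts each validation exonic position once per
(contig, strand) group after merging, and a position is covered when a
strand-compatible predicted exon contains it ('.' is a wildcard on
either side). Junction and isoform sensitivity require exact
coordinate matches of junctions / complete chains. Equal annotations
give 1.0 at all levels; adding predictions can only raise sensitivity;
isoform ≤ junction sensitivity whenever all validation transcripts are
multi-exon. Precision is not reported (see README scope notes).
Concordance assigns every distinct junction or chain to exactly one
membership cell. Expression binning uses geometric FPKM edges
(≤1, 1–10, 10–100, >100) by default and bins each gene by its highest
isoform FPKM.

## Gene statistics and conservation

Intron position classes are assigned in transcript orientation; a
single-intron transcript's intron is "first" (callers doing
first-vs-terminal contrasts should exclude single-intron transcripts to
avoid double counting — `IntronRecord` carries enough context to do
so). Host regions compare the two flanking exonic bases against the
CDS bounds: both 5' of the CDS start → five_prime_utr, both ≥ CDS end
→ three_prime_utr, both inside → cds, else mixed. Per-gene summaries
(UTR lengths) use the longest isoform by exonic length. Contrasts are
two-sided Mann–Whitney tests (scipy); empty groups skip the contrast
with a warning.

Conservation tracks are per-base scores in [0, 1] (PhastCons-style)
read from bedGraph-like text; uncovered positions are missing, not
zero, and are excluded from interval means (an interval with no scored
base is flagged NaN and excluded downstream). Short introns ≤ 65 bp
serve as the neutral-evolution proxy by the usual short-intron
convention; the threshold is a parameter.

## Synthetic cohort

The generator emulates the 2-sex × 2-strain, four-lane adult-fly study
design. Defaults: 64 genes of 4–5 exons (120–300 bp) and introns of
80–400 bp, intergenic gaps 4.8–6.4 kb, GC 0.45, coverage drawn from
3–50× (avoiding a ±0.5 band around the filter threshold so ordinary
plants never sit on the boundary), FPKM 0.5–200, six plants per
category. Gap sizing guarantees that intergenic plants keep >
run-on-window clearance from both neighbours and run-on fragments
(placed 0.2–1.2 kb downstream) never collide with anything else; each
plant category draws from its own seed-derived random stream so
category counts can change without perturbing the rest.

The reference sequence is written to guarantee its annotation: GT..AG
at every intron boundary (strand-aware), ATG/TAA at the planted CDS
ends, a TAA·TAA·TAA barrier opening the 3'UTR (truncating run-through
frames), in-frame stops inside the CDS and upstream ATGs in the 5'UTR
scrubbed, with a bounded deterministic repair loop that breaks any
remaining competing ORF. `find_orf` therefore recovers every planted
CDS exactly — a property the tests assert.

Threshold probes are planted on top of the regular categories: coverage
exactly 2.0 vs 2.01, and support 1 vs 2 samples. The truth table
records two outcomes per feature: `expected_survival` (support +
coverage rule only) and `expected_in_final` (additionally false for
fusions, which pass the thresholds but are removed structurally).

What the generator does **not** emulate: read-level noise, termini
jitter between samples (observed copies share exact termini, so
boundary extensions are exactly the planted values), expression
distributions beyond uniform ranges, sequence evolution, incomplete or
wrong reference models. Passing the planted-recovery tests therefore
demonstrates the correctness of the consolidation logic under its own
assumptions, not robustness to assembler noise — the support/coverage
filter's behaviour on noisy termini is exercised only through the
single-sample noise plants.

## Problem sizes and determinism

The test suite and the acceptance script run on one 64-gene, ~600 kb
cohort, 1000 random classification pairs, 500 random frame-impact
events, the exhaustive ≤4-exon pair grid over a 9-point coordinate
lattice (~33k pairs), and 200 random conservation intervals — sizes
chosen so the whole suite completes in seconds while every code path
is exercised. All randomness is seeded (numpy `default_rng` with
explicit child seeds); the generator is byte-deterministic, which the
tests verify by hashing an emitted directory twice.
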