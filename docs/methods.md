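# Methods

This note documents the models behind `chipperscan`, the parameters that
matter, the numerical choices, and what the synthetic-data generators do and
do not emulate.

## Coordinate conventions

All coordinates are 0-based, half-open internally; written outputs use
1-based inclusive positions except BED/bedGraph, which stay half-open. A
site's `spacer_start` is always the leftmost plus-strand-frame coordinate of
the protospacer. The "last base" and "third-last base" of the targeting
domain are read 5′→3′ on the guide's own strand, so on the minus strand they
map to the leftmost (`spacer_start`) and third-leftmost (`spacer_start + 2`)
plus-frame coordinates. The last-base coordinate is the plotting/hit-locus
coordinate; the third-last-base coordinate doubles as the neighbour-distance
coordinate and as the modelled Cas9 cut site (the blunt cut 3 bp 5′ of the
PAM, i.e. between targeting-domain bases 17 and 18). PAM classification
inspects only bases 2–3 of the 3-nt PAM (N is free), with exclusive
precedence NGG > NGA > OTHER. Ambiguity codes in input sequences are
rejected at load rather than skipped: the intended inputs are short, curated
regions where an N would silently delete targetable positions.

## In-silico digest (`chipper_sim`)

The digest is a seeded sampling process, not a chemistry model:

* **Ligation** concatenates regions sampled with replacement in random
  orientation into a linear concatemer (default ≥ 100 kb, emulating the
  >10-kb random ligation products that precede fragmentation). Circularity
  is not modelled; guides spanning ligation junctions are emitted but
  flagged and excluded from provenance-based analyses.
* **Fragmentation** draws `n_fragments` independent intervals with uniform
  starts and lengths uniform on [400, 450] bp. Independent draws rather than
  a physical partition: only end positions matter downstream, and sampling
  keeps the model simple and exactly seedable.
* **End release**: the left end of a fragment releases the first k top-strand
  bases, the right end the first k bottom-strand bases. Only the blunt
  G-bearing adaptor end can ligate to a repaired fragment end, so each end
  yields exactly one guide whose strand is fixed by which end it is. The
  released insert length k is drawn from `length_jitter`
  (default 19: 0.90, 18: 0.05, 20: 0.04, 17: 0.01). The 19/17-base split of
  the released duplex is a consequence of the enzyme's 25/27-nt cut distance
  minus the 8-bp adaptor spacer; the long strand defines the spacer and the
  17-base strand is not tracked separately. The jitter weights are a free
  modelling knob chosen to give a dominant 20-base targeting domain with
  minor ±1 shoulders, qualitatively matching observed digest length
  distributions; they are not measured values.
* **Clone sampling** draws `clone_count` clones uniformly with replacement
  over all released ends — the transformation bottleneck that fixes library
  composition (the reference scale is ~1.5 million clones from ~9 kb input).

Entries are aggregated by targeting-domain string; a domain released from
more than one distinct locus keeps all provenances and is flagged ambiguous,
mirroring multi-mapping downstream.

## Synthetic screen (`screen_sim`)

Per infected cell (infection rate 0.30, single integration — low titre is
chosen in such screens precisely to avoid multiple integrations): the guide
is multinomial over clone frequencies; Cas9 cuts with probability
`pam_activity[(variant, pam_class)]` (defaults WT: NGG 0.8, NGA 0.05,
OTHER 0; VQR: NGA 0.4, NGG 0.05 — invented magnitudes, documented as knobs
and excluded from any acceptance claim); if the cut site falls in a planted
element the cell's GFP bin is drawn from the element's `bin_profile`,
otherwise the cell stays GFP-negative. The optional GTGG exception (off by
default) models weak wild-type activity at a GTG PAM followed by G, applied
on the 4-base context 3′ of the protospacer.

Default element layout for a 10-kb locus: an 85-bp hairpin at the centre
(profile 0.05/0.15/0.30/0.50 over neg/low/med/high — cutting the hairpin
abolishes most silencing), a 66-bp 5′ element and a 60-bp 3′ element
(0.15/0.55/0.25/0.05 — partial biogenesis loss, mostly low GFP). Widths are
of the order of the deletions that validated real hit regions; the relative
med/high magnitudes are user parameters with no measured reference.

Sorting is pure: a cell's bin is exactly its drawn phenotype, and an
effect-free screen therefore has *empty* positive bins, which are flagged
and propagate as all-zero counts (the positive-frequency floor then takes
over). Sorter impurity, PCR chimeras and proliferation selection are
deliberately not modelled. Sequencing is a multinomial of `read_depth` reads
per sample over within-bin guide frequencies, with i.i.d. substitution
errors on the emitted reads (default 0). Reads carry the real amplicon
structure: spacer (no leading G — it sits in the sequencing primer), 20-nt
scaffold prefix, 6-nt sample barcode, constant tail; the first sample's
barcode is fixed to CGTGAT, the one printed in the protocol's primer design.

What passing tests on this generator show: the pipeline's bookkeeping
(clipping, demultiplexing, mapping, counting) is exactly invertible at zero
error rate, and the scoring/scan machinery recovers planted signal under a
faithful sampling model. What they do not show: robustness to sort impurity,
PCR artifacts, guide-specific cutting-efficiency variation, or chromatin
effects — none of which the generator emulates.

## Read processing (`readproc`)

Clipping searches each read for the literal 20-nt wildcard pattern
`GNNNNNNAGCTAGAAATAGC` (leftmost match); the spacer is the prefix, the
barcode the 6 nt after the match. Demultiplexing is exact by default; in
1-mismatch mode a configuration check rejects barcode tables whose pairwise
Hamming distance could make any read ambiguous. Mapping is an exhaustive
both-strand substring search over the input regions via a per-length
dictionary index, with 1-mismatch queries enumerating the 3L single-base
variants — exact, and fast for curated kilobase-scale regions (this is not a
genome-scale aligner; genome-wide off-target search is out of scope). Unique
hits are annotated with the reference PAM; multi-locus spacers stay in count
tables (an aligner would report them mapped, so they count in totals) but
are barred from positional analyses. Counting is by exact spacer string,
which is how "unique sgRNAs" are accounted in complexity analyses. Spacers
shorter than 10 nt are dropped. The targeting-domain length histogram is
reported over spacer length + 1 (the leading G counts) and normalised to the
20-base bin; a missing 20-base bin returns raw counts with a flag.

## Enrichment and hits (`enrichment`)

Frequencies are counts over total mapped reads per sample. Floors —
6.25×10⁻⁷ for negative-bin frequencies, 1×10⁻⁸ for positive-bin — are
applied to frequencies only, never counts, and only upward; the score is
exactly log2 of the floored ratio. Consequences worth knowing: a guide
absent from a positive bin scores at most log2(1e-8/6.25e-7) ≈ −5.97, and
the maximum attainable score at fixed positive frequency occurs at the
negative floor. The hit rule treats "high- or med-GFP" per replicate
(a replicate qualifies when either bin exceeds the strict threshold of 2),
then requires ≥ 2 qualifying replicates — the weakest reading consistent
with the rule's wording, and both threshold and replicate count are
parameters. The locus filter is an explicit interval parameter, not a
hard-coded locus. Positional tracks keep the best score per last-base
position (a plotting collapse only), NGG guides and positive scores only,
with the winning guide's strand retained.

## Cluster scan (`escscanner`)

The null is fitted per (replicate, bin) on the scores of *all* uniquely
mapped NGG guides of that sample — including negative and floored scores —
with the sample SD (n−1). A trimmed fit (drop a tail fraction before
fitting) is available but off by default; with heavy floor masses the plain
fit is already conservative because floored scores widen σ. Tail
probabilities are floored at 1e-300 so −log10 stays finite. The window value
is computed as the sum of member −log10 p (identically the log of the
product) via cumulative sums, so the per-window cost is O(1) and equivalence
with the direct product is tested to 1e-9. Members are all unique guides
whose last-base position falls in the 21-bp window, both strands pooled;
windows truncate at region edges. Raw −log10 values are reported with no
multiple-testing calibration — the statistic ranks positions; it is not a
calibrated p-value.

## Library QC (`libqc`)

Neighbour distances are successive differences of sorted third-last-base
coordinates pooled across strands within a region, never across regions.
Observed-library distances conventionally use the 1-mismatch mapping mode
(the one analysis where a mismatch is tolerated); everything else uses 0.
Saturation curves subsample mapped reads without replacement using a single
permutation per draw, prefix-sliced at each size, so nesting makes unique
counts exactly monotone; 5 independent draws report mean and range (whether
a single draw or an average is the convention is unspecified — the mean of
a few draws is stabler and exposes the spread). The capacity extrapolation
is deliberate conservative arithmetic: fold = clones / reference reads,
capacity = floor(fold) × input length, e.g. 1.5M clones against a 160,000-
read reference over 9 kb gives fold 9.375 and > 80 kb (81 kb) of coverable
input.

## Workflow and reproducibility

A single master seed derives one named child stream per stage (library,
screen, reads, QC) through `SeedSequence` spawning; reruns under the same
configuration are byte-identical, which the run manifest (input and artifact
SHA-256 checksums) makes checkable. Reports are rendered from artifacts only,
with no recomputation, and are plain Markdown.

## Problem sizes used in the test and acceptance suites

The packaged simulations run at desk scale, chosen as the smallest sizes at
which the statistical claims are comfortably testable: site-density checks
on 0.2–1 Mb of random DNA; digest checks at 10⁴–2×10⁴ fragments on a 10-kb
region; screens at 5×10⁵ cells, 3 replicates, 2×10⁵ reads per sample; the
planted-element recovery property over 20 seeded end-to-end runs plus 5
effect-free controls. Scaling any of these up changes precision, not
structure.

## Known limitations

* The digest does not model sequence-dependent sonication bias, ligation
  chemistry, EcoP15I star activity, or the post-sonication size selection's
  possible end-composition bias.
* The screen generator's PAM activities and bin profiles are free knobs;
  absolute enrichment magnitudes in simulations are not calibrated to any
  measured screen.
* The mapper tolerates at most one mismatch and no indels.
* Scan values are uncalibrated ranks; comparing absolute values across
  samples with very different guide counts is not meaningful.
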