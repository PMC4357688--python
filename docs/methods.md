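# Methods

This note records the models, parameter choices and numerical conventions
behind `mipkit`, and what the synthetic-data tests do and do not establish
about behavior on real sequencing data.

## Arm thermodynamics

Melting temperatures use the unified nearest-neighbor model for DNA/DNA
duplexes: ΔH° and ΔS° are summed over the 10 unique dinucleotide stacks
(the other 6 resolve by reverse-complement symmetry) plus one initiation
term per terminal base pair (A·T: +2.3 kcal/mol, +4.1 cal/mol·K; G·C:
+0.1, −2.8). Self-complementary sequences receive the −1.4 cal/mol·K
symmetry entropy and use C_T instead of C_T/4. The monovalent-salt
correction 0.368·(N−1)·ln[Na⁺] is applied to ΔS°.

Defaults: **C_T = 0.25 µM**, **[Na⁺] = 50 mM**, R = 1.987 cal/(mol·K).
These are conventional probe-hybridization figures, not measurements; all
constants sit on `ThermoModel` and can be swapped wholesale. The test suite
cross-checks the calculator against Biopython's independent `Tm_NN`
implementation at identical concentrations (agreement well inside 0.5 °C)
and verifies strand symmetry on 1000 random arms. Ambiguous bases are
refused — a candidate containing N is dropped at enumeration rather than
scored with an arbitrary stacking value.

## Tiling and arm geometry

Targets are tiled into `tile_length` = 100-bp tiles stepped by 50 bp. The
last tile is anchored to the region end; sub-100-bp regions (short exons
with splice junctions) get one tile centered on the region and expanded
symmetrically into flanking sequence. A region that would run off its
contig (including the 33-bp arm flank each side needs) is reported failed,
never fatal.

For arm length *l* ∈ {21..25} and shift *s* ∈ {0..4}, the arm's inner edge
sits *d* = (25 − *l*) + *s* bases outward from the tile boundary and the
arm extends *l* further bases outward. This is the one simple geometry in
which the 5 × 5 candidate grid per side produces gap-fill lengths
(100 + d_ext + d_lig) covering exactly 100–116 nt, which is therefore
adopted as the shift convention. The extension arm occupies the left
(upstream) flank and the ligation arm the right flank in Watson
coordinates; all Tm/GC figures are computed on the Watson strand — for a
duplex probe the complementary strand captures the opposite genomic strand
and is not separately scored.

Extension and ligation arms are selected **independently**, each minimizing
(|Tm − 60 °C|, |GC − 50%|, −*l*, *s*) lexicographically. Joint selection
(e.g. minimizing the arm-pair Tm spread) is a plausible alternative; the
independent rule is simpler, fully deterministic, and keeps the two sides'
failure accounting separable.

## Exclusion screen

A candidate is excluded if it (i) contains CTCTTC or GAAGAG, (ii) occurs
more than once in the genome, (iii) contains a homopolymer longer than 8
bases, or (iv) has GC outside (10%, 90%). Every candidate carries all
applicable flags, but the per-category failure counts attribute each
excluded candidate to its *first* failing criterion in the order above,
and a tile whose survivor set is empty is attributed to the majority
first-failing flag (ties in the same order).

Genomic redundancy is decided by **exact full-length occurrence counting**
on both strands, not by alignment: the criterion is perfect multi-placement,
and exact counting implements it directly and deterministically. Placements
are (contig, offset, strand) triples; a palindromic query names the same
duplex site on both strands, so its strand pair is collapsed and each site
counts once. The index anchors on 12-mers by default (correctness is
independent of the anchor length; it only trades memory against
verification work) and is validated against a naive overlapping-scan oracle
on random genomes.

## Precursor assembly

The precursor for microarray synthesis is, on the top strand:

    AmpF · spacer · CTCTTC · pad(1 nt) · [lig arm · backbone · barcode · ext arm] · pad(4 nt) · GAAGAG · spacer · AmpR

The 1-nt and 4-nt pads mirror EarI's (1/4) cut offsets so the top-strand
cuts land exactly at the MIP termini; assembly is verified by simulating
complete digestion and requiring the middle fragment to equal the MIP, and
by requiring exactly two recognition placements in the whole oligo. If a
junction accidentally creates a third site, pads are re-picked from
configured alternatives and the barcode redrawn. Primer, backbone and
spacer sequences are configurable placeholders validated to be
recognition-free; real panels would substitute their own amplification
chemistry here. Barcodes are 10 i.i.d. uniform bases drawn from a seeded
generator; collisions between probes are irrelevant (the dedup key is probe
× barcode) and collisions within a probe are tolerated at their natural
~1e-6 per-event-pair rate, exactly as in the wet assay.

## Capture simulator

The simulator emulates the statistical structure of a deeply sequenced
barcoded capture run. Per probe, the event count is
Poisson(mean_events × F) with F lognormal of unit mean; each event draws a
fresh barcode and, at heterozygous planted SNVs inside its gap-fill, either
allele with probability 1/2; each event is emitted as 1 + Geometric(r)
read pairs. Defaults (the simulated study conditions, chosen once):

| parameter | default | why |
|---|---|---|
| genome length | 50 kb | desk-scale; large enough that random 21–25-mers are unique |
| abundance σ | 1.3 | puts ≈60% of probes within a 10-fold abundance window, typical of un-rebalanced MIP panels |
| duplicate mean r | 2.45 | expected duplicate fraction r/(1+r) ≈ 0.71, typical of deep MIP sequencing |
| mean events/probe | 250 | a few hundred circles per probe, deep-capture scale |
| error rate | 1e-3 | Illumina substitution-error order of magnitude |
| read length | 150 | mates overlap across any 100–116-nt gap-fill |

The geometric duplicate model is memoryless and gives the closed-form
duplicate fraction used in the tests; real PCR duplication is
cycle-dependent and overdispersed. The simulator also omits indels, adapter
read-through, quality-by-cycle decay, chimeric/off-target capture and
strand biases — so a passing suite shows the *bookkeeping* (identification,
dedup, accounting, normalization) is exact under the stated model, not that
arm matching is robust to every artifact of real data.

## Read processing conventions

* **Arm matching**: R1 carries barcode (10 nt) then the extension arm; R2
  begins with the reverse-complemented ligation arm. Up to `max_mismatch`
  (default 1) mismatches per arm; the best total-mismatch probe must be
  unique, otherwise the pair is flagged ambiguous. An exact match on both
  arms short-circuits the scan (it cannot be beaten).
* **Gap-fill length**: inferred from the mate overlap. The probe's design
  length is tried first and kept if the implied R1/R2 overlap disagrees at
  ≤ 10% of positions; otherwise lengths within ±60 nt are scanned and the
  cleanest overlap wins (ties to the design length). Only 100–116-nt
  gap-fills are accepted as valid.
* **Merging**: where the mates overlap, the higher-quality base wins; ties
  go to R1. Uncovered gap positions (possible only with very short reads)
  become N with quality 0.
* **Dedup score**: "highest sum of base quality scores ≥ 15" is read
  Picard-style — the sum of those base qualities that are ≥ 15 — with the
  literal threshold reading (zero a pair whose total is < 15) available via
  `quality_mode="threshold"`. Score ties break to the lexicographically
  smallest pair id; output order is (probe, barcode), so dedup is
  deterministic and idempotent. Dedup runs pre-alignment on identified
  records; the key and score do not depend on mapping coordinates, so
  aligning first would change nothing.
* **Uniformity**: "fraction of probes within an f-fold range" is not a
  standard single definition; the default slides a log10 window of width
  log10(f) over the positive per-probe counts and reports the maximal
  contained fraction, with a median-centered window available via
  `method="median"`. Zero-count probes are excluded (undetected, not
  non-uniform).
* **Percent-unique at depth**: distinct keys in a seeded uniform subsample
  without replacement (default 2,000,000 reads), which normalizes
  circularized-product yield across conditions sequenced at different
  depths; it decreases in expectation as depth grows.

## Problem sizes in the shipped tests

The suite designs a 19-probe panel over a 1-kb region of a 50-kb random
reference, and the large simulated run uses ~25,000 events / ~50,000
molecules with error rate 0 and r = 1 (expected duplicate fraction 1/2,
checked within 3 binomial σ). The whole suite runs in well under a minute;
panel design at genome scale (hg-scale references, 10k-probe panels) is out
of the tested envelope, though nothing in the algorithms is quadratic in
genome length except index memory.

## Known limitations

* Redundancy screening is exact-match only; near-perfect paralogous sites
  that a permissive aligner would flag are not excluded.
* Common-SNP-aware arm design is not implemented; probes overlapping sample
  variants are only *flagged* downstream (`flag_arm_variants`), with a
  covariate table exported for external regression of capture yield.
* No consensus building across duplicates — the best pair is kept and the
  rest discarded; consensus calling would be preferable for low-input or
  degraded samples.
* Alignment, indel realignment and genotype calling are intentionally out
  of scope; the processor emits deduplicated gap-fill FASTQ for external
  tools.
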