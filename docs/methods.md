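# Methods

`coldscreen` implements the computational analysis of a pooled,
barcoded insertional-mutagenesis screen for cold acclimation in a
haploid microalga, together with a synthetic-data generator that
emulates the screen's design so that every stage of the pipeline can be
validated against known ground truth.

## Screen design and the statistic

The pooled mutant library (sample **CK1**) is split into two arms:
serial dilution and regrowth under control conditions gives **CK2**;
four days of growth at 10 °C gives **S10**; two consecutive recovery
cultures *from S10* give **S10R** (recovery descends from the
cold-stressed pool, not from CK1). Each mutant carries one randomly
integrated cassette with a unique internal barcode; sequencing a
barcode-PCR amplicon per sample measures each mutant's relative
abundance (its read count divided by the sample's recognized-read
total).

Screening statistic, per barcode:

    r_ctrl = (CK2/CK1),  r_cold = (S10/CK1)   (relative abundances)
    rr     = (r_cold + ε) / (r_ctrl + ε),     ε = 0.001

Barcodes with CK1 count ≥ 50 are retained; `rr > 3` (strictly) calls an
enriched hit, `rr < 0.3` (strictly) a depleted hit. Hits split into two
groups: **group 1** — constitutive growth defect relatively rescued in
cold (enriched, with `log2(r_ctrl + ε)` below a cut, default −1);
**group 2** — normal growth at control temperature but strong inhibition
specifically in cold (depleted, at or above the cut). S10R ratios are
reported (`r_rec`) but take no part in hit calling.

Numerical conventions worth stating:

* The ε = 0.001 offset is standard for log2 plotting of such ratios; we
  also apply it inside `rr` (numerator and denominator) so that barcodes
  with a zero count in one arm remain classifiable instead of producing
  0/0 or infinities. Without the offset a zero-S10 barcode has rr = 0;
  with it, rr = ε/(r_ctrl + ε), still deeply below the 0.3 cut for any
  normally growing mutant, so the extension changes no qualitative call.
* Thresholds are strict inequalities; a barcode at exactly rr = 3 or
  rr = 0.3 is not a hit.
* The group-split cut (`group_split_log2 = −1.0` on `log2(r_ctrl + ε)`)
  is a package choice: the two groups are qualitative phenotype classes
  and any monotone cut on control-arm depletion separates them; the cut
  is config-exposed and recorded in every run summary.
* Normalisation is per-sample relative abundance only. Spike-in or
  median-of-ratios normalisation is out of scope; consequently `rr` is
  invariant under any per-sample depth rescaling (tested).

Gene-level aggregation keeps every hit barcode that has a unique,
non-intergenic insertion annotation, groups them by gene, and reports
the per-gene group composition (n_group1/n_group2, dominant group with
an explicit tie flag, tie → group 2) rather than forcing a single label:
one gene can legitimately host barcodes of both phenotype classes.
Overlap with an early cold-induced gene list is an exact string-match
membership test on gene identifiers.

## Barcode extraction

A barcode-PCR read is `upstream anchor + barcode + downstream anchor +
cassette backbone`. Extraction finds the leftmost best occurrence of
the upstream anchor allowing at most `max_anchor_mismatches`
substitutions (default 1), takes the next `barcode_len` bases, and
confirms the downstream anchor when the read reaches that far. Reads
failing extraction are tallied by reason (anchor-missing,
ambiguous-base, truncated); recognized + no-call = total always holds.
Base qualities are ignored — two fixed anchors plus a fixed barcode
length constrain calls far more than a quality cutoff would. No
error-correction collapsing of barcodes is applied by default; an
optional directional collapse (absorb a barcode into a Hamming-1
neighbour with ≥ 10× its count) is available but off, since sequencing
errors produce low-count orphan barcodes that the CK1 ≥ 50 filter
removes anyway.

## Insertion-locus mapping

Paired reads couple a cassette mate (barcode) with a genomic mate (the
flank adjacent to the insertion junction). Flanks are aligned with an
in-package k-mer seed-and-extend aligner: exact k-mers vote for a
(chromosome, strand, diagonal); candidates with ≥ `min_seed_hits` votes
are verified by ungapped comparison; loci within `max_mismatch_frac`
(default 0.1) of the flank length are ranked by score = matches −
mismatches. Per barcode, records vote for their unique-best locus;
votes within ±3 bp on the same chromosome and strand are pooled; the
modal locus is called `unique` when it has ≥ `min_support` (default 2)
records and ≥ `min_agree_frac` (default 0.8) of mapped records, with
`ambiguous` (tied mode), `conflicting` (insufficient majority/support)
and `unmapped` otherwise. Ambiguous/conflicting barcodes are excluded
from gene assignment but retained in outputs with their status.

Coordinate convention (the junction itself has no published
convention): `pos` is the 1-based genomic coordinate of the flank's
first base, i.e. the first genomic base adjacent to the cassette; `+`
flanks read rightward from `pos`, `−` flanks leftward.

Seed length default is k = 17 with `min_seed_hits = 2`: for 60 bp
flanks with up to two substitutions the longest error-free segment is
at least ⌈58/3⌉ = 20 bases, which guarantees two on-diagonal seeds for
any error placement (any k ≤ 19 does; 21 provably does not), while
4^17 ≈ 1.7×10^10 keeps spurious diagonals negligible even on genomes
orders of magnitude larger than the simulated ones. Gapped alignment,
split-read junction reconstruction and multi-insertion clones are
out of scope; the full-scan Hamming oracle in the tests bounds what the
seeded aligner can miss.

## Insertion annotation

Gene models carry one representative transcript per gene (longest mRNA,
ties by lexicographically smallest identifier); introns are the gaps
between consecutive exons; UTR features, when present, take precedence
over the exon intervals that contain them. A position is classified
into exactly one of six categories — `five_prime_UTR`, `exon`,
`intron`, `three_prime_UTR`, `potential_promoter`, `intergenic` — by
fixed priority: genic sub-feature > promoter window > intergenic. The
promoter window is the 1000 bp immediately upstream of the TSS,
strand-aware and inclusive at exactly 1000 bp ("within 1 kb" read as
≤ 1000); among several candidate genes the nearest TSS wins, ties by
gene identifier. Only the position enters the rule — insertion strand
is carried through but ignored, and annotation is measured from the
representative transcript's TSS. Both choices are deliberate
simplifications; isoform-aware annotation is a non-goal.

## The synthetic screen generator

The generator is first-class, tested code. It emulates, in order:

1. **Reference** — uniform-random chromosomes; non-overlapping gene
   models (2–4 exons of 200–400 bp, introns 100–300 bp, UTRs 60–150 bp,
   inter-gene gaps ≥ 1.5 kb so promoter windows have room), strands
   random. Infeasible packings are rejected at configuration time with
   the violated constraint named.
2. **Library** — `n_mutants` insertions placed uniformly over the
   genome, one unique barcode each (default 22 bases). Each mutant gets
   a fitness class: *cold-sensitive* (f_ctrl ∈ [0.9, 1.0],
   f_cold ∈ [0.05, 0.3] — the group-2 phenotype), *constitutive*
   (f_ctrl ∈ [0.05, 0.3], f_cold ∈ [0.9, 1.0] — group 1), or *neutral*
   (f = 1). Class fractions default to 5%/5%. The truth table records
   each mutant's annotation category computed by the same classifier
   the pipeline uses (single source of truth) and its expected screen
   outcome under the noiseless abundance model.
3. **Abundance evolution** — a mutant with relative fitness f over g
   population doublings multiplies by 2^(f·g) before renormalisation;
   CK1 is uniform; CK2 applies (f_ctrl, g_ctrl) to CK1, S10 applies
   (f_cold, g_cold) to CK1, S10R applies (f_ctrl, g_rec) to S10. The
   defaults g_ctrl = g_cold = g_rec = 6 doublings represent two serial
   dilution/regrowth rounds (control arm), four days of cold growth,
   and two recovery cultures; this minimal multiplicative model is the
   standard Bar-seq fitness model and reproduces near-undetectable
   depletion for low-fitness mutants (f_cold ≤ 0.3 over 6 doublings is
   a ≥ 18-fold relative drop).
4. **Sequencing** — per sample, `depth_per_sample` reads drawn
   multinomially from the abundance vector (default 2×10^5); per-base
   substitution noise at `subst_error_rate` (default 0.002); constant
   Phred+33 qualities. LEAP pairs are emitted for CK1 and S10R, the
   two samples used for locus mapping; flanks at chromosome ends are
   truncated and flagged in the truth table.

What the generator does **not** model — and hence what passing tests do
not demonstrate about real data: PCR amplification bias (a single
multinomial draw stands in for the whole amplify-and-sequence chain),
indels and chimeric reads, cassette-insertion sequence bias,
multi-insertion clones, index-hopping or cross-contamination, and
selection during library construction. The anchors and barcode length
are package defaults for synthetic data, not the (unpublished)
internals of any real cassette; real runs must configure them.

Determinism: every stage draws from `numpy.random.default_rng` streams
keyed by (stage, seed), so identical configurations give byte-identical
FASTA/GFF3/FASTQ/TSV outputs, and stages can be re-run in isolation.

## Validation strategy and problem sizes

The real screen's raw sequencing data are not deposited, so validation
is property-based on synthetic data, at sizes chosen to keep the whole
suite around a minute while leaving no interesting case untested:

* exact arithmetic on a hand-written 8-barcode count matrix, verified
  against independent `fractions.Fraction` recomputation, including the
  CK1 = 49 vs 50 filter boundary and a zero-S10 barcode under ε;
* annotation vs a brute-force interval scanner on a simulated 200 kb,
  30-gene chromosome (1000 random positions plus every gene's
  1000/1001 bp promoter boundary, both strands);
* flank mapping vs a full-scan Hamming aligner on a 20 kb genome for
  500 flanks with 0–2 substitutions, plus 100% locus recovery from a
  noiseless simulated screen;
* null calibration: all-neutral pools (1000 mutants, depth 10^5, three
  seeds) — each run's mean rr lies within 3 standard errors of 1 and
  essentially no depleted hits fire. Note the arithmetic mean of a
  ratio of counts carries a finite-depth Jensen bias of order
  +1/E[count] (~+0.01 at 100 reads/barcode); the per-run 3-SE band
  accommodates exactly this, and the depletion rule at 3.3-fold is far
  outside sampling noise at these depths;
* parameter recovery: 500 mutants, 5% cold-sensitive, 5% constitutive,
  depth 2×10^5, three seeds, run through the full read-level pipeline —
  recall of cold-sensitive genes and precision of group-2 calls both
  ≥ 0.9 (in practice 1.0), with constitutive mutants recovered as
  group 1; expected margins are pre-verified on the exact closed-form
  abundances before any sampling enters;
* conservation and determinism: read bookkeeping, column sums, depth
  rescaling invariance, byte-identical reruns.

`scripts/acceptance.py` recomputes all of these quantities from scratch
with a caller-supplied seed.

## Known limitations

* The two-group split and the gene-level dominant-group rule are
  reporting conventions over a qualitative description; alternative
  cuts are a config knob away and recorded in run metadata.
* The aligner is ungapped; an insertion-adjacent indel in a real flank
  would lower its score or leave it unmapped rather than shift the
  call.
* One representative transcript per gene; promoter windows measured
  from that transcript's TSS.
* The CLI's `--threads` flag is reserved; all stages are single-core
  and results never depend on it.
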