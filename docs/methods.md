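# Methods

## Problem and model

Spliceosomal introns interrupt coding sequence at positions that can be
compared across species once they are expressed in a coordinate system that
survives sequence divergence: the column of a protein multiple alignment.
The package implements that comparison for multi-copy gene families (its
defaults are shaped by the core-histone families H2A, H2B, H3 and H4 in
fungi, where two clades are intron-rich and two are nearly intronless).

### Intron coordinates

For an intron preceded by `o` coding nucleotides (`cds_offset`):

- phase `= o mod 3` — 0 between codons, 1 or 2 inside a codon;
- anchor residue `= ⌊o/3⌋` (0-based) — the first residue any of whose codon
  nucleotides lie downstream of the intron.

The single formula gives phase-0 introns the following residue and
phase-1/2 introns the interrupted residue, so every intron maps to exactly
one residue and hence one alignment column. Introns anchored at the stop
codon (`anchor = protein length`) cannot be projected; they stay in the
gene reports and are excluded from the site matrix with a warning.
Coordinates are 1-based inclusive on disk (GFF3, reports) and 0-based
half-open in memory. Coding structure derives from CDS features only, so
UTR introns are invisible by construction. Non-GT..AG boundaries are
accepted with a warning; genes whose CDS length is not a multiple of three
or contains an internal stop are excluded with a warning rather than
aborting a whole run.

### Insertion-site identity

Two introns share a site when their anchors land in the same column of the
family alignment. Phase is recorded on every site but is *not* part of site
identity by default, because comparison on an amino-acid alignment operates
at residue granularity; `site_identity="column+phase"` enables the stricter
definition. Anchors are used exactly as aligned — sites in adjacent columns
separated by gap runs are never merged. The alignment itself is an input;
each row must degap to its gene's protein exactly, or the run aborts.

### Hot spots

A site is a hot spot of a clade when it carries at least `hotspot_fraction`
(default 1/3) of all that clade's introns in the family. The denominator is
per clade *and* per family — not per species and not pooled across families
— since hot-spot counts are reported per family per clade. The comparison
`count/total ≥ p/q` is evaluated as `count·q ≥ total·p` in integers, so a
site holding exactly one third is a hot spot regardless of floating-point
representation. Clades are disjoint user-supplied labels. No significance
test is attached to hot spots; cross-clade comparison reports (a) sites that
are hot spots in both clades and (b) hot spots occupied by at least one
intron of the other clade.

### Sequence-similar intron pairs

All unordered intron pairs (across families too) are scored with
Smith–Waterman local alignment under affine gaps. Defaults are the classic
DNA scoring of the FASTA suite: match +5, mismatch −4, gap open −16 (the
open cost includes the first gapped position), gap extend −4; `N` scores as
a mismatch against everything including itself. The kernel is a
numba-compiled linear-memory Gotoh recursion; unit tests pin it against an
exhaustive brute-force maximization on short sequences and against
Biopython's `PairwiseAligner` on longer ones.

Significance is assessed per pair by permutation: the shorter sequence is
shuffled `n_shuffles` times (default 200; shuffling the shorter reduces the
variance of the null) and rescored. Two statistics are reported:

- `empirical_p = (r + 1)/(n + 1)` with `r` the number of shuffled scores
  `≥` observed — assumption-free;
- `evalue = n · P(S ≥ observed)` under a Gumbel (extreme-value)
  distribution fitted to the `n` shuffled scores by maximum likelihood —
  the expected number of shuffled comparisons reaching the observed score.

The selection cutoff (default E < 0.02) applies to the Gumbel E-value;
when the shuffled scores are degenerate (zero spread, no fit possible) the
empirical p substitutes for it. The Gumbel fit solves the profile-likelihood
equation for the scale by bracketed root finding (moment estimate as the
starting bracket, method-of-moments fallback); it matches
`scipy.stats.gumbel_r.fit` to ~3 decimals but runs in ~0.1 ms, which matters
at tens of thousands of pairs. Whole-sequence mononucleotide permutation is
the default shuffle; `window:<k>` shuffling (permutation within consecutive
k-nt blocks, preserving local composition) is available.

Retained pairs are classified three ways: same site in the same family,
different sites in the same family, different families. Pairs involving an
unprojectable intron are excluded from classification with a warning. No
multiple-testing correction is applied across pairs (the selection is a
descriptive screen, not an inference); reports carry a note. Per-pair
shuffle seeds derive from SHA-256 of the master seed and the sorted
intron-id pair, so results are independent of input order and bit-identical
across runs.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with planted
truth for every stage:

- **Defaults** (the study conditions): 4 clades × 6 species; families H2A,
  H2B, H3, H4; 1–4 paralogs per species × family; protein length 100–140
  residues; two intron-bearing clades (mirroring the intron-rich
  Pezizomycotina and Basidiomycota against two nearly intronless yeast
  lineages); 2 planted dominant sites per bearing clade × family, of which
  1 column is shared across the bearing clades; site occupancy 0.85; a
  private (single-gene, unique-column) intron per gene at rate 0.08, in all
  clades — the rare yeast intron analog; intron lengths log-normal
  (μ=4.3, σ=0.5 on the log scale, median ≈74 nt) clipped to [20, 250] nt
  with GT..AG ends; protein divergence 0.10 between clades and 0.03 within;
  intron divergence 0.08 from the per-(family, site, clade) ancestral
  sequence. These values were chosen once as a realistic moderate-divergence
  regime yielding a survey of roughly two hundred introns; they are
  parameters of `SimConfig`, not tuning knobs.
- **Protein evolution is substitution-only** (family ancestor → clade
  ancestor → paralog), so the true alignment is gap-free and emitted
  directly. This deliberately isolates site projection and hot-spot logic
  from aligner error; gap handling is exercised by unit tests with
  hand-gapped rows instead.
- **Gain/loss is Bernoulli occupancy** per gene per planted site, not an
  explicit branch process on a tree; a tree-based loss model would add
  realism but no additional coverage of the pipeline's contracts.
- **Homology truth**: introns at one (family, site, clade) descend from one
  ancestral sequence, each copy mutated independently at the intron
  divergence; shared sites get independent ancestral sequences per clade,
  so true homologous pairs are within-clade. Private introns are unrelated
  random sequences. Every private intron takes a fresh unused column, so
  the planted distinct-site count is exact by construction.
- **Hot-spot truth** is computed from realized (not expected) carrier
  counts with the same exact rational rule, through an independent counting
  path from the pipeline's. Config validation rejects settings whose
  expected per-site fraction cannot reach the hot-spot threshold.

What passing planted-recovery tests shows: the pipeline's bookkeeping
(coordinates, strand handling, projection, counting, thresholding, pair
significance) is exact under the generator's assumptions. What it does not
show: robustness to alignment error, indels, annotation noise, non-canonical
gene structures, or compositionally biased introns — real-data phenomena the
generator deliberately omits.

## Numerical and design choices

- Exact integer cross-multiplication for the hot-spot boundary; `Fraction`
  thresholds end-to-end.
- Smith–Waterman uses 64-bit integer scores; no overflow for any realistic
  intron lengths.
- Site order, gene order, report row order and JSON key order are all
  deterministic; no timestamps are written, making report bundles
  byte-comparable.
- `copy_label` (H2A_1, H2A_2, …) numbers copies by ascending genomic
  position (ties by contig name); it is cosmetic and never used in
  computation.
- The determinism and recovery checks run the full pipeline at a reduced
  problem size (4 clades × 2 species for determinism; the default
  survey-scale config, ~200–260 introns, for recovery) — sizes chosen to
  exercise every code path at desk scale.

## Known limitations

- Alignments are consumed, never computed or quality-checked; a poor input
  alignment silently shifts insertion-site columns.
- The shuffle E-value inherits PRSS-style semantics: it is calibrated per
  pair, and no correction is applied across the quadratic number of pairs.
- Trans-splicing, programmed frameshifts, annotation lifting and gene
  prediction are out of scope; input GFF3 is trusted.
- The ≥ 1/3 hot-spot rule is a descriptive threshold with no attached
  significance model.
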