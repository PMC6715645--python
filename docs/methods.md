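# Methods

## Scope and model

karyokit treats a karyotype as an object to be *estimated* from replicate
metaphase spreads. A spread delivers 2n unlabeled chromosomes, each a
(short-arm, long-arm) length pair in µm with optional satellite /
secondary-constriction / NOR flags. The estimation pipeline is:

1. **normalise** arms so long ≥ short (the swap never changes total length);
2. **pair homologs** within each spread;
3. **rank pairs** by size within each spread;
4. **average** rank-aligned pairs across spreads;
5. **classify** (Levan types, heteromorphism, formula, Stebbins class).

Published per-pair tables enter at step 5 directly.

## Classification conventions

**Levan intervals.** Arm-ratio cut points default to 1.7 / 3.0 / 7.0 with
*lower-inclusive* boundaries: m [1, 1.7), sm [1.7, 3.0), st [3.0, 7.0),
t [7.0, ∞). Lower inclusivity is the unique choice consistent with every
boundary value in the bundled published tables (1.70 typed sm, 3.00 st,
7.5 and 8.0 t). Thresholds are a parameter (`LevanThresholds`) because other
traditions place the m/sm cut at √2 or 2.

**Heteromorphism.** Default policy: a pair is heteromorphic iff its homologs
fall in different Levan classes. An optional stricter policy also flags
same-type pairs whose ratios differ by more than δ (default 0.4); it is off
by default because type-level heteromorphism is what comparative tables
report. The package deliberately does *not* conclude that heteromorphic
pairs are sex chromosomes; they are flagged with a free-text note only.

**Formula.** Homomorphic pairs contribute 1 to their type, each homolog of a
heteromorphic pair 0.5; the canonical string is ordered t, st, sm, m, zeros
omitted, halves printed as `.5`. Counts always sum to the pair number, and
fractional parts occur iff a heteromorphic pair exists.

**Stebbins class.** Row from the proportion p of chromosomes with arm ratio
strictly above 2 (p = 0 → 1; p ≤ ½ → 2; ½ < p < 1 → 3; p = 1 → 4); column
from the largest/smallest ratio s (s < 2 → A; 2 ≤ s ≤ 4 → B; s > 4 → C).
p is computed over all 2n homologs by default (each heteromorphic homolog
counted separately); the per-pair "any homolog" convention is available and
gives identical classes on the bundled data. p is kept as an exact
`Fraction` so the closed boundaries p = 0, ½, 1 are decided without float
fuzz. Column B is closed ([2, 4]); no bundled case sits on s = 4. The class
is invariant to uniform scaling of all lengths because both p and s are.

## Pairing and ranking

Pairing is minimum-cost perfect matching on the complete graph over a
spread's complement with

    cost(i, j) = w_len·|relLen_i − relLen_j| + w_ratio·|log r_i − log r_j|

(defaults w_len = w_ratio = 1). Relative lengths (not µm) make the cost
condensation-invariant; the log on ratios makes 2-vs-4 and 1-vs-2
equidistant. The exact optimum is found by the blossom algorithm
(networkx `min_weight_matching`) for 2n ≤ 64 — an assignment-problem
reduction is not sound here because a symmetric assignment solution need
not be an involution — with a greedy sorted-adjacent fallback for larger
complements, labelled in `PairingResult.method`.

Ranks order pairs by decreasing mean length, ties broken by *increasing*
mean arm ratio, then input order. Note one consequence on the bundled
tetraploid: its heteromorphic pair ties another pair at relative length
1.89 and, having the larger mean ratio, ranks 28 rather than its printed
position 27. Formula and class are unaffected.

## Consensus averaging

Spreads carry no chromosome identity, so averaging is rank-based: each cell
is paired and ranked independently, then rank-k quantities are averaged
across cells. Relative lengths are computed per cell *before* averaging,
which removes the multiplicative condensation factor exactly (the consensus
is invariant to scaling any cell by c > 0 and to cell order). Arm ratios
are averaged on the log scale.

Within a pair the two homolog ratios are order statistics of noise unless
the pair is genuinely heteromorphic. Averaging the per-cell sorted ratios
separately would bias the upper one upward by roughly σ√(2/π) per cell — a
bias that does not shrink with more cells and that manufactures spurious
boundary-crossing heteromorphism. The consensus therefore splits homologs
(sorted by ratio) only when the mean within-pair log-ratio gap exceeds
`split_gap` (default 0.15 log units ≈ a factor 1.16; a real sm/m pair like
2.17 vs 1.67 has gap 0.26, while 2 % measurement noise contributes ≈ 0.03);
otherwise both homologs receive the pooled geometric mean. Fewer than 5
cells triggers a warning, reflecting the ≥ 5-spreads measurement
convention. A documented limitation of rank alignment: at high noise a
heteromorphic pair's rank can jitter between cells, diluting its gap.

Tetraploid comparisons: relative lengths are stored in the haploid-set
denomination (the convention of the published tables, whose tetraploid
column sums to ≈ 100); `monoploid_relative_lengths` exposes the per-genome
(haploid-set/2) rescale — values double for ploidy 4 — as an explicit
transform for diploid–tetraploid comparison.

## Rounding

All published-table comparisons round half-up at 2 decimals, applied to the
exact binary value of the computed quotient (`Decimal(x)`, not
`Decimal(repr(x))`): 5.51/2.00 is stored as 2.754999… and must report as
2.75 to agree with quotient tables computed in double precision. Internal
computation is never rounded.

## Synthetic metaphases

The generator (`SimSpec`) emulates the measurement structure of asymmetric,
modal plant karyotypes:

* pair k (1-based) has true length `largest_um · size_decay^(k−1)`;
  defaults 5.6 µm and 0.93 give largest/smallest = 0.93⁻¹⁵ ≈ 2.97, inside
  the 2.75–3.18 range typical of the diploid accessions;
* each pair's arm ratio is drawn uniformly inside its target Levan interval
  shrunk by a margin of 0.05 (telocentrics capped at ratio 9), so true
  types are never boundary-ambiguous under small noise;
* optionally one heteromorphic pair (rank, type_a, type_b) and a set of
  NOR-bearing ranks;
* per cell: one lognormal condensation scale s (σ default 0.15) multiplies
  every arm; each arm gets independent multiplicative lognormal noise with
  CV `noise_cv` (default 0.02, mean exactly 1); chromosomes are emitted in
  random order so the pipeline must re-pair them;
* satellite/constriction detection per NOR homolog with probability
  `sat_detect_base · exp(−coupling · max(1/s − 1, 0))` (defaults 0.5 and
  1.0): more condensed (shorter) spreads hide terminal constrictions, and
  at s = 1 a NOR pair shows the structure on exactly one homolog in ≈ 50 %
  of cells — the "visible in only one homolog" phenomenology.

All randomness flows from one `numpy` Generator keyed by `SimSpec.seed`
(cells from a child stream keyed by (seed, 1)), so bundles are
bit-reproducible.

What the generator does **not** emulate: overlapping/bent chromosomes and
segmentation error, chromatid asymmetry, satellite length (flags only;
satellite length is assumed included in the short arm), rDNA activity
biology, and between-cell aneuploidy. Passing recovery tests therefore
demonstrate correctness of the numerical pipeline under the stated noise
model, not robustness to microscopy artefacts.

**Problem sizes.** The recovery harness runs 16-pair diploid complements at
5 cells per accession (the measurement convention), 20 seeds for the
recovery-rate check and 200 random instances (2n ≤ 10) for the
exhaustive-matching oracle; these sizes match the study design while
keeping the whole suite fast.

## Degenerate inputs and numerical edges

* Arm ratios below 1 − 10⁻⁹ are rejected everywhere; ratios are re-ordered,
  not rejected, when arms are swapped.
* Odd complements are rejected at ingest (cannot pair), non-positive or
  missing arm lengths with row-numbered errors.
* Complements with 2n ≠ 16·ploidy warn (x = 16 is the basic number of the
  motivating genus) but proceed.
* Published relative-length columns that do not sum to ≈ 100 warn on
  construction rather than fail — several bundled accessions have this
  property (documented in `src/karyokit/data/NOTES.md`); the strict Σ = 100
  identity holds for everything the package computes itself.
* Exact rank ties are resolved deterministically (see above), so all
  outputs, including SVG idiograms, are byte-reproducible.

## Known limitations

* Rank-based consensus assumes the size order of pairs is stable across
  cells; very similar adjacent pairs can swap ranks under noise.
* The greedy pairing fallback ignores arm ratios entirely.
* Heteromorphism detection is type-level; a same-type size heteromorphism
  (as in satellited-pair size differences) is only caught with the strict
  policy enabled.
* The idiogram is a schematic (arm proportions and annotation positions),
  not a banding-resolution ideogram.
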