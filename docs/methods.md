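# Methods

This note documents the models and conventions implemented in `aprstat`, the
choices made where a convention was genuinely open, and what the synthetic
generators do and do not establish.

## Scope and inputs

APR annotations enter as interval tables; the package never runs an external
APR predictor. The bundled sliding-window hydropathy scorer (Kyte–Doolittle
scale, window 6, threshold 2.0 by default) is a *surrogate* for closed-loop
testing against planted synthetic APRs only; its outputs are tagged
`source=surrogate` everywhere and it makes no claim of reproducing any real
predictor's statistics. Disorder annotations, secondary-structure codes,
alignments and catalytic-site lists are likewise inputs, not computed.

## Sequence null models

* **Uniform random**: residues i.i.d. at 5% each.
* **Composition-matched random**: residues i.i.d. from a supplied 20-entry
  profile. The packaged natural profile (`F495_COMPOSITION`, the composition
  of a curated set of 495 small monomeric proteins) sums to exactly 1.
* **Scrambling** is implemented as the rejection procedure it models:
  residues of the parent are visited in random order and assigned to random
  positions of the output, redrawing on collisions. Property tests confirm
  the residue multiset is always preserved and that the procedure is
  empirically a uniform permutation generator. A library shuffle would be
  equivalent but would not exercise the algorithm itself.
* **Composition χ²** converts both profiles to counts per 1000 residues and
  returns the one-sample goodness-of-fit statistic Σ(O−E)²/E with the second
  argument as reference. This convention is adopted because it reproduces
  the published natural-vs-uniform value 160.84 exactly from the printed
  compositions; the statistic is deliberately asymmetric in its arguments.
  Categories empty in *both* profiles are skipped; observed mass on a
  zero-expected category is an error.
* **t-tests** default to the unequal-variance (Welch) form; the
  pooled-variance variant is available via `equal_var=True`. Two constant
  identical samples return (t=0, p=1) by definition.

## APR statistics

APR intervals are 1-based inclusive, minimum length 6, and must not overlap
within a source; intervals from different sources are never merged.
Gate-keeper frequencies at flank positions P_B−1…−3 / P_E+1…+3 use as
denominator the number of APRs for which that position exists — flanks
truncated by a terminus are excluded from numerator and denominator alike.
A residue flanking two adjacent APRs is counted once per APR (independent
per-APR counting). Dataset summaries (mean APR length, APR proportion,
sequence length) are computed over APR-containing sequences only.

## Conservation

Percent identity between aligned rows counts identical residues over
mutually non-gap columns (not any aligner's internal score). Homologue
filtering keeps rows with identity to the first (parent) row above the
threshold, optionally removing rows identical to the parent; the parent is
always retained. Each parent APR is located in a homologue via the parent's
aligned columns (never by substring search); gaps are removed from the
extracted variant. With `nAPR_total` = (#APRs)×(#rows) and `nAPR_uniq` =
Σ distinct variants per APR, conservation is
`100·(nAPR_total − nAPR_uniq)/nAPR_total`. This algebra yields 0 when every
variant is unique and approaches 100 for large perfectly conserved
families; for M rows its ceiling is `100·(M−1)/M`. Both parent-vs-each and
all-pairs mean identities are reported, as the convention behind published
"mean sequence identity" figures is ambiguous.

## Disorder contingency

Every residue is classified exactly once as (in/out of APR) ×
(disordered/ordered); residues not annotated disordered are assumed
ordered. Annotations extending beyond a sequence are a hard error (silent
clipping hides data corruption); overlapping disorder intervals merge with
a warning. The odds ratio is reported in both orientations (they are exact
reciprocals). Association uses Pearson χ² without continuity correction
plus a two-sided Fisher exact test; scipy's hypergeometric implementation
is fast even at ~2·10⁵ residues, so the exact test is always reported and
named in the output.

## Solvent accessibility and burial

SASA uses a Shrake–Rupley engine: deterministic golden-angle (Fibonacci)
spheres of 960 points per atom, probe 1.4 Å, Bondi-style van der Waals
radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å …; set recorded in
`structure.VDW_RADII`). Hydrogens are rejected at model construction;
hetero records are dropped on PDB read unless requested. Isolated atoms
evaluate to 4π(r+probe)² exactly; pairwise occlusion is validated against
the analytic spherical-cap formula within 1%, and biotite's independent
engine serves as a cross-check in tests. Because the point set is fixed,
removing occluders can only increase accessibility, so `TotSA ≥ SASAobs`
holds exactly and `Iso + SolvAcc/100 = 1` is an algebraic identity asserted
per segment.

Per-segment: `SASAobs` sums in-context residue ASA; `TotSA` re-runs the
same engine on the segment's atoms alone in the identical conformation;
`SASAexp` sums dataset-average per-type ASA. Sliding windows for the Iso
Z-score and RIso cover every window of the segment's length within runs of
consecutively numbered residues (chain breaks split runs); the segment's
own window is included in the mean and standard deviation. `sd = 0` leaves
the Z-score undefined (reported as None) while RIso is still returned.

Absolute ASA values from the original study's STRIDE-based computation
differ slightly from this engine; burial conclusions are therefore checked
as properties (identities, orderings, oracle agreement) rather than as
value matches to published distribution figures.

## Catalytic proximity

A catalytic residue contacts an APR when any of its heavy atoms is within
the cutoff (default 4.5 Å; 3.5 and 6.0 Å as variants) of a heavy atom of an
APR residue *other than itself* — self-pairs are ignored, so a residue
inside a multi-residue APR normally still counts as contacting. The decoy
null draws, per true site and per list, a uniform decoy from the standard
residues of the same chain (including the true residue and other catalytic
residues; `exclude_self` narrows this), optionally restricted to decoys
with ASA within ±10% of the true site's. Draws are independent with
replacement. The observed count is standardized against the per-list count
distribution: Z = (obs − mean)/sd. The default list count is 10⁴ (the
original analysis used 10⁶; the null mean and sd converge well before 10⁴
on the toy scales used here, and the count is configurable). Incidence
estimates round half away from zero for the headline integer; the raw
value is always reported.

## Synthetic generators

Defaults are the stated world of the analyses: 495 sequences, lengths
52–200 (mean 152, sd 34), natural background composition, ~0.9 APRs per
sequence with mean length 7.5 (min 6), gate-keeper flank occupancy 0.43
(≈ 2.6 gate-keepers per APR over six positions), 26.1% disordered residues,
target odds ratio 3.0, decoy contact proportion 0.4. APR windows are filled
from {V, I, L, F} weighted toward the β-branched pair, making them
recoverable by the hydropathy surrogate. Flank positions without a planted
gate-keeper are drawn from the background *excluding* gate-keepers, so the
planted rate equals the expected measured frequency exactly.

Disorder rates inside/outside APRs are solved (Brent root-finding) so the
*expected* table hits the target odds ratio at the stated coverage; the
realized table is emitted as ground truth. Toy structures use analytic
geometry (ideal helices on a triangular bundle plus a straight tail), so
the core-more-buried-than-tail ordering is provable rather than sampled.
Homologue families mutate columns independently at separate rates inside
and outside APR columns with no indels, and emit the exact distinct-variant
bookkeeping. What green synthetic tests establish is that each pipeline
stage recovers planted parameters at stated tolerances; they do not
establish agreement with any real corpus, predictor score distribution, or
crystallographic ASA.

## Numerical conventions and degenerate inputs

* One integer seed per invocation; all sub-draws derive from it
  (`numpy.random.default_rng` with spawned seed sequences); identical seed
  ⇒ byte-identical outputs.
* Ambiguity codes (B, J, O, U, X, Z) in input sequences raise by default;
  `drop_ambiguous` removes them.
* Zero-variance t-test inputs, zero-cell odds ratios (continuity-corrected
  on request), single-row alignments, sd = 0 Z-scores and empty APR tables
  all have defined, documented behaviours rather than NaN propagation.
* PDB reading takes the first model and the highest-occupancy altloc.

## Known limitations

* The surrogate predictor is intentionally crude; do not use it on real
  sequences in place of a validated predictor.
* Burial metrics require every segment residue to have coordinates; missing
  residues are an error, not an imputation.
* The decoy null treats "same protein structure" as "same chain"; widening
  to the full asymmetric unit is a flag away but changes the null.
* Conservation assumes the parent is alignable to every row
  (mutually non-gap columns exist); fully gapped pairs are an error.
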