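# Methods

This note records the models, algorithms and numerical choices behind
`seerfish`, and what the synthetic-data generators do and do not emulate.

## Barcoding model

Each taxon is encoded by an F-ary, length-R barcode: in round r the taxon's
probe carries the fluorophore of color `barcode[r]` (colors 1..F; three
colors map to FAM/Cy3/Cy5 in practice). The symbol 0 is reserved for
"no channel detected" in *observed* barcodes and never appears in a
codeword — for rRNA targets dropout is rare while off-target labeling is
not, so excluding the dark code removes the most likely confusion channel.

**Pool construction.** A codeword pool with pairwise Hamming distance
`>= min_hd` is built greedily: scan an ordering of all F^R words, keep a
word iff it is at distance `>= min_hd` from everything kept. The result is
maximal (every rejected word is within `min_hd` of a kept one) but
ordering-dependent, so `generate_pool` runs one lexicographic scan plus
seeded random shufflings (`restarts`) and returns the largest pool. For
F=3, R=8, HD 4 this reliably yields 60 codewords; the ordered assignment
count for 12 taxa, the falling factorial 60·59·…·49 ≈ 6.7 × 10²⁰,
is computed in exact integer arithmetic — it is what rules out exhaustive
codebook evaluation and motivates the genetic algorithm.

**Decoding rule.** With minimal distance 2k, an observed word is assigned
to the nearest codeword when the distance d\* is below k, or equal to k
with a unique nearest neighbor; otherwise it is unidentified. 0 symbols
count as mismatches. Odd minimal distances use k = floor(min_hd/2) with
the same uniqueness rule. Cells dark in more than 3 rounds are marked
lost before decoding. The vectorized decoder is checked in the test suite
against an exhaustive loop-based transcription of the rule over all 6561
zero-free length-8 ternary words.

## Hybridization intensity model

Hybridization efficiency follows the two-state isotherm
`E = e^(-ΔG/RT)·Cp / (1 + e^(-ΔG/RT)·Cp)` with R = 1.98720425 × 10⁻³
kcal·mol⁻¹·K⁻¹, default T = 319.15 K (46 °C) and Cp = 250 nM. It is
evaluated in log space so arbitrarily strong binding cannot overflow.

Probe–species pairs are classed by ΔG: specific at ΔG ≤ −13.0 kcal/mol,
background at ΔG ≥ −7.3, non-specific strictly between. The boundaries
are assigned to the outer classes because the non-specific band is defined
by strict inequalities. A cell of species i shows, in channel k of one
round, the sum over probes p present in that channel of lognormal draws
`10^N(μ_pi, σ_pi)`; in class mode μ is −0.3 / −0.9 / −2.0 (log10,
CCD-normalized, so −2 is 1% of detector range) with σ = 0.3, and in
measured mode μ and σ come from per-pair measurements. Draws are
independent per cell, per round and per probe. Channels carrying no probe
in a round receive a single background-class draw as a noise floor so the
arg-max is always defined; the floor is far below any class signal and
does not affect calling statistics measurably.

Simulated symbol calling is pure arg-max over channels (no dark symbol):
codewords contain no 0 and high-copy rRNA makes dropout negligible, so
simulation errors are color-to-color confusions only. Dropout is injected
explicitly where decoder behavior under 0 symbols is tested. Note that
even with perfectly specific probes the model produces a residual
~10⁻³ per-round confusion rate, because off channels sum several
background-class lognormal draws whose upper tail occasionally beats a
weak specific draw; over 12 × 1000 cells this leaves roughly zero to a
few two-error cells per run, which the HD4 decoder usually but not always
absorbs.

**Probe-candidate filter.** Candidates are kept iff 18–21 nt, GC fraction
0.45–0.60, at least 3 mismatches to every non-target sequence, and
on-target ΔG < −13.0 kcal/mol. ΔG values are inputs; computing them from
sequence is out of scope.

## Codebook optimization

The genetic algorithm scores a codebook by its simulated macro-F1:
simulate cells per taxon, call arg-max symbols, decode, evaluate. Each
generation keeps the 15 best codebooks, adds 12 mutants per elite (one
taxon's codeword replaced by a uniformly chosen unused pool codeword —
permuting symbols of a codeword would usually leave the pool, so redraw is
the only mutation that preserves the distance guarantee) and 5 fresh
random codebooks: population 200 = 15 + 180 + 5. All 200 are scored
together; because elites survive unchanged and scores are cached, the best
score trace is non-decreasing by construction. Scoring uses a smaller
simulation (default a few hundred cells per taxon) than final evaluation;
the fitness seed is derived from the codebook so a codebook's score is
stable across generations.

## Synthetic imaging and the pipeline

The generator plants ellipse cells (default semi-axes 1.0 × 0.35 µm,
uniform orientation) at random or Thomas-clustered positions, renders
per-round per-channel amplitudes from the intensity model, applies a
Gaussian point-spread blur (default σ = 1 px), additive Gaussian noise
(default sd 0.01, ~50× below a specific signal), optional shot noise, and
a per-round integer drift applied *circularly* (`np.roll`) so that
registration against the reference plane is exactly invertible and no
border information is lost. The reference plane renders cells dark
(−0.6) on a bright background (0.8), emulating phase contrast; root-style
stacks can instead segment an inverted universal-probe fluorescence
plane (`SegmentParams.invert=False`).

Pipeline stages and their numerical choices:

* **Registration** — integer, translation-only: the shift maximizing the
  circular cross-correlation of each round's reference plane against
  round 1, computed by FFT and exactly equal to the brute-force shift
  search (asserted in tests). Mean-subtraction removes the flat-offset
  bias; a zero-variance reference is an error.
* **Segmentation** — local (Gaussian-window, default 31 px) adaptive
  threshold with a required contrast of 0.05 over the local mean, hole
  filling, removal of components below 9 px, then watershed on the
  (σ = 1 px smoothed) distance transform with seeds at local maxima at
  least 5 px apart. This splits rod cells meeting tip-to-tip; two wide
  cells stacked side-by-side merge into one convex blob whose distance
  transform has a single peak — a known limitation shared with any
  distance-transform watershed, which is why the generators default to a
  3 µm minimum separation.
* **Extraction** — per-cell mean intensity and a pixel sample (capped at
  400 px/cell) per round and channel; the background sample is all
  out-of-label pixels subsampled to 10⁴. Ellipse axes and orientation
  come from second-moment region properties.
* **Symbol calling** — per round, each channel's cell pixel sample is
  compared with that channel's background sample by a one-sided Welch
  t-test (cell brighter, α = 0.05); no significant channel gives 0, else
  the significant channel with the greatest mean wins, ties broken toward
  the lowest channel index (and warned).
* **Decoding and matching** — lost rule, then the 2k decoder. Synthetic
  stacks are evaluated by matching each planted centroid to the segment
  covering it, so an over-segmented cell still counts as correctly
  identified while a missed or miscalled one does not.

## Spatial statistics

All spatial estimators operate on rasterized cell footprints (ellipses
drawn at the map's pixel size), so hit tests and coverage densities are
mutually consistent.

* **Coverage density** D is footprint area clipped to the region mask
  over mask area.
* **Linear-dipole correlation.** For each radius r, dipoles with uniform
  anchors and orientations are sampled until `n_dipoles` (default 10⁵)
  have both ends inside the mask; the hit probability P_r is the fraction
  whose ends land on cells of the two populations (either end assignment
  across taxa), and g(r) = P_r / (2 D_i D_j) across taxa or P_r / D²
  within one taxon. Under complete spatial randomness g = 1; the
  Monte-Carlo standard error is ≈ g/√(N·P_r), so calibration tests use
  maps with ~10% coverage where 10⁵ dipoles give ~3% precision. The
  optional confidence band bootstraps dipoles over an anchor-position
  grid (region resampling). Radii below the cell length are reported but
  dominated by same-cell hits (g ≫ 1 trivially for auto-correlation).
* **Contact frequency.** A contact is an intersection of 1-px-dilated
  footprints (a centroid-distance variant is available); frequency is
  events per µm² of mask. The null re-places every ellipse uniformly
  (positions and orientations) keeping per-taxon counts and axis lengths;
  significance is the empirical upper-tail p over `n_sims` placements,
  Bonferroni-corrected over tested pairs.
* **Association.** Co-occurrence counts cell pairs of two taxa with
  centroid distance ≤ 10 µm (configurable). The null permutes taxon
  labels over the same positions (abundances fixed), 100 permutations
  per root by default; the per-root fold is observed over the null mean,
  and the pooled empirical p compares the total observed count with
  permutation totals, Bonferroni over tested pairs. Pairs with fewer
  than 5 pooled observed events (configurable) are dropped as
  under-powered. With 100 permutations the smallest attainable p is
  1/101, so Bonferroni significance over many pairs requires raising
  `n_perm`.
* **Differential association** compares two groups of roots per pair:
  log2 fold change is the difference of mean per-root log2 folds, tested
  by a two-sided Welch t-test across roots and Bonferroni-corrected by
  the number of unique pairs detected (not dropped) across all roots in
  either group. Pairs absent or dropped in either group are flagged not
  applicable.

## Synthetic-data generators: what they do and do not show

The generators reproduce the statistical structure the estimators assume:
lognormal class intensities, ellipse cells, uniform or Thomas-process
layouts (with per-parent, shared, or paired taxon mixing; the paired-mode
`pair_fidelity` dial plants graded association strength). They do not
emulate autofluorescence, uneven illumination, sub-pixel or rotational
drift, dense biofilm packing, 3-D structure, or real probe ΔG spectra, so
passing tests demonstrate the correctness and calibration of the
algorithms — not instrument-level performance on real roots. The imaging
fixtures use 256 × 256 px fields with 48 cells and the spatial fixtures
400 × 400 px maps with 10³ cells, sizes chosen so each estimator's
Monte-Carlo error is small relative to the tested effect while the whole
suite runs in minutes on one core.

## Known limitations

* The greedy pool is maximal but not provably maximum; coding-theory
  bounds are out of scope.
* Registration is integer-translation only.
* The watershed cannot split side-by-side overlapping wide cells and the
  adaptive threshold expects a clean background.
* Association p-values are empirical and floor at 1/(n_perm + 1).
* Macro-averaged F1 treats taxa equally regardless of abundance;
  per-taxon values are always reported alongside.
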