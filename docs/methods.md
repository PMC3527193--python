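# Methods

This note records the conventions, numerical choices and limitations
behind `gwasfig`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genome coordinate layout

Each chromosome occupies a block of the global x axis whose length is its
*true marker span* — last minus first marker position in base pairs — not
a nominal chromosome length. Offsets are the cumulative sum of spans plus
a gap, so the recurrence `offset[k+1] = offset[k] + span[k] + gap` holds
in exact floating-point (every term is an integer span or the one fixed
gap value; the test suite asserts equality with `==`, not a tolerance).

* **Gap.** `gap_fraction` (default 0.005) times the summed span lengths
  is inserted between blocks purely for legibility; 0 gives strict
  contiguous tiling. The gap is cosmetic and explicit rather than an
  undocumented renderer behavior.
* **Ordering.** Chromosome labels that parse as integers sort
  numerically, remaining labels lexically after them, and the unknown
  chromosome always comes last. Labels are strings throughout; `0` (and
  the aliases `Un`, `UN`, `un`, `unknown`) mark the unknown chromosome.
* **Unknown chromosome.** Its markers are plotted at their sequential
  rank in file order — one marker per x unit — because their positions
  are meaningless. Its block length is therefore `n_markers − 1` rank
  units; the span object keeps the raw min/max positions as data facts
  but they play no role in x placement.
* **Degenerate spans.** A single-marker chromosome has zero span but
  still receives gap spacing so its point remains visible. With zero gap
  *and* zero span, adjacent offsets may coincide; layout validation
  requires non-decreasing rather than strictly increasing offsets for
  exactly this case.

## Value transforms and display filters

* **−log10 scale.** All P-value axes use −log10. P = 0 is accepted at
  read time; at transform time the policy either clamps it to a ceiling
  (default 50 −log10 units) or drops the marker. The ceiling is a display
  device, not a statistical claim.
* **Threshold vs cut-off.** The threshold P-value is drawn as a
  horizontal line (with optional shading of the band from 0 up to the
  line across the full x range — the shading extent was a genuinely open
  choice; a full-width band was chosen as the simplest assertable
  interpretation). The cut-off P-value *removes* markers with
  p > cutoff before plotting. The two are independent controls.
* **Proportional marker size.** Linear map of −log10(p) from the plotted
  trait's observed [min, max] onto [size_min, size_max] pixels; a
  degenerate range collapses to size_min. Monotonicity (smaller p never
  gets a smaller dot) is property-tested.

## Q-Q plots

Expected quantiles use the midpoint convention (i − 0.5)/N: it is
symmetric under rank reversal and avoids the edge bias of −log10 at the
extreme ranks. The i/(N+1) convention is implemented behind a flag for
comparison. The series pairs the i-th smallest observed P with the i-th
smallest expected quantile, emitted ascending in expected value, so both
arrays are sorted and permutation-invariant. No genomic-control lambda or
confidence band is computed.

## Figure specifications

Every builder returns a `FigureSpec` — series (x, y, axis, color, sizes,
symbols-vs-lines mode), axis descriptors, horizontal reference lines and
shaded bands — validated structurally (referential integrity of axes,
equal array lengths). Rasterization to PNG/SVG/PDF is a thin matplotlib
layer; identical spec + dimensions + format give byte-identical files
(SVG hash salt pinned, SVG/PDF dates stripped), which the tests assert by
checksum. Default aspect ratios: 2:1 Manhattan, 1:1 Q-Q, 4:3 others; all
overridable. Color "template1" is a two-color alternation and
"template2" a ten-color qualitative palette; both are documented
constants with no claim of fidelity to any other tool's colors.

The batch runner plans `n` Manhattan + `n` Q-Q + `n·c` chromosome jobs
(any kind can be disabled), writes deterministic
`trait__kind__chrom.ext` names plus a `MANIFEST.txt` index, and
overwrites existing files with a logged warning. The unknown chromosome
counts as one block of `c` because it receives its own chromosome
figure.

## Single-locus tests

The three per-marker tests use the standard biallelic cell-means
parameterisation with genotype classes g ∈ {0, 1, 2} (minor-allele
copies):

* genotypic — one-way ANOVA F across the classes present (2 numerator df
  when all three occur), against pooled within-class variance on n − k df;
* additive — contrast (ȳ₂ − ȳ₀)/2, two-sided t on the within df;
* dominance — contrast ȳ₁ − (ȳ₀ + ȳ₂)/2, likewise.

Markers with fewer than two classes (or, for the contrasts, a missing
class) get missing P-values rather than an error. When the residual
variance is exactly zero and the contrast is also zero the P-value is
defined as 1 (the constructed equal-means case). The implementation is
vectorised across markers; unit tests cross-check it marker-by-marker
against scipy's one-way ANOVA and statsmodels OLS contrast tests as
independent oracles. These tests are a documented emulation of a
single-locus analysis sufficient to generate structurally valid effect
tables; no two-locus (epistasis) machinery is included.

## Synthetic data

The P-value simulator draws sorted uniform positions per chromosome
(default 20 chromosomes × 500 markers over 100 Mb — a mid-density map
that keeps figures fast while leaving the Q-Q null band tight) and
independent uniform(0,1) P-values per trait; signal windows overwrite
P with 10^(−u), u uniform over the chosen −log10 strength range.
Unknown-chromosome fixtures get deliberately unsorted positions so the
sequential-order path is exercised. The genotype simulator draws
Hardy-Weinberg genotypes at uniform MAF in (0.05, 0.5) and phenotype
y = μ + Σ a(g−1) + d·1{g=1} + N(0, σ²), n = 200 individuals and 5,000
markers by default — the scale at which the null calibration checks run.
All generators are bit-reproducible under a fixed integer seed.

What the simulations do **not** emulate: linkage disequilibrium between
markers (genotypes are independent), population structure or relatedness,
case-control ascertainment, missing genotypes, and multi-trait
correlation. Passing calibration tests therefore demonstrates correctness
of the layout/transform/test machinery under idealised sampling, not
robustness of any association method on real data — the package draws
figures from P-values it is given; the simulators exist to make that
machinery testable end-to-end.

## Problem sizes in tests and the acceptance script

The worked-example batch (30 traits × 30 chromosomes × 1,000 markers,
960 figures) runs at 320-pixel width — figure count and structure, not
resolution, are what it verifies — and completes in roughly a minute on
one CPU. Calibration checks use 10⁴ uniform draws (Q-Q) and 5,000
markers × 200 individuals (type-I error), sizes at which 3-binomial-SE
bands are decisive yet runs take seconds.

## Known limitations

* The 100-trait cap applies to the summary format; effect tables have no
  trait cap but carry exactly three effects plus sample size.
* The converter is line-oriented and keeps fields verbatim; it does not
  re-type or validate values (that happens when the converted file is
  read as a table).
* No VCF/PLINK parsing; the converter is the documented bridge from
  other tools' output.
* Byte-stable rasterization is guaranteed within one environment
  (matplotlib/freetype versions pinned by the install), not across
  environments.
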