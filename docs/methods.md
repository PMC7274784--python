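# Methods

## The bin-plot model

All analysis operates on arcsinh-transformed intensities,
`t = asinh(v / c)`. The cofactor `c` compresses the instrument's linear
region near zero while behaving logarithmically for bright signal; it is
conventionally 50–200 for fluorescence data and 5 for mass cytometry.
`cytobin` defaults to 150 and records the per-channel cofactor in the
transformed table's metadata, because every downstream quantity — bin
width, positivity cutoffs, gate bounds — is expressed in transformed units
and is only reproducible when the cofactor travels with the analysis.
Negative post-compensation intensities are legal and pass through the odd,
strictly monotone transform unchanged. Spillover compensation, doublet and
dead-cell removal are assumed done upstream; the package deliberately
contains no compensation logic.

The X–Y plane of two markers is divided into square bins of width 0.2
transformed units. The grid is anchored at a fixed global origin (0, 0),
not at the data minimum: event (x, y) lands in bin
`(floor(x/w), floor(y/w))`, indices may be negative, and an event exactly
on an edge belongs to the higher bin (half-open convention). Anchoring at
a global origin is a deliberate choice — it makes bin (i, j) refer to the
same region of marker space in every sample, which is what allows bin
patterns to be compared across mice, experiments and concatenated cohorts.
The cost is that the grid is not adapted to any one sample's range; with a
0.2 width and arcsinh-scale data (~−0.5 to ~5) this is immaterial.

Per-bin statistics of the overlay marker Z: event count (density), Z⁺
frequency, mean of Z over all cells (MFI), mean of Z over Z⁺ cells only
(MFI⁺) and the relative standard error of the mean (RSEM = SEM/mean,
sample SD with n−1). Positivity is strict (`z > cutoff`, negativity
`z ≤ cutoff`); with two cutoffs per marker this yields well-defined
neg/low/hi trichotomies from half-open sub-ranges that partition the axis.
Cutoffs are in transformed units and would, on real data, be placed with
fluorescence-minus-one controls.

Validity rules: a bin needs `min_cells` total cells (default 10) for any
statistic to be displayed; MFI⁺ additionally needs `min_pos_cells`
positives (default 10) — otherwise the bin is drawn grey rather than
omitted, to distinguish "reliable but sparse positives" from "too few
cells altogether". Both minima are configurable; 5 is the customary
relaxation for sparse co-producer maps. RSEM is undefined (and the bin
invalid) for n < 2 or a non-positive bin mean: a relative error loses its
meaning at or below zero mean, and the package refuses to display it
rather than pick a sign convention. The RSEM statistic itself is the
certificate for the 10-cell rule: on synthetic cohorts the mean RSEM of
bins with ≥ 10 cells is strictly below that of smaller bins.

Quadrant percentages (black: quadrant/total, red: Z⁺/quadrant, green:
Z⁺/total, blue: Z⁺/total-Z⁺) are kept un-rounded internally; rounding to
one decimal happens only at display time. Quadrant membership uses
`x ≥ cutoff` for the high side, so the four quadrants partition the events
exactly.

Co-producer maps score each bin by the percentage of cells satisfying a
conjunction of signed predicates (`+` strictly above, `−` at or below the
marker's cutoff). A single positive predicate reduces exactly to the Z⁺
frequency statistic — a degenerate case the tests pin down.

`top_fraction` selects the `ceil(f · n⁺)` brightest Z⁺ cells; ties at the
boundary value are all included, making the selection deterministic and
order-independent at the price of occasionally exceeding the nominal
count (both sizes are recorded in the result's metadata).

The maximum-value bin of a table (`argmax_bin`) breaks value ties by cell
count and then by index: when several sparse bins saturate a frequency at
100%, the most populated one is the statistically preferable witness, and
the result does not depend on dict iteration order.

## Synthetic cohorts

The generator draws each subpopulation from a correlated Gaussian directly
in transformed space, adds optional Gaussian acquisition noise, and clips
at a floor (default −0.5) to mimic the small negative intensities that
survive compensation. Gaussians in transformed space — rather than
lognormal raw intensities — were chosen because every engine computation
happens post-transform and the ground truth stays analytic: the expected
Z⁺ fraction under any cutoff above the floor is a mixture of normal tail
probabilities (`expected_positive_fraction`), which the tests compare
against engine output under binomial 99% bounds. Clipping (not
reflection) keeps those tails exact for cutoffs above the floor.

Population counts are `round(fraction · n)` with the remainder assigned to
the largest population, so cohorts are exactly sized and deterministic
from the seed (`numpy.random.default_rng`).

The `lupus_like` preset emulates a gated CD4⁺CD44⁺ memory T-cell pool from
an autoimmune-prone mouse over seven markers (PD-1, IFN-γ, IL-21, TNF-α,
IL-2, IL-10, CXCR5): a 62% non-producing bulk, a 12% PD-1^hi
IL-10-enriched subset, a 10% PD-1^hi CXCR5⁺ follicular-helper-like subset,
an 8% PD-1^hi Th1-like subset, and the planted 8% PD-1^low IFN-γ^hi subset
co-expressing IL-21, TNF-α and IL-2 without CXCR5. Baseline modes sit at
0.2 (scale 0.25) and positive modes at 1.6–3.2 (scale 0.30), so every
positive/negative mode pair is separated by well over three pooled scales
and the preset cutoffs (placed between modes, as FMO controls would) are
unambiguous. Subset fractions of a few to ~10% echo the order of magnitude
of producing subsets in stimulated splenocytes; they are a modelling
choice, not a measurement.

What the preset does *not* emulate: spillover and spreading error,
acquisition-time drift, heavy-tailed or skewed populations, continuous
(rather than modal) marker gradients, and biological correlation
structure beyond what a user specifies per population. Tests passing on
this generator therefore certify the *engine's arithmetic and invariants*
— count conservation, oracle equivalence, pattern recovery, cutoff
robustness — not distributional realism of real cytometry files.

## Numerical choices

- Bin indices come from a vectorized `floor`; the brute-force test oracle
  re-derives membership from explicit interval comparisons and defers to
  the floor rule when floating-point rounding makes an edge ambiguous.
- Means and SDs are computed in float64 on transformed values; MFI is the
  arithmetic mean in transformed space (back-transforming to raw-scale
  means is deliberately out of scope).
- Bin-table CSVs serialize floats with `repr`, so export → import is
  bit-exact; invalid bins carry an empty value field. Grid metadata
  (markers, bin width, origin, minima, total events) rides in `#`-prefixed
  header lines.
- The FCS writer emits FCS 3.1 little-endian float32 (the reader also
  accepts float64 and unsigned-integer list mode), so write → read is
  exact at 32-bit precision; CSV event files round-trip in full float64
  precision (`%.17g` plus round-trip parsing).
- Rendering writes no volatile metadata, so identical tables and styles
  produce byte-identical images. The blue→yellow→red gradient is a
  monotone six-anchor interpolation; any monotone map would satisfy the
  contract, the anchors are an aesthetic choice. Automatic color limits
  anchor frequencies and densities at zero and MFI statistics at the data
  minimum; explicit limits are available for cross-panel comparability.
- 3D surfaces are exported as a rendered image plus a JSON grid (nulls for
  invalid bins) plus the bin-table CSV, keeping the underlying numbers
  alongside every figure.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on cohorts of 5 000–50 000
events; the brute-force oracle comparisons use 100 random tables of up to
500 events and up to 8 markers, and the planted-pattern check uses 20
independent 50 000-event cohorts. These sizes give the binomial bounds
used by the ground-truth tests comfortable power while keeping the whole
suite fast on a single CPU.

## Known limitations

- No automatic cutoff placement: cutoffs are inputs, as they come from
  FMO controls in practice.
- No compensation, unmixing, doublet/viability gating, clustering or
  embedding; the package starts from pre-processed, gated event tables.
- The FCS layer covers single-dataset list-mode files with float or
  unsigned-integer data — the subset exported by mainstream pre-processing
  tools — not the full standard (no multi-dataset files, no bit-packed
  widths, no log-amplifier $PnE decoding).
- Statistical comparison across groups of samples (beyond concatenation
  and shared-scale plotting) is out of scope.
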