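# cytobin

Bin-based pattern analysis and visualization of multi-parametric flow
cytometry data.

Conventional cytometry analysis collapses a marker to one threshold and
reports quadrant frequencies, which hides how a third marker's expression
is distributed *across* the two-dimensional landscape of two other markers.
`cytobin` implements the alternative used for dissecting polyfunctional
T-helper-cell responses: divide the X–Y plane of two markers (after
arcsinh transformation) into small equal-width bins and color each bin by a
statistic of a third marker Z, so that co-expression patterns — e.g. an
IL-21⁺ subset concentrated at PD-1^low IFN-γ^hi — become directly visible
and comparable across samples.

It is a library first (importable API plus `examples/`), with a thin
`cytobin` command-line tool on top for shell pipelines.

## Method

Intensities are transformed with `t = asinh(v / c)` (cofactor `c`, default
150, recorded per channel). The plane of markers X and Y is partitioned
into bins of width 0.2 × 0.2 transformed units anchored at a fixed origin,
so bin (i, j) covers `[0.2·i, 0.2·(i+1)) × [0.2·j, 0.2·(j+1))` and patterns
are comparable across samples. Per bin, with n cells and n⁺ cells whose
z exceeds the positivity cutoff (strict inequality):

- **density** — n;
- **freq_pos** — `100 · n⁺ / n`;
- **mfi_all** — mean of z over all n cells;
- **mfi_pos** — mean of z over the n⁺ positive cells ("relative
  expression level");
- **rsem** — relative standard error of the mean, `SEM(z) / mean(z)`
  (sample SD, n−1 denominator).

Bins with fewer than `min_cells` cells (default 10) carry no value; MFI⁺
additionally requires `min_pos_cells` positives (grey-bin rule).
Co-producer maps generalize `freq_pos` to conjunctions of predicates such
as IL-21⁺ ∧ CXCR5⁻. Quadrant summaries report, per quadrant around the
(x, y) cutoffs: the quadrant's share of all cells (black), the Z⁺ share
within the quadrant (red), the Z⁺ share of all cells (green) and the
quadrant's share of all Z⁺ cells (blue). A 3 × 3 category grid, top-fraction
selection of the brightest Z⁺ cells, neg/low/hi sub-range gating, FCS/CSV
I/O, sample concatenation and pseudo-color / 3D-surface rendering complete
the toolkit. A synthetic cohort generator with analytic ground truth makes
every computation testable without instrument data.

## Worked example

```sh
python examples/bin_plot_basics.py
```

generates a 50 000-event synthetic memory T-cell cohort with a planted
polyfunctional subset and prints:

```
341 occupied bins, 221 valid (>= 10 cells), 50000 events total
hottest bin: PD-1 in [1.4, 1.6), IFN-g in [2.6, 2.8) -> 100.0% IL-21+ of 256 cells
quadrant x-y-:  61.8% of cells (black),   0.0% IL-21+ within (red), ...
quadrant x+y+:  15.9% of cells (black),  49.7% IL-21+ within (red),  7.9% of all cells (green),  98.8% of all IL-21+ (blue)
```

The hottest IL-21 frequency bin falls at low-intermediate PD-1 and high
IFN-γ — the planted phenotype — while the quadrant numbers show how the
same cells would be summarized by conventional quadrant gating. The script
also writes the pseudo-colored bin plot (`il21_freq.png`). The other
examples cover co-producer maps, category grids with top-fraction
selection, cutoff robustness and 3D surfaces.

The same pipeline from the shell:

```sh
cytobin synth --preset lupus_like --n 50000 --seed 1 --out cohort/
cytobin binplot -i cohort/events.csv --x PD-1 --y IFN-g --z IL-21 \
    --stat freq_pos --cutoff PD-1=0.9 --cutoff IFN-g=1.4 --cutoff IL-21=1.3 \
    --out run/
```

writes `run/bin_table.csv`, `run/bin_plot.png` and `run/run_record.json`
(resolved config, input checksums, versions — enough to regenerate the
plot exactly).

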