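"""Cutoff robustness of bin patterns, and 3D surface export.

Shifting a positivity cutoff changes the absolute positive-cell
frequencies but barely moves the *pattern* of the bin map — the property
that makes bin plots comparable across samples whose cutoffs were placed
slightly differently.  Also exports the IL-21 frequency map as a 3D
surface with its underlying bin table.
"""

import os

from scipy.stats import spearmanr

from cytobin import (
    BinSpec,
    CutoffSet,
    bin_statistic,
    generate_events,
    lupus_like_cutoffs,
    lupus_like_preset,
    render_surface,
)

out_dir = os.environ.get("CYTOBIN_EXAMPLE_OUT", "example_output")
os.makedirs(out_dir, exist_ok=True)

cohort = generate_events(lupus_like_preset(n_events=50_000, seed=1))
base = lupus_like_cutoffs().cutoff("IL-10")

maps = {}
for c in (base - 0.1, base, base + 0.1):
    table = bin_statistic(
        cohort, "PD-1", "IFN-g", "IL-10", "freq_pos",
        CutoffSet(cutoffs={"IL-10": c}), BinSpec(),
    )
    maps[c] = {k: r.value for k, r in table.valid_bins.items()}
    overall = 100 * sum(r.n_pos for r in table.bins.values()) / table.total_events
    print(f"IL-10 cutoff {c:.1f}: overall IL-10+ = {overall:.2f}%")

for c in (base - 0.1, base + 0.1):
    common = sorted(set(maps[base]) & set(maps[c]))
    rho = spearmanr([maps[base][k] for k in common],
                    [maps[c][k] for k in common]).statistic
    print(f"rank correlation of bin maps, cutoff {base:.1f} vs {c:.1f}: "
          f"rho = {rho:.3f}")
print("-> the bin pattern is stable under cutoff shifts; with the preset's")
print("   well-separated modes even the absolute frequencies barely move.")

table = bin_statistic(
    cohort, "PD-1", "IFN-g", "IL-21", "freq_pos",
    lupus_like_cutoffs(), BinSpec(),
)
paths = render_surface(table, os.path.join(out_dir, "il21_surface.png"))
print("surface exports:", ", ".join(f"{k}={v}" for k, v in paths.items()))
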