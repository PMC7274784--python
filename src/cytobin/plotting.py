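"""Pseudo-colored bin plots and 3D surface exports.

Bin plots render each valid bin as a filled square at its footprint on the
transformed X-Y plane, colored by the bin statistic on a blue (low) ->
yellow (mid) -> red (high) gradient; co-producer maps use a monochrome
green scale instead.  Bins with too few cells are omitted entirely; bins
that fail only the positive-cell minimum (the MFI+ grey-bin rule) are drawn
grey.  Quadrant percentages are printed in the four corners in their
semantic colors (black / red / green / blue) and positivity cutoffs appear
as dashed guide lines.  Rendering is deterministic: the same table and
style produce byte-identical image files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap, Normalize  # noqa: E402

from .binning import BinStatTable, QuadrantSummary, export_bin_table  # noqa: E402
from .errors import ConfigError, EmptyInputError  # noqa: E402

__all__ = ["PlotStyle", "render_bin_plot", "render_surface", "pri_colormap",
           "green_colormap"]

_PRI_ANCHORS = ["#00005f", "#0040ff", "#00c0ff", "#ffff00", "#ff8000", "#d00000"]
_GREEN_ANCHORS = ["#f2fbf0", "#8fd08a", "#1a7a1a", "#003300"]


def pri_colormap() -> LinearSegmentedColormap:
    """Blue -> yellow -> red gradient for single-statistic bin plots."""
    return LinearSegmentedColormap.from_list("cytobin", _PRI_ANCHORS)


def green_colormap() -> LinearSegmentedColormap:
    """Monochrome green scale for co-producer frequency maps."""
    return LinearSegmentedColormap.from_list("cytobin_green", _GREEN_ANCHORS)


@dataclass(frozen=True)
class PlotStyle:
    """Appearance of a bin plot.

    ``scale_limits`` of None means automatic anchoring: (0, max) for
    frequency/density statistics and (min, max) for MFI statistics, so
    explicit limits are only needed for cross-panel comparability.
    """

    color_scale: str = "pri"          # "pri" or "green"
    scale_limits: tuple[float, float] | None = None
    invalid_color: str = "0.7"
    show_black: bool = True
    show_red: bool = True
    show_green: bool = True
    show_blue: bool = True
    cutoff_lines: tuple = ()          # (axis "x"|"y", value, dashed: bool)
    figsize: tuple[float, float] = (6.0, 5.4)
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.color_scale not in ("pri", "green"):
            raise ConfigError(f"unknown color scale {self.color_scale!r}")
        if self.scale_limits is not None:
            lo, hi = self.scale_limits
            if not lo < hi:
                raise ConfigError(
                    f"scale_limits must satisfy lo < hi, got ({lo}, {hi})"
                )

    def colormap(self) -> LinearSegmentedColormap:
        return pri_colormap() if self.color_scale == "pri" else green_colormap()


def _auto_limits(table: BinStatTable) -> tuple[float, float]:
    values = [r.value for r in table.bins.values() if r.value is not None]
    if not values:
        return (0.0, 1.0)
    lo, hi = min(values), max(values)
    desc = table.z_desc
    if desc.startswith(("freq_pos", "coproducer", "density")):
        lo = 0.0
    if hi <= lo:
        hi = lo + 1.0  # flat table: one color, no degenerate norm
    return (lo, hi)


def _grid(table: BinStatTable):
    """Dense value/validity grids spanning the occupied index range."""
    keys = list(table.bins)
    imin = min(i for i, _ in keys)
    imax = max(i for i, _ in keys)
    jmin = min(j for _, j in keys)
    jmax = max(j for _, j in keys)
    shape = (imax - imin + 1, jmax - jmin + 1)
    value = np.full(shape, np.nan)
    grey = np.zeros(shape, dtype=bool)
    for (i, j), rec in table.bins.items():
        a, b = i - imin, j - jmin
        if rec.valid and rec.value is not None:
            value[a, b] = rec.value
        elif rec.n >= table.bin_spec.min_cells:
            # enough cells but the statistic is unreliable (grey-bin rule /
            # undefined mean): shown grey rather than omitted
            grey[a, b] = True
    w = table.bin_spec.bin_width
    ox, oy = table.bin_spec.origin
    x_edges = ox + np.arange(imin, imax + 2) * w
    y_edges = oy + np.arange(jmin, jmax + 2) * w
    return x_edges, y_edges, value, grey


_QUAD_CORNERS = {
    # quadrant key -> (x-anchor, y-anchor, ha, va) in axes fraction
    "x-y-": (0.02, 0.02, "left", "bottom"),
    "x+y-": (0.98, 0.02, "right", "bottom"),
    "x-y+": (0.02, 0.98, "left", "top"),
    "x+y+": (0.98, 0.98, "right", "top"),
}


def _annotate_quadrants(ax, quadrants: QuadrantSummary, style: PlotStyle) -> None:
    families = [
        ("black_pct", "black", style.show_black),
        ("red_pct", "#c00000", style.show_red),
        ("green_pct", "#007000", style.show_green),
        ("blue_pct", "#0000c0", style.show_blue),
    ]
    for key, (xa, ya, ha, va) in _QUAD_CORNERS.items():
        stats = quadrants.quadrants[key]
        lines = [
            f"{getattr(stats, attr):.1f}"
            for attr, _color, show in families
            if show
        ]
        colors = [c for _a, c, show in families if show]
        # stack one line per family so each keeps its semantic color
        dy = 0.045 if va == "bottom" else -0.045
        y0 = ya
        for line, color in zip(lines, colors):
            ax.text(
                xa, y0, line, color=color, fontsize=8, fontweight="bold",
                ha=ha, va=va, transform=ax.transAxes,
            )
            y0 += dy


def render_bin_plot(
    table: BinStatTable,
    quadrants: QuadrantSummary | None = None,
    style: PlotStyle | None = None,
    path: str = "bin_plot.png",
) -> str:
    """Render a BinStatTable as a pseudo-colored bin plot; returns the path."""
    if not table.bins:
        raise EmptyInputError("cannot render an empty bin table")
    style = style or PlotStyle()
    limits = style.scale_limits or _auto_limits(table)
    x_edges, y_edges, value, grey = _grid(table)

    fig, ax = plt.subplots(figsize=style.figsize, dpi=style.dpi)
    cmap = style.colormap()
    norm = Normalize(vmin=limits[0], vmax=limits[1])
    mesh = ax.pcolormesh(
        x_edges, y_edges, np.ma.masked_invalid(value.T), cmap=cmap, norm=norm,
        shading="flat",
    )
    if grey.any():
        grey_layer = np.ma.masked_where(~grey.T, np.zeros_like(value.T))
        ax.pcolormesh(
            x_edges, y_edges, grey_layer,
            cmap=LinearSegmentedColormap.from_list(
                "grey", [style.invalid_color, style.invalid_color]
            ),
            shading="flat",
        )
    for axis, pos, dashed in style.cutoff_lines:
        kwargs = {"color": "black", "linewidth": 0.9,
                  "linestyle": "--" if dashed else "-"}
        if axis == "x":
            ax.axvline(pos, **kwargs)
        elif axis == "y":
            ax.axhline(pos, **kwargs)
        else:
            raise ConfigError(f"cutoff line axis must be 'x' or 'y', got {axis!r}")
    if quadrants is not None:
        _annotate_quadrants(ax, quadrants, style)
    ax.set_xlabel(f"{table.x_marker} (arcsinh units)")
    ax.set_ylabel(f"{table.y_marker} (arcsinh units)")
    ax.set_title(table.z_desc, fontsize=10)
    fig.colorbar(mesh, ax=ax, shrink=0.85)
    _save(fig, path, style.dpi)
    return path


def render_surface(table: BinStatTable, path: str = "surface.png") -> dict[str, str]:
    """3D surface of per-bin frequency or density, with data exports.

    Writes three files: the rendered image at ``path``, a JSON figure-data
    file (the dense grid with nulls for invalid bins) and the underlying
    bin table as CSV.  Returns the mapping of output kinds to paths.
    """
    desc = table.z_desc
    if not desc.startswith(("freq_pos", "coproducer", "density")):
        raise ConfigError(
            f"surface plots support frequency or density statistics, got {desc!r}"
        )
    if not table.bins:
        raise EmptyInputError("cannot render an empty bin table")
    x_edges, y_edges, value, _grey = _grid(table)
    xc = (x_edges[:-1] + x_edges[1:]) / 2
    yc = (y_edges[:-1] + y_edges[1:]) / 2
    X, Y = np.meshgrid(xc, yc)

    fig = plt.figure(figsize=(7, 5.6), dpi=150)
    ax = fig.add_subplot(projection="3d")
    Z = np.ma.masked_invalid(value.T)
    ax.plot_surface(X, Y, Z, cmap=pri_colormap(), edgecolor="none")
    ax.set_xlabel(table.x_marker)
    ax.set_ylabel(table.y_marker)
    ax.set_zlabel(desc)
    _save(fig, path, 150)

    stem = path.rsplit(".", 1)[0]
    json_path = stem + ".json"
    csv_path = stem + "_bins.csv"
    import json

    grid_json = {
        "x_marker": table.x_marker,
        "y_marker": table.y_marker,
        "z_desc": desc,
        "x_centers": [float(v) for v in xc],
        "y_centers": [float(v) for v in yc],
        "values": [
            [None if np.isnan(v) else float(v) for v in row] for row in value.T
        ],
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(grid_json, fh, indent=1)
        fh.write("\n")
    export_bin_table(table, csv_path)
    plt.close(fig)
    return {"image": path, "figure_json": json_path, "bin_table": csv_path}


def _save(fig, path: str, dpi: int) -> None:
    # strip volatile metadata so identical inputs give identical bytes
    if path.lower().endswith(".svg"):
        fig.savefig(path, dpi=dpi, metadata={"Date": None})
    else:
        fig.savefig(path, dpi=dpi)
    plt.close(fig)
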