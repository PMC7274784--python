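"""Fixed-width binning of a two-marker plane with per-bin overlay statistics.

The central idea: the X-Y plane of two markers (in arcsinh-transformed
units) is divided into equal square bins anchored at a fixed global origin,
and for every bin a statistic of a third (overlay) marker Z is computed:

``density``
    event count per bin (bins have equal area, so count is proportional
    to density).
``freq_pos``
    percentage of Z-positive cells (z strictly above the positivity
    cutoff) among the cells in the bin.
``mfi_all``
    mean transformed intensity of Z over all cells in the bin.
``mfi_pos``
    mean transformed intensity of Z over Z-positive cells only (the
    "relative expression level"); additionally requires a minimum number
    of positive cells to be considered reliable (grey-bin rule).
``rsem``
    relative standard error of the mean of Z — standard error (sample
    standard deviation, n-1 denominator) divided by the mean — used to
    certify per-bin statistical reliability.  Undefined for bins with
    fewer than two cells or a non-positive mean.

Bins with fewer than ``min_cells`` events are never assigned a value; the
default of 10 balances the detection of comparatively rare subpopulations
against statistical robustness, and 5 is a common relaxation for sparse
co-producer maps.

Because the bin grid is anchored at a fixed origin on the transformed axis
(not at the data minimum), bin patterns are directly comparable across
samples, experiments and concatenated cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InputError
from .events import EventTable

__all__ = [
    "BinSpec",
    "CutoffSet",
    "BinRecord",
    "BinStatTable",
    "QuadrantSummary",
    "CategoryGrid",
    "STAT_KINDS",
    "assign_bins",
    "bin_statistic",
    "coproducer_map",
    "quadrant_summary",
    "top_fraction",
    "category_grid",
    "export_bin_table",
    "read_bin_table",
]

STAT_KINDS = ("density", "freq_pos", "mfi_all", "mfi_pos", "rsem")

QUADRANT_KEYS = ("x-y-", "x+y-", "x-y+", "x+y+")


@dataclass(frozen=True)
class BinSpec:
    """Bin geometry and validity thresholds, in transformed units."""

    bin_width: float = 0.2
    origin: tuple[float, float] = (0.0, 0.0)
    min_cells: int = 10
    min_pos_cells: int = 10

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ConfigError(f"bin_width must be positive, got {self.bin_width}")
        if self.min_cells < 1 or self.min_pos_cells < 1:
            raise ConfigError("min_cells and min_pos_cells must be >= 1")


@dataclass(frozen=True)
class CutoffSet:
    """Per-marker positivity cutoffs (transformed units).

    Positivity is strict: a cell is Z-positive iff z > cutoff, negative iff
    z <= cutoff.  An optional hi-cutoff per marker defines neg/low/hi
    trichotomies: neg = (-inf, cutoff], low = (cutoff, hi], hi = (hi, inf).
    """

    cutoffs: Mapping[str, float] = field(default_factory=dict)
    hi_cutoffs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cutoffs", dict(self.cutoffs))
        object.__setattr__(self, "hi_cutoffs", dict(self.hi_cutoffs))
        for m, hi in self.hi_cutoffs.items():
            if m not in self.cutoffs:
                raise ConfigError(f"hi-cutoff for {m!r} without a base cutoff")
            if not self.cutoffs[m] < hi:
                raise ConfigError(
                    f"{m!r}: cutoff {self.cutoffs[m]} must be < hi-cutoff {hi}"
                )

    def cutoff(self, marker: str) -> float:
        if marker not in self.cutoffs:
            raise ConfigError(f"no positivity cutoff configured for {marker!r}")
        return float(self.cutoffs[marker])

    def has(self, marker: str) -> bool:
        return marker in self.cutoffs


@dataclass
class BinRecord:
    """Per-bin accounting: counts, the computed statistic, validity."""

    n: int
    n_pos: int
    value: float | None
    valid: bool


@dataclass
class BinStatTable:
    """2-D grid over the X-Y plane holding one statistic per bin."""

    x_marker: str
    y_marker: str
    z_desc: str
    bin_spec: BinSpec
    bins: dict[tuple[int, int], BinRecord]
    total_events: int
    quadrants: dict | None = None

    @property
    def valid_bins(self) -> dict[tuple[int, int], BinRecord]:
        return {k: r for k, r in self.bins.items() if r.valid}

    def bin_edges(self, key: tuple[int, int]) -> tuple[float, float]:
        i, j = key
        ox, oy = self.bin_spec.origin
        w = self.bin_spec.bin_width
        return (ox + i * w, oy + j * w)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), rec in sorted(self.bins.items()):
            x_low, y_low = self.bin_edges((i, j))
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "x_low": x_low,
                    "y_low": y_low,
                    "n": rec.n,
                    "n_pos": rec.n_pos,
                    "value": rec.value,
                    "valid": rec.valid,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["i", "j", "x_low", "y_low", "n", "n_pos", "value", "valid"],
        )


def assign_bins(
    events: EventTable,
    x_marker: str,
    y_marker: str,
    spec: BinSpec | None = None,
) -> np.ndarray:
    """Map each event to its (i, j) bin index on the X-Y plane.

    i = floor((x - origin_x) / bin_width), likewise j; half-open bins, so a
    value exactly on an edge belongs to the higher bin.  Indices may be
    negative for coordinates below the origin.
    """
    spec = spec or BinSpec()
    x = events.channel_values(x_marker)
    y = events.channel_values(y_marker)
    ox, oy = spec.origin
    i = np.floor((x - ox) / spec.bin_width).astype(np.int64)
    j = np.floor((y - oy) / spec.bin_width).astype(np.int64)
    return np.column_stack([i, j])


def _group_by_bin(idx: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Row indices of each occupied bin, keyed by (i, j)."""
    if len(idx) == 0:
        return {}
    order = np.lexsort((idx[:, 1], idx[:, 0]))
    sorted_idx = idx[order]
    change = np.any(np.diff(sorted_idx, axis=0) != 0, axis=1)
    starts = np.concatenate([[0], np.nonzero(change)[0] + 1, [len(idx)]])
    out: dict[tuple[int, int], np.ndarray] = {}
    for a, b in zip(starts[:-1], starts[1:]):
        key = (int(sorted_idx[a, 0]), int(sorted_idx[a, 1]))
        out[key] = order[a:b]
    return out


def _mean_sem_stats(z: np.ndarray, kind: str) -> tuple[float | None, bool]:
    """(value, defined) for the mean-based kinds on one bin's z-values."""
    if kind == "mfi_all":
        return float(np.mean(z)), True
    if kind == "rsem":
        if len(z) < 2:
            return None, False
        m = float(np.mean(z))
        if m <= 0:
            return None, False
        sem = float(np.std(z, ddof=1)) / math.sqrt(len(z))
        return sem / m, True
    raise AssertionError(kind)


def bin_statistic(
    events: EventTable,
    x_marker: str,
    y_marker: str,
    z_marker: str,
    kind: str,
    cutoffs: CutoffSet | None = None,
    spec: BinSpec | None = None,
) -> BinStatTable:
    """Compute one per-bin statistic of the overlay marker Z.

    ``freq_pos`` and ``mfi_pos`` require a positivity cutoff for Z; the
    others do not (when one is supplied anyway, n_pos is still recorded).
    Bins failing validity carry ``valid=False`` and no value.
    """
    spec = spec or BinSpec()
    cutoffs = cutoffs or CutoffSet()
    if kind not in STAT_KINDS:
        raise ConfigError(
            f"unknown statistic kind {kind!r}; expected one of {STAT_KINDS}"
        )
    needs_cutoff = kind in ("freq_pos", "mfi_pos")
    if needs_cutoff and not cutoffs.has(z_marker):
        raise ConfigError(f"statistic {kind!r} requires a cutoff for {z_marker!r}")
    z = events.channel_values(z_marker)
    pos = z > cutoffs.cutoff(z_marker) if cutoffs.has(z_marker) else None

    idx = assign_bins(events, x_marker, y_marker, spec)
    bins: dict[tuple[int, int], BinRecord] = {}
    for key, rows in _group_by_bin(idx).items():
        zb = z[rows]
        n = len(rows)
        n_pos = int(pos[rows].sum()) if pos is not None else 0
        valid = n >= spec.min_cells
        value: float | None = None
        if kind == "density":
            value = float(n)
        elif kind == "freq_pos":
            value = 100.0 * n_pos / n
        elif kind == "mfi_pos":
            valid = valid and n_pos >= spec.min_pos_cells
            if n_pos > 0:
                value = float(np.mean(zb[pos[rows]]))
        else:  # mfi_all, rsem
            value, defined = _mean_sem_stats(zb, kind)
            valid = valid and defined
        if not valid:
            value = None
        bins[key] = BinRecord(n=n, n_pos=n_pos, value=value, valid=valid)

    desc = f"{kind}({z_marker}"
    if cutoffs.has(z_marker):
        desc += f" > {cutoffs.cutoff(z_marker):g}"
    desc += ")"
    return BinStatTable(
        x_marker=x_marker,
        y_marker=y_marker,
        z_desc=desc,
        bin_spec=spec,
        bins=bins,
        total_events=events.n_events,
    )


def _predicate_mask(
    events: EventTable,
    predicates: Sequence[tuple[str, str]],
    cutoffs: CutoffSet,
) -> np.ndarray:
    mask = np.ones(events.n_events, dtype=bool)
    for marker, sign in predicates:
        if sign not in ("+", "-"):
            raise ConfigError(f"predicate sign must be '+' or '-', got {sign!r}")
        if not cutoffs.has(marker):
            raise ConfigError(f"co-producer predicate on {marker!r} without a cutoff")
        z = events.channel_values(marker)
        c = cutoffs.cutoff(marker)
        mask &= (z > c) if sign == "+" else (z <= c)
    return mask


def coproducer_map(
    events: EventTable,
    x_marker: str,
    y_marker: str,
    predicates: Sequence[tuple[str, str]],
    cutoffs: CutoffSet,
    spec: BinSpec | None = None,
) -> BinStatTable:
    """Per-bin frequency of cells satisfying a conjunction of +/- predicates.

    '+' means the marker is strictly above its cutoff, '-' at or below.  A
    single (Z, +) predicate reduces to ``bin_statistic`` with kind
    ``freq_pos``.  When cutoffs for the plane markers are available, the
    co-producer frequency per quadrant (relative to quadrant cells and to
    total cells) is attached as auxiliary information.
    """
    spec = spec or BinSpec()
    if not predicates:
        raise ConfigError("coproducer_map requires at least one predicate")
    sat = _predicate_mask(events, predicates, cutoffs)

    idx = assign_bins(events, x_marker, y_marker, spec)
    bins: dict[tuple[int, int], BinRecord] = {}
    for key, rows in _group_by_bin(idx).items():
        n = len(rows)
        n_sat = int(sat[rows].sum())
        valid = n >= spec.min_cells
        bins[key] = BinRecord(
            n=n,
            n_pos=n_sat,
            value=(100.0 * n_sat / n) if valid else None,
            valid=valid,
        )

    quadrants = None
    if cutoffs.has(x_marker) and cutoffs.has(y_marker) and events.n_events:
        quadrants = {}
        total = events.n_events
        for key, qmask in _quadrant_masks(events, x_marker, y_marker, cutoffs):
            nq = int(qmask.sum())
            ns = int((sat & qmask).sum())
            quadrants[key] = {
                "n": nq,
                "n_coproducer": ns,
                "pct_of_quadrant": 100.0 * ns / nq if nq else 0.0,
                "pct_of_total": 100.0 * ns / total,
            }

    desc = "coproducer(" + " & ".join(
        f"{m}{s}" for m, s in predicates
    ) + ")"
    return BinStatTable(
        x_marker=x_marker,
        y_marker=y_marker,
        z_desc=desc,
        bin_spec=spec,
        bins=bins,
        total_events=events.n_events,
        quadrants=quadrants,
    )


def _quadrant_masks(
    events: EventTable, x_marker: str, y_marker: str, cutoffs: CutoffSet
) -> Iterable[tuple[str, np.ndarray]]:
    """Quadrant membership: x below/at-or-above cutoff crossed with y."""
    x = events.channel_values(x_marker)
    y = events.channel_values(y_marker)
    cx, cy = cutoffs.cutoff(x_marker), cutoffs.cutoff(y_marker)
    x_hi, y_hi = x >= cx, y >= cy
    yield "x-y-", ~x_hi & ~y_hi
    yield "x+y-", x_hi & ~y_hi
    yield "x-y+", ~x_hi & y_hi
    yield "x+y+", x_hi & y_hi


@dataclass
class QuadrantStats:
    n: int
    n_pos: int
    black_pct: float  # quadrant cells / total cells
    red_pct: float    # Z+ in quadrant / quadrant cells
    green_pct: float  # Z+ in quadrant / total cells
    blue_pct: float   # Z+ in quadrant / total Z+ cells


@dataclass
class QuadrantSummary:
    """Four-quadrant auxiliary percentages around the (x, y) cutoffs.

    Semantics follow the pseudo-color display convention: black is the
    quadrant's share of all cells, red the Z-positive share within the
    quadrant, green the Z-positive share of all cells, blue the quadrant's
    share of all Z-positive cells.
    """

    x_marker: str
    y_marker: str
    z_marker: str
    x_cutoff: float
    y_cutoff: float
    z_cutoff: float
    total_events: int
    total_pos: int
    quadrants: dict[str, QuadrantStats]


def quadrant_summary(
    events: EventTable,
    x_marker: str,
    y_marker: str,
    z_marker: str,
    cutoffs: CutoffSet,
) -> QuadrantSummary:
    """Compute the black/red/green/blue percentage families per quadrant."""
    if events.n_events == 0:
        raise EmptyInputError("quadrant_summary requires at least one event")
    z = events.channel_values(z_marker)
    cz = cutoffs.cutoff(z_marker)
    pos = z > cz
    total = events.n_events
    total_pos = int(pos.sum())
    quads: dict[str, QuadrantStats] = {}
    for key, qmask in _quadrant_masks(events, x_marker, y_marker, cutoffs):
        nq = int(qmask.sum())
        np_q = int((pos & qmask).sum())
        quads[key] = QuadrantStats(
            n=nq,
            n_pos=np_q,
            black_pct=100.0 * nq / total,
            red_pct=100.0 * np_q / nq if nq else 0.0,
            green_pct=100.0 * np_q / total,
            blue_pct=100.0 * np_q / total_pos if total_pos else 0.0,
        )
    return QuadrantSummary(
        x_marker=x_marker,
        y_marker=y_marker,
        z_marker=z_marker,
        x_cutoff=cutoffs.cutoff(x_marker),
        y_cutoff=cutoffs.cutoff(y_marker),
        z_cutoff=cz,
        total_events=total,
        total_pos=total_pos,
        quadrants=quads,
    )


def top_fraction(
    events: EventTable,
    z_marker: str,
    cutoff: float,
    fraction: float,
) -> EventTable:
    """The highest-expressing fraction of Z-positive cells.

    Among cells with z strictly above the cutoff, returns the
    ceil(fraction * n_pos) cells of highest z; cells tied with the boundary
    value are all included, so the result can exceed the ceiling (the
    requested and actual sizes are recorded in meta).  No positive cells is
    not an error: the result is simply empty.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    z = events.channel_values(z_marker)
    pos = z > cutoff
    n_pos = int(pos.sum())
    if n_pos == 0:
        return events._subset(
            pos, top_fraction={"marker": z_marker, "fraction": fraction,
                               "n_pos": 0, "requested": 0, "selected": 0},
        )
    k = math.ceil(fraction * n_pos)
    # k-th largest positive value; all ties with it are included
    boundary = np.sort(z[pos])[::-1][k - 1]
    mask = pos & (z >= boundary)
    return events._subset(
        mask,
        top_fraction={
            "marker": z_marker,
            "fraction": fraction,
            "n_pos": n_pos,
            "requested": k,
            "selected": int(mask.sum()),
        },
    )


@dataclass
class CategoryGrid:
    """3x3 partition of the plane by two thresholds per axis.

    Category (a, b) holds events with x in the a-th x-interval and y in the
    b-th y-interval, a, b in {0 (low), 1 (mid), 2 (hi)}; intervals are
    half-open on the right, consistent with the gating convention.  For each
    requested marker two frequencies are reported per category: the positive
    share within the category and the positive share of the full parent
    population.
    """

    x_marker: str
    y_marker: str
    x_thresholds: tuple[float, float]
    y_thresholds: tuple[float, float]
    total_events: int
    counts: np.ndarray  # (3, 3) int, indexed [x_level, y_level]
    marker_freq: dict[str, np.ndarray]         # % positive within category
    marker_freq_of_parent: dict[str, np.ndarray]  # % positive of total

    def to_frame(self) -> pd.DataFrame:
        levels = ("low", "mid", "hi")
        rows = []
        for a in range(3):
            for b in range(3):
                row = {
                    "x_level": levels[a],
                    "y_level": levels[b],
                    "n": int(self.counts[a, b]),
                }
                for m in self.marker_freq:
                    row[f"{m}_freq_pct"] = self.marker_freq[m][a, b]
                    row[f"{m}_of_parent_pct"] = self.marker_freq_of_parent[m][a, b]
                rows.append(row)
        return pd.DataFrame(rows)


def category_grid(
    events: EventTable,
    x_marker: str,
    y_marker: str,
    x_thresholds: Sequence[float],
    y_thresholds: Sequence[float],
    markers: Sequence[tuple[str, float]] = (),
) -> CategoryGrid:
    """Partition events into nine expression-level categories."""
    xt = tuple(float(t) for t in x_thresholds)
    yt = tuple(float(t) for t in y_thresholds)
    for name, ts in (("x", xt), ("y", yt)):
        if len(ts) != 2 or not ts[0] < ts[1]:
            raise ConfigError(
                f"{name}_thresholds must be two ascending values, got {ts}"
            )
    x = events.channel_values(x_marker)
    y = events.channel_values(y_marker)
    ax = np.digitize(x, xt)  # 0: x < t1, 1: t1 <= x < t2, 2: x >= t2
    ay = np.digitize(y, yt)
    total = events.n_events
    counts = np.zeros((3, 3), dtype=np.int64)
    pos_masks = {}
    for m, c in markers:
        pos_masks[m] = events.channel_values(m) > float(c)
    freq = {m: np.full((3, 3), np.nan) for m in pos_masks}
    freq_parent = {m: np.zeros((3, 3)) for m in pos_masks}
    for a in range(3):
        for b in range(3):
            cat = (ax == a) & (ay == b)
            n = int(cat.sum())
            counts[a, b] = n
            for m, pm in pos_masks.items():
                np_cat = int((pm & cat).sum())
                if n:
                    freq[m][a, b] = 100.0 * np_cat / n
                if total:
                    freq_parent[m][a, b] = 100.0 * np_cat / total
    return CategoryGrid(
        x_marker=x_marker,
        y_marker=y_marker,
        x_thresholds=xt,
        y_thresholds=yt,
        total_events=total,
        counts=counts,
        marker_freq=freq,
        marker_freq_of_parent=freq_parent,
    )


def argmax_bin(table: BinStatTable) -> tuple[int, int]:
    """Index of the maximum-value valid bin.

    Ties on the value (common when sparse bins saturate a frequency at 100)
    are broken in favor of the bin with more cells — the statistically more
    reliable witness — then by the smallest (i, j), so the result is
    deterministic and order-independent.
    """
    valid = table.valid_bins
    if not valid:
        raise EmptyInputError("bin table has no valid bins")
    return min(
        valid,
        key=lambda k: (-valid[k].value, -valid[k].n, k),
    )


# ---------------------------------------------------------------------------
# Bin-table CSV export / import (bit-exact round trip)

_HEADER_KEYS = (
    "x_marker",
    "y_marker",
    "z_desc",
    "bin_width",
    "origin_x",
    "origin_y",
    "min_cells",
    "min_pos_cells",
    "total_events",
)


def export_bin_table(table: BinStatTable, path: str) -> None:
    """Write a BinStatTable as a delimited file that re-imports exactly.

    Metadata lines (``# key=value``) precede the header row; floats use
    ``repr`` so the round trip is bit-exact; invalid bins carry an empty
    value field.
    """
    spec = table.bin_spec
    meta = {
        "x_marker": table.x_marker,
        "y_marker": table.y_marker,
        "z_desc": table.z_desc,
        "bin_width": repr(spec.bin_width),
        "origin_x": repr(spec.origin[0]),
        "origin_y": repr(spec.origin[1]),
        "min_cells": spec.min_cells,
        "min_pos_cells": spec.min_pos_cells,
        "total_events": table.total_events,
    }
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for key in _HEADER_KEYS:
                fh.write(f"# {key}={meta[key]}\n")
            fh.write("i,j,x_low,y_low,n,n_pos,value,valid\n")
            for (i, j), rec in sorted(table.bins.items()):
                x_low, y_low = table.bin_edges((i, j))
                value = "" if rec.value is None else repr(rec.value)
                fh.write(
                    f"{i},{j},{repr(x_low)},{repr(y_low)},"
                    f"{rec.n},{rec.n_pos},{value},{rec.valid}\n"
                )
    except OSError as exc:
        raise InputError(f"cannot write bin table to {path!r}: {exc}") from exc


def read_bin_table(path: str) -> BinStatTable:
    """Re-import a bin table written by :func:`export_bin_table`."""
    meta: dict[str, str] = {}
    bins: dict[tuple[int, int], BinRecord] = {}
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read bin table {path!r}: {exc}") from exc
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("# "):
            key, _, val = line[2:].partition("=")
            meta[key] = val
        else:
            body_start = k
            break
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise InputError(f"{path!r}: missing bin-table metadata {missing}")
    for line in lines[body_start + 1 :]:
        if not line.strip():
            continue
        i, j, _x, _y, n, n_pos, value, valid = line.split(",")
        bins[(int(i), int(j))] = BinRecord(
            n=int(n),
            n_pos=int(n_pos),
            value=None if value == "" else float(value),
            valid=valid == "True",
        )
    spec = BinSpec(
        bin_width=float(meta["bin_width"]),
        origin=(float(meta["origin_x"]), float(meta["origin_y"])),
        min_cells=int(meta["min_cells"]),
        min_pos_cells=int(meta["min_pos_cells"]),
    )
    return BinStatTable(
        x_marker=meta["x_marker"],
        y_marker=meta["y_marker"],
        z_desc=meta["z_desc"],
        bin_spec=spec,
        bins=bins,
        total_events=int(meta["total_events"]),
    )
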