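"""Event tables and the elementary operations on them.

An :class:`EventTable` is the universal unit of data flow: an events x
channels matrix of fluorescence intensities (raw straight after ingest,
dimensionless after the arcsinh transform) with unique channel names, a
sample label and free-form metadata.  Metadata entries whose length equals
the number of events (e.g. ground-truth population labels, per-event sample
origin) are treated as per-event annotations and are subset and concatenated
alongside the matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

__all__ = [
    "EventTable",
    "TransformSpec",
    "GateSpec",
    "transform_events",
    "apply_gate",
    "concatenate",
]


def _check_channels(channels: Sequence[str]) -> None:
    if any(not isinstance(c, str) or c == "" for c in channels):
        raise FormatError("channel names must be non-empty strings")
    seen: dict[str, int] = {}
    for c in channels:
        seen[c] = seen.get(c, 0) + 1
    dupes = sorted(c for c, k in seen.items() if k > 1)
    if dupes:
        raise FormatError(f"duplicate channel names: {', '.join(dupes)}")


@dataclass
class EventTable:
    """Events x channels matrix with channel names and sample metadata."""

    data: pd.DataFrame
    sample_id: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_channels(list(self.data.columns))
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise FormatError(
                f"sample {self.sample_id!r}: event values contain NaN/Inf"
            )
        # normalise to a clean float frame with a positional index
        self.data = pd.DataFrame(
            values, columns=[str(c) for c in self.data.columns]
        )

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def channel_values(self, channel: str) -> np.ndarray:
        if channel not in self.data.columns:
            raise ConfigError(
                f"unknown channel {channel!r}; available: {', '.join(self.channels)}"
            )
        return self.data[channel].to_numpy()

    def _subset(self, mask: np.ndarray, **meta_updates) -> "EventTable":
        """Row subset that carries per-event metadata arrays along."""
        new_meta: dict = {}
        for key, val in self.meta.items():
            if _is_per_event(val, self.n_events):
                new_meta[key] = np.asarray(val)[mask]
            else:
                new_meta[key] = val
        new_meta.update(meta_updates)
        return EventTable(
            self.data.loc[mask].reset_index(drop=True),
            sample_id=self.sample_id,
            meta=new_meta,
        )


def _is_per_event(val, n: int) -> bool:
    return (
        isinstance(val, (list, tuple, np.ndarray, pd.Series))
        and len(val) == n
        and n > 0
    )


@dataclass(frozen=True)
class TransformSpec:
    """Per-channel arcsinh cofactors, in raw intensity units.

    Channels without an explicit entry use ``default_cofactor`` (150, the
    conventional choice for fluorescence cytometry).  The cofactor is an
    explicit recorded parameter because every downstream bin width and
    cutoff is interpreted in transformed units.
    """

    cofactors: Mapping[str, float] = field(default_factory=dict)
    default_cofactor: float = 150.0

    def __post_init__(self) -> None:
        for ch, cf in list(self.cofactors.items()) + [
            ("<default>", self.default_cofactor)
        ]:
            if not (cf > 0):
                raise ConfigError(f"cofactor for {ch!r} must be positive, got {cf}")

    def cofactor(self, channel: str) -> float:
        return float(self.cofactors.get(channel, self.default_cofactor))


@dataclass(frozen=True)
class GateSpec:
    """Conjunction of per-channel interval conditions, half-open [lower, upper).

    The half-open convention makes adjacent sub-ranges (e.g. PD-1 neg / low /
    hi) partition the axis without overlap.
    """

    conditions: tuple = ()

    def __post_init__(self) -> None:
        norm = []
        for cond in self.conditions:
            channel, lower, upper = cond
            lower = -math.inf if lower is None else float(lower)
            upper = math.inf if upper is None else float(upper)
            if not lower < upper:
                raise ConfigError(
                    f"gate on {channel!r}: lower bound {lower} must be < upper {upper}"
                )
            norm.append((str(channel), lower, upper))
        object.__setattr__(self, "conditions", tuple(norm))

    def describe(self) -> str:
        return " & ".join(
            f"{lo:g} <= {ch} < {hi:g}" for ch, lo, hi in self.conditions
        ) or "<all events>"

    def conjoin(self, other: "GateSpec") -> "GateSpec":
        return GateSpec(self.conditions + other.conditions)


def transform_events(raw: EventTable, spec: TransformSpec | None = None) -> EventTable:
    """Apply the inverse hyperbolic sine transform channel-wise.

    Each value v becomes asinh(v / cofactor(channel)).  The map is strictly
    monotone and odd, so negative post-compensation intensities pass through
    with their sign preserved.
    """
    spec = spec or TransformSpec()
    out = raw.data.copy()
    for ch in raw.channels:
        out[ch] = np.arcsinh(out[ch].to_numpy() / spec.cofactor(ch))
    meta = dict(raw.meta)
    meta["transform"] = {ch: spec.cofactor(ch) for ch in raw.channels}
    return replace(raw, data=out, meta=meta)


def apply_gate(events: EventTable, gate: GateSpec) -> EventTable:
    """Keep the events satisfying every gate condition (lower <= v < upper)."""
    mask = np.ones(events.n_events, dtype=bool)
    for channel, lower, upper in gate.conditions:
        v = events.channel_values(channel)
        mask &= (v >= lower) & (v < upper)
    return events._subset(
        mask, gate=gate.describe(), parent_events=events.n_events
    )


def concatenate(samples: Sequence[EventTable]) -> EventTable:
    """Stack samples into one pooled EventTable, first sample's rows first.

    All samples must share an identical *ordered* channel list; the per-event
    origin is retained in ``meta['origin']`` so pooled bin patterns remain
    traceable to their source sample.
    """
    if not samples:
        raise ConfigError("concatenate requires at least one sample")
    ref = samples[0].channels
    for s in samples[1:]:
        if s.channels != ref:
            raise ConfigError(
                f"channel mismatch: {ref} vs {s.channels} (order matters)"
            )
    if len(samples) == 1:
        return samples[0]
    data = pd.concat([s.data for s in samples], ignore_index=True)
    origin = np.concatenate(
        [np.repeat(s.sample_id, s.n_events) for s in samples]
    )
    meta: dict = {"origin": origin}
    # per-event metadata shared by all inputs is concatenated too
    common = set(samples[0].meta)
    for s in samples[1:]:
        common &= set(s.meta)
    for key in sorted(common):
        vals = [s.meta[key] for s in samples]
        if all(_is_per_event(v, s.n_events) for v, s in zip(vals, samples)):
            meta[key] = np.concatenate([np.asarray(v) for v in vals])
    return EventTable(
        data,
        sample_id="+".join(dict.fromkeys(s.sample_id for s in samples)),
        meta=meta,
    )
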