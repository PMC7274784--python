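"""Reading and writing event files.

Two on-disk forms are supported: FCS 3.0/3.1 list-mode files (the field's
native export format) and plain CSV event tables (header row of channel
names, one event per row) as the portable, diffable alternative.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import fcs
from .errors import FormatError, InputError
from .events import EventTable

__all__ = ["read_events", "write_events", "detect_format"]


def detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".fcs":
        return "fcs"
    if ext in (".csv", ".txt", ".tsv"):
        return "delimited"
    raise InputError(f"cannot infer format of {path!r}; pass format explicitly")


def read_events(path: str, format: str | None = None) -> EventTable:
    """Read a raw (untransformed) EventTable from an FCS or delimited file.

    Channel names come from stain names ($PnS) when present, else detector
    names; event order is preserved.  Duplicate channel names are a format
    error, unreadable files an input error naming the path.
    """
    format = format or detect_format(path)
    sample_id = os.path.splitext(os.path.basename(path))[0]
    if format == "fcs":
        values, names = fcs.read_fcs(path)
        return EventTable(pd.DataFrame(values, columns=names), sample_id=sample_id)
    if format == "delimited":
        try:
            frame = pd.read_csv(path, header=0, float_precision="round_trip")
        except OSError as exc:
            raise InputError(f"cannot read event file {path!r}: {exc}") from exc
        except Exception as exc:  # malformed CSV
            raise InputError(f"cannot parse event file {path!r}: {exc}") from exc
        # pandas mangles duplicate headers to 'CD4.1'; detect from the raw header
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").rstrip("\r")
        raw_names = [h.strip() for h in header.split(",")]
        dupes = sorted({n for n in raw_names if raw_names.count(n) > 1})
        if dupes:
            raise FormatError(
                f"{path!r}: duplicate channel names: {', '.join(dupes)}"
            )
        frame.columns = raw_names
        non_numeric = [
            c for c in frame.columns
            if not np.issubdtype(frame[c].dtype, np.number)
        ]
        if non_numeric:
            raise FormatError(
                f"{path!r}: non-numeric channel(s): {', '.join(non_numeric)}"
            )
        return EventTable(frame, sample_id=sample_id)
    raise InputError(f"unknown format {format!r} (expected 'fcs' or 'delimited')")


def write_events(events: EventTable, path: str, format: str | None = None) -> None:
    """Write an EventTable as FCS 3.1 (float32) or CSV (full precision)."""
    format = format or detect_format(path)
    if format == "fcs":
        fcs.write_fcs(path, events.values, events.channels)
    elif format == "delimited":
        events.data.to_csv(path, index=False, float_format="%.17g")
    else:
        raise InputError(f"unknown format {format!r} (expected 'fcs' or 'delimited')")
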