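"""Tucson decadal (.rwl) ring-width file reader/writer.

The Tucson convention: series identifier in columns 1-8, the year of the
first value on the line, then up to ten integer width values per line,
aligned to decade boundaries. Units are 0.001 mm when the series ends with
the -9999 terminator and 0.01 mm when it ends with 999 (dialect
auto-detected per series from its terminator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RingWidthSeries", "read_rwl", "write_rwl"]


@dataclass
class RingWidthSeries:
    """Ring widths (mm) for a single measured radius."""

    series_id: str
    first_year: int
    widths: np.ndarray  # mm, one per contiguous year
    tree_id: str = ""
    site: str = ""
    vigor: str = ""  # "ND" or "D"

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths < 0):
            raise ValueError(f"negative ring width in {self.series_id}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def __len__(self) -> int:
        return len(self.widths)


def read_rwl(path) -> list[RingWidthSeries]:
    """Parse a Tucson .rwl file into one RingWidthSeries per identifier."""
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or not rest:
                raise ValueError(f"line {lineno}: malformed Tucson line")
            try:
                year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-numeric field in Tucson record") from None
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((year, vals))

    out = []
    for sid in order:
        chunks = sorted(raw[sid], key=lambda c: c[0])
        values: list[int] = []
        first_year = chunks[0][0]
        expect = first_year
        for year, vals in chunks:
            if year != expect:
                raise ValueError(
                    f"series {sid}: decade line starting {year} does not follow "
                    f"{expect}")
            values.extend(vals)
            expect = year + len(vals)
        if not values:
            raise ValueError(f"series {sid}: no values")
        term = values[-1]
        if term == -9999:
            scale = 0.001
        elif term == 999:
            scale = 0.01
        else:
            raise ValueError(
                f"series {sid}: missing terminator (-9999 or 999), got {term}")
        widths = np.array(values[:-1], dtype=float) * scale
        out.append(RingWidthSeries(series_id=sid, first_year=first_year,
                                   widths=widths))
    return out


def write_rwl(series: list[RingWidthSeries], path, precision: float = 0.001) -> None:
    """Write series in Tucson decadal format.

    ``precision`` 0.001 mm (terminator -9999) or 0.01 mm (terminator 999).
    """
    if precision == 0.001:
        term = -9999
    elif precision == 0.01:
        term = 999
    else:
        raise ValueError("precision must be 0.001 or 0.01")
    with open(path, "w") as fh:
        for s in series:
            vals = [int(round(w / precision)) for w in s.widths] + [term]
            year = s.first_year
            i = 0
            while i < len(vals):
                # fill to the next decade boundary
                upto = 10 - (year % 10)
                chunk = vals[i:i + upto]
                fh.write(f"{s.series_id:<8s}{year:4d}"
                         + "".join(f"{v:6d}" for v in chunk) + "\n")
                i += len(chunk)
                year += len(chunk)
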