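"""Marker-trajectory and result-table I/O.

The trajectory format is a plain tab-separated text export modelled on
optical motion-capture software: two header lines declaring the capture
frequency and the marker names, a column-header line, then one row per
frame with a time stamp and X/Y/Z columns (millimetres) per marker.

Missing samples are represented either as blank cells (default dialect)
or as all-zero triplets (``missing="zero"``); both are surfaced as a
per-marker gap mask rather than silently carried as coordinates.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("none", "orthosis", "therapist")
DIRECTIONS = ("flexion", "abduction")

#: float columns reported in degrees; rounded to one decimal on output
_DEGREE_KEYWORDS = ("theta", "kappa", "rho", "alpha", "angle", "deg")


@dataclass
class MarkerFrameSeries:
    """Timestamped 3D positions of named markers on a uniform time base.

    Parameters
    ----------
    sample_rate : float
        Capture frequency in Hz.
    times : ndarray, shape (n,)
        Frame times in seconds, uniformly spaced at ``1/sample_rate``.
    markers : mapping of str -> ndarray, shape (n, 3)
        Per-marker positions in millimetres, in insertion order.
    gaps : mapping of str -> ndarray of bool, shape (n,)
        True where the marker sample is missing. Defaults to no gaps.
    """

    sample_rate: float
    times: np.ndarray
    markers: dict[str, np.ndarray]
    gaps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-6):
                raise ValueError("times must be uniform at 1/sample_rate")
        n = len(self.times)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        for name, xyz in self.markers.items():
            if xyz.shape != (n, 3):
                raise ValueError(f"marker {name!r} has shape {xyz.shape}, expected {(n, 3)}")
        for name in self.markers:
            self.gaps.setdefault(name, np.zeros(n, dtype=bool))
        for name, mask in self.gaps.items():
            if name not in self.markers:
                raise ValueError(f"gap mask for unknown marker {name!r}")
            self.gaps[name] = np.asarray(mask, dtype=bool)
            if self.gaps[name].shape != (n,):
                raise ValueError(f"gap mask for {name!r} has wrong length")
        for name, xyz in self.markers.items():
            ok = ~self.gaps[name]
            if not np.all(np.isfinite(xyz[ok])):
                raise ValueError(f"non-finite coordinates in marker {name!r} outside gaps")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerFrameSeries):
            return NotImplemented
        if self.sample_rate != other.sample_rate or self.marker_names != other.marker_names:
            return False
        if not np.array_equal(self.times, other.times):
            return False
        for name in self.markers:
            if not np.array_equal(self.gaps[name], other.gaps[name]):
                return False
            ok = ~self.gaps[name]
            if not np.array_equal(self.markers[name][ok], other.markers[name][ok]):
                return False
        return True


@dataclass
class TrialMetadata:
    """Labels attached to one recorded elevation trial."""

    participant: str
    condition: str
    direction: str
    repetition: int
    block_index: int = 0
    force_level: Optional[int] = None
    bottle_mass: float = 0.0
    borg_rating: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.condition == "orthosis":
            if self.force_level is None or not 1 <= int(self.force_level) <= 6:
                raise ValueError("orthosis trials need force_level in 1..6")
        if self.borg_rating is not None and not 6 <= self.borg_rating <= 20:
            raise ValueError("borg_rating must lie on the 6-20 Borg scale")


# ---------------------------------------------------------------------------
# trajectory TSV


def write_markers_tsv(series: MarkerFrameSeries, path: str | Path) -> None:
    """Write a marker series in the package's TSV dialect.

    Missing samples are written as blank cells.
    """
    path = Path(path)
    names = series.marker_names
    with path.open("w") as fh:
        fh.write(f"FREQUENCY\t{series.sample_rate:g}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(names) + "\n")
        cols = ["TIME"]
        for name in names:
            cols += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
        fh.write("\t".join(cols) + "\n")
        for i in range(series.n_frames):
            row = [format(series.times[i], ".17g")]
            for name in names:
                if series.gaps[name][i]:
                    row += ["", "", ""]
                else:
                    row += [format(v, ".17g") for v in series.markers[name][i]]
            fh.write("\t".join(row) + "\n")


def read_markers_tsv(path: str | Path, missing: str = "blank") -> MarkerFrameSeries:
    """Parse a marker-trajectory TSV file.

    Parameters
    ----------
    path : path
        File with ``FREQUENCY`` and ``MARKER_NAMES`` header lines followed
        by a column-header line and one row per frame.
    missing : {"blank", "zero"}
        Dialect flag: how missing samples are encoded in the body. With
        ``"zero"``, an all-zero X/Y/Z triplet is flagged as a gap.

    Raises
    ------
    ValueError
        On a malformed header, ragged rows, or an unknown dialect.
    """
    if missing not in ("blank", "zero"):
        raise ValueError(f"unknown missing-value dialect {missing!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("malformed header: need FREQUENCY, MARKER_NAMES and column lines")
    head0 = lines[0].split("\t")
    head1 = lines[1].split("\t")
    if head0[0] != "FREQUENCY" or len(head0) != 2:
        raise ValueError("malformed header: first line must be 'FREQUENCY\\t<Hz>'")
    try:
        rate = float(head0[1])
    except ValueError as exc:
        raise ValueError("malformed header: frequency is not a number") from exc
    if head1[0] != "MARKER_NAMES" or len(head1) < 2:
        raise ValueError("malformed header: second line must declare marker names")
    names = head1[1:]
    ncol = 1 + 3 * len(names)
    if len(lines[2].split("\t")) != ncol:
        raise ValueError("malformed header: column line does not match marker names")

    body = lines[3:]
    times = np.empty(len(body))
    data = np.full((len(body), 3 * len(names)), np.nan)
    for i, line in enumerate(body):
        cells = line.split("\t")
        if len(cells) != ncol:
            raise ValueError(f"ragged row at frame {i}: {len(cells)} cells, expected {ncol}")
        times[i] = float(cells[0])
        for j, cell in enumerate(cells[1:]):
            if cell != "":
                data[i, j] = float(cell)

    markers: dict[str, np.ndarray] = {}
    gaps: dict[str, np.ndarray] = {}
    for k, name in enumerate(names):
        xyz = data[:, 3 * k : 3 * k + 3]
        gap = np.any(np.isnan(xyz), axis=1)
        if missing == "zero":
            gap |= np.all(xyz == 0.0, axis=1)
        xyz = xyz.copy()
        xyz[gap] = 0.0
        markers[name] = xyz
        gaps[name] = gap
    return MarkerFrameSeries(sample_rate=rate, times=times, markers=markers, gaps=gaps)


# ---------------------------------------------------------------------------
# result tables


def _record_to_dict(rec) -> dict:
    if isinstance(rec, Mapping):
        return dict(rec)
    if hasattr(rec, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(rec)
    raise TypeError(f"unsupported record type {type(rec)!r}")


def write_results_csv(
    records: Sequence, path: str | Path, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Write homogeneous result records to CSV with a stable column order.

    Angle-valued float columns (names containing theta/kappa/rho/alpha/
    angle/deg) are rounded to one decimal, matching how degrees are
    reported. An empty record list yields a header-only file; pass
    ``columns`` to fix the header when no record exists to infer it from.
    """
    path = Path(path)
    dicts = [_record_to_dict(r) for r in records]
    if dicts:
        cols = list(dicts[0])
        for d in dicts[1:]:
            if list(d) != cols:
                raise ValueError("heterogeneous records: differing fields or field order")
        if columns is not None and list(columns) != cols:
            raise ValueError("explicit columns disagree with record fields")
        df = pd.DataFrame(dicts, columns=cols)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    for col in df.columns:
        if df[col].dtype.kind == "f" and any(k in col.lower() for k in _DEGREE_KEYWORDS):
            df[col] = df[col].round(1)
    df.to_csv(path, index=False)
    return df


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def results_to_string(records: Sequence) -> str:
    """Render records as the CSV text ``write_results_csv`` would produce."""
    buf = io.StringIO()
    dicts = [_record_to_dict(r) for r in records]
    pd.DataFrame(dicts).to_csv(buf, index=False)
    return buf.getvalue()
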