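"""Recording I/O and the standard 19-channel 10–20 montage.

A :class:`Recording` is the in-memory container for multichannel EEG used
throughout the package: a (channels x samples) array of amplitudes in
microvolts, an ordered list of unique 10–20 channel labels, a sampling rate
in Hz and an optional frequency-band tag set once a recording has been
band-limited.

Two on-disk representations are supported:

* **EDF** — plain 16-bit EDF, read back through :mod:`mne`.  Writing uses a
  self-contained encoder (ASCII header + little-endian int16 records), so
  amplitudes round-trip only to within the 16-bit quantisation of each
  channel's physical range.
* **table** — a delimited numeric table (TSV or CSV) with one column per
  channel and a single header row of labels.  The sampling rate travels in a
  JSON sidecar ``<path>.json`` or is supplied explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MontageError",
    "Recording",
    "RegionSpec",
    "MONTAGE_19",
    "FRONTAL_CHANNELS",
    "PARIETO_OCCIPITAL_CHANNELS",
    "default_montage",
    "read_recording",
    "write_recording",
]


class MontageError(ValueError):
    """Raised for duplicate, unknown or otherwise invalid channel labels."""


#: The 19 standard 10–20 electrodes in canonical order (node numbers 1–19).
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
PARIETO_OCCIPITAL_CHANNELS: tuple[str, ...] = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

_CANONICAL = {label.lower(): label for label in MONTAGE_19}


def canonical_label(raw: str) -> str:
    """Map a raw channel label onto its canonical 10–20 spelling.

    Matching is case-insensitive with surrounding whitespace stripped
    (EDF headers vary in both).  Unknown labels raise :class:`MontageError`.
    """
    key = raw.strip().lower()
    if key not in _CANONICAL:
        raise MontageError(f"unknown 10-20 channel label: {raw!r}")
    return _CANONICAL[key]


@dataclass(frozen=True)
class RegionSpec:
    """A named scalp region: a non-empty subset of montage channels."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError(f"region {self.name!r} has no channels")
        canon = tuple(canonical_label(c) for c in self.channels)
        if len(set(canon)) != len(canon):
            raise MontageError(f"region {self.name!r} repeats a channel")
        object.__setattr__(self, "channels", canon)


@dataclass
class Recording:
    """Multichannel EEG: amplitudes (uV), labels, sampling rate, band tag."""

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(c).strip() for c in self.channel_labels)
        if not labels:
            raise ValueError("recording has no channels")
        if len({c.lower() for c in labels}) != len(labels):
            raise MontageError("duplicate channel labels")
        self.channel_labels = labels
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a (channels x samples) matrix")
        if data.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        self.data = data
        if self.band is not None:
            lo, hi = self.band
            if not (0 <= lo < hi):
                raise ValueError(f"invalid band tag {self.band}")
            self.band = (float(lo), float(hi))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        target = label.strip().lower()
        for i, c in enumerate(self.channel_labels):
            if c.lower() == target:
                return i
        raise MontageError(f"channel {label!r} not in recording")

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


def default_montage() -> tuple[tuple[str, ...], RegionSpec, RegionSpec]:
    """Return the canonical 19-channel order and the two analysis regions.

    The frontal and parieto-occipital regions each hold seven channels and
    are disjoint; central and mid-temporal channels belong to neither.
    """
    frontal = RegionSpec("frontal", FRONTAL_CHANNELS)
    parieto = RegionSpec("parieto-occipital", PARIETO_OCCIPITAL_CHANNELS)
    return MONTAGE_19, frontal, parieto


# ---------------------------------------------------------------------------
# Delimited-table format
# ---------------------------------------------------------------------------

def _table_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_table(path: Path, fs: float | None) -> Recording:
    df = pd.read_csv(path, sep=_table_sep(path))
    band = None
    if fs is None:
        side = _sidecar(path)
        if not side.exists():
            raise ValueError(
                f"no sampling rate: pass fs= or provide sidecar {side.name}"
            )
        meta = json.loads(side.read_text())
        fs = meta["fs"]
        if meta.get("band") is not None:
            band = tuple(meta["band"])
    labels = tuple(canonical_label(c) for c in df.columns)
    if len(set(labels)) != len(labels):
        raise MontageError(f"duplicate channel labels in {path.name}")
    return Recording(labels, float(fs), df.to_numpy(dtype=float).T, band=band)


def _write_table(rec: Recording, path: Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, sep=_table_sep(path), index=False, float_format="%.10g")
    meta = {"fs": rec.fs, "band": list(rec.band) if rec.band else None}
    _sidecar(path).write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# EDF format
# ---------------------------------------------------------------------------

def _fmt_field(value, width: int) -> bytes:
    if isinstance(value, float) and value == int(value):
        value = int(value)
    s = str(value)
    if isinstance(value, float) and len(s) > width:
        for prec in range(width - 2, 0, -1):
            s = f"{value:.{prec}g}"
            if len(s) <= width:
                break
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    n = rec.n_samples
    # 1-second records when they tile the data exactly, else one big record.
    if rec.fs == int(rec.fs) and n % int(rec.fs) == 0 and n >= rec.fs:
        n_records, duration, spr = n // int(rec.fs), 1.0, int(rec.fs)
    else:
        n_records, duration, spr = 1, n / rec.fs, n

    ns = rec.n_channels
    pmins, pmaxs, scaled = [], [], []
    dmin, dmax = -32767, 32767
    for row in rec.data:
        pmin, pmax = float(row.min()), float(row.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        gain = (dmax - dmin) / (pmax - pmin)
        digital = np.round((row - pmin) * gain + dmin).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled.append(digital)

    header = b"".join([
        _fmt_field(0, 8),
        _fmt_field("X X X X", 80),
        _fmt_field("Startdate X X X X", 80),
        _fmt_field("01.01.00", 8),
        _fmt_field("00.00.00", 8),
        _fmt_field(256 * (ns + 1), 8),
        _fmt_field("", 44),
        _fmt_field(n_records, 8),
        _fmt_field(duration, 8),
        _fmt_field(ns, 4),
    ])
    per_signal = [
        [_fmt_field(lbl, 16) for lbl in rec.channel_labels],
        [_fmt_field("AgAgCl electrode", 80)] * ns,
        [_fmt_field("uV", 8)] * ns,
        [_fmt_field(p, 8) for p in pmins],
        [_fmt_field(p, 8) for p in pmaxs],
        [_fmt_field(dmin, 8)] * ns,
        [_fmt_field(dmax, 8)] * ns,
        [_fmt_field("", 80)] * ns,
        [_fmt_field(spr, 8)] * ns,
        [_fmt_field("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.writelines(block)
        for r in range(int(n_records)):
            for digital in scaled:
                fh.write(digital[r * spr:(r + 1) * spr].tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(canonical_label(c) for c in raw.ch_names)
    if len(set(labels)) != len(labels):
        raise MontageError(f"duplicate channel labels in {path.name}")
    data = raw.get_data() * 1e6  # mne holds EEG in volts; we keep microvolts
    return Recording(labels, float(raw.info["sfreq"]), data)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

_TABLE_SUFFIXES = {".tsv", ".csv", ".txt", ".tab"}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in {"edf", "table"}:
            raise ValueError(f"unknown format {format!r}")
        return format
    if path.suffix.lower() == ".edf":
        return "edf"
    if path.suffix.lower() in _TABLE_SUFFIXES:
        return "table"
    raise ValueError(f"cannot infer format from suffix of {path.name!r}")


def read_recording(path, format: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from EDF or a delimited table.

    Parameters
    ----------
    path : path-like
    format : {"edf", "table"}, optional
        Inferred from the suffix when omitted.
    fs : float, optional
        Sampling rate for table files without a JSON sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    return _read_edf(path) if fmt == "edf" else _read_table(path, fs)


def write_recording(rec: Recording, path, format: str | None = None) -> Path:
    """Write a recording as EDF or a delimited table; returns the path."""
    if not isinstance(rec, Recording):
        raise TypeError("write_recording expects a Recording")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_table(rec, path)
    return path


# ---------------------------------------------------------------------------
# Labeled square matrices (connectivity etc.) as TSV
# ---------------------------------------------------------------------------

def write_matrix(labels: Sequence[str], values: np.ndarray, path) -> Path:
    """Write a labeled square matrix as TSV with row/column headers."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_matrix(path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{Path(path).name}: row/column labels disagree")
    return tuple(df.columns), df.to_numpy(dtype=float)
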