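"""Minimal European Data Format (EDF) writer/reader.

Plain EDF (not EDF+): fixed-width ASCII headers, one-second data records,
16-bit little-endian samples, per-channel physical scaling.  Only the
features this package needs are implemented: equal sampling rate across
channels and an integer number of one-second records.
"""

from __future__ import annotations

from datetime import datetime
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["write_edf", "read_edf", "EdfParseError"]

_HDR = 256  # bytes, fixed part and per-signal block


class EdfParseError(ValueError):
    """Malformed EDF file (with channel / record context where known)."""


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    labels: Sequence[str],
    physical_dimension: str = "uV",
    start: datetime | None = None,
) -> None:
    """Write ``data`` (channels x samples, in ``physical_dimension`` units)
    as plain EDF with one-second records.

    Each channel's physical range is auto-scaled symmetrically to its
    absolute maximum, so quantisation error is at most range/65534.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_sig, n_samp = data.shape
    if len(labels) != n_sig:
        raise ValueError("one label per channel required")
    if fs <= 0 or int(fs) != fs:
        raise ValueError("EDF one-second records need an integer sampling rate")
    fs_i = int(fs)
    if n_samp % fs_i != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n_samp // fs_i
    start = start or datetime(2000, 1, 1, 0, 0, 0)

    dig_min, dig_max = -32768, 32767
    # symmetric range with headroom; use the header-rounded (6 s.f.) value
    # for scaling so writing is the exact inverse of the reader's affine map
    phys_max = np.array(
        [float(f"{v:.6g}") for v in np.maximum(np.abs(data).max(axis=1), 1e-9) * 1.05]
    )
    span = dig_max - dig_min
    digital = np.clip(
        np.round((data + phys_max[:, None]) * span / (2 * phys_max[:, None]))
        + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    header_bytes = _HDR * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))                      # patient id
        fh.write(_field("Startdate X X X X", 80))            # recording id
        fh.write(_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))                             # record duration, s
        fh.write(_field(str(n_sig), 4))

        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in labels:
            fh.write(_field("", 80))                         # transducer
        for _ in labels:
            fh.write(_field(physical_dimension, 8))
        for ch in range(n_sig):
            fh.write(_field(f"{-phys_max[ch]:.6g}", 8))
        for ch in range(n_sig):
            fh.write(_field(f"{phys_max[ch]:.6g}", 8))
        for _ in labels:
            fh.write(_field(str(dig_min), 8))
        for _ in labels:
            fh.write(_field(str(dig_max), 8))
        for _ in labels:
            fh.write(_field("", 80))                         # prefiltering
        for _ in labels:
            fh.write(_field(str(fs_i), 8))
        for _ in labels:
            fh.write(_field("", 32))

        # record-major, signal-sequential layout
        for rec in range(n_records):
            sl = slice(rec * fs_i, (rec + 1) * fs_i)
            fh.write(digital[:, sl].tobytes())


def _read_fields(fh, count: int, width: int, what: str) -> List[str]:
    raw = fh.read(count * width)
    if len(raw) != count * width:
        raise EdfParseError(f"truncated header while reading {what}")
    try:
        return [
            raw[i * width:(i + 1) * width].decode("ascii").strip()
            for i in range(count)
        ]
    except UnicodeDecodeError as exc:
        raise EdfParseError(f"non-ASCII header field in {what}") from exc


def read_edf(path) -> Tuple[np.ndarray, float, Tuple[str, ...]]:
    """Read a plain EDF file -> (channels x samples physical data, fs, labels)."""
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR)
        if len(fixed) != _HDR:
            raise EdfParseError("file shorter than the fixed EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_dur = float(fixed[244:252].decode("ascii").strip())
            n_sig = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EdfParseError("malformed fixed header") from exc
        if n_sig <= 0:
            raise EdfParseError("no signals declared")

        labels = tuple(_read_fields(fh, n_sig, 16, "labels"))
        _read_fields(fh, n_sig, 80, "transducers")
        _read_fields(fh, n_sig, 8, "physical dimensions")
        phys_min = [float(v) for v in _read_fields(fh, n_sig, 8, "physical minima")]
        phys_max = [float(v) for v in _read_fields(fh, n_sig, 8, "physical maxima")]
        dig_min = [int(v) for v in _read_fields(fh, n_sig, 8, "digital minima")]
        dig_max = [int(v) for v in _read_fields(fh, n_sig, 8, "digital maxima")]
        _read_fields(fh, n_sig, 80, "prefiltering")
        spr = [int(v) for v in _read_fields(fh, n_sig, 8, "samples per record")]
        _read_fields(fh, n_sig, 32, "reserved")

        if len(set(spr)) != 1:
            raise EdfParseError("mixed per-channel sampling rates are not supported")
        fs = spr[0] / record_dur

        rec_samples = sum(spr)
        payload = np.frombuffer(fh.read(), dtype="<i2")
        if len(payload) < n_records * rec_samples:
            raise EdfParseError(
                f"truncated data: expected {n_records} records of "
                f"{rec_samples} samples, got {len(payload) // rec_samples}"
            )
        payload = payload[: n_records * rec_samples]

    records = payload.reshape(n_records, n_sig, spr[0])
    # int32: the (digital - dig_min) shift below overflows int16
    digital = np.moveaxis(records, 1, 0).reshape(
        n_sig, n_records * spr[0]
    ).astype(np.int32)
    data = np.empty(digital.shape, dtype=float)
    for ch in range(n_sig):
        span_d = dig_max[ch] - dig_min[ch]
        if span_d == 0:
            raise EdfParseError(f"channel {labels[ch]!r}: zero digital span")
        gain = (phys_max[ch] - phys_min[ch]) / span_d
        data[ch] = (digital[ch] - dig_min[ch]) * gain + phys_min[ch]
    return data, fs, labels
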