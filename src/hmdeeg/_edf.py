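"""Minimal EDF (European Data Format) codec: 16-bit signals, one data record.

Covers exactly what the benchmark needs — multichannel equal-rate signals in
microvolts — and nothing else.  The whole recording is stored as a single
data record, which EDF permits and which keeps the sample stream contiguous.
Event annotations are handled outside this module (sidecar TSV).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["read_edf", "write_edf", "EDFFormatError"]

_DIG_MIN, _DIG_MAX = -32767, 32767  # symmetric digital range


class EDFFormatError(ValueError):
    """Raised for files this codec cannot represent or parse."""


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EDFFormatError(f"header field {value!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for fmt in (f"%.{p}g" for p in range(10, 0, -1)):
        s = fmt % value
        if len(s) <= width and abs(float(s) - value) <= 1e-4 * max(1.0, abs(value)):
            return s.ljust(width).encode("ascii")
    raise EDFFormatError(f"value {value!r} not representable in {width} ascii chars")


def write_edf(path, data_uv: np.ndarray, fs: float, labels,
              start: _dt.datetime | None = None) -> None:
    """Write ``data_uv`` (channels x samples, µV) as a one-record EDF file.

    The per-channel physical range is the exact signal range, so the
    quantization step is (max-min)/65534; out-of-range values cannot occur
    by construction, and non-finite input raises instead of clipping.
    """
    data = np.asarray(data_uv, dtype=float)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise EDFFormatError("data must be channels x samples matching labels")
    if not np.all(np.isfinite(data)):
        raise EDFFormatError("signal contains non-finite values")
    n_ch, n_samp = data.shape
    if n_samp == 0:
        raise EDFFormatError("empty signal")
    if fs <= 0:
        raise EDFFormatError("sampling rate must be positive")
    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)

    header = bytearray()
    header += _field("0", 8)
    header += _field("X X X X", 80)                      # patient id
    header += _field("Startdate X X X X", 80)            # recording id
    header += _field(start.strftime("%d.%m.%y"), 8)
    header += _field(start.strftime("%H.%M.%S"), 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field("1", 8)                             # number of records
    header += _num_field(n_samp / fs, 8)                 # record duration (s)
    header += _field(str(n_ch), 4)

    for lab in labels:
        header += _field(lab, 16)
    header += b"".join(_field("", 80) for _ in range(n_ch))   # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))  # dimension
    for v in pmins:
        header += _num_field(v, 8)
    for v in pmaxs:
        header += _num_field(v, 8)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))   # prefilter
    header += b"".join(_field(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))   # reserved

    # re-read the ascii ranges so the stored scaling is exactly invertible
    pmins_q = np.array([float(_num_field(v, 8)) for v in pmins])
    pmaxs_q = np.array([float(_num_field(v, 8)) for v in pmaxs])
    pmins_q = np.minimum(pmins_q, pmins)
    pmaxs_q = np.maximum(pmaxs_q, pmaxs)
    scale = (pmaxs_q - pmins_q) / (_DIG_MAX - _DIG_MIN)
    dig = np.rint((data - pmins_q[:, None]) / scale[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(dig.tobytes())


def read_edf(path):
    """Read an EDF file; returns ``(data_uv, fs, labels)``.

    All channels must share one sampling rate; mixed-rate files (e.g. an
    embedded annotation channel) are rejected.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EDFFormatError("truncated EDF header")

    def txt(off, width):
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    header_bytes = int(txt(184, 8))
    n_records = int(txt(236, 8))
    rec_dur = float(txt(244, 8))
    n_ch = int(txt(252, 4))
    if len(raw) < header_bytes:
        raise EDFFormatError("truncated EDF header")

    off = 256

    def col(width):
        nonlocal off
        vals = [txt(off + i * width, width) for i in range(n_ch)]
        off += width * n_ch
        return vals

    labels = col(16)
    col(80)                       # transducer
    col(8)                        # dimension
    pmins = np.array([float(v) for v in col(8)])
    pmaxs = np.array([float(v) for v in col(8)])
    dmins = np.array([int(v) for v in col(8)])
    dmaxs = np.array([int(v) for v in col(8)])
    col(80)                       # prefilter
    nsamps = np.array([int(v) for v in col(8)])
    col(32)                       # reserved

    if len(set(nsamps.tolist())) != 1:
        raise EDFFormatError("channels have mixed sampling rates")
    n_samp = int(nsamps[0])
    if rec_dur <= 0:
        raise EDFFormatError("non-positive record duration")
    fs = n_samp / rec_dur

    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * n_ch * n_samp
    if payload.size < expected:
        raise EDFFormatError("truncated EDF payload")
    payload = payload[:expected].reshape(n_records, n_ch, n_samp)
    dig = np.concatenate([payload[r] for r in range(n_records)], axis=1).astype(float)

    scale = (pmaxs - pmins) / (dmaxs - dmins)
    data = (dig - dmins[:, None]) * scale[:, None] + pmins[:, None]
    return data, fs, labels
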