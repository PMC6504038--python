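"""A minimal EDF/EDF+ writer.

Only what the package needs: continuous single- or multi-channel signals at
one sampling rate, 16-bit quantization, and optional EDF+ annotation files
in the Sleep-EDF hypnogram dialect (one annotations-only file with
``Sleep stage X`` text events). Used to export synthetic recordings so the
EDF ingestion path can be exercised end-to-end without external downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_HEADER_DATE = "01.01.00"
_HEADER_TIME = "00.00.00"


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _signal_headers(fields: list[list[str]], widths: list[int]) -> bytes:
    # EDF stores each per-signal field for all signals consecutively
    out = b""
    for col, width in zip(zip(*fields), widths):
        for value in col:
            out += _field(value, width)
    return out


def write_edf(
    path,
    signals: dict[str, np.ndarray],
    sampling_rate: float,
    physical_dim: str = "uV",
) -> Path:
    """Write continuous signals to an EDF file.

    All signals share ``sampling_rate``; the record duration is 1 s.
    Amplitudes are quantized to int16 over each signal's observed range, so
    a round trip agrees with the input to within one quantization step.
    """
    path = Path(path)
    names = list(signals)
    data = [np.asarray(signals[n], dtype=np.float64) for n in names]
    n_per_rec = int(round(sampling_rate))
    n_records = min(len(d) for d in data) // n_per_rec
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")

    dig_min, dig_max = -32768, 32767
    phys_ranges = []
    for d in data:
        lo, hi = float(d.min()), float(d.max())
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys_ranges.append((lo, hi))

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(_HEADER_DATE, 8),
            _field(_HEADER_TIME, 8),
            _field(str(256 * (1 + len(names))), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(len(names)), 4),
        ]
    )
    sig_fields = [
        [
            name,
            "",
            physical_dim,
            f"{lo:.6g}"[:8],
            f"{hi:.6g}"[:8],
            str(dig_min),
            str(dig_max),
            "",
            str(n_per_rec),
            "",
        ]
        for name, (lo, hi) in zip(names, phys_ranges)
    ]
    header += _signal_headers(sig_fields, [16, 80, 8, 8, 8, 8, 8, 80, 8, 32])

    digital = []
    for d, (lo, hi) in zip(data, phys_ranges):
        lo8, hi8 = float(f"{lo:.6g}"[:8]), float(f"{hi:.6g}"[:8])
        scale = (dig_max - dig_min) / (hi8 - lo8)
        dig = np.round((d - lo8) * scale + dig_min)
        digital.append(np.clip(dig, dig_min, dig_max).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for dig in digital:
                fh.write(dig[r * n_per_rec : (r + 1) * n_per_rec].tobytes())
    return path


def write_edf_annotations(
    path, annotations: list[tuple[float, float, str]]
) -> Path:
    """Write an annotations-only EDF+ file (Sleep-EDF hypnogram style).

    ``annotations`` is a list of ``(onset_s, duration_s, text)``. All
    time-stamped annotation lists go into a single data record.
    """
    path = Path(path)
    tal = b"+0\x14\x14\x00"  # record timestamp
    for onset, duration, text in annotations:
        tal += (
            f"+{onset:g}\x15{duration:g}\x14{text}\x14\x00".encode("utf-8")
        )
    if len(tal) % 2:
        tal += b"\x00"
    n_samples = len(tal) // 2  # 2-byte "samples" in the annotations signal

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(_HEADER_DATE, 8),
            _field(_HEADER_TIME, 8),
            _field(str(256 * 2), 8),
            _field("EDF+C", 44),
            _field("1", 8),
            _field("1", 8),
            _field("1", 4),
        ]
    )
    header += _signal_headers(
        [["EDF Annotations", "", "", "0", "1", "-32768", "32767", "", str(n_samples), ""]],
        [16, 80, 8, 8, 8, 8, 8, 80, 8, 32],
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(tal)
    return path
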