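"""EDF (European Data Format) reading and writing for recordings.

Reading delegates to MNE's EDF reader after a strict header/size
validation pass (fail-closed on truncated or malformed files). Writing is
a minimal EDF implementation: 16-bit samples, one-second data records,
symmetric physical range per channel — sufficient for round-tripping
synthetic recordings through standard EEG tooling.

A montage sidecar (``<file>.montage.json``) carries channel positions,
since EDF itself stores only labels.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .montage import Montage
from .preprocess import EEGRecording

__all__ = ["EdfFormatError", "read_edf", "write_edf", "write_montage_json", "read_montage_json"]

_HEADER_BYTES = 256


class EdfFormatError(ValueError):
    """Malformed or truncated EDF file; carries the offending byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        if isinstance(value, float):
            s = f"{value:.{max(1, width - 6)}g}"
        if len(s) > width:
            raise ValueError(f"field {s!r} does not fit in {width} bytes")
    return s.ljust(width).encode("ascii")


def write_montage_json(montage: Montage, path: str | Path) -> None:
    payload = {
        "channel_ids": list(montage.channel_ids),
        "positions": montage.positions.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_montage_json(path: str | Path) -> Montage:
    payload = json.loads(Path(path).read_text())
    return Montage(tuple(payload["channel_ids"]), np.asarray(payload["positions"]))


def write_edf(
    rec: EEGRecording,
    path: str | Path,
    patient: str = "X",
    recording: str = "synthetic resting-state EEG",
    sidecar: bool = True,
) -> None:
    """Write a recording as 16-bit EDF with one-second data records.

    Requires an integer sampling rate and a whole number of seconds of
    data. Quantization error is bounded by half the per-channel physical
    step (physical range / 65535).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {fs} Hz)"
        )
    n_records = rec.n_samples // fs
    n_ch = rec.n_channels

    # symmetric physical range; parse the formatted strings back so the
    # scaling used for quantization matches what a reader will see
    absmax = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) * 1.000001
    pmin_s = [_fmt(float(f"{-a:.6g}"), 8) for a in absmax]
    pmax_s = [_fmt(float(f"{a:.6g}"), 8) for a in absmax]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            _fmt("0", 8),
            _fmt(patient[:80], 80),
            _fmt(recording[:80], 80),
            _fmt("01.01.00", 8),
            _fmt("00.00.00", 8),
            _fmt(_HEADER_BYTES * (1 + n_ch), 8),
            _fmt("", 44),
            _fmt(n_records, 8),
            _fmt(1, 8),
            _fmt(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_fmt(cid[:16], 16) for cid in rec.montage.channel_ids),
            b"".join(_fmt("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_fmt("uV", 8) for _ in range(n_ch)),
            b"".join(pmin_s),
            b"".join(pmax_s),
            b"".join(_fmt(dmin, 8) for _ in range(n_ch)),
            b"".join(_fmt(dmax, 8) for _ in range(n_ch)),
            b"".join(_fmt("", 80) for _ in range(n_ch)),
            b"".join(_fmt(fs, 8) for _ in range(n_ch)),
            b"".join(_fmt("", 32) for _ in range(n_ch)),
        ]
    )
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(
        np.round((rec.data - pmin[:, None]) / scale[:, None]) + dmin,
        dmin,
        dmax,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    if sidecar:
        write_montage_json(rec.montage, path.with_suffix(path.suffix + ".montage.json"))


def _validate_edf_header(path: Path) -> tuple[int, int, list[str]]:
    """Parse and size-check the EDF header; raise EdfFormatError if broken."""
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise EdfFormatError("file shorter than the EDF header", offset=len(raw))
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        duration = float(raw[244:252].decode("ascii").strip())
        n_ch = int(raw[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise EdfFormatError(f"unparseable header field: {exc}", offset=236) from None
    header_bytes = _HEADER_BYTES * (1 + n_ch)
    if len(raw) < header_bytes:
        raise EdfFormatError("truncated signal header", offset=len(raw))
    sig = raw[_HEADER_BYTES:header_bytes]

    def field(block: int, start_per_signal: int, width: int) -> list[str]:
        base = start_per_signal * n_ch
        return [
            sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]

    labels = [
        sig[i * 16 : (i + 1) * 16].decode("ascii").strip() for i in range(n_ch)
    ]
    # samples-per-record field sits after 16+80+8+8+8+8+8+80 = 216 bytes/signal
    base = 216 * n_ch
    try:
        samples = [
            int(sig[base + i * 8 : base + (i + 1) * 8].decode("ascii").strip())
            for i in range(n_ch)
        ]
    except ValueError as exc:
        raise EdfFormatError(
            f"unparseable samples-per-record: {exc}", offset=_HEADER_BYTES + base
        ) from None
    expected = header_bytes + n_records * sum(samples) * 2
    if n_records < 0 or len(raw) < expected:
        raise EdfFormatError(
            f"file size {len(raw)} below expected {expected}", offset=len(raw)
        )
    if duration <= 0:
        raise EdfFormatError("non-positive record duration", offset=244)
    return n_records, n_ch, labels


def read_edf(path: str | Path, montage: Montage | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV).

    The montage is resolved, in order, from the ``montage`` argument, a
    ``<file>.montage.json`` sidecar, or — when channel labels follow the
    generated ``E###`` convention — the deterministic default montage. A
    channel-count mismatch with the resolved montage is an error.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _, n_ch, labels = _validate_edf_header(path)
    if montage is None:
        sidecar = path.with_suffix(path.suffix + ".montage.json")
        if sidecar.exists():
            montage = read_montage_json(sidecar)
        elif all(lab.startswith("E") and lab[1:].isdigit() for lab in labels):
            from .montage import make_montage

            montage = make_montage(n_ch)
        else:
            raise EdfFormatError(
                "no montage sidecar and channel labels are not auto-resolvable"
            )
    if montage.n_channels != n_ch:
        raise ValueError(
            f"montage has {montage.n_channels} channels but file has {n_ch}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    return EEGRecording(data_uv, float(raw.info["sfreq"]), montage)
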