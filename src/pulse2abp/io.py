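"""Reading, writing and segmenting paired waveform records.

Three interchangeable on-disk representations are supported:

* plain two-column CSV with ``#``-prefixed header metadata (dependency-free
  fixtures and exports),
* a minimal WFDB-style record (text ``.hea`` header plus interleaved
  little-endian int16 ``.dat``, format 16, with per-channel gain/baseline),
* an HDF5 archive laid out ``/subject/segment/{ppg,abp}``.

All readers expect 125 Hz records and reject anything else rather than
resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from pulse2abp.synth import PairedSegment

EXPECTED_FS = 125.0


class ChannelNotFoundError(KeyError):
    """A requested signal channel is not present in the record."""


class SamplingRateError(ValueError):
    """The record's sampling rate differs from the expected 125 Hz."""


@dataclass(frozen=True)
class RecordHandle:
    """Lightweight description of an on-disk record."""

    source_path: Path
    channels: tuple[str, ...]
    sampling_rate_hz: float
    n_samples: int


def _check_fs(fs: float, path: Path) -> None:
    if float(fs) != EXPECTED_FS:
        raise SamplingRateError(
            f"{path}: expected {EXPECTED_FS:g} Hz records, header says {fs:g} Hz "
            "(resampling is out of scope; reject)"
        )


# ---------------------------------------------------------------------------
# CSV records


def write_record_csv(path: Path, segment: PairedSegment) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {segment.sampling_rate_hz:g}\n")
        fh.write(f"# subject_id: {segment.subject_id}\n")
        fh.write(f"# segment_id: {segment.segment_id}\n")
        for key in ("sbp_mmHg", "dbp_mmHg", "lag_samples", "corruption"):
            if key in segment.meta:
                fh.write(f"# {key}: {segment.meta[key]}\n")
        fh.write("ppg,abp\n")
        np.savetxt(fh, np.column_stack([segment.ppg, segment.abp]),
                   fmt="%.17g", delimiter=",")


def _read_csv_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _read_record_csv(path: Path, ppg_channel: str, abp_channel: str) -> PairedSegment:
    meta = _read_csv_header(path)
    fs = float(meta.get("sampling_rate_hz", EXPECTED_FS))
    _check_fs(fs, path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    for ch in (ppg_channel, abp_channel):
        if ch not in frame.columns:
            raise ChannelNotFoundError(
                f"{path}: channel {ch!r} not found; available: {list(frame.columns)}"
            )
    return PairedSegment(
        ppg=frame[ppg_channel].to_numpy(float),
        abp=frame[abp_channel].to_numpy(float),
        sampling_rate_hz=fs,
        subject_id=meta.get("subject_id", "s0000"),
        segment_id=meta.get("segment_id", Path(path).stem),
        meta={k: v for k, v in meta.items() if k not in ("subject_id", "segment_id")},
    )


# ---------------------------------------------------------------------------
# WFDB-style records (text header + format-16 binary signal file)


def write_record_wfdb(header_path: Path, segment: PairedSegment,
                      channel_names: tuple[str, str] = ("PLETH", "ABP")) -> None:
    """Write a minimal WFDB-style record (format 16, per-channel gain)."""
    header_path = Path(header_path)
    record_name = header_path.stem
    dat_name = record_name + ".dat"
    signals = [np.asarray(segment.ppg), np.asarray(segment.abp)]
    n = len(segment)
    lines = [f"{record_name} 2 {segment.sampling_rate_hz:g} {n}"]
    ints = []
    for sig, name in zip(signals, channel_names):
        span = max(np.abs(sig).max(), 1e-12)
        gain = 30000.0 / span
        q = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
        ints.append(q)
        lines.append(f"{dat_name} 16 {gain:.6f}(0)/unit 16 0 0 0 0 {name}")
    header_path.write_text("\n".join(lines) + "\n")
    interleaved = np.empty(2 * n, dtype="<i2")
    interleaved[0::2] = ints[0]
    interleaved[1::2] = ints[1]
    (header_path.parent / dat_name).write_bytes(interleaved.tobytes())


def _parse_wfdb_header(path: Path) -> tuple[float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else EXPECTED_FS
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    n_sig = int(rec_tokens[1])
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0]
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        baseline = 0.0
        if "(" in gain_str:
            gain_str, base = gain_str.split("(")
            baseline = float(base.rstrip(")"))
        signals.append(
            {
                "file": tok[0],
                "format": fmt,
                "gain": float(gain_str) or 200.0,
                "baseline": baseline,
                "name": tok[-1],
            }
        )
    return fs, n_samples, signals


def _read_record_wfdb(path: Path, ppg_channel: str, abp_channel: str) -> PairedSegment:
    fs, n_samples, signals = _parse_wfdb_header(path)
    _check_fs(fs, path)
    names = [s["name"] for s in signals]
    for ch in (ppg_channel, abp_channel):
        if ch not in names:
            raise ChannelNotFoundError(
                f"{path}: channel {ch!r} not found; available: {names}"
            )
    if any(s["format"] != "16" for s in signals):
        raise ValueError(f"{path}: only format 16 signal files are supported")
    dat = path.parent / signals[0]["file"]
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    n_sig = len(signals)
    raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)
    if n_samples:
        raw = raw[:n_samples]
    out = {}
    for i, s in enumerate(signals):
        out[s["name"]] = (raw[:, i].astype(np.float64) - s["baseline"]) / s["gain"]
    return PairedSegment(
        ppg=out[ppg_channel],
        abp=out[abp_channel],
        sampling_rate_hz=fs,
        segment_id=path.stem,
    )


# ---------------------------------------------------------------------------
# HDF5 archive


def write_archive(path: Path, segments: Sequence[PairedSegment]) -> None:
    """Write segments to an HDF5 archive laid out /subject/segment/{ppg,abp}."""
    with h5py.File(path, "w") as h5:
        for seg in segments:
            grp = h5.require_group(seg.subject_id).create_group(seg.segment_id)
            grp.create_dataset("ppg", data=seg.ppg)
            grp.create_dataset("abp", data=seg.abp)
            grp.attrs["sampling_rate_hz"] = seg.sampling_rate_hz
            for key in ("sbp_mmHg", "dbp_mmHg", "lag_samples", "corruption"):
                if key in seg.meta:
                    grp.attrs[key] = seg.meta[key]


def read_archive(path: Path) -> list[PairedSegment]:
    segments = []
    with h5py.File(path, "r") as h5:
        for subject_id in sorted(h5):
            for segment_id in sorted(h5[subject_id]):
                grp = h5[subject_id][segment_id]
                fs = float(grp.attrs.get("sampling_rate_hz", EXPECTED_FS))
                _check_fs(fs, Path(path))
                meta = {k: grp.attrs[k] for k in grp.attrs if k != "sampling_rate_hz"}
                segments.append(
                    PairedSegment(
                        ppg=grp["ppg"][()],
                        abp=grp["abp"][()],
                        sampling_rate_hz=fs,
                        subject_id=subject_id,
                        segment_id=segment_id,
                        meta=meta,
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# Dispatch and segmentation


def write_record(path: Path, segment: PairedSegment) -> None:
    """Write one record; the format follows the file suffix (.csv or .hea)."""
    path = Path(path)
    if path.suffix == ".csv":
        write_record_csv(path, segment)
    elif path.suffix == ".hea":
        write_record_wfdb(path, segment)
    else:
        raise ValueError(f"unsupported record format: {path.suffix!r}")


def read_record(path: Path, ppg_channel: str = "ppg",
                abp_channel: str = "abp") -> PairedSegment:
    """Read the two raw aligned-in-time channels of a record, untouched.

    No filtering or normalization is applied here.  Records whose header
    declares a sampling rate other than 125 Hz are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        return _read_record_csv(path, ppg_channel, abp_channel)
    if path.suffix == ".hea":
        return _read_record_wfdb(path, ppg_channel, abp_channel)
    raise ValueError(f"unsupported record format: {path.suffix!r}")


def describe_record(path: Path) -> RecordHandle:
    path = Path(path)
    if path.suffix == ".csv":
        meta = _read_csv_header(path)
        frame = pd.read_csv(path, comment="#")
        return RecordHandle(
            source_path=path,
            channels=tuple(frame.columns),
            sampling_rate_hz=float(meta.get("sampling_rate_hz", EXPECTED_FS)),
            n_samples=len(frame),
        )
    if path.suffix == ".hea":
        fs, n_samples, signals = _parse_wfdb_header(path)
        return RecordHandle(
            source_path=path,
            channels=tuple(s["name"] for s in signals),
            sampling_rate_hz=fs,
            n_samples=n_samples,
        )
    raise ValueError(f"unsupported record format: {path.suffix!r}")


def segment_record(
    record: PairedSegment, segment_len: int, stride: int | None = None
) -> list[PairedSegment]:
    """Cut a continuous record into fixed-length segments.

    Segments are half-open windows ``[start, start + segment_len)`` taken
    every ``stride`` samples (non-overlapping by default); a tail shorter
    than ``segment_len`` is dropped.
    """
    if stride is None:
        stride = segment_len
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if segment_len < 1:
        raise ValueError(f"segment_len must be >= 1, got {segment_len}")
    n = len(record)
    if segment_len > n:
        warnings.warn(
            f"segment_len ({segment_len}) exceeds record length ({n}); "
            "no segments emitted",
            stacklevel=2,
        )
        return []
    out = []
    for k, start in enumerate(range(0, n - segment_len + 1, stride)):
        sl = slice(start, start + segment_len)
        out.append(
            PairedSegment(
                ppg=record.ppg[sl].copy(),
                abp=record.abp[sl].copy(),
                sampling_rate_hz=record.sampling_rate_hz,
                subject_id=record.subject_id,
                segment_id=f"{record.segment_id}_w{k:04d}",
                meta={"start_sample": start, **record.meta},
            )
        )
    return out
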