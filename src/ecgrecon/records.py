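"""The EcgRecord container and dataset I/O.

Two on-disk forms are supported:

* a portable array container — one ``signals.npz`` (one array per record) plus
  a ``metadata.csv`` sidecar with subject/record identifiers, sampling rate
  and comma-separated label names;
* minimal WFDB records — a ``.hea`` header plus a 16-bit little-endian ``.dat``
  signal file per record, the subset of the PhysioNet waveform-database format
  needed to exchange 12-lead signals (gain 1000 ADC units/mV, NaN mapped to
  the WFDB invalid-sample code -32768).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .leads import CANONICAL_LEADS

WFDB_INVALID = -32768
WFDB_GAIN = 1000.0  # ADC units per millivolt


class FormatError(ValueError):
    """Malformed record, header, or container."""


@dataclass
class EcgRecord:
    """One multichannel ECG: signal matrix plus identity and labels.

    signal is [L x T] (lead-major), in millivolts unless ``zscored`` metadata
    says otherwise.  labels is an optional multi-hot vector over label_names.
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = CANONICAL_LEADS
    subject_id: str = ""
    record_id: str = ""
    labels: np.ndarray | None = None
    label_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError(f"signal must be 2-D [L x T], got {self.signal.shape}")
        if self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[0]} rows vs {len(self.lead_names)} lead names")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.label_names),):
                raise ValueError("labels length must match label_names")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def with_signal(self, signal: np.ndarray, **changes) -> "EcgRecord":
        return replace(self, signal=signal, **changes)


# ---------------------------------------------------------------------------
# portable array container
# ---------------------------------------------------------------------------

def save_dataset(records: list[EcgRecord], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {rec.record_id: rec.signal for rec in records}
    if len(arrays) != len(records):
        raise ValueError("record_id values must be unique")
    np.savez(out_dir / "signals.npz", **arrays)
    rows = []
    for rec in records:
        label_str = ""
        if rec.labels is not None:
            label_str = ",".join(
                n for n, f in zip(rec.label_names, rec.labels) if f)
        rows.append({
            "record_id": rec.record_id,
            "subject_id": rec.subject_id,
            "fs": rec.fs,
            "lead_names": ",".join(rec.lead_names),
            "labels": label_str,
            "label_vocab": ",".join(rec.label_names),
        })
    pd.DataFrame(rows).to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def load_dataset(in_dir: str | Path) -> list[EcgRecord]:
    in_dir = Path(in_dir)
    sig_path = in_dir / "signals.npz"
    meta_path = in_dir / "metadata.csv"
    if not sig_path.exists() or not meta_path.exists():
        raise FormatError(f"{in_dir} is not a dataset directory")
    with np.load(sig_path) as npz:
        signals = {k: npz[k] for k in npz.files}
    meta = pd.read_csv(meta_path, dtype={"record_id": str, "subject_id": str},
                       keep_default_na=False)
    records = []
    for row in meta.itertuples():
        vocab = tuple(v for v in str(row.label_vocab).split(",") if v)
        names = tuple(str(row.labels).split(",")) if row.labels else ()
        labels = None
        if vocab:
            labels = np.array([1 if v in names else 0 for v in vocab], dtype=np.int8)
        records.append(EcgRecord(
            signal=signals[row.record_id],
            fs=float(row.fs),
            lead_names=tuple(str(row.lead_names).split(",")),
            subject_id=row.subject_id,
            record_id=row.record_id,
            labels=labels,
            label_names=vocab,
        ))
    return records


# ---------------------------------------------------------------------------
# minimal WFDB
# ---------------------------------------------------------------------------

def write_wfdb(rec: EcgRecord, out_dir: str | Path) -> Path:
    """Write a WFDB header/.dat pair (format 16, interleaved samples)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = rec.record_id or "record"
    L, T = rec.signal.shape
    adc = np.where(np.isnan(rec.signal), WFDB_INVALID,
                   np.rint(rec.signal * WFDB_GAIN)).astype("<i2")
    lines = [f"{name} {L} {rec.fs:g} {T}"]
    for i, lead in enumerate(rec.lead_names):
        first = int(adc[i, 0])
        lines.append(f"{name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 {first} 0 0 {lead}")
    lines.append(f"# subject_id: {rec.subject_id}")
    if rec.labels is not None:
        pos = ",".join(n for n, f in zip(rec.label_names, rec.labels) if f)
        lines.append(f"# labels: {pos}")
    (out_dir / f"{name}.hea").write_text("\n".join(lines) + "\n")
    adc.T.tofile(out_dir / f"{name}.dat")  # sample-major interleave
    return out_dir / f"{name}.hea"


def read_wfdb(hea_path: str | Path) -> EcgRecord:
    hea_path = Path(hea_path)
    try:
        lines = [ln for ln in hea_path.read_text().splitlines() if ln.strip()]
        head = lines[0].split()
        name, L, fs, T = head[0], int(head[1]), float(head[2]), int(head[3])
        leads, subject = [], ""
        for ln in lines[1:]:
            if ln.startswith("#"):
                if "subject_id:" in ln:
                    subject = ln.split("subject_id:")[1].strip()
                continue
            leads.append(ln.split()[-1])
        raw = np.fromfile(hea_path.with_suffix(".dat"), dtype="<i2")
        if raw.size != L * T:
            raise FormatError(f"dat file has {raw.size} samples, expected {L * T}")
        adc = raw.reshape(T, L).T.astype(np.float64)
    except (IndexError, ValueError, OSError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot parse WFDB record {hea_path}: {exc}") from exc
    signal = np.where(adc == WFDB_INVALID, np.nan, adc / WFDB_GAIN)
    return EcgRecord(signal=signal, fs=fs, lead_names=tuple(leads),
                     subject_id=subject, record_id=name)
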