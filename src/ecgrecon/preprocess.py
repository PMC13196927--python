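"""Preprocessing pipeline: lead reordering, Fourier resampling, NaN
imputation, per-lead z-scoring, segmentation and subject-grouped splitting.

Order of operations matters: imputation runs before Fourier resampling
(spectral interpolation is undefined on NaNs).  The canonical lead order is
I, II, III, aVR, aVL, aVF, V1..V6; all lead indices in reports refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .leads import CANONICAL_LEADS
from .records import EcgRecord, FormatError


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


def reorder_leads(rec: EcgRecord, target_order=CANONICAL_LEADS) -> EcgRecord:
    """Permute rows so lead_names equals target_order; values untouched."""
    if sorted(rec.lead_names) != sorted(target_order):
        missing = set(target_order) - set(rec.lead_names)
        extra = set(rec.lead_names) - set(target_order)
        raise FormatError(
            f"lead names are not a permutation of the target order "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})")
    if len(set(rec.lead_names)) != len(rec.lead_names):
        raise FormatError("duplicate lead names")
    perm = [rec.lead_names.index(name) for name in target_order]
    return rec.with_signal(rec.signal[perm], lead_names=tuple(target_order))


def resample_fourier(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample every lead to target_fs by Fourier zero-pad/truncation."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if np.isnan(rec.signal).any():
        raise ValueError("resampling requires a NaN-free signal; impute first")
    if target_fs == rec.fs:
        return rec.with_signal(rec.signal.copy())
    new_T = int(round(rec.n_samples * target_fs / rec.fs))
    resampled = scipy.signal.resample(rec.signal, new_T, axis=1)
    return rec.with_signal(resampled, fs=float(target_fs))


def impute_nans(rec: EcgRecord, window: int = 5) -> EcgRecord:
    """Replace each NaN by the mean of finite samples within +-window on the
    same lead, falling back to the lead mean; an all-NaN lead is an error."""
    if window < 1:
        raise ValueError("window must be >= 1")
    signal = rec.signal.copy()
    for i, lead in enumerate(rec.lead_names):
        row = signal[i]
        bad = np.flatnonzero(np.isnan(row))
        if bad.size == 0:
            continue
        finite = row[~np.isnan(row)]
        if finite.size == 0:
            raise FormatError(f"lead {lead} is entirely NaN")
        lead_mean = finite.mean()
        for j in bad:
            lo, hi = max(j - window, 0), min(j + window + 1, row.size)
            neigh = row[lo:hi]
            neigh = neigh[~np.isnan(neigh)]
            row[j] = neigh.mean() if neigh.size else lead_mean
    return rec.with_signal(signal)


def zscore_per_lead(rec: EcgRecord, eps: float = 1e-8) -> EcgRecord:
    """Standardize each lead with its own record-level mean and SD."""
    if np.isnan(rec.signal).any():
        raise ValueError("z-scoring requires a NaN-free signal")
    mean = rec.signal.mean(axis=1, keepdims=True)
    sd = rec.signal.std(axis=1, keepdims=True)
    out = (rec.signal - mean) / (sd + eps)
    meta = dict(rec.meta)
    meta["zscored"] = True
    return rec.with_signal(out, meta=meta)


def segment(rec: EcgRecord, seg_len: int = 1000, hop: int = 1000) -> list[EcgRecord]:
    """Cut into fixed-length windows; the trailing remainder is discarded."""
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if seg_len > rec.n_samples:
        raise ValueError(
            f"seg_len {seg_len} exceeds record length {rec.n_samples}")
    n_segs = (rec.n_samples - seg_len) // hop + 1
    out = []
    for k in range(n_segs):
        sl = slice(k * hop, k * hop + seg_len)
        meta = {key: (val[sl] if isinstance(val, np.ndarray)
                      and val.shape == (rec.n_samples,) else val)
                for key, val in rec.meta.items()}
        out.append(rec.with_signal(rec.signal[:, sl],
                                   record_id=f"{rec.record_id}_seg{k:03d}",
                                   meta=meta))
    return out


def subject_split(records: list[EcgRecord], spec: SplitSpec
                  ) -> tuple[list[EcgRecord], list[EcgRecord]]:
    """Partition records with disjoint subject_id sets (no identity leakage)."""
    subjects = sorted({rec.subject_id for rec in records})
    if len(subjects) < 2:
        raise ValueError("subject-grouped splitting needs at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(subjects))
    n_test = int(round(len(subjects) * spec.test_fraction))
    n_test = min(max(n_test, 1), len(subjects) - 1)
    test_set = {subjects[i] for i in order[:n_test]}
    train = [r for r in records if r.subject_id not in test_set]
    test = [r for r in records if r.subject_id in test_set]
    return train, test


def standard_pipeline(rec: EcgRecord, *, target_fs: float = 500.0,
                      nan_window: int = 5, zscore: bool = False,
                      seg_len: int | None = None, hop: int | None = None
                      ) -> list[EcgRecord]:
    """reorder -> impute -> resample -> (optional) z-score -> (optional) segment."""
    rec = reorder_leads(rec)
    rec = impute_nans(rec, window=nan_window)
    rec = resample_fourier(rec, target_fs)
    if zscore:
        rec = zscore_per_lead(rec)
    if seg_len is not None:
        return segment(rec, seg_len=seg_len, hop=hop or seg_len)
    return [rec]
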