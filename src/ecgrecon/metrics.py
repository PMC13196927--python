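"""Signal-level and diagnostic evaluation.

Per-lead MAE/MSE report (input leads excluded by default, matching how
reduced-lead reconstruction experiments are scored), Frechet distance between
Gaussian fits of embedding features (FID) with a pluggable embedder,
confusion-matrix diagnostics, rank-statistic AUROC with Youden-optimal
thresholds, and a blinded real-vs-generated set exporter for expert review.

FID is comparable only within one embedder; reports therefore carry the
embedder name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import sklearn.metrics

from .leads import CANONICAL_LEADS
from .maskvae import LeadMask
from .records import EcgRecord


class ConditioningError(np.linalg.LinAlgError):
    """Covariance input is non-PSD beyond tolerance."""


# ---------------------------------------------------------------------------
# pointwise errors
# ---------------------------------------------------------------------------

def mae(r: np.ndarray, g: np.ndarray) -> float:
    r, g = np.asarray(r, float), np.asarray(g, float)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {g.shape}")
    return float(np.mean(np.abs(r - g)))


def mse(r: np.ndarray, g: np.ndarray) -> float:
    r, g = np.asarray(r, float), np.asarray(g, float)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {g.shape}")
    return float(np.mean((r - g) ** 2))


# ---------------------------------------------------------------------------
# embedding-space Frechet distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureStats:
    """Gaussian summary (mean, covariance) of one embedded signal population."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "cov", np.asarray(self.cov, float))
        F = self.mean.shape[0]
        if self.cov.shape != (F, F):
            raise ValueError("cov must be F x F")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")


def feature_stats(signals, embedder) -> FeatureStats:
    """Mean and unbiased covariance of embedder outputs over a population."""
    feats = []
    for s in signals:
        x = s.signal if isinstance(s, EcgRecord) else np.asarray(s, float)
        feats.append(np.asarray(embedder(x), float))
    if len(feats) < 2:
        raise ValueError("need at least 2 signals for feature statistics")
    F = np.stack(feats)
    cov = np.cov(F, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return FeatureStats(mean=F.mean(axis=0), cov=(cov + cov.T) / 2.0, n=len(feats))


def _psd_sqrt(mat: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    if vals.min() < -tol * max(1.0, abs(vals.max())):
        raise ConditioningError(
            f"matrix has eigenvalue {vals.min():.3g} below the -{tol:g} tolerance")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureStats, b: FeatureStats) -> float:
    """||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The matrix square root is taken by symmetric eigendecomposition of
    A S_b A with A = S_a^{1/2}, small negative eigenvalues clipped.
    """
    if a.mean.shape != b.mean.shape:
        raise ValueError("feature dimensions differ")
    d2 = float(np.sum((a.mean - b.mean) ** 2))
    A = _psd_sqrt(a.cov)
    inner = _psd_sqrt(A @ b.cov @ A)
    val = d2 + float(np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(inner))
    if val < -1e-6:
        raise ConditioningError(f"FID evaluated to {val:.3g}")
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# built-in embedders
# ---------------------------------------------------------------------------

def mean_per_lead_embedder(x: np.ndarray) -> np.ndarray:
    """12-dim embedding: the temporal mean of each lead (analytic test case)."""
    return np.asarray(x, float).mean(axis=1)


class RandomProjectionEmbedder:
    """Seeded Gaussian projection of length-normalized signals to F features.

    Each lead is Fourier-resampled to a fixed internal length so the embedding
    is defined for any T; the projection matrix is fixed by the seed.
    """

    name = "random-projection"

    def __init__(self, n_features: int = 24, internal_len: int = 64, seed: int = 0):
        self.n_features = n_features
        self.internal_len = internal_len
        rng = np.random.default_rng(seed)
        dim = 12 * internal_len
        self.proj = rng.standard_normal((dim, n_features)) / np.sqrt(dim)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        xr = scipy.signal.resample(x, self.internal_len, axis=1)
        return xr.reshape(-1) @ self.proj


class VaeEncoderEmbedder:
    """Pooled posterior mean of a trained VAE encoder (mean and SD over T')."""

    name = "vae-encoder"

    def __init__(self, model):
        self.model = model

    def __call__(self, x: np.ndarray) -> np.ndarray:
        from .maskvae import pad_to_multiple
        xp, _ = pad_to_multiple(np.asarray(x, float), self.model.config.down_factor)
        mu, _ = self.model.encode(xp)          # [T' x d]
        return np.concatenate([mu.mean(axis=0), mu.std(axis=0)])


# ---------------------------------------------------------------------------
# per-lead report
# ---------------------------------------------------------------------------

@dataclass
class LeadReport:
    rows: pd.DataFrame            # columns: lead_name, lead_index, mse, mae
    overall_mse: float
    overall_mae: float
    fid_value: float
    embedder_name: str

    def to_frame(self) -> pd.DataFrame:
        overall = pd.DataFrame([{
            "lead_name": "Overall", "lead_index": "",
            "mse": self.overall_mse, "mae": self.overall_mae,
            "fid": self.fid_value,
        }])
        return pd.concat([self.rows.assign(fid=""), overall], ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lead_report(real_records: list[EcgRecord], recon_records: list[EcgRecord],
                mask: LeadMask, embedder, leads: str = "non-input") -> LeadReport:
    """Per-lead MAE/MSE plus one overall row; FID over full 12-lead signals.

    leads="non-input" (default) scores only the reconstructed leads;
    leads="all" scores all 12.
    """
    if len(real_records) != len(recon_records):
        raise ValueError("real and reconstructed record lists must pair up")
    if leads == "non-input":
        idx = list(mask.dropped_indices)
    elif leads == "all":
        idx = list(range(12))
    else:
        raise ValueError("leads must be 'all' or 'non-input'")
    real = np.concatenate([r.signal for r in real_records], axis=1)
    recon = np.concatenate([r.signal for r in recon_records], axis=1)
    if real.shape != recon.shape:
        raise ValueError("paired records must have equal shapes")
    rows = [{
        "lead_name": CANONICAL_LEADS[i], "lead_index": i,
        "mse": mse(real[i], recon[i]), "mae": mae(real[i], recon[i]),
    } for i in idx]
    f = fid(feature_stats(real_records, embedder),
            feature_stats(recon_records, embedder))
    return LeadReport(
        rows=pd.DataFrame(rows),
        overall_mse=mse(real[idx], recon[idx]),
        overall_mae=mae(real[idx], recon[idx]),
        fid_value=f,
        embedder_name=getattr(embedder, "name", embedder.__class__.__name__),
    )


# ---------------------------------------------------------------------------
# confusion diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 from counts.

    A metric whose denominator is zero is reported as NaN (undefined), never
    fabricated.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")

    def safe(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": safe(c.tp + c.tn, c.total),
        "sensitivity": safe(c.tp, c.tp + c.fn),
        "specificity": safe(c.tn, c.tn + c.fp),
        "precision": safe(c.tp, c.tp + c.fp),
        "f1": safe(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUROC needs both classes present")
    return float(sklearn.metrics.roc_auc_score(labels, scores))


def youden_threshold(scores: np.ndarray, labels: np.ndarray
                     ) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1 on the ROC curve;
    returns (threshold, sensitivity, specificity) at that operating point."""
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(labels, scores)
    k = int(np.argmax(tpr - fpr))
    return float(thresholds[k]), float(tpr[k]), float(1.0 - fpr[k])


# ---------------------------------------------------------------------------
# blinded set export
# ---------------------------------------------------------------------------

def export_blinded_set(real_records: list[EcgRecord],
                       generated_records: list[EcgRecord], n_each: int,
                       seed: int) -> tuple[list[EcgRecord], pd.DataFrame]:
    """A balanced, seeded-shuffled set of anonymized records plus the sealed
    key table mapping anonymous ids back to origin and source record."""
    if len(real_records) < n_each or len(generated_records) < n_each:
        raise ValueError(f"need at least {n_each} records of each kind")
    rng = np.random.default_rng(seed)
    chosen = ([("real", r) for r in real_records[:n_each]]
              + [("generated", r) for r in generated_records[:n_each]])
    order = rng.permutation(len(chosen))
    exported, key_rows = [], []
    for slot, j in enumerate(order):
        origin, rec = chosen[j]
        anon = f"blinded_{slot:04d}"
        exported.append(rec.with_signal(rec.signal.copy(), record_id=anon,
                                        subject_id="", labels=None,
                                        label_names=(), meta={}))
        key_rows.append({"anon_id": anon, "origin": origin,
                         "source_record_id": rec.record_id})
    return exported, pd.DataFrame(key_rows)
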