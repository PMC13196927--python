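"""Classical linear lead-transformation baseline.

Each of the 12 leads is regressed on the retained leads, pooling all time
samples across training records (optionally ridge-regularized).  Because
noise-free vectorcardiographic signals lie in the rank-3 subspace spanned by
any three independent lead rows, this baseline is *exact* on clean synthetic
data — which makes it both the classical comparison method and an analytic
oracle bracketing what any reconstructor can achieve.  The Goldberger
augmentation reproduces the four dependent limb leads from I and II by exact
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .leads import CANONICAL_LEADS
from .maskvae import LeadMask, mask_leads
from .records import EcgRecord


class ConditioningError(np.linalg.LinAlgError):
    """Retained-lead design matrix is rank deficient and ridge is zero."""


@dataclass
class LinearReconstructor:
    transform: np.ndarray          # [12 x r]
    retained: LeadMask
    fit_stats: np.ndarray          # per-lead training MSE, length 12
    identity_constraint: bool = True

    def __post_init__(self):
        r = len(self.retained.retained_indices)
        if self.transform.shape != (12, r):
            raise ValueError(f"transform must be 12 x {r}")

    def save_text(self, path: str | Path) -> Path:
        path = Path(path)
        header = "lead\t" + "\t".join(
            CANONICAL_LEADS[i] for i in self.retained.retained_indices)
        lines = [header]
        for i, name in enumerate(CANONICAL_LEADS):
            coefs = "\t".join(f"{v:.12g}" for v in self.transform[i])
            lines.append(f"{name}\t{coefs}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load_text(cls, path: str | Path) -> "LinearReconstructor":
        lines = Path(path).read_text().strip().splitlines()
        retained_names = lines[0].split("\t")[1:]
        rows = [list(map(float, ln.split("\t")[1:])) for ln in lines[1:]]
        return cls(transform=np.asarray(rows),
                   retained=LeadMask.from_retained(tuple(retained_names)),
                   fit_stats=np.full(12, np.nan))


def fit_linear(train_records: list[EcgRecord], mask: LeadMask,
               ridge: float = 0.0, identity_constraint: bool = True
               ) -> LinearReconstructor:
    """Least-squares fit of all 12 leads on the retained leads, pooling time
    samples across records.  Deterministic; order-invariant up to float
    summation."""
    if not train_records:
        raise ValueError("need at least one training record")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    ridx = mask.retained_indices
    pooled = np.concatenate([np.asarray(r.signal, float) for r in train_records],
                            axis=1)
    if np.isnan(pooled).any():
        raise ValueError("linear fit requires NaN-free signals; impute first")
    X = pooled[ridx]          # [r x Ttot]
    Y = pooled                # [12 x Ttot]
    G = X @ X.T
    if ridge == 0.0:
        if np.linalg.matrix_rank(G) < len(ridx):
            raise ConditioningError(
                "retained-lead Gram matrix is rank deficient; use ridge > 0")
    W = np.linalg.solve(G + ridge * np.eye(len(ridx)), X @ Y.T).T  # [12 x r]
    if identity_constraint:
        for k, i in enumerate(ridx):
            W[i] = 0.0
            W[i, k] = 1.0
    resid = Y - W @ X
    fit_stats = np.mean(resid ** 2, axis=1)
    return LinearReconstructor(transform=W, retained=mask, fit_stats=fit_stats,
                               identity_constraint=identity_constraint)


def apply_linear(lr: LinearReconstructor, x_masked: np.ndarray,
                 mask: LeadMask | None = None) -> np.ndarray:
    """Reconstruct [12 x T] from the retained rows of a masked input."""
    if mask is not None and not np.array_equal(mask.drop_flags,
                                               lr.retained.drop_flags):
        raise ValueError("mask does not match the fitted reconstructor")
    x_masked = np.asarray(x_masked, float)
    if x_masked.shape[0] != 12:
        raise ValueError("input must be [12 x T]")
    out = lr.transform @ x_masked[lr.retained.retained_indices]
    if lr.identity_constraint:
        out[lr.retained.retained_indices] = x_masked[lr.retained.retained_indices]
    return out


def reconstruct_records(lr: LinearReconstructor, records: list[EcgRecord]
                        ) -> list[EcgRecord]:
    out = []
    for rec in records:
        xm = mask_leads(rec.signal, lr.retained)
        out.append(rec.with_signal(apply_linear(lr, xm)))
    return out


def goldberger_augment(lead_i: np.ndarray, lead_ii: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact limb-lead algebra: (III, aVR, aVL, aVF) from leads I and II."""
    lead_i = np.asarray(lead_i, float)
    lead_ii = np.asarray(lead_ii, float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError("lead I and II must have equal length")
    iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return iii, avr, avl, avf
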