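"""Voltage-to-velocity-domain transformation via per-channel inversion.

The encoder compresses the m x n weight matrix into a feature tensor W'
of shape (m, m, p): p square sub-feature matrices W_sub.  Each channel is
inverted and applied to the measured voltage vector,

    v_sub = W_sub^{-1} U,

and the p resulting m-vectors are stacked column-wise into the m x p
velocity-feature matrix v'.  A learned encoder can emit near-singular
channels, so channels whose condition number exceeds ``cond_threshold``
fall back to the Moore-Penrose pseudo-inverse; the conditioning report
records which did.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["InversionReport", "invert_subfeatures", "transform", "transform_batch"]

DEFAULT_COND_THRESHOLD = 1e8


@dataclass
class InversionReport:
    """Per-channel condition numbers and which channels used a pseudo-inverse."""

    cond: np.ndarray
    pinv_channels: list = field(default_factory=list)
    cond_threshold: float = DEFAULT_COND_THRESHOLD

    def to_json(self) -> dict:
        return {
            "cond": self.cond.tolist(),
            "pinv_channels": [int(c) for c in self.pinv_channels],
            "cond_threshold": self.cond_threshold,
        }


def invert_subfeatures(
    Wp: np.ndarray, cond_threshold: float = DEFAULT_COND_THRESHOLD
) -> tuple[np.ndarray, InversionReport]:
    """Invert every m x m channel of the (m, m, p) feature tensor.

    Well-conditioned channels (2-norm condition number <= threshold) get
    the exact inverse; the rest get the pseudo-inverse and are flagged.
    """
    Wp = np.asarray(Wp, dtype=float)
    if Wp.ndim != 3 or Wp.shape[0] != Wp.shape[1]:
        raise ValueError(f"feature tensor must have shape (m, m, p), got {Wp.shape}")
    if not np.all(np.isfinite(Wp)):
        raise ValueError("feature tensor contains non-finite entries")
    m, _, p = Wp.shape
    inv = np.empty((m, m, p))
    cond = np.empty(p)
    fellback = []
    for j in range(p):
        A = Wp[:, :, j]
        cond[j] = np.linalg.cond(A)
        if np.isfinite(cond[j]) and cond[j] <= cond_threshold:
            inv[:, :, j] = np.linalg.inv(A)
        else:
            inv[:, :, j] = np.linalg.pinv(A)
            fellback.append(j)
    return inv, InversionReport(cond=cond, pinv_channels=fellback, cond_threshold=cond_threshold)


def transform(
    U: np.ndarray,
    Wp: np.ndarray,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    inverses: np.ndarray | None = None,
) -> np.ndarray:
    """Velocity-feature matrix v' (m, p): column j is W_sub^(j)^{-1} U.

    Precomputed ``inverses`` (from :func:`invert_subfeatures`) avoid
    re-factorizing when transforming many measurement vectors.
    """
    U = np.asarray(U, dtype=float).ravel()
    if inverses is None:
        inverses, _ = invert_subfeatures(Wp, cond_threshold)
    m = inverses.shape[0]
    if U.shape[0] != m:
        raise ValueError(f"voltage vector has length {U.shape[0]}, expected {m}")
    # v'[:, j] = inv[:, :, j] @ U
    return np.einsum("ikp,k->ip", inverses, U)


def transform_batch(
    U_batch: np.ndarray,
    Wp: np.ndarray,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> tuple[np.ndarray, InversionReport]:
    """Transform (N, m) voltages into (N, m, p) features in one pass."""
    inverses, report = invert_subfeatures(Wp, cond_threshold)
    U_batch = np.asarray(U_batch, dtype=float)
    out = np.einsum("ikp,nk->nip", inverses, U_batch)
    return out, report
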