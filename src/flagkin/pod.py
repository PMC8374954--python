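"""Proper orthogonal decomposition (POD) of the tangent-angle field.

The beating pattern is expanded as

    ψ(s_m, τ_n) = ψ0(s_m) + Σ_k B_k(τ_n) ψ_k(s_m),

where ψ0 is the time-average tangent-angle profile, the shape modes ψ_k are
orthonormal, time-independent angle profiles, and the dimensionless shape
coefficients B_k(τ) carry all the time dependence.  The modes are the right
singular vectors of the N×M deviation matrix X = ψ − ψ0 — equivalently the
eigenvectors of the M×M covariance matrix C_X = XᵀX — and B = X Ψᵀ.

For planar sperm beats the first two modes typically dominate (the beat is
close to a single traveling wave, which is exactly rank two), and the first
four capture essentially all of the movement; the B1–B2 plane ("B-space")
traces a closed loop once per beat cycle.

Sign convention: SVD leaves each mode's sign arbitrary, so each mode is
flipped (with its coefficient column) until its largest-magnitude entry is
positive.  This makes decompositions deterministic and comparable across
cells.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import TangentAngleField
from .errors import DataError, ParameterError

__all__ = [
    "ShapeModeDecomposition",
    "pod_decompose",
    "reconstruct_field",
    "variance_explained",
    "export_decomposition",
]


@dataclass
class ShapeModeDecomposition:
    """Mean shape, orthonormal shape modes, coefficients and spectrum."""

    psi0: np.ndarray  # (M,), radians
    modes: np.ndarray  # (K, M), orthonormal rows, radians
    coeffs: np.ndarray  # (N, K), dimensionless B_k(τ_n)
    singular_values: np.ndarray  # (K,), non-increasing
    variance_fractions: np.ndarray  # (K,), in [0, 1]; all zero for a static field
    arc_grid: np.ndarray  # (M,), μm
    times: np.ndarray  # (N,), s
    fps: float = 400.0
    body_length: float = 110.0
    degenerate_pairs: list = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def pod_decompose(t: TangentAngleField, *, degeneracy_rtol: float = 1e-6) -> ShapeModeDecomposition:
    """Decompose a tangent-angle field into shape modes.

    Nearly tied singular values (relative gap below ``degeneracy_rtol``) are
    flagged in ``degenerate_pairs``: within such a pair the mode plane is
    rotationally ambiguous and per-mode quantities should be interpreted
    jointly.
    """
    psi = np.asarray(t.psi, dtype=float)
    if psi.ndim != 2 or psi.shape[0] < 2 or psi.shape[1] < 2:
        raise DataError("need at least a 2x2 tangent-angle field")
    if not np.all(np.isfinite(psi)):
        raise DataError("NaN/inf in tangent-angle field")

    psi0 = psi.mean(axis=0)
    x = psi - psi0
    # SVD path; right singular vectors are the eigenvectors of C_X = XᵀX
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    modes = vt
    coeffs = x @ modes.T

    # deterministic sign: largest-|entry| element of each mode positive
    idx = np.argmax(np.abs(modes), axis=1)
    signs = np.sign(modes[np.arange(modes.shape[0]), idx])
    signs[signs == 0] = 1.0
    modes = modes * signs[:, None]
    coeffs = coeffs * signs[None, :]

    total = float(np.sum(s**2))
    # static field: rounding in the time mean leaves O(eps) residue, so the
    # zero-variance case is detected relative to the field magnitude
    floor = (1e-10 * max(1.0, float(np.abs(psi).max()))) ** 2 * psi.size
    if total > floor:
        var = s**2 / total
    else:
        var = np.zeros_like(s)

    degenerate = [
        (k, k + 1)
        for k in range(len(s) - 1)
        if s[k] > 0 and (s[k] - s[k + 1]) / s[k] < degeneracy_rtol
    ]
    return ShapeModeDecomposition(
        psi0=psi0,
        modes=modes,
        coeffs=coeffs,
        singular_values=s,
        variance_fractions=var,
        arc_grid=t.arc_grid.copy(),
        times=t.times.copy(),
        fps=t.fps,
        body_length=t.body_length,
        degenerate_pairs=degenerate,
    )


def reconstruct_field(d: ShapeModeDecomposition, k_max: int | None = None) -> TangentAngleField:
    """Truncated expansion ψ0 + Σ_{k<=k_max} B_k ψ_k as a tangent-angle field.

    With ``k_max`` equal to the full number of modes the input field is
    recovered to numerical precision.
    """
    if k_max is None:
        k_max = d.n_modes
    if not 1 <= k_max <= d.n_modes:
        raise ParameterError(f"k_max must be in [1, {d.n_modes}], got {k_max}")
    psi = d.psi0[None, :] + d.coeffs[:, :k_max] @ d.modes[:k_max, :]
    return TangentAngleField(
        psi=psi,
        arc_grid=d.arc_grid.copy(),
        times=d.times.copy(),
        fps=d.fps,
        body_length=d.body_length,
    )


def variance_explained(d: ShapeModeDecomposition, k_set) -> float:
    """Total variance fraction carried by the modes in ``k_set``
    (1-based mode indices, matching the B1/B2 naming)."""
    k_set = list(k_set)
    if len(k_set) == 0:
        return 0.0
    idx = np.asarray(k_set, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= d.n_modes:
        raise ParameterError(f"mode indices must be in [1, {d.n_modes}]")
    if len(set(idx.tolist())) != len(idx):
        raise ParameterError("duplicate mode indices")
    if d.degenerate_pairs:
        pairs = {k for pair in d.degenerate_pairs for k in pair}
        if pairs.intersection(idx.tolist()) and not pairs.issubset(idx.tolist()):
            warnings.warn(
                "variance requested for part of a degenerate mode pair; "
                "the split between tied modes is arbitrary",
                stacklevel=2,
            )
    return float(d.variance_fractions[idx].sum())


def export_decomposition(d: ShapeModeDecomposition, prefix: str | os.PathLike, k_max: int = 4) -> None:
    """Write ``<prefix>.json`` (ψ0, modes, spectrum) and ``<prefix>_coeffs.tsv``
    (frame, time_s, B1..BK)."""
    k_max = min(k_max, d.n_modes)
    payload = {
        "arc_grid_um": d.arc_grid.tolist(),
        "psi0_rad": d.psi0.tolist(),
        "modes_rad": d.modes[:k_max].tolist(),
        "singular_values": d.singular_values[:k_max].tolist(),
        "variance_fractions": d.variance_fractions[:k_max].tolist(),
        "n_modes_total": int(d.n_modes),
        "body_length_um": d.body_length,
    }
    with open(f"{prefix}.json", "w") as f:
        json.dump(payload, f, indent=1)
    cols = {"frame": np.arange(len(d.times)), "time_s": d.times}
    for k in range(k_max):
        cols[f"B{k + 1}"] = d.coeffs[:, k]
    pd.DataFrame(cols).to_csv(f"{prefix}_coeffs.tsv", sep="\t", index=False, float_format="%.9g")
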