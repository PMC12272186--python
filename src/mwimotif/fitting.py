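"""Regularized non-negative least-squares T2 spectrum fitting.

Each voxel signal is modeled as a non-negative combination of basis
signals (single-T2 curves in the conventional mode, data-driven motifs
otherwise):

    W* = argmin_{W >= 0}  1/2 ||D W - s||_2^2
                          + lambda_tikh ||W||_2^2 + lambda_l1 ||W||_1.

This is a non-negativity-constrained convex quadratic program with Hessian
``Q = D'D + 2 lambda_tikh I`` and linear term ``c = -D's + lambda_l1 1``.
It is solved exactly by completing the square -- Cholesky ``Q = R'R``,
``z = -R^{-T} c`` -- and handing ``min ||R W - z||, W >= 0`` to the
active-set NNLS solver, whose KKT conditions match the original program.

The motif weight vector ``W`` maps to the single-T2 spectrum through the
fraction matrix ``F`` (column i = motif i's fraction vector on the T2
grid): ``w = F W``.  The myelin water fraction is the spectral mass at
T2 <= 40 ms over the total mass (inclusive boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
from scipy.optimize import nnls

from .motifs import MYELIN_T2_CUTOFF_MS, MotifDictionary
from .scoring import SelectedBasis
from .simulate import SingleT2Dictionary, normalize_curves

__all__ = [
    "FitParams",
    "BasisSet",
    "SpectrumResult",
    "rnnls_fit",
    "assemble_spectrum",
    "compute_mwf",
    "fit_volume",
    "conventional_basis",
    "motif_basis",
]

#: value written into maps outside the mask
MAP_SENTINEL = np.nan


@dataclass(frozen=True)
class FitParams:
    """Regularization weights and fitting mode."""

    lambda_tikh: float = 0.001
    lambda_l1: float = 0.01
    mode: Literal["conventional", "data_driven"] = "data_driven"
    mwf_cutoff_ms: float = MYELIN_T2_CUTOFF_MS

    def __post_init__(self) -> None:
        if self.lambda_tikh < 0 or self.lambda_l1 < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class BasisSet:
    """Fitting basis: signal columns plus the weight-to-spectrum map.

    ``signal_matrix`` is ETL x |D| (columns are basis signals at the
    homogeneous B1+ plane); ``fraction_matrix`` is N_T2 x |D| with columns
    summing to 1 (identity for a single-T2 basis).  ``signal_stack``
    optionally carries the same columns at every B1+ plane
    (``(n_b1, etl, |D|)``) so voxels can be fitted at their own estimated
    transmit-field plane.
    """

    signal_matrix: np.ndarray
    fraction_matrix: np.ndarray
    t2_grid: np.ndarray
    basis_kind: Literal["single_t2", "motif"]
    signal_stack: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.signal_matrix.shape[1] != self.fraction_matrix.shape[1]:
            raise ValueError("signal and fraction matrices disagree on |D|")
        if self.fraction_matrix.shape[0] != len(self.t2_grid):
            raise ValueError("fraction matrix rows must match the T2 grid")
        colsum = self.fraction_matrix.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise ValueError("fraction-matrix columns must sum to 1")

    @property
    def n_basis(self) -> int:
        return self.signal_matrix.shape[1]


def conventional_basis(dictionary: SingleT2Dictionary) -> BasisSet:
    """Single-T2 basis at the homogeneous B1+ plane (F = identity)."""
    k = dictionary.b1_index(1.0)
    return BasisSet(
        signal_matrix=dictionary.curves[:, k, :].T.copy(),
        fraction_matrix=np.eye(dictionary.n_t2),
        t2_grid=dictionary.t2_grid,
        basis_kind="single_t2",
        signal_stack=np.transpose(dictionary.curves, (1, 2, 0)).copy(),
    )


def motif_basis(motifs: MotifDictionary, selection: SelectedBasis) -> BasisSet:
    """Basis of selected motifs (home plane columns + full B1+ stack)."""
    sub = motifs.select(np.asarray(selection.motif_indices))
    return BasisSet(
        signal_matrix=sub.signals_at_b1(1.0).T.copy(),
        fraction_matrix=sub.fraction_matrix(),
        t2_grid=motifs.source.t2_grid,
        basis_kind="motif",
        signal_stack=np.transpose(sub.signals, (1, 2, 0)).copy(),
    )


def rnnls_fit(basis: BasisSet, signal: np.ndarray, params: FitParams) -> np.ndarray:
    """Solve the regularized NNLS program for one voxel.

    Returns the non-negative weight vector ``W``; the objective at ``W``
    never exceeds the objective at zero (zero is feasible).
    """
    D = basis.signal_matrix
    s = np.asarray(signal, dtype=float)
    if s.shape != (D.shape[0],):
        raise ValueError("signal length does not match the basis ETL")
    Q = D.T @ D + 2.0 * params.lambda_tikh * np.eye(D.shape[1])
    c = -D.T @ s + params.lambda_l1 * np.ones(D.shape[1])
    for jitter in (0.0, 1e-12, 1e-9):
        try:
            R = scipy.linalg.cholesky(Q + jitter * np.eye(len(Q)), lower=False)
            break
        except scipy.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - Q is PSD by construction
        raise RuntimeError("Hessian factorization failed")
    z = scipy.linalg.solve_triangular(R, -c, trans="T")
    W, _ = nnls(R, z)
    return W


def assemble_spectrum(W: np.ndarray, basis: BasisSet) -> np.ndarray:
    """T2 spectrum w = F W on the single-T2 grid (non-negative)."""
    W = np.asarray(W, dtype=float)
    if W.shape != (basis.n_basis,):
        raise ValueError("weight vector length does not match the basis")
    return basis.fraction_matrix @ W


def compute_mwf(
    spectrum: np.ndarray,
    t2_grid: np.ndarray,
    cutoff_ms: float = MYELIN_T2_CUTOFF_MS,
) -> float:
    """Myelin water fraction: mass at T2 <= cutoff over total mass.

    Returns NaN when the spectrum is identically zero.
    """
    w = np.asarray(spectrum, dtype=float)
    if np.any(w < 0):
        raise ValueError("spectrum must be non-negative")
    total = w.sum()
    if total == 0:
        return float("nan")
    return float(w[np.asarray(t2_grid) <= cutoff_ms].sum() / total)


@dataclass
class SpectrumResult:
    """Maps produced by a volume fit (input geometry, NaN outside mask)."""

    mwf: np.ndarray
    equivalent_t2: np.ndarray
    residual: np.ndarray
    weights: np.ndarray  # (n_masked, |D|) in mask order
    spectra: np.ndarray  # (n_masked, n_t2)
    mask: np.ndarray
    n_failed: int = 0


def fit_volume(
    signals: np.ndarray,
    mask: np.ndarray,
    basis: BasisSet,
    params: FitParams,
    dictionary: SingleT2Dictionary | None = None,
    plane_indices: np.ndarray | None = None,
    similarity_xi: float | None = None,
) -> SpectrumResult:
    """Fit every masked voxel and assemble MWF / equivalent-T2 maps.

    Voxel signals are L2-normalized to match the basis columns.  With
    ``plane_indices`` (one B1+ plane per masked voxel) each voxel is
    fitted against the basis columns at its own transmit-field plane
    (requires ``basis.signal_stack``); otherwise the homogeneous-plane
    columns are used for all voxels.  With ``similarity_xi`` set, each
    voxel's fit is restricted to the basis atoms *similar* to it (squared
    L2 residual below the threshold) -- atoms that cannot plausibly model
    a voxel are excluded from its decomposition, which suppresses
    cross-tissue weight leakage.  Because a multicompartment voxel may
    need a *combination* of atoms that are individually dissimilar, the
    full basis is also tried, and kept when it reduces the squared
    residual at least four-fold (real structure rather than noise
    chasing); voxels similar to no atom always use the full basis.
    The equivalent T2 is found by synthesizing the fitted
    homogeneous signal ``D W`` and matching it against the single-T2
    dictionary at the homogeneous plane (``dictionary`` defaults to none,
    skipping that map).  Voxel fits are independent, so results do not
    depend on any partitioning of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vox = normalize_curves(np.asarray(signals, dtype=float)[mask], "unit_l2")

    n_vox = vox.shape[0]
    if plane_indices is not None:
        if basis.signal_stack is None:
            raise ValueError("per-plane fitting requires basis.signal_stack")
        plane_indices = np.asarray(plane_indices, dtype=np.int64)
        if plane_indices.shape != (n_vox,):
            raise ValueError("plane_indices must give one plane per masked voxel")

    weights = np.zeros((n_vox, basis.n_basis))
    residual = np.zeros(n_vox)
    n_failed = 0
    plane_bases: dict[int, BasisSet] = {}

    def basis_for(j: int) -> BasisSet:
        if plane_indices is None:
            return basis
        k = int(plane_indices[j])
        if k not in plane_bases:
            plane_bases[k] = BasisSet(
                signal_matrix=basis.signal_stack[k],
                fraction_matrix=basis.fraction_matrix,
                t2_grid=basis.t2_grid,
                basis_kind=basis.basis_kind,
            )
        return plane_bases[k]

    def fit_columns(bj: BasisSet, s: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, float]:
        sub = BasisSet(
            signal_matrix=bj.signal_matrix[:, cols],
            fraction_matrix=bj.fraction_matrix[:, cols],
            t2_grid=bj.t2_grid,
            basis_kind=bj.basis_kind,
        )
        Wsub = rnnls_fit(sub, s, params)
        W = np.zeros(bj.n_basis)
        W[cols] = Wsub
        return W, float(np.linalg.norm(bj.signal_matrix @ W - s))

    all_cols = np.arange(basis.n_basis)
    for j in range(n_vox):
        bj = basis_for(j)
        try:
            if similarity_xi is None:
                W, res = fit_columns(bj, vox[j], all_cols)
            else:
                d2 = np.sum((bj.signal_matrix.T - vox[j]) ** 2, axis=1)
                cols = np.flatnonzero(d2 < similarity_xi)
                if 0 < len(cols) < basis.n_basis:
                    W, res = fit_columns(bj, vox[j], cols)
                    W_full, res_full = fit_columns(bj, vox[j], all_cols)
                    if res_full**2 < 0.25 * res**2:
                        W, res = W_full, res_full
                else:
                    W, res = fit_columns(bj, vox[j], all_cols)
        except RuntimeError:
            W, res = np.zeros(basis.n_basis), float("nan")
            n_failed += 1
        weights[j] = W
        residual[j] = res

    spectra = weights @ basis.fraction_matrix.T
    totals = spectra.sum(axis=1)
    myelin_mass = spectra[:, np.asarray(basis.t2_grid) <= params.mwf_cutoff_ms].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mwf_flat = np.where(totals > 0, myelin_mass / np.maximum(totals, 1e-300), np.nan)

    eq_flat = np.full(n_vox, np.nan)
    if dictionary is not None:
        k = dictionary.b1_index(1.0)
        plane = dictionary.curves[:, k, :]
        synth = weights @ basis.signal_matrix.T
        ok = np.linalg.norm(synth, axis=1) > 0
        synth_n = normalize_curves(synth[ok], dictionary.normalization_mode)
        d2 = np.sum(plane**2, axis=1)[None, :] - 2.0 * synth_n @ plane.T
        eq_flat[ok] = dictionary.t2_grid[np.argmin(d2, axis=1)]

    def to_map(flat: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, MAP_SENTINEL)
        out[mask] = flat
        return out

    return SpectrumResult(
        mwf=to_map(mwf_flat),
        equivalent_t2=to_map(eq_flat),
        residual=to_map(residual),
        weights=weights,
        spectra=spectra,
        mask=mask,
        n_failed=n_failed,
    )
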