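"""MESE echo-train signal simulation and single-T2 dictionaries.

Multi-echo spin-echo (MESE) trains acquired with imperfect refocusing pulses
deviate from mono-exponential decay because stimulated and indirect echoes
mix longitudinal and transverse magnetization between echoes.  The extended
phase graph (EPG) formalism tracks the full set of dephased coherence
configurations and reproduces these effects for a given refocusing flip
angle, echo spacing and relaxation times.

This module provides

* :func:`simulate_epg_mese` -- EPG simulation of a CPMG-conditioned MESE
  train (excitation about y, refocusing about x, crusher gradients on both
  sides of each refocusing pulse),
* :func:`simulate_exponential` -- the ideal-refocusing mono-exponential
  limit, useful for 3D acquisitions and as an analytic cross-check,
* :func:`build_single_t2_dictionary` -- decay curves tabulated on a
  (T2, B1+) grid, the atoms from which multicomponent motifs are built.

The transmit-field scale ``b1_scale`` multiplies the nominal refocusing flip
angle at every refocusing pulse (1.0 = homogeneous field).  The excitation
pulse is taken as ideal; slice-profile integration is deliberately out of
scope, so the EPG is evaluated at a single effective flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SequenceParams",
    "SingleT2Dictionary",
    "simulate_epg_mese",
    "simulate_exponential",
    "build_single_t2_dictionary",
]

NormalizationMode = Literal["unit_l2", "unit_first_echo", "raw"]


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of a 2D MESE protocol.

    Parameters
    ----------
    etl
        Echo train length (number of refocusing pulses / echoes), >= 2.
    echo_spacing
        Inter-echo spacing in milliseconds; the first echo forms at
        ``t = echo_spacing``.
    excitation_flip
        Nominal excitation flip angle in degrees (90 for MESE).
    refocusing_flip
        Nominal refocusing flip angle in degrees (180 for MESE).
    t1
        Assumed longitudinal relaxation time in milliseconds.  T1 is not
        fitted anywhere in this package; 1000 ms is typical for white
        matter at 3T.
    """

    etl: int = 11
    echo_spacing: float = 12.0
    excitation_flip: float = 90.0
    refocusing_flip: float = 180.0
    t1: float = 1000.0

    def __post_init__(self) -> None:
        if int(self.etl) != self.etl or self.etl < 2:
            raise ValueError(f"etl must be an integer >= 2, got {self.etl}")
        if not (self.echo_spacing > 0):
            raise ValueError("echo_spacing must be positive")
        if not (self.t1 > 0):
            raise ValueError("t1 must be positive")
        for name in ("excitation_flip", "refocusing_flip"):
            v = getattr(self, name)
            if not (0 < v <= 200):
                raise ValueError(f"{name} must lie in (0, 200] degrees, got {v}")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times in ms: n * echo_spacing, n = 1..etl."""
        return self.echo_spacing * np.arange(1, self.etl + 1)


def _check_t2(t2: float) -> float:
    t2 = float(t2)
    if not np.isfinite(t2) or t2 <= 0:
        raise ValueError(f"t2 must be finite and positive, got {t2}")
    return t2


def _epg_rf_matrix(alpha: float, phi: float) -> np.ndarray:
    """RF rotation acting on the (F+, F-, Z) configuration triplet."""
    c2, s2 = np.cos(alpha / 2) ** 2, np.sin(alpha / 2) ** 2
    sa, ca = np.sin(alpha), np.cos(alpha)
    ei, e2i = np.exp(1j * phi), np.exp(2j * phi)
    return np.array(
        [
            [c2, e2i * s2, -1j * ei * sa],
            [s2 / e2i, c2, 1j * sa / ei],
            [-0.5j * sa / ei, 0.5j * sa * ei, ca],
        ]
    )


def simulate_epg_mese(t2: float, seq: SequenceParams, b1_scale: float = 1.0) -> np.ndarray:
    """Simulate MESE echo amplitudes with the extended phase graph.

    Parameters
    ----------
    t2
        Transverse relaxation time in ms.
    seq
        Sequence parameters; ``seq.t1`` supplies longitudinal relaxation.
    b1_scale
        Transmit-field scale; the refocusing flip applied at every pulse is
        ``b1_scale * seq.refocusing_flip``.

    Returns
    -------
    numpy.ndarray
        Transverse magnetization magnitude at each echo time
        ``n * echo_spacing``, shape ``(etl,)``.  At ``b1_scale`` such that
        the effective refocusing flip is 180 deg this reduces to
        ``exp(-n * echo_spacing / t2)``.
    """
    t2 = _check_t2(t2)
    b1_scale = float(b1_scale)
    if not (0 < b1_scale <= 2):
        raise ValueError(f"b1_scale must lie in (0, 2], got {b1_scale}")

    etl = seq.etl
    n_states = etl + 1  # highest accessible dephasing order
    # Rows: F+(k), F-(k), Z(k) for k = 0..n_states-1 (Hennig/Weigel bookkeeping).
    omega = np.zeros((3, n_states + 1), dtype=complex)
    omega[2, 0] = 1.0

    # Ideal excitation with 90 deg phase offset to the refocusing axis (CPMG).
    exc = _epg_rf_matrix(np.deg2rad(seq.excitation_flip), np.pi / 2)
    omega = exc @ omega

    refoc = _epg_rf_matrix(np.deg2rad(b1_scale * seq.refocusing_flip), 0.0)

    tau = seq.echo_spacing / 2.0
    e2 = np.exp(-tau / t2)
    e1 = np.exp(-tau / seq.t1)

    def relax(om: np.ndarray) -> None:
        om[0] *= e2
        om[1] *= e2
        om[2] *= e1
        om[2, 0] += 1.0 - e1  # longitudinal recovery feeds only the k=0 state

    def grad(om: np.ndarray) -> None:
        # Unit crusher: F(k) -> F(k+1); F- stores F(-k), which shifts toward 0.
        om[0, 1:] = om[0, :-1]
        om[1, :-1] = om[1, 1:]
        om[1, -1] = 0.0
        om[0, 0] = np.conj(om[1, 0])

    echoes = np.empty(etl)
    for n in range(etl):
        relax(omega)
        grad(omega)
        omega = refoc @ omega
        relax(omega)
        grad(omega)
        echoes[n] = np.abs(omega[0, 0])
    return echoes


def simulate_exponential(t2: float, seq: SequenceParams) -> np.ndarray:
    """Mono-exponential decay sampled at the echo times (ideal refocusing)."""
    t2 = _check_t2(t2)
    return np.exp(-seq.echo_times / t2)


@dataclass(frozen=True)
class SingleT2Dictionary:
    """Simulated decay curves on a (T2, B1+) grid.

    ``curves[i, k]`` is the amplitude vector for ``t2_grid[i]`` at
    ``b1_grid[k]``, stored after applying ``normalization_mode``.
    """

    t2_grid: np.ndarray
    b1_grid: np.ndarray
    curves: np.ndarray  # (n_t2, n_b1, etl)
    seq: SequenceParams
    backend: str
    normalization_mode: NormalizationMode = "unit_l2"

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2_grid, dtype=float)
        b1 = np.asarray(self.b1_grid, dtype=float)
        if t2.ndim != 1 or b1.ndim != 1:
            raise ValueError("grids must be 1-D")
        if len(t2) > 1 and not np.all(np.diff(t2) > 0):
            raise ValueError("t2_grid must be strictly increasing")
        if len(b1) > 1 and not np.all(np.diff(b1) > 0):
            raise ValueError("b1_grid must be strictly increasing")
        if self.curves.shape[:2] != (len(t2), len(b1)):
            raise ValueError("curves shape inconsistent with grids")

    @property
    def etl(self) -> int:
        return self.curves.shape[2]

    @property
    def n_t2(self) -> int:
        return len(self.t2_grid)

    @property
    def n_b1(self) -> int:
        return len(self.b1_grid)

    def b1_index(self, b1_scale: float) -> int:
        """Index of an (exact, up to fp tolerance) grid B1+ value."""
        i = int(np.argmin(np.abs(self.b1_grid - b1_scale)))
        if not np.isclose(self.b1_grid[i], b1_scale, atol=1e-9):
            raise ValueError(f"b1_scale {b1_scale} is not on the grid {self.b1_grid}")
        return i


def normalize_curves(curves: np.ndarray, mode: NormalizationMode) -> np.ndarray:
    """Normalize amplitude vectors along the last axis."""
    curves = np.asarray(curves, dtype=float)
    if mode == "raw":
        return curves
    if mode == "unit_l2":
        denom = np.linalg.norm(curves, axis=-1, keepdims=True)
    elif mode == "unit_first_echo":
        denom = curves[..., :1]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if np.any(denom == 0):
        raise ValueError("cannot normalize an all-zero curve")
    return curves / denom


def build_single_t2_dictionary(
    t2_spec: tuple[float, float, int],
    b1_spec: tuple[float, float, int],
    seq: SequenceParams,
    backend: Literal["epg", "exponential"] = "epg",
    normalization_mode: NormalizationMode = "unit_l2",
) -> SingleT2Dictionary:
    """Build a single-T2 decay dictionary.

    Parameters
    ----------
    t2_spec
        ``(t2_min, t2_max, n_t2)``; T2 values are logarithmically spaced.
    b1_spec
        ``(b1_min, b1_max, n_b1)``; B1+ values are linearly spaced (e.g.
        0.80 to 1.20 in steps of 0.05 for ``n_b1=9``).
    backend
        ``"epg"`` for the stimulated-echo-aware model, ``"exponential"``
        for ideal refocusing (B1+-independent).
    """
    t2_min, t2_max, n_t2 = t2_spec
    b1_min, b1_max, n_b1 = b1_spec
    if n_t2 < 1 or n_b1 < 1:
        raise ValueError("grid sizes must be >= 1")
    if t2_min <= 0:
        raise ValueError("t2_min must be positive")
    if n_t2 > 1 and not (t2_min < t2_max):
        raise ValueError("t2_min must be < t2_max")
    if n_b1 > 1 and not (b1_min < b1_max):
        raise ValueError("b1_min must be < b1_max")

    t2_grid = np.geomspace(t2_min, t2_max, n_t2)
    b1_grid = np.linspace(b1_min, b1_max, n_b1)

    curves = np.empty((n_t2, n_b1, seq.etl))
    if backend == "exponential":
        col = np.array([simulate_exponential(t2, seq) for t2 in t2_grid])
        curves[:] = col[:, None, :]
    elif backend == "epg":
        for k, b1 in enumerate(b1_grid):
            for i, t2 in enumerate(t2_grid):
                curves[i, k] = simulate_epg_mese(t2, seq, b1)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    curves = normalize_curves(curves, normalization_mode)
    return SingleT2Dictionary(
        t2_grid=t2_grid,
        b1_grid=b1_grid,
        curves=curves,
        seq=seq,
        backend=backend,
        normalization_mode=normalization_mode,
    )
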