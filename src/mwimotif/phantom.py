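"""Synthetic ground-truth phantoms for end-to-end validation.

Two generators are provided:

* :func:`build_shepp_logan` -- a 2-D multicompartment head phantom.  The
  classic Shepp-Logan ellipse image (from scikit-image, nearest-neighbor
  resampled) supplies the geometry; its five distinct non-zero gray levels
  become five tissue classes, each assigned a multicomponent T2
  configuration.  A smooth radial transmit-field (B1+) profile, optionally
  quantized to the dictionary grid, modulates the simulated MESE signal.
* :func:`build_tube_phantom` -- an emulation of a physical
  capillary-tube phantom: each tube is one "huge voxel" whose signal is the
  area-weighted sum of three compartment decays (background 80 ms, capillary
  fillings 60 ms and 20 ms), with the short-T2 area fraction as ground
  truth.  The default nine fractions are 0, 0, 3.8, 7.1, 11.1, 14.3, 18.5,
  21.7 and 26.2%.

Component fractions weight *unit-L2-normalized* decay curves, exactly as
the multicomponent spectral model combines its dictionary atoms; the
ground-truth myelin fraction is then the relative spectral *energy* below
40 ms, the same quantity the fitted spectrum reports.  (Pass
``component_normalization="raw"`` for proton-density-weighted mixing.)

Rician noise is added per voxel with sigma = first-echo amplitude / SNR
(magnitude of the signal plus a complex Gaussian), leaving ground-truth
maps untouched.  All generation is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .motifs import MYELIN_T2_CUTOFF_MS
from .simulate import (
    SequenceParams,
    normalize_curves,
    simulate_epg_mese,
    simulate_exponential,
)

__all__ = [
    "TissueConfig",
    "PhantomVolume",
    "default_tissues",
    "snap_tissues_to_grid",
    "build_shepp_logan",
    "add_rician_noise",
    "build_tube_phantom",
    "TUBE_SHORT_FRACTIONS",
]


@dataclass(frozen=True)
class TissueConfig:
    """A multicompartment tissue: component T2s (ms) and fractions."""

    t2s: tuple[float, ...]
    fractions: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.t2s) != len(self.fractions):
            raise ValueError("t2s and fractions lengths differ")
        if not (1 <= len(self.t2s) <= 3):
            raise ValueError("1 to 3 compartments supported")
        f = np.asarray(self.fractions)
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("fractions must lie in (0, 1]")
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1")

    @property
    def mwf(self) -> float:
        """Ground-truth myelin water fraction (mass at T2 <= 40 ms)."""
        t2 = np.asarray(self.t2s)
        f = np.asarray(self.fractions)
        return float(f[t2 <= MYELIN_T2_CUTOFF_MS].sum())


def default_tissues() -> list[TissueConfig]:
    """Five white-matter-like tissue classes.

    Two- and three-compartment mixtures with a myelin pool (T2 15-30 ms,
    fraction 0.05-0.30 on the 0.05 fraction grid) and intra/extracellular
    pools at 60-120 ms, spanning realistic white-matter MWF values.
    """
    return [
        TissueConfig((20.0, 80.0), (0.10, 0.90), "wm_generic"),
        TissueConfig((15.0, 70.0), (0.20, 0.80), "wm_dense_myelin"),
        TissueConfig((25.0, 100.0), (0.05, 0.95), "wm_sparse_myelin"),
        TissueConfig((20.0, 60.0, 120.0), (0.15, 0.45, 0.40), "wm_three_pool"),
        TissueConfig((30.0, 90.0), (0.25, 0.75), "wm_heavy_myelin"),
    ]


def snap_tissues_to_grid(
    tissues: list[TissueConfig], t2_grid: np.ndarray
) -> list[TissueConfig]:
    """Replace each component T2 by the nearest value on a dictionary grid.

    Keeps recovery experiments well-posed: every ground-truth configuration
    is exactly expressible on the fitting grid.
    """
    g = np.asarray(t2_grid, dtype=float)
    out = []
    for t in tissues:
        snapped = tuple(float(g[np.argmin(np.abs(g - x))]) for x in t.t2s)
        if len(set(snapped)) != len(snapped):
            raise ValueError(f"grid too coarse: components of {t.label!r} collide")
        out.append(replace(t, t2s=snapped))
    return out


@dataclass
class PhantomVolume:
    """Simulated MESE volume with ground truth."""

    signals: np.ndarray  # (nx, ny, etl)
    ground_truth_mwf: np.ndarray
    ground_truth_b1: np.ndarray
    tissue_labels: np.ndarray  # int map, 0 = background
    mask: np.ndarray
    seq: SequenceParams
    voxel_size_mm: float = 2.5
    snr: float = np.inf
    seed: int | None = None
    tissues: list[TissueConfig] = field(default_factory=list)


def _radial_b1_field(
    shape: tuple[int, int],
    b1_span: tuple[float, float] = (0.85, 1.15),
    quantize_step: float | None = 0.05,
) -> np.ndarray:
    """Smooth radial B1+ profile, highest at the center.

    Mimics the center-bright transmit profile of a head coil; optionally
    quantized to the dictionary's B1+ grid step so the truth is on-grid.
    """
    nx, ny = shape
    y, x = np.mgrid[0:nx, 0:ny]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # Linear in radius so the quantized iso-B1 rings have equal width.
    r = np.sqrt(((x - cx) / cx) ** 2 + ((y - cy) / cy) ** 2)
    lo, hi = b1_span
    fld = hi - (hi - lo) * np.clip(r, 0.0, 1.0)
    if quantize_step:
        fld = np.round(fld / quantize_step) * quantize_step
    return fld


def build_shepp_logan(
    size: int = 90,
    tissues: list[TissueConfig] | None = None,
    seq: SequenceParams | None = None,
    backend: str = "epg",
    b1_span: tuple[float, float] = (0.85, 1.15),
    b1_quantize_step: float | None = 0.05,
    voxel_size_mm: float = 2.5,
    component_normalization: str = "unit_l2",
) -> PhantomVolume:
    """Noiseless multicompartment Shepp-Logan phantom.

    The five non-zero gray levels of the resampled Shepp-Logan image are
    assigned the five tissue configurations in ascending gray-level order.
    Each voxel's signal is the fraction-weighted sum of component decay
    curves simulated at the voxel's local B1+.
    """
    tissues = list(tissues) if tissues is not None else default_tissues()
    seq = seq or SequenceParams()
    if not any(any(t2 < MYELIN_T2_CUTOFF_MS for t2 in t.t2s) for t in tissues):
        raise ValueError("at least one tissue must contain a sub-40 ms component")

    img = resize(
        shepp_logan_phantom(), (size, size), order=0, anti_aliasing=False, preserve_range=True
    )
    levels = [v for v in np.unique(img) if v > 0]
    labels = np.zeros(img.shape, dtype=np.int32)
    for lab, v in enumerate(levels, start=1):
        labels[img == v] = 1 + (lab - 1) % len(tissues)
    mask = labels > 0

    b1_field = _radial_b1_field((size, size), b1_span, b1_quantize_step)

    sim = simulate_epg_mese if backend == "epg" else None
    if backend not in ("epg", "exponential"):
        raise ValueError(f"unknown backend {backend!r}")

    # Cache decay curves per (t2, b1) pair actually present.
    cache: dict[tuple[float, float], np.ndarray] = {}

    def curve(t2: float, b1: float) -> np.ndarray:
        key = (t2, b1 if backend == "epg" else 1.0)
        if key not in cache:
            c = sim(t2, seq, b1) if backend == "epg" else simulate_exponential(t2, seq)
            cache[key] = normalize_curves(c, component_normalization)
        return cache[key]

    signals = np.zeros((size, size, seq.etl))
    gt_mwf = np.full((size, size), np.nan)
    for lab, tissue in enumerate(tissues, start=1):
        sel = labels == lab
        if not sel.any():
            continue
        gt_mwf[sel] = tissue.mwf
        for b1 in np.unique(b1_field[sel]):
            here = sel & (b1_field == b1)
            sig = sum(
                f * curve(t2, float(b1)) for t2, f in zip(tissue.t2s, tissue.fractions)
            )
            signals[here] = sig

    gt_b1 = np.where(mask, b1_field, np.nan)
    return PhantomVolume(
        signals=signals,
        ground_truth_mwf=gt_mwf,
        ground_truth_b1=gt_b1,
        tissue_labels=labels,
        mask=mask,
        seq=seq,
        voxel_size_mm=voxel_size_mm,
        tissues=tissues,
    )


def add_rician_noise(volume: PhantomVolume, snr: float, seed: int) -> PhantomVolume:
    """Add magnitude (Rician) noise at the given first-echo SNR.

    Per voxel, ``sigma = first_echo / snr``; each echo amplitude ``a`` is
    replaced by ``|a + n_re + i n_im|`` with independent
    ``Normal(0, sigma)`` components.  Ground-truth maps are untouched.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return replace(volume, snr=snr, seed=seed)
    rng = np.random.default_rng(seed)
    sig = volume.signals
    sigma = sig[..., :1] / snr
    noisy = np.abs(
        sig + rng.normal(0.0, 1.0, sig.shape) * sigma + 1j * rng.normal(0.0, 1.0, sig.shape) * sigma
    )
    return replace(volume, signals=noisy, snr=snr, seed=seed)


#: short-T2 (20 ms) area fractions of the nine emulated tubes
TUBE_SHORT_FRACTIONS = (0.0, 0.0, 0.038, 0.071, 0.111, 0.143, 0.185, 0.217, 0.262)
#: middle-compartment (60 ms) area fractions, one per tube
TUBE_MID_FRACTIONS = (0.0, 0.05, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18)


def build_tube_phantom(
    short_fractions: tuple[float, ...] = TUBE_SHORT_FRACTIONS,
    mid_fractions: tuple[float, ...] = TUBE_MID_FRACTIONS,
    compartment_t2s: tuple[float, float, float] = (80.0, 60.0, 20.0),
    seq: SequenceParams | None = None,
    backend: str = "epg",
    n_replicates: int = 40,
    snr: float = np.inf,
    seed: int = 0,
    component_normalization: str = "unit_l2",
) -> tuple[np.ndarray, np.ndarray]:
    """Emulated capillary-tube phantom signals with known short-T2 fractions.

    Each tube occupies a single voxel; its signal is the area-weighted sum
    of the three compartment decays (background, mid-T2 capillaries,
    short-T2 capillaries).  ``n_replicates`` independent copies per tube
    emulate repeated slices/offsets; with finite ``snr`` each copy gets its
    own Rician noise.

    Returns ``(signals, truth)`` with signals shaped
    ``(n_tubes * n_replicates, etl)`` and truth the matching ground-truth
    short-T2 fraction per row.
    """
    if len(short_fractions) != len(mid_fractions):
        raise ValueError("fraction lists must have equal length")
    seq = seq or SequenceParams(etl=24, echo_spacing=7.9)
    t_bg, t_mid, t_short = compartment_t2s

    def curve(t2: float) -> np.ndarray:
        c = simulate_epg_mese(t2, seq, 1.0) if backend == "epg" else simulate_exponential(t2, seq)
        return normalize_curves(c, component_normalization)

    c_bg, c_mid, c_short = curve(t_bg), curve(t_mid), curve(t_short)
    rows = []
    truth = []
    for fs, fm in zip(short_fractions, mid_fractions):
        if fs + fm > 1:
            raise ValueError("capillary areas exceed the tube cross-section")
        sig = (1 - fs - fm) * c_bg + fm * c_mid + fs * c_short
        rows.append(np.tile(sig, (n_replicates, 1)))
        truth.extend([fs] * n_replicates)
    signals = np.vstack(rows)
    truth_arr = np.asarray(truth)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = signals[:, :1] / snr
        signals = np.abs(
            signals
            + rng.normal(0.0, 1.0, signals.shape) * sigma
            + 1j * rng.normal(0.0, 1.0, signals.shape) * sigma
        )
    return signals, truth_arr
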