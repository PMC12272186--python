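"""Multicomponent-T2 (mcT2) motif dictionaries.

A *motif* is a specific sub-voxel water-pool configuration: a set of
component T2 values drawn from the single-T2 grid, relative fractions
summing to one, and a transmit-field (B1+) scale.  Its signal is the
fraction-weighted combination of the component decay curves.  The motif
dictionary enumerates every such configuration on a discrete fraction grid,
then prunes configurations that are not physiological for white matter:

* rule A -- no component below the myelin cutoff (default 40 ms);
* rule B -- total fraction of sub-cutoff components exceeding the myelin
  ceiling (default 30%);
* rule C -- equivalent single-T2 outside the range observed in the masked
  tissue.

For a two-compartment dictionary the number of motifs is
``[C(n_t2, 1) + C(n_t2, 2) * (n_frac - 2)] * n_b1``: each distinct T2 pair
takes one of the ``n_frac - 2`` strictly interior fraction splits, pure
single-T2 motifs are counted once, and everything is crossed with the B1+
grid.  The fraction grid {0, Δf, 2Δf, ..., 1} contains ``1/Δf + 1`` values
including both endpoints.

Configurations are stored crossed with the *full* B1+ grid so that the B1+
correction can form the Eq.-style homogeneous/inhomogeneous signal ratio for
any motif; scoring and spectrum fitting use the B1+ = 1.0 plane.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator

import numpy as np

from .simulate import SingleT2Dictionary, normalize_curves

__all__ = [
    "FractionGrid",
    "MotifDictionary",
    "count_motifs",
    "enumerate_motifs",
    "fit_equivalent_single_t2",
    "prune_motifs",
    "estimate_wm_t2_range",
]

MYELIN_T2_CUTOFF_MS = 40.0


@dataclass(frozen=True)
class FractionGrid:
    """Admissible fraction values {0, delta_f, ..., 1}."""

    delta_f: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.delta_f <= 0.5):
            raise ValueError("delta_f must lie in (0, 0.5]")
        n = 1.0 / self.delta_f
        if abs(n - round(n)) > 1e-9:
            raise ValueError("1/delta_f must be an integer so the grid reaches 1")

    @property
    def n_frac(self) -> int:
        """Number of grid values including both 0 and 1."""
        return int(round(1.0 / self.delta_f)) + 1

    @property
    def values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_frac)

    @property
    def interior(self) -> np.ndarray:
        """Strictly positive fractions below 1 (the two-compartment splits)."""
        return self.values[1:-1]


def count_motifs(n_t2: int, n_frac: int, n_b1: int) -> int:
    """Size of the two-compartment motif dictionary by combinatorics.

    ``[C(n_t2,1) + C(n_t2,2) * (n_frac - 2)] * n_b1`` -- pure single-T2
    motifs plus every distinct T2 pair at every interior fraction split,
    crossed with the B1+ grid.  For the published grid (200 T2 values,
    fraction step 0.05 i.e. 21 grid values, 9 B1+ values) this is 3,404,700.
    """
    if n_t2 < 1 or n_b1 < 1:
        raise ValueError("grid sizes must be positive")
    if n_frac < 2:
        raise ValueError("the fraction grid must contain at least {0, 1}")
    return (comb(n_t2, 1) + comb(n_t2, 2) * (n_frac - 2)) * n_b1


@dataclass
class MotifDictionary:
    """Enumerated (and possibly pruned) motif configurations.

    Attributes
    ----------
    component_indices
        ``(n_cfg, n_comp_max)`` int array of T2 grid indices, ``-1`` padding
        for configurations with fewer components.  Indices are strictly
        increasing within a row.
    fractions
        ``(n_cfg, n_comp_max)`` float array, zero-padded; each row sums to 1.
    signals
        ``(n_cfg, n_b1, etl)`` motif signals, normalized per the source
        dictionary's mode.
    equivalent_t2
        ``(n_cfg, n_b1)`` best-matching single-T2 (ms) per configuration and
        B1+ plane; NaN until :func:`fill_equivalent_t2` runs.
    global_score
        Per-configuration score filled by the scoring module.
    """

    source: SingleT2Dictionary
    component_indices: np.ndarray
    fractions: np.ndarray
    signals: np.ndarray
    equivalent_t2: np.ndarray | None = None
    global_score: np.ndarray | None = None
    pruning_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.component_indices.shape != self.fractions.shape:
            raise ValueError("component_indices and fractions shapes differ")
        if self.signals.shape[0] != self.component_indices.shape[0]:
            raise ValueError("signals row count mismatch")
        live = self.fractions > 0
        if self.n_motifs and not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("fractions must sum to 1 per motif")
        if np.any((self.component_indices < 0) & live):
            raise ValueError("positive fraction on a padded component")

    @property
    def n_motifs(self) -> int:
        return self.component_indices.shape[0]

    @property
    def b1_grid(self) -> np.ndarray:
        return self.source.b1_grid

    @property
    def etl(self) -> int:
        return self.signals.shape[2]

    def component_t2s(self, i: int) -> np.ndarray:
        """Component T2 values (ms) of configuration ``i``, padding removed."""
        idx = self.component_indices[i]
        return self.source.t2_grid[idx[idx >= 0]]

    def motif_fractions(self, i: int) -> np.ndarray:
        f = self.fractions[i]
        return f[f > 0]

    def short_fraction(self, cutoff_ms: float = MYELIN_T2_CUTOFF_MS) -> np.ndarray:
        """Summed fraction of components with T2 < cutoff, per configuration."""
        t2 = np.where(
            self.component_indices >= 0,
            self.source.t2_grid[np.clip(self.component_indices, 0, None)],
            np.inf,
        )
        return np.where(t2 < cutoff_ms, self.fractions, 0.0).sum(axis=1)

    def mwf(self, cutoff_ms: float = MYELIN_T2_CUTOFF_MS) -> np.ndarray:
        """Myelin water fraction of each motif (mass at T2 <= cutoff)."""
        t2 = np.where(
            self.component_indices >= 0,
            self.source.t2_grid[np.clip(self.component_indices, 0, None)],
            np.inf,
        )
        return np.where(t2 <= cutoff_ms, self.fractions, 0.0).sum(axis=1)

    def signals_at_b1(self, b1_scale: float = 1.0) -> np.ndarray:
        """Motif signal matrix ``(n_cfg, etl)`` at one B1+ plane."""
        return self.signals[:, self.source.b1_index(b1_scale), :]

    def fraction_matrix(self) -> np.ndarray:
        """F in w = F W: ``(n_t2, n_cfg)`` map from motif weights to the T2 grid."""
        F = np.zeros((self.source.n_t2, self.n_motifs))
        rows = self.component_indices
        for i in range(self.n_motifs):
            live = rows[i] >= 0
            F[rows[i, live], i] += self.fractions[i, live]
        return F

    def select(self, keep: np.ndarray) -> "MotifDictionary":
        """New dictionary restricted to configurations where ``keep`` holds."""
        return MotifDictionary(
            source=self.source,
            component_indices=self.component_indices[keep],
            fractions=self.fractions[keep],
            signals=self.signals[keep],
            equivalent_t2=None if self.equivalent_t2 is None else self.equivalent_t2[keep],
            global_score=None if self.global_score is None else self.global_score[keep],
            pruning_report=dict(self.pruning_report),
        )


def _iter_configs(n_t2: int, n_comp: int, frac_grid: FractionGrid) -> Iterator[tuple[tuple[int, ...], tuple[float, ...]]]:
    """Yield (t2 indices, fractions) with distinct increasing indices and
    positive grid fractions summing to 1, in deterministic order."""
    n_steps = frac_grid.n_frac - 1  # integer fraction units, f = k / n_steps
    # Pure motifs first.
    for i in range(n_t2):
        yield (i,), (1.0,)
    if n_comp >= 2:
        for i, j in itertools.combinations(range(n_t2), 2):
            for k in range(1, n_steps):
                yield (i, j), (k / n_steps, (n_steps - k) / n_steps)
    if n_comp >= 3:
        for i, j, l in itertools.combinations(range(n_t2), 3):
            for k1 in range(1, n_steps - 1):
                for k2 in range(1, n_steps - k1):
                    k3 = n_steps - k1 - k2
                    yield (i, j, l), (k1 / n_steps, k2 / n_steps, k3 / n_steps)


def enumerate_motifs(
    dictionary: SingleT2Dictionary,
    n_comp: int = 2,
    frac_grid: FractionGrid | None = None,
) -> MotifDictionary:
    """Enumerate every motif configuration on the fraction grid.

    Signals are built as fraction-weighted sums of the stored (normalized)
    single-T2 curves and re-normalized per the dictionary's mode, for every
    B1+ plane at once.
    """
    if n_comp not in (2, 3):
        raise ValueError("n_comp must be 2 or 3")
    if n_comp > dictionary.n_t2:
        raise ValueError("n_comp exceeds the number of distinct T2 grid values")
    frac_grid = frac_grid or FractionGrid()

    configs = list(_iter_configs(dictionary.n_t2, n_comp, frac_grid))
    n_cfg = len(configs)
    idx = np.full((n_cfg, n_comp), -1, dtype=np.int64)
    frac = np.zeros((n_cfg, n_comp))
    for r, (ii, ff) in enumerate(configs):
        idx[r, : len(ii)] = ii
        frac[r, : len(ff)] = ff

    # signals[r, k, :] = sum_n frac[r, n] * curves[idx[r, n], k, :]
    safe = np.clip(idx, 0, None)
    signals = np.einsum("rn,rnke->rke", frac, dictionary.curves[safe])
    signals = normalize_curves(signals, dictionary.normalization_mode)

    return MotifDictionary(
        source=dictionary,
        component_indices=idx,
        fractions=frac,
        signals=signals,
    )


def fit_equivalent_single_t2(
    signal: np.ndarray,
    dictionary: SingleT2Dictionary,
    b1_scale: float = 1.0,
) -> float:
    """Grid T2 (ms) whose curve is L2-closest to ``signal`` at one B1+ plane.

    Ties break toward the lower T2.  Signal and dictionary must share the
    same normalization; the signal is re-normalized defensively.
    """
    signal = np.asarray(signal, dtype=float)
    if np.allclose(signal, 0):
        raise ValueError("cannot fit an all-zero signal")
    signal = normalize_curves(signal, dictionary.normalization_mode)
    plane = dictionary.curves[:, dictionary.b1_index(b1_scale), :]
    d2 = np.sum((plane - signal) ** 2, axis=1)
    return float(dictionary.t2_grid[int(np.argmin(d2))])  # argmin takes first (lower T2) tie


def fill_equivalent_t2(motifs: MotifDictionary) -> MotifDictionary:
    """Fill ``equivalent_t2`` for every configuration and B1+ plane in place."""
    src = motifs.source
    eq = np.empty((motifs.n_motifs, src.n_b1))
    for k in range(src.n_b1):
        plane = src.curves[:, k, :]  # (n_t2, etl)
        sig = motifs.signals[:, k, :]  # (n_cfg, etl)
        # ||p - s||^2 = ||p||^2 - 2 p.s + ||s||^2; the ||s||^2 term is constant per row
        d2 = np.sum(plane**2, axis=1)[None, :] - 2.0 * sig @ plane.T
        eq[:, k] = src.t2_grid[np.argmin(d2, axis=1)]
    motifs.equivalent_t2 = eq
    return motifs


def estimate_wm_t2_range(
    signals: np.ndarray,
    dictionary: SingleT2Dictionary,
    percentiles: tuple[float, float] = (1.0, 99.0),
    margin_steps: float = 2.0,
) -> tuple[float, float]:
    """Range of single-T2 values present in the masked tissue.

    Fits each voxel signal to the best (T2, B1+) dictionary entry, takes
    the requested percentiles of the fitted T2 values, and widens them by
    ``margin_steps`` logarithmic grid steps on each side.  The widening
    absorbs the systematic offset between a voxel's joint (T2, B1+)
    single-T2 fit and a motif's fixed-plane equivalent T2 (a single-T2
    curve can trade B1+ against T2), keeping rule C an *outlier* filter
    rather than a tight band.

    Parameters
    ----------
    signals
        ``(n_voxels, etl)`` masked voxel signals, any scaling.
    """
    signals = normalize_curves(np.asarray(signals, dtype=float), dictionary.normalization_mode)
    flat = dictionary.curves.reshape(-1, dictionary.etl)  # (n_t2 * n_b1, etl)
    d2 = np.sum(flat**2, axis=1)[None, :] - 2.0 * signals @ flat.T
    best = np.argmin(d2, axis=1) // dictionary.n_b1
    t2s = dictionary.t2_grid[best]
    lo, hi = np.percentile(t2s, percentiles)
    g = dictionary.t2_grid
    step = g[1] / g[0] if len(g) > 1 else 1.0
    factor = step**margin_steps
    return float(lo / factor), float(hi * factor)


def prune_motifs(
    motifs: MotifDictionary,
    wm_t2_range: tuple[float, float],
    short_t2_cutoff: float = MYELIN_T2_CUTOFF_MS,
    max_short_fraction: float = 0.30,
) -> MotifDictionary:
    """Remove non-physiological configurations.

    Rule A: no component T2 strictly below ``short_t2_cutoff``.
    Rule B: summed fraction of sub-cutoff components exceeds
    ``max_short_fraction``.
    Rule C: equivalent single-T2 (at the B1+ = 1.0 plane, or the plane
    closest to 1.0) outside ``wm_t2_range``.

    The pruning report itemizes removals; a motif failing several rules is
    counted under the first that fires (A, then B, then C).
    """
    if motifs.equivalent_t2 is None:
        fill_equivalent_t2(motifs)

    src = motifs.source
    t2 = np.where(
        motifs.component_indices >= 0,
        src.t2_grid[np.clip(motifs.component_indices, 0, None)],
        np.inf,
    )
    has_short = np.any(t2 < short_t2_cutoff, axis=1)
    short_frac = motifs.short_fraction(short_t2_cutoff)
    k_home = int(np.argmin(np.abs(src.b1_grid - 1.0)))
    eq_home = motifs.equivalent_t2[:, k_home]

    rule_a = ~has_short
    rule_b = ~rule_a & (short_frac > max_short_fraction + 1e-12)
    rule_c = ~rule_a & ~rule_b & ((eq_home < wm_t2_range[0]) | (eq_home > wm_t2_range[1]))
    keep = ~(rule_a | rule_b | rule_c)

    if not np.any(keep):
        counts = {"A": int(rule_a.sum()), "B": int(rule_b.sum()), "C": int(rule_c.sum())}
        binding = max(counts, key=counts.get)
        raise RuntimeError(
            f"pruning removed every motif (counts {counts}); rule {binding} is binding -- "
            "check the WM T2 range and the short-T2 cutoff against the data"
        )

    out = motifs.select(keep)
    out.pruning_report = {
        "enumerated": motifs.n_motifs,
        "removed_rule_a_no_short_component": int(rule_a.sum()),
        "removed_rule_b_short_fraction": int(rule_b.sum()),
        "removed_rule_c_equivalent_t2": int(rule_c.sum()),
        "retained": int(keep.sum()),
    }
    return out
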