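"""Transmit-field (B1+) estimation and signal correction.

Imperfect refocusing pulses (local flip angle = B1+ scale x nominal flip)
bias MESE decay curves through stimulated-echo pathways.  The correction
works entirely from the MESE data itself, in three stages:

1. *Initial map* -- per voxel, exhaustive search for the motif (over all
   configurations and B1+ planes) whose signal is L2-closest to the voxel
   signal; the motif's B1+ plane is the initial estimate.
2. *Spatial smoothing* -- iterated conditional modes on the discrete B1+
   grid, minimizing per voxel a data term (best motif residual at each
   candidate B1+ plane) plus an L1 smoothness prior over a 2-D kernel:
   ``cost(b) = min_i ||d_i(b) - s_j||_2 + mu/|N_k| * sum_r |b - B1(r)|``.
   Sweeps are Jacobi-style (neighbors from the previous sweep), so the
   result is independent of traversal order; iteration stops when no voxel
   changes or after ``n_iter_max`` sweeps.
3. *Correction* -- the voxel signal is moved to the homogeneous condition
   echo-wise via the best-matching motif's curve ratio:
   ``s_cor(t) = s(t) * d(t) / d(B1_opt, t)`` where ``d`` is the same motif
   at B1+ = 100%.

The data term at every candidate plane re-minimizes over motifs (the cost
is a function of B1+ alone), which allows precomputing a compact
``(n_b1, n_voxels)`` residual table once per dataset.

Transmit-fold degeneracy
------------------------
With a single effective flip angle, the MESE signal is *exactly* invariant
under ``b1 -> 2 - b1`` (a refocusing rotation by beta and by 360 - beta
produce mirror-image magnetization with identical magnitude), so the data
determine only ``|b1 - 1|``.  Signal models that integrate a slice profile
break this symmetry; a single-flip EPG does not.  When the dictionary
exhibits the degeneracy (mirror planes carry identical curves), estimation
runs on the folded grid and reports the ``<= 1.0`` representative of each
fold class.  The Eq.-16-style correction ratio is identical for both
branches, so MWF fitting is unaffected by the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import MotifDictionary
from .simulate import normalize_curves

__all__ = ["B1Params", "B1Map", "initial_b1_map", "smooth_b1_map", "correct_signals"]

#: sentinel stored outside the mask
B1_SENTINEL = np.nan


@dataclass(frozen=True)
class B1Params:
    """Smoothing parameters for the iterative B1+ refinement.

    mu
        Weight of the L1 smoothness prior (0 disables smoothing).
    kernel_extent_mm
        Side length of the square in-plane kernel, in mm; converted to an
        odd voxel count.  The center voxel is not its own neighbor.
    n_iter_max
        Cap on the number of full-image sweeps.
    """

    mu: float = 1.0
    kernel_extent_mm: float = 15.0
    n_iter_max: int = 200

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.n_iter_max < 1:
            raise ValueError("n_iter_max must be >= 1")
        if not (self.kernel_extent_mm > 0):
            raise ValueError("kernel extent must be positive")

    def kernel_half_width(self, voxel_size_mm: float) -> int:
        """Half-width in voxels of the odd-sized kernel."""
        n = int(round(self.kernel_extent_mm / voxel_size_mm))
        if n % 2 == 0:
            n += 1
        return max(n // 2, 1)


@dataclass
class B1Map:
    """Per-voxel B1+ scale restricted to the dictionary grid."""

    values: np.ndarray  # (nx, ny), NaN outside the mask
    mask: np.ndarray
    b1_grid: np.ndarray
    iterations_run: int = 0
    converged: bool = True

    def grid_indices(self) -> np.ndarray:
        """Integer grid index per masked voxel (flat, mask order)."""
        vals = self.values[self.mask]
        idx = np.argmin(np.abs(vals[:, None] - self.b1_grid[None, :]), axis=1)
        return idx


def _residual_table(signals: np.ndarray, motifs: MotifDictionary) -> np.ndarray:
    """Min-over-motifs L2 residual per (B1+ plane, voxel).

    ``signals`` is ``(n_voxels, etl)`` and must share the motif dictionary's
    normalization.  Chunked over motifs so peak memory stays bounded.
    """
    n_vox = signals.shape[0]
    n_b1 = motifs.source.n_b1
    table = np.full((n_b1, n_vox), np.inf)
    chunk = max(1, int(2e7) // max(n_vox, 1))
    for k in range(n_b1):
        plane = motifs.signals[:, k, :]
        for lo in range(0, plane.shape[0], chunk):
            block = plane[lo : lo + chunk]
            d2 = (
                np.sum(block**2, axis=1)[:, None]
                - 2.0 * block @ signals.T
                + np.sum(signals**2, axis=1)[None, :]
            )
            np.minimum(table[k], d2.min(axis=0), out=table[k])
    return np.sqrt(np.maximum(table, 0.0))


def _fold_classes(motifs: MotifDictionary, atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray] | None:
    """Detect the b1 <-> 2 - b1 signal degeneracy on the dictionary grid.

    Returns ``(folded_grid, members)`` where ``folded_grid`` holds the
    <= 1.0 representative of each fold class and ``members[c]`` lists the
    original plane indices in class ``c`` -- or None when the grid has no
    mirror pairs or the backend distinguishes them.
    """
    b1 = motifs.source.b1_grid
    classes: dict[float, list[int]] = {}
    for k, b in enumerate(b1):
        rep = round(min(b, 2.0 - b), 9)
        classes.setdefault(rep, []).append(k)
    if all(len(v) == 1 for v in classes.values()):
        return None
    sample = motifs.signals[:: max(1, motifs.n_motifs // 64)]
    for members in classes.values():
        k0 = members[0]
        for k in members[1:]:
            if not np.allclose(sample[:, k0, :], sample[:, k, :], atol=atol):
                return None  # backend breaks the mirror symmetry
    reps = sorted(classes)
    return (
        np.asarray(reps),
        [np.asarray(classes[r], dtype=np.int64) for r in reps],
    )


def _fold_table(
    table: np.ndarray, motifs: MotifDictionary
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse mirror-degenerate planes of a residual table.

    Returns ``(table, grid)`` unchanged when no degeneracy is present.
    """
    fold = _fold_classes(motifs)
    if fold is None:
        return table, motifs.source.b1_grid
    grid, members = fold
    folded = np.stack([table[m].min(axis=0) for m in members])
    return folded, grid


def _tie_broken_argmin(cost: np.ndarray, b1_grid: np.ndarray) -> np.ndarray:
    """Argmin over the B1+ axis (axis 0), ties toward B1+ closest to 1.0."""
    # Perturb by a lexicographic tie-break key that never exceeds cost gaps
    # of interest: sort candidate order by (|b1 - 1|, b1) and pick the first
    # index attaining the minimum in that order.
    order = np.lexsort((b1_grid, np.abs(b1_grid - 1.0)))
    reordered = cost[order]
    pick = order[np.argmin(reordered, axis=0)]
    return pick


def initial_b1_map(
    signals: np.ndarray,
    motifs: MotifDictionary,
    mask: np.ndarray,
    _table: np.ndarray | None = None,
) -> B1Map:
    """Exhaustive-search B1+ estimate per masked voxel.

    Returns the B1+ plane of the globally best-matching motif; ties break
    toward the grid value closest to 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vox = normalize_curves(signals[mask], motifs.source.normalization_mode)
    table = _residual_table(vox, motifs) if _table is None else _table
    table, b1_grid = _fold_table(table, motifs)
    idx = _tie_broken_argmin(table, b1_grid)
    values = np.full(mask.shape, B1_SENTINEL)
    values[mask] = b1_grid[idx]
    return B1Map(values=values, mask=mask, b1_grid=b1_grid)


def _neighbor_offsets(half_width: int) -> list[tuple[int, int]]:
    return [
        (dx, dy)
        for dx in range(-half_width, half_width + 1)
        for dy in range(-half_width, half_width + 1)
        if (dx, dy) != (0, 0)
    ]


def smooth_b1_map(
    signals: np.ndarray,
    motifs: MotifDictionary,
    b1_init: B1Map,
    params: B1Params,
    voxel_size_mm: float = 1.0,
) -> B1Map:
    """Iteratively smooth the B1+ map on the discrete grid (ICM).

    With ``mu = 0`` the output equals ``b1_init`` exactly.  Each sweep
    updates every masked voxel to the grid value minimizing data residual
    plus ``mu/|N_k|`` times the summed absolute difference to its in-mask
    kernel neighbors (previous sweep's values).
    """
    mask = b1_init.mask
    vox = normalize_curves(signals[mask], motifs.source.normalization_mode)
    table = _residual_table(vox, motifs)  # (n_b1, n_masked)
    table, b1_grid = _fold_table(table, motifs)
    if len(b1_grid) != len(b1_init.b1_grid) or not np.allclose(b1_grid, b1_init.b1_grid):
        raise ValueError("b1_init grid does not match the (possibly folded) estimation grid")

    if params.mu == 0:
        out = B1Map(
            values=b1_init.values.copy(),
            mask=mask,
            b1_grid=b1_grid,
            iterations_run=0,
            converged=True,
        )
        return out

    half = params.kernel_half_width(voxel_size_mm)
    offsets = _neighbor_offsets(half)
    nx, ny = mask.shape
    flat_index = -np.ones(mask.shape, dtype=np.int64)
    flat_index[mask] = np.arange(mask.sum())
    coords = np.argwhere(mask)

    # Padded neighbor index matrix per masked voxel (in-mask, in-bounds only);
    # -1 entries point at a zero-weight slot.
    n_vox = int(mask.sum())
    nbr = np.full((n_vox, len(offsets)), -1, dtype=np.int64)
    for c, (dx, dy) in enumerate(offsets):
        u = coords[:, 0] + dx
        v = coords[:, 1] + dy
        ok = (u >= 0) & (u < nx) & (v >= 0) & (v < ny)
        ok[ok] &= mask[u[ok], v[ok]]
        nbr[ok, c] = flat_index[u[ok], v[ok]]
    valid = nbr >= 0
    n_nbr = np.maximum(valid.sum(axis=1), 1)

    current = np.argmin(np.abs(b1_init.values[mask][:, None] - b1_grid[None, :]), axis=1)
    order = np.lexsort((b1_grid, np.abs(b1_grid - 1.0)))  # tie-break toward 1.0
    previous = None
    converged = False
    it = 0
    for it in range(1, params.n_iter_max + 1):
        prev_vals = b1_grid[current]
        nv = np.where(valid, prev_vals[np.clip(nbr, 0, None)], np.nan)
        # prior[b, j] = sum_r |b1_grid[b] - B1_prev(r)| over valid neighbors r
        prior = np.nansum(
            np.abs(b1_grid[:, None, None] - nv[None, :, :]), axis=2
        )
        cost = table + (params.mu / n_nbr)[None, :] * prior
        new = order[np.argmin(cost[order], axis=0)]
        if np.array_equal(new, current):
            converged = True
            break
        if previous is not None and np.array_equal(new, previous):
            # Jacobi sweeps can settle into a two-state cycle; both states
            # are fixed points of the alternating update -- keep the current.
            converged = True
            break
        previous = current
        current = new

    values = np.full(mask.shape, B1_SENTINEL)
    values[mask] = b1_grid[current]
    return B1Map(
        values=values,
        mask=mask,
        b1_grid=b1_grid,
        iterations_run=it,
        converged=converged,
    )


def correct_signals(
    signals: np.ndarray,
    b1_map: B1Map,
    motifs: MotifDictionary,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Move masked voxel signals to the homogeneous (B1+ = 100%) condition.

    For each voxel, the best-matching motif at the voxel's estimated B1+
    plane supplies the curve ratio ``d(t) / d(B1_opt, t)`` applied
    echo-wise.  Voxels estimated at B1+ = 1.0 are returned unchanged;
    unmasked voxels pass through untouched.
    """
    mask = b1_map.mask if mask is None else np.asarray(mask, dtype=bool)
    src = motifs.source
    k_home = src.b1_index(1.0)
    out = np.array(signals, dtype=float, copy=True)
    vox_raw = signals[mask]
    vox = normalize_curves(vox_raw, src.normalization_mode)
    # Map (possibly folded) estimates onto source-grid plane indices.
    vals = b1_map.values[mask]
    plane_idx = np.argmin(np.abs(vals[:, None] - src.b1_grid[None, :]), axis=1)

    for k in np.unique(plane_idx):
        sel = plane_idx == k
        if k == k_home:
            continue  # identity ratio by construction
        plane = motifs.signals[:, k, :]
        d2 = (
            np.sum(plane**2, axis=1)[:, None]
            - 2.0 * plane @ vox[sel].T
        )
        best = np.argmin(d2, axis=0)
        d_inhom = motifs.signals[best, k, :]
        if np.any(d_inhom == 0):
            raise ValueError("degenerate motif curve with a zero amplitude")
        d_home = motifs.signals[best, k_home, :]
        corrected = vox_raw[sel] * d_home / d_inhom
        tmp = out[mask]
        tmp[sel] = corrected
        out[mask] = tmp
    return out
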