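"""Independent reference implementations used only to check the package.

These deliberately share no code with ``mwimotif``: the isochromat
simulator integrates Bloch rotation matrices over discrete spin phases,
the RNNLS oracle evaluates the objective on a dense grid, and the metric
formulas are written out longhand.
"""

from __future__ import annotations

import itertools

import numpy as np


def isochromat_mese(
    t2: float,
    etl: int,
    echo_spacing: float,
    refocusing_flip_deg: float,
    b1_scale: float,
    t1: float = 1000.0,
    excitation_flip_deg: float = 90.0,
    n_spins: int = 720,
) -> np.ndarray:
    """Brute-force MESE simulation: rotation matrices + crusher dephasing.

    Each spin accrues a fixed phase per half echo-spacing (ideal crusher
    pair); the echo is the magnitude of the complex mean transverse
    magnetization over >= 360 uniformly spread phases.
    """
    theta = 2 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    M = np.zeros((n_spins, 3))
    M[:, 2] = 1.0

    def rot_y(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rot_x(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    M = M @ rot_y(np.deg2rad(excitation_flip_deg)).T
    tau = echo_spacing / 2.0
    e2, e1 = np.exp(-tau / t2), np.exp(-tau / t1)
    R = rot_x(np.deg2rad(b1_scale * refocusing_flip_deg))
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def relax_dephase(M):
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        x = M[:, 0] * cos_t - M[:, 1] * sin_t
        y = M[:, 0] * sin_t + M[:, 1] * cos_t
        M[:, 0], M[:, 1] = x, y
        return M

    echoes = []
    for _ in range(etl):
        M = relax_dephase(M)
        M = M @ R.T
        M = relax_dephase(M)
        echoes.append(abs(np.mean(M[:, 0] + 1j * M[:, 1])))
    return np.asarray(echoes)


def rnnls_objective(D: np.ndarray, s: np.ndarray, W: np.ndarray, lam_t: float, lam_1: float) -> float:
    r = D @ W - s
    return 0.5 * float(r @ r) + lam_t * float(W @ W) + lam_1 * float(np.abs(W).sum())


def rnnls_grid_search(
    D: np.ndarray, s: np.ndarray, lam_t: float, lam_1: float, w_max: float = 1.5, n: int = 61
) -> tuple[np.ndarray, float]:
    """Dense grid search over the non-negative weight box (small problems)."""
    grid = np.linspace(0.0, w_max, n)
    best_w, best_obj = None, np.inf
    for combo in itertools.product(grid, repeat=D.shape[1]):
        w = np.asarray(combo)
        obj = rnnls_objective(D, s, w, lam_t, lam_1)
        if obj < best_obj:
            best_obj, best_w = obj, w
    return best_w, best_obj


def pairwise_auc(scores, labels) -> float:
    """AUC by exhaustive pair counting (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def longhand_map_metrics(est, tru):
    """MAE / RMSD / Pearson / Bland-Altman written out explicitly."""
    est = np.asarray(est, dtype=float)
    tru = np.asarray(tru, dtype=float)
    d = est - tru
    mae = np.abs(d).sum() / len(d)
    rmsd = np.sqrt((d**2).sum() / len(d))
    ex, et = est - est.mean(), tru - tru.mean()
    r = (ex * et).sum() / np.sqrt((ex**2).sum() * (et**2).sum())
    mean_diff = d.mean()
    sd = np.sqrt(((d - mean_diff) ** 2).sum() / (len(d) - 1))
    return mae, rmsd, r, mean_diff, (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
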