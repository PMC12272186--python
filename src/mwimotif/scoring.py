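"""Global motif scoring and pseudo-orthogonal basis selection.

Every motif is compared against every masked voxel signal.  The per-pair
cost is a squared-L2 data residual plus an entropy penalty on the motif's
fraction vector (favoring simple spectral configurations):

    kappa_ij = alpha_ij + beta_i,
    alpha_ij = ||d_i - s_j||_2^2,
    beta_i   = lambda_ent * sum_n (-f_n log f_n).

``alpha`` is the *squared* L2 difference so that the similarity threshold
``xi_mv = delta_mv**2 * ETL`` reads as "per-echo RMS difference below
delta_mv"; a (motif, voxel) pair is similar when ``alpha < xi_mv``, and
alpha is clipped at ``clip_factor * xi_mv`` so grossly dissimilar voxels
cannot dominate a motif's score.  Costs are normalized per motif to [0, 1]
(kappa_hat = 1 - kappa / max_j kappa) and summed over voxels into a global
score K_i.

The final basis is picked greedily in descending K_i under a coverage /
distinctness rule: a candidate enters the basis if its similar-voxel set
adds enough not-yet-covered voxels, or if it is spectrally distinct
(equivalent T2 in log-ms, or myelin fraction) from every accepted motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .motifs import MotifDictionary, fill_equivalent_t2
from .simulate import normalize_curves

__all__ = [
    "CostParams",
    "ScoreTable",
    "entropy_penalty",
    "similarity_threshold",
    "compute_costs",
    "normalize_and_aggregate",
    "select_basis",
]


@dataclass(frozen=True)
class CostParams:
    """Cost-model parameters.

    lambda_ent
        Entropy regularization weight (0.001 for in-vivo-like data).
    delta_mv
        Per-echo amplitude tolerance defining motif/voxel similarity; the
        published values are 0.01 (in vivo and high-SNR simulations,
        relaxed toward 0.02 at low SNR) and 0.008 (physical phantom).
    clip_factor
        Residuals are clipped at ``clip_factor * xi_mv`` (default 5).
    """

    lambda_ent: float = 0.001
    delta_mv: float = 0.01
    clip_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_ent < 0:
            raise ValueError("lambda_ent must be >= 0")
        if not (self.delta_mv > 0):
            raise ValueError("delta_mv must be > 0")
        if not (self.clip_factor > 1):
            raise ValueError("clip_factor must exceed 1")


def entropy_penalty(fractions: np.ndarray, lambda_ent: float) -> float:
    """beta = lambda_ent * Shannon entropy (natural log) of the fractions."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fractions must be strictly positive")
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("fractions must sum to 1")
    return float(lambda_ent * np.sum(-f * np.log(f)))


def similarity_threshold(delta_mv: float, etl: int) -> float:
    """xi_mv = delta_mv^2 * ETL (a squared-L2 budget of delta_mv per echo)."""
    if not (delta_mv > 0):
        raise ValueError("delta_mv must be > 0")
    if etl < 1:
        raise ValueError("etl must be >= 1")
    return delta_mv**2 * etl


@dataclass
class ScoreTable:
    """Motif-vs-voxel cost aggregates.

    ``alpha``/``kappa`` (dense, motif x voxel) are kept only when the
    problem is small enough (unit-test scale); the per-motif aggregates and
    the sparse similarity structure are always present.
    """

    xi_mv: float
    n_voxels: int
    beta: np.ndarray  # (n_motifs,)
    kappa_sum: np.ndarray  # (n_motifs,) sum_j kappa_ij
    kappa_max: np.ndarray  # (n_motifs,) max_j kappa_ij
    similar: sparse.csr_matrix  # motif x voxel, data = alpha where alpha < xi_mv
    alpha_min: np.ndarray | None = None  # (n_voxels,) best alpha over all motifs
    alpha: np.ndarray | None = None
    kappa: np.ndarray | None = None
    kappa_hat: np.ndarray | None = None
    global_score: np.ndarray | None = None

    @property
    def n_motifs(self) -> int:
        return len(self.beta)

    def similar_set(self, i: int) -> np.ndarray:
        """Voxel indices similar to motif ``i``."""
        return self.similar.indices[self.similar.indptr[i] : self.similar.indptr[i + 1]]


_DENSE_LIMIT = 2_000_000  # keep alpha/kappa when n_motifs * n_voxels is below this


def compute_costs(
    motifs: MotifDictionary,
    signals: np.ndarray,
    mask: np.ndarray | None,
    params: CostParams,
    plane_indices: np.ndarray | None = None,
    chunk_size: int = 4096,
    keep_dense: bool | None = None,
) -> ScoreTable:
    """Score every motif against every masked voxel.

    ``signals`` may be an image array (``mask`` selects voxels) or an
    already-flat ``(n_voxels, etl)`` array with ``mask=None``.  Signals are
    normalized to the dictionary's mode.  ``plane_indices`` gives, per
    masked voxel, the B1+ plane at which motif signals are compared
    (typically the estimated transmit-field plane); by default every voxel
    is compared at the homogeneous plane, which assumes B1+ correction has
    been applied.  Computation is chunked over motifs; peak memory is
    O(chunk_size * n_voxels).
    """
    if mask is not None:
        signals = signals[np.asarray(mask, dtype=bool)]
    vox = normalize_curves(np.asarray(signals, dtype=float), motifs.source.normalization_mode)
    if vox.shape[1] != motifs.etl:
        raise ValueError("signal length does not match motif ETL")

    n_motifs, n_vox = motifs.n_motifs, vox.shape[0]
    if plane_indices is None:
        plane_indices = np.full(n_vox, motifs.source.b1_index(1.0), dtype=np.int64)
    plane_indices = np.asarray(plane_indices, dtype=np.int64)
    if plane_indices.shape != (n_vox,):
        raise ValueError("plane_indices must give one B1+ plane per masked voxel")

    xi = similarity_threshold(params.delta_mv, motifs.etl)
    clip_at = params.clip_factor * xi

    beta = np.array(
        [entropy_penalty(motifs.motif_fractions(i), params.lambda_ent) for i in range(n_motifs)]
    )

    if keep_dense is None:
        keep_dense = n_motifs * n_vox <= _DENSE_LIMIT
    alpha_dense = np.empty((n_motifs, n_vox)) if keep_dense else None
    kappa_dense = np.empty((n_motifs, n_vox)) if keep_dense else None

    kappa_sum = np.zeros(n_motifs)
    kappa_max = np.zeros(n_motifs)
    alpha_min = np.full(n_vox, np.inf)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    vox_sq = np.sum(vox**2, axis=1)
    for k in np.unique(plane_indices):
        vsel = np.flatnonzero(plane_indices == k)
        vk = vox[vsel]
        for lo in range(0, n_motifs, chunk_size):
            block = motifs.signals[lo : lo + chunk_size, k, :]
            alpha = (
                np.sum(block**2, axis=1)[:, None] - 2.0 * block @ vk.T + vox_sq[vsel][None, :]
            )
            np.maximum(alpha, 0.0, out=alpha)
            alpha_min[vsel] = np.minimum(alpha_min[vsel], alpha.min(axis=0))
            sim = alpha < xi
            clipped = np.minimum(alpha, clip_at)
            kappa = clipped + beta[lo : lo + len(block), None]
            kappa_sum[lo : lo + len(block)] += kappa.sum(axis=1)
            np.maximum(
                kappa_max[lo : lo + len(block)], kappa.max(axis=1),
                out=kappa_max[lo : lo + len(block)],
            )
            r, c = np.nonzero(sim)
            rows.append(r + lo)
            cols.append(vsel[c])
            vals.append(alpha[sim])
            if keep_dense:
                alpha_dense[lo : lo + len(block)][:, vsel] = alpha
                kappa_dense[lo : lo + len(block)][:, vsel] = kappa

    similar = sparse.coo_matrix(
        (
            np.concatenate(vals) if vals else np.empty(0),
            (
                np.concatenate(rows) if rows else np.empty(0, dtype=np.int64),
                np.concatenate(cols) if cols else np.empty(0, dtype=np.int64),
            ),
        ),
        shape=(n_motifs, n_vox),
    ).tocsr()
    return ScoreTable(
        xi_mv=xi,
        n_voxels=n_vox,
        beta=beta,
        kappa_sum=kappa_sum,
        kappa_max=kappa_max,
        similar=similar,
        alpha_min=alpha_min,
        alpha=alpha_dense,
        kappa=kappa_dense,
    )


def normalize_and_aggregate(table: ScoreTable) -> ScoreTable:
    """Fill normalized scores and the per-motif global score K_i.

    kappa_hat_ij = 1 - kappa_ij / max_j kappa_ij, so
    K_i = sum_j kappa_hat_ij = n_voxels - kappa_sum_i / kappa_max_i.
    A motif whose cost is zero for every voxel (perfect match everywhere)
    gets kappa_hat = 1 for all voxels.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(table.kappa_max > 0, table.kappa_sum / table.kappa_max, 0.0)
    table.global_score = table.n_voxels - ratio
    if table.kappa is not None:
        denom = np.where(table.kappa_max > 0, table.kappa_max, 1.0)
        table.kappa_hat = np.where(
            table.kappa_max[:, None] > 0, 1.0 - table.kappa / denom[:, None], 1.0
        )
    return table


@dataclass
class SelectedBasis:
    """Ordered basis of motif configuration indices with provenance."""

    motif_indices: np.ndarray
    global_scores: np.ndarray
    reasons: list[str] = field(default_factory=list)  # "coverage" or "distinct"
    covered_fraction: float = 0.0


def select_basis(
    motifs: MotifDictionary,
    table: ScoreTable,
    signals: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    plane_indices: np.ndarray | None = None,
    max_motifs: int = 50,
    min_new_coverage: float = 0.05,
    coverage_slack: float = 0.05,
    noise_floor_factor: float = 3.0,
    gain_tie_factor: float = 0.9,
    support_weight_frac: float = 0.05,
) -> SelectedBasis:
    """Pseudo-orthogonal basis selection (cluster, then decompose).

    Two stages, both operating globally across the masked tissue:

    1. *Clustering* -- greedy near-best set cover.  A voxel is coverable by
       a motif when the motif is similar to it (``alpha < xi_mv``) and
       near-best for it (``alpha <= best_alpha + slack``; ``best_alpha``
       is the voxel's minimum residual over the whole dictionary and
       ``slack = max(coverage_slack * xi_mv, median(best_alpha))`` adapts
       to the residual noise floor).  Each round the motifs that would
       newly cover the most voxels (within ``gain_tie_factor`` of the
       leader) compete, and the one with the smallest trimmed-mean
       residual over its new voxels wins (global score K_i breaks ties);
       its newly covered voxels form one cluster.  Aggregating residuals
       over a whole cluster is what discriminates between configurations
       whose single-voxel signals are degenerate.

    2. *Decomposition* -- each cluster's dominant B1+ plane subgroup is
       aggregated into a noise-debiased signal: per echo,
       ``sqrt(mean(M^2) - 2*sigma^2)`` with sigma estimated from the
       spread across members (the second moment of a Rician magnitude is
       ``A^2 + 2 sigma^2``, so this undoes the magnitude-noise floor that
       a plain mean or median retains at low SNR).  The aggregate is
       decomposed by plain NNLS over the entire motif dictionary at that
       plane; the sparse support (weights above ``support_weight_frac``
       of the total) joins the basis.  A cluster of two-compartment
       tissue returns its own motif; tissue with more pools than the
       dictionary's compartment count returns the small motif set whose
       combination represents it.

    The resulting basis is deduplicated, ordered by descending K_i and
    capped at ``max_motifs``; clusters beyond the cap are dropped.
    Requires ``signals`` (image or flat array matching the score table's
    voxel order) for the cluster medians; ``plane_indices`` must match the
    ones used in :func:`compute_costs`.
    """
    if table.global_score is None:
        normalize_and_aggregate(table)
    if motifs.equivalent_t2 is None:
        fill_equivalent_t2(motifs)
    if table.alpha_min is None:
        raise ValueError("score table lacks per-voxel best residuals")
    if table.similar.nnz == 0:
        raise RuntimeError(
            "no motif has a similar voxel (all residuals exceed xi_mv); "
            "delta_mv should scale with the noise level -- increase it"
        )
    if signals is None:
        raise ValueError("select_basis needs the (corrected) voxel signals")
    if mask is not None:
        signals = signals[np.asarray(mask, dtype=bool)]
    raw = np.asarray(signals, dtype=float)
    vox = normalize_curves(raw, motifs.source.normalization_mode)
    if vox.shape[0] != table.n_voxels:
        raise ValueError("signals do not match the score table voxel count")
    if plane_indices is None:
        plane_indices = np.full(table.n_voxels, motifs.source.b1_index(1.0), dtype=np.int64)
    plane_indices = np.asarray(plane_indices, dtype=np.int64)

    best = table.alpha_min
    coverable = best < table.xi_mv
    # The per-voxel minimum over thousands of correlated motifs sits below
    # the true residual noise level (a min-statistic); inflating its median
    # keeps near-best coverage tolerant of that bias.  The cap at xi_mv/2
    # stops the tolerance from swallowing genuinely distinct tissues at
    # very low SNR.
    slack = max(
        coverage_slack * table.xi_mv,
        noise_floor_factor * float(np.median(best[coverable])),
    )
    slack = min(slack, 0.5 * table.xi_mv)

    # Near-best incidence with residual payloads (the tiny offset keeps
    # exact-zero residuals as explicit entries).
    nb = table.similar.copy()
    keep = nb.data <= best[nb.indices] + slack
    nb.data = np.where(keep, nb.data + 1e-30, 0.0)
    nb.eliminate_zeros()
    nb_bool = nb.copy()
    nb_bool.data = np.ones_like(nb_bool.data)
    covered = ~coverable  # only coverable voxels need representatives

    scores = table.global_score
    clusters: list[np.ndarray] = []
    reps: list[int] = []
    while len(clusters) < max_motifs and not covered.all():
        uncovered = ~covered
        gains = nb_bool.dot(uncovered.astype(np.float64))
        gmax = gains.max()
        if gmax < 1:
            break
        cand = np.flatnonzero(gains >= gain_tie_factor * gmax)
        cost = np.empty(len(cand))
        for c, i in enumerate(cand):
            lo, hi = nb.indptr[i], nb.indptr[i + 1]
            vals = nb.data[lo:hi][uncovered[nb.indices[lo:hi]]]
            cost[c] = _trimmed_mean(vals)
        i = int(cand[np.lexsort((-scores[cand], cost))[0]])
        lo, hi = nb.indptr[i], nb.indptr[i + 1]
        members = nb.indices[lo:hi]
        newly = members[uncovered[members]]
        covered[members] = True
        clusters.append(newly)
        reps.append(i)

    # Stage 2: sparse decomposition of each cluster's aggregate signal at
    # the cluster's dominant B1+ plane.
    from scipy.optimize import nnls  # local import: scipy.optimize is heavy

    min_decompose = 8  # below this, a median is too noisy to decompose
    support: list[int] = []
    reasons: list[str] = []
    order_by_size = np.argsort([-len(c) for c in clusters], kind="stable")
    for ci in order_by_size:
        rep, cluster = reps[ci], clusters[ci]
        planes, counts = np.unique(plane_indices[cluster], return_counts=True)
        k = int(planes[np.argmax(counts)])
        sub = cluster[plane_indices[cluster] == k]
        if len(sub) < min_decompose:
            # Median too noisy to trust a sparse decomposition: keep the
            # consensus representative for small-but-real clusters, and
            # contribute nothing for stray handfuls of voxels.
            if len(cluster) >= min_decompose and rep not in support:
                support.append(int(rep))
                reasons.append("cluster_representative")
            continue
        if len(sub) >= 2 * min_decompose:
            # Keep the core half best matched to the representative so
            # stray members (e.g. transmit-plane misassignments) cannot
            # bias the aggregate.
            d_rep = motifs.signals[rep, k, :]
            a_rep = np.sum((vox[sub] - d_rep) ** 2, axis=1)
            sub = sub[np.argsort(a_rep)[: len(sub) // 2]]
        med = _debiased_aggregate(raw[sub])
        nrm = np.linalg.norm(med)
        if nrm == 0:
            continue
        med = med / nrm
        d_plane = motifs.signals[:, k, :]
        w, dec_res = nnls(d_plane.T, med)
        if dec_res**2 > slack or w.sum() == 0:
            # The aggregate is not representable by the dictionary at the
            # working tolerance (e.g. a stray cluster of transmit-field
            # misassignments): contribute no basis atoms.
            continue
        # Backward-prune the support: drop minor atoms, refit restricted.
        active = np.flatnonzero(w > 0)
        for _ in range(4):
            keep_local = w[active] >= support_weight_frac * w[active].sum()
            if keep_local.all() or not keep_local.any():
                break
            active = active[keep_local]
            w_a, _ = nnls(d_plane[active].T, med)
            w = np.zeros_like(w)
            w[active] = w_a
            active = active[w[active] > 0]
        for ki in active:
            if ki not in support:
                support.append(int(ki))
                reasons.append("cluster_decomposition")

    if not support:  # every cluster was gated out: fall back to representatives
        support = list(dict.fromkeys(reps))
        reasons = ["cluster_representative"] * len(support)

    # Pseudo-orthogonality: drop atoms indistinguishable (within the
    # working tolerance) from an atom contributed by a larger cluster.
    k_home_sig = motifs.signals_at_b1(1.0)
    kept: list[int] = []
    kept_reasons: list[str] = []
    for atom, reason in zip(support, reasons):
        d = k_home_sig[atom]
        if any(np.sum((k_home_sig[a] - d) ** 2) < slack for a in kept):
            continue
        kept.append(atom)
        kept_reasons.append(reason)
    support, reasons = kept, kept_reasons

    order = np.argsort(-scores[support], kind="stable")
    idx = np.asarray(support, dtype=np.int64)[order][:max_motifs]
    n_coverable = int(coverable.sum())
    n_covered = int((covered & coverable).sum())
    return SelectedBasis(
        motif_indices=idx,
        global_scores=scores[idx],
        reasons=[reasons[o] for o in order[:max_motifs]],
        covered_fraction=float(n_covered / max(n_coverable, 1)),
    )


def _debiased_aggregate(raw: np.ndarray) -> np.ndarray:
    """Per-echo amplitude estimate for a stack of same-tissue voxels.

    Uses the Rician second moment E[M^2] = A^2 + 2 sigma^2, with sigma
    estimated per echo from the robust spread across members.  Assumes the
    members share scale (same tissue and acquisition); with no noise this
    reduces to the plain RMS of identical signals.
    """
    from scipy.stats import median_abs_deviation

    if raw.shape[0] < 4:
        return np.median(raw, axis=0)
    sigma = median_abs_deviation(raw, axis=0, scale="normal")
    return np.sqrt(np.maximum(np.mean(raw**2, axis=0) - 2.0 * sigma**2, 0.0))


def _trimmed_mean(vals: np.ndarray, trim: float = 0.25) -> float:
    """Mean of the central portion; robust to a minority of outliers."""
    if len(vals) == 0:
        return np.inf
    if len(vals) < 5:
        return float(np.mean(vals))
    lo = int(np.floor(trim * len(vals)))
    s = np.sort(vals)
    return float(s[: len(s) - lo].mean())  # trim only the high tail


def _fraction_step(motifs: MotifDictionary) -> float:
    """Smallest positive fraction present = the fraction-grid step."""
    pos = motifs.fractions[motifs.fractions > 0]
    return float(pos.min()) if len(pos) else 0.05
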