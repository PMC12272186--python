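"""End-to-end MWF mapping pipelines.

``run_data_driven`` executes the full data-driven flow on a masked MESE
volume: single-T2 dictionary, motif enumeration + pruning, B1+ estimation
and signal correction, global motif scoring, pseudo-orthogonal basis
selection, and voxelwise RNNLS fitting.  ``run_conventional`` fits the same
(B1+-corrected) data against the plain single-T2 basis with its own
regularization weights; its B1+ correction uses the single-T2 dictionary's
B1+ planes as "motifs".

Default regularization follows the numerical-phantom / in-vivo operating
point: lambda_tikh = 0.001, lambda_l1 = 0.01, lambda_ent = 0.001,
delta_mv = 0.01, mu = 1 (conventional: lambda_tikh = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import b1 as b1mod
from .fitting import (
    BasisSet,
    FitParams,
    SpectrumResult,
    conventional_basis,
    fit_volume,
    motif_basis,
)
from .motifs import (
    FractionGrid,
    MotifDictionary,
    enumerate_motifs,
    estimate_wm_t2_range,
    fill_equivalent_t2,
    prune_motifs,
)
from .scoring import CostParams, SelectedBasis, compute_costs, normalize_and_aggregate, select_basis
from .simulate import SequenceParams, SingleT2Dictionary, build_single_t2_dictionary

__all__ = ["PipelineConfig", "PipelineResult", "run_data_driven", "run_conventional"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the data-driven pipeline needs beyond the data itself."""

    t2_range_ms: tuple[float, float] = (10.0, 800.0)
    n_t2: int = 60
    b1_range: tuple[float, float] = (0.80, 1.20)
    n_b1: int = 9
    backend: str = "epg"
    n_comp: int = 2
    delta_f: float = 0.05
    short_t2_cutoff_ms: float = 40.0
    max_short_fraction: float = 0.30
    wm_percentiles: tuple[float, float] = (1.0, 99.0)
    # B1+ correction
    mu: float = 0.2
    kernel_extent_mm: float = 15.0
    b1_n_iter_max: int = 200
    b1_handling: str = "plane"  # "plane": score/fit at each voxel's plane;
    #                             "correct": ratio-correct signals to B1+=1
    # scoring / selection
    delta_mv: float = 0.01
    lambda_ent: float = 0.001
    max_motifs: int = 50
    min_new_coverage: float = 0.05
    # fitting (weights are stated for unit-L2-normalized signals; see the
    # methods note for the mapping from raw-signal-scale conventions)
    lambda_tikh: float = 1e-6
    lambda_l1: float = 1e-5
    conventional_lambda_tikh: float = 1e-4  # 100x the data-driven weight,
    conventional_lambda_l1: float = 1e-5    # preserving the published ratio


@dataclass
class PipelineResult:
    """Fit maps plus the intermediate objects needed for inspection."""

    result: SpectrumResult
    b1_map: b1mod.B1Map | None
    dictionary: SingleT2Dictionary
    motifs: MotifDictionary | None = None
    selection: SelectedBasis | None = None
    basis: BasisSet | None = None
    wm_t2_range: tuple[float, float] | None = None


def _build_dictionary(seq: SequenceParams, cfg: PipelineConfig) -> SingleT2Dictionary:
    return build_single_t2_dictionary(
        (cfg.t2_range_ms[0], cfg.t2_range_ms[1], cfg.n_t2),
        (cfg.b1_range[0], cfg.b1_range[1], cfg.n_b1),
        seq,
        backend=cfg.backend,
        normalization_mode="unit_l2",
    )


def _b1_correct(
    signals: np.ndarray,
    mask: np.ndarray,
    motifs: MotifDictionary,
    cfg: PipelineConfig,
    voxel_size_mm: float,
) -> tuple[np.ndarray, b1mod.B1Map]:
    params = b1mod.B1Params(
        mu=cfg.mu, kernel_extent_mm=cfg.kernel_extent_mm, n_iter_max=cfg.b1_n_iter_max
    )
    init = b1mod.initial_b1_map(signals, motifs, mask)
    smoothed = b1mod.smooth_b1_map(signals, motifs, init, params, voxel_size_mm)
    corrected = b1mod.correct_signals(signals, smoothed, motifs)
    return corrected, smoothed


def run_data_driven(
    signals: np.ndarray,
    mask: np.ndarray,
    seq: SequenceParams,
    config: PipelineConfig = PipelineConfig(),
    voxel_size_mm: float = 2.5,
    dictionary: SingleT2Dictionary | None = None,
) -> PipelineResult:
    """Run the complete data-driven MWF mapping pipeline.

    ``signals`` is an image array whose last axis is the echo dimension;
    ``mask`` selects the tissue to learn motifs from and to fit.
    """
    mask = np.asarray(mask, dtype=bool)
    dictionary = dictionary or _build_dictionary(seq, config)

    enumerated = enumerate_motifs(dictionary, config.n_comp, FractionGrid(config.delta_f))
    fill_equivalent_t2(enumerated)
    wm_range = estimate_wm_t2_range(signals[mask], dictionary, config.wm_percentiles)
    pruned = prune_motifs(
        enumerated,
        wm_t2_range=wm_range,
        short_t2_cutoff=config.short_t2_cutoff_ms,
        max_short_fraction=config.max_short_fraction,
    )

    b1_params = b1mod.B1Params(
        mu=config.mu, kernel_extent_mm=config.kernel_extent_mm, n_iter_max=config.b1_n_iter_max
    )
    b1_init = b1mod.initial_b1_map(signals, pruned, mask)
    b1_map = b1mod.smooth_b1_map(signals, pruned, b1_init, b1_params, voxel_size_mm)

    if config.b1_handling == "plane":
        # Score and fit each voxel at its own estimated transmit-field
        # plane (equivalent to the ratio correction, but exact where that
        # correction is only approximate for multicompartment mixtures).
        vals = b1_map.values[mask]
        plane_indices = np.argmin(
            np.abs(vals[:, None] - dictionary.b1_grid[None, :]), axis=1
        ).astype(np.int64)
        work_signals = signals
    elif config.b1_handling == "correct":
        plane_indices = None
        work_signals = b1mod.correct_signals(signals, b1_map, pruned)
    else:
        raise ValueError(f"unknown b1_handling {config.b1_handling!r}")

    cost_params = CostParams(lambda_ent=config.lambda_ent, delta_mv=config.delta_mv)
    table = compute_costs(pruned, work_signals, mask, cost_params, plane_indices=plane_indices)
    normalize_and_aggregate(table)
    pruned.global_score = table.global_score
    selection = select_basis(
        pruned,
        table,
        signals=work_signals,
        mask=mask,
        plane_indices=plane_indices,
        max_motifs=config.max_motifs,
        min_new_coverage=config.min_new_coverage,
    )
    basis = motif_basis(pruned, selection)

    fit_params = FitParams(
        lambda_tikh=config.lambda_tikh, lambda_l1=config.lambda_l1, mode="data_driven"
    )
    result = fit_volume(
        work_signals,
        mask,
        basis,
        fit_params,
        dictionary=dictionary,
        plane_indices=plane_indices,
        similarity_xi=table.xi_mv,
    )
    return PipelineResult(
        result=result,
        b1_map=b1_map,
        dictionary=dictionary,
        motifs=pruned,
        selection=selection,
        basis=basis,
        wm_t2_range=wm_range,
    )


def run_conventional(
    signals: np.ndarray,
    mask: np.ndarray,
    seq: SequenceParams,
    config: PipelineConfig = PipelineConfig(),
    voxel_size_mm: float = 2.5,
    dictionary: SingleT2Dictionary | None = None,
    apply_b1_correction: bool = True,
) -> PipelineResult:
    """Conventional RNNLS fit against the single-T2 basis.

    The B1+ correction (when enabled) treats each single-T2 curve as a
    one-component motif, i.e. searches the dictionary's (T2, B1+) planes.
    """
    mask = np.asarray(mask, dtype=bool)
    dictionary = dictionary or _build_dictionary(seq, config)

    b1_map = None
    corrected = signals
    if apply_b1_correction:
        single_motifs = _single_t2_as_motifs(dictionary)
        corrected, b1_map = _b1_correct(signals, mask, single_motifs, config, voxel_size_mm)

    basis = conventional_basis(dictionary)
    fit_params = FitParams(
        lambda_tikh=config.conventional_lambda_tikh,
        lambda_l1=config.conventional_lambda_l1,
        mode="conventional",
    )
    result = fit_volume(corrected, mask, basis, fit_params, dictionary=dictionary)
    return PipelineResult(result=result, b1_map=b1_map, dictionary=dictionary, basis=basis)


def _single_t2_as_motifs(dictionary: SingleT2Dictionary) -> MotifDictionary:
    """View the single-T2 dictionary as pure one-component motifs."""
    n = dictionary.n_t2
    return MotifDictionary(
        source=dictionary,
        component_indices=np.arange(n, dtype=np.int64)[:, None],
        fractions=np.ones((n, 1)),
        signals=dictionary.curves.copy(),
    )
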