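import numpy as np
import pytest

from mwimotif import (
    PipelineConfig,
    SequenceParams,
    add_rician_noise,
    build_shepp_logan,
    build_single_t2_dictionary,
    default_tissues,
    run_conventional,
    run_data_driven,
    snap_tissues_to_grid,
)


@pytest.fixture(scope="session")
def seq11():
    """The 2D MESE protocol used throughout: ETL 11, 12 ms spacing."""
    return SequenceParams(etl=11, echo_spacing=12.0)


@pytest.fixture(scope="session")
def small_dict(seq11):
    """Small EPG dictionary for motif-level unit tests."""
    return build_single_t2_dictionary((10, 800, 12), (0.8, 1.2, 3), seq11, backend="epg")


@pytest.fixture(scope="session")
def phantom_dict(seq11):
    """Working-resolution dictionary: 60 log-spaced T2, 9 B1+ planes."""
    return build_single_t2_dictionary((10, 800, 60), (0.8, 1.2, 9), seq11, backend="epg")


@pytest.fixture(scope="session")
def phantom_tissues(phantom_dict):
    return snap_tissues_to_grid(default_tissues(), phantom_dict.t2_grid)


@pytest.fixture(scope="session")
def phantom_noiseless(seq11, phantom_tissues):
    return build_shepp_logan(size=90, tissues=phantom_tissues, seq=seq11)


def _mwf_mae_pp(result_mwf, truth_mwf, mask):
    return float(np.nanmean(np.abs(result_mwf - truth_mwf)[mask]) * 100.0)


def _b1_folded_mae_pp(est, truth, mask):
    """|B1-1| comparison: the transmit fold is the identifiable quantity."""
    fe = np.abs(np.abs(est - 1.0) - np.abs(truth - 1.0))
    return float(np.nanmean(fe[mask]) * 100.0)


@pytest.fixture(scope="session")
def pipeline_runs(seq11, phantom_dict, phantom_noiseless):
    """Data-driven and conventional runs across the tested SNRs.

    Shared by the recovery, ordering, stability and B1 acceptance tests so
    each (SNR, seed) volume is processed once.
    """
    vol0 = phantom_noiseless
    runs = {}
    for snr, seeds in ((500, (11,)), (200, (11,)), (50, (11, 23, 37))):
        delta_mv = 0.02 if snr == 50 else 0.01
        cfg = PipelineConfig(delta_mv=delta_mv)
        for seed in seeds:
            noisy = add_rician_noise(vol0, snr, seed)
            dd = run_data_driven(
                noisy.signals, noisy.mask, seq11, cfg,
                voxel_size_mm=vol0.voxel_size_mm, dictionary=phantom_dict,
            )
            conv = run_conventional(
                noisy.signals, noisy.mask, seq11, cfg,
                voxel_size_mm=vol0.voxel_size_mm, dictionary=phantom_dict,
            )
            runs[(snr, seed)] = {
                "noisy": noisy,
                "dd": dd,
                "conv": conv,
                "dd_mae_pp": _mwf_mae_pp(dd.result.mwf, vol0.ground_truth_mwf, vol0.mask),
                "conv_mae_pp": _mwf_mae_pp(conv.result.mwf, vol0.ground_truth_mwf, vol0.mask),
                "dd_b1_mae_pp": _b1_folded_mae_pp(
                    dd.b1_map.values, vol0.ground_truth_b1, vol0.mask
                ),
            }
    return runs
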