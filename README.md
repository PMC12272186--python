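# mwimotif

Data-driven multicomponent-T2 (mcT2) analysis of multi-echo spin-echo
(MESE) MRI for **myelin water fraction (MWF)** mapping.

Myelin water — trapped between myelin sheaths — relaxes fast (T2 ≲ 40 ms)
compared with intra/extracellular water (T2 ≈ 60–120 ms). Resolving the T2
spectrum per voxel and integrating the short-T2 mass yields the MWF, a
proxy for myelin content used to study demyelinating disease. The
voxelwise inversion, however, is severely ill-posed: at clinical echo
train lengths many different spectra explain the same decay curve, and
stimulated echoes from transmit-field (B1+) inhomogeneity bias the signal
away from multi-exponential behaviour.

`mwimotif` implements a data-driven remedy: instead of inverting each
voxel against a generic single-T2 dictionary, it first analyses **all**
masked voxels jointly to extract a compact set of tissue-specific mcT2
*motifs* — configurations (T2 components, fractions, B1+) with their
simulated decay signals — and then fits each voxel as a sparse
non-negative combination of those motifs.

## Model

Per voxel, the MESE signal is modelled as

    s = D W,   W ≥ 0,

where the columns of `D` are motif signals simulated with the extended
phase graph (EPG) formalism (stimulated/indirect echoes included), and
the weights solve the regularized non-negative least-squares program

    min_{W≥0}  ½‖DW − s‖₂² + λ_Tikh‖W‖₂² + λ_L1‖W‖₁ .

Each motif carries a fraction vector on the T2 grid; the fitted spectrum
is `w = F W` and `MWF = Σ_{T2≤40ms} w / Σ w`. The preprocessing stages
are:

1. **Single-T2 dictionary** — EPG decay curves on a log T2 grid
   (10–800 ms) × B1+ grid (80–120 %).
2. **Motif dictionary** — all two-compartment combinations on a 0.05
   fraction grid (the published grids give 3,404,700 elements), pruned to
   physiologically plausible white-matter configurations.
3. **B1+ estimation** — exhaustive per-voxel search plus iterative
   L1-smoothed refinement on the discrete B1+ grid; voxels are
   subsequently analysed at their own transmit-field plane.
4. **Global scoring & selection** — every motif is scored against every
   voxel (residual + entropy penalty, cost clipping, per-motif
   normalization, summed into a global score); voxel clusters are formed
   by near-best set cover and each cluster's noise-debiased aggregate
   signal is decomposed into its sparse motif support, giving a
   pseudo-orthogonal basis.
5. **Voxelwise RNNLS fit** → MWF, equivalent-T2, residual and B1+ maps.

Ground-truth validation uses the bundled synthetic generators: a 90×90
Shepp–Logan multicompartment phantom with a smooth quantized B1+ field
and Rician noise, and a capillary-tube phantom emulation with configured
short-T2 fractions (0–26.2 %).

## Worked example

```python
import numpy as np
import mwimotif as mw

seq  = mw.SequenceParams(etl=11, echo_spacing=12.0)       # 2D MESE protocol
dic  = mw.build_single_t2_dictionary((10, 800, 60), (0.80, 1.20, 9), seq)
tiss = mw.snap_tissues_to_grid(mw.default_tissues(), dic.t2_grid)
vol  = mw.build_shepp_logan(size=90, tissues=tiss, seq=seq)
noisy = mw.add_rician_noise(vol, snr=500, seed=1)

res = mw.run_data_driven(noisy.signals, noisy.mask, seq,
                         mw.PipelineConfig(), dictionary=dic,
                         voxel_size_mm=vol.voxel_size_mm)

rep = mw.compare_maps(res.result.mwf, vol.ground_truth_mwf, vol.mask)
print(f"selected motifs: {len(res.selection.motif_indices)}")
print(f"MWF mean absolute error: {rep.mae:.3f} percentage points")
b1_err = np.nanmean(np.abs(np.abs(res.b1_map.values - 1)
                           - np.abs(vol.ground_truth_b1 - 1))[vol.mask]) * 100
print(f"B1+ mean absolute error: {b1_err:.3f} percentage points")
```

Output (seed 1):

```
selected motifs: 4
MWF mean absolute error: 0.085 percentage points
B1+ mean absolute error: 0.052 percentage points
```

The selected motifs are the tissue configurations the phantom was built
from (two of the five classes occupy regions of only a few voxels and are
folded into their nearest neighbours); the MWF error of 0.085 pp at SNR 500 means the
fitted myelin fraction deviates from the constructed ground truth by less
than a tenth of a percentage point on average, and the transmit-field map
is recovered to a twentieth of a grid step.

A command-line interface wraps the same pipeline:

```bash
mwimotif phantom --size 90 --snr 200 --seed 7 --out ph/
mwimotif fit --signals ph/signals.nii.gz --mask ph/mask.nii.gz --out maps/
mwimotif evaluate --estimate maps/mwf.nii.gz --truth ph/gt_mwf.nii.gz --mask ph/mask.nii.gz
```

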