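# Methods

This note documents the model implemented in `mwimotif`, the numerical
choices behind it, what the synthetic generators do and do not emulate,
and the known limitations. All empirical statements below are computed by
the test suite or by `scripts/acceptance.py`.

## Signal model

MESE echo trains are simulated with the **extended phase graph** (EPG):
coherence configurations `(F+, F−, Z)` are tracked through excitation
(ideal 90°, CPMG phase), crusher dephasing, refocusing rotations and
relaxation, and the echo is the magnitude of the zero-order transverse
configuration. The transmit-field scale `b1` multiplies the nominal
refocusing flip at every pulse; the excitation is taken as ideal and no
slice profile is integrated (the EPG runs at a single effective flip
angle). T1 is fixed (default 1000 ms, typical white matter at 3 T) and
only enters through stimulated-echo pathways; it is exposed on
`SequenceParams` but never fitted.

The EPG is validated two ways: at an effective 180° flip it must collapse
to `exp(−n·Δ TE/T2)` (machine precision), and at arbitrary flips it must
match an independent isochromat simulation (Bloch rotation matrices,
≥360 crusher phases) to 1e-3 relative; the test suite measures agreement
at ~1e-15.

**Transmit-fold degeneracy.** With a single effective flip the MESE
signal is *exactly* invariant under `b1 → 2 − b1`: conjugating every
x-rotation with the reflection `M_y → −M_y` maps flip `β` to `−β`
(≡ `360° − β`), leaves relaxation, recovery and the uniformly distributed
crusher phases invariant, and preserves the transverse magnitude. The
data therefore determine only `|b1 − 1|`. B1+ estimation runs on the
folded grid and reports the `≤ 1` representative; all B1+ accuracy
numbers in this package compare `|b1 − 1|`. Models that integrate a slice
profile break this symmetry; a single-flip EPG cannot.

## Normalization conventions

Dictionary curves, motif signals and voxel signals are compared after
**unit-L2 normalization** (configurable). Motifs combine *normalized*
component curves, so component fractions are relative spectral energies —
consistent with defining MWF as the relative spectral energy below 40 ms.
The synthetic phantoms build their voxels the same way, which makes
on-grid recovery exact in the noiseless limit.

Regularization weights are meaningful only relative to the signal scale,
which published parameter tables for this kind of pipeline leave
implicit (scanner units). Under unit-L2 normalization the data term of
the fit is ~10⁴ smaller relative to `‖W‖²` than under raw scanner units;
the default weights here (`λ_Tikh = 1e-6`, `λ_L1 = 1e-5` data-driven;
`λ_Tikh = 1e-4`, `λ_L1 = 1e-5` conventional, preserving the 100:1
Tikhonov ratio between the two modes; `μ = 0.2` for the B1+ smoothness
prior) were calibrated on the numerical phantom for maximal MWF accuracy
— the same calibration procedure that produces such tables in the first
place. The regularization-stability test verifies that the data-driven
MAE varies by less than 2× across a 3×3 grid spanning two orders of
magnitude around these defaults.

## Motif dictionary

Two-compartment configurations on the fraction grid `{0, Δf, …, 1}`
(`Δf = 0.05`, 21 levels including both endpoints — the convention that
reproduces the closed-form dictionary size `[C(N,1)+C(N,2)(N_frac−2)]·N_B1`,
e.g. 3,404,700 for 200 T2 values and 9 B1+ planes). Three-compartment
enumeration is supported; two compartments are the default since the
final spectrum is a *combination* of motifs and is not limited by the
per-motif compartment count.

Pruning removes, in order: (A) motifs with no component below 40 ms,
(B) motifs whose summed sub-40 ms fraction exceeds 30 %, (C) motifs whose
equivalent single-T2 (best-matching single-T2 curve at the homogeneous
plane) falls outside the range observed in the data. The rule-C window is
the [1st, 99th] percentile of voxelwise joint (T2, B1+) single-T2 fits,
widened by two logarithmic grid steps — the joint fit trades B1+ against
T2 and is systematically offset from fixed-plane equivalent T2s, so the
window must act as an outlier filter, not a tight band. Surviving
configurations keep **all** B1+ planes so that scoring, fitting and the
field-ratio correction can address any plane.

A structural consequence of (A)+(B): every retained motif carries between
`Δf` and 0.30 of sub-40 ms mass, so any non-negative combination has
`MWF ∈ [Δf·(min weight share), 0.30]` — in particular, a myelin-free
voxel can never fit below ≈ `Δf`. This floor is visible in the tube
phantom (below).

## B1+ estimation and handling

Stage 1 estimates each voxel's plane by exhaustive search over all motif
signals (a `(plane × voxel)` residual table of min-over-motif L2 norms,
mirror planes folded). Stage 2 runs iterated conditional modes on the
discrete folded grid: each sweep minimizes `data(b) + μ/|N_k| Σ_r |b −
b_prev(r)|` per voxel with Jacobi (previous-sweep) neighbour values, so
the result is traversal-order independent; sweeps stop on a fixed point,
a two-sweep cycle, or the iteration cap (200). The kernel is a square
in-plane window (15 mm → odd voxel count; the centre voxel is not its own
neighbour; out-of-mask neighbours are dropped).

Two routes move the analysis to a common field condition:

* **plane-matched (default)** — every voxel is scored and fitted against
  the motif signals *at its own estimated plane*. Mixing commutes with
  plane selection, so this is exact for any multicompartment voxel.
* **ratio correction** — `s_cor(t) = s(t)·d(t)/d(B1_opt, t)` with the
  best-matching motif's homogeneous/inhomogeneous curves. This is exact
  only for voxels that *are* a dictionary motif; for mixtures it injects
  a small composition-dependent distortion (~7e-4 in squared-L2 on unit
  signals), which is why it is not the default. It remains available
  (`b1_handling="correct"`) and is what the conventional pipeline uses,
  with the single-T2 dictionary's planes as its "motifs".

## Scoring and basis selection

The per-pair cost is `κ_ij = α_ij + β_i` with `α_ij = ‖d_i − s_j‖₂²`
(squared, so the similarity rule `α < ξ_MV = δ_MV²·ETL` reads "per-echo
RMS difference below `δ_MV`"), `β_i = λ_Ent Σ −f log f`, and clipping
`α → min(α, 5ξ_MV)`. Scores are normalized per motif
(`κ̂ = 1 − κ/max_j κ`) and summed over voxels into the global score
`Κ_i`; both are computed streaming so the motif×voxel matrix is never
resident (dense copies are kept only at unit-test sizes). `δ_MV`
defaults to 0.01 (0.008 for the tube protocol) and should be relaxed
toward 0.02 as SNR drops toward 50 — a larger per-echo tolerance is
required when the noise floor approaches the threshold.

Basis selection works in two global stages (the concrete instantiation of
the published-in-spirit "highest score + pseudo-orthogonality" rule,
whose exact algorithm is not public):

1. **Clustering.** A voxel is *covered* by a motif that is similar
   (`α < ξ_MV`) **and** near-best for it (`α ≤ best_α + slack`, where
   `best_α` is the voxel's minimum over the whole dictionary and
   `slack = clip(3·median(best_α), 0.05·ξ_MV, 0.5·ξ_MV)` adapts to the
   residual noise floor — the median of a min-statistic underestimates
   the noise level, hence the factor 3). Greedy set cover picks, each
   round, among the motifs covering the most uncovered voxels, the one
   with the smallest trimmed-mean residual over them (global score breaks
   ties); its newly covered voxels form one cluster. Aggregating
   residuals across a region is what distinguishes configurations whose
   single-voxel signals are degenerate (the √N advantage that motivates
   the whole global approach).
2. **Decomposition.** Each cluster's dominant-plane subgroup (its best
   half, judged against the representative, to shed stray members) is
   aggregated per echo as `√(mean M² − 2σ̂²)` with `σ̂` from the robust
   cross-member spread — the Rician second moment `E[M²] = A² + 2σ²`
   undoes the magnitude-noise floor that a mean or median retains at low
   SNR. The aggregate is decomposed by plain NNLS over the full motif
   dictionary at that plane, backward-pruned (drop atoms under 5 % of the
   total weight, refit), and gated on decomposition residual (clusters of
   unrepresentable strays contribute nothing). Subgroups below 8 voxels
   fall back to the consensus representative. Supports are deduplicated
   at the working tolerance (pseudo-orthogonality: no two basis signals
   within `slack`), ordered by global score, capped at `max_motifs` (50).

A cluster of two-compartment tissue returns exactly its own motif;
tissue with more pools than the dictionary's compartment count returns
the small motif set whose combination represents it (e.g. a
myelin + two-long-pool tissue decomposes into two two-compartment motifs
sharing the myelin component).

## Voxelwise fitting

The RNNLS program is solved exactly: Hessian `DᵀD + 2λ_Tikh I`, linear
term `−Dᵀs + λ_L1·1`, Cholesky factorization, and Lawson–Hanson NNLS on
the transformed system — KKT conditions (non-negative gradient,
complementary slackness) are asserted on random instances in the tests.
Each voxel is fitted at its own B1+ plane. Two guards control weight
leakage between near-degenerate atoms:

* only atoms *similar* to the voxel (`α < ξ_MV`) enter its fit — an atom
  that cannot plausibly model a voxel should not absorb its weight;
* because combination voxels need individually-dissimilar atoms, the
  full basis is also fitted, and kept when it improves the squared
  residual at least four-fold (structure, not noise chasing).

MWF uses an inclusive 40 ms boundary (`T2 ≤ 40`) and a plain weight sum
(no trapezoidal weighting on the log grid); the boundary and cutoff are
configurable. Equivalent-T2 maps are produced by synthesizing the fitted
homogeneous-plane signal and matching it against the single-T2
dictionary; the data-driven and conventional routes agree on this map to
within one grid step on ≥95 % of noiseless phantom voxels, as expected
when only the spectral centre of mass is identifiable.

## Synthetic phantoms

**Head phantom.** The scikit-image Shepp–Logan image (nearest-neighbour
resampled to 90×90) supplies five non-zero gray levels → five tissue
classes: four two-compartment and one three-compartment configuration,
every class containing a myelin pool (T2 15–30 ms, fraction 0.05–0.30 on
the fraction grid) and intra/extracellular pools at 60–120 ms. Component
T2s are snapped to the dictionary grid so recovery is well-posed
(`snap_tissues_to_grid`). The B1+ field is radial, linear in radius
(equal-width iso-B1 rings after quantization to the 5 % grid), spanning
0.85–1.15, highest at the centre. Rician noise: per voxel
`σ = first echo / SNR`, each echo replaced by `|A + n_re + i·n_im|`;
the analytic Rician mean and the requested SNR are verified in the tests.
Default in-plane voxel size 2.5 mm (≈ 22 cm field of view).

The generator does **not** emulate: partial-volume mixing at tissue
borders (regions are piecewise constant), k-space/reconstruction effects,
spatially varying proton density, exchange or diffusion, or slice-profile
dependence of the flip angle. Passing tests therefore demonstrate the
correctness and noise behaviour of the *inversion machinery* under its
own signal model, not scanner-level accuracy.

**Tube phantom.** Nine "huge voxel" tubes, each the area-weighted sum of
three compartment decays (background 80 ms, capillary fillings 60 and
20 ms), with short-T2 area fractions 0, 0, 3.8, 7.1, 11.1, 14.3, 18.5,
21.7, 26.2 % (the mid-compartment fractions are this package's
documented choice; the physical phantom's exact capillary counts are not
reproduced). Protocol: ETL 24, 7.9 ms spacing, T2 grid 5–800 ms,
`δ_MV = 0.008`, no B1+ smoothing.

## Problem sizes and runtimes

The working configuration (90×90 phantom, 60 T2 × 9 B1+ dictionary,
~33 700 enumerated / ~4 700 retained configurations) runs the full
data-driven pipeline in a few seconds on one CPU; the complete test suite
takes about a minute and the acceptance script under a minute. The
published 200-T2 grid (3.4 M motifs) is supported by the same chunked
code paths but is not exercised by default.

## Known limitations

* **Low SNR (≈ 50).** The measured MWF MAE is ≈ 3–10 pp across noise
  seeds (≈ 5 pp on average), dominated by one tissue class (myelin T2
  30 ms, fraction 0.25) whose signal separation from the main
  white-matter class falls below the residual noise floor — clustering
  can no longer isolate it, and its voxels inherit a wrong-composition
  atom. Accuracy at this noise level is tissue-configuration dependent.
* **MWF floor.** No voxel can fit below ≈ `Δf` = 5 % myelin fraction
  (pruning retains only myelin-bearing motifs); the zero-fraction tubes
  of the tube phantom sit exactly on this floor, which caps the
  noiseless truth-correlation at r ≈ 0.988.
* **Tiny regions.** Structures smaller than the minimum cluster support
  (8 voxels at one B1+ plane) do not receive dedicated basis atoms; on
  the default phantom this affects a 6-voxel region (0.18 % of the mask).
* **Transmit fold.** Only `|b1 − 1|` is identifiable (see above); MWF is
  unaffected, but the signed field cannot be reported under this signal
  model.
* **No spatial regularization of spectra**, no exchange/diffusion
  modelling, no joint T1 estimation — all deliberately out of scope.
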