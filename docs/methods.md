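# Methods

## Problem and model

Organotypic 3D co-cultures of prostate cancer cells and cancer-associated
fibroblasts (CAFs) are imaged as two-channel confocal z-stacks: a red
channel for the multicellular tumour organoids and a green channel for the
thin, curvilinear CAF strands.  Stacks in this regime are strongly
anisotropic — roughly 0.5 µm per in-plane pixel against 10–40 µm between
slices — and fluorescence intensity varies widely between structures in the
same image, so neither a global intensity threshold nor a 2D maximum
intensity projection supports the question the data were collected for:
whether tumour and CAF structures make physical contact in 3D.

`mrfseg` labels every voxel as background (0), tumour (1) or CAF (2) by
minimising the energy of a conditional Markov random field on the voxel
lattice:

    E(x) = Σ_i u_{i;x_i} + Σ_{(i,j)} w_{ij} · 1[x_i ≠ x_j]

with each voxel connected to its 6 face neighbours (4 in-plane, 2 across
slices; 4-neighbour in the single-slice mode).

### Observations: local entropy

The observation z_i at a voxel is not the raw intensity but the local
Shannon entropy (base 2) of the 256-bin intensity histogram in a 9×9
in-plane window, computed per slice and per channel on 8-bit data with
symmetric (mirror, edge-inclusive) border padding.  Entropy is invariant to
the local mean, so dim and bright structures score alike; smooth background
scores near zero.  Values are bounded by log2(min(window², 256)) ≈ 6.34
bits for the default window.  Filtering is strictly 2D: at 10 µm slice
spacing a 3D texture window would mix physically distant material.
16-bit inputs are first rescaled to 8-bit over the full dynamic range
(v ↦ round(v·255/65535)), not per-image min–max, so mixture fits stay
comparable across stacks.

### Label densities: per-channel Gaussian mixtures

For each channel, a three-component univariate Gaussian mixture is fitted
to the entropy values of every slice; components are interpreted by
increasing mean as *background*, *out of focus* and *in focus*.  The slice
whose fit has the greatest sum of pairwise distances between component
means — the slice where the three populations are most clearly represented
— is selected as the reference fit, independently per channel.  With
f_{c,r} the fitted component densities and m_c the weight-renormalised
background+out-of-focus mixture of channel c, the three label densities on
the (red, green) entropy plane are

    π_T(r,g) = f_{R,if}(r)·m_G(g),   π_C(r,g) = m_R(r)·f_{G,if}(g),
    π_B(r,g) = m_R(r)·m_G(g),

and the unary potentials are u_{i;l} = −log max(π_l(z_i), ε) with density
floor ε = 1e-12.  In single-channel mode the three univariate components
serve directly as the label densities (background / foreground /
intermediate), and the intermediate label is folded into background when
scoring against binary ground truth — the same role the out-of-focus
component plays inside m_c above.

### Pairwise potentials

For differing labels at neighbouring voxels i, j:

    w_ij = (1 / dist(i,j)) · (λ0 + λ1 · exp(−‖z_i − z_j‖² / (2β)))

and zero for equal labels (Potts structure).  dist is measured in units of
the in-plane pixel size: 1 within a slice and dz/dx between slices, so with
the default spacing a between-slice edge carries 1/20 of the in-plane
weight — the z neighbours inform the labelling without dominating it.
λ0 and λ1 are set from the unary field, λ0 = min u and λ1 = max u − λ0, so
the two term families share one scale; β controls smoothness (larger β →
smoother labelling) and is the only manually set parameter.

### Minimisation: α-expansion

Starting from the per-voxel argmin of the unaries (the "mixtures"
labelling), sweeps over α ∈ (background, tumour, CAF) solve each
"keep current label vs switch to α" move exactly as a minimum s-t cut;
a move is accepted only if it strictly lowers the total energy, and the
procedure stops when a full sweep accepts nothing (at most 10 sweeps).
Voxels already labelled α are folded into their neighbours' keep-costs
rather than entering the graph.  The output energy never exceeds the
initial (mixtures) energy; with λ0 = λ1 = 0 the output *is* the mixtures
labelling, voxel for voxel.  α-expansion guarantees expansion-local
optimality and a factor-2 bound with respect to the global minimum, not
global optimality; on tiny random lattices it occasionally terminates in a
verified local optimum slightly above the exhaustive minimum.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `entropy_window` | 9 px | texture window side; larger = smoother entropy, wider halo around objects |
| `beta` | 1/40 | pairwise contrast scale; working range [1/100, 1/10]; presets `if` 1/40, `live` 1/50, `fak` 1/60 per imaging protocol |
| `eps` | 1e-12 | density floor; bounds unaries at −log ε ≈ 27.6 |
| `n_init` | 10 | EM restarts per slice fit |
| `max_sweeps` | 10 | α-expansion sweep cap (convergence is usually 2–3 sweeps) |
| spacing | 10, 0.5, 0.5 µm | dz, dy, dx; sets the between-slice edge weight dz/dx |

## Numerical choices

- **EM.** Univariate weighted EM, 3 components, variance floor 1e-6 bits²,
  stopping when the log-likelihood improves by less than 1e-8 or after 500
  iterations, best of `n_init` restarts.  Restart 0 initialises means at
  the (1/6, 1/2, 5/6) quantiles; the rest draw random quantile levels so a
  far-out mode of a skewed distribution is still seeded.  Fitting operates
  on a 1024-bin histogram of the values (weighted EM): the bin width
  (~0.006 bits for full-range entropy data) is far below any component
  width of interest, the fitted parameters are unchanged to ~1e-3, and the
  cost becomes independent of image size.  All slices of a channel run
  through one lock-step vectorised batch.
- **Pairwise weight floor.** λ0 = min u is negative whenever a label
  density peaks above 1 (a very concentrated background entropy mode does
  this), which would make some differing-label costs negative — outside
  the Potts family and non-submodular.  Weights are floored at 0, the
  minimal projection back onto valid Potts weights, identically in the
  energy and in the move graphs.
- **Max-flow.** Move graphs are solved with scipy's integer max-flow;
  float capacities are scaled by 1e8 (shrunk automatically if a capacity
  would exceed int32) and the source side is recovered by BFS on the
  positive residual graph.  Quantisation error per edge is below 1e-8.
- **Ties.** Mixtures/argmin ties break toward the lower label index;
  expansion moves that do not strictly lower the energy are rejected, so
  runs are reproducible without randomness in the minimiser.
- **Otsu baselines.** Thresholds maximise the between-class variance over a
  256-bin histogram, ties to the smallest threshold; entropy values are
  first binned linearly to 256 levels over [0, log2(window²)].  The
  threshold is computed on the reference slice and applied to the stack.
  Voxels foreground in both channels are assigned tumour or CAF with
  probability ½ (seeded).
- **Scoring.** Macro F1 is the harmonic mean of the macro-averaged
  precision and recall over the three classes (the mean of per-class F1s
  is also reported, as the two conventions differ).  Classes with empty
  denominators score 0; binary single-channel truth is averaged over the
  two present classes only.
- **Morphometry.** Volume = labelled voxel count; surface = labelled voxels
  with a differing-label 6-neighbour (stack boundary excluded); contact =
  tumour voxels touching CAF plus CAF voxels touching tumour.  Counts are
  anisotropy-blind, matching how such quantities are reported for this
  kind of data.

## Synthetic phantoms

The generator builds geometry in physical micrometre coordinates and
rasterises onto the anisotropic grid: spherical tumour organoids (default
radius 10–18 µm, so a few z-slices but tens of in-plane pixels) and CAF
strands as dilated 3D random walks (radius 5 µm, mostly in-plane), with a
configurable fraction of strands seeded touching an organoid surface and
the rest kept face-adjacency-clear of tumour voxels.  Intensities are
i.i.d. Gaussian speckle (sd 25) around a per-object mean drawn from
45–180, on a smooth background (mean 30, sd 2).  The wide mean range is
deliberate: weakly fluorescent objects barely above background are the
case where texture separates what a global intensity threshold cannot,
which is the regime the method exists for.  The default stack is
12×128×128 with 10/0.5/0.5 µm spacing (dz/dx = 20); this keeps a full
four-method benchmark run over five seeds within a few minutes on one
core while preserving the anisotropy and object-scale relations of the
real protocol.

What the phantom does *not* model: point-spread blur, out-of-focus haze,
photobleaching, realistic CAF branching, or correlated noise.  In
particular there is no explicit out-of-focus class — the middle mixture
component captures the partial-window halo at object borders instead.
Passing phantom benchmarks therefore demonstrates the pipeline's
mechanics (texture separability → density construction → energy
minimisation) under the stated geometry and noise, not performance on
real fluorescence data.

## Known limitations

- Expansion-local optima: the minimiser can terminate above the global
  minimum (factor-2 guarantee); observed on ~10% of tiny random instances,
  not observed to matter on phantom-scale problems.
- Structures of the same class that touch are not separated (by design —
  the unit of interest is the multicellular structure).
- The entropy halo widens every object by roughly half the window size;
  the mixture's middle component absorbs most, but boundary voxels
  dominate the residual error of all methods.
- β is set per experiment, not learned; values outside [1/100, 1/10]
  trigger a warning, not an error.
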