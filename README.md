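# cardiocs

Compressed sensing, reconstruction and biometric identification for cardiac
biosignals (ECG and PPG), built as an importable Python library with a thin
`cardiocs` command-line interface.

Wearable and ambulatory cardiac monitors produce long single-channel records
that are expensive to store and transmit. Compressed sensing acquires such a
signal `x ∈ R^N` through far fewer linear measurements `y = Φx`, with
`Φ ∈ R^{M×N}` a random Gaussian matrix and `M = CR·N` for a compression ratio
`CR < 1`, and recovers it by exploiting sparsity: `x = Dθ` with `θ` sparse in
a dictionary `D` (an orthonormal DCT basis or a redundant dictionary learned
by K-SVD). This package implements that pipeline end to end and asks the
question that matters for wearables: **does identity survive compression?**
Fiducial-based feature vectors are extracted from signals before and after
the sense→reconstruct round trip and fed to a one-vs-one SVM identifier; if
reconstruction is faithful, the recognition rate is unchanged.

## The recovery algorithms

Greedy solvers recover `θ` from `y` by repeatedly correlating the residual
`r` with the columns (atoms) of `A = ΦD`, selecting atoms, and re-fitting by
least squares:

* **OMP** — one best atom per iteration; needs the sparsity `k` a priori.
* **SWOMP** — "stagewise weak" selection: every atom with
  `|⟨r, a_i⟩| ≥ α·max_j |⟨r, a_j⟩|` at once (`0 < α ≤ 1`); needs `α` and an
  iteration count, both set by hand.
* **SWAMP** — the adaptive refinement this package centres on. A restricted
  isometry argument gives an initial sparsity estimate `k₀` (grow `k₀` until
  `‖A_Λ₀ᵀ y‖₂ > sqrt((1−δ_k)/(1+δ_k))·‖y‖₂` for the top-`k₀` correlation
  set `Λ₀`); the threshold `α` is auto-corrected so the first selection
  offers between `k₀` and `S_max` candidates; later stages add at most
  `L = stage·L₀` atoms each, sorted by descending correlation, and the
  support may never exceed `S_max = ⌊M/2⌋`. Termination is by residual
  tolerance `ε₁ ≈ 10⁻³`, the support cap, or stagnation — no a-priori
  sparsity or iteration count required.

Reconstruction quality is measured by (with `ρ = ‖x−x̂‖₂/‖x‖₂`):
`SNR = −20·log₁₀ρ` (dB), the matching rate `MR = 1 − ρ`, and
`RMSE = sqrt(mean (x_i − x̂_i)²)`.

Around the solvers sit a synthetic signal generator (sum-of-Gaussians ECG and
PPG beats with analytically exact fiducials, per-subject jitter, seeded
noise), coif3 wavelet denoising with universal thresholding, DWT-assisted
fiducial detection (R/Q/S/P/T plus wave boundaries; systolic peak and valley
for PPG), Table-style feature vectors (21 ECG / 12 PPG entries,
RR-normalized distances plus signed amplitudes), and a one-vs-one RBF-SVM
identifier with majority voting — `n(n−1)/2` pairwise classifiers for `n`
subjects.

## Worked example

`examples/03_compress_and_reconstruct.py` senses an exactly-100-sparse
1024-dimensional DCT-domain signal at CR 0.7 (M = 717) and recovers it with
all three solvers:

```
N=1024, M=717 measurements (CR=0.7)
omp    support=100 stop=max_iter     MR=1.000000 RMSE=7.60e-16
swomp  support=100 stop=stagnation   MR=1.000000 RMSE=7.73e-16
swamp  support=100 stop=residual_tol MR=1.000000 RMSE=6.90e-16
```

All three find the exact 100-atom support; SWAMP does so without being told
`k = 100`. `examples/05_identification.py` runs the full identity question on
8 synthetic subjects:

```
training windows: 24, test windows: 24
mean reconstruction MR on test windows: 0.9923
recognition rate before reconstruction: 0.9583
recognition rate after  reconstruction: 0.9583
difference: +0.0000
```

The identifier performs identically on original and reconstructed signals —
compression at ratio 0.7 did not cost identification accuracy. The other
examples cover signal synthesis, K-SVD dictionary learning, and
denoising/feature extraction; each prints what it computes and what the
numbers mean. The same stages are available from the shell via
`cardiocs simulate | train-dict | compress | reconstruct | denoise |
features | train-id | identify | evaluate | run`.

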