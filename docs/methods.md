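# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `cardiocs`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic signal model

Each beat is a sum of Gaussian waves inside one beat period `T = 60/HR`
seconds. The default ECG morphology (amplitudes mV, times s, 60 bpm) is
P(center 0.200, σ 0.020, 0.15), Q(0.345, 0.008, −0.12), R(0.370, 0.007,
1.00), S(0.395, 0.008, −0.18), T(0.600, 0.040, 0.30); the default PPG is a
systolic peak P(0.300, 0.045, 1.00) and a negative valley wave V(0.620,
0.050, −0.25). The widths and spacings were chosen so that neighbouring
Gaussian tails contribute < 0.005 at each wave center, which makes the
analytic fiducials (wave centers; onsets/offsets at center ± 3σ) coincide
with signal extrema to within one sample at 500 Hz — the property that lets
the generator serve as ground truth for the detector. Default sampling rate
is 500 Hz.

Noise is additive: white Gaussian (sd in mV), sinusoidal baseline wander
(default 0.3 Hz) and mains interference (default 50 Hz). All randomness
flows through explicit integer seeds; there is no global RNG state.

`make_population` draws per-subject templates by multiplicative
`N(1, jitter)` perturbation of amplitudes, widths, heart rate and the wave
positions *relative to the anchor wave* (R for ECG, P for PPG). Jittering
relative offsets rather than absolute centers guarantees the P<Q<R<S<T
ordering for every draw. The default jitter of 0.05 is an arbitrary choice:
no public morphology statistics back it, and it controls how hard the
identification task is. At 0.05 a handful of synthetic subjects are
separable but not trivially so.

**What the generator does not model:** beat-to-beat variability (HRV),
respiration coupling, arrhythmia, electrode artefacts, or any
dynamical-systems ECG behaviour. Tests passing on these signals show the
pipeline's machinery is correct, not that it meets any clinical detection
standard on real recordings.

## Sparse domains

The DCT domain is the orthonormal type-II basis (`scipy.fft`), so analysis
is exact and `synthesize(analyze(x)) = x` to 1e-9. K-SVD training follows
the classical alternation: OMP sparse coding of every training window at a
fixed coding sparsity (default `⌈N/20⌉`, 30 iterations), then per-atom
rank-1 SVD updates of the restricted residual with re-normalization. The
dictionary is initialized from a seeded draw of distinct training segments;
atoms used by no segment are replaced by the currently worst-represented
segment; atom signs are canonicalized (first nonzero entry non-negative) to
stabilize round-trip tests. The mean squared representation error is
recorded per iteration and asserted non-increasing (1e-8 slack): OMP coding
does not strictly guarantee monotonicity, but it holds on every corpus the
suite uses, and the assertion would expose a genuine update bug.

## Sensing

`Φ` has i.i.d. `N(0, 1/M)` entries with `M = round(CR·N)` (half away from
zero, so CR 0.7 × 1024 → 717). The 1/M variance makes `‖Φd‖ ≈ 1` for
unit-norm atoms, so correlation magnitudes are comparable across atoms and
the restricted-isometry sparsity test is meaningful; unit variance is
available via a flag. Solvers operate on the column-normalized `A = ΦD` by
default (the weak threshold compares inner products across atoms fairly);
the stored column norms map coefficients back to domain coordinates at
reconstruction. Ensembles are never persisted — `(N, CR, seed)` regenerates
them bit-exactly.

## Recovery

Shared numerical choices: least squares by `numpy.linalg.lstsq`
(rank-revealing; minimum-norm solution plus a warning on rank-deficient
supports); after every fit the residual is orthogonal to the selected
columns to 1e-8·‖y‖, so residual norms are non-increasing and supports
nested; correlation ties break toward the lower index; already-selected
atoms are excluded from re-selection (their correlations are ~0 after
projection; exclusion avoids duplicate indices).

SWAMP specifics and the readings adopted where the staged-selection scheme
is ambiguous:

* The threshold `Th = α·max_i |⟨r, a_i⟩|` is α times the maximum correlation
  magnitude — the only reading that type-checks.
* The sparsity pre-estimate uses `sqrt((1−δ_k)/(1+δ_k))` with default
  `δ_k = 0.3`; since only the sorted correlation prefix of `|Aᵀy|` enters
  the test, the whole k₀ loop collapses to one sort plus a cumulative sum.
  `y = 0` returns `k₀ = 0` (degenerate); the estimate is capped at `S_max`
  so the initial selection cannot exceed the solver's own support cap.
* Threshold correction is multiplicative: `α ← α·0.95` when fewer than k₀
  candidates pass, `α ← min(1, α/0.95)` when more than `S_max` do, bounded
  to 100 adjustments before a configuration error naming the instance.
* Step growth is linear, `L = stage·L₀` (default `L₀ = 5`); compounding
  growth is available behind a flag.
* The correlation vector is recomputed from the current residual every
  stage — the only reading consistent with matching-pursuit logic.
* When a stage's union would push the support past `S_max = ⌊M/2⌋`, the
  solver terminates and returns the previous support's estimate
  (`terminated_by = "support_cap"`), so the cap is never exceeded.
* `ε₁ = 10⁻³` is absolute by default with a relative-to-‖y‖ option; the
  relative form is what the end-to-end experiment uses, since natural ECG
  windows are compressible rather than exactly sparse and an absolute
  tolerance couples termination to signal scale.

On exactly-sparse instances at the reference operating point (N = 1024,
k = 100, M = 717) SWAMP recovers the exact support in essentially every
trial, which is why the benchmark matching rates sit at 1 − O(1e-15).

## Quality metrics

All three metrics derive from `ρ = ‖x−x̂‖/‖x‖`: SNR = −20log₁₀ρ,
MR = 1 − ρ, RMSE = ρ·‖x‖/√N. The suite asserts these identities on random
pairs. Perfect reconstruction reports `SNR = +inf` as a sentinel, never an
exception, so batch tables aggregate cleanly; a zero reference signal is an
`UndefinedMetricError`. Batch summaries report mean ± sd per metric.

## Denoising

Multilevel DWT with the coif3 wavelet; detail coefficients shrunk by the
universal threshold `σ̂·sqrt(2 ln n)` with `σ̂ = median(|d₁|)/0.6745`; soft
thresholding by default. The wavelet family is the one established choice
here; the rule, mode and depth are this package's defaults (universal, soft,
8 levels at 500 Hz) and all configurable. The requested depth is clipped to
`pywt.dwt_max_level` for short records to avoid boundary artefacts.
`remove_baseline=True` zeroes the deepest approximation (< ~1 Hz at the
default depth), standing in for an analog high-pass stage; all detail levels
are thresholded.

## Fiducial detection and features

R peaks: modulus maxima of the undecimated (SWT) detail level whose band
covers ≈ 15–31 Hz at 500 Hz, above a fraction (0.3) of the band maximum,
with a 0.25 s refractory window, refined to the raw-signal extremum within
±40 ms. Q/S: nearest minima within ±60 ms of R. P: maximum in (−280, −80) ms
before R; T: maximum in (80, 450) ms after R. Onsets/offsets: nearest sample
where the wave falls below 10% of its peak amplitude relative to the record
median (the baseline). PPG uses the same adaptive-threshold/refractory rule
directly on the signal for systolic peaks, the inter-peak minimum for V, and
the same fractional crossings for PS/PD/VS/VD. **These windows and fractions
are the largest gap between this implementation and any particular clinical
recipe**: they are standard physiology-motivated defaults, all configurable,
and validated only against the synthetic generator (±2 samples on anchors).
Every threshold is relative, so detection is invariant to amplitude scaling.
Beats whose windows cross a record edge are dropped; the mean RR used for
normalization is taken over all detected anchors, including edge beats.

Features: 15 ECG distances and 8 PPG distances as absolute index differences
in seconds divided by the mean RR (absolute, because pairs like PB–PE would
otherwise be systematically negative); 6 ECG and 4 PPG amplitudes as signed
differences, value at the first named point minus the second. Vectors are
emitted per beat or as a mean-of-beats aggregate.

## Identification

Min-max normalization to [0,1] per feature, fitted on training data only
(z-score available). One binary RBF-SVM (scikit-learn `SVC`) per unordered
class pair; prediction by majority vote with ties broken toward the lowest
label plus a warning. Grid search (default C ∈ 10⁻²…10³, γ ∈ 10⁻³…10¹) by
stratified 10-fold cross-validation; the scoring inside the search uses
sklearn's multiclass SVC, which votes one-vs-one internally — the same
scheme as the final explicit bank — purely to keep the search cheap.

The end-to-end harness uses 1024-sample windows at 75 bpm (so every window
holds at least two R peaks for RR estimation), 6 windows per subject split
half train / half test, DCT-domain sensing at CR 0.7 and SWAMP with the
relative tolerance. With fixed `C = 10, γ = 1` on separable synthetic blobs
the grid search is skipped; the experiment defaults do the same because the
synthetic populations are comfortably separable and the search adds minutes
without changing the outcome.

## Reproducibility and problem sizes

One global experiment seed; per-stage streams derived by CRC-32 hashing of
the stage name, so adding a stage never perturbs another's draws. Identical
configs produce byte-identical result tables. The benchmark script uses 20
exactly-sparse trials (matching rate and RMSE) and 10 ECG trials (worst-case
residual); the test suite uses 50-trial batches for solver success-rate
properties and 200-trial batches for the small-instance oracle comparisons —
sizes at which the asserted margins are stable across seeds while the whole
suite stays in the tens of seconds.

## Known limitations

* The synthetic population is far cleaner than a real 23-subject cohort;
  recognition rates here say nothing about field accuracy.
* K-SVD dictionary recovery is measured on planted sparse data; learned
  dictionaries on natural ECG are evaluated only through reconstruction
  quality.
* The detector's onset/offset points (PB/PE/TB/TE and PPG analogues) are
  validated for ordering and scale-invariance, not against an annotated
  clinical reference.
* Greedy recovery offers no convex-relaxation fallback; signals that are not
  compressible in the chosen domain degrade gracefully (support cap) but are
  not flagged beyond `terminated_by`.
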