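# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and simulator

A 60 GHz Doppler sensor mixes transmitted and reflected microwaves; the
baseband output follows chest-wall displacement (the received frequency is
f_r ≈ f₀ + 2 v f₀ / c for surface velocity v, so a 60 GHz carrier resolves
sub-millimeter cardiac motion). The simulator works directly on the
demodulated single-channel displacement signal at 250 Hz and superposes:

* **Beat train.** Each subject has a fixed beat template: a sum of
  damped-sinusoid atoms a·exp(−(t−ℓ)/τ)·sin(2πf(t−ℓ)), with center
  frequencies drawn in 18–42 Hz (inside the 15–50 Hz band where
  heartbeat-induced chest micro-vibrations live), latencies ≤ 0.25 s and
  decays 0.02–0.08 s, peak-normalized to 1. One atom is dominant (amplitude
  1, decay 0.02–0.03 s, latency ≤ 0.05 s) and 2–5 satellites are weaker
  (amplitude 0.08–0.25): this emulates the sharply peaked aortic-opening
  complex plus smaller components seen in real seismocardiograms, and gives
  realistic peak-to-mean ratios in the beat windows (a template with evenly
  weighted atoms would smear energy across the whole window and make every
  beat look low-SNR to the gating stage). Templates of different subjects
  are re-drawn until pairwise normalized cross-correlation < 0.95.
  R-peak instants follow RR ~ N(μ_RR, σ_RR²) truncated to
  [0.5 s, 1.5·μ_RR], with μ_RR drawn in 0.7–1.0 s (seated resting adults)
  and σ_RR = 0.03 s.
* **Respiration** — a sinusoid at 0.2–0.35 Hz with amplitude 5× the beat
  peak; chest displacement from breathing genuinely dwarfs the cardiac
  micro-vibration, which is what makes the band-pass stage load-bearing.
* **Power line** — 60 Hz sinusoid, amplitude 0.5.
* **White noise** — Gaussian, σ = 0.02 by default. The generator exposes
  this as the one free noise knob; the default keeps the post-filter beat
  SNR distribution straddling the 4/6 gates rather than saturating them.
* **Motion bursts** — Poisson-timed (2/min) half-sine transients of 0.5 s
  and 10× beat amplitude; their spectral mass sits below 5 Hz, so they are
  separable in frequency, as body motion is for the real sensor.

All draws come from one seeded generator; recordings are bit-identical
across runs and platforms at the level of the RNG contract.

What the simulator does **not** model: I/Q quadrature channels and
arctangent demodulation, range processing, posture changes, day-to-day
physiological drift, or any coupling between respiration and beat amplitude
(amplitude modulation). Tests passing on this data therefore demonstrate
that the chain recovers identity when beat morphology is stable and
subject-distinct; they say nothing about cross-session drift on real skin.

## Preprocessing

The 15–50 Hz band isolates the beat: respiration is below 10 Hz, power-line
interference at 60 Hz. The filter is a Chebyshev-II band-pass designed from
the stopband requirement (edges 7.5/60 Hz, 21 dB one-pass) and applied
forward-backward, giving ≥ 40 dB two-pass attenuation at 0.3 Hz and 60 Hz
with < 1 dB loss at 30 Hz and zero phase. A Butterworth of modest order was
considered and rejected: from a 50 Hz band edge it cannot reach 40 dB by
60 Hz.

Decimation to 125 Hz uses a zero-phase Chebyshev-I anti-alias low-pass and
keeps every second sample; peak indices map as i → ⌊i/2⌋ with neighbors
deduplicated. Beats are cut as 64-sample (0.512 s) windows centered on the
peak — shorter than the shortest admissible RR interval, and a power-of-two
time axis for square spectrograms. Windows touching an edge are dropped,
not padded (padding would distort both the SNR score and the CWT edges).

Per-beat SNR is max|x| / mean|x| over the band-passed, down-sampled window
(the gate is applied after the full chain, matching its position in the
processing order). Beats enter training at SNR ≥ 4 and testing at SNR ≥ 6;
the looser training gate deliberately admits noisier beats.

## Beat detector

A conformer stack (macaron half-step feed-forward modules around
self-attention and a depthwise convolution of kernel 31) regresses a
saliency trace trained toward triangular targets: 1 at each annotated
R-peak, linear decay to 0 over ±12 samples (±48 ms at 250 Hz, covering
typical SCG peak jitter), overlaps resolved by elementwise max. Default
dimensions: 5 blocks, model width 30, 3 heads, feed-forward width 512,
batch 512, 300 epochs, Adam at 1e-4, MSE loss. Inputs are 512-sample
windows with 50% overlap, standardized per window (zero mean, unit
variance) so the detector is gain-invariant. Inside the macaron blocks the
feed-forward and convolution modules use ReLU, and layer normalization
stands where a batch statistic would otherwise appear, keeping
single-example inference identical to batched inference.

Peaks are read off the trace as local maxima ≥ 0.5 separated by at least
0.33 s (≈ 180 bpm cap); among conflicting maxima the larger wins, ties to
the earlier index. Both knobs are exposed. Detection runs at 250 Hz; the
predicted peak indices are halved after the waveform is decimated.

The network kit (`dopplerauth.nn`) is a deliberately small piece of
infrastructure: explicit forward/backward passes per layer, float32
arithmetic, Adam. Every layer's backward pass is checked against central
finite differences in float64 in the test suite.

## Time–frequency features

The CWT is evaluated as an exact Riemann sum over the 64-sample window
(signal taken as zero outside), which keeps the transform linear and
identical to direct quadrature of the defining integral; with 64
frequencies × 64 shifts × 64 samples per beat this is a single small matrix
product per beat and needs no FFT approximation. The grid has 64 (or, at
reduced scale, 24) log-spaced frequencies over 10–60 Hz at 125 Hz — the
pass-band plus margins. Scales follow the Morlet center-frequency relation
a = ω₀ f_s / (2π f) with ω₀ = 6.

Magnitude images are min-max scaled to [0, 1] per beat (a constant matrix
maps to zeros) and linearly resampled on the time axis to a square image —
magnitude rather than log-power because the decoder's sigmoid mean targets
a [0, 1] image. A five-beat sliding average then suppresses beat-to-beat
noise (output length n − 4, re-normalized). Note that with ω₀ = 6 the
wavelet's relative bandwidth is f/6: a fixed ±5 Hz neighborhood around an
atom frequency captures most of the energy only near the low band edge;
energy-localization checks are phrased accordingly.

Augmentation (training split only; the test split is never augmented):
per image, ±2-column time shifts with edge replication, one time-stretch by
a factor uniform in [0.9, 1.1] resampled back, one additive white-noise
copy (σ = 0.05, clipped), and one mixup λA + (1−λ)B with λ ~ Beta(0.2,
0.2). Mixup partners are drawn within the same subject by default: the
latent prior is label-conditioned, so cross-class mixing would corrupt the
conditional target; a `mixup_cross_class` flag exists for study.
Single-member classes skip mixup. Stretch range and noise level are
exposed, not asserted as canonical.

## Conditional VAE

Decoder p_θ(x|z) with sigmoid-bounded mean μ_θ(z); label-conditioned prior
p_ψ(z|y) = N(μ_ψ(y), σ_ψ²(y)) produced by a small FFN from the one-hot
label; label-free posterior q_φ(z|x) = N(μ_φ(x), σ_φ²(x)). Training
maximizes the ELBO; the loss per item is pixel-summed squared error of the
reconstruction from one reparameterized sample z = μ + ε⊙σ plus β·KL of
posterior from prior (β = 1 by default), with the KL in closed form —
sampling it would only add variance. An optional Bernoulli cross-entropy
reconstruction is provided, consistent with the bounded decoder mean; the
squared-error form is the default training loss. Sum-over-pixels (rather
than mean) keeps the reconstruction and KL terms on comparable scales at
these image sizes.

Architecture (the layer kinds are fixed; counts and channels are this
package's interpretation): encoder = three 3×3 conv blocks (16/32/64
channels by default) each followed by 2×2 max-pooling, then an FFN to
(μ, log σ²); decoder mirrors it with an FFN and three 2×2-stride-2
transposed convolutions; prior = one-hot → 64-wide FFN → (μ, log σ²).
Log-variances are hard-clipped to ±10 with gradient masking for numerical
safety; the posterior/prior heads are initialized small so training starts
near N(0, I). Hyperparameters: latent dimension 50, batch 64, 300 epochs,
Adam at 1e-5 (reduced-scale runs shorten and re-rate this; see below).

Inference uses encoder **means**, not samples, so decisions are
deterministic; a sampled-z mode exists via `reparameterize`.

## Enrollment and decisions

Each registered subject's gallery entry is the per-dimension mean and
sample variance (n−1, floored at ε = 1e-6) of their training latents.
Mahalanobis distance uses this per-subject diagonal covariance: with latent
dimension 50 and tens of enrollment beats a full covariance is singular,
and pooling across subjects would blur exactly the per-cluster geometry the
prior was trained to create (a pooled mode is available). Verification
accepts strictly below threshold — a distance equal to the threshold is
rejected. Five-beat majority voting groups five consecutive gated test
beats (disjoint groups, stride 5); a voted verification at threshold τ
accepts iff ≥ 3 of 5 beats accept, which is equivalent to the median of
the five distances falling below τ — the evaluation exploits this to sweep
voted FRR/FAR curves directly. Voted identification takes the mode of the
five per-beat picks, ties broken by smallest mean distance, then lowest id.

## Evaluation protocol

Each 60 s recording splits chronologically: first 48 s train/enroll, next
12 s test (half-open boundary; a beat exactly at 48 s is a test beat).
Verification is leave-one-subject-out: the held-out subject is absent from
training and their test beats are unregistered impostor probes. Within a
fold, every remaining subject serves in turn as the target (label 1), the
other enrolled subjects aggregate to label 0, each contributing a seeded
without-replacement subsample of ⌊n/(K−2)⌋ training beats so the two labels
balance (1/11 at K = 13). Fold metrics are macro-averaged over all
(held-out, target) pairs — the protocol is ambiguous between "one target
per fold" and "all targets in turn"; running all targets is a superset of
both readings.

Threshold sweeps use the sorted unique probe distances (±∞ sentinels);
accept iff d < τ. FRR is non-increasing and FAR non-decreasing in τ, so
FRR−FAR has a unique sign change; the EER is the exact grid crossing if one
exists, otherwise the linear interpolation between the adjacent candidate
thresholds (verified against a brute-force scan in the tests). BAC and F1
are reported at the EER threshold of the same task's sweep — the protocol
reports all three together without fixing an operating point, and the EER
point is the only one the sweep itself distinguishes. Identification
trains one K-label model on all subjects and scores nearest-center
accuracy, overall and macro-averaged per subject.

## Problem sizes

Full-scale defaults (above) mirror the deployment configuration. The
synthetic recovery benchmark and the acceptance script run a documented
reduced configuration (`PipelineConfig.reduced()`): 5 subjects × 60 s
simulated at noise σ = 0.05 (above the generator default, as a harder
condition), 24×24 spectrograms, a 2-block / 96-wide-FFN detector trained
for 100 epochs on 24 windows of 128 samples at lr 1e-3, CVAE with 4/8/16
channels trained 60 epochs at lr 3e-3, no augmentation. These sizes are the package's choice
of a desk-scale experiment: one 5-subject cohort evaluates in about a
minute on a single CPU while exercising every stage, including
detector-driven segmentation. The shorter schedules need the higher
learning rates; the paper-scale schedules (300 epochs at 1e-4/1e-5) remain
the defaults.

## Known limitations

* The simulator's subjects differ more cleanly than real people measured on
  different days; absolute benchmark numbers characterize the pipeline, not
  human-subject performance.
* The conformer and CVAE run on a numpy backend built for clarity and
  testability; it is single-threaded BLAS-bound and not suited to
  large-scale training.
* Re-enrollment after physiological drift is supported only by re-running
  enrollment; no template-update algorithm is provided.
* Only the 250 Hz → 125 Hz decimation path is implemented; other
  acquisition rates raise an unsupported-rate error by design.
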