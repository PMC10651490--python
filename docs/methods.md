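# Methods

`ifshear` implements the quantitative chain linking head-motion-driven
interstitial-fluid flow in the brainstem to the shear stress it exerts on
cells, plus the physiological readout computations (blood-pressure /
heart-rate variability, nerve activity) used to assess the downstream
antihypertensive effect. This note records the models, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not establish.

## Interstitial geometry (`geometry`)

**Preprocessing.** Volumes are resampled to isotropic voxels by trilinear
interpolation under a voxel-centre convention (the centre of voxel *i* at
spacing *s* sits at (i + ½)·s), then smoothed with a uniform box filter.
The reference workflow for two-photon stacks of dye-filled extracellular
space resamples ~1 μm anisotropic voxels to 0.2072 μm cubes and smooths
over 5 voxels (~1 μm); both are parameters here. Constants are preserved
exactly by both steps, which the tests rely on.

**Extraction.** The interstitial space is taken as the top 20% of voxels
by fluorescence — the conventional extracellular volume fraction of brain
tissue (ε ≈ 0.2) motivates the quantile. Implementation choices the rule
itself leaves open:

* foreground is *strictly above* the (1 − 0.2) linear-interpolation
  sample quantile, so an all-constant image gives an empty foreground
  rather than an arbitrary one;
* connected components use 26-connectivity (8-connectivity in-plane);
  maximal connectivity avoids splitting thin diagonal channels;
* components above 5,000 voxels lose exactly ⌈0.5·size⌉ of their
  lowest-intensity voxels (stable sort, ties broken by voxel index), the
  foreground is re-labelled — required for the subsequent size filter to
  be well defined — and components below 50 voxels are discarded.

**Ellipse fits.** Each cluster's footprint in the analysis slice (chosen
as the slice of highest mean fluorescence along the stack axis, or given
explicitly) is summarised by its second-central-moment ellipse with axis
lengths 4·√λ, the standard image-moments convention. The per-voxel square
self-moment s²/12 is added to the footprint covariance so one-voxel-wide
footprints keep a finite minor axis; footprints under 3 voxels are
skipped. For isotropic footprints the major-axis angle is undefined and
reported as 0 by convention.

**Pore-size distribution.** Cross-sectional areas (footprint voxel count
× in-plane voxel area) are fitted by a maximum-likelihood log-normal
(μ̂ = mean log a, σ̂ = ML standard deviation of log a). The mode is
exp(μ̂ − σ̂²). The FWHM is measured on the fitted continuous density, not
on a histogram, and has the closed form

    fwhm_low, fwhm_high = mode · exp(∓ σ̂ √(2 ln 2)),

obtained by solving f(a) = f(mode)/2 in log space. A degenerate sample
(σ̂ → 0) or fewer than 10 areas is an error, not a silent fit.

**Centroidal line.** Per-slice unweighted centres of mass along the
rostral–caudal (y) axis are fitted with a straight line for x(y) and a
four-parameter sigmoid z = c + d/(1 + exp(−(y − y₀)/s)) for z(y),
matching the dorsal–ventral flexure of the lower brainstem; if the
sigmoid does not converge the fit falls back to linear and is flagged.
Orientation statistics are axial (doubled-angle) circular statistics:
resultant length 1 means all cluster major axes are parallel, and the
circular s.d. reduces to the ordinary s.d. for small scatter.

## Tracer spread and flow velocity (`tracer`)

Tracer voxels are those at or above 1.02 × the mean intensity of a
user-supplied air reference box — the threshold is inclusive, and scale
invariance (multiplying the whole scan by a constant) holds because the
threshold tracks the air mean. The largest connected component is taken
as the bolus (a single injection); "spread" is the axis-aligned extent
(max − min + 1 voxels, in mm), the simplest metric consistent with
per-axis reporting. Serial scans are assumed pre-aligned; no
registration is attempted. The per-axis post/pre fold-change scales a
literature sedentary baseline of 0.2 μm/s: a two- to three-fold spread
enhancement gives the working flow-velocity range 0.4–0.6 μm/s.

## Permeability and shear stress (`shear`)

The interstitial space is modelled as a porous medium. Permeability
follows Kozeny–Carman with the equivalent circular diameter
d = √(4·area/π) of the measured cross-section:

    K_p = ε³ d² / (36 K (1 − ε)²),     τ = μ u / √K_p.

Both formulas are pluggable strategy functions so an alternative algebra
can be swapped without touching callers. τ is monotone in every argument
over the physical domain (increasing in μ, u, K; decreasing in d and in
ε for ε ≤ 0.5), so envelope bounds over parameter ranges are attained at
corners of the range cross-product; all 2⁵ corners are evaluated and the
attaining corners reported, and a brute-force grid search in the tests
confirms the corner property.

Defaults (config-overridable, converted from μm/s, μm², mPa·s at the
interface; SI internally):

| parameter | default | rationale |
|---|---|---|
| u | 0.4–0.6 μm/s | 2–3 × the 0.2 μm/s sedentary baseline, from the tracer analysis |
| K (Kozeny) | 4.5–5.5 | oriented channel-like pores |
| area | 0.0083–0.18 μm² | pore cross-section envelope from the imaging chain |
| ε | 0.2 | brain extracellular volume fraction |
| μ | 0.8 mPa·s | CSF-like interstitial fluid at body temperature |

Viscosity is deliberately a point default rather than a range: the
published envelope this chain reproduces (≈ 0.076–0.53 Pa) is consistent
with a single CSF-like viscosity of 0.8 mPa·s, whereas folding a
0.7–1.0 mPa·s range into the corner search widens the upper bound well
past it. Users who want viscosity uncertainty can pass
`mu_mpa_s=(0.7, 1.0)` explicitly.

With the defaults the chain yields K_p ≈ 6.7×10⁻¹⁹–1.8×10⁻¹⁷ m² and
τ ≈ 0.076–0.59 Pa — sub-pascal stresses of the magnitude that modulates
mechanosensitive signalling in glia.

## Cardiovascular variability (`cardio`)

* **MAP** = DBP + (SBP − DBP)/3; SBP < DBP is an error.
* **Cuff aggregation**: a value of the day is the mean of exactly three
  same-morning readings; a value of the week is the mean of the daily
  values and is *undefined* (not an error) below three recorded days.
* **RRI cleaning** is two fixed-order passes: (1) remove intervals
  < 0.5 s or > 1.5 s; (2) scan survivors in order and remove values
  outside 0.6–1.4 × the mean of the 10 immediately preceding *retained*
  values. The first 10 retained values lack history and are exempt; the
  order matters (a fixture in the tests shows the reversed order changes
  the outcome) and is fixed. Halved/doubled ectopic intervals are the
  canonical violations of the relative rule.
* **Validity**: over the last 300 s, a beat's pressure fails when
  flagged invalid, missing, or SBP < 50 mm Hg; the BP channel fails when
  failed-beat time exceeds 4% of the window, the RRI channel when the
  cleaning removal fraction exceeds 10%. Both bounds are strict — exactly
  4% / 10% passes. A beat belongs to the window when its interbeat
  interval lies inside it.
* **Band power**: the central 256 s of the last 300 s are resampled to a
  uniform 4 Hz grid by cubic interpolation over *time* (so SBP and RRI
  share a frequency axis), mean-removed, Hanning-windowed with 1/mean(w²)
  power compensation, and integrated over the band on the one-sided
  periodogram. A full-scale sinusoid of amplitude a inside the band
  returns a²/2 (Parseval), which calibrates the analysis; 4 Hz is the
  conventional tachogram rate and comfortably resolves the 0.4 Hz band
  edge. A single 256-s segment with a single window is used — no Welch
  averaging. LF = [0.04, 0.15) Hz and HF = [0.15, 0.4] Hz, half-open at
  0.15 Hz so no bin is double-counted.
* **Normalisation**: begin/end period values are divided by the mean of
  the begin period; per-participant period means require ≥ 4 valid
  sessions by default (configurable for the documented three-session
  exception).

## Nerve activity (`nerve`)

The rectify-and-integrate chain is: mean subtraction (DC removal), a
4th-order zero-phase forward–backward Butterworth band-pass at
50–10,000 Hz — the upper edge is clipped to 0.45 × rate when it exceeds
Nyquist, as it does at the default 3 kHz sampling, and the clipping is
logged — full-wave rectification, then a first-order leaky integrator
y_t = α|x_t| + (1 − α)y_{t−1} with α = Δt/(τ + Δt), τ = 3 ms. "Integrated
and smoothed with a 3 ms time constant" is read as this single RC stage,
the standard hardware meaning; no separate running sum is added. The
integrated trace is averaged per interbeat window [t_b, t_{b+1}), the
post-mortem background level is subtracted, and each beat is expressed
as a percentage of the mean of the 10 beats immediately preceding the
event (baseline = 100%). A non-positive baseline after background
subtraction is an error: the signal is indistinguishable from noise.

## Synthetic data (`synthetic`)

The study deposited no raw imaging or physiological recordings, so every
pipeline input is generated with known ground truth; all randomness comes
from one seeded `numpy` generator per call and identical spec + seed give
bit-identical output.

* **Pore volumes** — straight tubes with elliptical (default circular)
  cross-sections, i.i.d. log-normal areas, and directions scattered
  around a preferred axis, on a noisy background. Orientation jitter is
  implemented as two independent N(0, σ) transverse direction
  components, so the signed angle seen in any plane containing the axis
  is exactly N(0, σ) and the recovered in-plane circular s.d. is
  directly comparable to the jitter parameter. Defaults: a thin
  64×24×64 substack at 0.1 μm spacing, 8 channels with median area
  0.8 μm² (σ_log = 0.4), foreground–background contrast 100:10 with
  noise s.d. 5. The channel volume fraction (~17–20%) matches the
  top-20% extraction quantile, and a single channel stays below the
  5,000-voxel trim threshold — that rule targets merged blobs, and
  halving an intact tube would bias its measured cross-section.
  Channel placement is rejection-sampled for non-overlap with bounded
  retries (error on failure).
* **Tracer scans** — an anisotropic Gaussian bolus on a background set
  to the air level (so only tracer crosses the 1.02× threshold), with a
  fixed corner air box and analytic per-axis level-set extents recorded
  as ground truth; boundary truncation is flagged, not fatal.
* **Beat series** — interbeat intervals mean_rri + LF and HF sinusoidal
  modulations evaluated at the running beat time, SBP with the analogous
  LF term; ectopic beats are RRI halvings/doublings at recorded indices
  (placed after beat 12 so the relative cleaning rule has history),
  dropouts blank the pressure readings. Defaults: 600 s at 1 s mean
  interval, 0.10/0.25 Hz modulation at 30/20 ms, SBP 140/85 mm Hg with
  3 mm Hg LF amplitude — a resting hypertensive-range recording.
* **Nerve signals** — Gaussian-envelope bursts (s.d. 30 ms) of a 300 Hz
  carrier, centred 150 ms after each beat (systolic latency; also keeps
  each burst inside its own interbeat window), plus DC offset and white
  noise; per-beat amplitudes are the ground truth.

**What passing tests show — and don't.** The generators exercise the
analysis rules (thresholds, ordering, band edges, normalisations) and
end-to-end recovery of known geometry and spectral content. They do not
emulate two-photon point-spread blur, CT beam hardening, tissue contrast
in CT (tissue is set to the air level), curved or branching channels,
baroreflex closed-loop coupling between pressure and RRI, or
non-stationary recordings. Agreement on synthetic data therefore
validates the computations, not the biology or the imaging physics.

## Problem sizes

The recovery suites use 13 volumes × 8 channels per seed (≥ 100 pooled
channels, five seeds) for the pore-distribution check, 25 volumes × 4
channels for orientation, 600-s beat series, and 60-s nerve records —
sizes at which the statistical tolerances (mode within 20%, FWHM within
25%, Spearman > 0.95) are comfortably resolved while the whole suite
runs in well under a minute.

## Known limitations

* The exact algebra behind the published shear-stress table is not
  printed in the source text; the Kozeny–Carman + τ = μu/√K_p form
  adopted here reproduces the published envelope only approximately, and
  alternatives (hydraulic radius instead of equivalent diameter) are
  accommodated via the strategy hooks rather than resolved.
* Whether the original 100-slice ellipse analysis pools clusters across
  slices or summarises per slice is unspecified; this implementation
  measures one chosen slice per volume and pools across volumes.
* Tracer "spread" as axis-aligned extent is one of several defensible
  metrics (second moments, convex hull); extent was chosen for
  simplicity and per-axis reporting.
* Serial CT scans are assumed rigidly aligned.
* Spectral absolute units depend on the (unstated) original resampling
  choices; the begin-period normalisation makes relative comparisons
  insensitive to this, absolute LF power less so.
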