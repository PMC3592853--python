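# Methods

This note documents the models behind `clustrack`, the parameters that
matter, the design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## The physical picture

A membrane transporter (GLUT4 in adipocytes is the motivating system)
exists at the cell surface in two exchanging pools: freely diffusing
monomers (D ≈ 0.09 µm²/s) and molecules confined in elongated
nanodomains of roughly 170 × 90 nm. Single photoactivated molecules are
imaged by TIRF at 200 ms frames with ~30 nm localization precision, at
activation densities sparse enough (0.01–0.1 /µm²) that trajectories do
not cross. A molecule confined in a cluster leaves it by one of three
first-order routes: photobleaching (an artifact of observation),
lateral dissociation back into the monomer pool, and endocytosis.

## Synthetic-data generator (`clustrack.sim`)

The generator is first-class, tested code: every analysis stage is
validated by recovering the parameters it was generated with.

**Spatial model.** Molecules perform 2D Brownian steps (per-coordinate
variance 2·D·t_int) in a rectangular field with reflecting edges.
Clusters are ellipses with per-cluster axes drawn from the configured
mean ± spread; confined molecules diffuse inside with a reflecting
boundary, implemented by radial folding in unit-disc coordinates with a
uniform-redraw fallback for steps much longer than the domain (the
stationary distribution of reflecting Brownian motion in a disc is
uniform, which is also what the folding scheme preserves; at the
default parameters the per-frame step, ~190 nm, already exceeds the
domain, so successive confined positions are effectively independent
uniform draws — exactly the regime in which the MSD plateau identity
plateau = R² holds).

**Association.** Two capture mechanisms are implemented. The preset
default is *rate-based*: a free molecule binds a cluster with
first-order rate k_a and is placed uniformly inside the nearest cluster.
This pins the stationary clustered fraction at k_a/(k_a+k_d) exactly,
independent of time step and cluster geometry. The alternative,
*geometric* capture (probability `p_capture` upon landing inside a
cluster ellipse), is physically more literal but its effective
association rate depends on frame interval and cluster density; it is
available for studies of the encounter process itself. Preset k_a
values are fixed by detailed balance against the measured stationary
fractions: basal k_a = k_d·0.48/0.52 = 0.111 min⁻¹, insulin
k_a = k_d·(27/71) = 0.118 min⁻¹.

**Hazards.** Applied per frame in the fixed order bleach → endocytosis
(clustered only) → dissociation, with per-frame probabilities
1 − exp(−rate·Δt). Bleaching uses the *illuminated* time t_exp per
frame, which is what makes the effective bleaching rate scale with the
relative exposure p = t_exp/t_int. At the default rates (≪ 1 per
frame) the ordering is immaterial; it is fixed for reproducibility.

**Observation model.** Localizations are true positions plus
independent N(0, σ²) noise per coordinate (σ = 30 nm per axis — chosen
per-axis rather than radial because the morphology correction subtracts
σ² from each covariance eigenvalue). Blinking switches a molecule dark
with per-frame probability 0.05 for a geometric(½) duration truncated
at 3 frames, matching the tracker's 3-frame gap rule.

**Kinetic sampler.** `simulate_dwell_times` bypasses space entirely:
dwell durations are minima of competing exponential clocks at rates
p·K_b, K_d, K_e, quantized to whole frames (a molecule lost during
frame k is observed for k frames) and right-censored at the acquisition
end. This gives the kinetics stage an exactly specified test bed at
negligible cost.

**Default conditions** (the study conditions, not tuning knobs):
basal K_d = 0.12, K_e = 0.57 min⁻¹; insulin K_d = 0.31,
K_e = 0.34 min⁻¹; ATP-depleted (`*_kcn`) variants identical but
K_e = 0; D_free = D_in = 0.092 µm²/s; cluster axes 170 ± 30 × 90 ± 30 nm;
σ_loc = 30 nm; t_exp = 200 ms with t_int ∈ {0.2, 0.5, 1, 2} s. The
bleaching rate is not a published quantity; the default K_b = 2 min⁻¹
makes bleaching dominate at p = 1, which is the regime that makes the
extrapolation necessary in the first place. Cluster density (0.3 /µm²)
is likewise a package choice of the right order for puncta visible in
TIRF images.

**Movie rendering.** Emitters contribute isotropic 2D Gaussian PSFs
integrated over pixels by error functions (photons conserved exactly
before noise), plus Poisson shot noise; the bulk channel renders
planted clusters as static puncta. The fusion simulator adds
two-channel event movies: a reporter flash (step + 0.25 s exponential
decay, i.e. 1–2 frames) and cargo that either persists as a punctum or
is released after a 0.5–1.5 s delay and diffuses away.

## MSD analysis (`clustrack.msd`)

Time-averaged MSD uses all ordered pairs at each integer-frame lag;
pairs spanning blink gaps contribute at their true lag. The diffusion
fit is weighted least squares of MSD(t) = 4Dt + C over the first 4 lags
(weights = pair counts). Four lags balance confinement-induced
curvature against variance; the number is configurable and recorded.
Negative D estimates (noise-dominated tracks) are flagged, not clamped,
so estimator bias stays measurable.

**Envelope classification.** The 95% band is the per-lag 2.5–97.5
percentile range of individual time-averaged MSD curves from ≥100
(default 1000) simulated random walks conditioned on a single global D
(per-track conditioning is a flag away but not the default). Because
the band width depends on track length, `classify_tracks` builds
envelopes per track-length bucket (multiples of 10 frames). A
trajectory is directed/confined when its curve stays above/below the
band for 5 consecutive lags. Only the first `run_rule + 1` lags are
examined: individual TA-MSD values are strongly correlated across lags,
so widening the window lets ordinary random walks drift outside the
band somewhere along the curve and be misclassified — with the 6-lag
window, measured specificity on pure random walks is 97.8–98.8% at 30-
and 100-point lengths, while confinement at the relevant sizes is
visible from lag 1 and detection of 120 nm domains stays at 100%.

**Known bias: whole-trajectory classification under exchange.**
Classification is per whole trajectory (no state-switching
segmentation, by design). A track that switches state mid-life —
a monomer captured during observation, or a clustered molecule that
dissociates — has a depressed average MSD and usually classifies as
confined. Under the basal preset the effect is nearly invisible
(measured confined fraction 0.49–0.51 against a stationary 0.48)
because the pools are near-symmetric; under the insulin preset, whose
faster dissociation mixes more tracks, the measured free fraction runs
about 0.05 below the stationary value (0.66–0.67 vs 0.72). Tests
assert the recovered fractions at tolerances that include this
documented bias. Passing them shows the classifier reproduces the
population split of exchanging two-state diffusers; it does not show
the bias is absent.

**Confinement size.** The plateau region starts at the first lag where
MSD < 0.5·4·D_free·t; the plateau is the count-weighted mean MSD beyond
it, and diameter = 2√(plateau − 4σ²) by the uniform-disc identity.
A noise floor exceeding the plateau clamps the estimate to zero with a
flag. Recovery is within a few percent at 60–240 nm true diameters with
σ = 30 nm.

## Morphology (`clustrack.morphology`)

Cluster regions are defined by residency (≥30 frames within a 125 nm
radius of the running centroid, blink gaps ≤3 frames tolerated), with
overlapping runs of different molecules merged; free-diffusion
positions never enter a region. Ellipse axes come from covariance
eigenvalues under the uniform-ellipse convention (variance a²/4 along a
semi-axis a), corrected by quadrature subtraction of σ² — the paper-
style "corrected for localization uncertainty" reading; eigenvalues
driven below a (5 nm)² floor are clamped and flagged. Circularity is
4πA/P² (normalizing a circle to 1; the alternative π A/P² convention
differs only by this constant) of the alpha-shape outline at a 50 nm
probe radius. The probe radius is a config knob: smaller probes carve
raggeder outlines and lower circularity (measured population means move
by ~0.05–0.1 between 30 and 50 nm probes on synthetic clusters).

**Generator limitation.** Planted clusters are smooth ellipses, so
reconstructed synthetic regions score circularity ≈0.85 — close to the
smooth 170 × 90 ellipse value of 0.864. Real clusters are irregular
(tubular and branched outlines), which is what drives measured
circularities far below the smooth-ellipse value on real data. Shape
*irregularity* is outside the generator's model, so no test asserts a
low absolute circularity; the oracle-backed values (circle = 1, smooth
ellipse = 0.864) and the scatter/probe sensitivities are what the suite
pins down.

The intensity-based clustered fraction segments puncta on a
time-averaged projection (median background, MAD threshold, dilation to
catch PSF tails) and reports background-subtracted puncta flux over
total offset-subtracted flux — photon bookkeeping that recovers a
planted 30% punctum to ±2% and the 48% clustered-fraction regime to
within the 0.40–0.50 band.

## Kinetics (`clustrack.kinetics`)

Dwell extraction applies the loss rule symmetric to the tracker: a
dwell ends at the last in-cluster frame before an absence (no
localization, or localization outside the region grown by a 60 nm
margin) longer than 3 frames; dwells alive at the end of acquisition
are censored. Matched against ground truth, ≥95% of true dwells of ≥5
frames are recovered within ±1 frame.

The disappearance rate is fit by a least-squares exponential to the
dwell histogram (bin width = frame interval), excluding censored
records — harmless for an exponential, since truncation rescales but
does not reshape the histogram. Weights matter: weighting bins by
observed counts biases the decay steep (downward-fluctuating bins get
overweighted), so the fit iterates with model-based weights
(σ_bin = √max(model, 0.5)), which brings the bias below 1% across the
protocol grid. The censored-exponential MLE (with a half-frame midpoint
correction for quantization) is provided as the efficient alternative;
the histogram method remains the default because it is the procedure
the field reports. Standard errors come from a seeded bootstrap over
records (default 500 resamples) or, when speed matters, the analytic
K/√n.

`decompose_rates` fits K vs p per branch by weighted linear regression
(weights 1/SE²); the endocytosis-off intercept is K_d, the control
intercept K_d + K_e, the slope K_b. Branches are fit independently by
default (a pooled-slope option exists; whether the original analysis
shared a slope is unknown). The decomposition is exact on noiseless
lines and recovers K_d and K_e within ~5–10% at 2000 dwells per
protocol; the weakest-determined quantity is the basal K_d (intercept
extrapolated far below the smallest measured K), at ~8% relative SE
under those conditions.

Both association-rate conventions are always reported: the quoted form
K_a = K_d·[free]/[clustered] and the detailed-balance form
K_a = K_d·[clustered]/[free] (under which K_a·[free] = K_d·[clustered]
balances). For near-symmetric basal fractions they almost coincide;
they diverge for insulin, and neither is silently "corrected".
`flattened_vesicle_diameter` equates sphere surface area πD² to flat
disc area ¼πD², giving D_cluster = 2·D_GSV.

## Fusion (`clustrack.fusion`)

Flash detection thresholds the smoothed excess over a trailing
per-pixel median baseline at 5 robust SDs, labels spatiotemporally
connected components, and keeps those that rise within 2 frames, fall
back within 20, and span ≥20 voxels (a real flash covers the PSF
footprint for several frames; smoothed shot noise makes only small
blobs). Duplicate components of one flash are merged.

Classification uses the 1 µm-radius ROI trace of the cargo channel.
The thresholds are fractional in the post-event peak elevation —
dispersal when the elevation falls below 25% of peak within 20 s,
retention when it stays above 50% throughout the retention window —
because absolute criteria fail on both sides: the shot-noise SD of a
120-pixel ROI mean is a fraction of a photon (an absolute
baseline+2σ bar is never reached), and a micron disc at
D ≈ 0.09 µm²/s retains half its released cargo for ~5 s, so any
dispersal window much shorter than ~20 s classifies true dispersal as
retention. Fractional thresholds are also what make the call invariant
to overall intensity scale. The release delay is read from a tight
300 nm central ROI (half-drop time), which tracks the punctum
dissolving rather than the slow emptying of the full disc; measured
delay errors are ~0.2 s against truth.

## Pipeline and reproducibility

All randomness flows from one root seed through per-stage substreams
(SeedSequence spawn keys from a stable CRC of the stage name — Python's
built-in string hash is process-randomized and must not be used for
this). Reruns with the same config are bit-identical. Stage outputs are
CSVs with commented headers recording schema version, units and
producing parameters.

The pipeline's classification stage needs the sparse-activation regime
the experimental design enforces (~1 activated molecule per cluster):
at simultaneous densities ≳1 /µm² the linker merges co-clustered
molecules and inflates the confined fraction. The default field size
(25 × 25 µm at 200 molecules, ~0.3 /µm²) keeps runs in the valid
regime.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes chosen
to hold Monte-Carlo error well inside each tolerance: 100 tracks × 100
frames for the pooled D fit (sampling SE ≪ the 10% band), 2000 dwell
records per protocol for the K(p) decomposition (basal K_d SE ≈ 8%
against a 15% band), 200 confined tracks for the plateau estimator, 300
clusters for the morphology recovery, 1000 replicates for envelopes and
specificity measurements, and a few tens of fusion events across
movies. These are the package's standard verification sizes; all scale
linearly if tighter checks are wanted.

## Known limitations

* The generator plants smooth elliptical clusters; real cluster-shape
  irregularity (and hence low absolute circularity) is not emulated.
* Whole-trajectory motion classification biases fractions when tracks
  switch state mid-observation (quantified above); a state-switching
  segmentation is explicitly out of scope.
* Rate-based association relocates a molecule into the nearest cluster
  at binding, a small teleport that the tracker sees as a track break
  at sparse densities — harmless for population statistics but not a
  model of the encounter process (use geometric capture for that).
* No 3D, no drift, no spectral photophysics beyond
  activate/blink/bleach; the evanescent-field helper implements the
  customary first-order two-wavelength intensity ratio
  exp((z/δ_b)(1 − λ_a/λ_b)), not a full angular-spectrum model.
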