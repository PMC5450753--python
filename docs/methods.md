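# Methods

This note documents the models, algorithms, default parameters and design
choices behind `denserp`, and what the synthetic data do and do not emulate.

## Forward model

The volume conductor is an analytic N-shell concentric sphere. For each
Legendre degree `n` the radial potential in shell `j` is
`A_j r^n + B_j r^-(n+1)` (plus the source's outgoing term in the innermost
shell); continuity of potential and of radial current density at every
interface, together with zero radial current at the scalp, gives a small
linear system per degree whose solution yields the surface transfer
coefficient `t_n` (for a homogeneous sphere, `t_n = (2n+1)/n` in closed
form — the package's test oracle). The scalp potential of a dipole at
eccentricity `b` with radial/tangential moment components `m_r`, `m_t` is

    Φ = 1/(4π σ₁ R²) Σₙ t_n (b/R)^(n-1) [ n m_r P_n(cos γ) + m_t P_n¹(cos γ) ]

evaluated by stable upward recurrences for `P_n` and `P_n'` (the tangential
term is computed as `(m·r̂_e − cos γ · m·r̂_s) Σ t_n x^(n-1) P_n'`, which has
no sin γ singularity). Defaults: 4 shells of radii 80/82/87/92 mm
(adult-like proportions; the literature conductivities 0.25, 1.8, 0.018,
0.44 S/m for brain, CSF, skull, scalp; the eyeball compartment of realistic
models has no counterpart in a concentric sphere). The series is truncated
at 60 terms; a guard verifies that per-source term magnitudes decay over the
last ten degrees and names the offending source otherwise. Lead-field
columns are re-referenced to the common average, so they sum to zero.
Units: geometry mm, moments nA·m, potentials µV.

The source space is a regular voxel grid (default 7 mm, the resolution used
for cortical parcellations in dense-array source analysis) centered on the
sphere, keeping locations within `inner radius − margin` (default margin
7 mm; dipoles very close to the brain surface converge slowly and dominate
the norm weighting). Each location carries the canonical axis-aligned
orthonormal orientation triple, so there are `3 N_v` dipoles.

Sensors are an offset spherical Fibonacci lattice (boundary offset 0.36,
the uniformity-optimized variant) restricted to a cap covering 75% of the
sphere — a deterministic stand-in for a 128-channel geodesic net; with
N = 128 on a 92 mm scalp the inter-sensor spacing is ≈ 2–3 cm. Labels are
`E1…E128` in construction order.

## Regularizer

The LORETA constraint is `W = EᵀDᵀDE`. `D` is the 7-point discrete
Laplacian over grid locations (six axis neighbors +1, center −k where k is
the number of neighbors actually present — a Neumann-like boundary rule
that annihilates constants everywhere), Kronecker-extended over the
orientation triple. `E` is diagonal with the Euclidean norm of each
location's three lead-field columns (one scalar per location repeated over
its triple), so superficial, high-gain sources are penalized more — the
usual lead-field normalization that counteracts depth bias. `W` is
symmetric positive semi-definite with a one-dimensional nullspace
(the `E⁻¹·constant` field); solving through `W` adds a relative diagonal
jitter of 1e-8, chosen because much smaller jitters make the sparse
factorization so ill-conditioned that the optimality residual of the
solution degrades.

## Inverse

The estimate minimizes `‖Φ − KJ‖² + λ JᵀWJ` and is computed as
`Ĵ = W⁻¹Kᵀ(KW⁻¹Kᵀ + λI)⁻¹Φ` — the algebraically equivalent sensor-space
form, preferred because the source-space normal equations are dense and
`3N_v`-sized. λ defaults to 10⁻³. `MinimumNorm` replaces `W` by the
identity. Intensity is the per-location moment norm; "standardized units"
divide it by its root-mean-square over locations (a scale-free convention;
the raw norms are also returned). Peaks are extracted by greedy
non-maximum suppression with a minimum separation (default 20 mm).

Known behavior: superficial (parietal/occipital) patches localize to within
about one grid spacing of truth; deep anterior-midline patches show the
classic depth bias — the intensity peak drifts tens of millimetres toward
the surface even for noiseless topographies. The localization claims of
this package are therefore made for superficial sources only.

## Synthetic data

Each of four stereotyped components is a Gaussian bump in time (unit peak,
parameterized by peak latency and FWHM) times a cortical patch: Gaussian
weights (SD = `source_extent`, default 12 mm, truncated at 3 SD) over grid
locations, radially oriented, projected through `K`. The projected
topography is normalized so that its mean over the component's three
strongest channels is one; condition amplitudes are thereby expressed
directly in µV at those "measurement channels" (the package's documented
stand-in for a published electrode montage). Defaults:

| name | peak (ms) | FWHM (ms) | patch center (mm)  | condition amplitudes (µV)            |
|------|-----------|-----------|--------------------|--------------------------------------|
| N1a  | 124       | 60        | (15, −52, 0)       | −1.2 everywhere                      |
| N1b  | 164       | 70        | (−15, −52, 7)      | −3.3 everywhere                      |
| P3a  | 288       | 120       | (0, 25, 35)        | 2.05 / 1.37 / 1.75 / 1.75            |
| P3b  | 364       | 120       | (0, −30, 55)       | 4.32 / 3.40 / 4.06 / 2.93            |

(amplitude order: partner accept / partner reject / peer accept / peer
reject). Per subject, a shared amplitude offset ~ N(0, subject_sd²)
(1.5–2 µV) is drawn per component; per trial an independent amplitude
perturbation ~ N(0, trial_sd²) is added. The paired contrast cancels the
shared offset, so the standardized paired effect at n trials is
`d = Δ / √(2 (trial_sd² + background_window_sd²) / n)`, where
`background_window_sd` is the calibrated SD that background and sensor
noise contribute to one epoch's window-mean at the measurement channels.

**Calibration.** The default effects are anchored at d ≈ 0.33 for the
partner P3a and P3b contrasts and d ≈ 0.41 for the peer P3b contrast at 30
trials per condition (the peer P3a contrast is exactly null). Because the
partner and peer P3b contrasts share one noise SD but have different
condition deltas, both cannot be matched exactly; the common SD splits the
difference. The background's window-mean contribution was measured once on
noise-only simulations through the full preprocessing chain
(4.4–5.5 µV per epoch at the default background) and frozen; `trial_sd`
defaults are then `√(target_total² − background_window_sd²)`. At these
effects the paired test at n = 75, α = .05 has power ≈ 0.81 for the partner
contrasts and ≈ 0.94 for the peer P3b contrast, so roughly one replication
in five fails to reach significance on a partner contrast — an inherent
property of the anchored effect sizes, visible in any 20-seed
significance-rate estimate.

**Noise.** Background EEG is generated as random transient dipoles (rate
200/s, pooled over 192 random source locations/orientations) projected
through `K`: pulse widths log-uniform over 30–120 ms (the theta/alpha band
that dominates ongoing EEG) with amplitudes ∝ width^−1/2, which shapes the
ensemble spectrum as 1/f within the band; the projected signal is rescaled
to a median channel RMS of 4 µV. This level leaves ≈ 0.7 µV of residual
noise on a 30-trial subject-condition ERP, consistent with the grand-average
standard-error bands of published dense-array P3 work, and is the largest
background compatible with the anchored effect sizes (the noise budget is
fixed by d and Δ). White sensor noise adds 2 µV RMS. Eye blinks are a
stereotyped 300 ms biphasic waveform (±120 µV peaks at the most anterior
sensor, decaying with angular distance, e-folding 35°) at 3/min Poisson
times. With probability 0.02 per channel a recording's channel is replaced
by high-amplitude noise (120 µV RMS white plus a 250 µV slow sine), which
the 80 ms/200 µV rule reliably flags. Events are scheduled every 1.3 s
(≥ the 1 s epoch length, enforced) in shuffled condition order; scheduling,
amplitudes and noise use separate per-subject seed substreams, so outputs
are bit-reproducible and independent of streaming order.

**What is not emulated.** Real skull geometry and the eyeball compartment;
true geodesic-net coordinates; non-stationary alpha bursts, muscle/line
noise and ocular drift; latency jitter across trials and subjects
(components are time-locked by construction); subject-by-condition random
interactions (the subject offset is shared across conditions); the task's
filler trials and block structure. Passing recovery tests on these data
therefore demonstrates the correctness of the decomposition machinery under
the model's assumptions, not robustness to every artifact of real
recordings.

## Preprocessing

Zero-phase band-pass 0.1–30 Hz: Hamming-window linear-phase FIR, built as a
high-pass (0.1 Hz transition width — ~8000 taps, the price of a 0.1 Hz
edge) cascaded with a low-pass (7.5 Hz transition width), applied by
centered convolution so the group delay is exactly compensated. Epochs are
half-open `[−200, 800)` ms (250 samples at 250 Hz; sample 50 is stimulus
onset). Bad channels are detected per recording on concatenated epochs:
centered 80 ms moving average, flag if smoothed max−min > 200 µV; flagged
channels are replaced by spherical-spline interpolation (Perrin-style,
order m = 4, 50 Legendre terms, ridge 1e-8 on the spline system). Ocular
artifacts: an epoch is dropped if peak-to-peak on any of the four most
anterior sensors exceeds 150 µV (the generator's blink has ≈ 240 µV p2p
frontally; clean background stays far below). Retained epochs are averaged
per condition; averages are baseline-corrected to the pre-stimulus mean and
re-referenced to the common average (two commuting idempotent projections,
applied in that order). Subjects with fewer than 10 artifact-free trials in
any condition are excluded (the strictest reading of the exclusion rule;
configurable).

## Decomposition

*Parallel test.* Eigenvalues of the data's correlation matrix are compared
with the mean scree of seeded standard-normal surrogates of identical shape
(default 20); the retained count is the leading run of actual eigenvalues
strictly above the surrogate mean. Under a pure white-noise null this rule
keeps a median of zero factors but occasionally keeps several (scree
fluctuations are correlated across ranks); on ERP data, temporally
correlated noise legitimately contributes retained factors beyond the
signal rank. Zero-variance data retain nothing.

*Temporal PCA + promax.* Covariance-based PCA over subject × condition ×
channel observations with time points as variables. The retained loadings
are varimax-rotated with Kaiser normalization (rows scaled to unit
communality during rotation) — without it, overlapping deflections shift
each other's factor peaks by 10–20 ms — then obliquely rotated by
Hendrickson–White promax with power κ = 3 (κ = 1 reproduces varimax
exactly). Sign convention: each loading's absolutely largest element is
positive. Scores are recomputed by least squares on the oblique loadings,
so `scores · loadingsᵀ` is exactly the retained-subspace reconstruction;
factor correlations are the correlations of those scores.

*Spatial infomax ICA.* The factor scores are rearranged to subject ×
condition × factor observations over channel variables, PCA-whitened to the
requested dimension, and unmixed by infomax with the logistic nonlinearity
and natural-gradient updates (learning rate 0.01, annealed ×0.9 when
successive update directions differ by more than 60°; minibatches of
`ceil(min(5 ln N, 0.3 N))` observations in seeded random order; convergence
when the per-pass weight change drops
below 1e-7, flagged rather than raised on failure at 1024 passes). Maps are
normalized to unit norm and positive peak; activations are computed on the
*uncentered* scores because the observation mean carries the grand-average
component amplitude. The component activations are sparse across
observations (each temporal factor's rows activate essentially one map),
which is the super-Gaussian structure infomax assumes.

*Assembly and selection.* Every (temporal factor, spatial component) pair
is a candidate; its reconstruction for a subject/condition cell is
`coef · map ⊗ loading` in µV, and its `amplitude` rescales the coefficient
by the loading's peak and the map's mean over its three strongest channels,
matching the generator's µV convention. `variance_percent` is the
candidate's reconstruction sum-of-squares as a share of the (column-
centered) data total; because factors and maps are oblique the shares carry
cross terms and sum only approximately to the retained share. Candidates
below 0.5% are discarded; the published remaining triage (dipole-like maps,
recognizable ERP morphology) is supported by QC fields (peak latency,
neighbor-difference map smoothness) but not automated.

## Statistics

Windowed mean amplitudes average the component's reconstructed µV waveform
over a half-open latency window and a channel set (default: the component's
three strongest map channels; canonical windows 344–384, 268–308, 144–184,
104–144 ms are assigned by nearest peak latency). The two-level
repeated-measures ANOVA is computed from the within-subject sums of squares
and equals the squared paired t statistic on `(1, n−1)` degrees of freedom;
zero-variance differences return an `F = +∞` sentinel with a warning. The
reported effect size is `√(2F/n)` = √2 × Cohen's d of the paired
difference — a convention reverse-engineered from published component
tables (it reproduces all eight published values within ±0.01), documented
as such rather than authoritative. Contrasts are partner accept-vs-reject
and peer accept-vs-reject per component, uncorrected at α = .05 by default;
Holm correction is available behind a flag.

## Pipeline

TOML-configured stages (simulate → preprocess → decompose → stats →
localize) with strict key validation, per-stage seed substreams derived
from one global seed, and JSON reports serialized at fixed precision so
identical runs are byte-identical. The simulate stage materializes the
generative *plan* (forward model, specs, ground truth, event tables);
recordings are regenerated from the seed during preprocessing, keeping the
on-disk footprint small at full study scale. Manifests record content
digests of inputs and outputs; re-running a stage whose inputs are
unchanged is a no-op.

## Known limitations

- The two N1 components (124/164 ms, 40 ms apart with 60–70 ms FWHM and
  nearly identical occipital topographies) merge into one temporal factor
  on some seeds; the P3a/P3b pair separates reliably.
- Logistic infomax assumes super-Gaussian sources. In the realistic regime
  (many temporal factors, each map active in a small fraction of
  observations) the activations are sparse and the assumption holds; in the
  zero-noise limit with few factors the activations become strongly bimodal
  and the fixed point is slightly biased, capping noise-free map recovery
  near r ≈ 0.96–0.99. With zero between-subject variability as well, the
  observations degenerate entirely and no ICA is identifiable.
- LORETA depth bias for deep anterior sources (above).
- Variance shares of oblique candidates are not additive (cross terms of a
  few percentage points on realistic data).
- The spherical-spline and forward models share the spherical geometry, so
  leave-one-out interpolation tests are easier than on a real head.
- Amplitude-level Monte-Carlo (`simulate_amplitude_tables`) reproduces the
  generative distribution of measured window amplitudes exactly, but not
  decomposition-induced attenuation, which slightly reduces realized
  contrasts in the full pipeline relative to the configured effects.
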