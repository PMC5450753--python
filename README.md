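# denserp

Dense-array ERP analysis with known ground truth: synthetic 128-channel EEG,
preprocessing, two-step temporal-PCA / spatial-ICA component decomposition,
repeated-measures component statistics, and LORETA source estimation on a
multi-shell spherical head model.

## The problem

Event-related potentials to social feedback contain overlapping deflections —
an occipital N1 (~100–170 ms), a frontocentral P3a (~290 ms) and a parietal
P3b (~360 ms) — superimposed in time and space at the scalp. Windowed
channel averages therefore mix components, blurring condition effects such
as "acceptance > rejection". The remedy studied here is a two-step
statistical decomposition: a temporal PCA with oblique (promax) rotation
separates the time courses, and a spatial infomax ICA on the factor scores
separates the scalp maps, giving spatiotemporal components whose amplitudes
can be tested subject-by-subject. Because such studies rarely deposit raw
EEG, the package ships a fully specified generator whose ground truth makes
every pipeline stage testable: 75 subjects × 4 conditions (partner/peer ×
acceptance/rejection), 30 trials per condition at 250 Hz, with published
component latencies, condition means and standardized effect sizes built in.

## The model

Scalp potentials follow the linear forward model

    Φ(t) = K J(t) + ε(t)

where `K` (N_e × 3N_v) is the lead field of an analytic 4-shell concentric
sphere (brain/CSF/skull/scalp conductivities 0.25/1.8/0.018/0.44 S/m),
`J` the dipole moments on a 7 mm voxel grid with orientation triples, and
`ε` spatially correlated background noise. Components are Gaussian bumps in
time projected from cortical patches through `K`. The decomposition treats
time points as PCA variables over subject × condition × channel
observations (factor count by Horn's parallel test, Kaiser-normalized
varimax followed by promax, κ = 3), then runs infomax ICA (logistic
nonlinearity, natural gradient) over channels on the factor scores.
Condition contrasts use the two-level repeated-measures ANOVA, `F(1, n−1)`,
which equals the squared paired t statistic; effect sizes are reported as
`√(2F/n)`. Source estimation minimizes `‖Φ − KJ‖² + λ JᵀWJ` with the
LORETA constraint `W = EᵀDᵀDE` (7-point discrete Laplacian `D`, lead-field
column-norm weighting `E`, λ = 10⁻³), solved in the stable sensor-space
form `Ĵ = W⁻¹Kᵀ(KW⁻¹Kᵀ + λI)⁻¹Φ`.

## Worked example

```python
from denserp.headmodel import (build_head_model, place_sensors,
                               build_source_space, compute_lead_field,
                               DEFAULT_RADII_MM, DEFAULT_CONDUCTIVITIES)
from denserp.simulate import (SimConfig, NoiseModel, make_default_ground_truth,
                              iter_subject_recordings)
from denserp.pipeline import preprocess_recording, DEFAULT_CONFIG
from denserp.preprocessing import build_erp_dataset
from denserp.decomposition import TwoStepDecomposition
from denserp.stats import run_planned_contrasts, format_contrast_report

head = build_head_model(DEFAULT_RADII_MM, DEFAULT_CONDUCTIVITIES)
sensors = place_sensors(128, head.scalp_radius, coverage=0.75)
src = build_source_space(head, spacing=7.0, margin=7.0)
K = compute_lead_field(head, src, sensors)

specs, truth = make_default_ground_truth(src, K)
cfg = SimConfig(n_subjects=20, trials_per_condition=30, seed=42)
epoch_sets = [preprocess_recording(rec, sensors, DEFAULT_CONFIG["preprocess"])
              for rec, _ in iter_subject_recordings(cfg, specs, truth,
                                                    NoiseModel(), K, src, sensors)]
erp = build_erp_dataset(epoch_sets, min_trials=10)

res = TwoStepDecomposition(erp, seed=0, sensors=sensors).fit()
print(res.summary())
print(format_contrast_report(run_planned_contrasts(res.selected[:3], erp)))
```

prints (abridged):

```
Two-step temporal-PCA / spatial-ICA decomposition
  temporal factors: 13 (parallel test over 250 ranks)
  spatial components: 9
  candidates: 117, selected: 36 (variance floor 0.5%)

   component   var %  peak ms  partner_accept  partner_reject     peer_accept     peer_reject
  T 0xS2       19.20      368            5.09            4.45            4.89            3.30
  T 3xS0       11.19      288           -2.17           -1.08           -1.79           -1.38
  ...

 component window contrast    F(1,df)        p  effect   mean A   mean B
     T0xS2    P3b  partner       1.04   0.3200    0.32     4.89     4.27
     T0xS2    P3b     peer       4.77   0.0417*   0.69     4.69     3.16
     T3xS0    P3a  partner       5.03   0.0371*   0.71    -2.10    -1.04
     T3xS0    P3a     peer       1.13   0.3021    0.34    -1.73    -1.34
```

`T0xS2` is the parietal P3b component (peak 368 ms, 19% of variance): at
this reduced n = 20 its peer acceptance-vs-rejection contrast is significant
(F(1,19) = 4.77, p = .042) with acceptance larger (4.69 vs 3.16 µV).
`T3xS0` is the frontocentral P3a (288 ms) with a significant partner
contrast but no peer contrast — the qualitative pattern the generator
encodes. (This component's map convention puts its positive peak on the
occipital pole, so its frontal amplitudes print negative; the contrast is
sign-invariant.) At the full n = 75 the component-truth correlations exceed
0.95 temporally and 0.99 spatially.

The same analysis is scriptable end-to-end:

```sh
denserp run-all --seed 1 --out out/           # full 75-subject study
denserp report --out out/                     # contrast table
```

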