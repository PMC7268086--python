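# megfc

Beamformer source reconstruction and default-mode-network (DMN) functional
connectivity for resting-state MEG, with a ground-truth-known synthetic
cohort simulator.

## The problem

Cingulate-gyrus epilepsy is hard to localize with scalp recordings, and its
effect on large-scale resting networks is a candidate biomarker. The
analysis implemented here compares two groups of resting-state MEG
recordings (patients vs. controls) on the functional connectivity of twelve
DMN seed regions — bilateral angular gyri (AG), posterior
cingulate/precuneus (PCC), ventral and dorsal medial prefrontal cortex
(vMPFC, dMPFC), inferior temporal gyri (ITG) and anterior cingulate (ACC) —
in three oscillatory bands: alpha (8–13 Hz), beta (14–30 Hz) and gamma
(31–80 Hz). It is aimed at methods researchers who need the full chain —
forward model, inverse solution, connectivity, statistics — as tested,
seedable code rather than a GUI pipeline.

## The method

Per subject: a 50-Hz notch, segmentation into consecutive 500-ms epochs,
robust-z rejection of epochs containing spike-like transients, and random
selection of a fixed number of clean epochs. For each band, the band-passed
epochs drive a two-step scalar beamformer on a single-sphere head model
scanned on a 6-mm grid: per voxel, partial sensor coverage is selected from
the lead-field row norms, a minimum-variance unit-gain vector beamformer

W = (LᵀC⁻¹L)⁻¹ LᵀC⁻¹

is built on the (diagonally loaded) partial-sensor covariance C, the source
orientation η is the dominant eigenvector of WCWᵀ, and the scalar source
activity is Q(r, t) = ηᵀW b(t). Accumulated source imaging sums |Q(r, t)|
over time per voxel, and peaks closer than 10 mm are merged. Seed signals
are the beamformer outputs inside each ROI's 6-mm sphere; per-epoch Pearson
correlations

R(Xa, Xb) = C(Xa, Xb) / (S_Xa · S_Xb)

are pooled across epochs by Fisher-z averaging into a per-subject, per-band
12×12 FC matrix, and node degree counts the edges with |R| > 0.3,
s_i = Σ_j w_ij. Groups are compared per ROI pair and per node with
two-sided pooled-variance t-tests (α = .05, uncorrected primary;
Benjamini–Hochberg reported alongside), and clinical covariates with
Spearman rank correlations.

The synthetic cohort generator states the matching forward world: one
tangential dipole per ROI in a conducting sphere under a 102-channel radial
magnetometer hemisphere, band-limited Gaussian sources with band-specific
pairwise coupling (Cholesky mixing to a target correlation matrix), sensor
noise at a stated SNR, 50-Hz line interference, and Poisson-timed spike
bursts. The default presets elevate 2 / 26 / 42 of the 66 ROI pairs in
α / β / γ for patients, with LAG–LPCC the most elevated pair in every band.

## Worked example

```python
from megfc.simulate import CohortConfig, simulate_cohort
from megfc.pipeline import analyze_cohort, PipelineParams

config = CohortConfig(n_per_group=5, duration=10.0, sampling_rate=250.0, seed=7)
cohort = simulate_cohort(config)
result = analyze_cohort(cohort.recordings, params=PipelineParams(n_epochs=16, seed=7))
print("patient-elevated significant FC pairs:", result.fc_stats.counts("patient_higher"))
```

prints

```
patient-elevated significant FC pairs: {'alpha': 0, 'beta': 20, 'gamma': 35}
```

— the band-graded group effect: more patient-elevated connections at higher
frequencies (at this small n the two alpha-band elevations fall below the
significance threshold). The most affected pair is the left angular gyrus /
left posterior cingulate connection; its gamma-band row of
`result.fc_stats.table` reads

```
 band  mean_patient  mean_control         t            p
gamma         0.430         0.028    29.11     2.1e-09
```

The same run is available from the shell: `megfc run-all --out results/`
writes recordings, per-subject FC/degree tables, group statistics and a run
manifest; `megfc report` prints the packaged clinical cohort summary
(15 patients, mean age 21.2 ± ~5 y, 11/4 male/female, 80% seizure-free,
93% focal cortical dysplasia).

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the package's main computation from scratch: it summarizes the
packaged clinical table, simulates a seeded reduced-scale two-group cohort,
executes the complete pipeline (notch → epoch → reject → select →
band-pass → beamform → FC → degree → group statistics) and writes the JSON
result file.
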