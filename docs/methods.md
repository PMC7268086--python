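# Methods

This note records the models, parameter choices and numerical conventions
behind `megfc`, and what the green test suite does and does not establish.

## Forward model and geometry

The head is a homogeneous conducting sphere (radius 0.09 m) centred at the
origin. Lead fields use the closed-form current-dipole-in-sphere solution
(Sarvas), sampled at radial magnetometers; two exact consequences are used
as invariants: radial dipoles are silent, and a dipole at the centre is
silent for every orientation. Because of radial silence every voxel's
3-column lead field has numerical rank 2; beamformer weights are therefore
computed in the tangential 2-space obtained from the lead field's SVD and
flagged as rank-deficient, with unit gain enforced (and tested) in that
effective basis.

The sensor array is a deterministic Fibonacci spiral of 102 radial
magnetometers on the upper hemisphere at radius 0.12 m — a desk-scale
idealization of a 306-channel whole-head system that preserves the
structure of the inverse problem without gradiometer physics.

MNI coordinates (mm) are mapped to the model frame by a fixed isotropic
scaling of 0.7e-3 m/mm, which places every packaged DMN seed inside
0.9 × head_radius, the spherical mask of the 6-mm scanning grid
(10 395 voxels). No individual coregistration is modelled.

## Inverse solution

Per band, the sensor covariance is pooled over the retained 500-ms epochs
(per-epoch channel means removed) and loaded with 5% of its mean diagonal;
the loading stabilizes inversion when samples per channel are few (short
recordings, narrow bands). Partial sensor coverage per voxel keeps channels
whose lead-field row norm is at least 10% of the row-norm maximum, expanded
to a floor of 30 channels by descending norm with index tie-breaks. The
vector beamformer is the standard minimum-variance unit-gain solution; the
scalar orientation is the dominant eigenvector of the 3×3 source covariance
WCWᵀ, sign-fixed by the largest-magnitude component. On top of that, the
extraction stage applies a geometric sign convention — the orientation is
flipped to have positive dot product with the voxel's dominant lead-field
direction — because a scalar beamformer's output sign is otherwise
data-dependent and not comparable across subjects or groups.

Accumulated source imaging sums |Q(r, t)| over time. The literal signed sum
would cancel oscillatory activity almost entirely, so the magnitude sum is
the default and the signed variant sits behind a flag. The time-slice
index recorded with each image (1 ≤ s ≤ n/2) is bookkeeping only; no
computation consumes it. Peak reporting keeps local maxima (within a
1.5-spacing neighbourhood), then greedily merges peaks closer than 10 mm,
strongest first — the merge order is a package choice; the 10-mm rule is
the method's.

## Connectivity and statistics

Seed signals average the scalar beamformer output over the grid voxels
inside each ROI's 6-mm (MNI) sphere, sign-aligned to the voxel nearest the
centre; the nearest voxel is used when the sphere contains none (at 6-mm
spacing this is the common case). FC is the Pearson correlation of the
band-passed source time series themselves — not amplitude envelopes, which
are available behind a flag — computed per epoch and pooled by Fisher-z
averaging (variance-stabilized; the method text is silent on epoch
pooling). The normalizing quantity in the correlation is the covariance:
that is the only reading of the printed formula that keeps R in [−1, 1].
Signed R is stored; the absolute value enters only at the degree threshold
(|R| > 0.3, binary counting by default, weighted sum behind a switch).

Group comparisons use pooled-variance Student t-tests (Welch behind a
flag), two-sided, with uncorrected p < .05 as the primary criterion and a
Benjamini–Hochberg column always reported alongside — neither replaces the
other. Spearman correlations use average ranks with the t-approximation
p-value. The clinical summarizer reports both population and sample SDs:
the packaged integer ages give SD 5.0/5.1 years while the published table
prints 4.9, so the printed SD is evidently derived from unrounded ages and
is not reproducible from the table itself; the means and counts are.

## Synthetic world

Each ROI source is the sum of three unit-RMS band-limited Gaussian
components. Within a band, a target correlation matrix is assembled from
pairwise coupling coefficients (validated positive semidefinite) and
realized by Cholesky mixing of independent noises before filtering; for a
single coupled pair this is exactly the shared-component construction
x_a = √c·z + √(1−c)·e_a, and it generalizes it to overlapping pairs.
Filtering is identical across rows, so mixing and filtering commute and the
population correlation of the band components equals the specified c.

Dipole orientations are tangential (radial ones are silent) and fixed per
ROI from a CRC of the ROI name — stable across subjects so that correlation
signs are cohort-comparable. Defaults: sampling 1 000 Hz, 20-s recordings
(40 epochs at the published scale), source-to-sensor-noise 20 dB (the
study reports no amplitudes or SNR; 20 dB keeps single-dipole localization
within one grid spacing, which is the regime the localization tests
certify), line amplitude 0.5 × signal RMS, spikes 2/min as 80-ms
raised-cosine bursts at 10× channel RMS — unambiguous for the robust-z
rejection stage (z = 6, MAD-based, floored at machine-epsilon scale so
constant data is never flagged). Covariates: patient age ~ N(21, 5²)
truncated to [10, 35], duration ~ N(12, 5²) truncated positive, 11:4 male
skew — anchored to the published cohort moments.

Group presets elevate 2 / 26 / 42 of the 66 pairs in α / β / γ over a
uniform 0.15 baseline (elevated levels 0.40–0.45; LAG–LPCC 0.50–0.55,
largest in every band), mirror-symmetric across hemispheres. The sets are a
package construction; the counts and the LAG–LPCC emphasis are the
published pattern.

What the generator does not emulate: cortical geometry and individual
anatomy, gradiometers, physiological artifact waveforms (cardiac, ocular),
non-stationary coupling, and 1/f background spectra. A green test therefore
certifies algorithmic correctness and statistical calibration under the
stated world, not performance on real MEG.

## Known limitation: signed LCMV correlations under sustained coupling

With twelve simultaneous dipoles and *sustained* coupling, the
minimum-variance filter partially cancels a voxel's correlated partner
(negative cross-leakage growing with c). For isolated coupled pairs —
the alpha/beta preset structure — the reconstructed *signed* correlation is
then anti-monotone in the true coupling; the dense gamma structure
survives. This reproduces a known property of LCMV functional connectivity
rather than a defect of the implementation: it persists with the analytic
population covariance, true orientations, any loading from 5% to 200%, and
SNR from −5 to 20 dB. Consequently the effect-structure and
coupling-recovery simulations are evaluated on the generated ROI source
signals (the connectivity and statistics stages), while the sensor-level
beamformer chain is certified by the localization, unit-gain, silence and
type-I-calibration simulations, which are insensitive to this cancellation.
Real resting-state coupling is transient, which weakens the cancellation —
one reason published seed-based MEG results do not show the inversion.

## Numerical conventions

Butterworth band-passes (order 5 per edge) and the Q = 30 notch are applied
zero-phase (forward–backward), giving ≥ 60 dB an octave beyond band edges
and ≥ 40 dB at the line frequency in steady state; attenuation figures are
steady-state properties, so tests evaluate them away from filter edge
transients. Epoch selection consumes randomness only when a strict subset
must be chosen. Orientation eigenvalue ties (within 1e-12 relative) break
deterministically on eigenvector order and are flagged. Flat source images
yield the lowest-index voxel as a flagged deterministic peak. All
randomness flows from integer seeds through `numpy.random.SeedSequence`
spawning (per-subject streams independent of cohort size).
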