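# Methods

This note documents the models, estimators and numerical choices behind
`nanogap`, in the order data flows through the pipeline.

## Synthetic acquisition model

The generator emulates a TIRF single-particle acquisition of bilayer-
anchored probes under a cell contact.  Defaults reflect the acquisition
conditions the analysis is designed for:

| parameter | default | meaning |
|---|---|---|
| `frame_interval` | 0.03 s | camera exposure per frame |
| `n_frames` | 1000 | one acquisition (1 min) |
| `d_out` | 0.6 µm²/s | probe diffusion in the free bilayer |
| `d_in` | 0.6 µm²/s | diffusion inside the contact (or a per-pixel map) |
| `survival_prob` | 0.93 | per-frame track continuation → mean length ≈ 14 |
| `sigma_loc` | 0.03 µm | per-axis Gaussian localization noise |
| `pixel_size` | 0.16 µm | typical 100× EMCCD back-projection |
| `particle_density_out` | 0.5 µm⁻² | single-particle tracking regime |
| `eps_enter`, `eps_exit` | 0 kT | boundary barriers (scalar or per-pixel map) |

The spacer channel is a uniform background plus a contact region whose
mean is elevated and modulated by a smoothed Gaussian random field
(relative sd 0.3, correlation length 4 px) plus white camera noise.  The
default contact is a 6 µm-radius disk; contact shapes from real data can
be substituted as masks.

Particle dynamics per frame: an isotropic Gaussian step with per-axis sd
√(2·D_local·Δt).  Crossing detection uses the continuous step segment
sampled at sub-pixel spacing against the mask (not endpoint pixels), so
large steps cannot tunnel through the boundary.  A step whose segment
first crosses the boundary inward is accepted with probability
exp(−ε_enter), outward with exp(−ε_exit); ε may be a per-pixel map,
evaluated at the crossing point.  Rejected steps are reflected specularly
about the local boundary tangent (the normal comes from the smoothed mask
gradient), which preserves the step-length distribution; if the reflected
endpoint would land on the wrong side (sharp corners), the particle stays
at the last pre-crossing point.  Only the first boundary encounter within
one frame interval is treated as a proposal.  Tracks terminate with
probability 1 − `survival_prob` per frame (geometric lifetimes) and dead
particles are replaced by fresh ones drawn uniformly in the configured
start region, keeping density stationary.  Reported localizations add
independent Gaussian noise of sd `sigma_loc` per axis.

Every proposal (direction, accepted/rejected, crossing point) and every
true position is recorded in the ground truth, which is what makes
estimator-recovery tests possible.

What the generator does **not** model: probe photophysics (blinking,
bleaching) beyond track termination, camera EM gain, membrane topography
(strictly 2D), inter-particle interactions and crowding, and the
molecular origin of the barriers.  Passing recovery tests therefore shows
the estimators are correct for barrier-limited free diffusion at
realistic sampling and noise — not that real contacts obey that model.

## Contact segmentation

The mask derives from the spacer channel (temporal mean, if a stack):
Gaussian smoothing (σ = 1 px), Sobel gradient, threshold at 0.2× the
maximal gradient.  The thresholded edge ring is closed (disk radius
2 px), hole-filled, and eroded by the gradient band's outer half-width
(smoothing σ + 1 px) to recentre the boundary on the true edge; the
filled ring otherwise extends systematically outward.  Components smaller
than 0.5 µm² are discarded (bilayer inhomogeneities) and the largest
component is returned — one contact per field.  A constant or empty image
yields an explicit "no contact" result (`None`), not an exception.

Conventions: pixel (row, col) with origin top-left, pixel *i* covering
the half-open interval [i, i+1); physical x = col × pixel size.  A
localization on a mask pixel counts as inside; boundary pixels are mask
pixels with a non-mask 4-neighbour.  Distances to the boundary are
measured sub-pixel against the densely resampled 0.5-level contour —
pixel-lattice distances quantize the touch band and break the noise
margin described below.  The dilated-mask annulus (dilation minus
original) provides a control boundary in the free bilayer.

## Crossing energetics

`p = n_success / n_attempts` and `ε = −ln p` (kT ≡ 1), with
Clopper–Pearson 95% intervals on `p` propagated through the logarithm.
Zero successes give a censored result with lower bound `ln n_attempts`.
Attempts from one track are treated as independent Bernoulli trials — a
stated simplification, since a single particle can attempt repeatedly.

Attempt counting is the one genuinely open design in this estimator, and
the ground-truth generator settled it.  Counting per *approach episode*
(a maximal run of localizations within a touch band of the boundary)
seems natural, but has two biases that do **not** cancel against a
barrier-free baseline: a particle reflected at the boundary can retry
within the same episode (success inflates with the number of retries),
and a rejected fast attempt whose endpoints both lie outside the band
leaves no trace (failures go uncounted, successes of equally fast
accepted crossings are counted).  Both effects scale with the barrier
itself, so episode counting under-recovers a 1.5 kT barrier by ≈ 0.4 kT
even after baseline subtraction.

The default is therefore per-step counting: each frame-to-frame step from
side *s* is an attempt if it either flips side (success) or stays on side
*s* while passing within the touch band (failure).  The attempt
denominator is then proportional to boundary occupancy regardless of
outcome, so the success rate factorizes as exp(−ε) times a geometry- and
sampling-dependent factor, and the barrier-free null baseline subtracts
additively.  Steps with an endpoint closer to the boundary than the
noise margin (default 0.09 µm ≈ 3× localization precision) are discarded:
the apparent side of such points is unreliable and the spurious flips
otherwise contaminate the success counts.  Episode counting remains
available (`mode="episode"`) for descriptive per-approach statistics.

Defaults: touch band 0.16 µm (one pixel), and only tracks with ≥ 5
localizations after first touching the border enter the tallies, which
avoids biasing toward attempts whose outcome was never observed.  Raw ε
values are reported with the null baseline alongside; the baseline is
never silently subtracted.

Breach-zone analysis splits the boundary contour into segments of
≈ 1 µm (≥ 3 required), assigns entry attempts to the nearest segment and
reports Spearman's ρ between per-segment entry success rate and mean
local spacer intensity; segments without attempts are excluded.

## Jump-distance diffusion

Squared consecutive-frame displacements are fitted by nonlinear least
squares of the empirical CDF (plotting positions (i−½)/n) against
`1 − exp(−r²/r₀²)`; `D = (r₀² − 4σ²)/(4Δt)`, floored at zero.  σ is
supplied, not co-fitted: with single-lag data D and σ are not jointly
identifiable.  A single-population fit is used throughout.  Bootstrap
(default 1000 resamples of the jumps with replacement) gives the 2.5–97.5%
interval on D; the fit requires ≥ 50 jumps.  Jumps spanning a frame gap
are excluded; a jump belongs to the region (and map pixel, and intensity
zone) of its *starting* localization.  Unvisited map pixels carry NaN,
never 0.  Intensity zones are equal-count quantile bins of the contact
pixels (default 4) — robust to skewed intensity histograms.  Mean speed
is mean jump distance divided by Δt.  The retention fraction is the share
of inside-starting tracks whose every localization stays inside.

## Null model and comparisons

The null run re-uses the track generator with both barriers at zero and
uniform D, at density and D matched to the experiment, with particles
started inside or outside the contact; repeats (default 20) with
independent seeds give an empirical 2.5–97.5% envelope per quantity.
Experimental values outside the envelope are flagged.  Both sides must
use identical estimator settings (touch band, margins, filters) — a
mismatch is a hard error, because the estimators' baselines depend on
those settings and the comparison is only meaningful when they cancel.

## Statistics

Condition groups (per-cell scalars) are compared by one-way ANOVA with
Tukey–Kramer post hoc pairwise tests (studentized range with the
unequal-n correction, via statsmodels).  Groups with zero within-group
variance yield a flagged result rather than an exception.

## Auxiliary estimates

The diffusive collision count of a dilute solution with a surface uses
the one-sided absorbing-wall uptake `N(t) = A·c₀·√(D·t/π)` (the time
integral of the flux `J(t) = ½·c₀·√(D/(π·t))`); the formula choice is
recorded in the output.  Nonspecific binding-rate bounds: lower =
observed binding events / theoretical collisions; upper = binding
fraction among tracked particles.

## Problem sizes and determinism

Validation runs use a 128×128 px field (20.5 µm), a 6 µm disk contact and
1000-frame acquisitions (~2–3·10⁵ localizations, ~1–2·10³ boundary
attempts per run); the diffusion-recovery runs use a 192×192 px
barrier-free field with ~2.6·10⁴ jumps from ~2000 tracks.  These sizes
put binomial and bootstrap confidence intervals well below the effect
sizes being checked.  All stochastic operations take explicit integer
seeds; a fixed seed reproduces output tables bit-for-bit.

## Known limitations

- The Boltzmann ratio estimator gives *relative* penalties; absolute
  values include a sampling baseline and are only interpretable against
  the matched null.
- Greedy mutual-nearest-neighbour linking is adequate at the low
  densities simulated; it is not a substitute for global assignment or
  motion-model linking at high density.
- The specular-reflection barrier is a generative convention; other
  microscopic barrier mechanisms (e.g. position-dependent potentials)
  would change the meaning of ε at strong noise.
- CIs treat attempts as independent; repeated attempts by one particle
  are positively correlated, so real intervals are somewhat wider.
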