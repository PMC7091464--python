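# nanogap

Single-particle analysis of probe behaviour at cell–bilayer contacts.

When a cell adheres to a supported lipid bilayer (SLB) through spacer
proteins, the two membranes are held at a gap of a few tens of nanometres.
Membrane-anchored probes of known hydrodynamic diameter — quantum dots in
the motivating experiments — diffuse in the bilayer and report on the
physical constraints inside that gap: whether they can enter at all, how
hard the boundary is to cross, how much they slow down inside, and whether
they get trapped.  `nanogap` implements the complete analysis chain for
such TIRF single-particle-tracking experiments, together with a
ground-truth Brownian-dynamics generator, so every estimator can be
validated against data with known parameters.

It is intended for biophysicists analysing single-particle tracking data
at cell contacts (immunological synapses, adhesion zones) and for anyone
who needs a tested reference implementation of jump-distance diffusion
fitting and Boltzmann barrier-crossing estimation.

## The quantities computed

- **Gap geometry** — the spacer complex sets a gap `P = spacer + ligand`;
  for a probe of diameter `Q` the controlling quantity is
  `Δ(P, Q) = P − Q`.  Probes larger than the gap (`Δ < 0`) are expected to
  be excluded.
- **Exclusion** — probe densities inside vs outside the segmented contact
  on the first acquisition frame give the relative density
  `ρ = (n_in/A_in)/(n_out/A_out)` and `exclusion = 1 − ρ`.
- **Energy penalties** — boundary-crossing attempts and successes give
  `p = n_success / n_attempts` and, via the Boltzmann distribution,
  `ε = −ln p` in units of kT, separately for entry and exit.  Raw `ε`
  contains a sampling baseline; it is always interpreted against a
  matched barrier-free null simulation.
- **Diffusion** — squared frame-to-frame jump distances follow
  `P(r², Δt) = 1 − exp(−r²/r₀²)` with `r₀² = 4DΔt + 4σ²` for free
  diffusion with localization precision σ; fitting the empirical CDF
  yields `D`, with bootstrap confidence intervals.  Per-pixel
  jump-distance maps and spacer-intensity-zone fits resolve spatial
  heterogeneity; the retention fraction quantifies trapping.
- **Null model** — barrier-free Brownian motion over the same contact
  mask, at matched density and D, pushed through identical estimators.

## Worked example

Simulate an acquisition with a 1.0 kT entry and 0.5 kT exit barrier at a
6 µm disk contact, segment the contact from the spacer channel, and run
the estimators:

```python
from nanogap import (SimulationParams, DiskContact, generate_spacer_image,
                     simulate_tracks, contact_mask, relative_density,
                     tally_crossings, energy_penalty, jump_distances,
                     fit_jd_cumulative, retention_fraction)

params = SimulationParams(seed=42, eps_enter=1.0, eps_exit=0.5)
image, _ = generate_spacer_image(params, DiskContact(radius_um=6.0))
mask = contact_mask(image, pixel_size=params.pixel_size)

locs, truth = simulate_tracks(params, mask)
tracks = locs[locs.groupby("track_id")["frame"].transform("size") >= 6]

tally = tally_crossings(tracks, mask)
enter, exit_ = energy_penalty(tally)
```

This prints (abridged):

```
contact area: 112.8 um^2
10319 tracks longer than five frames
first-frame relative density: 1.01 (exclusion -0.01)
entry:  130/1635 attempts -> eps_enter = 2.53 kT [2.37, 2.71]
exit:   137/1210 attempts -> eps_exit  = 2.18 kT [2.02, 2.34]
D_inside: 0.599 um^2/s (95% CI 0.592-0.605, n = 48796)
D_outside: 0.588 um^2/s (95% CI 0.584-0.591, n = 137827)
retention: 0.86 of 2831 inside-starting tracks never leave
```

The first frame shows no exclusion (the run starts uniform; depletion
builds up as the entry barrier acts), both diffusion fits recover the
generating 0.6 µm²/s, and the raw penalties sit well above the generating
barriers because they include the attempt-sampling baseline.  Comparing
against a barrier-free null run with `energetics.baseline_corrected`
recovers the true barriers:

```
eps_enter - null baseline: 0.85 kT (95% CI 0.65 to 1.04)   # truth 1.0
eps_exit  - null baseline: 0.53 kT (95% CI 0.34 to 0.73)   # truth 0.5
```

The same chain is available from the shell:

```
nanogap simulate --seed 42 --out-dir run/
nanogap mask --image run/spacer.tif --out run/mask.tif
nanogap track --input run/localizations.csv --out run/tracks.csv
nanogap energetics --tracks run/tracks.csv --mask run/mask.tif
nanogap run --out-dir results/        # full pipeline with provenance
```

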