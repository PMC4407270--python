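# Methods

## Locus timing model

A barrier locus is described by a set of flanking origins, each with a side
(`blocking`: centromere-distal, its fork is arrested at the barrier in the
active orientation; `converging`: centromere-proximal, its fork merges at the
barrier), an origin-midpoint-to-barrier distance in bp, and a per-S-phase
firing efficiency. All origins fire at the same moment of S-phase by default
(per-origin offsets exist as an extension knob, default 0), and forks travel
at a constant velocity, default 3.0 kb/min. Travel time is then
`distance / velocity`; reported times are rounded half-away-from-zero at
0.1 min, which reproduces every published table entry.

For one S-phase the model reduces each firing subset to three numbers:
blockage (earliest arrival over fired blocking origins), convergence
(earliest arrival over fired converging origins) and the arrest window
`W = max(convergence − blockage, 0)`. Conventions:

* **No blocking origin fired** → no arrest ever happens; the window is
  *undefined*.
* **No converging origin fired**, or convergence falls beyond the
  configurable observation horizon (default 90 min) → the window opened but
  its end is unobserved: *censored*. Censored mass is reported separately and
  never averaged into the mean window.
* **"Defined"** in summaries means the arrest window *opened* (blockage
  occurred) — the numeric plus censored mass; the mean is over numeric
  outcomes only.
* **Converging fork first** → the locus replicates passively; `W = 0`, not
  negative and not undefined (simulated timelines record blockage =
  convergence, an empty arrest interval).

`window_distribution_enumerate` iterates all 2^n subsets with weight
`∏ e_i ∏ (1−e_j)` and is exact to floating precision; it refuses n > 20 and
points the caller to the Monte-Carlo route, which matches it within binomial
error (checked at 3 SE per bin at n = 10,000).

Note on deletion monotonicity: removing a converging origin shifts the window
distribution upward in the stochastic-dominance sense on the defined scale
(censored treated as +∞). The *conditional* mean over numeric outcomes can
nevertheless decrease under a finite horizon, because the largest windows
migrate into the censored mass; tests therefore check dominance generally and
mean monotonicity only on maps without censored mass.

### Origin efficiencies are placeholders

Only one efficiency is published: ori-1253, the strongest converging-side
origin, fires in 84% of S-phases; the study states only that the eight
origins range from 22% to 84%. The packaged map therefore carries placeholder
efficiencies, chosen once within that range so that (a) the nearest blocking
origin (2.6 min away) fires often enough (0.45) to account for the early
20–25-min first appearances of barrier-colocalized Rad52, (b) distal blocking
origins fill in the later appearances, and (c) the resulting colocalization
incidence in active-orientation cells sits near the observed ~60%. The map
file flags them as placeholders; every placeholder-sensitive result in this
package should be read as conditional on them.

## Per-cell simulator

`simulate_cell` draws, per cell (minutes post-anaphase unless said
otherwise):

| parameter | default | basis |
|---|---|---|
| S-phase start | Uniform(10, 15) | first PCNA foci 10–15 min post-anaphase |
| origin firing | Bernoulli(e_i), independent | stochastic origin usage |
| recruitment lag (blockage → Rad52 focus) | Uniform(7.4, 12.4) | derived bracket; only the bracket is published |
| restart delay (blockage → restarted fork) | Uniform(10, 60) | stated ~10–60 min estimate; family configurable, `inf` disables restart |
| Rad52 persistence after resolution | 0 | endpoint not defined molecularly; knob |
| PCNA foci end | Uniform(40, 70) | PCNA decline 40–45 min, gone by 70 |
| collapse hazard downstream | 0 per kb | switched on for reporter-site analyses |

The cell's fate is a race: the fork restarts if `blockage + delay <
convergence`, otherwise the opposing fork terminates the event. The Rad52
interval is `[blockage + lag, min(restart, convergence) + persistence]`,
absent when that interval is empty (window shorter than the lag) or no
blockage occurred; when convergence is censored and restart is disabled the
interval is truncated at the horizon. After restart the fork advances at the
configured velocity and accrues collapse events as a homogeneous Poisson
process in distance, truncated where it meets the opposing fork (the two
approach at equal speed, so the track is `v·(convergence − restart)/2`) or at
the horizon. Discontinuous Rad52 tracks are *not* generated by the barrier
pathway; the gaps that do appear in summaries come from the background-focus
layer below. Whether persistent Rad52 at a moving fork or repeated
recombination rounds underlie long tracks is deliberately not asserted.

Seeding: one root `SeedSequence`, one spawned child stream per cell, so
growing a population never reshuffles earlier cells.

`restart_fraction` (restarted / blocked cells) is the computational proxy for
the restarted:converged structure ratio seen on 2D gels; it assumes the two
structure classes are equally detectable, which is not established.

## Synthetic microscopy

The renderer emulates the imaging regime: 19 frames at 5-min intervals
(0–90 min), 16 z-planes at 0.3 µm, three channels (locus marker, Rad52,
PCNA). Nuclei are uniform-intensity ellipsoids (100 counts) on a 20-count
field; foci are 3D Gaussian spots added to the expectation; Poisson shot
noise plus Gaussian read noise (σ = 4) are applied last, so the noise-free
expectation is exact and photon conservation (noisy plane means = noise-free
means) holds by construction. Values not published and set here as
assumptions: pixel size 0.16 µm (16-µm EMCCD pixels through a 100×
objective), nuclear radius 1.2 µm, PSF σ 0.20 µm (xy) / 0.50 µm (z), focus
amplitudes 500–600 counts (5–6× nuclear background). Photobleaching, cell
growth and movement are not modelled (cells were immobilized); the published
denoising/deconvolution steps are not emulated — scoring runs on raw
synthetic frames.

Truth-space colocalization is binary per frame: a barrier-engaged Rad52 focus
is rendered within ≤ 0.12 µm (sub-pixel) of the marker; any other focus at
≥ 0.8 µm. A background ("elsewhere") repair-focus layer gives each cell, with
probability 0.79, one 1–2-timepoint Rad52 event at a random time (20–80 min),
which sits at the marker by chance with probability 0.25. These three numbers
are calibrated to the inactive-orientation observations (~79% of cells with
some Rad52 focus; ~20% with a chance colocalization lasting 1.5 timepoints on
average) and produce them within sampling error. Background events are
snapped to whole acquisition frames (an event shorter than one frame interval
would otherwise almost never be sampled).

A movie is a `(time, channel, z, y, x)` uint16 stack; coordinates are
0-based, z index 0 at the bottom plane. Files round-trip bit-exactly through
multi-page TIFF with a JSON sidecar (parameters, layout, seed) that is
required on read; ground truth is a separate JSON. Multi-cell fields place
one nucleus per square tile; pipelines that only need per-cell statistics
render each cell as its own small field (identical model, flat memory).

## Focus scoring

Detection codifies the published manual rules. Background = median intensity
inside the cell mask, re-estimated once with first-pass focus voxels
excluded (a `frame-median` estimator is available since the original
background definition is unstated). Threshold = k × background with
k ∈ [3, 5], default 3 (all thresholds are exposed so a user can sweep k as
the human scorers implicitly did). Connected components (26-connectivity)
above threshold are kept iff some z-section contains a solid 2×2-pixel
square — the "2×2 pixel volume" rule read in-plane, since the z-step and
pixel pitch differ. Colocalization pairs foci across channels when their 3D
voxel sets share ≥ 2 voxels (a 2D max-projection fallback mode exists);
each focus pairs with at most one partner, largest overlap first,
deterministic tie-break. Lowering k from 5 to 3 never removes calls.

Rasters stage each cell on its own anaphase clock: staged timepoint t ∈
{0, 5, …, 90} maps to the acquisition frame minimising |frame − (anaphase +
t)|, ties to the earlier frame; cells whose 90-min window is not fully
covered are excluded from summaries. Summaries report colocalization
incidence, mean colocalized timepoints **with both denominators** (all cells,
and colocalizing cells only — the published 3.8 does not say which), the
longest consecutive run, the fraction of cells whose colocalization ends
before PCNA-focus loss, and discontinuity statistics. `duration_bounds`
converts n consecutive detections at interval Δ into the implied duration
interval [(n−1)Δ, nΔ): 3.4 timepoints → 12 to <17 min, 5.8 → 24 to <29 min.

## Recombination statistics

Condition summaries are arithmetic means and sample SDs (n−1). Fold changes
are ratios of condition means, formatted as printed: ≥ 10 → nearest integer,
< 10 → one decimal ("99-fold", "3.3-fold"); the *overall* recombinant
frequency of a condition is the sum of its conversion and deletion means
(left implicit in the source; made explicit here). Deletion percentages are
class mean / total mean, rounded to an integer. The comparison procedure is
Shapiro–Wilk per group (gate at 0.05, groups failing it are flagged but still
compared, as the source used t-tests throughout), Levene's test to choose
pooled vs Welch, then a two-sided independent-samples t-test; zero variance
in both groups with equal means degenerates to p = 1 with a flag. No
multiple-comparison correction is applied, matching the per-comparison
p-values of the source. Type-I error is calibrated under a Gaussian null
(10,000 replicates, n = 15/group, within 3 SE of α = 0.05): that isolates
the procedure's calibration from the robustness question of applying t-tests
to skewed data.

The per-colony generator draws from a log-normal matched by moments to each
condition's mean/SD — strictly positive and right-skewed like
fluctuation-assay frequencies; the family is configurable, and a mean of 0
with positive SD is rejected as infeasible. It works at the frequency level
only (plating counts behind each frequency are not published).

## What a green test does and does not establish

The synthetic movies contain exactly one nucleus per cell, no drift, no
bleaching, uniform nuclear background and Gaussian spots; detection scores
on raw frames. Green detection/recovery tests therefore establish that the
codified scoring rules are implemented correctly and recover the generator's
statistics — not that they would reproduce manual scores on real denoised,
deconvolved data. Likewise, population summaries are conditional on the
placeholder efficiencies and on the uniform-bracket forms chosen for the
kinetic parameters.

## Known limitation: the restart fraction

With the published geometry — the dominant converging origin 25.1 min from
the barrier at 84% efficiency, simultaneous firing, 3 kb/min — an arrest
window rarely exceeds 22.5 min. A restart delay of Uniform(10, 60) min then
wins the race in only ~24% of blocked cells, not the ~50% suggested by the
~1:1 restarted:converged gel-structure ratio. No admissible efficiency
assignment (range 22–84%, ori-1253 the proximal maximum) raises the fraction
above ~0.3. The corresponding calibration check is left failing rather than
widened: either the gel ratio reflects structure lifetimes rather than
per-cell fractions (abundance ∝ frequency × lifetime, and the two structures
need not be equally detectable), or the effective restart delay is shorter
than the stated bracket. The simulator exposes the delay family so either
hypothesis can be explored.
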