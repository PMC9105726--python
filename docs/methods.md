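# Methods

## Scope and design

`megsim` is a self-contained simulation study: every input is generated by
the package itself (no MRI data, no recorded MEG). The study asks how the
choice of measured field component — normal (NOR), tangential along
latitude (TAN-LAT), tangential along longitude (TAN-LON), or combinations
— affects signal power, SNR, and single-dipole localization for on-scalp
OPM arrays versus a helmet SQUID system, as noise strength, sensor count,
and source depth vary.

## Head geometry

Each synthetic subject is three nested closed surfaces (scalp, skull,
brain) built from a subdivided icosahedron; subdivision order 4 (the
default) gives 2562 vertices and 5120 triangles per layer, the resolution
of standard BEM meshes. Layer radii default to scalp radius minus 6 mm
(skull) and minus 12 mm (brain): a typical combined scalp-plus-skull
thickness. A smooth seeded radial modulation (low spherical-harmonic
degrees only, amplitude 2% by default) emulates head asphericity; the same
angular pattern scales all three layers, so they can never intersect.
Cohorts span scalp radii 0.087–0.096 m over 8 subjects — realistic adult
head-size variability — so that bigger heads receive more OPM sensors.

The conductor sphere used by the forward model is the least-squares sphere
fit to the scalp vertices (algebraic initialization, geometric
refinement). Conductivities (0.3, 0.006, 0.3 S/m) are provenance metadata:
for MEG, the external field of a spherically symmetric conductor is
independent of the radial conductivity profile, so no computation reads
them. This spherical closed form stands in for a boundary-element forward
solution on realistic anatomy; it preserves every mechanism the study
examines (distance scaling, component anisotropy, depth dependence,
radial silence) while being exactly testable. Absolute field values on
real, non-spherical heads would differ quantitatively.

## Source space

Candidate sources form a cortical shell: directions uniform on the
sphere, depths (distance to the nearest scalp vertex) uniform over a
window, positions kept strictly inside the brain surface with a 1 mm
radial margin. The default window 1.3–3.5 cm below the scalp emulates the
depth span of the cortical mantle; the true white-matter surface of a
folded cortex is not modelled, so the synthetic shell has no gyral
clustering and a flatter depth distribution than real anatomy. Depth
sweeps build a dedicated deeper shell so that bins up to 5.5 ± 0.5 cm are
populated. Simulated targets draw positions uniformly (with replacement)
from the candidates and orientations uniformly on the unit sphere, with
fixed moment magnitude q = 100 nAm.

## Sensor arrays

**OPM sites.** Scalp-mesh vertices inside a spherical cap about the +z
(inferior–superior) axis are packed greedily in a seeded random order with
a minimum center spacing equal to the larger footprint dimension (15 mm of
the nominal 10 × 15 mm housing; conservative, since housing orientation is
unspecified) until no admissible candidate remains. The cap half-angle
(66°) was calibrated once so that the default head-size range yields
71–93 sites, then frozen; with it the cohort spans 77–89 sites (mean ~81).
Each site carries a right-handed triad: e_nor radial, e_lat along lines of
latitude (ẑ × e_nor, normalized), e_lon = e_nor × e_lat; at the poles a
fixed Gram–Schmidt fallback from the x-axis applies. A channel integrates
the projected field over the 8 corners of a 3 mm cube (the vapor cell)
centered 6.5 mm above the site along the normal, weights 1/8 — the
geometry of a commercial rectangular OPM whose sensitive cell sits behind
the housing face. Channel order is site-major, component-minor, so all
component subsets share sites and ordering.

**SQUID helmet.** 125 sites are chosen by farthest-point sampling from a
dense Fibonacci-spiral candidate set on the helmet surface (scalp offset
outward by 25 mm), skipping candidates closer than one pickup-coil
diameter to an accepted site. The helmet cap covers the hemisphere (90°):
a commercial whole-head system covers the head down to the ears regardless
of how much scalp the OPM cap spans. Axial first-order gradiometers
integrate 4 points at 90° spacing on each pickup circle (radius 7.75 mm),
proximal coil sign +1, distal coil (50 mm baseline) −1, sensing along the
site normal; they reject spatially uniform fields exactly. The
magnetometer layouts (NOR / TAN-LAT / TAN-LON) reuse the proximal coil
points with the orientation switched to the respective triad axis.

**Sensor removal.** Thinning removes whole sites (all components
together), retaining round((1−f)·S) sites (minimum 4) by farthest-point
subsampling so survivors stay quasi-equidistant; the retained site set is
identical across component configurations of the same subject.

## Noise models

*Ambient*: per channel, per sample, an independent zero-mean Gaussian of
SD σ — the same amplitude for every array and component, emulating
far-field environmental noise after it reaches the sensors. The
realization depends only on (seed, sample), so a σ-sweep rescales one
fixed realization; this variance reduction makes SNR exactly monotone in
σ and lets sweep grid points share dipole draws.

*Spontaneous brain*: 100 dipoles per sample, positions drawn from the
same source space as the targets, orientations uniform, all with moment
q_spont; the noise map is their superposed forward field. The draw depends
on (seed, sample) but not on the array, so every array observes the same
interfering sources — on-scalp sensors, being closer, see systematically
stronger brain noise. No temporal correlation, 1/f structure, or
physiological artifact is modelled.

## ECD fit

The moment at a fixed position is the minimum-norm least-squares solution
through the local leadfield (singular values below 1e-10 of the block
maximum truncated, which leaves the magnetically silent radial component
at zero). The position minimizes the optimal-moment residual in two
stages: a coarse scan over a seeded subset of source-space candidates
(default 200; ties break to the lowest candidate index), then Nelder–Mead
simplex refinement (position tolerance 0.02 mm, relative residual
tolerance 1e-8, at most 2000 evaluations) with a penalty proportional to
the distance outside the brain interior. The interior test is radial
against the brain surface with a 1 mm margin (a configuration switch
relaxes it to the conductor sphere). Non-convergence returns the
best-so-far result flagged, never an exception. Because simulation and
fit share the forward model, noise-free recovery is essentially exact
(micrometers); all reported localization errors are therefore
noise-driven, not solver artifacts. Note that the noise-free residual
valley is strongly anisotropic — amplitude refitting absorbs most of the
field change along the depth direction, and near-radial moments are weak
— so coarse spatial scans (including exhaustive grids at millimeter
resolution) locate the minimum poorly along the valley axis even though
the refined fit is exact; this is why the refinement stage restarts from
several coarse candidates.

## Metrics and averaging

Per sample: RMS of the noise-free signal map; RMS of the realized noise
map; SNR = 20·log₁₀(RMS_signal/RMS_noise) (undefined — reported as NaN —
when no noise was added); RE = √(mean((B_s−B_r)²)/mean(B_r²)) between the
observed (noisy) map B_s and the reconstruction B_r of the fitted dipole —
note the denominator is the *reconstruction*, an asymmetric convention
kept deliberately; Pearson CC between the same two maps; and d_s,f, the
Euclidean distance between simulated and fitted dipole positions
(positions only; orientation and amplitude errors are separate outputs of
the fit table). Sweeps average each metric over the samples of a subject,
then report mean ± SD (ddof = 1) across subjects.

## Sweep drivers and default grids

σ ∈ {0, 25, 75, 150, 225, 300, 375} fT; q_spont ∈ {0, 1, 2, 3, 5, 7} nAm;
fractions removed ∈ {0, 0.25, 0.5, 0.75, 0.85, 0.9}; depth bins
h ∈ {1.5, 2.5, 3.5, 4.5, 5.5} cm with half-width 0.5 cm. The endpoints and
the fixed cases (75 fT, 3 nAm) are the study conditions; interior spacing
is a package choice. The seed hierarchy (master → subject → named streams
for targets, ambient, spontaneous noise, fitting) makes every driver
byte-reproducible and makes shared grid points (σ = 0 vs q_spont = 0)
agree exactly across drivers. Depth bins unreachable for some subject are
dropped from aggregation and reported in the result's provenance.

## Problem sizes in the shipped checks

The test suite exercises the full geometry but scales Monte-Carlo sizes to
keep a desktop run short: most geometry tests use subdivision-3 meshes
(identical construction, ~4× cheaper); fitting-heavy sweep checks use 2–3
subjects × 20 samples; the noise-free recovery check uses one subject ×
100 samples × 8 configurations; the exhaustive-grid fit oracle scans the
whole brain interior at 2 mm on one subject for 20 dipoles.
`scripts/acceptance.py` runs the RMS-based quantities at full protocol
size (8 subjects × 100 samples); they involve no fitting and complete in
seconds.

## Known limitations

* Spherical-conductor fields differ quantitatively from BEM solutions on
  real head shapes; quantities tied to absolute field amplitudes (e.g.
  the OPM/SQUID RMS gain) land near, but not exactly at, values obtained
  with realistic anatomy. In this geometry the measured component-matched
  gain is ≈ 2.0 (real-anatomy studies report ≈ 2.5): a conformal
  "scalp + 25 mm" helmet keeps SQUIDs closer to the sources than a rigid
  helmet over real heads does.
* The OPM cap (66°, forced by the site-count calibration at 15 mm
  spacing) covers less of the head than physically distributed arrays
  with the same sensor count. Two consequences observed in this geometry:
  combining all three components helps localization at *every* sensor
  count (not only low counts — the full-count OPM-ALL vs OPM-NOR gap
  exceeds one across-subject SD), and under pure brain noise the
  TAN-LON single component can localize slightly better than OPM-ALL.
  The corresponding broad-coverage findings should be read with this
  coverage difference in mind.
* Single-dipole sources and single-dipole inverse only; no distributed
  inverse solutions, no multi-dipole fitting.
* Sensor calibration errors, gain mismatch, crosstalk, and movement
  artifacts are out of scope; sensors are ideal integrators of the field.
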