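# Methods

## Relative-activity statistic

The unit of comparison is log relative activity, log(RA) =
log₁₀(Emax/EC₅₀) = log₁₀(Emax) + pEC₅₀.  Emax is the fitted upper
asymptote in nM cAMP and EC₅₀ is molar; the nM/M constant cancels in any
difference of log(RA), and the test suite asserts this cancellation
implicitly by checking differences only.  The mutant value is corrected
for cell-surface expression by subtracting log₁₀ of the expression
fraction, and

Δlog(RA) = log(RA)₍WT₎ − [log(RA)₍mut₎ − log₁₀ f],  f = %WT / 100.

Sign convention: positive = impaired mutant.  This follows the loss- and
gain-of-function pattern of the assay itself (a mutant with lower
potency/efficacy gives a positive value; a mutant with increased potency
a negative one).

Error propagation is first-order (delta method), with all components
treated as independent and combined in quadrature:

SE² = SE(pEC₅₀ʷ)² + SE(pEC₅₀ᵐ)² + [SE(Emaxʷ)/(Emaxʷ ln10)]²
      + [SE(Emaxᵐ)/(Emaxᵐ ln10)]² + [(SE(%)/%)/ln10]².

The 95 % CI uses the normal multiplier 1.96 in from-summary mode; the
per-experiment mode (below) defaults to a Student-t multiplier.

### Two computation modes

*From-summary* operates on tabulated means ± SEMs — the natural mode
when only a published table is available.  *Per-experiment* refits every
paired WT/mutant experiment, corrects each with that experiment's own
ELISA percentage, and reports the across-experiment mean ± SEM with a
t(n−1) CI.  The two differ by Jensen-type effects that are small at
assay-like noise.  The t multiplier in per-experiment mode is the
calibrated choice at n ≈ 4–6: Monte-Carlo checks (see
`synthetic_pharm.recovery_report`) give ~94–96 % coverage and a ~4–5 %
false-positive rate under the null, whereas 1.96 on 4 degrees of freedom
would undercover.  Whether a published SEM column is the propagated SE
or an across-experiment SEM is generally ambiguous; the package exposes
both so either convention can be reproduced.

### Curve fitting

Three-parameter logistic, Hill slope fixed at 1, unweighted least
squares over all replicate points (`scipy.optimize.curve_fit`).
Initialisation: basal = min response, Emax = max response, pEC₅₀ = −x of
the point nearest half-maximum; pEC₅₀ bounded to [4, 14] (1 pM–100 µM on
the concentration scale).  A failed or singular optimisation returns
`converged=False`, never an exception — flat curves are unidentifiable
in pEC₅₀ and land here.  A converged fit whose span (Emax − basal) is
≤ 3× the residual SD is flagged `no_curve` and excluded from Δlog(RA),
mirroring the "response too weak to fit" convention for dead mutants.

ELISA normalisation forms (A490 − A650)/A595 per well, subtracts the
per-experiment background-well mean from the WT and mutant means, and
expresses mutant as % of the same experiment's WT before averaging
across experiments (day-to-day transfection variation makes raw ratios
incomparable across days).  Negative corrected percentages are allowed
and flagged.  Competition binding fits a one-site displacement curve;
mutant affinity changes are read from the span (top − bottom, i.e.
specific binding) relative to WT, with the ratio SE by the delta method
using the full asymptote covariance — at tracer concentrations below Kd
this is a more sensitive readout than pIC₅₀ shifts.

## Synthetic alanine-scan generator

`PharmTruth` defaults encode the assay design: an 8-point log-spaced
1 pM–1 µM concentration grid, triplicate technical replicates, five
independent experiments.  Noise model: multiplicative lognormal on
responses with σ = 0.15 (variance grows with signal, matching
plate-reader cAMP data; the lognormal is mean-corrected so E[noise] = 1)
plus a Gaussian day effect (σ = 0.1) on pEC₅₀ *shared* by the WT and
mutant of the same experiment, emulating the paired same-plate design —
this common-mode term cancels in per-experiment Δlog(RA), which is what
makes the paired analysis efficient.  ELISA ratios get additive Gaussian
noise (σ = 0.03 on a WT corrected ratio of 0.5 over background 0.1,
giving expression SEMs of a few percent at n = 5, the magnitude seen in
real scans).  One integer seed drives every draw.

What the generator does **not** emulate: plate-position and edge
effects, correlated replicate errors within a well row, cAMP standard
curve interpolation error, receptor reserve/system bias, or radioligand
counting statistics beyond Gaussian noise on counts.  Passing recovery
and calibration tests therefore show that the estimator and its CI are
correct under the stated error model, not that real assays meet that
model.

## Ensemble PCA

Frames are Cα-only and non-mass-weighted.  Before the covariance is
formed, every frame is superposed (Kabsch, via Biopython's
SVDSuperimposer; reflections excluded) onto the running mean, iterating
until the mean shifts by < 1e-6 Å RMS.  The 3N×3N covariance is
normalised by the number of frames, so the eigenvalue sum equals the
total mean-square fluctuation.  Eigenvalues are clipped at zero
(numerical negatives ~ −1e-13 Å²); "non-zero" means > 1e-8 of the
largest.  Eigenvector signs are fixed so frames tagged `active` project
positively (fallback: first non-zero component positive).  Projections
are taken after superposing the query conformation onto the subspace
mean — coordinates handed to the ED driver must be aligned the same way
(`EssentialSubspace.align`).

## Essential-dynamics driving

The driving protocol is the core computation: after each overdamped
Langevin step (x ← x − (dt/γ)∇E + √(2kTdt/γ)·ξ, kB = 1, Å units,
defaults dt = 0.01, γ = 1, T = 0.01), the component of the coordinates
along the fixed unit eigenvector is reset so the projection equals
step × increment exactly; the final projection is therefore exact to
machine precision and the projection series is affine in the step index.
A harmonic-restraint alternative (`constraint="restraint"`) tracks the
moving target softly instead.  Negative increments drive the reverse
(active→inactive) transition.  Replicates are independently seeded from
the one config seed and merged frame-by-frame by the lowest score
(default scorer: recorded potential energy; any structure→scalar
callable can substitute), ties to the lowest replicate index.

The all-atom force field behind the original protocol is out of scope;
the engine here is an elastic network.  A single-basin network anchored
at the inactive state cannot support the driven transition — its
constrained minimum at large projection is a deformed structure far from
the active endpoint (measured final RMSD larger than the starting
separation), and a soft-min double well traps the run in local minima of
the far basin.  The package therefore uses a **morphing two-state
network** (`MorphPotential`): springs on every Cα pair within 10 Å of
either endpoint, with rest lengths interpolated linearly from inactive
to active pair distances as driving progress goes 0→1.  At progress 1
the active structure is the exact energy minimum, so the driven run
tracks adiabatically and lands on the endpoint (final RMSD ≈ 3–4 % of
the initial separation on the default toy bundle).  The single-basin
`ToyPotential` (springs within a 10 Å cutoff, k = 1 energy/Å², zero
energy and gradient at its reference) remains the surface for relaxation
and gradient checks.

Step counts are scaled to the toy system: ~10³ steps with the increment
chosen as (total projection change)/steps reproduce the protocol's
fixed-increment schedule at toy scale; replicate count defaults to 10,
with 2–3 used in tests.

## Toy bundle

Seven ideal helices (rise 1.5 Å/residue, helical radius 2.3 Å, 100°
twist/residue) stand on a 10 Å ring, alternating direction (antiparallel
packing); the membrane normal is z with the cytoplasm at negative z.
The ring radius puts facing Cα atoms of adjacent helices at ~4–5 Å, so a
5 Å contact cutoff yields a sparse, realistic interhelical contact set.
Residue indices follow CLR-like ranges (TM1 starts at 145 … TM7 at 365)
so the named scan positions (V190, I218, Y227, N305, L345, H374, …) land
on their proper helices with their class B (Wootten) labels attached.
Activation is a rigid rotation of TM5+TM6 about the least-squares TM3
axis (default 25°) plus an optional kink of the cytoplasmic half of TM6
at a chosen residue (default mid-helix).  The generator records which
contacts its own geometry breaks and forms (an independent brute-force
scan); the contact-rearrangement analysis must reproduce these lists
exactly on the noiseless endpoints.  Thermal ensembles add i.i.d.
isotropic Gaussian displacements per atom per frame.

Helix axes — both for the pivot construction and the bend-angle metric —
are estimated from the second differences of the Cα trace, which are
exactly radial for an ideal helix; their common normal is the axis.
This stays exact for segments as short as 4 residues, where a
least-squares line through the positions of a non-integer number of
turns tilts by several degrees (enough to corrupt a bend-angle readout).
Collinear traces fall back to the line fit.  The bend angle is the
arccos of the two half-axis directions, reported per frame with
mean ± SD and max.

## Contact analyses

Contacts are Cα–Cα (deterministic at toy scale; a side-chain-centroid
variant would need full atoms).  "Persistent" means occupancy strictly
greater than the persistence fraction (default 0.8) in every supplied
simulation; with persistence = 1 the rule degenerates to "in every
frame" (a strict inequality would be unsatisfiable).  Pairs within 2 of
each other in sequence are excluded to suppress trivial backbone
neighbours.  Raising the cutoff can only add pairs (monotonicity,
property-tested).  The rearrangement table classifies pairs persistent
in only one state as Inactive/Active and in both as Shared, ordered by
helix then residue.  Representative frames minimise RMSD to the
iteratively aligned ensemble mean, ties to the lowest index.

## Numerical and testing notes

- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical
  datasets, ensembles and trajectories.
- Monte-Carlo checks use 150–1000 repeats; the calibration test runs
  1000 WT/mutant pairs per scenario, chosen as the smallest size at
  which a 92–98 % coverage band is a meaningful test of a 95 % interval.
- Grid-search oracles in the tests (logistic fit, contact counting,
  best-score merging, rigid-placement sampling) are deliberately written
  as brute-force enumerations independent of the library code paths they
  check.
- Degenerate inputs: flat concentration–response curves are reported
  unconverged rather than raising; zero-length springs get a zero-force
  convention; single-frame ensembles are rejected for PCA (no
  fluctuations) but valid everywhere a static structure makes sense.

## Known limitations

- The elastic-network/Langevin engine shares only the *protocol* with
  biased all-atom simulation; energies, timescales and the 2 fs step
  have no physical counterpart here, and increments are in Å of
  collective coordinate per step, not nm.
- Cα-only contacts cannot resolve side-chain rotamer switches; the
  rearrangement table reports backbone-level packing changes only.
- From-summary error propagation assumes independent Gaussian errors on
  each tabulated component; correlations between Emax and pEC₅₀
  estimates from the same fit are ignored, which slightly overstates the
  SE when both come from one curve.
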