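# Methods

## The PPII dihedral criterion

A residue conformation counts as polyproline II when both backbone
dihedrals are defined and fall inside a rectangular window centred at
φ = −75°, ψ = +150° with half-width 20°.  Membership uses circular
distance and is inclusive at the boundary: the published criterion is
written as "± 20°" without stating strictness, and the inclusive choice
makes classification deterministic at exact boundary values (the default
window never touches ±180°, but circular distance keeps user-shifted
windows correct there).  ω dihedrals are neither computed nor filtered
on, and proline and glycine receive no special treatment — the criterion
is a pure (φ, ψ) box.  The window covers (40/360)² ≈ 1.23% of the
(φ, ψ) torus, which is the base rate a uniform-random ensemble must
reproduce and a useful sanity check on any classifier change.

Torsions follow the IUPAC sign convention (cis = 0°, trans = 180°,
positive clockwise viewed along the central bond); the test suite
cross-checks the implementation against MDAnalysis' torsion routine on
random geometries, keeping the two routes independent.

## Ensemble statistics

The substrate is a per-frame, per-chain, per-residue (φ, ψ) table with a
strictly increasing time axis (ns).  All content statistics are ratios
of counts: PPII-classified observations over observations with both
dihedrals defined.  Chain termini, which lack φ or ψ, are excluded from
denominators rather than counted as non-PPII — counting them would bias
short segments (the 14-residue CtS loses 2 of 14 residues to termini)
downward by a constant factor.  Per-residue populations report NaN, not
0, for residues with no defined observations.

Windowed content at report time t averages frames in the half-open
interval (t − w, t] with w = 50 ns by default, so the value at 50 ns is
the 0–50 ns average; report times are multiples of the stride and a
trailing partial window is dropped, not padded.  Per-chain traces are
never pooled across chains, but per-GGM-repeat traces are pooled over
all chains (one trace per repeat).  The scalar `run_summary` is the
observation-weighted mean over windows and chains; an equal-chain-weight
variant is available because a published scalar of this kind could have
been computed either way — with equal frame counts and a shared sequence
the two coincide.

Canonical segments for the GroEL system: CtC is the 24-residue tail
PKNDAADLGAAGGMGGMGGMGGMM (C-terminal Lys/His solubility tags of the
synthetic peptides are excluded — they are absent in the protein), CtS
the last 14 residues AGGMGGMGGMGGMM, and the four GGM repeats sit at CtS
positions 2–4, 5–7, 8–10 and 11–13, leaving the leading Ala and final
Met unassigned.  Segment maps are inferred from the sequence when the
CtS stretch is present and can always be supplied explicitly.

## CD analysis

The population estimate is the empirical two-state calibration
%PPII = 100·([Θ]max + 5560)/15140, with [Θ]max the maximum sampled mean
residue ellipticity between 210 and 230 nm.  The maximum is read off the
sampled grid without interpolation (ties break to the lower wavelength),
because it is read off measured spectra the same way.  The output is not
clamped to [0, 100]: out-of-range values almost always mean wrong units
or a missing baseline, and silently truncating them would hide that; a
warning is raised instead.

Melts are ordinary least squares of ellipticity on temperature
(scipy.stats.linregress), reporting intercept (the 0 °C value), slope
per °C, Pearson r and standard errors.  A flat trace returns slope 0
with r reported as 0 and a degeneracy flag rather than an error, so
batch runs survive flat controls.  The non-cooperativity check requires
|r| ≥ 0.95 (linear PPII melts reach R ≈ 0.96–0.98) *and* no systematic
curvature in the residuals.  Curvature is detected with a one-sided
Wald–Wolfowitz runs test on residual signs (too few runs ⇒ rejection at
α = 0.01) rather than a fixed longest-run cutoff, because the expected
longest run grows with trace length and a fixed cutoff either misses
curvature on long traces or false-alarms on short noisy ones; a literal
`max_sign_run` limit remains available as an option.  Residuals below
10⁻⁹ of the signal scale count as zero so exact fits pass trivially.

Difference spectra are pointwise subtractions on identical wavelength
grids (an opt-in intersection handles mismatched grids; disjoint grids
are always an error).  A helper converts raw millidegrees to mean
residue ellipticity via MRE = θ·MRW/(10·l·c) with MRW = mass/(n−1),
i.e. per peptide bond.

## NMR classification

Δδ¹³Cα = δ_obs − δ_coil against a packaged Wishart-style random-coil
table (25 °C reference, DSS-referenced, no neighbour corrections; an
optional uniform linear temperature coefficient about 25 °C is off by
default).  The residue rules, with configurable defaults:

* α-helix: Δδ ≥ +1.0 ppm and J (if measured) < 5.5 Hz;
* β-strand: Δδ ≤ −0.7 ppm and J (if measured) > 8.0 Hz;
* coil-or-PPII: |Δδ| ≤ 0.4 ppm and J (if measured) in [5.5, 8.0] Hz;
* everything else — intermediate shifts, or shift and coupling that
  contradict each other — is ambiguous.

PPII and statistical coil are deliberately merged: residue-level NMR
cannot separate them, and encoding that epistemic limit prevents
overclaiming; the CD branch carries the population estimate.  The Δδ
cutoffs are documented configuration, not literature constants.  Missing
data propagate as NaN, never as 0, and a residue with neither shift nor
coupling is an error (or skipped at segment level).

The segment verdict "no alpha/beta; coil-or-PPII" requires α and β
fractions below 0.1 *and* an ambiguous fraction below 0.5 — a segment
where most residues are unclassifiable should be called inconclusive,
not coil.  Small perturbations (< 0.05 ppm) of a comfortably-coil table
cannot flip the verdict, which the tests check.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes
and none of the physics.  Defaults mirror the experimental system: seven
independent chains of the CtS sequence, 1 ns frame spacing, per-residue
occupancies in the 15–40% regime (default 0.25).

**Two-state dihedral ensembles.**  Each (chain, residue) is an
independent two-state Markov chain.  With stationary PPII probability p
and persistence κ (frames), the per-frame switching probabilities are
(1 − p)/κ out of the PPII state and p/κ out of the coil state.  This
keeps the stationary occupancy exactly p for every κ ≥ 1, reduces to
iid Bernoulli draws at κ = 1, and gives mean dwell times κ/(1 − p)
(PPII) and κ/p (coil).  A single per-state dwell target cannot coexist
with an arbitrary stationary occupancy, so persistence is defined as
this symmetric slow-down factor; real trajectories publish no
autocorrelation to match, so κ = 1 is the (arbitrary, flagged) default.
PPII-state angles are uniform strictly inside the window and coil-state
angles uniform outside it (rejection sampling), so nominal occupancy and
classifiable occupancy coincide exactly — Gaussian state distributions
would leak across the boundary and bias recovery tests.  Chain termini
are emitted as NaN, as measured chains have them.  One seed expands into
per-chain, per-residue substreams by numpy SeedSequence spawning;
identical specs give bit-identical ensembles.

**Backbone builder.**  Chains grow by internal-coordinate (natural
extension) placement with ideal geometry — N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, angles 111.0°/116.6°/121.7°, ω = 180° — from a canonical
first-residue frame.  It is the independent oracle for the dihedral
code (build at (φ, ψ), re-measure, require agreement to 10⁻⁶ °) and the
source of multi-model PDB fixtures.

**CD series.**  spectrum(T) = p(T)·basis_PPII + (1 − p(T))·basis_coil
with p linear in T (default 43.3% at 0 °C, −0.09 %/°C).  The basis
spectra are Gaussian bands on a 205–260 nm grid: the PPII basis has the
positive 212 nm band (9 nm width) plus a deep-UV negative band at
195 nm; the coil basis is negative at 212 nm with a slightly weaker
deep-UV band.  The 212 nm amplitudes are pinned exactly to +9580 and
−5560 deg·cm²·dmol⁻¹ — the 100% and 0% endpoints of the population
calibration — so the calibration inverts the prescribed p(T) exactly,
and the grid starts at 205 nm so the deep-UV band contributes only a
small tail, which keeps temperature difference spectra proportional to
the PPII basis (cosine similarity ≈ 0.9999).  Measured spectra extend to
190 nm; the synthetic default deliberately stops where the two-band
approximation is clean.

**Shift tables.**  Observed ¹³Cα values are coil references plus uniform
noise of half-width `dca_scale` (default 0.2 ppm, the "very small"
regime), couplings uniform in [5.5, 8.0] Hz.

## What passing tests do and do not show

The synthetic generator satisfies the analysis' assumptions *exactly*:
two discrete states, no classification leakage, iid or exactly-Markov
kinetics, noiseless linear CD mixtures, context-free coil references.
Passing recovery tests therefore demonstrates correctness of the
estimators, not robustness to real data, where PPII is a fuzzy basin,
states exchange on many timescales, CD baselines drift and coil
references carry sequence-context errors.  The MD populations published
for the chaperonin system come from 21 × 1 μs simulations of
half-million-atom complexes; this package analyses such ensembles but
cannot regenerate them, and its trajectory-branch validation is
parameter recovery on synthetic ensembles of matched size (7 chains ×
14 residues × 2000 frames, occupancies 0.16–0.35) chosen to run in
seconds.

## Numerical choices

* Angles in degrees everywhere, wrapped to (−180, 180]; −180 maps to
  +180.  Collinear torsion geometries raise a dedicated error naming the
  atoms rather than returning garbage.
* Dihedral recovery tolerance 10⁻⁶ ° (builder round-trip); PDB-mediated
  round trips tolerate 0.2° from the format's 0.001 Å coordinate
  precision.
* Windowed-content report times use a relative 10⁻⁹ tolerance on frame
  time comparisons so binary float time axes tile cleanly.
* Statistical tests in the suite use 3 standard errors on fixed seeds;
  estimator-bias checks require < 0.01 absolute at 1000–2000 frames.

## Known limitations

* The coil reference table is context-free; Gly/Pro neighbour effects of
  a few tenths of a ppm are real and not modelled (an extension point,
  not a default).
* The CD calibration is empirical and peptide-class specific; applying
  it outside short Gly/Pro-rich peptides can exceed [0, 100]% (hence the
  warning rather than a clamp).
* `population_at` from a 217 nm melt line slightly underestimates the
  212 nm spectral maximum; the spectrum route and the melt route are both
  exposed and labelled, and they agree only up to that band-shape factor.
* The simulator's persistence parameter is a modelling convenience with
  no experimental counterpart in the system studied.
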