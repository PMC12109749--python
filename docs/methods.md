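# Methods

This note documents the models, conventions and numerical choices behind
`dnabow`, and what its validation does and does not establish.

## The system

The object of study is a 30-bp DNA duplex ("DNA bow") held sharply bent
(~160° end-to-end turning of the helical axis) and further tightened by a
constraint between the C6 atoms of residues 2 and 29 of strand B.  Bending
destabilises base-pairing; stabilising agents (here Mg²⁺) shift the bow back
toward intact B-form.  The package quantifies that shift through geometric
trajectory metrics, melting temperatures, and FRET proximity ratios.

Residues are numbered continuously: strand B 1–30 (5′→3′), complement
31–60, pair *i* = (*i*, 61−*i*) — so pair 4 is (4, 57) and pair 21 is
(21, 40).  5′-terminal residues (1 and 31) carry no phosphate, standard PDB
practice, giving 58 phosphates; whether the original models kept terminal
phosphates is unknown, so this convention is flagged here.  Units are fixed:
Å, ns, °C; Mg²⁺ concentrations are carried in mM for simulation-style
conditions and µM for experimental-style ones.

## Reference Watson–Crick geometry

Ideal nucleotide coordinates (with hydrogens) come from the Chemical
Component Dictionary bundled with biotite, read at run time.  A pair is
assembled by placing the two nucleotides in an idealised coplanar frame
(C1′–C1′ along x, glycosidic angle λ = 54.5°, C1′–C1′ = 10.44 Å initial)
and then refining the second base's in-plane pose (3 degrees of freedom) by
least squares against canonical heavy-atom hydrogen-bond distances
(A·T: N6–O4 2.95, N3–N1 2.82; G·C: N4–O6 2.91, N1–N3 2.95, N2–O2 2.86 Å)
with a collinearity penalty on each D–H⋯A angle.  The refined pairs show
bond distances 2.87–2.92 Å, angular deviations ≤ 2°, intra-pair C6–C6
6.36/6.41 Å (the canonical ~6.4 Å), and detect exactly 3 (G·C) / 2 (A·T)
bonds under the 3.0 Å / 20° criterion.  The optimisation is deterministic
and cached per pair type.

## Duplex builder

Pair frames are placed along a circular arc whose tangent turns by the bend
angle end-to-end, with rise 3.38 Å and twist 36° per step (sequence-
independent).  Whole nucleotides ride rigidly on their pair frame, so
phosphates sit at a fixed offset from the base; consecutive backbone
residues are *not* covalently spliced and sugar puckers are the CCD ideals.
The builder is a geometry generator for analysis validation, not a
simulation-ready structure tool.

## Synthetic trajectory model

Each frame is derived from the mean structure by three mechanisms:

- **Fluctuation.**  Every residue is displaced by an independent isotropic
  Gaussian vector; the per-pair σ profile (length 30) applies to both
  partners.  Per-atom RMSF is then σ√3 in closed form.  Defaults: σ =
  0.35 Å internally, 0.6 Å at the two terminal pairs (fraying ends).
- **Opening.**  Each pair carries a two-state telegraph process with a
  stationary open probability and a mean open dwell (default 2 ns).  Open
  pairs are pulled apart by 9 Å along the C6–C6 axis, which removes all WC
  hydrogen bonds by construction.  Default open probabilities: 0.02
  internal, 0.30/0.15 at the outermost/next pairs, 0.10 around pair 10 —
  the qualitative per-residue pattern of the destabilised bow; the
  magnitudes are illustrative, not fitted, since no quantitative fraying
  rates are available.
- **Spring.**  The end-to-end constraint is emulated geometrically, not as
  an integrated force: the bend angle relaxes exponentially (τ = 10 ns
  default) until the C6(2)–C6(29) chord reaches the target.  The minimum
  reachable chord for this geometry is ~10.5 Å (the C6 atoms are off-axis),
  so the default target is 12 Å.

Ions (box default 90 × 120 × 90 Å, DNA centred): a bound fraction starts
attached to randomly chosen phosphates at the bind distance (default 3.3 Å,
radial jitter 0.05 Å) for an exponential duration (default mean 20 ns),
then random-walks with reflecting walls (step 2 Å/frame); the rest diffuse
freely throughout.  There is no re-binding mechanism, but a freed ion that
wanders back within the shell cutoff is counted by the residence analysis —
total residence therefore exceeds the bound dwell, and ground-truth recovery
of the exponential mean uses each ion's *first* contiguous shell visit.

Default run length is 2600 frames at 0.1 ns spacing, mirroring the
proportions of a 260-ns production run at desk scale; reporting windows are
expressed as a trailing fraction (default 100/260) so scaled runs keep the
same proportions.

**What the generator does not emulate:** solvent, energetics, correlated
collective motion, sequence-dependent helical parameters, and Mg²⁺
hydration chemistry.  One consequence worth knowing: because residue
displacements are uncorrelated, a given RMSF amplitude disrupts hydrogen
bonds far more than the same amplitude of correlated motion in real MD —
at the default σ the mostly-closed duplex averages well under one bond per
pair.  Condition *comparisons* (the package's purpose) are unaffected, but
absolute ⟨N_hb⟩ values at a given σ should not be read as physical.

## Analyses

- **Superposition** is unweighted least squares (SVD Kabsch, reflections
  excluded); mass weighting is available but off by default, since the
  metrics are defined over "all atoms" without weighting.  RMSD/RMSF default
  to the DNA atoms (chains B/C) — diffusing ions would otherwise dominate.
  RMSF uses the two-pass procedure (align to last frame → average →
  re-align to average).  A wholeness guard (single-linkage connectivity of
  each residue at 5 Å) catches periodic-image splitting; inter-residue
  distances are deliberately not checked because pair opening legitimately
  displaces whole residues by ~9 Å.
- **ΔWC** is read as purine-N1 to pyrimidine-N3 — the only N1/N3 pairing
  that spans the pair; both distances are computed without superposition
  (rigid-motion invariant).
- **Hydrogen bonds** follow the VMD-style convention: the cutoff angle is
  the maximum deviation of D–H⋯A from 180°.  Donors are polar heavy atoms
  (N/O/S/F) with ≥ 1 hydrogen attached by a 1.25 Å distance rule; atoms
  within 1.8 Å are treated as covalently bonded and excluded.  Per-pair
  counts keep only bonds whose donor and acceptor sit on the two residues of
  the same WC pair; other inter-strand bonds are available from the raw
  detector.  Smoothing is a centred moving average with truncated windows at
  the edges (window 101 frames), chosen over reflection padding for
  reproducibility.
- **Ion shells** use the minimum distance to *any* DNA atom (not only P),
  with the minimal-image convention when a box is present.  Q5 =
  2N_Mg + N_Na − N_Cl is asserted frame-wise.  Tn5 is total occupancy, not
  the longest interval; gap tolerance defaults to 0 frames.  "Lasting" Mg–P
  pairs are those within 3.5 Å for ≥ 50% of the trailing window — the
  persistence thresholds are package choices, exposed as parameters.
- **Tm extraction** differentiates first (central differences, one-sided at
  the ends; no pre-smoothing by default) and fits a Gaussian plus constant
  baseline over the full grid, initialised at the derivative argmax.  The
  baseline absorbs nonzero wings; on synthetic curves it leaves the centre
  unbiased.  Boundary peaks raise an error; non-convergence is flagged,
  never silently replaced; two comparable peaks (≥ half the main prominence)
  report the global maximum with a multimodality flag.
- **FRET** reads intensities at the nearest grid points to 570/670 nm by
  default (an averaging window is available for noisy spectra); no
  background subtraction or spectral corrections are applied — the proximity
  ratio is deliberately the uncorrected surrogate.

## Validation protocol and problem sizes

Ground-truth recovery, not archived data, validates each stage: σ profiles
via RMSF (σ√3 within 5% at 5000 frames; with 60 independent residues the
superposition fit absorbs ~2–3% of the fluctuation, which sits inside that
band), open probabilities via ΔWC-threshold occupancy and via the unbiased
hydrogen-bond estimator p = 1 − E[N_hb]/E[N_hb | closed] (closed-state
reference from ΔWC-classified frames) within ±0.05 at 5000 frames with a
0.5 ns open dwell — the fast-switching regime keeps the occupancy
estimator's effective sample size adequate; exponential residence means
within ±20% from 100 ions over 200 ns; Mg–P bind distance within ±0.1 Å.
Detector correctness is established against exhaustive brute-force oracles
(all-triples hydrogen bonds, rotation-space search for superposition,
all-pairs shell counts).  Directional condition contrasts (destabilised vs
stabilised) check the full chain end to end at 800 frames per condition.

Passing these tests shows the *analyses* are correct and the *pipeline* is
deterministic; it does not show that the generator reproduces real bent-DNA
dynamics — the generator is a test harness with known truth, not a
simulator.

## Known limitations

- Backbone connectivity between neighbouring residues is approximate; do
  not feed built structures to a force field without repair.
- The telegraph model has no cooperativity between neighbouring pairs.
- Bound ions never re-bind after release.
- Tm fitting assumes a single dominant melting transition; multiphasic
  curves are flagged, not decomposed.
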