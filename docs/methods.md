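# Methods

`mtbinder` analyses how a compact, partly positively charged binder domain
(a dynein microtubule-binding domain, MTBD) associates with a filament (a
two-dimer microtubule segment) carrying four intrinsically disordered,
Glu/Asp-rich C-terminal tails (E-hooks).  The package covers model
building, synthetic conformational ensembles, contact statistics,
fluctuation and clustering analysis, rigid-body MM/GB binding energies,
and continuum electrostatics.  This note records the models, the defaults
and why they were chosen, and what the synthetic data do and do not show.

## Structural model

Structures are array-backed atom collections with named index groups
(`binder`, `filament`, `tail_A`–`tail_D`).  Coordinates are Cartesian Å,
right-handed; in synthetic systems the filament long axis is x and the
perpendicular offset axis is z.

Disordered tails are built as extended Cα traces: one pseudo-atom per
residue at the canonical 3.8 Å Cα–Cα spacing, plus one side-chain
pseudo-atom ("SC") 2.5 Å off the trace for every ionizable residue,
carrying that residue's formal charge.  Only coarse electrostatics and
contact statistics of the tails are analysed downstream, so atomistic side
chains would add parameters without adding information; the extended-chain
builder is fully reproducible with no external dependencies.

Ionization is a fixed-pKa rule table evaluated at pH 7: Asp/Glu −1,
Lys/Arg +1, His neutral (model pKa 6.0), Cys/Tyr neutral.  This is the
fully-ionized regime that continuum pKa calculations predict for these
systems at physiological pH.  Termini are left uncharged by default
because the tails are internal fragments of tubulin, not free peptides;
a flag can enable charged termini.

The offset protocol translates the binder group rigidly along the unit
offset axis by each of {0, 5, 15, 25, 35, 45, 55} Å.  Clash relief — used
when a binder is superimposed into a filament-bound pose — translates the
binder along +z in 0.5 Å steps until no binder–filament heavy-atom pair is
below the cutoff (default 2.0 Å).  This deterministic scheme was chosen
over side-chain repacking because it is auditable and testable; it never
moves filament or tail atoms.

## Synthetic ensembles

The generator emulates the *statistical* structure of restrained implicit-
solvent MD of the bound complex, not its physics.  Ensembles are
Monte-Carlo perturbation chains:

- **Filament** atoms get isotropic Gaussian jitter of σ = 0.1 Å,
  emulating harmonic positional restraints.
- **Binder** atoms get isotropic jitter whose per-atom 3-D RMS equals
  `fluctuation_base + fluctuation_distance_gain · offset` (defaults 1.0 Å
  and 0.02 Å/Å).  The per-axis σ is that value divided by √3, so the
  measured Cα RMSF is, by construction, linear in the offset with slope
  `fluctuation_distance_gain` — making slope recovery by regression a
  well-posed quantitative check.  The defaults put RMSF in the 1–2 Å range
  typical of restrained domain simulations.
- **Tails** are re-sampled every frame as self-avoiding persistent walks
  from their anchors.  With probability `exp(−gap / contact_decay_length)`
  (gap = anchor-to-binder distance; default decay 15 Å), a frame contains
  a planted *contact event*: the walk visits up to four of the binder's
  nearest positive sites in turn, parking one bead at 3.8 Å from each,
  with the charged side-chain pseudo-atoms oriented toward their targets,
  then heads back out.  Without an event the walk drifts up and away from
  the binder and is kept at least 5 Å from every binder atom, so
  non-event frames contribute exactly zero contacts.  At or beyond
  `zero_contact_distance` (default 50 Å) no events are planted at all,
  which pins the contact count to zero for the 55 Å offset.

The multi-point touch with oriented side chains implements the guided
soft-binding picture — a polyelectrolyte laying transiently across a
positive surface patch — and makes each planted event net-favorable in the
MM/GB energy model (ion pairing plus dispersion outweighing desolvation),
so that stripping the tails flips the mean binding energy from negative to
positive, the qualitative contrast the energetics stage is designed to
expose.  The exit-after-touch rule prevents the chain from wrapping the
binder, which would bury far more surface than a transient touch and
drown the ion-pairing signal in desolvation penalty.

The binder is a compact blob of ~150 Cα pseudo-residues (minimum spacing
3.2 Å, radius 12 Å).  Charge layouts: `interface_clustered` places ≥ 70%
(by construction ~80%) of the positive pseudo-charges within 10 Å of the
interface plane (the cytoplasmic-like layout); `scattered` distributes
them uniformly, redrawn until fewer than half sit near the interface (the
axonemal-like layout).  The default net charge is +3 e with 12 positive
sites; the published systems pair clustered/0 e and scattered/+3 e, which
tests construct explicitly.

What the synthetic data do **not** emulate: temporal correlation (frames
are independent), solvent, thermodynamic weighting of tail conformations,
and sequence-specific tail structure.  Consequences: (i) passing tests
show the *analysis pipeline* recovers planted statistics, not that the
physics of any real system is reproduced; (ii) tail conformations have no
basins, so Daura clustering of tails at a 1.5 Å cutoff yields many tiny
clusters (top population < 1%) rather than the few dominant states real
trajectories show — the clustering stage is therefore validated against
planted blob fixtures and published matrices instead.

## Contacts

A contact is a heavy-atom pair, one atom from the tail group and one from
the binder group, within 4.0 Å, counted once per frame per pair.  Counting
uses a k-d tree but is bit-identical to the all-pairs definition (and is
tested against it).  Analyses use the trailing half of each replicate run
(configurable window) and average across runs frame-by-frame.  Aggregation
reports per-residue totals and per-segment counts with percentages
`100·count/total`, rounded half-up to two decimals to match the published
table convention.  Rankings break count ties toward the lower residue
number.

## Fluctuations and clustering

Superposition is Kabsch (proper rotations only).  RMSF is computed per Cα
about the ensemble-average structure: each frame is fitted to the mean and
the mean recomputed once (mean → fit → mean), which converges to well
below measurement noise for these ensembles.  The scalar ensemble RMSF is
the arithmetic mean over residues; replicate runs are averaged per residue
first.  The reference for superposition defaults to all binder Cα.

Daura clustering: the frame with the most neighbours within the RMSD
cutoff (2.0 Å for the binder, 1.5 Å for tails) seeds a cluster with those
neighbours, members are removed, and the procedure repeats.  Neighbour
counts tie-break toward the lowest frame index; this is documented because
cluster identity depends on it.  Populations are percentages of *all*
frames and are not renormalised after truncation to the top five.
Bound/free comparison computes the superposed RMSD between every pair of
representatives and flags per-column minima (the free-state cluster most
similar to each bound cluster); per-row minima are also available because
the published bolding convention is ambiguous in places.  Tail RMSD is
superposed on the tail itself by default (fit-on-body is available via the
selection argument).

## MM/GB energetics

`E = E_elec + E_VDW` with `E_elec` = Coulomb (ε = 1 reference state, no
cutoff) + generalized-Born polarization and `E_VDW` a 12-6 Lennard-Jones
sum.  GB uses Still's pairwise function
`f_ij = sqrt(r² + R_i R_j exp(−r²/4R_iR_j))` with Debye screening
`exp(−κ f)` (κ from I = 0.15 M at 300 K) and solvent ε = 80; self terms
use `f_ii = R_i`.  Effective Born radii come from Hawkins–Cramer–Truhlar
pairwise descreening with the standard screening factor 0.72 on the
descreener radius and a 12.0 Å interaction cutoff.  The generic
Lennard-Jones type (ε = 0.4 kcal/mol, r_min = 4.0 Å) is sized for
residue-level pseudo-atoms, where well depths are several times atomistic
values; per-atom parameters can be supplied for all-atom inputs.

Binding energies follow the rigid-body protocol: complex and isolated
parts are evaluated at identical coordinates, so ΔE = E_complex − E_binder
− E_filament isolates interaction plus the descreening change on
association.  Ensemble binding energies average over snapshots with at
least one tail–binder contact (deterministic even stride when capped),
optionally after deleting tail atoms from both complex and parts at fixed
coordinates; the reported spread is the population SD over the selected
snapshots.  Absolute energies are GB-flavour-dependent and are not
comparable to any particular MD package's output; the meaningful outputs
are the Eq-structure identities and the with-tails vs without-tails
contrast.

## Linearized Poisson–Boltzmann electrostatics

The solver discretizes ∇·(ε∇φ) − ε_out κ² φ = −4πCρ on a cubic lattice
with the 7-point stencil; C = e²/4πε₀kT (~557 Å at 300 K) makes φ come
out in kT/e.  Defaults follow common continuum practice: 2 grid points
per Å, perfil 70 (the solute's longest dimension fills 70% of the box),
ε 2/80, I = 0.15 M, 1.4 Å probe.  Charges spread to their 8 surrounding
nodes by trilinear weighting.  The solute interior — the union of
probe-inflated atom spheres — takes ε_in; this is a deliberate
simplification of a molecular-surface construction and is documented as
such (validation is against analytic oracles, not against any particular
solver's surface).  κ² is nonzero only in solvent.  Face dielectrics are
harmonic means of adjacent nodes.  Boundary potentials are a
Debye-screened Coulomb monopole sum over all charges; the interior is
solved by Jacobi-preconditioned conjugate gradients to a 1e-8 relative
residual (non-convergence raises).  Against the Debye–Hückel closed form
(unit charge, uniform ε = 80, I = 0.15 M) the solver is within 2.8% at
10–15 Å at the default resolution, and halving the grid spacing moves the
far field by < 1%.

Field lines integrate E = −∇φ (centred differences, trilinear
interpolation) with fixed-step 4th-order Runge–Kutta from each seed in
both directions, terminating at the grid boundary, below a field-magnitude
floor, or within a sink radius of a charge site.  Surface potentials are
the mean of trilinear φ samples on each atom's solvent-exposed sphere
points (golden-spiral quadrature, points inside neighbouring atoms
discarded; buried atoms report NaN).

## Pipeline

`run_pipeline` chains build → offset sweep → ensembles → contacts → RMSF →
fits → tail clustering (bound vs the beyond-threshold offset as the free
stand-in) → binding energies (with/without tails) → LPBE map of the
binder, writing TSVs, a Markdown report, and a JSON manifest with seed and
per-stage wall time.  All stages are deterministic under a fixed seed
(the ensemble generator derives one RNG stream per replicate run and
offset).  Default problem sizes — 500 frames × 3 runs per offset, 60
energy snapshots, every 5th frame for tail clustering, 1 grid/Å for the
pipeline's LPBE stage — were chosen so a full sweep completes in a few
minutes on one CPU while keeping standard errors small relative to the
planted effects; `scripts/acceptance.py` recomputes the headline numbers
at exactly these sizes.

## Numerical details and edge cases

- Degenerate superposition inputs (fewer than 3 points, collinear sets)
  raise; reflections are never returned.
- Overlapping atoms (r < 1e-6 Å) raise in Coulomb and LJ sums.  The
  ensemble generator additionally nudges apart any atom pair that random
  chain geometry brings within 0.8 Å, keeping nonbonded terms finite.
- Deeply buried atoms clamp the inverse Born radius at 1e-3 Å⁻¹.
- Percentage rounding is decimal half-up, two places.
- Empty contact groups count zero rather than raising; an ensemble energy
  request with no contact-bearing snapshot raises with the frame count.

## Known limitations

- The synthetic tails have no conformational memory or sequence-specific
  structure; tail cluster populations are uninformative (see above).
- GB and LPBE use pseudo-atom radii and a sphere-union dielectric surface;
  absolute solvation and binding energies are model-scale quantities.
- The clash-relief translation is a stand-in for whatever manual curation
  a real model-building workflow would use.
- The LPBE boundary condition (screened monopole sum) underestimates
  multipole structure for very elongated, highly charged solutes close to
  the box edge; the default perfil of 70 leaves a modest margin, and
  tighter boxes should be checked against a larger-box run.
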