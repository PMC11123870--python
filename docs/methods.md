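# Methods

## Scope and data model

`micellekit` consumes trajectories (it does not produce them by MD): ordered
frames of per-atom coordinates with an orthorhombic box, plus a static
topology (names, elements, masses, partial charges, molecule membership,
role labels, bonds). Internal units are nm, ps, amu, elementary charge and
degrees, matching GRO conventions. PDB and XYZ coordinates (Å) are divided
by ten on read. Triclinic boxes raise an explicit unsupported error. Roles
(`cage`, `chain`, `head`, `water`, `ion`, `embedded`, `other`) are supplied
by the topology sidecar or config selections, never inferred from chemistry.

Before any COM, gyration or inertia computation, molecules are made whole
across the periodic boundary by bond-graph traversal (each bonded neighbour
placed at its minimum image relative to the atom it was reached from), and
the aggregate is then re-centred by translating each molecule's COM to its
minimum image relative to the heaviest molecule. Unwrapping is defined only
modulo a whole-box translation; all reported quantities are invariant to
that freedom.

## Size and shape

* `Rg` is the mass-weighted RMS distance from the selection COM (with the
  square root; this is the only reading dimensionally consistent with
  reported radii in nm), summed over all atoms of the micelle selection.
* `Rs = √(5/3)·Rg`, the radius of the uniform hard sphere with the same
  gyration radius.
* Inertia moments are the eigenvalues of the mass-weighted inertia tensor
  about the selection COM — principal moments, not lab-frame diagonal
  entries, which would be orientation-dependent and meaningless for a
  tumbling aggregate. `Iavg` is the arithmetic mean of all three (stamped
  in output metadata). Eccentricity uses the linear form
  `e = 1 − Imin/Iavg`; the square-root alternative cannot reproduce the
  (Imax/Imin, e) pairings reported for real CFA micelles (e.g. 1.27 with
  0.14), the linear form can.
* The gyration tensor is the mass-weighted second-moment tensor; components
  are reported as `Rg_kk = √λ_k` sorted descending, with the identity
  `Σλ_k = Rg²` enforced by test.
* Statistics (mean ± sd) are taken over a trailing window, default the
  final 10% of frames, mirroring the usual practice of analysing only the
  equilibrated tail of a production run. The sd is the population standard
  deviation of the per-frame series.

## SASA

Lee–Richards slice integration: each atom's sphere (Bondi radius + probe,
probe default 0.14 nm) is cut into z-slices (default 0.005 nm); on a slice
the atom contributes a circle, and arcs inside any neighbour circle are
removed by interval merging on the circle; the accessible angle φ adds
`φ·R·dz` of area, since a spherical zone's area is latitude-independent.
Atoms fully inside another sphere get zero; exactly coincident equal
spheres are deduplicated by index so two superimposed atoms count once.
The calculation uses no periodic images — the micelle is made whole and
isolated first, as when solvent is stripped before a surface calculation.
Halving the slice width changes the micelle total by < 0.5%; agreement with
an independent 960-point sphere-sampling estimate is within 2% on random
clusters. Hydrogens are included by default (Bondi 0.12 nm) and can be
excluded; per-element radius overrides are config keys.

## Chain conformation

Dihedrals follow the IUPAC convention (cis = 0°, trans = 180°), computed by
the standard atan2 construction and validated against MDAnalysis'
`calc_dihedrals` sign convention. A gauche defect is a circular distance
from trans exceeding 60° (so ring-locked dihedrals near ±60° are permanent
defects). Probabilities pool frames × chain instances per dihedral label;
dihedral quadruples are taken along ordered per-chain atom-id lists
(head → cage), label k covering atoms k..k+3.

θ is computed per molecule per frame as the angle between the molecular
axis (cage COM → centroid of the head atoms of all chains) and the outward
radial direction (micelle COM → cage COM). θ = 0 means the cage points at
the micelle centre with heads in solution; θ > 90° (head folded toward the
centre) is counted and flagged. The micelle COM uses all surfactant atoms
by default; a cages-only mode exists because the choice is genuinely open
and affects θ only at the degree level. A per-chain θ variant is not the
default: the head centroid is stabler against single-chain excursions.

## Solvation and hydrogen bonds

g(r) is a minimum-image pair histogram normalised by exact shell volumes
and the mean target density over the box, averaged over frames and
reference atoms; self-pairs are excluded, and r_max is clipped to half the
smallest box edge with a warning. The hydration number is a direct
minimum-image count of water oxygens within the cutoff (default 0.35 nm),
equivalent to the g(r) integral up to binning; counts use a periodic
k-d tree.

Hydrogen bonds are geometric: donor–acceptor distance ≤ 0.35 nm plus an
angle test. The published "120°" criterion is ambiguous between an angle at
the hydrogen and at the donor; the default is the common literature rule
∠(D–H···A) ≥ 120°, with ∠(H–D···A) ≤ 60° selectable (`angle_convention`).
Donor hydrogens are resolved from topology bonds; donors without bonded H
are skipped with a warning. Water oxygens are identified as role `water` +
element O.

`C_HB(t)` uses the intermittent definition — a broken-and-reformed bond
counts — because decay over multi-ps windows is only meaningful when
re-formation is allowed; time origins are every frame up to T − max_lag
(default max_lag 20% of the window), and the normalisation by ⟨h(0)h(0)⟩
over the same origins fixes C(0) = 1. The estimator is validated against
the closed-form autocorrelation of a two-state Markov chain,
`C(t) = π₁ + (1 − π₁)(1 − p01 − p10)^t`.

## β classification

For each of the four leave-one-out triples of cage COMs: plane through the
triple, angle vector from the triple centroid to the fourth COM, and
β = arcsin(|v·n̂|/|v|), i.e. the angle between the vector and its projection
onto the plane, folded to [0°, 90°] since the normal's sign is arbitrary.
All four β are pooled into a histogram (default 10° bins); a frame is
classified planar when all four β ≤ 10°, tetrahedral when all four ≥ 60°,
else intermediate. The pooled histogram carries no frame-level rule, so
both are emitted; the all-four rule is the strictest consistent reading and
the thresholds are config keys. The procedure is tetramer-specific and
errors on any other aggregation number. Collinear triples are flagged NaN
(or raised in strict mode).

## Dipoles

μ = Σ qᵢ(rᵢ − r_ref), |μ| in Debye via 1 e·nm = 48.0321 D. The surfactants
carry net charge, so |μ| depends on the reference point: the default is the
selection COM and the reference is stamped into every output. Embedded
cavity species can be included (`with_embedded`) or not; the two modes
differ exactly by the embedded charges' term, an identity kept under test.
Reported dipoles are per molecule plus the across-molecule mean. Absolute
published dipole values depend on a specific optimised geometry and charge
set that are not distributed with any trajectory; the module reproduces
them only given equivalent inputs.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
the dynamics: frames are independent seeded samples, with no forces or
thermostat.

* Four cages as Fibonacci-sphere shells (default 60 pseudo-atoms, radius
  0.35 nm — C60-like, giving cage-COM contacts at the ~1.0 nm crystal
  spacing) at tetrahedral / planar-square / interpolated vertices with
  edge 1.0 nm and per-frame Gaussian COM jitter (default 0.02 nm).
* Chains grown by natural-extension (NeRF) placement with bond 0.153 nm and
  angle 111°, dihedrals sampled trans (180°) or gauche (±60°) per a
  per-label probability vector; the default profile pins ring-locked
  dihedrals at probability 0 or 1 and flexible ones at 0.3–0.8, the shape a
  real amphiphile chain shows. Atom 13 sits at the cage, atom 1 is the
  head; positions 2, 6, 7, 8 are nitrogens; atoms 1–2 carry the `head`
  role, with +1 e on each N2 when charging is enabled (five chains → +5 per
  molecule, neutralised by bulk Cl⁻).
* Water oxygens (or rigid 3-site waters with OH 0.09572 nm / 104.52° for
  hydrogen-bond fixtures) Poisson-placed at a given density outside
  exclusion spheres around the cages; planted first-shell counts put an
  exact number of oxygens at an exact radius around tagged chain atoms,
  with bulk water kept 0.45 nm away from those tags so the planted count is
  recovered exactly. Ions go on prescribed shells around tagged atoms or
  uniformly in bulk.
* Bonds are emitted along each cage shell, from cage to chain, and from
  cage to embedded species; they exist so unwrapping and donor-H resolution
  work, and are connectivity metadata, not a force field.
* All randomness flows through one `numpy` Generator seeded from the spec;
  identical specs produce byte-identical output files.

Defaults are desk-scale: box 6 nm and water density 0.3 nm⁻³ rather than
the production-scale 10 nm box with ~33 nm⁻³ water, so a full pipeline run
takes seconds; both are ordinary fields. What passing tests show is that
the analysis machinery recovers planted geometric and statistical ground
truth; they do not certify force-field-level realism of any observable.

## Numerical choices and degenerate inputs

* Eigen-solves use `numpy.linalg.eigvalsh`; eigenvalues are sorted, and
  near-degenerate (collinear) geometries are flagged while still returning
  values.
* Dihedrals with collinear inner atoms raise a degenerate-angle error;
  θ frames with the cage at the micelle COM are skipped with a warning.
* The SASA arc-merging tie-break for coincident equal atoms keeps the
  lower-index atom.
* Window statistics always contain at least one frame; mean ± sd are
  recomputable from the stored per-frame series exactly.

## Known limitations

Orthorhombic boxes only; no trajectory writing in compressed binary
formats; no force-field assignment; β classification fixed to tetramers;
no Connolly surface or SASA hydrophobicity split; no hydrogen-bond kinetic
rate fitting. One published table row (the mixed-ion system) prints an
Rg/Rs pair inconsistent with Rs = √(5/3)·Rg at two-decimal rounding
(1.14 → 1.4717, printed 1.48); the relation itself, applied to the
other systems' Rg values, reproduces their printed Rs exactly, and the
inconsistent pair is documented rather than targeted.
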