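# Methods

## The protonation model

A titratable site (Asp, Glu, His, Cys or Lys side chain) in a constant-pH
ensemble is protonated in a fraction λ of the molecules, where λ follows the
Hill equation for the protonation/deprotonation equilibrium,

    λ(pH) = 1 / (1 + 10^( n · (pH − pKa) )),

with Hill coefficient n = 1 by default (independent single-proton sites;
this is the Henderson–Hasselbalch protonated fraction). λ is assigned once
per ambient pH when the effective parameter set is built and held constant
during sampling — one canonical ensemble per pH value. Sites are treated as
independent; no coupled multi-site titration model is provided.

Each site's pKa is the amino-acid model value (Glu 4.4, Asp 4.0, Lys 10.4,
His 6.5, Cys 9.5) unless an individual override is supplied. Cysteines in
disulfide bridges are never titrated (λ frozen at 1). Histidine carries two
parameters: the λ for deprotonation of the doubly protonated imidazolium,
and a binary tautomer flag choosing whether the neutral endpoint is the ε-
or δ-protonated form (default ε, the more common neutral tautomer in folded
proteins). A second histidine constant, 9.1, is stored alongside the model
pKa as the value associated with the tautomer channel; it does not enter
the default single-transition λ model.

## Individual pKa assignment from ensemble predictions

Per-frame pKa predictions for a residue (e.g. from PROPKAtraj applied to an
existing trajectory) are summarized by their median and population standard
deviation. The assignment rule is:

* threshold = 1 pKa unit, or the prediction standard deviation when that
  exceeds 1 (a broad distribution should not override the model value);
* if |median − model pKa| > threshold, the residue is assigned the median;
  otherwise it keeps the model value.

The replacement value is the median — the same statistic the deviation is
measured with. The population (ddof = 0) standard deviation is used; at
realistic frame counts the distinction from the sample form is immaterial.
The upstream predictor's accuracy constant (RMSD 0.89 pKa units for PROPKA)
is recorded as metadata only.

## The effective force field

Topology is fixed: no protons are created or destroyed, so particle number,
masses and all bonded terms are pH-independent and the kinetic energy
carries no pH dependence. The proton's presence is encoded in the nonbonded
terms only:

* titratable proton: Coulomb and Lennard-Jones pair energies scaled by λ
  (U_elec = λ·k_C·q_i q_j/r, U_LJ = λ·4ε[(σ/r)¹²−(σ/r)⁶]);
* every other atom of the titratable residue: charge interpolated linearly,
  q(λ) = q_prot − (1−λ)·Δq, where Δq is the difference between the
  protonated- and deprotonated-state template charges. Charge differences
  are localized within the residue (residue-template force fields assign
  protonation charge shifts within the residue; no cross-residue bleed).

Scaling is applied at the parameter level so any standard pairwise
evaluator reproduces it: the proton's stored charge is λ·q_prot and its
stored LJ ε is λ²·ε, which under Lorentz–Berthelot combination
(ε_ij = √(ε_i ε_j), σ_ij = (σ_i+σ_j)/2) scales each proton–environment pair
energy by exactly λ. (Two simultaneously titrating protons interact with a
λ_i·λ_j factor, the natural product form.) At λ = 0 the proton remains in
the topology as a zero-charge, zero-ε ghost particle. λ = 0 and λ = 1
short-circuit to the exact template values so the endpoints reproduce the
protonated/deprotonated states bit-for-bit. 1–4 nonbonded pairs are kept at
full strength after scaling; the 1–4 treatment is a property of the
evaluator and can be changed there.

The Coulomb constant is fixed at k_C = 332.0636 kcal·Å/(mol·e²) (CHARMM
convention). Units throughout: Å, kcal/mol, elementary charge, degrees, K.

## Net-charge conservation

Because residue charges move with pH, the solute's net charge drifts by a
non-integer amount. To keep total system charge pH-independent — the
analogue of a wet-lab titration where the bath absorbs the protons — the
excess relative to a target (default: the net charge of the fully
protonated, counterion-balanced build) is spread over the water molecules.
Default mode: a uniform shift on every water oxygen, the minimal per-
molecule perturbation that leaves hydrogen charges standard. An alternative
mode divides the correction over all water atoms. Geometry, solute charges
and water LJ parameters are untouched; the correction is order-independent
in the water list.

## Energy evaluation and sampling

The reference evaluator sums Coulomb + 12-6 LJ over all non-excluded pairs
(1–2 and 1–3 pairs excluded, from connectivity inferred by covalent
distance criteria: < 1.3 Å for X–H, < 1.9 Å for heavy–heavy), with the
CHARMM energy-switching polynomial

    S(r) = (r_c²−r²)²(r_c²+2r²−3r_on²)/(r_c²−r_on²)³,  r_on < r < r_c,

between the switch-on distance (10 Å) and cutoff (12 Å); S is C¹ at both
boundaries. Two implementations exist deliberately: a vectorized
neighbor-listed path (k-d tree) and an explicit O(N²) double loop over the
scalar pair formulas, kept independent so one can validate the other.
Electrostatics are direct-sum (no PME) and there is no pressure coupling —
sufficient for every property assertable at desk scale, which is this
module's purpose.

Sampling uses the BAOAB-splitting Langevin integrator at constant volume
(default dt = 2 fs, T = 310 K, friction 5 ps⁻¹, masses by element), with
forces from the analytic gradient of the switched nonbonded energy plus
optional harmonic restraints (positional anchors, flat-bottom spherical
wall, axis confinement). Runs are bit-reproducible given a seed. Water-bond
constraints are not implemented; toy systems use rigid (frozen) or absent
waters instead.

### Toy titration-curve recovery

The end-to-end validation couples every stage: a one-site toy system is
built, λ assigned, parameters scaled, charge neutralized, and sampled at
each pH of a grid. The construct is a mobile probe bead shuttling along an
axis between two attractor sites of one titratable pseudo-residue whose
template charges make site-A attraction proportional to λ (including a
small λ-scaled charge on the titratable proton itself) and site-B
attraction proportional to 1−λ. The two binding wells are therefore equally
deep at λ = ½, so the per-frame bound fraction (probe within half the
site separation of the site-A anchor) crosses ½ at pH = pKa, and fitting
1/(1+10^(pH−m)) to the bound fractions recovers the input pKa as m. Well
depths are ~2 k_BT at the endpoints, giving many barrier crossings per run.
The probe's well-to-well transition time (tens of ps) is the correlation
time that dominates the statistical error of each bound fraction, so the
default run length is 240 000 steps (480 ps) per pH over pH 2–9 — a few
hundred transitions per run, about 6–7 minutes single-core for the full
grid — with the first 20% of frames discarded as burn-in.

## Trajectory analysis

Operators consume a `TrajectoryEnsemble` (one atom table, stacked frames,
pH label): inter-subunit Cα distances, backbone RMSD after least-squares
(Kabsch) superposition on the same selection, side-chain χ1/χ2 dihedral
2-D histograms (10° bins over (−180°, 180°], standard χ atom quadruples),
hydrogen-bond donor–acceptor distance densities (Gaussian KDE, Scott's
bandwidth, configurable), minimum side-chain heavy-atom distances, and the
retained fraction of native contacts. Native contacts are defined on a
reference structure as heavy-atom pairs from residues ≥ 3 apart in sequence
(or on different chains) within a 5 Å cutoff, counted with a hard step
function — only the cutoff, not a smoothed estimator, is part of the
definition used here; both the sequence-separation rule and the cutoff are
configurable. All operators are invariant under global rotation/translation
of the frames and under frame reordering; constant-valued samples get a
narrow-Gaussian degenerate density so summaries remain well defined.

## Synthetic fixtures and what they do (not) show

All test inputs are generated: idealized titratable peptides (correct
residue net charges — e.g. protonated Glu 0, deprotonated −1 — exact by a
balancing-atom construction; no heavy-atom clashes; the titratable proton
present), lattice TIP3P-like water boxes, two-state trajectories with a
planted inter-chain distance shift plus isotropic Gaussian noise, Gaussian
pKa prediction samples, and the toy titration construct. The charge sets
and geometries are this package's own synthetic templates, not a published
force field, and the fixtures are geometric rather than physical: passing
tests demonstrate the correctness of the scaling algebra, bookkeeping,
estimators and samplers, not the thermodynamic accuracy of any particular
force field or the behavior of a real membrane transporter at microsecond
scale.

## Numerical choices and limitations

* Overlapping non-excluded atoms (r < 1e−6 Å) raise a singular-geometry
  error; non-positive Hill coefficients, distances, or malformed inputs
  raise typed errors rather than propagating NaNs.
* Problem sizes used in validation: 216-water boxes (~670 atoms) for charge
  conservation, ≤ 100-atom random clouds (100 seeded repeats) for the
  evaluator cross-check, 120k-step toy titrations — all chosen as the
  smallest systems that make the corresponding property measurable.
* Known limitations: no PME/reciprocal-space electrostatics, no barostat,
  no SHAKE constraints, no coupled-site titration, no on-the-fly λ updates
  from instantaneous conformational pKas, no mmCIF or binary trajectory
  formats (multi-model PDB is the native trajectory format; DCD/XTC
  adapters are deliberately out of scope).
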