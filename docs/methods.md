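# Methods

This note records the models, conventions and numerical choices behind
`thiopair`, and what the synthetic test surface does and does not establish.

## Backbone frames and the residue-pair transform

Each backbone-complete residue carries an orthonormal frame: origin at CA,
e₁ = unit(CA→N), e₃ = unit(e₁ × CA→C), e₂ = e₃ × e₁.  Any fixed orthonormal
convention would do — the hash only ever compares transforms computed under
the same convention — and this one is cheap and singular only for degenerate
backbones.  `relative_transform(a, b)` re-expresses frame-a coordinates in
frame b (x_b = R x_a + t); it is invariant under global rigid motions by
construction, which is what makes the hash a descriptor of *internal*
geometry.

Transforms are discretized by flooring: translation components at 1.0 Å,
canonical Z-Y-X Euler angles at 15.0°.  Floor (half-open bins) keeps keys
integer-exact; the middle Euler angle is restricted to [−90°, 90°], and
within 10⁻⁶ deg of gimbal lock the third angle is zeroed before binning, so
discretization is total.  The Euler-bin realization is this package's
declared hash function, with the 1.0 Å / 15.0° resolutions as the default
working point.  No neighbour-bin expansion happens at query
time — bin-boundary coverage is the job of the augmentation below.

## Exemplars, augmentation and the database

A disulfide exemplar is the transform between the two bonded residues'
frames plus the four side-chain dihedrals (χ₁, χ₂ of each cysteine).  χ₂
(CA–CB–SG–SG′) is a property of the *pair* — with a two-atom side chain it
orients the partner sulfur, not any atom of its own residue — so pair
construction and measurement treat it as a closure variable.

Mining keeps Cys–Cys pairs with SG–SG ≤ 2.5 Å from structures better than
2.0 Å resolution (synthetic fixtures are exempt), and emits both residue
orderings so the database is direction-insensitive.

Each exemplar is stored once as-is plus `n_perturb` = 100 perturbed copies.
A perturbation jitters the four χ angles and the inter-residue transform by
uniform deltas, rejection-sampled until no reconstructed side-chain heavy
atom (CB/SG, either residue) has moved more than `max_disp` = 5 Å.  Whether
a bound on "side-chain degrees of freedom" should act on the χ angles alone
or also on the inter-residue transform is a genuine design choice; this
package perturbs both, because the augmentation's purpose — populating hash
bins adjacent to each observed geometry — requires the transform to move,
and the displacement bound covers both readings.  Sampling
scales shrink geometrically on rejection, so termination is guaranteed and
the χ deltas vanish as `max_disp` → 0.

Because the unperturbed entry is always stored, self-recall of every source
transform is exact by construction; the tests verify this at the full
162-exemplar × 101-entry setting.

## Side-chain construction and minimization

Side chains are built by internal-to-Cartesian (NeRF) placement from one
ideal-geometry table (`_ideal.py`): CA–CB 1.53 Å, CB–SG 1.81 Å, N-CA-CB
110.5°, CA-CB-SG 114.4°, S–S 2.04 Å, CB-S-S 104.2°, |χ₃| 87°.  The CB
improper (−122.585° for dihedral C-N-CA-CB) was solved so that CB-CA-C is
110.1° with L-chirality, and the constant used to grow a backbone outward
from its side chain is derived numerically from the same table, so forward
construction and measurement invert each other to ~1e-9.

Placement minimization relaxes a hit's rotamers against

    score = (d − 2.04)² + 0.002·[(θ_a − 104.2)² + (θ_b − 104.2)²]
          + (1 − cos(|χ₃| − 87°))

with distances in Å and angles in degrees.  Only χ₁ of each side is an
independent variable (see above); derivative-free coordinate descent with
step halving (start 30°, max 200 sweeps, stop at score < 1e-4 or step <
1e-4°) is monotone by construction and suffices for a smooth 2-D problem.
The angle weight 0.002 makes a 10° angle strain comparable to a 0.14 Å bond
strain — angles are the softest of the three restraints, as befits the
geometry of strained but real disulfides.  A placement is *accepted* when
S–S ∈ [1.8, 2.3] Å, |χ₃| ∈ [60°, 120°] and it has no steric clashes; the
window is this package's declared acceptance criterion, bracketing the
canonical bridge geometry with room for modest strain.

Clash checking reports heavy-atom contacts between placed side-chain atoms
and their environment below a 3.2 Å cutoff, excluding pairs within three
covalent bonds and pairs inside one residue.  Same-residue contacts are
rotamer-internal strain, not environment clashes; with them included, every
gauche/trans rotamer would self-clash through its 1-4/1-5 backbone contacts
(SG···O sits at 3.15 Å), which would make the check vacuous.  Penicillamine
accommodation re-runs the same check with the two β-methyls (CB–CG 1.53 Å,
tetrahedral) present; since the Pen atom set strictly contains the Cys set,
Pen clash counts dominate Cys counts site-for-site.

## Heterodimer design operations

Splitting a scaffold moves no atom: residues are re-assigned to two chains
at the cut point, excised ranges are dropped (refusing any excision that
keeps one partner of a disulfide while deleting the other), and disulfides
spanning the cut simply become interchain.  The optional Gly-Pro β-turn
join is grown with ideal type-II′ turn dihedrals from the upstream strand
and is explicitly approximate — no loop closure is attempted, because
downstream sequence design is outside this package's scope.

Role assignment makes the chain with fewer bonded thiol sites the Pen
carrier (fewest mutations), ties broken toward the shorter chain.

Hairpin facing pairs are classified with a heavy-atom hydrogen-bond
criterion: a pair is HB iff both inter-residue N···O distances are ≤ 3.5 Å
(no hydrogens are modelled anywhere in the package).  Inter-strand disulfide
sites are recommended at exactly the non-HB pairs.

RMSD to an experimental structure is the least-squares superposition RMSD
over the common atom set (residues matched by chain + number or an explicit
mapping, atoms intersected by name); `ensemble_mean_rmsd` averages over the
conformers of an NMR-style ensemble, and a model index selects single
conformers (model 0 = first deposited, the usual lowest-energy convention).

## The combinatorial pairing model

The directed chemistry is abstracted to an ordering of bond-type scores:
w(Cys–Pen) = 2 > w(Cys–Cys) = 1 > w(Pen–Pen) = 0.5 > w(free) = 0.  Only the
ordering is load-bearing — it encodes that the diselenide oxidant's mixed
intermediate is ejected on Cys but stable on Pen, funnelling flux into
Cys–Pen bonds — and the scale is configurable.  States are complete
matchings of the thiol sites (maximum matchings when parity forces free
sites; optionally any matching); a state's topology follows from the
molecule graph with one edge per intermolecular bond.  No kinetics, yields
or selenosulfide species are simulated.

The orthogonality screen flags an ordered (Cys chain i, Pen chain j) pair as
cross-reactive when the foreign Pen chain has at least as many Pen sites as
chain i has Cys sites *and*, when backbones are supplied, the foreign Pen
chain is structurally interchangeable with design i's own Pen partner (equal
length and backbone RMSD < 2.0 Å).  Structural similarity of the two
Pen-bearing chains is the experimentally identified mechanism for the one
observed cross-reaction, which is why the comparison is Pen-chain j against
Pen-chain i rather than against the Cys chain.

Tryptic digestion cleaves C-terminally of Lys/Arg except before Pro;
disulfide-linked fragments merge into species.  Every fragment mass includes
one water (peptides are hydrolysis products), and each S–S bond subtracts
2.015650 Da (two hydrogens); mass bookkeeping is therefore exact:
Σ species = Σ chains − 2.015650·bonds + 18.010565·(fragments − chains).
Residue monoisotopic masses come from the standard table, with penicillamine
as cysteine + 2×CH₂ (residue mass 131.04049 Da).

## Synthetic fixtures: what they emulate, what they do not

* `ideal_helix` / `ideal_strand` grow backbones by NeRF at textbook
  dihedrals (α: −57/−47; β: −139/135) with one ideal-geometry table, so
  every geometric expectation is closed-form (helix rise 1.5 Å, screw
  ~99.4°/residue).
* `ideal_hairpin` builds both strands at ideal β dihedrals and fits strand
  B's rigid placement by least squares to targets: N···O = 2.9 Å both ways
  on the hydrogen-bonded pairs (alternating, HB adjacent to the turn),
  CA–CA 5.3 Å on HB pairs, and converging CBs (CB–CB 4.0 Å, CA–CA 4.4 Å) on
  non-HB pairs so that inter-strand disulfides are geometrically plausible
  there — the defining feature of non-HB pairs in real sheets.  The
  two-residue turn is grown with type-I′ dihedrals and does not exactly
  close onto strand B.
* `exemplar_grid` synthesizes 162 ideal bridges over the canonical rotamer
  wells (χ₁/χ₂ ∈ {−60°, 60°, 180°}, χ₃ ∈ {±87°}) as the fixture-scale
  stand-in for a mined library of observed disulfide geometries.
* `bonded_scaffold` places 1–20 ideal bridges 25 Å apart, restricted to the
  50 of 162 well combinations whose bridge is internally clash-free (the
  remaining 112 put the partner backbones into collision and stay in the
  grid only as hash exemplars).
* `macrocyclizable_chain` grows two β strands outward from an exact
  canonical bridge, so its termini are disulfide-closable by construction;
  its mid-chain join is sequence-level only.
* `heterodimer_design_set` reproduces the screened heterodimers' thiol
  counts and folds (2-Cys helix + 2-Pen strand; 3-Cys + 3-Pen strand pair
  with a Pen strand matching the first design's; two helical pairs of
  different lengths) as synthetic stand-ins for the real designs, whose full
  sequences the package does not ship.

Passing tests on these fixtures establishes the algorithms' contracts —
recall, invariances, exact combinatorics, mass balance — on ideal geometry.
They do not establish recall or precision on crystallographic data, where
resolution noise, non-ideal bond geometry and real rotamer distributions
apply; nor do flat fixture hairpins reproduce the twist of real sheets.

## Known limitations

* The backbone never moves: "minimization" is the restrained side-chain
  relaxation only; no force field, no sequence design.
* Comparisons against deposited NMR structures require those coordinate
  files as user input; the package ships no experimental data.
* The pairing model is thermodynamic bookkeeping over bond-type counts;
  isomer populations, kinetics and yields are out of scope.
* Multi-model structures are handled by selecting one model at a time (or
  averaging RMSDs over models); assemblies and symmetry expansion are not.

## Problem sizes used in the shipped checks

The self-recall and oracle checks run the full 162-exemplar grid at 100
perturbations (16 362 entries); re-derivation runs scaffolds of one to five
bridges with 20 perturbations per exemplar; rigid-motion invariance uses 20
random motions; the mass and hairpin checks use 100 random digest systems
and 20 hairpins (strands of 3–8 residues).  These sizes keep the whole suite
around a minute on one CPU while exercising every code path at full default
parameters where it matters (hash resolutions, perturbation magnitude,
restraint targets and the acceptance window are never scaled down).
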