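# thiopair

Disulfide placement by residue-pair-transform hashing, and design of
disulfide-bridged peptide heterodimers with orthogonal Cys–Pen pairing.

## The problem

Pairs of short peptides can be crosslinked into structurally defined
heterodimers by several interchain disulfide bonds, provided two problems are
solved at once:

1. **Geometry** — where on a backbone can a disulfide actually go?  A bridge
   requires the two residues' backbones to sit in one of the narrow relative
   orientations that cysteine rotamers can span with an S–S bond of ~2.04 Å
   and χ₃ ≈ ±87°.
2. **Connectivity** — once the chains carry several thiols, how do you make
   them pair *across* chains instead of collapsing into intrachain loops or
   mispaired oligomers?  Directed pairing chemistry solves this: under a
   diselenide oxidant, cysteine–penicillamine (Pen, β,β-dimethyl-cysteine)
   bonds form preferentially, because the selenosulfide intermediate is
   ejected rapidly on Cys (intramolecular ring closure) but is stabilized on
   Pen by the two β-methyls.

`thiopair` implements the computational side of this workflow for structural
bioinformaticians and peptide designers:

* **`geometry` / `hashdb` / `stapler`** — the residue-pair-transform (RPX)
  machinery.  Every residue gets an orthonormal backbone frame (origin at CA,
  axes from N and C); the rigid transform between two frames is discretized
  (1.0 Å translation bins, 15.0° Z-Y-X Euler bins) into an integer key.  A
  database of observed disulfide geometries, each augmented with 100 random
  side-chain perturbations bounded by 5 Å of atom displacement, maps keys to
  cysteine rotamers (χ₁/χ₂ of both residues).  Scanning a model is then a
  hash lookup per residue pair; hits are minimized against canonical
  disulfide restraints (S–S 2.04 Å, C–S–S 104.2°, |χ₃| 87°) with the
  backbone fixed, and clash-checked — including whether the bulkier Pen fits.
* **`heterodesign`** — scaffold-to-heterodimer surgery: split a chain while
  keeping its disulfides intact, excise regions, join β-strands with a
  Gly-Pro turn, assign which chain carries Pen, classify β-hairpin facing
  pairs as hydrogen-bonded or not (inter-strand disulfides belong at the
  non-H-bonded pairs), propose terminal macrocyclization disulfides, and
  compare designs with experimental structures (optimal-superposition RMSD,
  including NMR-ensemble means).
* **`pairing`** — an exact combinatorial model of the directed chemistry:
  enumerate all disulfide connectivity states of a peptide mixture, rank
  them with bond-type preference weights (Cys–Pen > Cys–Cys > Pen–Pen >
  free), screen heterodimer sets for mutual orthogonality, and predict
  tryptic-fragment monoisotopic masses for connectivity verification by
  LC–MS.
* **`synthfix`** — deterministic synthetic fixtures (ideal helices, hairpins
  with correct H-bond registers, canonical disulfide exemplar grids), so the
  entire package runs and tests without downloading a single structure.

## Worked example

Generate a fixture scaffold with two known disulfides, build a hash database
from it plus the canonical exemplar grid, and re-discover the bridges:

```sh
$ thiopair fixtures --kind scaffold --n-disulfides 2 --seed 1 --out scaffold.pdb
wrote scaffold.pdb
$ thiopair build-db --in scaffold.pdb --fixture --fixture-grid \
      --n-perturb 100 --seed 3 --out db.bin
db.bin: 166 exemplars, 16766 entries, 16321 keys
$ thiopair scan --db db.bin --in scaffold.pdb
chain_a res_a  chain_b res_b  ss_dist chi1_a chi2_a chi1_b chi2_b chi3  score    n_clashes pen_ok_a pen_ok_b
A       1      A       5      2.040   60.0   -180.0 60.0   -180.0 -87.0 0.00000  0         1        1
A       15     A       11     2.037   -60.1  -60.0  60.0   180.0  87.0  0.00002  0         1        0
```

Both bridges come back with canonical geometry (S–S ≈ 2.04 Å, χ₃ ≈ ±87°,
zero clashes); `pen_ok_a/b` report whether penicillamine is sterically
accommodated at each end.

The combinatorial pairing model, on the two-Cys peptide WGCGKGGGCG mixed with
its two-Pen partner:

```sh
$ thiopair pairings --seq "WGCGKG{3}CG" --seq "WG[Pen]GKG{3}[Pen]G"
3 states (degenerate top)
score 4  heterodimeric  CP=2 CC=0 PP=0 free=0  [0.3-1.3 0.9-1.9]
score 4  heterodimeric  CP=2 CC=0 PP=0 free=0  [0.3-1.9 0.9-1.3]
score 1.5      monomeric  CP=0 CC=1 PP=1 free=0  [0.3-0.9 1.3-1.9]
```

The four thiols admit exactly three perfect matchings.  The two top-ranked
states are the doubly bridged heterodimers (two Cys–Pen bonds each, a
topological degeneracy the score cannot split); the pair of disulfide-cyclic
monomers ranks below — the combinatorial restatement of why the directed
chemistry yields heterodimers as the major product.

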