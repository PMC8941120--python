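"""Deterministic synthetic fixtures: ideal secondary structure, disulfide
exemplar grids and annotated peptide sequences.

Everything the test surface needs is generated here from ideal stereochemistry
(the constants table in ``_ideal``), so no structure ever has to be
downloaded.  All generators are deterministic for a fixed specification.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from . import _ideal
from .geometry import (
    DisulfideExemplar,
    Frame,
    _CB_IMPROPER,
    build_disulfide_pair,
    exemplar_from_pair,
    place_atom,
)
from .structio import Atom, Chain, Residue, Structure

__all__ = [
    "ideal_helix",
    "ideal_hairpin",
    "ideal_strand",
    "exemplar_grid",
    "model_peptide_sequences",
    "bonded_scaffold",
    "build_backbone",
]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def build_backbone(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    chain_id: str = "A",
    start_seqnum: int = 1,
    omega: float = _ideal.OMEGA,
) -> list[Residue]:
    """Grow an N/CA/C/O(/CB) backbone by NeRF from per-residue (phi, psi).

    phi of the first residue and psi of the last are irrelevant to heavy-atom
    positions except for the final carbonyl O, which uses the stated psi.
    CB is added for every non-glycine residue.
    """
    n = len(sequence)
    if len(phi_psi) != n:
        raise ValueError("phi_psi must match sequence length")
    coords: list[dict[str, np.ndarray]] = []
    th = np.radians(_ideal.N_CA_C)
    first = {
        "N": np.array([_ideal.N_CA, 0.0, 0.0]),
        "CA": np.zeros(3),
        "C": _ideal.CA_C * np.array([np.cos(th), np.sin(th), 0.0]),
    }
    coords.append(first)
    for i in range(1, n):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_next = place_atom(
            prev["N"], prev["CA"], prev["C"],
            _ideal.C_N, _ideal.CA_C_N, psi_prev,
        )
        ca_next = place_atom(
            prev["CA"], prev["C"], n_next,
            _ideal.N_CA, _ideal.C_N_CA, omega,
        )
        c_next = place_atom(
            prev["C"], n_next, ca_next,
            _ideal.CA_C, _ideal.N_CA_C, phi_psi[i][0],
        )
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: anti to the next N (dihedral psi + 180)
    for i, res in enumerate(coords):
        psi = phi_psi[i][1]
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"],
            _ideal.C_O, _ideal.CA_C_O, psi + 180.0,
        )
    residues = []
    for i, (aa, res) in enumerate(zip(sequence, coords)):
        resname = _THREE.get(aa)
        if resname is None:
            raise ValueError(f"unknown one-letter code {aa!r}")
        atoms = [
            Atom("N", "N", res["N"]),
            Atom("CA", "C", res["CA"]),
            Atom("C", "C", res["C"]),
            Atom("O", "O", res["O"]),
        ]
        if aa != "G":
            cb = place_atom(
                res["C"], res["N"], res["CA"],
                _ideal.CA_CB, _ideal.N_CA_CB, _CB_IMPROPER,
            )
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(resname=resname, seqnum=start_seqnum + i,
                    chain_id=chain_id, atoms=atoms)
        )
    return residues


def ideal_helix(sequence: str, seed: int = 0, chain_id: str = "A") -> Structure:
    """Ideal alpha-helix (phi = -57, psi = -47, omega = 180)."""
    if len(sequence) < 4:
        raise ValueError("helix needs at least 4 residues")
    residues = build_backbone(
        sequence, [HELIX_PHI_PSI] * len(sequence), chain_id=chain_id
    )
    return Structure(
        chains=[Chain(chain_id, residues)], id=f"helix{len(sequence)}",
        fixture=True,
    )


def ideal_strand(
    sequence: str, chain_id: str = "A", start_seqnum: int = 1
) -> list[Residue]:
    """One extended beta strand (phi = -139, psi = 135)."""
    return build_backbone(
        sequence, [STRAND_PHI_PSI] * len(sequence),
        chain_id=chain_id, start_seqnum=start_seqnum,
    )


def _rigid_apply(residues: list[Residue], rot: np.ndarray, trans: np.ndarray):
    for r in residues:
        for a in r.atoms:
            a.coord = rot @ a.coord + trans


def _pack_transform(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(x[:3]).as_matrix(), x[3:]


def ideal_hairpin(
    strand_a: str,
    strand_b: str,
    turn: str = "NG",
    chain_id: str = "A",
) -> Structure:
    """Antiparallel beta-hairpin with alternating HB / non-HB facing pairs.

    Both strands are ideal beta conformation; strand B is an antiparallel
    rigid copy whose placement is least-squares fitted so that the
    hydrogen-bonded facing pairs (every second pair, starting at the pair
    flanking the turn) have N...O distances at 2.9 A in both directions.
    The two turn residues are appended with type-I' beta-turn dihedrals and
    do not close the loop exactly (no loop-closure optimization).
    """
    n = len(strand_a)
    if len(strand_b) != n:
        raise ValueError("strand lengths must be equal")
    if len(turn) != 2:
        raise ValueError("turn must have exactly 2 residues")
    res_a = ideal_strand(strand_a, chain_id=chain_id, start_seqnum=1)
    # strand B grown with its own sequence, placed rigidly afterwards;
    # built residue k of B faces residue n-k+1 ... i.e. B runs antiparallel
    res_b = ideal_strand(strand_b, chain_id=chain_id, start_seqnum=n + 3)

    # initial guess: 2-fold rotation of strand A about the sheet normal
    # through a point offset ~2.4 A to the H-bond side
    ca = np.array([r.atom("CA").coord for r in res_a])
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    co = np.array(
        [r.atom("O").coord - r.atom("C").coord for r in res_a]
    )
    v = np.zeros(3)
    for i, d in enumerate(co):
        v += d * (1 if i % 2 == 0 else -1)
    v -= np.dot(v, u) * u
    v /= np.linalg.norm(v)
    normal = np.cross(u, v)
    center = ca.mean(axis=0) + 2.4 * v
    # C2 about `normal` through `center`
    from scipy.spatial.transform import Rotation

    c2 = Rotation.from_rotvec(np.pi * normal).as_matrix()

    # facing pairs: A residue i (1-based) faces B chain position n-i+1;
    # B's residue list res_b[k] (k 0-based) faces res_a[n-1-k].
    # HB pairs: every second pair starting with the turn-adjacent one
    # (res_a[n-1] with res_b[0]).
    pairs = [(n - 1 - k, k) for k in range(n)]

    def residuals(x: np.ndarray) -> np.ndarray:
        rot, trans = _pack_transform(x)
        out = []
        for k, (ia, kb) in enumerate(pairs):
            a_ca = res_a[ia].atom("CA").coord
            b_ca = rot @ res_b[kb].atom("CA").coord + trans
            if k % 2 == 0:  # hydrogen-bonded pair
                a_n = res_a[ia].atom("N").coord
                a_o = res_a[ia].atom("O").coord
                b_n = rot @ res_b[kb].atom("N").coord + trans
                b_o = rot @ res_b[kb].atom("O").coord + trans
                out.append(np.linalg.norm(a_n - b_o) - 2.9)
                out.append(np.linalg.norm(b_n - a_o) - 2.9)
                out.append(0.5 * (np.linalg.norm(a_ca - b_ca) - 5.3))
            else:
                # non-HB pairs: CBs converge so that an inter-strand
                # disulfide is geometrically accommodated
                out.append(0.3 * (np.linalg.norm(a_ca - b_ca) - 4.4))
                if res_a[ia].has_atom("CB") and res_b[kb].has_atom("CB"):
                    a_cb = res_a[ia].atom("CB").coord
                    b_cb = rot @ res_b[kb].atom("CB").coord + trans
                    out.append(
                        0.5 * (np.linalg.norm(a_cb - b_cb) - 4.0)
                    )
        return np.asarray(out)

    # seed placements from the C2 construction (axis through the sheet
    # normal, offset half the inter-strand separation to either side);
    # as-built B overlays A, so the C2 of A is a reasonable start for B
    best = None
    for offset in (2.4 * v, -2.4 * v):
        p = ca.mean(axis=0) + offset
        rot0 = c2
        trans0 = p - rot0 @ p
        x0 = np.concatenate(
            [Rotation.from_matrix(rot0).as_rotvec(), trans0]
        )
        fit = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
        if best is None or fit.cost < best.cost:
            best = fit
    rot, trans = _pack_transform(best.x)
    _rigid_apply(res_b, rot, trans)

    # 2-residue turn appended from strand A's end (type I' dihedrals)
    turn_res = build_backbone(
        strand_a[-1] + turn,
        [STRAND_PHI_PSI, (60.0, 30.0), (90.0, 0.0)],
        chain_id=chain_id,
        start_seqnum=n,
    )
    # rigidly align the seed residue onto strand A's last residue
    from .geometry import backbone_frame

    fa = backbone_frame(res_a[-1])
    ft = backbone_frame(turn_res[0])
    rot_t = fa.axes @ ft.axes.T
    trans_t = fa.origin - rot_t @ ft.origin
    _rigid_apply(turn_res, rot_t, trans_t)

    residues = res_a + turn_res[1:] + res_b
    return Structure(
        chains=[Chain(chain_id, residues)],
        id=f"hairpin{n}",
        fixture=True,
    )


def facing_pairs(n: int) -> list[tuple[int, int]]:
    """Seqnum pairs (A-strand residue, B-strand residue) facing each other
    in an ``ideal_hairpin`` with strand length ``n`` (turn residues n+1, n+2)."""
    return [(i, 2 * n + 3 - i) for i in range(1, n + 1)]


# --------------------------------------------------------------------------
# exemplar grid


CHI_WELLS = (-60.0, 60.0, 180.0)
CHI3_WELLS = (-87.0, 87.0)


def exemplar_grid(
    chi1_a_values=CHI_WELLS,
    chi2_a_values=CHI_WELLS,
    chi3_values=CHI3_WELLS,
    chi2_b_values=CHI_WELLS,
    chi1_b_values=CHI_WELLS,
) -> list[DisulfideExemplar]:
    """Synthetic disulfide exemplars over a grid of canonical rotamer wells.

    Stands in, at fixture scale, for a library of disulfide geometries
    observed in high-resolution structures: every exemplar is an ideal
    bridge (S-S 2.04 A, CB-S-S angles 104.2 deg) whose five dihedrals are
    drawn from the canonical chi wells.  The default 3x3x2x3x3 grid yields
    162 exemplars.
    """
    out = []
    for c1a in chi1_a_values:
        for c2a in chi2_a_values:
            for c3 in chi3_values:
                for c2b in chi2_b_values:
                    for c1b in chi1_b_values:
                        ra, rb = build_disulfide_pair(c1a, c2a, c3, c2b, c1b)
                        tag = f"grid:{c1a:g},{c2a:g},{c3:g},{c2b:g},{c1b:g}"
                        out.append(exemplar_from_pair(ra, rb, source=tag))
    return out


def bonded_scaffold(k: int, seed: int = 0) -> Structure:
    """A fixture structure containing ``k`` known disulfides.

    Each bridge is an ideal Cys-Cys pair at grid-well dihedrals, rigidly
    moved to its own location 25 A from the others so bridges do not
    interact; residues within one bridge are 4 positions apart in sequence.
    """
    if not 1 <= k <= 20:
        raise ValueError("k must be in 1..20")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    wells = _clash_free_wells()
    picks = rng.choice(len(wells), size=k, replace=False)
    from scipy.spatial.transform import Rotation

    for i, w in enumerate(picks):
        ra, rb = build_disulfide_pair(
            *wells[w], seqnum_a=10 * i + 1, seqnum_b=10 * i + 5
        )
        rot = Rotation.random(random_state=np.random.default_rng(seed + i + 1)
                              ).as_matrix()
        trans = np.array([25.0 * i, 0.0, 0.0])
        for r in (ra, rb):
            for a in r.atoms:
                a.coord = rot @ a.coord + trans
        residues.extend([ra, rb])
    return Structure(
        chains=[Chain("A", residues)], id=f"scaffold{k}", fixture=True
    )


_WELL_CACHE: list = []


def _clash_free_wells() -> list[tuple[float, float, float, float, float]]:
    """Rotamer-well combinations whose ideal bridge is sterically clean.

    Some grid combinations place the partner backbones on top of each other;
    those are legitimate hash exemplars (placement-time clash checks reject
    them) but unusable as ground-truth bridges in fixtures.
    """
    if _WELL_CACHE:
        return _WELL_CACHE
    from .stapler import Placement, check_clashes

    for c1a in CHI_WELLS:
        for c2a in CHI_WELLS:
            for c3 in CHI3_WELLS:
                for c2b in CHI_WELLS:
                    for c1b in CHI_WELLS:
                        ra, rb = build_disulfide_pair(
                            c1a, c2a, c3, c2b, c1b, seqnum_a=1, seqnum_b=5
                        )
                        s = Structure(chains=[Chain("A", [ra, rb])],
                                      fixture=True)
                        rep = check_clashes(
                            s,
                            Placement(("A", 1), ("A", 5),
                                      (c1a, c2a, c1b, c2b)),
                        )
                        if rep.n_clashes == 0:
                            _WELL_CACHE.append((c1a, c2a, c3, c2b, c1b))
    return _WELL_CACHE


def macrocyclizable_chain(
    k: int = 5,
    chis: tuple[float, float, float, float, float] = (180.0, 180.0, -87.0,
                                                      180.0, -60.0),
    chain_id: str = "A",
) -> Structure:
    """A 2k-residue chain whose termini can close a canonical disulfide.

    The first and last residues' backbones are placed exactly at the
    inter-residue transform of an ideal bridge with the given five dihedrals
    (defaults are canonical rotamer wells, so the transform is covered by
    ``exemplar_grid``); two beta strands are grown outward from them.  The
    mid-chain connection is a sequence-level join only, not a closed loop.
    """
    from .geometry import backbone_frame

    ra, rb = build_disulfide_pair(*chis, seqnum_a=1, seqnum_b=2 * k)

    def align_onto(residues: list[Residue], which: int, target) -> None:
        src = backbone_frame(residues[which])
        rot = target.axes @ src.axes.T
        trans = target.origin - rot @ src.origin
        _rigid_apply(residues, rot, trans)

    strand1 = ideal_strand("A" * k, chain_id=chain_id, start_seqnum=1)
    align_onto(strand1, 0, backbone_frame(ra))
    strand2 = ideal_strand("A" * k, chain_id=chain_id, start_seqnum=k + 1)
    align_onto(strand2, -1, backbone_frame(rb))
    return Structure(
        chains=[Chain(chain_id, strand1 + strand2)],
        id=f"macro{2 * k}",
        fixture=True,
    )


def heterodimer_design_set():
    """Synthetic stand-ins for the four experimentally screened heterodimers.

    The fixture set reproduces the designs' thiol counts and chain folds
    rather than their full sequences: hd1 is
    an alpha-helix with 2 Cys paired to a beta-strand with 2 Pen; hd2 is a
    beta-strand pair with 3 Cys / 3 Pen whose Pen strand matches hd1's Pen
    strand backbone; hd3 and hd4 are helical (coiled-coil-like) pairs of
    different lengths with 2 Cys / 2 Pen each.
    """
    from .pairing import HeterodimerDesign

    def strand_structure(n, chain_id="P"):
        return Structure(
            chains=[Chain(chain_id, ideal_strand("A" * n, chain_id=chain_id))],
            fixture=True,
        )

    return [
        HeterodimerDesign(
            name="hd1",
            cys_sites=(3, 10),
            pen_sites=(2, 7),
            cys_backbone=ideal_helix("A" * 14, chain_id="C"),
            pen_backbone=strand_structure(8),
        ),
        HeterodimerDesign(
            name="hd2",
            cys_sites=(2, 5, 8),
            pen_sites=(2, 5, 8),
            cys_backbone=strand_structure(8, chain_id="C"),
            pen_backbone=strand_structure(8),
        ),
        HeterodimerDesign(
            name="hd3",
            cys_sites=(4, 11),
            pen_sites=(4, 11),
            cys_backbone=ideal_helix("A" * 14, chain_id="C"),
            pen_backbone=ideal_helix("A" * 14, chain_id="P"),
        ),
        HeterodimerDesign(
            name="hd4",
            cys_sites=(5, 13),
            pen_sites=(5, 13),
            cys_backbone=ideal_helix("A" * 18, chain_id="C"),
            pen_backbone=ideal_helix("A" * 18, chain_id="P"),
        ),
    ]


# --------------------------------------------------------------------------
# model peptide sequences


def model_peptide_sequences() -> dict[str, str]:
    """The four model peptide sequences, in the package's sequence grammar.

    Peptides 1 and 4 carry only Cys; 2 only Pen; 3 mixes three Cys with one
    Pen.  ``{n}`` expands the preceding residue to n copies and ``[Pen]`` is
    penicillamine.
    """
    return {
        "peptide1": "WGCGKG{3}CG",
        "peptide2": "WG[Pen]GKG{3}[Pen]G",
        "peptide3": "WGCG{2}KG{2}CGKG{3}[Pen]GKG{3}CGW",
        "peptide4": "WGCG{2}KG{2}CGKG{3}CGKG{3}CGW",
    }
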