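"""Scaffold-to-heterodimer design operations.

A disulfide-rich single-chain scaffold becomes a two-chain heterodimer by
severing the chain at a cut point, excising superfluous regions, and joining
remaining beta-strands with a Gly-Pro turn motif; the existing disulfides
must survive the surgery (they become interchain bonds).  The synthetic
chemistry then dictates thiol roles: all bonded thiols on one chain become
penicillamine, the partner chain keeps cysteine.  Inter-strand disulfides on
beta-hairpins belong at non-hydrogen-bonded facing pairs, and a terminal
macrocyclization disulfide can be proposed from the hash database.
``rmsd_to_model`` compares designs with experimental (e.g. NMR) structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import backbone_frame
from .hashdb import HashDatabase
from .stapler import (
    MinimizeParams,
    Placement,
    check_clashes,
    minimize_disulfide,
    scan_structure,
)
from .structio import Chain, Residue, Structure

__all__ = [
    "SplitPlan",
    "RoleAssignment",
    "split_scaffold",
    "assign_roles",
    "classify_hairpin_pairs",
    "recommended_disulfide_sites",
    "propose_macrocycle_disulfide",
    "rmsd_to_model",
    "ensemble_mean_rmsd",
    "find_disulfide_bridges",
]

Site = tuple[str, int]

# N...O heavy-atom distance treated as a backbone hydrogen bond
HBOND_NO_CUTOFF = 3.5


@dataclass(frozen=True)
class SplitPlan:
    """How to sever and trim a scaffold chain.

    ``cut_point``: last residue kept on the first product chain.
    ``remove_ranges``: inclusive (chain, start, end) residue ranges to excise.
    ``join``: optionally bridge two residues left adjacent after excision
    with a beta-turn motif (default Gly-Pro).
    """

    cut_point: Site
    remove_ranges: list[tuple[str, int, int]] = field(default_factory=list)
    join: tuple[int, int, str] | None = None  # (a_end, b_start, motif)

    def __post_init__(self) -> None:
        spans = sorted(
            (c, lo, hi) for c, lo, hi in self.remove_ranges
        )
        for (c1, lo1, hi1), (c2, lo2, hi2) in zip(spans, spans[1:]):
            if c1 == c2 and lo2 <= hi1:
                raise ValueError("remove_ranges overlap")
        for c, lo, hi in spans:
            if lo > hi:
                raise ValueError(f"invalid range {c}:{lo}-{hi}")
            if c == self.cut_point[0] and lo <= self.cut_point[1] <= hi:
                raise ValueError("cut_point lies inside a removed range")


@dataclass(frozen=True)
class RoleAssignment:
    cys_chain: str
    pen_chain: str
    interchain_bonds: tuple  # ((cys_site, pen_site), ...)
    intrachain_bonds: tuple = ()


def find_disulfide_bridges(s: Structure, cutoff: float = 2.5) -> list[tuple[Site, Site]]:
    """All thiol pairs with SG-SG distance within ``cutoff``."""
    thiols = [
        r for r in s.residues()
        if r.resname in ("CYS", "PEN") and r.has_atom("SG")
    ]
    out = []
    for i, ra in enumerate(thiols):
        for rb in thiols[i + 1:]:
            d = np.linalg.norm(ra.atom("SG").coord - rb.atom("SG").coord)
            if d <= cutoff:
                out.append(
                    ((ra.chain_id, ra.seqnum), (rb.chain_id, rb.seqnum))
                )
    return out


def _in_ranges(site: Site, ranges) -> bool:
    return any(
        site[0] == c and lo <= site[1] <= hi for c, lo, hi in ranges
    )


def split_scaffold(s: Structure, plan: SplitPlan) -> Structure:
    """Sever a chain into two, excise ranges, optionally insert a turn motif.

    No kept atom moves, so disulfides spanning the cut stay geometrically
    intact and become interchain.  A removal that keeps one partner of a
    disulfide while excising the other is refused with the bond named.
    """
    chain_id, cut_seq = plan.cut_point
    chain = s.chain(chain_id)

    bridges = find_disulfide_bridges(s)
    for a, b in bridges:
        ra, rb = _in_ranges(a, plan.remove_ranges), _in_ranges(b, plan.remove_ranges)
        if ra != rb:
            kept, gone = (a, b) if rb else (b, a)
            raise ValueError(
                f"removal would destroy disulfide {a[0]}:{a[1]}-{b[0]}:{b[1]} "
                f"(partner {gone[0]}:{gone[1]} excised, {kept[0]}:{kept[1]} kept)"
            )

    new_ids = _fresh_chain_ids(s, chain_id)
    first, second = [], []
    for res in chain.residues:
        if _in_ranges((chain_id, res.seqnum), plan.remove_ranges):
            continue
        target = first if res.seqnum <= cut_seq else second
        target.append(
            Residue(res.resname, res.seqnum, "", [
                a for a in res.atoms
            ])
        )
    if not first or not second:
        raise ValueError("cut point leaves an empty chain")

    chains = []
    for cid, residues in zip(new_ids, (first, second)):
        for r in residues:
            r.chain_id = cid
        chains.append(Chain(cid, residues))

    out = Structure(
        chains=[c for c in s.chains if c.chain_id != chain_id] + chains,
        id=s.id + "_split",
        resolution=s.resolution,
        fixture=s.fixture,
    )
    if plan.join is not None:
        a_end, b_start, motif = plan.join
        _insert_turn_motif(out, a_end, b_start, motif)
    return out


def _fresh_chain_ids(s: Structure, removed: str) -> tuple[str, str]:
    used = {c.chain_id for c in s.chains} - {removed}
    ids = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if c not in used]
    return ids[0], ids[1]


# ideal type-II' beta-turn dihedrals for the two inserted motif residues
_TURN_PHI_PSI = [(60.0, -120.0), (-80.0, 0.0)]

_ONE = {"G": "GLY", "P": "PRO", "N": "ASN", "D": "ASP", "A": "ALA"}


def _insert_turn_motif(s: Structure, a_end: int, b_start: int, motif: str) -> None:
    """Append motif residues after ``a_end``, with ideal turn dihedrals.

    The motif backbone is grown from the a_end residue by NeRF and is
    approximate: it does not close the loop onto ``b_start`` (no loop-closure
    optimization).  Residues are numbered a_end+1, ...; downstream residues
    are renumbered upward if the numbering would collide.
    """
    from .synthfix import STRAND_PHI_PSI, build_backbone

    chain = None
    for c in s.chains:
        seqs = {r.seqnum for r in c.residues}
        if a_end in seqs and b_start in seqs:
            chain = c
            break
    if chain is None:
        raise ValueError(
            f"join endpoints {a_end}, {b_start} not on one product chain"
        )
    if len(motif) != len(_TURN_PHI_PSI):
        raise ValueError("turn motif must have exactly 2 residues")

    anchor = chain.residue(a_end)
    seed_seq = "A" + "".join(motif)
    grown = build_backbone(
        seed_seq,
        [STRAND_PHI_PSI] + _TURN_PHI_PSI,
        chain_id=chain.chain_id,
        start_seqnum=a_end,
    )
    # align the seed residue's backbone onto the anchor
    fa = backbone_frame(anchor)
    ft = backbone_frame(grown[0])
    rot = fa.axes @ ft.axes.T
    trans = fa.origin - rot @ ft.origin
    for r in grown[1:]:
        for a in r.atoms:
            a.coord = rot @ a.coord + trans

    n_insert = len(motif)
    if b_start - a_end - 1 < n_insert:
        shift = n_insert - (b_start - a_end - 1)
        for r in chain.residues:
            if r.seqnum >= b_start:
                r.seqnum += shift
    for r, name in zip(grown[1:], motif):
        r.resname = _ONE.get(name, name)
    idx = chain.residues.index(anchor) + 1
    chain.residues[idx:idx] = grown[1:]


def assign_roles(s: Structure, interchain_bonds) -> RoleAssignment:
    """Designate one chain as the penicillamine carrier.

    Every bond must be interchain between the same two chains; the chain
    touching fewer bonded thiol sites takes the Pen role (fewest mutations),
    ties broken toward the shorter chain.
    """
    chains_seen: dict[str, set[int]] = {}
    for a, b in interchain_bonds:
        if a[0] == b[0]:
            raise ValueError(
                f"bond {a}-{b} is intrachain; only interchain bonds get roles"
            )
        chains_seen.setdefault(a[0], set()).add(a[1])
        chains_seen.setdefault(b[0], set()).add(b[1])
    if len(chains_seen) != 2:
        raise ValueError("bonds must connect exactly two chains")
    (c1, sites1), (c2, sites2) = sorted(chains_seen.items())
    n1, n2 = len(s.chain(c1)), len(s.chain(c2))
    if (len(sites1), n1) <= (len(sites2), n2):
        pen_chain, cys_chain = c1, c2
    else:
        pen_chain, cys_chain = c2, c1
    bonds = tuple(
        (a, b) if a[0] == cys_chain else (b, a) for a, b in interchain_bonds
    )
    return RoleAssignment(
        cys_chain=cys_chain, pen_chain=pen_chain, interchain_bonds=bonds
    )


# --------------------------------------------------------------------------
# beta-hairpin pair classification


def classify_hairpin_pairs(
    s: Structure,
    strand_a: tuple[str, int, int],
    strand_b: tuple[str, int, int],
) -> list[tuple[tuple[Site, Site], str]]:
    """Label facing cross-strand pairs of an antiparallel pair of strands.

    A facing pair is HB when both backbone N...O distances between the two
    residues are within 3.5 A (heavy-atom criterion, no hydrogens), non-HB
    otherwise.  Strands must be antiparallel and in register.
    """
    ca_id, a_lo, a_hi = strand_a
    cb_id, b_lo, b_hi = strand_b
    res_a = [s.chain(ca_id).residue(i) for i in range(a_lo, a_hi + 1)]
    res_b = [s.chain(cb_id).residue(i) for i in range(b_lo, b_hi + 1)]
    if len(res_a) != len(res_b):
        raise ValueError("strand ranges differ in length (register mismatch)")
    da = res_a[-1].atom("CA").coord - res_a[0].atom("CA").coord
    db_ = res_b[-1].atom("CA").coord - res_b[0].atom("CA").coord
    if float(np.dot(da, db_)) >= 0:
        raise ValueError("strands are not antiparallel")
    pairs = list(zip(res_a, reversed(res_b)))
    caca = [
        float(np.linalg.norm(x.atom("CA").coord - y.atom("CA").coord))
        for x, y in pairs
    ]
    if np.mean(caca) > 7.0:
        raise ValueError("strand ranges are not facing (register mismatch > 1)")
    out = []
    for x, y in pairs:
        hb = (
            np.linalg.norm(x.atom("N").coord - y.atom("O").coord)
            <= HBOND_NO_CUTOFF
            and np.linalg.norm(y.atom("N").coord - x.atom("O").coord)
            <= HBOND_NO_CUTOFF
        )
        out.append(
            (
                ((x.chain_id, x.seqnum), (y.chain_id, y.seqnum)),
                "HB" if hb else "non-HB",
            )
        )
    return out


def recommended_disulfide_sites(
    s: Structure,
    strand_a: tuple[str, int, int],
    strand_b: tuple[str, int, int],
) -> list[tuple[Site, Site]]:
    """Inter-strand disulfide sites: exactly the non-hydrogen-bonded pairs."""
    return [
        pair
        for pair, label in classify_hairpin_pairs(s, strand_a, strand_b)
        if label == "non-HB"
    ]


# --------------------------------------------------------------------------
# macrocyclization


def propose_macrocycle_disulfide(
    s: Structure,
    chain_id: str,
    db: HashDatabase,
    terminal_window: int = 3,
    clash_cutoff: float = 3.2,
    params: MinimizeParams = MinimizeParams(),
) -> list[Placement]:
    """Terminal disulfides closing a chain into a macrocycle.

    Scans only pairs with one residue within ``terminal_window`` of the
    N-terminus and the other within ``terminal_window`` of the C-terminus,
    then minimizes, clash-checks and ranks; may be empty.
    """
    chain = s.chain(chain_id)
    if len(chain) < 6:
        raise ValueError("macrocyclization needs at least 6 residues")
    n_term = {r.seqnum for r in chain.residues[:terminal_window]}
    c_term = {r.seqnum for r in chain.residues[-terminal_window:]}
    hits = scan_structure(s, db, min_seq_sep=1)
    best: dict[frozenset, Placement] = {}
    for cand in hits:
        sites = (cand.res_a, cand.res_b)
        if not all(site[0] == chain_id for site in sites):
            continue
        seqs = {site[1] for site in sites}
        if not (seqs & n_term and seqs & c_term):
            continue
        m = minimize_disulfide(s, cand, params)
        from dataclasses import replace

        m = replace(m, clash=check_clashes(s, m, cutoff=clash_cutoff))
        if not m.is_valid():
            continue
        cur = best.get(m.pair)
        if cur is None or m.score < cur.score:
            best[m.pair] = m
    return sorted(best.values(), key=lambda p: p.score)


# --------------------------------------------------------------------------
# comparison with experimental structures


_BACKBONE_SET = ("N", "CA", "C", "O")


def _common_coords(
    design: Structure,
    experimental: Structure,
    mode: str,
    mapping: dict[Site, Site] | None,
) -> tuple[np.ndarray, np.ndarray]:
    exp_res = {(r.chain_id, r.seqnum): r for r in experimental.residues()}
    xs, ys = [], []
    for r in design.residues():
        site = (r.chain_id, r.seqnum)
        target = mapping.get(site) if mapping is not None else site
        if target is None or target not in exp_res:
            continue
        other = exp_res[target]
        names = [a.name for a in r.atoms]
        if mode == "backbone":
            names = [n for n in names if n in _BACKBONE_SET]
        for name in names:
            if other.has_atom(name):
                xs.append(r.atom(name).coord)
                ys.append(other.atom(name).coord)
    if not xs:
        raise ValueError("no common atoms between the two structures")
    return np.asarray(xs), np.asarray(ys)


def rmsd_to_model(
    design: Structure,
    experimental: Structure,
    mode: str = "all_heavy",
    mapping: dict[Site, Site] | None = None,
) -> float:
    """Least-squares superposition RMSD over the common atom set (Angstrom).

    Residues correspond by chain + seqnum unless an explicit ``mapping``
    (design site -> experimental site) is given; atom sets are intersected
    by name.  ``mode`` is ``all_heavy`` or ``backbone`` (N/CA/C/O).
    Symmetric in its arguments and invariant to rigid motions of either.
    """
    if mode not in ("all_heavy", "backbone"):
        raise ValueError(f"unknown mode {mode!r}")
    xs, ys = _common_coords(design, experimental, mode, mapping)
    xs = xs - xs.mean(axis=0)
    ys = ys - ys.mean(axis=0)
    _, rssd = Rotation.align_vectors(xs, ys)
    return float(rssd / np.sqrt(len(xs)))


def ensemble_mean_rmsd(
    design: Structure,
    models: list[Structure],
    mode: str = "all_heavy",
    mapping: dict[Site, Site] | None = None,
) -> float:
    """Mean superposition RMSD of a design against each conformer of an ensemble."""
    if not models:
        raise ValueError("empty ensemble")
    return float(
        np.mean([rmsd_to_model(design, m, mode, mapping) for m in models])
    )
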