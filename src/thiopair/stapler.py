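"""Disulfide placement: scan, minimize, clash-check, apply.

``scan_structure`` hashes every candidate residue-pair transform of a model
against a :class:`~thiopair.hashdb.HashDatabase` and turns each hit into a
:class:`Placement`.  ``minimize_disulfide`` then relaxes the placed side
chains against canonical disulfide restraints (S-S 2.04 A, CB-S-S 104.2 deg,
|chi3| 87 deg) with the backbone fixed, and ``check_clashes`` /
``check_pen_accommodation`` report steric feasibility, including whether the
bulkier penicillamine (two beta-methyls at CB) fits at a site.

A placement is accepted when, after minimization, its geometry falls in the
validity window ``ss_dist`` in [1.8, 2.3] A, ``|chi3|`` in [60, 120] deg,
with zero clashes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _ideal
from .geometry import (
    DisulfideGeometry,
    backbone_frame,
    dihedral,
    bond_angle,
    place_cys_sidechain,
    relative_transform,
    wrap_angle,
)
from .hashdb import HashDatabase, query
from .structio import Residue, Structure

__all__ = [
    "Placement",
    "ClashReport",
    "MinimizeParams",
    "VALIDITY_SS_RANGE",
    "VALIDITY_CHI3_RANGE",
    "scan_structure",
    "minimize_disulfide",
    "check_clashes",
    "check_pen_accommodation",
    "apply_placement",
    "find_disulfides",
]

VALIDITY_SS_RANGE = (1.8, 2.3)
VALIDITY_CHI3_RANGE = (60.0, 120.0)

Site = tuple[str, int]  # (chain_id, seqnum)


@dataclass(frozen=True)
class ClashReport:
    n_clashes: int
    worst_overlap: float
    contacts: tuple = ()


@dataclass(frozen=True)
class Placement:
    """One candidate disulfide: residue pair, rotamers and diagnostics."""

    res_a: Site
    res_b: Site
    rotamers: tuple[float, float, float, float]  # chi1_a, chi2_a, chi1_b, chi2_b
    geometry: DisulfideGeometry | None = None
    clash: ClashReport | None = None
    score: float | None = None
    pen_site: str = "none"  # none | a | b
    converged: bool = True
    source: str = ""

    @property
    def pair(self) -> frozenset:
        return frozenset((self.res_a, self.res_b))

    def is_valid(self) -> bool:
        g = self.geometry
        return (
            g is not None
            and VALIDITY_SS_RANGE[0] <= g.ss_dist <= VALIDITY_SS_RANGE[1]
            and VALIDITY_CHI3_RANGE[0] <= abs(g.chi3) <= VALIDITY_CHI3_RANGE[1]
            and (self.clash is None or self.clash.n_clashes == 0)
        )


@dataclass(frozen=True)
class MinimizeParams:
    w_dist: float = 1.0
    w_angle: float = 0.002      # per squared degree of CB-S-S deviation
    w_torsion: float = 1.0
    max_iter: int = 200
    tol: float = 1e-4
    step0: float = 30.0         # initial chi step, degrees
    min_step: float = 1e-4


def _lookup(s: Structure, site: Site) -> Residue:
    return s.chain(site[0]).residue(site[1])


def scan_structure(
    s: Structure,
    db: HashDatabase,
    min_seq_sep: int = 3,
    interchain_only: bool = False,
) -> list[Placement]:
    """Hash every candidate residue-pair transform against the database.

    Ordered pairs are scanned (the database stores both orderings of each
    exemplar): intrachain pairs need sequence separation >= ``min_seq_sep``;
    all interchain pairs are eligible, and only those when
    ``interchain_only``.  Each payload returned by the hash lookup becomes
    one pre-minimization Placement.  Backbone-incomplete residues are
    skipped with a warning.
    """
    residues = []
    for res in s.residues():
        if not res.backbone_complete:
            warnings.warn(
                f"skipping backbone-incomplete residue "
                f"{res.chain_id}:{res.seqnum}",
                stacklevel=2,
            )
            continue
        residues.append(res)
    frames = {(r.chain_id, r.seqnum): backbone_frame(r) for r in residues}
    # candidate pruning: no stored transform can match when the CA-CA
    # distance exceeds the largest stored translation bin
    max_t = 0.0
    for key in db.table:
        hi = (np.abs(np.asarray(key[:3], dtype=float)) + 1.0) * db.config.cart_res
        max_t = max(max_t, float(np.linalg.norm(hi)))
    out: list[Placement] = []
    for ra in residues:
        fa = frames[(ra.chain_id, ra.seqnum)]
        for rb in residues:
            if ra is rb:
                continue
            if ra.chain_id == rb.chain_id:
                if interchain_only:
                    continue
                if abs(ra.seqnum - rb.seqnum) < min_seq_sep:
                    continue
            fb = frames[(rb.chain_id, rb.seqnum)]
            if np.linalg.norm(fa.origin - fb.origin) > max_t:
                continue
            for payload in query(db, relative_transform(fa, fb)):
                out.append(
                    Placement(
                        res_a=(ra.chain_id, ra.seqnum),
                        res_b=(rb.chain_id, rb.seqnum),
                        rotamers=payload.chis,
                        source=payload.source,
                    )
                )
    return out


# --------------------------------------------------------------------------
# restrained minimization


def _bridge_geometry(
    res_a: Residue, res_b: Residue, chi1_a: float, chi1_b: float
) -> DisulfideGeometry:
    """Geometry of the bridge with SG positions rebuilt from chi1 on each side.

    With a two-atom (CB-SG) side chain the only free dihedrals are the two
    chi1; each chi2 (CA-CB-SG-SG') is determined by ring closure and is
    measured, not set.
    """
    a = place_cys_sidechain(res_a, chi1_a)
    b = place_cys_sidechain(res_b, chi1_b)
    na, caa, cba, sga = (a.atom(x).coord for x in ("N", "CA", "CB", "SG"))
    nb, cab, cbb, sgb = (b.atom(x).coord for x in ("N", "CA", "CB", "SG"))
    return DisulfideGeometry(
        ss_dist=float(np.linalg.norm(sga - sgb)),
        chi1_a=chi1_a,
        chi2_a=dihedral(caa, cba, sga, sgb),
        chi1_b=chi1_b,
        chi2_b=dihedral(cab, cbb, sgb, sga),
        chi3=dihedral(cba, sga, sgb, cbb),
        angle_a=bond_angle(cba, sga, sgb),
        angle_b=bond_angle(sga, sgb, cbb),
    )


def restraint_score(g: DisulfideGeometry, p: MinimizeParams = MinimizeParams()) -> float:
    """Deviation of a bridge from canonical disulfide geometry.

    score = w_dist (d - 2.04)^2
          + w_angle [(angle_a - 104.2)^2 + (angle_b - 104.2)^2]
          + w_torsion (1 - cos(|chi3| - 87 deg))

    Zero exactly at the canonical geometry; each term is smooth and bounded
    below by zero.
    """
    d = (g.ss_dist - _ideal.SS_BOND) ** 2 * p.w_dist
    a = (
        (g.angle_a - _ideal.CB_S_S) ** 2 + (g.angle_b - _ideal.CB_S_S) ** 2
    ) * p.w_angle
    t = (1.0 - np.cos(np.radians(abs(g.chi3) - _ideal.CHI3_CANONICAL))) * p.w_torsion
    return float(d + a + t)


def minimize_disulfide(
    s: Structure, p: Placement, params: MinimizeParams = MinimizeParams()
) -> Placement:
    """Locally optimize the placed side chains against the disulfide restraints.

    Derivative-free coordinate descent over (chi1_a, chi1_b) with step
    halving; the backbone never moves and the score is non-increasing by
    construction.  Non-convergence within ``params.max_iter`` sweeps returns
    the best placement found with ``converged=False``.
    """
    res_a = _lookup(s, p.res_a)
    res_b = _lookup(s, p.res_b)
    chis = [p.rotamers[0], p.rotamers[2]]
    geo = _bridge_geometry(res_a, res_b, *chis)
    score = restraint_score(geo, params)
    step = params.step0
    converged = False
    for _ in range(params.max_iter):
        if score < params.tol:
            converged = True
            break
        improved = False
        for i in (0, 1):
            for delta in (step, -step):
                trial = list(chis)
                trial[i] = wrap_angle(trial[i] + delta)
                tg = _bridge_geometry(res_a, res_b, *trial)
                ts = restraint_score(tg, params)
                if ts < score - 1e-15:
                    chis, geo, score = trial, tg, ts
                    improved = True
        if not improved:
            step *= 0.5
            if step < params.min_step:
                converged = True
                break
    return replace(
        p,
        rotamers=(geo.chi1_a, geo.chi2_a, geo.chi1_b, geo.chi2_b),
        geometry=geo,
        score=score,
        converged=converged,
    )


# --------------------------------------------------------------------------
# clash checking


_RESIDUE_BONDS = [
    ("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
    ("CB", "SG"), ("CB", "CG1"), ("CB", "CG2"), ("CB", "CG"),
    ("CB", "OG"), ("CB", "OG1"), ("CB", "SG1"),
]


def _bond_graph(s: Structure, extra_bonds=()) -> dict:
    """Adjacency over (chain, seqnum, atom name) covering residue-internal
    bonds, peptide bonds, and any extra (e.g. the placed S-S bond)."""
    adj: dict[tuple, set] = {}

    def link(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    for chain in s.chains:
        prev = None
        for res in chain.residues:
            names = {a.name for a in res.atoms}
            for u, v in _RESIDUE_BONDS:
                if u in names and v in names:
                    link((chain.chain_id, res.seqnum, u),
                         (chain.chain_id, res.seqnum, v))
            if (
                prev is not None
                and prev.has_atom("C")
                and res.has_atom("N")
                and np.linalg.norm(
                    prev.atom("C").coord - res.atom("N").coord
                ) < 2.0
            ):
                link((chain.chain_id, prev.seqnum, "C"),
                     (chain.chain_id, res.seqnum, "N"))
            prev = res
    for u, v in extra_bonds:
        link(u, v)
    return adj


def _within_bonds(adj: dict, u, v, nmax: int) -> bool:
    if u == v:
        return True
    seen = {u}
    frontier = {u}
    for _ in range(nmax):
        nxt = set()
        for w in frontier:
            nxt |= adj.get(w, set())
        if v in nxt:
            return True
        nxt -= seen
        seen |= nxt
        frontier = nxt
        if not frontier:
            break
    return False


# atom pairs closer than the cutoff but separated by more than this many
# covalent bonds count as clashes (1-4 and closer pairs are excluded);
# contacts inside one residue are rotamer-internal strain, not clashes,
# and are excluded altogether
_BOND_EXCLUSION = 3


def check_clashes(
    s: Structure, p: Placement, cutoff: float = 3.2
) -> ClashReport:
    """Steric contacts of the placed side-chain atoms against the environment.

    Heavy-atom pairs between the placement's side-chain atoms (CB, SG and any
    Pen methyls on both residues) and all other atoms closer than ``cutoff``
    are reported, excluding same-residue pairs and pairs within
    ``_BOND_EXCLUSION`` covalent bonds (the placed S-S bond is part of the
    bond graph).
    """
    applied = apply_placement(s, p)
    adj = _bond_graph(
        applied,
        extra_bonds=[((*p.res_a, "SG"), (*p.res_b, "SG"))],
    )
    sidechain_names = ("CB", "SG", "CG1", "CG2")
    placed: list[tuple] = []
    for site in (p.res_a, p.res_b):
        res = _lookup(applied, site)
        for a in res.atoms:
            if a.name in sidechain_names:
                placed.append(((*site, a.name), a.coord))
    contacts = []
    for chain in applied.chains:
        for res in chain.residues:
            for a in res.atoms:
                key = (chain.chain_id, res.seqnum, a.name)
                for pkey, pcoord in placed:
                    if key[:2] == pkey[:2]:
                        continue  # same residue
                    d = float(np.linalg.norm(a.coord - pcoord))
                    if d >= cutoff:
                        continue
                    if _within_bonds(adj, key, pkey, _BOND_EXCLUSION):
                        continue
                    pair = tuple(sorted((key, pkey)))
                    contacts.append((pair, d))
    # deduplicate (both atoms may be side-chain atoms)
    uniq = {}
    for pair, d in contacts:
        uniq[pair] = d
    contacts = sorted(uniq.items(), key=lambda kv: kv[1])
    worst = max((cutoff - d for _, d in contacts), default=0.0)
    return ClashReport(
        n_clashes=len(contacts), worst_overlap=worst,
        contacts=tuple(contacts),
    )


def check_pen_accommodation(
    s: Structure, p: Placement, site: str, cutoff: float = 3.2
) -> ClashReport:
    """Clash report with the chosen residue rebuilt as penicillamine.

    ``site`` is ``"a"`` or ``"b"``.  The residue gains the two beta-methyl
    carbons; accommodation holds when the report shows zero clashes.
    """
    if site not in ("a", "b"):
        raise ValueError("site must be 'a' or 'b'")
    return check_clashes(s, replace(p, pen_site=site), cutoff=cutoff)


def apply_placement(s: Structure, p: Placement) -> Structure:
    """Return a new Structure with the placement's residues mutated.

    Both residues become CYS (or PEN per ``pen_site``) with side chains at
    the placement's chi1 rotamers; the input structure is untouched.  The
    bridge is recorded in ``Structure.ssbonds``.
    """
    out = s.copy()
    for site, chi1, tag in (
        (p.res_a, p.rotamers[0], "a"),
        (p.res_b, p.rotamers[2], "b"),
    ):
        chain = out.chain(site[0])
        try:
            res = chain.residue(site[1])
        except KeyError:
            raise KeyError(f"residue {site[0]}:{site[1]} not in structure")
        rebuilt = place_cys_sidechain(res, chi1, as_pen=(p.pen_site == tag))
        chain.residues[chain.residues.index(res)] = rebuilt
    out.ssbonds.append((p.res_a, p.res_b))
    return out


# --------------------------------------------------------------------------
# pipeline


def find_disulfides(
    s: Structure,
    db: HashDatabase,
    min_seq_sep: int = 3,
    interchain_only: bool = False,
    clash_cutoff: float = 3.2,
    params: MinimizeParams = MinimizeParams(),
) -> list[Placement]:
    """Scan, minimize, clash-check and deduplicate; returns valid placements.

    Placements for the same unordered residue pair are deduplicated after
    minimization: within a 1e-2 score tie the lowest chi1_a wins.  The result
    is sorted by score (best first).
    """
    candidates = scan_structure(
        s, db, min_seq_sep=min_seq_sep, interchain_only=interchain_only
    )
    by_pair: dict[frozenset, Placement] = {}
    for cand in candidates:
        m = minimize_disulfide(s, cand, params)
        m = replace(m, clash=check_clashes(s, m, cutoff=clash_cutoff))
        if not m.is_valid():
            continue
        cur = by_pair.get(m.pair)
        if (
            cur is None
            or m.score < cur.score - 1e-2
            or (abs(m.score - cur.score) <= 1e-2
                and m.rotamers[0] < cur.rotamers[0])
        ):
            by_pair[m.pair] = m
    return sorted(by_pair.values(), key=lambda q: q.score)
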