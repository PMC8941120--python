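"""Combinatorial model of Cys/Pen disulfide pairing.

Under a diselenide oxidant, thiol-diselenide exchange is fast and reversible
on cysteine (the selenosulfide intermediate is ejected by intramolecular ring
closure) but slow on penicillamine, whose two beta-methyls shield the sulfur
and stabilize the mixed intermediate.  The net kinetic effect is an ordering
of bond-type preferences, Cys-Pen > Cys-Cys > Pen-Pen > free thiol, which
this module encodes as configurable weights over complete pairing states
(matchings of the thiol sites).  The enumeration, ranking, cross-reactivity
screen and tryptic-fragment mass bookkeeping are exact and combinatorial; no
kinetics or yields are simulated.

Sequence grammar: one-letter amino-acid codes, ``[Pen]`` for penicillamine,
``{n}`` expanding the preceding residue to n copies ("G{3}" -> "GGG").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from pyteomics import mass as _pmass

from .heterodesign import rmsd_to_model
from .structio import Structure

__all__ = [
    "ThiolSite",
    "PairingState",
    "PreferenceWeights",
    "HeterodimerDesign",
    "parse_sequence",
    "parse_thiol_sequence",
    "enumerate_pairing_states",
    "rank_states",
    "orthogonality_screen",
    "tryptic_fragments",
    "monoisotopic_mass",
    "WATER",
    "DISULFIDE_LOSS",
]

WATER = 18.0105646863
DISULFIDE_LOSS = 2.0156500638  # two hydrogens per S-S bond

# residue monoisotopic masses from the standard table; penicillamine is
# cysteine plus two methylene equivalents
_PEN_RESIDUE_MASS = _pmass.std_aa_mass["C"] + 2 * 14.0156500642


@dataclass(frozen=True)
class ThiolSite:
    molecule: int
    position: int            # 1-based residue index within the molecule
    kind: str                # CYS | PEN
    chain_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("CYS", "PEN"):
            raise ValueError(f"invalid thiol kind {self.kind!r}")


SitePair = tuple[tuple[int, int], tuple[int, int]]  # ((mol, pos), (mol, pos))


@dataclass(frozen=True)
class PreferenceWeights:
    """Ordinal encoding of the oxidant-directed bond-type preference."""

    w_cys_pen: float = 2.0
    w_cys_cys: float = 1.0
    w_pen_pen: float = 0.5
    w_free: float = 0.0


@dataclass(frozen=True)
class PairingState:
    """One complete disulfide connectivity over a set of thiol sites."""

    bonds: tuple[SitePair, ...]
    free: tuple[tuple[int, int], ...]
    n_cys_pen: int
    n_cys_cys: int
    n_pen_pen: int
    n_free: int
    topology: str            # monomeric | heterodimeric | higher-order
    score: float | None = None

    def score_with(self, w: PreferenceWeights) -> float:
        return (
            w.w_cys_pen * self.n_cys_pen
            + w.w_cys_cys * self.n_cys_cys
            + w.w_pen_pen * self.n_pen_pen
            + w.w_free * self.n_free
        )


# --------------------------------------------------------------------------
# sequence grammar


def parse_sequence(text: str) -> list[str]:
    """Expand a sequence in the grammar into residue tokens ('A', ..., 'Pen').

    Underscore run-length notation ``G_3_`` is accepted as a synonym of
    ``G{3}``.
    """
    if not text:
        raise ValueError("empty sequence")
    tokens: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unterminated '[' at position {i}")
            tok = text[i + 1:j]
            if tok.lower() != "pen":
                raise ValueError(f"unknown bracket token {tok!r} at position {i}")
            tokens.append("Pen")
            i = j + 1
        elif ch in "{_":
            close = "}" if ch == "{" else "_"
            j = text.find(close, i + 1)
            if j < 0 or not text[i + 1:j].isdigit():
                raise ValueError(f"bad repeat count at position {i}")
            if not tokens:
                raise ValueError(f"repeat with no preceding residue at {i}")
            n = int(text[i + 1:j])
            if n < 1:
                raise ValueError(f"repeat count must be >= 1 at position {i}")
            tokens.extend([tokens[-1]] * (n - 1))
            i = j + 1
        elif ch.isalpha() and ch.upper() in "ACDEFGHIKLMNPQRSTVWY":
            tokens.append(ch.upper())
            i += 1
        else:
            raise ValueError(f"unknown token {ch!r} at position {i}")
    return tokens


def parse_thiol_sequence(text: str, molecule: int = 0) -> list[ThiolSite]:
    """Thiol sites (Cys and Pen) of an annotated sequence, in order."""
    sites = []
    for pos, tok in enumerate(parse_sequence(text), start=1):
        if tok == "C":
            sites.append(ThiolSite(molecule=molecule, position=pos, kind="CYS"))
        elif tok == "Pen":
            sites.append(ThiolSite(molecule=molecule, position=pos, kind="PEN"))
    return sites


# --------------------------------------------------------------------------
# state enumeration


def _classify_topology(
    n_molecules: int, bonds: tuple[SitePair, ...]
) -> str:
    parent = list(range(n_molecules))

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (ma, _), (mb, _) in bonds:
        ra, rb = root(ma), root(mb)
        if ra != rb:
            parent[ra] = rb
    sizes: dict[int, int] = {}
    for m in range(n_molecules):
        r = root(m)
        sizes[r] = sizes.get(r, 0) + 1
    biggest = max(sizes.values(), default=1)
    if biggest >= 3:
        return "higher-order"
    if biggest == 2:
        return "heterodimeric"
    return "monomeric"


def enumerate_pairing_states(
    molecules: list[list[ThiolSite]], allow_free: bool = False
) -> list[PairingState]:
    """All admissible disulfide connectivities over the given thiol sites.

    With ``allow_free=False`` the enumeration returns maximum matchings:
    perfect matchings when the total site count is even ((2n-1)!! states),
    otherwise every matching leaving the single parity-forced free site.
    ``allow_free=True`` admits any number of unpaired thiols.
    """
    sites: list[ThiolSite] = [s for mol in molecules for s in mol]
    if len(sites) < 2:
        raise ValueError("need at least two thiol sites")
    keys = [(s.molecule, s.position) for s in sites]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate thiol positions")
    kind = {k: s.kind for k, s in zip(keys, sites)}
    max_free = len(sites) % 2 if not allow_free else len(sites)

    states: list[PairingState] = []

    def recurse(remaining: tuple, bonds: tuple, free: tuple) -> None:
        if len(free) > max_free:
            return
        if not remaining:
            if len(remaining) == 0 and (allow_free or len(free) == max_free):
                states.append(_make_state(len(molecules), bonds, free, kind))
            return
        first, rest = remaining[0], remaining[1:]
        for j, other in enumerate(rest):
            recurse(
                rest[:j] + rest[j + 1:],
                bonds + (tuple(sorted((first, other))),),
                free,
            )
        recurse(rest, bonds, free + (first,))

    recurse(tuple(keys), (), ())
    return states


def _make_state(n_molecules, bonds, free, kind) -> PairingState:
    counts = {"CYS|PEN": 0, "CYS|CYS": 0, "PEN|PEN": 0}
    for a, b in bonds:
        counts["|".join(sorted((kind[a], kind[b])))] += 1
    return PairingState(
        bonds=tuple(sorted(bonds)),
        free=tuple(sorted(free)),
        n_cys_pen=counts["CYS|PEN"],
        n_cys_cys=counts["CYS|CYS"],
        n_pen_pen=counts["PEN|PEN"],
        n_free=len(free),
        topology=_classify_topology(n_molecules, bonds),
    )


def rank_states(
    states: list[PairingState],
    w: PreferenceWeights = PreferenceWeights(),
) -> tuple[list[PairingState], bool]:
    """States sorted by preference score (best first) plus a degeneracy flag.

    The flag is set when at least two states tie at the top within 1e-9;
    ties are ordered deterministically by their bond lists.
    """
    if not states:
        raise ValueError("no states to rank")
    scored = [replace(s, score=s.score_with(w)) for s in states]
    scored.sort(key=lambda s: (-s.score, s.bonds, s.free))
    degenerate = (
        len(scored) > 1 and abs(scored[0].score - scored[1].score) <= 1e-9
    )
    return scored, degenerate


# --------------------------------------------------------------------------
# orthogonality screen


@dataclass(frozen=True)
class HeterodimerDesign:
    """One designed heterodimer: a Cys-bearing and a Pen-bearing chain."""

    name: str
    cys_sites: tuple[int, ...]           # interchain Cys positions
    pen_sites: tuple[int, ...]           # interchain Pen positions
    cys_backbone: Structure | None = None
    pen_backbone: Structure | None = None


def _pen_chains_similar(
    a: Structure, b: Structure, threshold: float
) -> tuple[bool, str]:
    ra = list(a.residues())
    rb = list(b.residues())
    if len(ra) != len(rb):
        return False, f"pen-chain lengths differ ({len(ra)} vs {len(rb)})"
    mapping = {
        (x.chain_id, x.seqnum): (y.chain_id, y.seqnum)
        for x, y in zip(ra, rb)
    }
    r = rmsd_to_model(a, b, mode="backbone", mapping=mapping)
    if r < threshold:
        return True, f"pen-chain backbone RMSD {r:.2f} A < {threshold:g} A"
    return False, f"pen-chain backbone RMSD {r:.2f} A >= {threshold:g} A"


def orthogonality_screen(
    designs: list[HeterodimerDesign],
    rmsd_threshold: float = 2.0,
) -> dict[tuple[str, str], tuple[str, str]]:
    """Pairwise cross-reactivity of a heterodimer set.

    For each ordered pair (Cys chain of design i, Pen chain of design j,
    i != j) the pair is flagged cross-reactive when (a) the foreign Pen
    chain carries at least as many Pen sites as the Cys chain has Cys sites,
    and (b) where backbones are available, the foreign Pen chain is
    structurally similar to design i's own Pen chain (same length, backbone
    RMSD below ``rmsd_threshold``).  Returns
    {(cys_design, pen_design): (verdict, reason)}.
    """
    if len(designs) < 2:
        raise ValueError("need at least two designs to screen")
    out: dict[tuple[str, str], tuple[str, str]] = {}
    for di in designs:
        for dj in designs:
            if di.name == dj.name:
                continue
            if len(dj.pen_sites) < len(di.cys_sites):
                out[(di.name, dj.name)] = (
                    "orthogonal",
                    f"{len(dj.pen_sites)} Pen sites cannot satisfy "
                    f"{len(di.cys_sites)} Cys sites",
                )
                continue
            if di.pen_backbone is not None and dj.pen_backbone is not None:
                similar, why = _pen_chains_similar(
                    dj.pen_backbone, di.pen_backbone, rmsd_threshold
                )
                if not similar:
                    out[(di.name, dj.name)] = ("orthogonal", why)
                    continue
                out[(di.name, dj.name)] = (
                    "cross-reactive",
                    f"site counts compatible and {why}",
                )
            else:
                out[(di.name, dj.name)] = (
                    "cross-reactive",
                    "site counts compatible (no backbones supplied)",
                )
    return out


# --------------------------------------------------------------------------
# masses and tryptic digestion


def _residue_mass(token: str) -> float:
    if token == "Pen":
        return _PEN_RESIDUE_MASS
    try:
        return _pmass.std_aa_mass[token]
    except KeyError:
        raise ValueError(f"unknown residue {token!r}") from None


def monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass of one peptide chain (residues + one water), Da."""
    return sum(_residue_mass(t) for t in parse_sequence(sequence)) + WATER


@dataclass(frozen=True)
class Fragment:
    molecule: int
    start: int               # 1-based, inclusive
    end: int
    tokens: tuple[str, ...]

    @property
    def sequence(self) -> str:
        return "".join(t if t != "Pen" else "[Pen]" for t in self.tokens)

    @property
    def mass(self) -> float:
        return sum(_residue_mass(t) for t in self.tokens) + WATER


def _digest(tokens: list[str], molecule: int) -> list[Fragment]:
    cuts = []
    for i, tok in enumerate(tokens[:-1]):
        if tok in ("K", "R") and tokens[i + 1] != "P":
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(tokens)]
    return [
        Fragment(
            molecule=molecule,
            start=lo + 1,
            end=hi,
            tokens=tuple(tokens[lo:hi]),
        )
        for lo, hi in zip(bounds, bounds[1:])
    ]


def tryptic_fragments(
    sequences: list[str],
    bonds: PairingState | list[SitePair] | tuple[SitePair, ...] = (),
) -> list[tuple[tuple[Fragment, ...], float]]:
    """Tryptic digest with disulfide-linked fragments merged into species.

    Cleavage is C-terminal to Lys/Arg except before Pro.  Fragments joined
    by disulfide bonds form one species whose monoisotopic mass is the sum
    of the chain masses minus 2.01565 Da per bond.  Species are returned
    sorted by mass.
    """
    bond_list = tuple(bonds.bonds) if isinstance(bonds, PairingState) else tuple(bonds)
    frags: list[Fragment] = []
    site_to_frag: dict[tuple[int, int], int] = {}
    for m, seq in enumerate(sequences):
        tokens = parse_sequence(seq)
        for frag in _digest(tokens, m):
            idx = len(frags)
            frags.append(frag)
            for pos in range(frag.start, frag.end + 1):
                if frag.tokens[pos - frag.start] in ("C", "Pen"):
                    site_to_frag[(m, pos)] = idx

    parent = list(range(len(frags)))

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in bond_list:
        if a not in site_to_frag or b not in site_to_frag:
            missing = a if a not in site_to_frag else b
            raise ValueError(
                f"bond endpoint {missing} is not a thiol position"
            )
        parent[root(site_to_frag[a])] = root(site_to_frag[b])

    groups: dict[int, list[int]] = {}
    for i in range(len(frags)):
        groups.setdefault(root(i), []).append(i)
    n_bonds_in: dict[int, int] = {}
    for a, b in bond_list:
        n_bonds_in[root(site_to_frag[a])] = (
            n_bonds_in.get(root(site_to_frag[a]), 0) + 1
        )
    species = []
    for r, members in groups.items():
        fs = tuple(frags[i] for i in sorted(members))
        mass_total = sum(f.mass for f in fs) - DISULFIDE_LOSS * n_bonds_in.get(r, 0)
        species.append((fs, mass_total))
    species.sort(key=lambda kv: kv[1])
    return species
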