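"""Minimal hierarchical atomic model with gemmi-backed PDB/mmCIF I/O.

The rest of the package works with this deliberately small Structure/Chain/
Residue/Atom hierarchy; reading and writing the crystallographic formats is
delegated to gemmi.  Conventions: heavy atoms only (hydrogens dropped on
input, never written), one altloc kept per atom (highest occupancy, ties by
alphabetic label), author residue numbering, coordinates in Angstrom.
Penicillamine is carried as residue name ``PEN`` and written as HETATM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ParseError",
    "read_structure",
    "write_structure",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C")

# residues gemmi's PDB writer should emit as ATOM; everything else is HETATM
_STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)


class ParseError(ValueError):
    """A structure file could not be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")


@dataclass
class Residue:
    resname: str
    seqnum: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def backbone_complete(self) -> bool:
        return all(self.has_atom(n) for n in BACKBONE_ATOMS)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqnum: int) -> Residue:
        for r in self.residues:
            if r.seqnum == seqnum:
                return r
        raise KeyError(f"{self.chain_id}:{seqnum}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    id: str = ""
    resolution: float | None = None
    method: str | None = None
    fixture: bool = False  # synthetic fixtures bypass resolution filters
    ssbonds: list = field(default_factory=list)  # [((chain, seq), (chain, seq))]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residues(self):
        for c in self.chains:
            yield from c.residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        return Structure(
            chains=[
                Chain(
                    c.chain_id,
                    [
                        Residue(
                            r.resname,
                            r.seqnum,
                            r.chain_id,
                            [
                                Atom(a.name, a.element, a.coord.copy(),
                                     a.occupancy, a.altloc)
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            id=self.id,
            resolution=self.resolution,
            method=self.method,
            fixture=self.fixture,
            ssbonds=list(self.ssbonds),
        )


# --------------------------------------------------------------------------
# reading


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by alphabetic altloc label
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 0,
) -> Structure:
    """Read a PDB or mmCIF file into the package's Structure model.

    ``model_index`` selects one model of a multi-model (NMR) deposition;
    hydrogens are discarded and alternate locations resolved to a single
    atom each.  Residues missing any of N/CA/C are retained and can be
    identified through ``Residue.backbone_complete``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = st[model_index]

    chains: list[Chain] = []
    for gchain in model:
        residues = []
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc="",
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    resname=gres.name,
                    seqnum=gres.seqid.num,
                    chain_id=gchain.name,
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method = (
        st.info["_exptl.method"] if "_exptl.method" in st.info else None
    ) or None
    out = Structure(
        chains=chains, id=st.name or path.stem, resolution=resolution,
        method=method,
    )
    for res in out.residues():
        if not res.backbone_complete:
            warnings.warn(
                f"residue {res.chain_id}:{res.seqnum} ({res.resname}) is "
                "backbone-incomplete",
                stacklevel=2,
            )
    return out


# --------------------------------------------------------------------------
# writing


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a Structure as PDB; nonstandard residues (e.g. PEN) become HETATM."""
    if format != "pdb":
        raise ValueError(f"unsupported output format: {format}")
    seen: set[str] = set()
    for chain in s.chains:
        if chain.chain_id in seen:
            raise ValueError(f"duplicate chain id {chain.chain_id!r}")
        seen.add(chain.chain_id)
        for res in chain.residues:
            if not res.atoms:
                raise ValueError(
                    f"residue {chain.chain_id}:{res.seqnum} has no atoms"
                )

    st = gemmi.Structure()
    st.name = s.id or "design"
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.seqnum, " ")
            gres.het_flag = "A" if res.resname in _STANDARD_RESNAMES else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    for (ca_id, sa), (cb_id, sb) in s.ssbonds:
        con = gemmi.Connection()
        con.type = gemmi.ConnectionType.Disulf
        try:
            gcs = {c.name: c for c in st[0]}
            ga = next(r for r in gcs[ca_id] if r.seqid.num == sa)
            gb = next(r for r in gcs[cb_id] if r.seqid.num == sb)
            con.partner1 = gemmi.make_address(gcs[ca_id], ga, ga["SG"][0])
            con.partner2 = gemmi.make_address(gcs[cb_id], gb, gb["SG"][0])
        except (KeyError, StopIteration, RuntimeError):
            continue  # bond names a residue without an SG; skip the record
        st.connections.append(con)
    st.write_pdb(str(path))
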