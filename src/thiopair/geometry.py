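"""Backbone frames, rigid residue-pair transforms and disulfide geometry.

The residue-pair transform (RPX) machinery lives here: an orthonormal frame is
attached to every backbone-complete residue, and the rigid transform between two
frames is the quantity the hash database discretizes.  Side chains are built
from internal coordinates (NeRF), so a disulfide exemplar is fully described by
the inter-residue transform plus the four side-chain dihedrals
(chi1/chi2 of each cysteine).

Conventions
-----------
* Frame: origin at CA; e1 = unit(CA->N); e3 = unit(e1 x (CA->C)); e2 = e3 x e1.
* relative_transform(a, b) re-expresses coordinates written in frame ``a`` in
  frame ``b``:  x_b = R x_a + t.
* Dihedrals are IUPAC-signed and reported in (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _ideal
from .structio import Atom, Residue

__all__ = [
    "Frame",
    "RelativeTransform",
    "DisulfideGeometry",
    "DisulfideExemplar",
    "backbone_frame",
    "relative_transform",
    "disulfide_internal_coords",
    "place_cys_sidechain",
    "perturb_exemplar",
    "build_disulfide_pair",
    "reconstruct_exemplar_pair",
    "canonical_backbone",
    "place_atom",
    "dihedral",
    "bond_angle",
    "wrap_angle",
]


# --------------------------------------------------------------------------
# elementary vector geometry


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in (-180, 180] degrees (IUPAC sign)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(float(np.degrees(np.arctan2(y, x))))


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C (NeRF).

    D is bonded to C with length ``bond``, angle B-C-D = ``angle_deg`` and
    dihedral A-B-C-D = ``dihedral_deg``.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


# --------------------------------------------------------------------------
# frames and transforms


@dataclass(frozen=True)
class Frame:
    """Orthonormal backbone frame: origin at CA, right-handed axes."""

    origin: np.ndarray
    axes: np.ndarray  # columns are e1, e2, e3

    def to_global(self, local: np.ndarray) -> np.ndarray:
        """Map local coordinates into global coordinates."""
        return np.asarray(local) @ self.axes.T + self.origin


@dataclass(frozen=True)
class RelativeTransform:
    """Rigid map between two frames' coordinate descriptions: x_b = R x_a + t."""

    rotation: np.ndarray
    translation: np.ndarray

    @staticmethod
    def identity() -> "RelativeTransform":
        return RelativeTransform(np.eye(3), np.zeros(3))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation

    def compose(self, other: "RelativeTransform") -> "RelativeTransform":
        """self after other:  x -> self(other(x))."""
        return RelativeTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RelativeTransform":
        rt = self.rotation.T
        return RelativeTransform(rt, -rt @ self.translation)


def backbone_frame(residue: Residue) -> Frame:
    """Orthonormal frame of a backbone-complete residue.

    Raises ``ValueError`` naming the residue when N, CA or C is missing.
    """
    try:
        n = residue.atom("N").coord
        ca = residue.atom("CA").coord
        c = residue.atom("C").coord
    except KeyError as exc:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.seqnum} ({residue.resname}) "
            f"is missing backbone atom {exc.args[0]}"
        ) from None
    e1 = n - ca
    e1 = e1 / np.linalg.norm(e1)
    v = c - ca
    e3 = np.cross(e1, v)
    e3 = e3 / np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return Frame(origin=ca.copy(), axes=np.column_stack([e1, e2, e3]))


def relative_transform(a: Frame, b: Frame) -> RelativeTransform:
    """Transform re-expressing frame-``a`` coordinates in frame ``b``.

    Invariant under any global rigid motion applied to both frames;
    ``relative_transform(a, a)`` is the identity.
    """
    rot = b.axes.T @ a.axes
    trans = b.axes.T @ (a.origin - b.origin)
    return RelativeTransform(rot, trans)


def frame_from_transform(t: RelativeTransform) -> Frame:
    """The frame whose relative transform to the identity frame is ``t``.

    If frame A is the identity frame, returns frame B such that
    ``relative_transform(A, B) == t``.
    """
    axes = t.rotation.T
    origin = -axes @ t.translation
    return Frame(origin=origin, axes=axes)


# --------------------------------------------------------------------------
# canonical residue construction


def canonical_backbone() -> dict[str, np.ndarray]:
    """Ideal N/CA/C coordinates whose backbone frame is the identity frame."""
    ca = np.zeros(3)
    n = np.array([_ideal.N_CA, 0.0, 0.0])
    th = np.radians(_ideal.N_CA_C)
    c = _ideal.CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    return {"N": n, "CA": ca, "C": c}


def make_backbone_residue(
    resname: str,
    seqnum: int,
    chain_id: str,
    frame: Frame | None = None,
) -> Residue:
    """A backbone-only residue (N, CA, C) placed at ``frame`` (default identity)."""
    local = canonical_backbone()
    if frame is None:
        frame = Frame(np.zeros(3), np.eye(3))
    atoms = [
        Atom(name=name, element=name[0], coord=frame.to_global(xyz))
        for name, xyz in local.items()
    ]
    return Residue(resname=resname, seqnum=seqnum, chain_id=chain_id, atoms=atoms)


# improper dihedral C-N-CA-CB placing CB off the backbone (L-chirality);
# solved so that CB-CA-C = 110.1 deg with the ideal N-CA-CB angle
_CB_IMPROPER = -122.5847821139
_CB_CA_C = 110.1
_C_BRANCH_CACHE: list[float] = []


def _c_branch() -> float:
    """dihedral(SG-CB-CA-C) minus chi1 for the ideal side-chain geometry.

    Locates the carbonyl C when a backbone is grown outward from the side
    chain; derived once numerically so it is the exact inverse of
    ``place_cys_sidechain`` for any chi1.
    """
    if not _C_BRANCH_CACHE:
        res = make_backbone_residue("CYS", 1, "A")
        res = place_cys_sidechain(res, 0.0)
        sg, cb, ca, c = (res.atom(x).coord for x in ("SG", "CB", "CA", "C"))
        _C_BRANCH_CACHE.append(dihedral(sg, cb, ca, c))
    return _C_BRANCH_CACHE[0]


def place_cys_sidechain(
    residue: Residue,
    chi1: float,
    chi2: float | None = None,
    as_pen: bool = False,
) -> Residue:
    """Build a Cys (or Pen) side chain onto a backbone-complete residue.

    CB is placed from ideal internal coordinates off N/CA/C, SG by ``chi1``
    (dihedral N-CA-CB-SG).  ``chi2`` (CA-CB-SG-SG') orients the disulfide
    partner, not any atom of this residue; it is accepted for interface
    symmetry and used by the pair builders.  With ``as_pen`` the two
    beta-methyl carbons CG1/CG2 are added tetrahedrally at CB.

    Returns a new residue; the input is not modified.
    """
    n = residue.atom("N").coord
    ca = residue.atom("CA").coord
    c = residue.atom("C").coord
    cb = place_atom(c, n, ca, _ideal.CA_CB, _ideal.N_CA_CB, _CB_IMPROPER)
    sg = place_atom(n, ca, cb, _ideal.CB_SG, _ideal.CA_CB_SG, chi1)
    resname = "PEN" if as_pen else "CYS"
    atoms = [
        Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.altloc)
        for a in residue.atoms
        if a.name in ("N", "CA", "C", "O")
    ]
    atoms.append(Atom("CB", "C", cb))
    atoms.append(Atom("SG", "S", sg))
    if as_pen:
        # two methyls complete the tetrahedral substitution at CB
        cg1 = place_atom(n, ca, cb, _ideal.CB_CG, _ideal.TETRAHEDRAL,
                         chi1 + 120.0)
        cg2 = place_atom(n, ca, cb, _ideal.CB_CG, _ideal.TETRAHEDRAL,
                         chi1 - 120.0)
        atoms.append(Atom("CG1", "C", cg1))
        atoms.append(Atom("CG2", "C", cg2))
    return Residue(
        resname=resname,
        seqnum=residue.seqnum,
        chain_id=residue.chain_id,
        atoms=atoms,
    )


# --------------------------------------------------------------------------
# disulfide geometry


@dataclass(frozen=True)
class DisulfideGeometry:
    """Internal coordinates of one S-S bridge (distances Angstrom, angles deg)."""

    ss_dist: float
    chi1_a: float
    chi2_a: float
    chi1_b: float
    chi2_b: float
    chi3: float
    angle_a: float  # CB-SG-SG'
    angle_b: float  # SG-SG'-CB'


def disulfide_internal_coords(res_a: Residue, res_b: Residue) -> DisulfideGeometry:
    """Measure the full internal-coordinate description of an S-S bridge."""
    for res in (res_a, res_b):
        for name in ("CB", "SG"):
            if not res.has_atom(name):
                raise ValueError(
                    f"residue {res.chain_id}:{res.seqnum} has no {name} atom"
                )
    na, caa, cba, sga = (res_a.atom(x).coord for x in ("N", "CA", "CB", "SG"))
    nb, cab, cbb, sgb = (res_b.atom(x).coord for x in ("N", "CA", "CB", "SG"))
    return DisulfideGeometry(
        ss_dist=float(np.linalg.norm(sga - sgb)),
        chi1_a=dihedral(na, caa, cba, sga),
        chi2_a=dihedral(caa, cba, sga, sgb),
        chi1_b=dihedral(nb, cab, cbb, sgb),
        chi2_b=dihedral(cab, cbb, sgb, sga),
        chi3=dihedral(cba, sga, sgb, cbb),
        angle_a=bond_angle(cba, sga, sgb),
        angle_b=bond_angle(sga, sgb, cbb),
    )


# --------------------------------------------------------------------------
# exemplars


@dataclass(frozen=True)
class DisulfideExemplar:
    """One observed (or synthesized) disulfide: inter-residue transform + rotamers."""

    transform: RelativeTransform
    rotamers: tuple[float, float, float, float]  # chi1_a, chi2_a, chi1_b, chi2_b
    source: str = ""
    resolution: float | None = None
    perturbed: bool = False


def build_disulfide_pair(
    chi1_a: float,
    chi2_a: float,
    chi3: float,
    chi2_b: float,
    chi1_b: float,
    seqnum_a: int = 1,
    seqnum_b: int = 2,
) -> tuple[Residue, Residue]:
    """Construct an ideal disulfide-bonded Cys pair from its five dihedrals.

    Residue A sits at the identity frame; residue B's backbone is grown out
    through the bridge by NeRF, so every internal coordinate of the result
    equals its input by construction (S-S bond 2.04 A, CB-S-S angles 104.2 deg).
    """
    res_a = make_backbone_residue("CYS", seqnum_a, "A")
    res_a = place_cys_sidechain(res_a, chi1_a, chi2_a)
    na, caa, cba, sga = (res_a.atom(x).coord for x in ("N", "CA", "CB", "SG"))

    sgb = place_atom(caa, cba, sga, _ideal.SS_BOND, _ideal.CB_S_S, chi2_a)
    cbb = place_atom(cba, sga, sgb, _ideal.CB_SG, _ideal.CB_S_S, chi3)
    cab = place_atom(sga, sgb, cbb, _ideal.CA_CB, _ideal.CA_CB_SG, chi2_b)
    nb = place_atom(sgb, cbb, cab, _ideal.N_CA, _ideal.N_CA_CB, chi1_b)
    cb_ = place_atom(sgb, cbb, cab, _ideal.CA_C, _CB_CA_C,
                     chi1_b + _c_branch())
    res_b = Residue(
        resname="CYS",
        seqnum=seqnum_b,
        chain_id="A",
        atoms=[
            Atom("N", "N", nb),
            Atom("CA", "C", cab),
            Atom("C", "C", cb_),
            Atom("CB", "C", cbb),
            Atom("SG", "S", sgb),
        ],
    )
    return res_a, res_b


def exemplar_from_pair(
    res_a: Residue,
    res_b: Residue,
    source: str = "",
    resolution: float | None = None,
) -> DisulfideExemplar:
    """Record a bonded residue pair as an exemplar (transform + chi rotamers)."""
    geo = disulfide_internal_coords(res_a, res_b)
    t = relative_transform(backbone_frame(res_a), backbone_frame(res_b))
    return DisulfideExemplar(
        transform=t,
        rotamers=(geo.chi1_a, geo.chi2_a, geo.chi1_b, geo.chi2_b),
        source=source,
        resolution=resolution,
    )


def reconstruct_exemplar_pair(e: DisulfideExemplar) -> tuple[Residue, Residue]:
    """Realize an exemplar as two Cys residues (A at identity, B at the transform)."""
    res_a = make_backbone_residue("CYS", 1, "A")
    res_a = place_cys_sidechain(res_a, e.rotamers[0], e.rotamers[1])
    frame_b = frame_from_transform(e.transform)
    res_b = make_backbone_residue("CYS", 2, "A", frame=frame_b)
    res_b = place_cys_sidechain(res_b, e.rotamers[2], e.rotamers[3])
    return res_a, res_b


def _sidechain_coords(e: DisulfideExemplar) -> np.ndarray:
    ra, rb = reconstruct_exemplar_pair(e)
    return np.array(
        [ra.atom("CB").coord, ra.atom("SG").coord,
         rb.atom("CB").coord, rb.atom("SG").coord]
    )


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def perturb_exemplar(
    e: DisulfideExemplar, max_disp: float, rng_seed: int
) -> DisulfideExemplar:
    """Randomly perturb an exemplar's side-chain degrees of freedom.

    Both residues' (chi1, chi2) and the inter-residue transform are jittered
    by uniform deltas, rejection-sampled until no reconstructed side-chain
    heavy atom (CB/SG of either residue) moves more than ``max_disp``
    Angstrom.  Deterministic for a fixed seed.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    rng = np.random.default_rng(rng_seed)
    ref = _sidechain_coords(e)
    # lever arms: SG swings ~1.65 A per radian of chi1; frame origin offset ~3 A
    chi_scale = min(60.0, np.degrees(max_disp / (2.0 * _ideal.CB_SG)))
    trans_scale = max_disp / 2.0
    rot_scale = min(30.0, np.degrees(max_disp / 8.0))
    for attempt in range(400):
        if attempt and attempt % 50 == 0:
            chi_scale *= 0.7
            trans_scale *= 0.7
            rot_scale *= 0.7
        d_chis = rng.uniform(-chi_scale, chi_scale, size=4)
        d_t = rng.uniform(-trans_scale, trans_scale, size=3)
        d_r = _random_rotation(rng, rot_scale)
        cand = replace(
            e,
            rotamers=tuple(
                wrap_angle(c + d) for c, d in zip(e.rotamers, d_chis)
            ),
            transform=RelativeTransform(
                d_r @ e.transform.rotation, e.transform.translation + d_t
            ),
            perturbed=True,
        )
        disp = np.linalg.norm(_sidechain_coords(cand) - ref, axis=1).max()
        if disp <= max_disp:
            return cand
    # scales shrink geometrically, so this is unreachable in practice
    raise RuntimeError("perturbation rejection sampling failed to converge")
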