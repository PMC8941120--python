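"""Hash database of disulfide residue-pair transforms.

A disulfide can bridge a residue pair when the rigid transform between the two
backbone frames matches the transform of some observed disulfide.  The
database discretizes each exemplar transform into an integer key (translation
binned at ``cart_res`` Angstrom, Z-Y-X Euler angles binned at ``ang_res``
degrees) and stores the exemplar's cysteine rotamers (chi1/chi2 of both
residues) as the payload.  Coverage of each exemplar's neighbourhood comes
from storing ``n_perturb`` random perturbations of its side-chain degrees of
freedom (default 100, each bounded by ``max_disp`` = 5 A of side-chain atom
displacement); lookups are exact key matches with no neighbour-bin expansion.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    DisulfideExemplar,
    RelativeTransform,
    backbone_frame,
    exemplar_from_pair,
    perturb_exemplar,
    relative_transform,
)
from .structio import Structure

__all__ = [
    "HashDbConfig",
    "RotamerPayload",
    "HashDatabase",
    "discretize",
    "mine_exemplars",
    "build_database",
    "query",
    "persist",
    "load",
]

_MAGIC = b"THIOPAIRDB\n"
_VERSION = 1

# thiol-bearing residue types whose SG pairs are mined
_THIOL_RESNAMES = ("CYS", "PEN")


@dataclass(frozen=True)
class HashDbConfig:
    """Build parameters of a hash database.

    Defaults: 1.0 A cartesian and 15.0 degree angular hash resolution, 100
    perturbations per exemplar bounded by 5 A side-chain displacement,
    exemplars mined from structures better than 2.0 A resolution with SG-SG
    within 2.5 A.
    """

    cart_res: float = 1.0
    ang_res: float = 15.0
    n_perturb: int = 100
    max_disp: float = 5.0
    resolution_cutoff: float = 2.0
    ss_mining_cutoff: float = 2.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cart_res <= 0 or self.ang_res <= 0:
            raise ValueError("hash resolutions must be positive")
        if self.n_perturb < 0:
            raise ValueError("n_perturb must be >= 0")


@dataclass(frozen=True)
class RotamerPayload:
    """Cysteine rotamers stored under one transform key."""

    chi1_a: float
    chi2_a: float
    chi1_b: float
    chi2_b: float
    source: str = ""

    @property
    def chis(self) -> tuple[float, float, float, float]:
        return (self.chi1_a, self.chi2_a, self.chi1_b, self.chi2_b)


TransformKey = tuple[int, int, int, int, int, int]


def _euler_zyx(rotation: np.ndarray) -> np.ndarray:
    """Canonical Z-Y-X Euler angles in degrees, middle angle in [-90, 90].

    Within 1e-6 degrees of gimbal lock the third angle is set to zero, so
    discretization never fails on a degenerate rotation.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ang = Rotation.from_matrix(rotation).as_euler("zyx", degrees=True)
    if abs(abs(ang[1]) - 90.0) < 1e-6:
        ang[2] = 0.0
    return ang


def discretize(t: RelativeTransform, cfg: HashDbConfig) -> TransformKey:
    """Integer hash key of a transform: floor-binned translation and Euler angles."""
    t_bins = np.floor(np.asarray(t.translation) / cfg.cart_res).astype(int)
    r_bins = np.floor(_euler_zyx(t.rotation) / cfg.ang_res).astype(int)
    return (int(t_bins[0]), int(t_bins[1]), int(t_bins[2]),
            int(r_bins[0]), int(r_bins[1]), int(r_bins[2]))


def bin_center_transform(key: TransformKey, cfg: HashDbConfig) -> RelativeTransform:
    """The transform at the center of a key's bin (inverse of discretize up to half a bin)."""
    t = (np.asarray(key[:3], dtype=float) + 0.5) * cfg.cart_res
    ang = (np.asarray(key[3:], dtype=float) + 0.5) * cfg.ang_res
    rot = Rotation.from_euler("zyx", ang, degrees=True).as_matrix()
    return RelativeTransform(rot, t)


# --------------------------------------------------------------------------
# mining and building


def mine_exemplars(
    structures: list[Structure], cfg: HashDbConfig
) -> list[DisulfideExemplar]:
    """Extract disulfide exemplars from structures.

    Keeps CYS-CYS (or PEN) pairs with SG-SG distance within
    ``cfg.ss_mining_cutoff`` from structures better than
    ``cfg.resolution_cutoff`` A resolution (synthetic fixtures are exempt
    from the resolution filter).  Both residue orderings of every bridge are
    emitted so the database is direction-insensitive.
    """
    exemplars: list[DisulfideExemplar] = []
    for s in structures:
        if not s.fixture:
            if s.resolution is None:
                warnings.warn(
                    f"structure {s.id!r} has no resolution metadata; skipped",
                    stacklevel=2,
                )
                continue
            if s.resolution >= cfg.resolution_cutoff:
                continue
        thiols = [
            r
            for r in s.residues()
            if r.resname in _THIOL_RESNAMES
            and r.has_atom("SG")
            and r.has_atom("CB")
            and r.backbone_complete
        ]
        for i, ra in enumerate(thiols):
            for rb in thiols[i + 1:]:
                d = float(
                    np.linalg.norm(ra.atom("SG").coord - rb.atom("SG").coord)
                )
                if d > cfg.ss_mining_cutoff:
                    continue
                tag = (
                    f"{s.id}:{ra.chain_id}{ra.seqnum}-{rb.chain_id}{rb.seqnum}"
                )
                exemplars.append(
                    exemplar_from_pair(ra, rb, source=tag,
                                       resolution=s.resolution)
                )
                exemplars.append(
                    exemplar_from_pair(rb, ra, source=tag + ":rev",
                                       resolution=s.resolution)
                )
    return exemplars


@dataclass
class HashDatabase:
    """Key -> rotamer payload store together with its build parameters."""

    config: HashDbConfig
    table: dict[TransformKey, list[RotamerPayload]] = field(default_factory=dict)
    n_exemplars: int = 0

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.table.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HashDatabase):
            return NotImplemented
        return (
            self.config == other.config
            and self.n_exemplars == other.n_exemplars
            and self.table == other.table
        )


def build_database(
    exemplars: list[DisulfideExemplar], cfg: HashDbConfig
) -> HashDatabase:
    """Build the hash table from exemplars with perturbation augmentation.

    Each exemplar contributes one entry for its own transform plus
    ``cfg.n_perturb`` entries for bounded random perturbations, so
    ``n_entries == len(exemplars) * (1 + cfg.n_perturb)``.  Deterministic for
    a fixed ``cfg.rng_seed``.
    """
    if not exemplars:
        raise ValueError("cannot build a database from zero exemplars")
    db = HashDatabase(config=cfg, n_exemplars=len(exemplars))
    for i, ex in enumerate(exemplars):
        variants = [ex]
        for j in range(cfg.n_perturb):
            seed = int(
                np.random.SeedSequence([cfg.rng_seed, i, j]).generate_state(1)[0]
            ) % (2**31)
            variants.append(perturb_exemplar(ex, cfg.max_disp, seed))
        for var in variants:
            key = discretize(var.transform, cfg)
            payload = RotamerPayload(*var.rotamers, source=ex.source)
            db.table.setdefault(key, []).append(payload)
    return db


def query(db: HashDatabase, t: RelativeTransform) -> list[RotamerPayload]:
    """Payloads stored under the transform's key; empty when the bin is unseen."""
    return list(db.table.get(discretize(t, db.config), ()))


def query_pair(db: HashDatabase, res_a, res_b) -> list[RotamerPayload]:
    """Convenience: query with the transform between two residues' frames."""
    t = relative_transform(backbone_frame(res_a), backbone_frame(res_b))
    return query(db, t)


# --------------------------------------------------------------------------
# persistence: magic + length-prefixed JSON header + packed arrays


def persist(db: HashDatabase, path: str | Path) -> None:
    """Write the database as a single versioned binary container."""
    keys: list[TransformKey] = []
    chis: list[tuple[float, float, float, float]] = []
    source_table: list[str] = []
    source_idx: dict[str, int] = {}
    src_col: list[int] = []
    for key, payloads in db.table.items():
        for p in payloads:
            keys.append(key)
            chis.append(p.chis)
            if p.source not in source_idx:
                source_idx[p.source] = len(source_table)
                source_table.append(p.source)
            src_col.append(source_idx[p.source])
    key_arr = np.asarray(keys, dtype=np.int32).reshape(-1, 6)
    chi_arr = np.asarray(chis, dtype=np.float64).reshape(-1, 4)
    src_arr = np.asarray(src_col, dtype=np.int32)
    header = json.dumps(
        {
            "version": _VERSION,
            "config": asdict(db.config),
            "n_exemplars": db.n_exemplars,
            "n_entries": len(keys),
            "sources": source_table,
        },
        sort_keys=True,
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(key_arr.tobytes())
        fh.write(chi_arr.tobytes())
        fh.write(src_arr.tobytes())


def load(path: str | Path) -> HashDatabase:
    """Read a persisted database; truncation or version mismatch is an error."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob.startswith(_MAGIC):
        raise ValueError(f"{path}: not a thiopair hash database")
    off = len(_MAGIC)
    (hlen,) = struct.unpack_from("<Q", blob, off)
    off += 8
    header = json.loads(blob[off:off + hlen].decode())
    off += hlen
    if header["version"] != _VERSION:
        raise ValueError(
            f"{path}: database version {header['version']} "
            f"!= supported {_VERSION}"
        )
    n = header["n_entries"]
    need = off + n * 6 * 4 + n * 4 * 8 + n * 4
    if len(blob) < need:
        raise ValueError(f"{path}: truncated database file")
    key_arr = np.frombuffer(blob, dtype=np.int32, count=n * 6, offset=off)
    off += n * 6 * 4
    chi_arr = np.frombuffer(blob, dtype=np.float64, count=n * 4, offset=off)
    off += n * 4 * 8
    src_arr = np.frombuffer(blob, dtype=np.int32, count=n, offset=off)
    sources = header["sources"]
    db = HashDatabase(
        config=HashDbConfig(**header["config"]),
        n_exemplars=header["n_exemplars"],
    )
    key_arr = key_arr.reshape(-1, 6)
    chi_arr = chi_arr.reshape(-1, 4)
    for i in range(n):
        key = tuple(int(x) for x in key_arr[i])
        db.table.setdefault(key, []).append(
            RotamerPayload(*chi_arr[i], source=sources[src_arr[i]])
        )
    return db
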