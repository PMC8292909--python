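"""Binding-site definition and rigid-body pose sampling.

The binding pocket is delineated by a flooding (region-growing) algorithm on a
1 Å voxel lattice: starting from an unoccupied seed voxel, the flood expands
through 6-connected unoccupied neighbors and is truncated at a Euclidean
radius from the seed.  A voxel is occupied when any heavy atom lies within
``r_occ`` of its center.  The lattice is anchored to world coordinates
(voxel index = floor(xyz / spacing)), so a sub-voxel shift of the seed leaves
the flooded set unchanged.

Pose ensembles are rigid-body placements of a given ligand conformer: uniform
random rotations (quaternion method) combined with translations to uniformly
drawn flooded-voxel centers, accepted when clash-free against the protein.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


@dataclass
class Atom:
    element: str
    xyz: np.ndarray
    residue_id: str = ""
    chain_id: str = ""
    vdw_radius: float = 1.7


@dataclass
class Structure:
    """A protein (or synthetic pocket) as a flat atom list."""

    atoms: list[Atom]

    def __post_init__(self):
        coords = self.coords
        if len(self.atoms) and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if any(a.vdw_radius <= 0 for a in self.atoms):
            raise ValueError("vdW radius must be > 0")

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_coords(self) -> np.ndarray:
        c = [a.xyz for a in self.atoms if a.element != "H"]
        return np.array(c, dtype=float) if c else np.zeros((0, 3))

    @classmethod
    def from_pdb(cls, path) -> "Structure":
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        s = parser.get_structure("s", str(path))
        atoms = []
        for model in s:
            for chain in model:
                for res in chain:
                    for at in res:
                        el = (at.element or at.get_name()[0]).strip().capitalize()
                        atoms.append(Atom(
                            element=el,
                            xyz=np.array(at.coord, dtype=float),
                            residue_id=f"{chain.id}:{res.id[1]}",
                            chain_id=chain.id,
                        ))
            break  # first model only
        return cls(atoms=atoms)


@dataclass
class FloodParams:
    spacing: float = 1.0
    r_occ: float = 2.0
    max_radius: float = 12.0
    d_site: float = 4.5


@dataclass
class PocketSite:
    voxels: np.ndarray          # (n, 3) integer lattice indices (world-anchored)
    spacing: float
    origin: np.ndarray          # seed voxel center, Å
    center: np.ndarray          # centroid of voxel centers, Å
    residues: frozenset = frozenset()

    def voxel_centers(self) -> np.ndarray:
        return (self.voxels + 0.5) * self.spacing

    def to_json(self, path=None) -> str:
        d = {
            "voxels": self.voxels.tolist(),
            "spacing": self.spacing,
            "origin": self.origin.tolist(),
            "center": self.center.tolist(),
            "residues": sorted(self.residues),
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "PocketSite":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            voxels=np.array(d["voxels"], dtype=int),
            spacing=d["spacing"],
            origin=np.array(d["origin"]),
            center=np.array(d["center"]),
            residues=frozenset(d["residues"]),
        )


class SeedBuriedError(ValueError):
    pass


class PocketTooSmallError(RuntimeError):
    pass


_NEIGHBORS6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def flood_fill_site(s: Structure, seed_xyz, params: FloodParams | None = None) -> PocketSite:
    """Breadth-first flood from the seed voxel through unoccupied 6-connected
    voxels, truncated at ``max_radius`` (Euclidean, voxel center to seed voxel
    center).  Deterministic."""
    params = params or FloodParams()
    if not s.atoms:
        raise ValueError("empty structure")
    seed_xyz = np.asarray(seed_xyz, dtype=float)
    heavy = s.heavy_coords()
    tree = cKDTree(heavy)
    sp = params.spacing

    def center_of(idx):
        return (np.asarray(idx, dtype=float) + 0.5) * sp

    seed_idx = tuple(np.floor(seed_xyz / sp).astype(int))
    d0, _ = tree.query(center_of(seed_idx))
    if d0 < params.r_occ:
        raise SeedBuriedError("seed_buried")
    seed_center = center_of(seed_idx)

    # breadth-first by frontier level; occupancy queried in batches
    visited = {seed_idx}
    flooded = [seed_idx]
    frontier = [seed_idx]
    while frontier:
        cand = []
        for cur in frontier:
            for off in _NEIGHBORS6:
                nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nxt not in visited:
                    visited.add(nxt)
                    cand.append(nxt)
        if not cand:
            break
        arr = np.array(cand, dtype=float)
        centers = (arr + 0.5) * sp
        in_range = np.linalg.norm(centers - seed_center, axis=1) <= params.max_radius
        dists, _ = tree.query(centers)
        keep = in_range & (dists >= params.r_occ)
        frontier = [c for c, k in zip(cand, keep) if k]
        flooded.extend(frontier)

    voxels = np.array(sorted(flooded), dtype=int)
    centers = (voxels + 0.5) * sp
    # residues with >=1 atom within d_site of any flooded voxel center
    residues = set()
    if len(heavy):
        ctree = cKDTree(centers)
        for a in s.atoms:
            if a.element == "H" or not a.residue_id:
                continue
            d, _ = ctree.query(np.asarray(a.xyz, dtype=float))
            if d <= params.d_site:
                residues.add(a.residue_id)
    return PocketSite(
        voxels=voxels,
        spacing=sp,
        origin=seed_center,
        center=centers.mean(axis=0),
        residues=frozenset(residues),
    )


def site_from_residues(s: Structure, residue_ids, params: FloodParams | None = None) -> PocketSite:
    """Seed the flood at the unoccupied voxel nearest the centroid of the
    named residues' atoms (e.g. the 25 S1-site residues R249…F400)."""
    params = params or FloodParams()
    wanted = set(residue_ids)
    present = {a.residue_id for a in s.atoms}
    missing = sorted(wanted - present)
    if missing:
        raise KeyError(f"residues not in structure: {missing}")
    pts = np.array([a.xyz for a in s.atoms if a.residue_id in wanted], dtype=float)
    centroid = pts.mean(axis=0)
    heavy = s.heavy_coords()
    tree = cKDTree(heavy)
    sp = params.spacing
    # spiral outward over lattice shells until an unoccupied voxel is found
    base = np.floor(centroid / sp).astype(int)
    for radius in range(0, int(np.ceil(params.max_radius / sp)) + 1):
        best = None
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                for dz in range(-radius, radius + 1):
                    if max(abs(dx), abs(dy), abs(dz)) != radius:
                        continue
                    idx = base + (dx, dy, dz)
                    c = (idx + 0.5) * sp
                    d, _ = tree.query(c)
                    if d >= params.r_occ:
                        dist = np.linalg.norm(c - centroid)
                        if best is None or dist < best[0]:
                            best = (dist, c)
        if best is not None:
            return flood_fill_site(s, best[1], params)
    raise SeedBuriedError("seed_buried")


@dataclass
class Conformer:
    """A ligand conformer: elements + 3D coordinates (site-independent)."""

    id: str
    elements: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords shape mismatch")

    @classmethod
    def from_rdkit(cls, mol, mol_id: str = "") -> "Conformer":
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        return cls(id=mol_id, elements=[a.GetSymbol() for a in mol.GetAtoms()], coords=coords)


@dataclass
class PoseEnsemble:
    ligand: Conformer
    rotations: np.ndarray       # (n, 3, 3)
    translations: np.ndarray    # (n, 3) applied after rotation about ligand centroid
    rng_seed: int

    @property
    def n_poses(self) -> int:
        return len(self.rotations)

    def pose_coords(self, i: int) -> np.ndarray:
        c = self.ligand.coords
        centroid = c.mean(axis=0)
        return (c - centroid) @ self.rotations[i].T + self.translations[i]


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform rotations on SO(3) via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


def generate_poses(site: PocketSite, ligand: Conformer, protein: Structure | None = None,
                   n: int = 64, seed: int = 0, clash_cutoff: float = 2.2,
                   max_attempts_factor: int = 10_000) -> PoseEnsemble:
    """Rejection-sample ``n`` clash-free rigid placements of the ligand inside
    the flooded region.  Deterministic given (inputs, seed)."""
    if len(site.voxels) == 0:
        raise ValueError("empty site")
    rng = np.random.default_rng(seed)
    centers = site.voxel_centers()
    prot = protein.heavy_coords() if protein is not None else np.zeros((0, 3))
    tree = cKDTree(prot) if len(prot) else None
    lig = ligand.coords - ligand.coords.mean(axis=0)
    heavy_mask = np.array([e != "H" for e in ligand.elements])

    rots, trans = [], []
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(rots) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PocketTooSmallError("pocket_too_small")
        R = random_rotations(1, rng)[0]
        t = centers[rng.integers(len(centers))]
        placed = lig @ R.T + t
        if tree is not None:
            d, _ = tree.query(placed[heavy_mask])
            if np.min(d) < clash_cutoff:
                continue
        rots.append(R)
        trans.append(t)
    return PoseEnsemble(
        ligand=ligand,
        rotations=np.array(rots),
        translations=np.array(trans),
        rng_seed=seed,
    )
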