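"""Voxel-grid featurization of protein–ligand poses.

A pose and its protein are shifted to a frame whose origin is the binding-site
center, optionally augmented by a random rigid rotation+translation (so the
network cannot memorize a preferred orientation), and rasterized onto a cubic
lattice of binary occupancy channels — one channel per (entity, element class)
pair, like the RGB channels of an image pixel.  Default: 30×30×30 voxels at
1 Å spacing, 16 channels = {protein, ligand} × {C, N, O, S, P, B, halogen,
other}.  A reduced 2-channel {protein, ligand} scheme is available for
desk-scale training runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .structure import Conformer, PocketSite, Structure, random_rotations

HALOGENS = {"F", "Cl", "Br", "I"}
ELEMENT_CLASSES = ("C", "N", "O", "S", "P", "B", "halogen", "other")


def element_class(el: str) -> str:
    if el in HALOGENS:
        return "halogen"
    if el in ("C", "N", "O", "S", "P", "B"):
        return el
    return "other"


@dataclass(frozen=True)
class GridSpec:
    edge_voxels: int = 30
    spacing: float = 1.0
    scheme: str = "entity_element"   # or "entity"

    def __post_init__(self):
        if self.edge_voxels < 4 or self.spacing <= 0:
            raise ValueError("invalid grid spec")
        if self.scheme not in ("entity_element", "entity"):
            raise ValueError(f"unknown channel scheme {self.scheme!r}")

    @property
    def n_channels(self) -> int:
        return 16 if self.scheme == "entity_element" else 2

    def channel_of(self, entity: str, el: str) -> int:
        base = 0 if entity == "protein" else 1
        if self.scheme == "entity":
            return base
        return base * 8 + ELEMENT_CLASSES.index(element_class(el))

    def fingerprint(self) -> str:
        s = f"{self.edge_voxels}|{self.spacing}|{self.scheme}"
        return hashlib.sha1(s.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {"edge_voxels": self.edge_voxels, "spacing": self.spacing, "scheme": self.scheme}


@dataclass
class ComplexFrame:
    """Protein + one ligand pose in site-centered coordinates."""

    protein_elements: list[str]
    protein_coords: np.ndarray
    ligand_elements: list[str]
    ligand_coords: np.ndarray

    def __post_init__(self):
        self.protein_coords = np.asarray(self.protein_coords, dtype=float).reshape(-1, 3)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float).reshape(-1, 3)


def center_frame(structure: Structure, pose_coords, ligand: Conformer,
                 site: PocketSite) -> ComplexFrame:
    """Translate protein and pose so the site center sits at the origin."""
    c = np.asarray(site.center, dtype=float)
    return ComplexFrame(
        protein_elements=structure.elements,
        protein_coords=structure.coords - c,
        ligand_elements=ligand.elements,
        ligand_coords=np.asarray(pose_coords, dtype=float) - c,
    )


def augment(frame: ComplexFrame, seed: int, t_max: float = 2.0) -> ComplexFrame:
    """Apply one uniform random rotation about the origin plus a translation
    uniform in [-t_max, t_max]^3 to the whole complex.  Seeded."""
    rng = np.random.default_rng(seed)
    R = random_rotations(1, rng)[0]
    t = rng.uniform(-t_max, t_max, size=3)
    return ComplexFrame(
        protein_elements=frame.protein_elements,
        protein_coords=frame.protein_coords @ R.T + t,
        ligand_elements=frame.ligand_elements,
        ligand_coords=frame.ligand_coords @ R.T + t,
    )


def rasterize(frame: ComplexFrame, spec: GridSpec | None = None) -> np.ndarray:
    """Binary occupancy tensor (channels, edge, edge, edge), uint8.

    Voxel cubes are half-open [x, x+spacing); the grid spans
    [-edge/2*spacing, +edge/2*spacing) per axis.  Atoms outside are ignored.
    """
    spec = spec or GridSpec()
    e = spec.edge_voxels
    grid = np.zeros((spec.n_channels, e, e, e), dtype=np.uint8)
    half = e * spec.spacing / 2.0
    for entity, els, coords in (
        ("protein", frame.protein_elements, frame.protein_coords),
        ("ligand", frame.ligand_elements, frame.ligand_coords),
    ):
        if len(els) == 0:
            continue
        idx = np.floor((coords + half) / spec.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < e), axis=1)
        for el, (i, j, k), ok in zip(els, idx, inside):
            if ok:
                grid[spec.channel_of(entity, el), i, j, k] = 1
    return grid


def save_grids(path, grids: np.ndarray, spec: GridSpec, labels=None, provenance: dict | None = None):
    """Persist grid tensors to HDF5 (values uint8; spec and provenance attrs)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=np.asarray(grids, dtype=np.uint8), compression="gzip")
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels, dtype=float))
        fh.attrs["spec"] = json.dumps(spec.to_dict())
        fh.attrs["provenance"] = json.dumps(provenance or {})


def load_grids(path):
    import h5py

    with h5py.File(path, "r") as fh:
        grids = fh["values"][...]
        labels = fh["labels"][...] if "labels" in fh else None
        spec = GridSpec(**json.loads(fh.attrs["spec"]))
    return grids, labels, spec
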