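"""Synthetic fixtures for every pipeline stage.

Nothing here aims at physical realism: the pocket is a hollow atom shell, the
ligands are compact atom blobs or hand-verified SMILES with planted filter
violations, and the affinity oracle is contact counting with Gaussian noise.
Each generator is deterministic given (spec, seed) and returns an exact truth
table so downstream stages can be tested by equality where noise is zero.

The pocket shell places atoms exactly on voxel centers and its companion
``flood_params`` uses r_occ = 0.9·spacing, so the flooded voxel count has a
closed form (cavity_edge³).  The default pocket is sealed — any mouth would
let a flood escape into the exterior, destroying the closed form; an optional
``mouth`` carves one anyway for pose-sampling experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .featurize import ComplexFrame, GridSpec, rasterize
from .net import boltzmann_aggregate
from .proteomics import GroupDesign
from .structure import Atom, Conformer, FloodParams, Structure, flood_fill_site, generate_poses


# ---------------------------------------------------------------------------
# pockets

@dataclass
class PocketSpec:
    cavity_edge: int = 7        # voxels per side of the empty interior
    wall_thickness: int = 1     # voxels of shell atoms
    spacing: float = 1.0
    jitter: float = 0.03        # Å, small enough to keep occupancy exact
    mouth: bool = False

    def __post_init__(self):
        if self.cavity_edge < 0 or self.wall_thickness < 1:
            raise ValueError("invalid pocket spec")
        if self.jitter * np.sqrt(3) >= 0.1 * self.spacing:
            raise ValueError("jitter too large for exact occupancy")

    @property
    def expected_voxels(self) -> int:
        """Closed-form flooded voxel count for the sealed default."""
        return self.cavity_edge ** 3

    def flood_params(self) -> FloodParams:
        return FloodParams(
            spacing=self.spacing,
            r_occ=0.9 * self.spacing,
            max_radius=2.0 * (self.cavity_edge + 2 * self.wall_thickness) * self.spacing,
        )

    def cavity_center(self) -> np.ndarray:
        return np.full(3, self.cavity_edge * self.spacing / 2.0)


def make_pocket(seed: int = 0, spec: PocketSpec | None = None) -> Structure:
    """Hollow cubic shell with an empty cavity_edge³ interior; atoms on voxel
    centers (plus sub-resolution jitter), one atom per shell voxel."""
    spec = spec or PocketSpec()
    rng = np.random.default_rng(seed)
    c, w, sp = spec.cavity_edge, spec.wall_thickness, spec.spacing
    if c == 0:
        # degenerate: a solid block, every interior voxel occupied
        pass
    lo, hi = -w, c + w
    atoms = []
    n = 0
    mouth_col = (c // 2, c // 2) if spec.mouth else None
    for i in range(lo, hi):
        for j in range(lo, hi):
            for k in range(lo, hi):
                in_cavity = 0 <= i < c and 0 <= j < c and 0 <= k < c
                if in_cavity:
                    continue
                if mouth_col is not None and i >= c and (j, k) == mouth_col:
                    continue  # channel through the +x wall
                xyz = (np.array([i, j, k]) + 0.5) * sp
                xyz = xyz + rng.uniform(-spec.jitter, spec.jitter, 3)
                atoms.append(Atom(element="C", xyz=xyz, residue_id=f"A:{n}", chain_id="A"))
                n += 1
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# ligand blobs (point-cloud conformers for pose/scoring tests)

def make_ligand_blob(n_atoms: int, seed: int = 0, min_sep: float = 1.1) -> Conformer:
    """Compact random heavy-atom cloud with pairwise separation >= min_sep."""
    rng = np.random.default_rng(seed)
    radius = 1.1 * n_atoms ** (1 / 3)
    pts = []
    while len(pts) < n_atoms:
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    coords = np.array(pts) - np.mean(pts, axis=0)
    return Conformer(id=f"blob{seed}", elements=["C"] * n_atoms, coords=coords)


# ---------------------------------------------------------------------------
# filter-fixture library

# hand-verified SMILES pools; each violator breaks exactly one rule
CLEAN_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccc2[nH]ccc2c1",
    "Clc1ccc(cc1)C(=O)Nc1ccccn1", "COc1ccc(CCN)cc1",
    "O=C(NC1CC1)c1ccco1", "CC(=O)Nc1ccc(O)cc1",
    "OCC1OC(O)C(O)C(O)C1O", "Fc1ccc(cc1)S(=O)(=O)N1CCOCC1",
    "CCN(CC)C(=O)c1ccncc1", "Brc1cncc(c1)C#N",
    "CC1CCN(CC1)C(=O)COc1ccccc1", "N#Cc1ccc(cc1)N1CCNCC1",
    "CC(C)NCC(O)COc1ccccc1", "O=c1[nH]c2ccccc2[nH]1",
    "Cc1ccc(cc1)S(=O)(=O)N", "OC(=O)c1cccnc1",
    "c1ccc(nc1)N1CCOCC1", "CC(N)Cc1ccccc1",
]
SALT_SUFFIXES = [".[Na+]", ".Cl", ".[K+]", ".O"]  # stripped by standardization
VIOLATOR_SMILES = {
    "mw_below_min": ["CCO", "CC(C)=O", "OCCO", "CCN"],
    "mw_above_max": ["Ic1c(I)c(I)c(I)c(I)c1I", "Brc1c(I)c(I)c(I)c(I)c1I"],
    "too_many_chiral": ["CC(F)C(F)C(F)C(F)C(F)C(F)C(F)CO",
                        "OCC(O)C(O)C(O)C(O)C(O)C(O)C(O)CO"],
    "too_many_atoms": ["Cc1c(C)c(C)c(-c2c(C)c(C)c(-c3c(C)c(C)c(C)c(C)c3C)c(C)c2C)c(C)c1C"],
    "too_many_rotatable": ["CCOCCOCCOCCOCCOCCOCC", "CCCOCCOCCOCCOCCOCCOC"],
    "element_not_allowed": ["C[Si](C)(C)CCCO", "CC[Se]CC"],
    "pains": ["O=C1NC(=S)SC1=Cc1ccccc1", "O=C1NC(=S)SC1=Cc1ccc(C)cc1"],
    "parse_error": ["C1CC(", "C(C", "totally-not-smiles"],
}


def make_ligand_library(n: int, seed: int = 0, planted: dict | None = None,
                        n_salts: int = 0):
    """(records, truth): ``records`` are (id, smiles); ``truth`` maps id ->
    expected outcome ("pass" or the violated rule).  ``planted`` gives exact
    per-rule violator counts; remaining entries (and salt forms, which
    standardize away) pass everything."""
    if n < 1:
        raise ValueError("n >= 1")
    planted = dict(planted or {})
    unknown = set(planted) - set(VIOLATOR_SMILES)
    if unknown:
        raise ValueError(f"unknown rules: {sorted(unknown)}")
    n_bad = sum(planted.values())
    if n_bad + n_salts > n:
        raise ValueError("planted inventory exceeds n")
    rng = np.random.default_rng(seed)
    entries = []  # (truth, smiles)
    for rule, count in sorted(planted.items()):
        pool = VIOLATOR_SMILES[rule]
        for i in range(count):
            entries.append((rule, pool[i % len(pool)]))
    for i in range(n_salts):
        base = CLEAN_SMILES[i % len(CLEAN_SMILES)]
        entries.append(("pass", base + SALT_SUFFIXES[i % len(SALT_SUFFIXES)]))
    i = 0
    while len(entries) < n:
        entries.append(("pass", CLEAN_SMILES[i % len(CLEAN_SMILES)]))
        i += 1
    order = rng.permutation(len(entries))
    records, truth = [], {}
    for pos, j in enumerate(order):
        mol_id = f"syn-{pos:04d}"
        records.append((mol_id, entries[j][1]))
        truth[mol_id] = entries[j][0]
    return records, truth


# ---------------------------------------------------------------------------
# affinity oracle

@dataclass
class OracleParams:
    a0: float = 4.0             # baseline pK
    a1: float = 0.2             # pK per protein contact
    a2: float = 1.0             # pK penalty per clash pair
    contact_cutoff: float = 4.0
    clash_cutoff: float = 1.0
    noise_sd: float = 0.0       # Gaussian, pK units

    def __post_init__(self):
        if self.a1 <= 0 or self.a2 < 0 or self.noise_sd < 0:
            raise ValueError("require a1 > 0, a2 >= 0, noise_sd >= 0")


def oracle_affinity(pocket: Structure, pose_coords, params: OracleParams | None = None,
                    rng: np.random.Generator | None = None) -> float:
    """pK label = a0 + a1·(ligand heavy atoms with a pocket atom within
    contact_cutoff) − a2·(atom pairs closer than clash_cutoff) + noise."""
    params = params or OracleParams()
    pose = np.asarray(pose_coords, dtype=float)
    prot = pocket.heavy_coords()
    tree = cKDTree(prot)
    d, _ = tree.query(pose)
    contacts = int(np.sum(d <= params.contact_cutoff))
    clashes = sum(len(tree.query_ball_point(p, params.clash_cutoff)) for p in pose)
    label = params.a0 + params.a1 * contacts - params.a2 * clashes
    if params.noise_sd > 0:
        label += (rng or np.random.default_rng()).normal(0, params.noise_sd)
    return float(label)


# ---------------------------------------------------------------------------
# full screening dataset

@dataclass
class ScreenDataset:
    grids: np.ndarray           # (n, n_poses, C, e, e, e) uint8
    labels: np.ndarray          # (n,) aggregated noisy pK
    pose_oracle: np.ndarray     # (n, n_poses) noise-free per-pose labels
    ids: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    grid_spec: GridSpec


def make_screen_dataset(n_complexes: int, seed: int = 0,
                        params: OracleParams | None = None,
                        n_poses: int = 8, test_fraction: float = 0.2,
                        grid_spec: GridSpec | None = None,
                        beta: float = 1.0,
                        label_noise_sd: float = 0.1) -> ScreenDataset:
    """Pocket + random ligand blob + pose ensemble + oracle labels per complex.

    The complex label is the Boltzmann aggregate (same β the scorer uses) of
    noise-free per-pose oracle values plus Gaussian noise.  The train/test
    split is by compound — no pose leakage.
    """
    if n_complexes < 10:
        raise ValueError("n >= 10")
    params = params or OracleParams()
    spec = grid_spec or GridSpec(edge_voxels=16, spacing=1.0, scheme="entity")
    rng = np.random.default_rng(seed)
    pspec = PocketSpec(cavity_edge=7)
    center_shift = pspec.cavity_center()
    all_grids, labels, pose_vals, ids = [], [], [], []
    for i in range(n_complexes):
        pocket = make_pocket(seed=int(rng.integers(2 ** 31)), spec=pspec)
        n_atoms = int(rng.integers(4, 15))
        lig = make_ligand_blob(n_atoms, seed=int(rng.integers(2 ** 31)))
        site = flood_fill_site(pocket, center_shift, pspec.flood_params())
        ens = generate_poses(site, lig, protein=pocket, n=n_poses,
                             seed=int(rng.integers(2 ** 31)),
                             clash_cutoff=params.clash_cutoff)
        gset, oset = [], []
        for p in range(n_poses):
            coords = ens.pose_coords(p)
            oset.append(oracle_affinity(pocket, coords, params))
            frame = ComplexFrame(pocket.elements, pocket.coords - site.center,
                                 lig.elements, coords - site.center)
            gset.append(rasterize(frame, spec))
        all_grids.append(np.stack(gset))
        pose_vals.append(oset)
        y = boltzmann_aggregate(np.array(oset), beta)
        if label_noise_sd > 0:
            y += rng.normal(0, label_noise_sd)
        labels.append(y)
        ids.append(f"cpx-{i:04d}")
    order = rng.permutation(n_complexes)
    n_test = max(1, int(round(test_fraction * n_complexes)))
    return ScreenDataset(
        grids=np.stack(all_grids),
        labels=np.array(labels),
        pose_oracle=np.array(pose_vals),
        ids=ids,
        train_idx=np.sort(order[n_test:]),
        test_idx=np.sort(order[:n_test]),
        grid_spec=spec,
    )


# ---------------------------------------------------------------------------
# TMT fixture

def make_tmt_fixture(n_proteins: int = 1000, n_planted: int = 50,
                     planted_lfc: float = -1.0, within_sd: float = 0.1,
                     seed: int = 0, loading_factors=None):
    """10-plex reporter intensity matrix: 3 −Tet + 3 +Tet + 4 unused channels.

    Log-normal intensities; the planted log2 effect is applied to the +Tet
    group; per-channel loading factors emulate unequal sample loading and are
    removed exactly by channel mean-normalization.

    Returns (matrix, design, truth) with truth = list of planted protein ids.
    """
    if n_planted > n_proteins:
        raise ValueError("planted effects exceed n_proteins")
    rng = np.random.default_rng(seed)
    channels = ([f"ctrl_{i}" for i in range(1, 4)] + [f"tet_{i}" for i in range(1, 4)]
                + [f"extra_{i}" for i in range(1, 5)])
    if loading_factors is None:
        loading_factors = rng.uniform(0.5, 2.0, len(channels))
    base = rng.normal(20.0, 1.5, n_proteins)                    # log2 abundance
    planted_ids = [f"P{i:04d}" for i in range(n_planted)]
    log2 = base[:, None] + rng.normal(0, within_sd, (n_proteins, len(channels)))
    tet_cols = [3, 4, 5]
    log2[:n_planted, tet_cols] += planted_lfc
    m = 2.0 ** log2
    m *= np.asarray(loading_factors)[None, :]
    df = pd.DataFrame(m, index=[f"P{i:04d}" for i in range(n_proteins)], columns=channels)
    design = GroupDesign(control=["ctrl_1", "ctrl_2", "ctrl_3"],
                         treatment=["tet_1", "tet_2", "tet_3"])
    return df, design, planted_ids
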