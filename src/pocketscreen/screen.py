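"""Library screening, ranking, top-K and diverse-subset selection.

Each compound conformer gets an ensemble of rigid poses inside the site, each
pose is voxelized and scored by the trained model, and the per-pose scores are
Boltzmann-averaged into one affinity (higher = better, pKi scale).  Compounds
are ranked by that score (ties broken by id), the top K (default 5000) are
retained, and a structurally diverse subset (default 89) is chosen by greedy
max-min selection on Tanimoto distances over Morgan fingerprints (radius 2,
2048 bits), seeded at the top-ranked candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import GridSpec, ComplexFrame, rasterize
from .net import ScoringModel
from .structure import Conformer, PocketSite, Structure, generate_poses


@dataclass
class RankedRow:
    id: str
    score: float
    rank: int


def score_library(model: ScoringModel, library: list[Conformer], site: PocketSite,
                  protein: Structure | None = None, n_poses: int = 64, seed: int = 0,
                  clash_cutoff: float = 2.2) -> list[RankedRow]:
    """Pose → grid → aggregate score for every compound; returns a table
    sorted descending by score (ties by id, ascending).  Deterministic per
    seed; compounds whose pose sampling fails are skipped."""
    spec = model.grid_spec
    prot_el = protein.elements if protein is not None else []
    prot_xyz = (protein.coords if protein is not None else np.zeros((0, 3)))
    scored = []
    for i, lig in enumerate(library):
        sub_seed = (seed * 1_000_003 + i * 7919) % (2 ** 31)
        try:
            ens = generate_poses(site, lig, protein=protein, n=n_poses,
                                 seed=sub_seed, clash_cutoff=clash_cutoff)
        except Exception:
            continue
        grids = np.stack([
            rasterize(ComplexFrame(prot_el, prot_xyz - site.center, lig.elements,
                                   ens.pose_coords(p) - site.center), spec)
            for p in range(ens.n_poses)
        ])
        agg, _ = model.predict_affinity(grids)
        scored.append((lig.id, float(agg)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [RankedRow(id=c, score=s, rank=r + 1) for r, (c, s) in enumerate(scored)]


def top_k(table: list[RankedRow], k: int = 5000) -> list[RankedRow]:
    if k < 0:
        raise ValueError("k must be >= 0")
    return table[:k]


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def tanimoto_distance_matrix(fps) -> np.ndarray:
    from rdkit import DataStructs

    n = len(fps)
    D = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], list(fps[i + 1:]))
            D[i, i + 1:] = 1.0 - np.array(sims)
    return D + D.T


def pick_diverse(candidates: list[tuple[str, str]], k: int = 89,
                 radius: int = 2, n_bits: int = 2048,
                 dist_matrix: np.ndarray | None = None) -> list[str]:
    """Greedy max-min diversity selection.

    ``candidates``: (id, smiles) in rank order — the first (top-ranked) entry
    seeds the selection.  Each subsequent pick maximizes the minimum Tanimoto
    distance to the already-selected set; ties broken by id (lexicographic).
    A precomputed distance matrix may be passed instead of SMILES.
    """
    if not candidates:
        raise ValueError("need >= 1 candidate")
    ids = [c[0] for c in candidates]
    if dist_matrix is None:
        fps = [morgan_fingerprint(smi, radius, n_bits) for _, smi in candidates]
        dist_matrix = tanimoto_distance_matrix(fps)
    n = len(ids)
    k = min(k, n)
    selected = [0]
    min_dist = dist_matrix[0].copy()
    min_dist[0] = -np.inf
    while len(selected) < k:
        best = None
        for j in range(n):
            if j in selected:
                continue
            cand = (min_dist[j], ids[j])
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = (cand[0], cand[1], j)
        j = best[2]
        selected.append(j)
        min_dist = np.minimum(min_dist, dist_matrix[j])
    return [ids[j] for j in selected]


def write_ranked_csv(path, table: list[RankedRow]) -> None:
    with open(path, "w") as fh:
        fh.write("id,score,rank\n")
        for row in table:
            fh.write(f"{row.id},{row.score:.6f},{row.rank}\n")
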