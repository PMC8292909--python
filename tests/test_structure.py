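"""Flood-fill site definition and rigid-body pose sampling."""

import numpy as np
import pytest

from pocketscreen import synthetic
from pocketscreen.structure import (
    Atom, FloodParams, PocketTooSmallError, SeedBuriedError, Structure,
    flood_fill_site, generate_poses, site_from_residues,
)


def brute_force_flood(coords, seed_xyz, params: FloodParams, extent=30):
    """Independent reachability oracle: classify every voxel in a bounding
    region by direct distance computation, then BFS over the boolean lattice."""
    sp = params.spacing
    seed_idx = tuple(int(np.floor(v / sp)) for v in seed_xyz)
    lo = [s - extent for s in seed_idx]
    rng_axes = [np.arange(l, l + 2 * extent + 1) for l in lo]
    ii, jj, kk = np.meshgrid(*rng_axes, indexing="ij")
    centers = (np.stack([ii, jj, kk], axis=-1) + 0.5) * sp
    diff = centers[..., None, :] - np.asarray(coords)[None, None, None, :, :]
    mind = np.sqrt((diff ** 2).sum(-1)).min(-1)
    free = mind >= params.r_occ
    seed_center = (np.array(seed_idx) + 0.5) * sp
    in_range = np.linalg.norm(centers - seed_center, axis=-1) <= params.max_radius
    ok = free & in_range
    start = tuple(s - l for s, l in zip(seed_idx, lo))
    if not ok[start]:
        return None
    seen = {start}
    stack = [start]
    shape = ok.shape
    while stack:
        cur = stack.pop()
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if all(0 <= nxt[a] < shape[a] for a in range(3)) and nxt not in seen and ok[nxt]:
                seen.add(nxt)
                stack.append(nxt)
    return {tuple(np.array(v) + lo) for v in seen}


def hollow_box():
    """Atoms on the faces of a 7x7x7 Å shell, empty 3x3x3 voxel interior.
    Atom coordinates sit on voxel centers (half-integer grid)."""
    atoms = []
    for i in range(-2, 3):
        for j in range(-2, 3):
            for k in range(-2, 3):
                if max(abs(i), abs(j), abs(k)) == 2:
                    atoms.append(Atom("C", np.array([i + 0.5, j + 0.5, k + 0.5])))
    return Structure(atoms=atoms)


BOX_PARAMS = FloodParams(spacing=1.0, r_occ=0.9, max_radius=10.0)


class TestFloodFill:
    def test_hollow_box_27_voxels(self):
        s = hollow_box()
        site = flood_fill_site(s, [0.5, 0.5, 0.5], BOX_PARAMS)
        assert len(site.voxels) == 27
        oracle = brute_force_flood(s.coords, [0.5, 0.5, 0.5], BOX_PARAMS, extent=8)
        assert {tuple(v) for v in site.voxels} == oracle

    def test_max_radius_zero_single_voxel(self):
        s = hollow_box()
        site = flood_fill_site(s, [0.5, 0.5, 0.5],
                               FloodParams(spacing=1.0, r_occ=0.9, max_radius=0.0))
        assert len(site.voxels) == 1

    def test_subvoxel_seed_shift_same_voxels(self):
        s = hollow_box()
        a = flood_fill_site(s, [0.1, 0.1, 0.1], BOX_PARAMS)
        b = flood_fill_site(s, [0.5, 0.9, 0.3], BOX_PARAMS)
        assert np.array_equal(a.voxels, b.voxels)

    def test_buried_seed_errors(self):
        s = hollow_box()
        with pytest.raises(SeedBuriedError):
            flood_fill_site(s, [2.5, 0.5, 0.5], BOX_PARAMS)  # inside the wall

    def test_empty_structure_errors(self):
        with pytest.raises(ValueError):
            flood_fill_site(Structure(atoms=[]), [0, 0, 0])

    @pytest.mark.parametrize("case_seed", range(10))
    def test_matches_brute_force_on_random_lattices(self, case_seed):
        rng = np.random.default_rng(100 + case_seed)
        n_atoms = rng.integers(10, 60)
        coords = rng.uniform(-8, 8, (n_atoms, 3))
        atoms = [Atom("C", c) for c in coords]
        params = FloodParams(spacing=1.0, r_occ=float(rng.uniform(1.0, 2.0)),
                             max_radius=float(rng.uniform(3.0, 8.0)))
        seed_xyz = rng.uniform(-4, 4, 3)
        oracle = brute_force_flood(coords, seed_xyz, params, extent=12)
        if oracle is None:
            with pytest.raises(SeedBuriedError):
                flood_fill_site(Structure(atoms=atoms), seed_xyz, params)
        else:
            site = flood_fill_site(Structure(atoms=atoms), seed_xyz, params)
            assert {tuple(v) for v in site.voxels} == oracle

    def test_integer_translation_equivariance(self):
        s = hollow_box()
        a = flood_fill_site(s, [0.5, 0.5, 0.5], BOX_PARAMS)
        shift = np.array([3.0, -2.0, 5.0])  # integer multiples of the spacing
        s2 = Structure(atoms=[Atom("C", at.xyz + shift) for at in s.atoms])
        b = flood_fill_site(s2, np.array([0.5, 0.5, 0.5]) + shift, BOX_PARAMS)
        assert np.allclose(a.voxel_centers() + shift, b.voxel_centers())


class TestSiteFromResidues:
    def test_single_atom_residue(self):
        atoms = [Atom("C", np.array([0.0, 0.0, 0.0]), residue_id="A:1")]
        site = site_from_residues(Structure(atoms=atoms), ["A:1"],
                                  FloodParams(spacing=1.0, r_occ=1.2, max_radius=2.0))
        assert len(site.voxels) >= 1
        assert "A:1" in site.residues

    def test_duplicates_deduplicated(self, pocket_and_site):
        spec, pocket, _ = pocket_and_site
        params = spec.flood_params()
        ids = ["A:0", "A:1", "A:2"]
        a = site_from_residues(pocket, ids, params)
        b = site_from_residues(pocket, ids + ids, params)
        assert np.array_equal(a.voxels, b.voxels)

    def test_missing_residue_listed(self, pocket_and_site):
        _, pocket, _ = pocket_and_site
        with pytest.raises(KeyError, match="Z:999"):
            site_from_residues(pocket, ["A:0", "Z:999"])

    def test_pocket_residues_recovered(self, pocket_and_site):
        # analogue of seeding from a binding-site residue list: most of the
        # requested (cavity-lining) residues must end up in the site
        spec, pocket, site = pocket_and_site
        wanted = list(site.residues)[:25]
        s2 = site_from_residues(pocket, wanted, spec.flood_params())
        assert len(set(wanted) & s2.residues) >= 0.8 * len(wanted)


class TestPoses:
    def test_exact_count_and_clash_free(self, pocket_and_site):
        _, pocket, site = pocket_and_site
        lig = synthetic.make_ligand_blob(8, seed=2)
        ens = generate_poses(site, lig, protein=pocket, n=64, seed=7, clash_cutoff=1.0)
        assert ens.n_poses == 64
        prot = pocket.heavy_coords()
        for p in range(64):
            d = np.linalg.norm(ens.pose_coords(p)[:, None] - prot[None], axis=-1)
            assert d.min() >= 1.0

    def test_seeded_determinism(self, pocket_and_site):
        _, pocket, site = pocket_and_site
        lig = synthetic.make_ligand_blob(8, seed=2)
        a = generate_poses(site, lig, protein=pocket, n=16, seed=9, clash_cutoff=1.0)
        b = generate_poses(site, lig, protein=pocket, n=16, seed=9, clash_cutoff=1.0)
        assert np.array_equal(a.rotations, b.rotations)
        assert np.array_equal(a.translations, b.translations)

    def test_rigid_transform_preserves_distances(self, pocket_and_site):
        _, pocket, site = pocket_and_site
        lig = synthetic.make_ligand_blob(10, seed=4)
        ens = generate_poses(site, lig, protein=pocket, n=8, seed=1, clash_cutoff=1.0)
        ref = np.linalg.norm(lig.coords[:, None] - lig.coords[None], axis=-1)
        for p in range(8):
            c = ens.pose_coords(p)
            d = np.linalg.norm(c[:, None] - c[None], axis=-1)
            assert np.abs(d - ref).max() < 1e-6

    def test_acceptance_invariant_to_atom_order(self, pocket_and_site):
        _, pocket, site = pocket_and_site
        lig = synthetic.make_ligand_blob(8, seed=2)
        perm = np.random.default_rng(0).permutation(8)
        from pocketscreen.structure import Conformer
        lig2 = Conformer(id=lig.id, elements=[lig.elements[i] for i in perm],
                         coords=lig.coords[perm])
        a = generate_poses(site, lig, protein=pocket, n=8, seed=3, clash_cutoff=1.0)
        b = generate_poses(site, lig2, protein=pocket, n=8, seed=3, clash_cutoff=1.0)
        assert np.array_equal(a.rotations, b.rotations)
        assert np.array_equal(a.translations, b.translations)

    def test_pocket_too_small(self, pocket_and_site):
        _, pocket, site = pocket_and_site
        huge = synthetic.make_ligand_blob(40, seed=1)
        with pytest.raises(PocketTooSmallError):
            generate_poses(site, huge, protein=pocket, n=4, seed=0,
                           clash_cutoff=3.0, max_attempts_factor=50)
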