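"""Water picking, hydrogen-bond enumeration, histidine tautomer rules."""

import numpy as np
import pytest

from rsmap import (DensityMap, FilterParams, ImagingModel, assess_his_tautomer,
                   enumerate_hbonds, pick_waters, synthesize_potential)
from rsmap.model import AtomRecord, StructureModel, classify_atoms, derive_bonds


def _model(atom_specs):
    """atom_specs: (name, element, resname, seq, chain, xyz)."""
    atoms = [AtomRecord(i + 1, n, e, r, s, c, xyz)
             for i, (n, e, r, s, c, xyz) in enumerate(atom_specs)]
    m = StructureModel(atoms)
    classify_atoms(m)
    derive_bonds(m)
    return m


# --- water picking ---------------------------------------------------------

def test_constant_map_yields_no_waters(small_model):
    m = DensityMap(np.ones((16, 16, 16)), 1.0)
    assert pick_waters(m, small_model) == []


def test_planted_waters_recovered(helix_model, helix_selfmap):
    # plant strong Gaussian peaks at plausible water positions + noise
    clean, im = helix_selfmap
    rng = np.random.default_rng(17)
    polar = [a for a, t in zip(helix_model.atoms, helix_model.tags())
             if a.element in ("N", "O") and a.residue_name != "HOH"]
    planted = []
    base = clean.values.std()
    vals = clean.values.copy()
    tries = 0
    while len(planted) < 10 and tries < 4000:
        tries += 1
        host = polar[rng.integers(len(polar))]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = np.asarray(host.xyz) + rng.uniform(2.6, 3.2) * u
        if np.min(np.linalg.norm(helix_model.xyz - p, axis=1)) < 2.5:
            continue
        if planted and np.min(np.linalg.norm(np.array(planted) - p, axis=1)) < 3.0:
            continue
        g = clean.grid_coords(p)[0]
        if np.any(g < 3) or np.any(g >= np.array(clean.shape) - 3):
            continue
        zz, yy, xx = np.indices(clean.shape)
        d2 = ((zz - g[0]) ** 2 + (yy - g[1]) ** 2 + (xx - g[2]) ** 2) * clean.voxel ** 2
        vals += 5.0 * base * np.exp(-d2 / (2 * 0.4 ** 2))
        planted.append(p)
    assert len(planted) == 10
    noisy = DensityMap(vals + rng.normal(0, 0.3 * base, vals.shape),
                       clean.voxel, tuple(clean.origin))
    sites = pick_waters(noisy, helix_model, threshold_sigma=3.0)
    found = 0
    for p in planted:
        if any(np.linalg.norm(s.position - p) < 0.5 for s in sites):
            found += 1
    assert found >= 9
    # no spurious strong sites far from every planted peak
    spurious = [s for s in sites
                if all(np.linalg.norm(s.position - p) > 1.0 for p in planted)]
    assert len(spurious) == 0


def test_peak_too_close_to_model_rejected():
    model = _model([("N", "N", "ALA", 1, "A", (8.0, 8.0, 8.0)),
                    ("CA", "C", "ALA", 1, "A", (9.46, 8.0, 8.0)),
                    ("C", "C", "ALA", 1, "A", (10.0, 9.4, 8.0)),
                    ("O", "O", "ALA", 1, "A", (9.3, 10.4, 8.0))])
    m = DensityMap(np.zeros((16, 16, 16)), 1.0)
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 0.1, m.shape)
    # peak 1.5 Å from the backbone N → occupied, must be rejected
    g = m.grid_coords(np.array([6.5, 8.0, 8.0]))[0]
    vals[int(g[0]), int(g[1]), int(g[2])] = 5.0
    noisy = DensityMap(vals, 1.0)
    sites = pick_waters(noisy, model, threshold_sigma=1.8)
    assert all(np.linalg.norm(s.position - [6.5, 8.0, 8.0]) > 0.9 for s in sites)


def test_water_positions_shift_with_whole_voxel_translation(helix_model, helix_selfmap):
    clean, im = helix_selfmap
    rng = np.random.default_rng(3)
    noisy_vals = clean.values + rng.normal(0, 0.2 * clean.values.std(), clean.shape)
    m1 = DensityMap(noisy_vals, clean.voxel, tuple(clean.origin))
    shift_vox = np.array([2, -1, 3])  # z, y, x voxels
    shift_xyz = shift_vox[::-1] * clean.voxel  # Å, (x, y, z)
    m2 = DensityMap(np.roll(noisy_vals, shift_vox, axis=(0, 1, 2)),
                    clean.voxel, tuple(clean.origin))
    moved = helix_model.with_xyz(helix_model.xyz + shift_xyz)
    s1 = pick_waters(m1, helix_model, 2.5)
    s2 = pick_waters(m2, moved, 2.5)
    assert len(s1) == len(s2)
    if s1:
        p1 = sorted(map(tuple, np.round([s.position for s in s1], 3)))
        p2 = sorted(map(tuple, np.round([s.position - shift_xyz for s in s2], 3)))
        assert np.allclose(p1, p2, atol=clean.voxel / 2)


# --- hydrogen bonds --------------------------------------------------------

def test_two_waters_heavy_atom_criterion():
    pair = _model([("O", "O", "HOH", 1, "W", (0.0, 0.0, 0.0)),
                   ("O", "O", "HOH", 2, "W", (2.8, 0.0, 0.0))])
    bonds = enumerate_hbonds(pair)
    # O↔O found once in each donor direction; count unique pairs
    keys = {frozenset((b.donor_index, b.acceptor_index)) for b in bonds}
    assert len(keys) == 1
    far = _model([("O", "O", "HOH", 1, "W", (0.0, 0.0, 0.0)),
                  ("O", "O", "HOH", 2, "W", (4.0, 0.0, 0.0))])
    assert enumerate_hbonds(far) == []


def test_strand_pair_nh_oc_bonds_found():
    # an idealized two-strand ladder: N-H donors facing C=O acceptors at 2.9 Å
    specs = []
    for i in range(4):
        x = 3.5 * i
        specs += [("N", "N", "GLY", i + 1, "A", (x, 0.0, 0.0)),
                  ("H", "H", "GLY", i + 1, "A", (x, 1.0, 0.0)),
                  ("CA", "C", "GLY", i + 1, "A", (x + 1.2, -0.8, 0.0)),
                  ("C", "C", "GLY", i + 1, "A", (x + 2.3, 0.2, 0.0)),
                  ("O", "O", "GLY", i + 1, "A", (x + 2.3, 1.42, 0.0))]
    for i in range(4):
        x = 3.5 * i
        y = 3.9
        specs += [("N", "N", "GLY", i + 1, "B", (x + 2.3, y, 0.0)),
                  ("H", "H", "GLY", i + 1, "B", (x + 2.3, y - 1.0, 0.0)),
                  ("CA", "C", "GLY", i + 1, "B", (x + 1.2, y + 0.9, 0.0)),
                  ("C", "C", "GLY", i + 1, "B", (x, y + 0.1, 0.0)),
                  ("O", "O", "GLY", i + 1, "B", (x, y - 1.1, 0.0))]
    m = _model(specs)
    bonds = enumerate_hbonds(m, dmax=3.5, angle_min=90.0)
    inter = [b for b in bonds
             if m.atoms[b.donor_index].chain != m.atoms[b.acceptor_index].chain]
    # hand enumeration: every B-chain N-H faces an A-chain C=O at 2.48 Å
    # and every A-chain N-H faces a B-chain O where the ladder aligns
    donors_b = {(m.atoms[b.donor_index].chain, m.atoms[b.donor_index].residue_seq)
                for b in inter if m.atoms[b.donor_index].chain == "B"}
    assert donors_b == {("B", i + 1) for i in range(4)}


def test_hbond_count_invariant_under_rigid_motion(helix_model):
    theta = 0.7
    R = np.array([[1, 0, 0],
                  [0, np.cos(theta), -np.sin(theta)],
                  [0, np.sin(theta), np.cos(theta)]])
    moved = helix_model.with_xyz(helix_model.xyz @ R.T + np.array([1.0, 2.0, -3.0]))
    moved.bonds = helix_model.bonds
    b1 = enumerate_hbonds(helix_model)
    b2 = enumerate_hbonds(moved)
    assert len(b1) == len(b2)
    assert {(b.donor_index, b.acceptor_index) for b in b1} == \
        {(b.donor_index, b.acceptor_index) for b2_ in [b2] for b in b2_}


# --- histidine tautomers ---------------------------------------------------

HIS_CORE = [("CG", "C", "HIS", 10, "A", (0.0, 0.0, 0.0)),
            ("ND1", "N", "HIS", 10, "A", (1.19, 0.71, 0.0)),
            ("CD2", "C", "HIS", 10, "A", (-0.86, 1.05, 0.0)),
            ("CE1", "C", "HIS", 10, "A", (0.88, 2.02, 0.0)),
            ("NE2", "N", "HIS", 10, "A", (-0.45, 2.33, 0.0))]


def test_isolated_his_is_ambiguous():
    m = _model(HIS_CORE)
    calls = assess_his_tautomer(m)
    assert len(calls) == 1
    assert calls[0].call == "ambiguous"
    assert calls[0].rationale == set()


def test_no_histidine_returns_empty(small_model):
    no_his = StructureModel([a for a in small_model.atoms
                             if a.residue_name != "HIS"])
    assert assess_his_tautomer(no_his) == []


def test_carboxylate_near_nd1_gives_n1():
    # ASP OD1 2.8 Å from ND1 → ND1 protonated → N1 tautomer, rationale R1
    nd1 = np.array([1.19, 0.71, 0.0])
    m = _model(HIS_CORE + [("OD1", "O", "ASP", 3, "A", tuple(nd1 + [2.8, 0, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N1"
    assert calls[0].rationale == {"R1"}


def test_metal_on_ne2_gives_n1():
    ne2 = np.array([-0.45, 2.33, 0.0])
    m = _model(HIS_CORE + [("ZN", "Zn", "ZN", 90, "A", tuple(ne2 + [0, 2.2, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N1"
    assert calls[0].rationale == {"R2"}


def test_carbonyl_near_ne2_gives_n3():
    # an unambiguous acceptor facing NE2 → NE2 donates → H at N_ε → N3
    ne2 = np.array([-0.45, 2.33, 0.0])
    m = _model(HIS_CORE + [("O", "O", "GLY", 3, "A", tuple(ne2 + [0, 2.9, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N3"
    assert calls[0].rationale == {"R3"}


def test_amide_near_nd1_gives_n3():
    # an unambiguous donor facing ND1 → ND1 accepts → H at N_ε → N3
    nd1 = np.array([1.19, 0.71, 0.0])
    m = _model(HIS_CORE + [("N", "N", "GLY", 3, "A", tuple(nd1 + [2.9, 0, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N3"
    assert calls[0].rationale == {"R3"}


def test_clash_at_nd1_gives_n3():
    nd1 = np.array([1.19, 0.71, 0.0])
    m = _model(HIS_CORE + [("CB", "C", "ALA", 3, "A", tuple(nd1 + [2.5, 0, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N3"
    assert calls[0].rationale == {"R4"}


def test_conflicting_rules_return_ambiguous():
    # same-precedence conflicting evidence at one nitrogen → ambiguous
    nd1 = np.array([1.19, 0.71, 0.0])
    m = _model(HIS_CORE +
               [("O", "O", "GLY", 3, "A", tuple(nd1 + [2.9, 0, 0])),     # R3: protonate
                ("N", "N", "GLY", 4, "A", tuple(nd1 + [0, -2.9, 0]))])   # R3: deprotonate
    calls = assess_his_tautomer(m)
    assert calls[0].call == "ambiguous"


def test_rule_pairs_consistent_combinations():
    nd1 = np.array([1.19, 0.71, 0.0])
    ne2 = np.array([-0.45, 2.33, 0.0])
    # R1 at ND1 (protonate) + R4 clash at NE2 (deprotonate) → consistent N1
    m = _model(HIS_CORE +
               [("OD2", "O", "ASP", 3, "A", tuple(nd1 + [2.7, 0, 0])),
                ("CB", "C", "ALA", 4, "A", tuple(ne2 + [0, 2.6, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call == "N1"
    assert calls[0].rationale == {"R1", "R4"}
    # R1 at both nitrogens → both protonated → HisH+
    m2 = _model(HIS_CORE +
                [("OD2", "O", "ASP", 3, "A", tuple(nd1 + [2.7, 0, 0])),
                 ("OE1", "O", "GLU", 4, "A", tuple(ne2 + [0, 2.7, 0]))])
    assert assess_his_tautomer(m2)[0].call == "HisH+"
    # R1 protonate ND1 vs R3-donor deprotonate ND1 → precedence picks R1
    m3 = _model(HIS_CORE +
                [("OD2", "O", "ASP", 3, "A", tuple(nd1 + [2.7, 0, 0])),
                 ("N", "N", "GLY", 4, "A", tuple(nd1 + [0, -2.9, 0]))])
    assert assess_his_tautomer(m3)[0].call == "N1"


def test_hish_never_from_clash_evidence_alone():
    nd1 = np.array([1.19, 0.71, 0.0])
    ne2 = np.array([-0.45, 2.33, 0.0])
    m = _model(HIS_CORE +
               [("CB", "C", "ALA", 3, "A", tuple(nd1 + [2.5, 0, 0])),
                ("CB", "C", "ALA", 4, "A", tuple(ne2 + [0, 2.5, 0]))])
    calls = assess_his_tautomer(m)
    assert calls[0].call != "HisH+"  # both-deprotonated is contradictory
    assert calls[0].call == "ambiguous"
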