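"""Structure comparison: pairing, rotamer inversion, outliers, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsmap import (compare_models, deviation_stats, flag_peptide_flips,
                   invert_symmetric_rotamers, pair_atoms, partition_errors,
                   perturb_model)
from rsmap.model import AtomRecord, StructureModel


def test_pairing_self_is_total(helix_model):
    p = pair_atoms(helix_model, helix_model)
    n_heavy = int((helix_model.elements != "H").sum())
    assert len(p) == n_heavy
    assert not p.unmatched_a and not p.unmatched_b


def test_pairing_with_missing_residue(helix_model):
    keep = [a for a in helix_model.atoms if a.residue_seq != 5 or a.chain != "A"]
    truncated = StructureModel(keep)
    p = pair_atoms(helix_model, truncated)
    removed_heavy = sum(1 for a in helix_model.atoms
                        if a.residue_seq == 5 and a.chain == "A" and a.element != "H")
    assert len(p.unmatched_a) == removed_heavy
    assert not p.unmatched_b


def test_pairing_invariant_to_atom_order(helix_model):
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(helix_model))
    scrambled = StructureModel([helix_model.atoms[i] for i in perm])
    p1 = pair_atoms(helix_model, helix_model)
    p2 = pair_atoms(helix_model, scrambled)
    # same set of matched A-side atoms, mapped to the same atom identities
    def ident(m, j):
        a = m.atoms[j]
        return (a.chain, a.residue_seq, a.name)
    m1 = {i: ident(helix_model, j) for i, j in p1.pairs}
    m2 = {i: ident(scrambled, j) for i, j in p2.pairs}
    assert m1 == m2


def test_pairing_include_h_flag(helix_model):
    ph = pair_atoms(helix_model, helix_model, include_h=True)
    assert len(ph) == len(helix_model)
    with pytest.raises(ValueError):
        empty = StructureModel([AtomRecord(1, "CA", "C", "ALA", 99, "Z", (0, 0, 0))])
        pair_atoms(helix_model, empty)


def test_rotamer_inversion_label_swap_resolves_exactly(helix_model):
    # exchange OD1/OD2 labels of one ASP: post-swap deviation must vanish
    atoms = list(helix_model.atoms)
    idx = {a.name: i for i, a in enumerate(atoms)
           if a.residue_name == "ASP" and a.residue_seq == 4}
    i1, i2 = idx["OD1"], idx["OD2"]
    import dataclasses
    swapped = list(atoms)
    swapped[i1] = dataclasses.replace(atoms[i1], xyz=atoms[i2].xyz)
    swapped[i2] = dataclasses.replace(atoms[i2], xyz=atoms[i1].xyz)
    model_b = StructureModel(swapped)
    p = pair_atoms(helix_model, model_b)
    stats_pre = deviation_stats(p, helix_model, model_b, "all")
    p2 = invert_symmetric_rotamers(p, helix_model, model_b)
    assert len(p2.swapped_residues) == 1
    assert p2.swapped_residues[0][1] == 4
    stats_post = deviation_stats(p2, helix_model, model_b, "all")
    assert stats_post.rmsd < 1e-9
    assert stats_post.rmsd <= stats_pre.rmsd


def test_rotamer_inversion_identity_no_swaps(helix_model):
    p = pair_atoms(helix_model, helix_model)
    p2 = invert_symmetric_rotamers(p, helix_model, helix_model)
    assert p2.swapped_residues == []


def test_rotamer_inversion_never_raises_rmsd(helix_model):
    for seed in range(5):
        pb, _ = perturb_model(helix_model, 0.8, seed=seed)
        p = pair_atoms(helix_model, pb)
        pre = deviation_stats(p, helix_model, pb, "all").rmsd
        p2 = invert_symmetric_rotamers(p, helix_model, pb)
        post = deviation_stats(p2, helix_model, pb, "all").rmsd
        assert post <= pre + 1e-12


def test_deviation_stats_identity(helix_model):
    p = pair_atoms(helix_model, helix_model)
    r = deviation_stats(p, helix_model, helix_model, "all")
    assert r.rmsd == 0.0
    assert r.outlier_fraction == 0.0


def test_outlier_rule_hand_quartiles():
    # 9 pairs at 0.1 Å + 1 pair at 5 Å: the single big one is the sole outlier
    atoms_a, atoms_b = [], []
    for i in range(10):
        off = 5.0 if i == 9 else 0.1
        atoms_a.append(AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A",
                                  (float(3 * i), 0.0, 0.0)))
        atoms_b.append(AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A",
                                  (float(3 * i) + off, 0.0, 0.0)))
    ma, mb = StructureModel(atoms_a), StructureModel(atoms_b)
    p = pair_atoms(ma, mb)
    r = deviation_stats(p, ma, mb, "all")
    assert int(r.outlier_mask.sum()) == 1
    assert r.outlier_fraction == pytest.approx(0.1)
    assert r.rmsd_clean == pytest.approx(0.1, rel=1e-9)
    assert r.rmsd_outliers == pytest.approx(5.0, rel=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=5, max_value=200), st.integers(min_value=0, max_value=10_000))
def test_outlier_rule_matches_bruteforce(n, seed):
    rng = np.random.default_rng(seed)
    dev = np.abs(rng.normal(0.3, 0.2, n)) + rng.exponential(0.2, n)
    q1 = np.quantile(dev, 0.25)
    q3 = np.quantile(dev, 0.75)
    expect = dev > q3 + 1.5 * (q3 - q1)
    atoms_a = [AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A",
                          (float(5 * i), 0.0, 0.0)) for i in range(n)]
    atoms_b = [AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A",
                          (float(5 * i), float(dev[i]), 0.0)) for i in range(n)]
    ma, mb = StructureModel(atoms_a), StructureModel(atoms_b)
    r = deviation_stats(pair_atoms(ma, mb), ma, mb, "all")
    assert np.array_equal(r.outlier_mask, expect)


def test_rmsd_symmetric(helix_model):
    pb, _ = perturb_model(helix_model, 0.5, seed=4)
    r_ab = deviation_stats(pair_atoms(helix_model, pb), helix_model, pb, "all")
    r_ba = deviation_stats(pair_atoms(pb, helix_model), pb, helix_model, "all")
    assert r_ab.rmsd == pytest.approx(r_ba.rmsd, rel=1e-12)


def test_subsets_use_own_quartiles(helix_model):
    pb, _ = perturb_model(helix_model, 0.3, outlier_fraction=0.1,
                          outlier_scale=2.0, seed=8)
    p = pair_atoms(helix_model, pb)
    r_all = deviation_stats(p, helix_model, pb, "all")
    r_bb = deviation_stats(p, helix_model, pb, "backbone")
    r_ca = deviation_stats(p, helix_model, pb, "ca")
    assert r_ca.n_pairs < r_bb.n_pairs < r_all.n_pairs
    for r in (r_all, r_bb, r_ca):
        assert r.rmsd_clean <= r.rmsd


def test_partition_errors_printed_reference_values():
    e_a, e_b = partition_errors(0.35, 1.56, 2.8)
    assert round(e_a, 2) == 0.17
    assert round(e_b, 2) == 0.31
    # identities
    assert e_a ** 2 + e_b ** 2 == pytest.approx(0.35 ** 2, rel=1e-12)
    assert e_a / e_b == pytest.approx(1.56 / 2.8, rel=1e-12)


def test_partition_errors_symmetry_and_zero():
    e_a, e_b = partition_errors(1.0, 2.0, 2.0)
    assert e_a == pytest.approx(2 ** -0.5)
    assert e_b == pytest.approx(2 ** -0.5)
    assert partition_errors(0.0, 1.5, 2.8) == (0.0, 0.0)
    with pytest.raises(ValueError):
        partition_errors(0.5, -1.0, 2.0)


def test_partition_recovery_from_synthetic_pair(helix_model):
    # independent Gaussian errors on both models recover through partitioning
    big = StructureModel(helix_model.atoms * 20)  # ~2500 atoms for statistics
    e_a, e_b = 0.2, 0.4
    pa, _ = perturb_model(big, e_a, seed=101)
    pb, _ = perturb_model(big, e_b, seed=202)
    p = pair_atoms(pa, pb)
    dev = np.linalg.norm(pa.xyz[[i for i, _ in p.pairs]] -
                         pb.xyz[[j for _, j in p.pairs]], axis=1)
    rmsd = float(np.sqrt(np.mean(dev ** 2)))
    ea_hat, eb_hat = partition_errors(rmsd, e_a, e_b)  # d_a/d_b set to e_a/e_b
    assert ea_hat == pytest.approx(e_a, rel=0.10)
    assert eb_hat == pytest.approx(e_b, rel=0.10)


def test_peptide_flip_detected(helix_model):
    # rotate one carbonyl O ~180° about the Cα(i)–Cα(i+1) axis
    import dataclasses
    atoms = list(helix_model.atoms)
    by_key = {(a.residue_seq, a.name): i for i, a in enumerate(atoms)
              if a.chain == "A"}
    i_o = by_key[(6, "O")]
    ca1 = np.array(atoms[by_key[(6, "CA")]].xyz)
    ca2 = np.array(atoms[by_key[(7, "CA")]].xyz)
    axis = (ca2 - ca1) / np.linalg.norm(ca2 - ca1)
    o = np.array(atoms[i_o].xyz)
    rel = o - ca1
    # Rodrigues rotation by π about the Cα–Cα axis
    flipped = ca1 + 2 * axis * (rel @ axis) - rel
    atoms[i_o] = dataclasses.replace(atoms[i_o], xyz=tuple(flipped))
    mb = StructureModel(atoms)
    p = pair_atoms(helix_model, mb)
    flips = flag_peptide_flips(p, helix_model, mb)
    assert flips == [("A", 6, 7)]


def test_peptide_flip_gate_suppresses_global_shift(helix_model):
    shifted = helix_model.with_xyz(helix_model.xyz + 3.0)
    p = pair_atoms(helix_model, shifted)
    assert flag_peptide_flips(p, helix_model, shifted) == []
    assert flag_peptide_flips(pair_atoms(helix_model, helix_model),
                              helix_model, helix_model) == []


def test_compare_models_end_to_end(helix_model):
    pb, _ = perturb_model(helix_model, 0.3, outlier_fraction=0.1,
                          outlier_scale=2.3, seed=3)
    out = compare_models(helix_model, pb)
    assert set(out) >= {"pairing", "all", "backbone", "ca"}
    assert "RMSD" in out["all"].summary()
    d = out["all"].to_dict()
    assert d["rmsd"] > 0


def test_superpose_removes_rigid_motion(helix_model):
    # rotate + translate a copy; superposed comparison returns ~zero RMSD
    theta = 0.4
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved = helix_model.with_xyz(helix_model.xyz @ R.T + np.array([5.0, -3.0, 2.0]))
    out = compare_models(helix_model, moved, superpose_first=True)
    assert out["all"].rmsd < 1e-6
    out2 = compare_models(helix_model, moved, superpose_first=False)
    assert out2["all"].rmsd > 1.0
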