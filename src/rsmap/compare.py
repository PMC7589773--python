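"""Structure comparison: pairing, symmetric-rotamer inversion, IQR outlier
statistics, resolution-proportional error partitioning, peptide-flip flags.

Models of the same construct are paired on (chain, residue number, atom
name); no superposition is applied by default (structures refined in a
common frame, as icosahedral capsid deposits are), though a least-squares
superposition is available behind a flag.  Deviations are per-atom scalar
distances; outliers are Tukey-fenced per subset (deviation > Q3 + 1.5·IQR,
quartiles by linear interpolation); an RMSD over n% of atoms partitions
into per-structure coordinate errors in proportion to nominal resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtomPairing", "ComparisonResult", "pair_atoms",
           "invert_symmetric_rotamers", "deviation_stats", "partition_errors",
           "flag_peptide_flips", "compare_models", "superpose"]

# terminal atom pairs that are chemically (pseudo-)symmetric and swappable
SYMMETRIC_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "ARG": (("NH1", "NH2"),),
    "LEU": (("CD1", "CD2"),),
    "VAL": (("CG1", "CG2"),),
    # amide O/N: pseudo-symmetric (a 180° chi flip nearly exchanges them)
    "ASN": (("OD1", "ND2"),),
    "GLN": (("OE1", "NE2"),),
}


@dataclass
class AtomPairing:
    """Matched atom indices between two models plus the unmatched remainders."""

    pairs: list  # [(ia, ib), ...]
    unmatched_a: list
    unmatched_b: list
    swapped_residues: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def _key(atom) -> tuple:
    return (atom.chain, atom.residue_seq, atom.name.strip().upper())


def pair_atoms(model_a, model_b, include_h: bool = False) -> AtomPairing:
    """Deterministic pairing on (chain, residue number, atom name).

    Hydrogens are excluded by default (comparison partners at lower
    resolution typically lack them).  Altloc duplicates keep the first
    record per key.
    """
    def usable(a):
        return include_h or a.element.upper() != "H"

    bmap: dict[tuple, int] = {}
    for j, b in enumerate(model_b.atoms):
        if usable(b):
            bmap.setdefault(_key(b), j)
    pairs, una = [], []
    used_b: set[int] = set()
    seen_a: set[tuple] = set()
    for i, a in enumerate(model_a.atoms):
        if not usable(a):
            continue
        k = _key(a)
        if k in seen_a:
            una.append(i)
            continue
        seen_a.add(k)
        j = bmap.get(k)
        if j is None or j in used_b:
            una.append(i)
        else:
            pairs.append((i, j))
            used_b.add(j)
    unb = [j for j, b in enumerate(model_b.atoms) if usable(b) and j not in used_b]
    if not pairs:
        raise ValueError("no atoms could be paired between the models")
    return AtomPairing(pairs, una, unb)


def invert_symmetric_rotamers(pairing: AtomPairing, model_a, model_b) -> AtomPairing:
    """Swap (pseudo-)symmetric terminal pairs where it strictly lowers the
    residue's sum of squared deviations; returns a remapped pairing and
    records the swapped residues."""
    xa, xb = model_a.xyz, model_b.xyz
    pair_of_a = dict(pairing.pairs)
    # index pairs by residue of model_a
    byres: dict[tuple, dict[str, int]] = {}
    for ia, _ in pairing.pairs:
        at = model_a.atoms[ia]
        byres.setdefault((at.chain, at.residue_seq, at.residue_name.upper()),
                         {})[at.name.strip().upper()] = ia
    swapped: list = []
    new_pairs = dict(pair_of_a)
    for (chain, seq, resname), atoms in byres.items():
        for n1, n2 in SYMMETRIC_PAIRS.get(resname, ()):
            if n1 not in atoms or n2 not in atoms:
                continue
            i1, i2 = atoms[n1], atoms[n2]
            j1, j2 = new_pairs.get(i1), new_pairs.get(i2)
            if j1 is None or j2 is None:
                continue
            cur = np.sum((xa[i1] - xb[j1]) ** 2) + np.sum((xa[i2] - xb[j2]) ** 2)
            alt = np.sum((xa[i1] - xb[j2]) ** 2) + np.sum((xa[i2] - xb[j1]) ** 2)
            if alt < cur - 1e-12:
                new_pairs[i1], new_pairs[i2] = j2, j1
                swapped.append((chain, seq, resname, n1, n2))
    out = AtomPairing([(i, j) for i, j in sorted(new_pairs.items())],
                      pairing.unmatched_a, pairing.unmatched_b,
                      swapped_residues=pairing.swapped_residues + swapped)
    return out


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    """Q1 and Q3 by linear interpolation (the common 'type 7' convention)."""
    return (float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75)))


@dataclass
class ComparisonResult:
    """Deviation statistics for one atom subset of a paired comparison."""

    subset: str
    n_pairs: int
    deviations: np.ndarray
    rmsd: float
    rmsd_clean: float
    outlier_mask: np.ndarray
    outlier_fraction: float
    rmsd_outliers: float
    q1: float
    q3: float
    swapped_residues: list = field(default_factory=list)
    flipped_peptides: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Subset: {self.subset} ({self.n_pairs} atom pairs)",
            f"  RMSD                      {self.rmsd:.3f} Å",
            f"  outliers (> Q3 + 1.5·IQR) {100 * self.outlier_fraction:.1f}%"
            f"  (RMSD {self.rmsd_outliers:.3f} Å)" if self.outlier_fraction > 0 else
            "  outliers (> Q3 + 1.5·IQR) 0.0%",
            f"  RMSD after removal        {self.rmsd_clean:.3f} Å",
        ]
        if self.swapped_residues:
            lines.append(f"  rotamer inversions        {len(self.swapped_residues)}")
        if self.flipped_peptides:
            lines.append(f"  flipped peptides          {len(self.flipped_peptides)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "subset": self.subset, "n_pairs": self.n_pairs,
            "rmsd": self.rmsd, "rmsd_after_outlier_removal": self.rmsd_clean,
            "outlier_fraction": self.outlier_fraction,
            "outlier_rmsd": self.rmsd_outliers,
            "n_swapped_residues": len(self.swapped_residues),
            "n_flipped_peptides": len(self.flipped_peptides),
        }


def deviation_stats(pairing: AtomPairing, model_a, model_b,
                    subset: str = "all") -> ComparisonResult:
    """RMSD with Tukey-fence outlier analysis on the chosen subset.

    ``subset`` ∈ {"all", "backbone", "ca"}; each subset's quartiles come
    from its own deviation distribution.
    """
    xa, xb = model_a.xyz, model_b.xyz
    idx = []
    for ia, ib in pairing.pairs:
        at = model_a.atoms[ia]
        name = at.name.strip().upper()
        if subset == "backbone" and name not in ("N", "CA", "C", "O", "OXT"):
            continue
        if subset == "ca" and name != "CA":
            continue
        idx.append((ia, ib))
    if not idx:
        raise ValueError(f"no paired atoms in subset {subset!r}")
    if len(idx) < 4:
        raise ValueError(f"subset {subset!r} has {len(idx)} pairs; need >= 4 for quartiles")
    ia = np.array([p[0] for p in idx])
    ib = np.array([p[1] for p in idx])
    dev = np.linalg.norm(xa[ia] - xb[ib], axis=1)
    q1, q3 = _quartiles(dev)
    fence = q3 + 1.5 * (q3 - q1)
    out = dev > fence
    rmsd = float(np.sqrt(np.mean(dev ** 2)))
    clean = dev[~out]
    rmsd_clean = float(np.sqrt(np.mean(clean ** 2))) if clean.size else 0.0
    rmsd_out = float(np.sqrt(np.mean(dev[out] ** 2))) if out.any() else 0.0
    return ComparisonResult(
        subset=subset, n_pairs=len(idx), deviations=dev, rmsd=rmsd,
        rmsd_clean=rmsd_clean, outlier_mask=out,
        outlier_fraction=float(out.mean()), rmsd_outliers=rmsd_out,
        q1=q1, q3=q3, swapped_residues=list(pairing.swapped_residues))


def partition_errors(rmsd: float, d_a: float, d_b: float) -> tuple[float, float]:
    """Partition an inter-model RMSD into independent per-structure errors
    proportional to nominal resolution.

    e_a = rmsd·d_a/√(d_a² + d_b²), e_b = rmsd·d_b/√(d_a² + d_b²); then
    e_a² + e_b² = rmsd² and e_a/e_b = d_a/d_b.
    """
    if rmsd < 0 or d_a <= 0 or d_b <= 0:
        raise ValueError("rmsd must be >= 0 and resolutions positive")
    den = np.hypot(d_a, d_b)
    return (float(rmsd * d_a / den), float(rmsd * d_b / den))


def flag_peptide_flips(pairing: AtomPairing, model_a, model_b,
                       o_threshold: float = 2.0, ca_gate: float = 0.5) -> list:
    """Flag peptides whose carbonyl O moved > ``o_threshold`` Å while both
    flanking Cα stayed < ``ca_gate`` Å — the tubular-backbone flip signature."""
    xa, xb = model_a.xyz, model_b.xyz
    dev_by_key: dict[tuple, float] = {}
    for ia, ib in pairing.pairs:
        at = model_a.atoms[ia]
        dev_by_key[(at.chain, at.residue_seq, at.name.strip().upper())] = \
            float(np.linalg.norm(xa[ia] - xb[ib]))
    flips = []
    residues = sorted({(a.chain, a.residue_seq) for a in model_a.atoms})
    for chain, seq in residues:
        d_o = dev_by_key.get((chain, seq, "O"))
        d_ca1 = dev_by_key.get((chain, seq, "CA"))
        d_ca2 = dev_by_key.get((chain, seq + 1, "CA"))
        if d_o is None or d_ca1 is None or d_ca2 is None:
            continue
        if d_o > o_threshold and d_ca1 < ca_gate and d_ca2 < ca_gate:
            flips.append((chain, seq, seq + 1))
    return flips


def superpose(model_a, model_b, pairing: AtomPairing):
    """Least-squares rigid superposition of B onto A over the paired atoms
    (Kabsch); returns a transformed copy of ``model_b``."""
    xa = model_a.xyz[[p[0] for p in pairing.pairs]]
    xb = model_b.xyz[[p[1] for p in pairing.pairs]]
    ca, cb = xa.mean(0), xb.mean(0)
    H = (xb - cb).T @ (xa - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return model_b.with_xyz((model_b.xyz - cb) @ R.T + ca)


def compare_models(model_a, model_b, include_h: bool = False,
                   invert_rotamers: bool = True,
                   superpose_first: bool = False) -> dict:
    """Full comparison: all/backbone/Cα subsets, rotamer inversion, flips.

    Returns a dict of :class:`ComparisonResult` keyed by subset plus the
    pairing itself under ``"pairing"``.
    """
    pairing = pair_atoms(model_a, model_b, include_h=include_h)
    if superpose_first:
        model_b = superpose(model_a, model_b, pairing)
    if invert_rotamers:
        pairing = invert_symmetric_rotamers(pairing, model_a, model_b)
    out: dict = {"pairing": pairing}
    for subset in ("all", "backbone", "ca"):
        try:
            out[subset] = deviation_stats(pairing, model_a, model_b, subset)
        except ValueError:
            continue
    flips = flag_peptide_flips(pairing, model_a, model_b)
    for k in ("all", "backbone", "ca"):
        if k in out:
            out[k].flipped_peptides = flips
    return out
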