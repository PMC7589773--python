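"""Synthetic inputs at desk scale: toy models, simulated maps, perturbed pairs.

Everything here is a pure function of a :class:`SyntheticSpec` (seed
included), so any fixture can be regenerated exactly.  Toy chains are built
from idealized internal coordinates — bond lengths, angles and φ/ψ typical
of refined structures — never from fragments of deposited entries.  Maps
are model potentials filtered at a known d½ with additive white Gaussian
real-space noise, the simplest noise model consistent with FSC-based
recovery checks (no coloring, no CTF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import DensityMap, mask_within
from .model import AtomRecord, StructureModel, classify_atoms, derive_bonds
from .synth import FilterParams, ImagingModel, synthesize_potential

__all__ = ["SyntheticSpec", "make_toy_model", "simulate_map", "perturb_model"]


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic map/model experiment.

    ``noise`` is the standard deviation of the white noise added to the
    *full* map, relative to the standard deviation of the clean signal over
    the whole reconstruction box; each half map receives √2 times that.
    The box-wide reference keeps the planted SNR meaningful for Fourier
    statistics (FSC) as well as masked real-space ones — a mask-relative
    reference would make the same nominal SNR far noisier in Fourier space
    for a sparse box.  ``voxel`` must not undersample ``d_half``
    (voxel ≤ d_half/3).
    """

    n_residues: int = 20
    fold: str = "helix"            # helix | strand-pair | coil
    b_mean: float = 10.0           # Å²
    b_spread: float = 5.0          # Å²
    n_waters: int | None = None    # default: one per two residues
    hydrogens: bool = True
    voxel: float = 0.5             # Å
    box: float | None = None       # Å; default: model extent + 6 Å margin
    d_half: float = 1.5            # Å
    filter_order: int = 5
    noise: float = 0.0             # relative to masked signal RMS
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.fold not in ("helix", "strand-pair", "coil"):
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.voxel > self.d_half / 3.0 + 1e-9:
            raise ValueError("voxel undersamples d_half (need voxel <= d_half/3)")
        if self.n_waters is None:
            self.n_waters = self.n_residues // 2


# ---------------------------------------------------------------------------
# internal-coordinate chain building

def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Position d: |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) = dihedral."""
    a, b, c = map(np.asarray, (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n

# ideal backbone geometry
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "N-H": 1.010, "CA-HA": 1.090, "CA-CB": 1.530}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
      "C-N-H": 119.3}

_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}
_COIL_TABLE = [(-57.0, -47.0), (-139.0, 135.0), (-80.0, 150.0), (-60.0, -30.0),
               (-120.0, 120.0)]

# side-chain internal coordinates: name, (ref_a, ref_b, ref_c), bond, angle, dihedral
# dihedral strings 'chi1'/'chi1+120'... are resolved per residue
_SIDE_CHAINS: dict[str, list] = {
    "ALA": [
        ("HB1", ("N", "CA", "CB"), 1.09, 109.5, "60"),
        ("HB2", ("N", "CA", "CB"), 1.09, 109.5, "180"),
        ("HB3", ("N", "CA", "CB"), 1.09, 109.5, "300"),
    ],
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.417, 110.8, "chi1"),
        ("HB2", ("N", "CA", "CB"), 1.09, 109.5, "chi1+120"),
        ("HB3", ("N", "CA", "CB"), 1.09, 109.5, "chi1-120"),
        ("HG", ("CA", "CB", "OG"), 0.96, 109.5, "180"),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 113.8, "chi1"),
        ("HB2", ("N", "CA", "CB"), 1.09, 109.5, "chi1+120"),
        ("HB3", ("N", "CA", "CB"), 1.09, 109.5, "chi1-120"),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, "-20"),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, "160"),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi1"),
        ("HB2", ("N", "CA", "CB"), 1.09, 109.5, "chi1+120"),
        ("HB3", ("N", "CA", "CB"), 1.09, 109.5, "chi1-120"),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, "90"),
        ("CD2", ("CA", "CB", "CG"), 1.36, 129.7, "-90"),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 108.0, "180"),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, "180"),
        ("HD1", ("CB", "CG", "ND1"), 1.01, 126.0, "0"),
        ("HD2", ("CB", "CG", "CD2"), 1.08, 126.0, "0"),
        ("HE1", ("CG", "ND1", "CE1"), 1.08, 125.0, "180"),
    ],
}
_SEQ_PATTERN = ("ALA", "SER", "ALA", "ASP", "ALA", "HIS", "ALA", "SER")


def _build_chain(n_res: int, fold: str, rng: np.random.Generator,
                 hydrogens: bool, chain_id: str = "A", seq_offset: int = 0,
                 origin=(0.0, 0.0, 0.0)):
    """One extended chain of the residue pattern at the fold's φ/ψ."""
    if fold in _PHI_PSI:
        phi_psi = [_PHI_PSI[fold]] * n_res
    else:
        phi_psi = [_COIL_TABLE[i % len(_COIL_TABLE)] for i in range(n_res)]
    names = [_SEQ_PATTERN[i % len(_SEQ_PATTERN)] for i in range(n_res)]
    origin = np.asarray(origin, float)
    # backbone trace
    bb: list[dict] = []
    n0 = origin + np.array([0.0, 0.0, 0.0])
    ca0 = origin + np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.radians(_A["N-CA-C"])
    c0 = ca0 + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi, psi = phi_psi[i]
        _, psi_prev = phi_psi[i - 1]
        prev = bb[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B["C-N"], _A["CA-C-N"], psi_prev)
        ca = _place(prev["CA"], prev["C"], n, _B["N-CA"], _A["C-N-CA"], 180.0)
        c = _place(prev["C"], n, ca, _B["CA-C"], _A["N-CA-C"], phi)
        bb.append({"N": n, "CA": ca, "C": c})
    # carbonyl O (and OXT on the last residue)
    for i, res in enumerate(bb):
        psi = phi_psi[i][1]
        res["O"] = _place(res["N"], res["CA"], res["C"], _B["C-O"], _A["CA-C-O"],
                          psi + 180.0)
        if i == n_res - 1:
            res["OXT"] = _place(res["N"], res["CA"], res["C"], _B["C-O"],
                                _A["CA-C-O"], psi)
    atoms: list[tuple[str, str, np.ndarray]] = []  # (resname, atomname, xyz)
    for i, res in enumerate(bb):
        resname = names[i]
        coords = dict(res)
        # CB (L-configuration improper) except the toy chain has no GLY
        coords["CB"] = _place(res["C"], res["N"], res["CA"], _B["CA-CB"], 110.4, -122.6)
        chi1 = -60.0
        for name, (ra, rb, rc), bond, angle, dih in _SIDE_CHAINS[resname]:
            # dihedral spec is either a number or 'chi1(+/-offset)'
            if dih.startswith("chi1"):
                tor = chi1 + (float(dih[4:]) if len(dih) > 4 else 0.0)
            else:
                tor = float(dih)
            coords[name] = _place(coords[ra], coords[rb], coords[rc],
                                  bond, angle, tor)
        if hydrogens:
            coords["HA"] = _place(res["C"], res["N"], res["CA"], _B["CA-HA"],
                                  109.0, 119.0)
            if i > 0:
                coords["H"] = _place(bb[i - 1]["CA"], bb[i - 1]["C"], res["N"],
                                     _B["N-H"], _A["C-N-H"], 180.0)
        order = ["N", "CA", "C", "O", "OXT", "CB"] + \
            [s[0] for s in _SIDE_CHAINS[resname]] + ["H", "HA"]
        for name in order:
            if name in coords and (hydrogens or not name.startswith("H")):
                atoms.append((resname, name, coords[name], i + 1 + seq_offset, chain_id))
    return atoms


def make_toy_model(spec: SyntheticSpec) -> StructureModel:
    """Build the toy protein + waters the spec describes.

    Helix fold gives consecutive Cα–Cα ≈ 3.8 Å with α-helical rise; the
    strand-pair fold lays two extended strands side by side at sheet
    spacing; coil cycles through a small φ/ψ table.  Waters sit 2.6–3.2 Å
    from polar atoms.  B-factors are drawn from N(b_mean, b_spread²),
    clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.fold == "strand-pair":
        n1 = spec.n_residues - spec.n_residues // 2
        n2 = spec.n_residues // 2
        raw = _build_chain(n1, "strand", rng, spec.hydrogens, "A", 0)
        if n2 >= 2:
            raw += _build_chain(n2, "strand", rng, spec.hydrogens, "B", 0,
                                origin=(0.6, 4.8, 0.0))
    else:
        fold = "helix" if spec.fold == "helix" else "coil"
        raw = _build_chain(spec.n_residues, fold, rng, spec.hydrogens, "A", 0)

    records: list[AtomRecord] = []
    serial = 0
    for resname, name, xyz, seq, chain in raw:
        serial += 1
        el = "H" if name.startswith("H") else name[0]
        b = float(np.clip(rng.normal(spec.b_mean, spec.b_spread), 0.0, None))
        records.append(AtomRecord(serial, name, el, resname, seq, chain,
                                  tuple(np.round(xyz, 4)), b_iso=b))
    # waters near polar atoms
    polar = [r for r in records if r.element in ("N", "O")]
    existing = np.array([r.xyz for r in records])
    waters: list[np.ndarray] = []
    attempts = 0
    while len(waters) < spec.n_waters:
        attempts += 1
        if attempts > 200 * max(spec.n_waters, 1):
            raise ValueError(f"cannot place {spec.n_waters} waters around this model")
        host = polar[rng.integers(len(polar))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(2.6, 3.2)
        p = np.asarray(host.xyz) + dist * direction
        d_all = np.linalg.norm(existing - p, axis=1)
        if d_all.min() < 2.4:
            continue
        if waters and min(np.linalg.norm(np.array(waters) - p, axis=1)) < 2.8:
            continue
        waters.append(p)
    for wi, p in enumerate(waters):
        serial += 1
        b = float(np.clip(rng.normal(spec.b_mean + 5.0, spec.b_spread), 0.0, None))
        records.append(AtomRecord(serial, "O", "O", "HOH", 1000 + wi, "W",
                                  tuple(np.round(p, 4)), b_iso=b))
        if spec.hydrogens:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            perp = np.cross(axis, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            half = np.radians(104.5 / 2)
            for hn, sgn in (("H1", 1.0), ("H2", -1.0)):
                serial += 1
                hp = p + 0.96 * (np.cos(half) * axis + sgn * np.sin(half) * perp)
                records.append(AtomRecord(serial, hn, "H", "HOH", 1000 + wi, "W",
                                          tuple(np.round(hp, 4)), b_iso=b))
    m = StructureModel(records)
    classify_atoms(m)
    derive_bonds(m)
    return m


def _grid_template(model: StructureModel, spec: SyntheticSpec) -> DensityMap:
    xyz = model.xyz
    lo, hi = xyz.min(0), xyz.max(0)
    if spec.box is None:
        extent = float((hi - lo).max()) + 12.0  # 6 Å margin per side
        n = int(np.ceil(extent / spec.voxel / 2) * 2)
    else:
        n = int(round(spec.box / spec.voxel))
        need = (hi - lo) + 10.0  # ≥5 Å margin per side
        if np.any(need > n * spec.voxel):
            raise ValueError("model does not fit in the requested box with a 5 Å margin")
    center = (lo + hi) / 2
    origin = center - n * spec.voxel / 2
    return DensityMap(np.zeros((n, n, n)), spec.voxel, tuple(origin))


def simulate_map(model: StructureModel, spec: SyntheticSpec,
                 imaging: ImagingModel | None = None
                 ) -> tuple[DensityMap, DensityMap, DensityMap, dict]:
    """Clean-signal + noise simulation: returns (full, half A, half B, truth).

    The clean map is the model potential filtered at the spec's d½.  Both
    half maps get independent N(0, (√2·noise·RMS)²) white noise; the full
    map is their average.  ``truth`` records every planted parameter and
    the noise σ actually used.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    grid = _grid_template(model, spec)
    if imaging is None:
        imaging = ImagingModel(filt=FilterParams(spec.d_half, spec.filter_order))
    clean = synthesize_potential(model, grid, imaging)
    mask = mask_within(clean, model, None, 2.0, source="all atoms")
    signal_rms = float(clean.values.std())
    masked_rms = float(clean.values[mask.values].std())
    sigma_full = spec.noise * signal_rms
    sigma_half = sigma_full * np.sqrt(2.0)
    n1 = rng.normal(0.0, 1.0, clean.shape) * sigma_half if sigma_half > 0 else 0.0
    n2 = rng.normal(0.0, 1.0, clean.shape) * sigma_half if sigma_half > 0 else 0.0
    half1 = clean.copy(clean.values + n1)
    half2 = clean.copy(clean.values + n2)
    full = clean.copy((half1.values + half2.values) / 2.0)
    truth = {
        "seed": spec.seed, "d_half": spec.d_half, "filter_order": spec.filter_order,
        "scale": imaging.scale, "b_envelope": imaging.b_envelope,
        "magnification": imaging.magnification,
        "noise_relative": spec.noise, "noise_sigma_full": sigma_full,
        "noise_sigma_half": sigma_half, "signal_rms_box": signal_rms,
        "signal_rms_masked": masked_rms,
        "voxel": spec.voxel, "grid": list(clean.shape),
    }
    return full, half1, half2, truth


def perturb_model(model: StructureModel, error_scale: float,
                  outlier_fraction: float = 0.0, outlier_scale: float = 0.0,
                  seed: int = 0) -> tuple[StructureModel, np.ndarray]:
    """Displace every atom isotropically; a random fraction gets outlier-scale
    errors.  Returns the perturbed model and the planted-outlier mask.

    ``error_scale`` / ``outlier_scale`` are 3-D RMS displacements (Å): each
    coordinate receives N(0, (scale/√3)²), so the expected RMSD against the
    unperturbed model equals the scale.
    """
    if not (0.0 <= outlier_fraction <= 1.0):
        raise ValueError("outlier_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(model)
    is_out = rng.random(n) < outlier_fraction
    sig = np.where(is_out, outlier_scale, error_scale) / np.sqrt(3.0)
    disp = rng.normal(0.0, 1.0, (n, 3)) * sig[:, None]
    return model.with_xyz(model.xyz + disp), is_out
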