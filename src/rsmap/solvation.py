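"""Solvent picking, hydrogen-bond enumeration, histidine tautomer assignment.

Waters are picked conservatively: local map maxima above a σ threshold
(1.8 σ by default), far enough from modeled atoms to be unoccupied, and
close enough to a polar partner that hydrogen bonding is plausible.

Histidine tautomers (N1: H at N_δ; N3: H at N_ε; HisH+: both) are assigned
from chemical rationale alone: (R1) a carboxylate oxygen within H-bond
range of a ring nitrogen raises its pKa → that nitrogen protonated; (R2)
metal coordination of one nitrogen lowers its pKa → the hydrogen sits on
the other; (R3) an unambiguous H-bond donor facing a nitrogen implies that
nitrogen accepts (deprotonated), an unambiguous acceptor implies it donates
(protonated); (R4) a steric clash if protonated implies deprotonated.
Precedence R2 > R1 > R3 > R4; evidence that survives precedence but still
conflicts yields "ambiguous".  The intrinsic ~4:1 N3:N1 preference of free
histidine is background chemistry only — it never enters the rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .maps import DensityMap
from .model import StructureModel

__all__ = ["WaterSite", "HBond", "TautomerCall", "pick_waters",
           "enumerate_hbonds", "assess_his_tautomer"]

# donor heavy atoms (N/O/S carrying at least one H) per residue atom name
DONOR_ATOMS = {
    "backbone": {"N"},
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
ACCEPTOR_ATOMS = {
    "backbone": {"O", "OXT"},
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
CARBOXYLATE_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
# unambiguous H-bond partners for the tautomer rules
AMIDE_N = {"N", "ND2", "NE2"}  # backbone + ASN/GLN side-chain amides
CARBONYL_O = {"O", "OXT", "OD1", "OE1"}  # backbone + ASN/GLN amide carbonyls


@dataclass
class WaterSite:
    """A picked solvent peak with its nearest polar partner."""

    position: np.ndarray
    peak_sigma: float
    partner_index: int | None
    partner_distance: float


@dataclass
class HBond:
    donor_index: int
    acceptor_index: int
    distance: float
    hydrogen_index: int | None = None
    angle: float | None = None  # D-H···A, degrees


@dataclass
class TautomerCall:
    chain: str
    residue_seq: int
    call: str  # N1 | N3 | HisH+ | ambiguous
    rationale: set = field(default_factory=set)
    contacts: list = field(default_factory=list)


def _is_polar(atom) -> bool:
    return atom.element.upper() in ("N", "O")


def pick_waters(dmap: DensityMap, model: StructureModel,
                threshold_sigma: float = 1.8,
                min_model_distance: float = 2.2,
                polar_range: tuple[float, float] = (2.4, 3.5),
                merge_distance: float = 1.0) -> list[WaterSite]:
    """Pick candidate solvent sites from unoccupied map peaks.

    Local maxima above ``threshold_sigma`` (in map-σ units), farther than
    ``min_model_distance`` Å from any modeled atom, and within
    ``polar_range`` of a polar (N/O) atom or an already accepted water.
    Peaks merging within ``merge_distance`` keep the higher one.
    """
    sig = dmap.sigma
    if sig == 0.0:
        return []
    v = dmap.values
    local_max = (v == ndimage.maximum_filter(v, size=3, mode="nearest"))
    above = v > threshold_sigma * sig + dmap.mean
    cand = np.argwhere(local_max & above)  # (n, 3) z,y,x
    if len(cand) == 0:
        return []
    pos = dmap.position_of(cand)           # (n, 3) x,y,z Å
    heights = v[cand[:, 0], cand[:, 1], cand[:, 2]] / sig
    order = np.argsort(-heights)
    pos, heights = pos[order], heights[order]
    # unoccupied: far from every modeled atom
    tree_model = cKDTree(model.xyz)
    d_model, _ = tree_model.query(pos)
    keep = d_model >= min_model_distance
    pos, heights = pos[keep], heights[keep]
    if len(pos) == 0:
        return []
    # merge nearby peaks, higher wins (list is height-sorted)
    accepted_pos: list[np.ndarray] = []
    accepted_h: list[float] = []
    for p, h in zip(pos, heights):
        if any(np.linalg.norm(p - q) < merge_distance for q in accepted_pos):
            continue
        accepted_pos.append(p)
        accepted_h.append(float(h))
    # hydrogen-bonding plausibility against polar atoms and prior waters
    polar_idx = [i for i, a in enumerate(model.atoms) if _is_polar(a)]
    polar_xyz = model.xyz[polar_idx] if polar_idx else np.empty((0, 3))
    lo, hi = polar_range
    sites: list[WaterSite] = []
    for p, h in zip(accepted_pos, accepted_h):
        partner, dist = None, np.inf
        if len(polar_xyz):
            dd = np.linalg.norm(polar_xyz - p, axis=1)
            j = int(np.argmin(dd))
            partner, dist = polar_idx[j], float(dd[j])
        ok = partner is not None and lo <= dist <= hi
        if not ok:  # bridge through an accepted water
            for w in sites:
                dw = float(np.linalg.norm(w.position - p))
                if lo <= dw <= hi:
                    ok, partner, dist = True, None, dw
                    break
        if ok:
            sites.append(WaterSite(p, h, partner, dist))
    return sites


def _donors_acceptors(model: StructureModel):
    donors, acceptors = [], []
    for i, a in enumerate(model.atoms):
        res = a.residue_name.upper()
        name = a.name.strip().upper()
        if res in ("HOH", "WAT", "DOD"):
            if a.element.upper() == "O":
                donors.append(i)
                acceptors.append(i)
            continue
        if name in DONOR_ATOMS["backbone"] and res != "PRO":
            donors.append(i)
        if name in DONOR_ATOMS.get(res, ()):
            donors.append(i)
        if name in ACCEPTOR_ATOMS["backbone"]:
            acceptors.append(i)
        if name in ACCEPTOR_ATOMS.get(res, ()):
            acceptors.append(i)
    return donors, acceptors


def _bonded_hydrogens(model: StructureModel) -> dict[int, list[int]]:
    hs: dict[int, list[int]] = {}
    for i, j in model.bonds:
        if model.atoms[j].element.upper() == "H":
            hs.setdefault(i, []).append(j)
        elif model.atoms[i].element.upper() == "H":
            hs.setdefault(j, []).append(i)
    return hs


def enumerate_hbonds(model: StructureModel, dmax: float = 3.5,
                     angle_min: float = 90.0) -> list[HBond]:
    """All donor–acceptor pairs with D···A ≤ dmax (Å).

    When the donor carries a modeled hydrogen, the D–H···A angle must be at
    least ``angle_min`` degrees — a deliberately generous cutoff, since
    near-linear ideals over-reject real bonds at modest resolution.
    """
    donors, acceptors = _donors_acceptors(model)
    if not donors or not acceptors:
        return []
    xyz = model.xyz
    hmap = _bonded_hydrogens(model)
    tree = cKDTree(xyz[acceptors])
    bonds: list[HBond] = []
    for d in donors:
        for jj in tree.query_ball_point(xyz[d], dmax):
            a = acceptors[jj]
            if a == d:
                continue
            da = model.atoms[d], model.atoms[a]
            if da[0].chain == da[1].chain and da[0].residue_seq == da[1].residue_seq \
                    and da[0].residue_name == da[1].residue_name:
                continue  # intra-residue contacts are not H-bonds here
            dist = float(np.linalg.norm(xyz[d] - xyz[a]))
            if dist < 1.5:
                continue
            hyds = hmap.get(d, [])
            if hyds:
                best_h, best_ang = None, -1.0
                for h in hyds:
                    v1 = xyz[d] - xyz[h]
                    v2 = xyz[a] - xyz[h]
                    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
                    if ang > best_ang:
                        best_h, best_ang = h, ang
                if best_ang < angle_min:
                    continue
                bonds.append(HBond(d, a, dist, best_h, best_ang))
            else:
                bonds.append(HBond(d, a, dist))
    return bonds


def assess_his_tautomer(model: StructureModel, hbonds: list[HBond] | None = None,
                        ions: list[int] | None = None,
                        carboxylate_cutoff: float = 3.0,
                        metal_cutoff: float = 2.6,
                        clash_cutoff: float = 2.9) -> list[TautomerCall]:
    """Assign N1/N3/HisH+ tautomers to every histidine by chemical rationale.

    Evidence per ring nitrogen: R1 carboxylate O ≤ ``carboxylate_cutoff`` →
    protonated; R2 metal ≤ ``metal_cutoff`` of one N → hydrogen on the other
    N; R3 an unambiguous donor within H-bond range → deprotonated, an
    unambiguous acceptor → protonated; R4 heavy-atom contact <
    ``clash_cutoff`` incompatible with an added hydrogen → deprotonated.
    ``ions`` are declared atom indices — no ion typing is attempted.
    Returns an empty list when the model has no histidine.
    """
    xyz = model.xyz
    if ions is None:
        ions = [i for i, t in enumerate(model.tags()) if t == "ion"]
    his_n: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(model.atoms):
        if a.residue_name.upper() == "HIS" and a.name.strip().upper() in ("ND1", "NE2"):
            his_n.setdefault((a.chain, a.residue_seq), {})[a.name.strip().upper()] = i
    calls: list[TautomerCall] = []
    for (chain, seq), nitro in sorted(his_n.items()):
        # evidence[n] holds 'protonated' / 'deprotonated' votes with rule tags
        evidence: dict[str, list[tuple[str, str, tuple]]] = {"ND1": [], "NE2": []}
        contacts: list = []
        for nname, ni in nitro.items():
            for j, b in enumerate(model.atoms):
                if b.chain == chain and b.residue_seq == seq and \
                        b.residue_name.upper() == "HIS":
                    continue
                d = float(np.linalg.norm(xyz[ni] - xyz[j]))
                key = (b.residue_name, b.chain, b.residue_seq, b.name.strip().upper(), round(d, 2))
                bn = b.name.strip().upper()
                if j in ions and d <= metal_cutoff:
                    evidence[nname].append(("R2", "deprotonated", key))
                    contacts.append(key)
                elif (b.residue_name.upper(), bn) in CARBOXYLATE_O and d <= carboxylate_cutoff:
                    evidence[nname].append(("R1", "protonated", key))
                    contacts.append(key)
                elif b.element.upper() != "H" and d <= 3.5 and d >= 2.0:
                    if bn in AMIDE_N and b.element.upper() == "N":
                        evidence[nname].append(("R3", "deprotonated", key))
                        contacts.append(key)
                    elif bn in CARBONYL_O and b.element.upper() == "O" \
                            and b.residue_name.upper() not in ("HOH", "WAT"):
                        evidence[nname].append(("R3", "protonated", key))
                        contacts.append(key)
                # R4: a nonpolar heavy atom too close to accommodate an added H
                if b.element.upper() == "C" and j not in ions and 1.8 < d < clash_cutoff:
                    evidence[nname].append(("R4", "deprotonated", key))
                    contacts.append(key)
        # R2 on one N implies the hydrogen on the OTHER N
        for nname, other in (("ND1", "NE2"), ("NE2", "ND1")):
            if any(r == "R2" for r, _, _ in evidence[nname]):
                evidence[other].append(("R2", "protonated", ("implied-by-metal",)))
        call, rationale = _resolve_tautomer(evidence)
        calls.append(TautomerCall(chain, seq, call, rationale, contacts))
    return calls


_PRECEDENCE = ("R2", "R1", "R3", "R4")


def _resolve_tautomer(evidence: dict) -> tuple[str, set]:
    state: dict[str, str | None] = {}
    rationale: set = set()
    for n in ("ND1", "NE2"):
        verdict = None
        for rule in _PRECEDENCE:
            votes = {v for r, v, _ in evidence[n] if r == rule}
            if len(votes) == 1:
                verdict = votes.pop()
                rationale.add(rule)
                break
            if len(votes) > 1:
                return "ambiguous", rationale | {rule}
        state[n] = verdict
    nd1, ne2 = state["ND1"], state["NE2"]
    if nd1 is None and ne2 is None:
        return "ambiguous", set()
    if nd1 == "protonated" and ne2 == "protonated":
        # R4 yields only 'deprotonated' votes, so HisH+ can never rest on clashes
        return "HisH+", rationale
    n1_evidence = nd1 == "protonated" or ne2 == "deprotonated"
    n3_evidence = ne2 == "protonated" or nd1 == "deprotonated"
    if n1_evidence and not n3_evidence:
        return "N1", rationale
    if n3_evidence and not n1_evidence:
        return "N3", rationale
    return "ambiguous", rationale
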