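"""Atom-class observability by occupancy titration of model-map correlation.

How strongly does each class of atoms (protein hydrogens, solvent oxygens,
...) actually contribute to the experimental map?  The occupancies of one
class are swept from 1 toward 0, the model potential is recalculated, and
the masked correlation against the experimental map is recorded — the
scoring mask is built once from ALL atoms (2.0 Å radius by default) and
held fixed, so every correlation sees the same map volume.

Two statistics come out of a titration:

* the least-squares slope of CC versus occupancy, normalized by the class's
  total electron count (ΔCC per electron) — the raw curve summary;
* the *signal fraction*: the occupancy at which the masked CC is maximized.

The second is the meaningful "fraction of the expected signal".  Writing
the calc map as R + αC (rest + α·class) and the experimental map as
O = k(R + βC) + noise, the CC maximizer over α has the closed form

    α* = (n0·r1 − n1·r0) / (n1·r1 − n0·c2)

with n0 = ⟨O,R⟩, n1 = ⟨O,C⟩, r0 = |R|², r1 = ⟨R,C⟩, c2 = |C|² (all
mean-centered over the mask), and α* = β exactly in the noise-free case —
a fully present class titrates to 1, an absent one to 0, a class at a
quarter of its expected scattering to 0.25.  The raw CC slope does not
share this property: near a well-fit model CC responds quadratically
around the matching occupancy, so its slope conflates the class signal
with a normalization drag.  Signal fractions are reported relative to
side-chain carbons by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DensityMap, GridMask, mask_within
from .synth import ImagingModel, apply_imaging_filters, synthesize_potential

__all__ = ["TitrationCurve", "titrate_class", "signal_ratio",
           "class_signal_report", "DEFAULT_OCCUPANCIES"]

DEFAULT_OCCUPANCIES = (1.0, 0.75, 0.5, 0.25, 0.0)


@dataclass
class TitrationCurve:
    """Masked CC versus class occupancy multiplier for one atom class."""

    class_tag: str
    occupancies: np.ndarray
    cc: np.ndarray
    electrons: int
    signal_fraction: float = float("nan")

    def __post_init__(self):
        self.occupancies = np.asarray(self.occupancies, float)
        self.cc = np.asarray(self.cc, float)
        if self.electrons <= 0:
            raise ValueError("class has no electrons")

    @property
    def raw_slope(self) -> float:
        """Least-squares slope of CC vs occupancy over all points."""
        return float(np.polyfit(self.occupancies, self.cc, 1)[0])

    @property
    def slope(self) -> float:
        """Per-electron slope: ΔCC per occupancy unit per electron in the class."""
        return self.raw_slope / self.electrons


def _class_decomposition(obs: DensityMap, model, imaging: ImagingModel,
                         class_tag: str):
    """Split the calc map into (rest, class) components; synthesis is linear in q."""
    tags = model.tags()
    in_class = tags == class_tag
    if not in_class.any():
        raise ValueError(f"no atoms in class {class_tag!r}")
    q = model.occupancy
    q_rest = np.where(in_class, 0.0, q)
    q_class = np.where(in_class, q, 0.0)
    im_raw = ImagingModel(magnification=imaging.magnification)
    if q_rest.any():
        rest = synthesize_potential(model.with_occupancy(q_rest), obs, im_raw).values
    else:
        rest = np.zeros(obs.shape)
    cls = synthesize_potential(model.with_occupancy(q_class), obs, im_raw).values
    # imaging filters are linear: apply to the components once, mix afterwards
    rest = apply_imaging_filters(rest, obs.voxel, imaging.filt, imaging.b_envelope)
    cls = apply_imaging_filters(cls, obs.voxel, imaging.filt, imaging.b_envelope)
    return rest, cls, in_class


def _inner_products(obs: DensityMap, rest: np.ndarray, cls: np.ndarray,
                    mask: GridMask):
    m = mask.values
    o = obs.values[m]
    r = rest[m]
    c = cls[m]
    o = o - o.mean()
    r = r - r.mean()
    c = c - c.mean()
    return {"n0": float(o @ r), "n1": float(o @ c), "r0": float(r @ r),
            "r1": float(r @ c), "c2": float(c @ c), "o2": float(o @ o)}


def _signal_fraction(ip: dict) -> float:
    """Occupancy maximizing CC(α) = (n0+α n1)/(|O|·√(r0+2α r1+α² c2))."""
    den = ip["n1"] * ip["r1"] - ip["n0"] * ip["c2"]
    if den == 0.0:
        return float("nan")
    return (ip["n0"] * ip["r1"] - ip["n1"] * ip["r0"]) / den


def titrate_class(obs: DensityMap, model, imaging: ImagingModel, class_tag: str,
                  occupancies=DEFAULT_OCCUPANCIES, mask_radius: float = 2.0,
                  mask: GridMask | None = None) -> TitrationCurve:
    """CC vs occupancy multiplier for one atom class, all else untouched.

    The multiplier applies on top of the model's stored occupancies, so
    alternate conformers keep their relative weights.  Occupancies must be
    monotone.  The returned curve also carries the CC-maximizing
    ``signal_fraction``.
    """
    occ = np.asarray(occupancies, float)
    if len(occ) < 2 or not (np.all(np.diff(occ) < 0) or np.all(np.diff(occ) > 0)):
        raise ValueError("occupancy grid must be strictly monotone with >= 2 points")
    if np.any(occ < 0) or np.any(occ > 1):
        raise ValueError("occupancies must lie in [0, 1]")
    if mask is None:
        mask = mask_within(obs, model, None, mask_radius, source="all atoms")
    rest, cls, in_class = _class_decomposition(obs, model, imaging, class_tag)
    electrons = int(model.atomic_number[in_class].sum())
    ip = _inner_products(obs, rest, cls, mask)
    ccs = []
    no = np.sqrt(ip["o2"])
    for a in occ:
        num = ip["n0"] + a * ip["n1"]
        den = no * np.sqrt(max(ip["r0"] + 2 * a * ip["r1"] + a * a * ip["c2"], 0.0))
        ccs.append(num / den if den > 0 and no > 0 else 0.0)
    return TitrationCurve(class_tag, occ, np.array(ccs), electrons,
                          signal_fraction=_signal_fraction(ip))


def signal_ratio(curve: TitrationCurve, reference: TitrationCurve) -> float:
    """Per-electron slope of ``curve`` relative to ``reference`` (side-chain C
    by convention)."""
    if abs(reference.slope) < 1e-14:
        raise ValueError("reference curve has zero slope")
    return curve.slope / reference.slope


def class_signal_report(obs: DensityMap, model, imaging: ImagingModel,
                        classes=("protein_H", "solvent_H", "solvent_O",
                                 "backbone", "side_chain_C"),
                        reference: str = "side_chain_C",
                        occupancies=DEFAULT_OCCUPANCIES,
                        mask_radius: float = 2.0) -> dict:
    """Titrate several classes; report slopes and reference-normalized signal.

    ``signal_ratio`` in the output is the class's CC-maximizing occupancy
    divided by the reference class's (side-chain carbons ≈ fully present,
    so the reference quotient is ≈ 1); ``slope_ratio`` is the per-electron
    slope quotient.
    """
    mask = mask_within(obs, model, None, mask_radius, source="all atoms")
    tags = set(model.tags())
    curves: dict[str, TitrationCurve] = {}
    for c in classes:
        if c in tags:
            curves[c] = titrate_class(obs, model, imaging, c, occupancies, mask=mask)
    if reference not in curves:
        raise ValueError(f"reference class {reference!r} absent from the model")
    ref = curves[reference]
    out: dict[str, dict] = {}
    for c, cv in curves.items():
        out[c] = {
            "electrons": cv.electrons,
            "per_electron_slope": cv.slope,
            "slope_ratio": signal_ratio(cv, ref) if abs(ref.slope) > 1e-14
                           else float("nan"),
            "signal_fraction": cv.signal_fraction,
            "signal_ratio": cv.signal_fraction / ref.signal_fraction
                            if ref.signal_fraction not in (0.0,) else float("nan"),
            "occupancies": cv.occupancies.tolist(),
            "cc": cv.cc.tolist(),
        }
    return out
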