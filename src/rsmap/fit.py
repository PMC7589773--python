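"""Model-map agreement scoring and refinement of scalar imaging parameters.

The centerpiece is :class:`ImagingRefinement`, a fitted-model object in the
statsmodels mold: construct it from an experimental map and an atomic model,
call :meth:`~ImagingRefinement.fit`, and receive :class:`ImagingFitResults`
with the refined parameters, the final masked correlation, a per-iteration
trace and a ``summary()`` table.

The objective is the Pearson correlation between experimental and
model-calculated potential over grid points within a mask radius of the
atoms.  The linear scale k and additive offset are profiled out in closed
form by least squares at each evaluation (the CC optimum is identical); the
remaining scalars — envelope B, magnification, and the Butterworth d½ — are
refined by cycles of bounded golden-section line searches, which is
derivative-free and deterministic.

Envelope B, a uniform atomic-B shift, and d½ act multiplicatively on the
cached Fourier transform of the raw (unfiltered) model potential, so only
magnification changes force a resynthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .maps import DensityMap, GridMask, mask_within
from .synth import (FilterParams, ImagingModel, apply_imaging_filters,
                    freq_grid, synthesize_potential)

__all__ = ["masked_cc", "fsc_curve", "fsc_resolution", "FSCCurve",
           "ImagingRefinement", "ImagingFitResults", "refine_imaging",
           "CovarianceError"]


class CovarianceError(ValueError):
    """Raised when a requested parameter set is perfectly covariant."""


def masked_cc(obs: DensityMap, calc: DensityMap, mask: GridMask) -> float:
    """Pearson correlation of two congruent maps over masked voxels.

    Invariant to affine rescaling of either map.
    """
    if obs.shape != calc.shape:
        raise ValueError("maps are not congruent")
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    a = obs.values[m]
    b = calc.values[m]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero variance within the mask: correlation undefined")
    return float(a @ b / (na * nb))


@dataclass
class FSCCurve:
    """Fourier shell correlation between two half maps, one shell per Fourier voxel."""

    shell_s: np.ndarray          # shell centers, 1/Å
    fsc: np.ndarray              # correlation per shell
    voxel: float
    shape: tuple[int, int, int]
    n_terms: np.ndarray = field(default=None)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# s(1/A)\tFSC\n")
            for s, f in zip(self.shell_s, self.fsc):
                fh.write(f"{s:.6f}\t{f:.6f}\n")


def fsc_curve(half1: DensityMap, half2: DensityMap) -> FSCCurve:
    """Per-shell normalized cross-correlation of Fourier coefficients."""
    if half1.shape != half2.shape or not np.isclose(half1.voxel, half2.voxel):
        raise ValueError("half maps are not congruent")
    F1 = np.fft.rfftn(half1.values)
    F2 = np.fft.rfftn(half2.values)
    s = freq_grid(half1.shape, half1.voxel)
    ds = 1.0 / (half1.shape[2] * half1.voxel)       # one Fourier voxel
    shell = np.rint(s / ds).astype(int)
    nsh = shell.max() + 1
    num = np.bincount(shell.ravel(), weights=(F1 * np.conj(F2)).real.ravel(), minlength=nsh)
    p1 = np.bincount(shell.ravel(), weights=np.abs(F1).ravel() ** 2, minlength=nsh)
    p2 = np.bincount(shell.ravel(), weights=np.abs(F2).ravel() ** 2, minlength=nsh)
    cnt = np.bincount(shell.ravel(), minlength=nsh)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = num / np.sqrt(p1 * p2)
    fsc = np.nan_to_num(fsc, nan=0.0)
    centers = np.arange(nsh) * ds
    nyq = 0.5 / half1.voxel
    keep = (centers <= nyq) & (cnt > 0)
    keep[0] = True
    return FSCCurve(centers[keep], fsc[keep], half1.voxel, half1.shape, cnt[keep])


def fsc_resolution(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Resolution (Å) at the first downward threshold crossing.

    Linear interpolation in (s, FSC) between shells.  Returns
    ``(resolution, crossed)``; without a crossing the Nyquist resolution is
    returned with ``crossed=False``.
    """
    s, f = curve.shell_s, curve.fsc
    for i in range(1, len(s)):
        if f[i] < threshold <= f[i - 1]:
            frac = (f[i - 1] - threshold) / (f[i - 1] - f[i])
            sc = s[i - 1] + frac * (s[i] - s[i - 1])
            return float(1.0 / sc), True
    return float(2.0 * curve.voxel), False


_BOUNDS = {
    "b_envelope": (-100.0, 300.0),
    "b_atomic": (-100.0, 300.0),
    "magnification": (0.95, 1.05),
    "d_half": None,  # set from the voxel at fit time: [2*voxel, 100]
}
_FITTABLE = ("k", "b_envelope", "b_atomic", "magnification", "d_half")


@dataclass
class ImagingFitResults:
    """Refined imaging parameters with diagnostics."""

    imaging: ImagingModel
    cc: float
    cc_start: float
    mask_radius: float
    n_atoms: int
    converged: bool
    trace: list
    fit_which: tuple
    b_atomic_shift: float = 0.0

    @property
    def d_half(self) -> float | None:
        return self.imaging.filt.d_half if self.imaging.filt else None

    def summary(self) -> str:
        rows = [
            ("scale k", f"{self.imaging.scale:.6g}", ""),
            ("offset", f"{self.imaging.offset:.6g}", ""),
            ("envelope B", f"{self.imaging.b_envelope:.3f}", "A^2"),
            ("atomic B shift", f"{self.b_atomic_shift:.3f}", "A^2"),
            ("magnification", f"{self.imaging.magnification:.5f}", ""),
            ("d_half", f"{self.d_half:.3f}" if self.d_half else "unfiltered", "A"),
            ("masked CC", f"{self.cc:.4f}", ""),
            ("starting CC", f"{self.cc_start:.4f}", ""),
            ("mask radius", f"{self.mask_radius:.2f}", "A"),
            ("atoms", str(self.n_atoms), ""),
            ("converged", str(self.converged), ""),
        ]
        width = max(len(r[0]) for r in rows)
        lines = ["Imaging refinement results", "=" * 38]
        lines += [f"{name:<{width}}  {val:>12} {unit}" for name, val, unit in rows]
        lines.append(f"refined: {', '.join(self.fit_which)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scale": self.imaging.scale, "offset": self.imaging.offset,
            "b_envelope": self.imaging.b_envelope,
            "b_atomic_shift": self.b_atomic_shift,
            "magnification": self.imaging.magnification,
            "d_half": self.d_half,
            "filter_order": self.imaging.filt.order if self.imaging.filt else None,
            "cc": self.cc, "cc_start": self.cc_start,
            "mask_radius": self.mask_radius, "n_atoms": self.n_atoms,
            "converged": self.converged,
            "trace": [(str(p), float(v), float(c)) for p, v, c in self.trace],
        }


class ImagingRefinement:
    """Refine scalar imaging parameters of a model against an experimental map.

    Parameters
    ----------
    obs : DensityMap
        Experimental map.
    model : StructureModel
        Atomic model in the same frame.
    start : ImagingModel, optional
        Starting parameters; the filter's d½ here seeds the search.
    mask_radius : float
        Å radius of the scoring mask around atoms (2.0 by default, the
        sharpened-map convention; 1.8 for unsharpened-style comparisons).
    selection : ndarray, optional
        Boolean atom selection restricting both the mask and the synthesis
        reference (e.g. a core β-barrel subset).
    """

    def __init__(self, obs: DensityMap, model, start: ImagingModel | None = None,
                 mask_radius: float = 2.0, selection: np.ndarray | None = None,
                 filter_order: int = 5, truncation: float | None = None):
        self.obs = obs
        self.model = model
        self.mask_radius = float(mask_radius)
        self.selection = selection
        self.filter_order = int(filter_order)
        self.truncation = truncation
        if start is None:
            start = ImagingModel(filt=FilterParams(max(3.0 * obs.voxel, 2.0),
                                                   order=filter_order))
        self.start = start
        self.mask = mask_within(obs, model, selection, mask_radius,
                                source=f"atoms within {mask_radius} Å")
        if not self.mask.values.any():
            raise ValueError("degenerate mask: no voxels within the radius")
        self._raw_F = None
        self._raw_mag = None

    # -- internals ---------------------------------------------------------

    def _raw_fft(self, magnification: float) -> np.ndarray:
        """FFT of the unfiltered, envelope-free model potential (cached per m)."""
        if self._raw_F is None or self._raw_mag != magnification:
            im = ImagingModel(magnification=magnification)
            raw = synthesize_potential(self.model, self.obs, im,
                                       truncation=self.truncation)
            self._raw_F = np.fft.rfftn(raw.values)
            self._raw_mag = magnification
            self._s = freq_grid(self.obs.shape, self.obs.voxel)
        return self._raw_F

    def _calc_values(self, p: dict) -> np.ndarray:
        F = self._raw_fft(p["magnification"]).copy()
        btot = p["b_envelope"] + p["b_atomic"]
        if btot != 0.0:
            F *= np.exp(-btot * self._s ** 2 / 4.0)
        if p["d_half"] is not None:
            filt = FilterParams(p["d_half"], self.filter_order)
            F *= 1.0 / np.sqrt(1.0 + (self._s / filt.s_cut) ** (2 * filt.order))
        return np.fft.irfftn(F, s=self.obs.shape, axes=(0, 1, 2))

    def _cc(self, p: dict) -> float:
        calc = self._calc_values(p)
        m = self.mask.values
        a = self.obs.values[m]
        b = calc[m]
        a = a - a.mean()
        b = b - b.mean()
        nb = np.linalg.norm(b)
        na = np.linalg.norm(a)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(a @ b / (na * nb))

    def _least_squares_scale(self, p: dict) -> tuple[float, float]:
        """Closed-form k, offset minimizing ||obs - (k·calc + c)||² in the mask."""
        calc = self._calc_values(p)
        m = self.mask.values
        a = self.obs.values[m]
        b = calc[m]
        vb = b.var()
        if vb == 0.0:
            return 1.0, float(a.mean())
        k = float(np.cov(a, b, bias=True)[0, 1] / vb)
        c = float(a.mean() - k * b.mean())
        return k, c

    # -- public ------------------------------------------------------------

    def fit(self, fit_which=("d_half",), tol: float = 1e-5,
            max_passes: int = 20) -> ImagingFitResults:
        """Maximize the masked CC over the named scalars.

        ``fit_which`` ⊆ {"k", "b_envelope", "b_atomic", "magnification",
        "d_half"}.  k (with an additive offset) is profiled by least squares —
        it does not change the CC optimum.  Envelope B and a uniform atomic-B
        shift are exactly covariant; requesting them together with k raises
        :class:`CovarianceError`.
        """
        fit_which = tuple(fit_which)
        if not fit_which:
            raise ValueError("fit_which must name at least one parameter")
        for p in fit_which:
            if p not in _FITTABLE:
                raise ValueError(f"unknown parameter {p!r}; choose from {_FITTABLE}")
        if {"k", "b_envelope", "b_atomic"} <= set(fit_which):
            raise CovarianceError(
                "scale, envelope B and a uniform atomic-B shift are covariant "
                "and cannot all be refined together")
        if {"b_envelope", "b_atomic"} <= set(fit_which):
            raise CovarianceError(
                "envelope B and a uniform atomic-B shift are exactly covariant")

        start = self.start
        params = {
            "b_envelope": start.b_envelope,
            "b_atomic": 0.0,
            "magnification": start.magnification,
            "d_half": start.filt.d_half if start.filt else None,
        }
        if "d_half" in fit_which and params["d_half"] is None:
            params["d_half"] = max(3.0 * self.obs.voxel, 2.0)
        scan_params = [p for p in fit_which if p != "k"]
        cc0 = self._cc(params)
        cc_prev = cc0
        trace: list = [("start", float("nan"), cc0)]
        converged = False
        d_bounds = (2.0 * self.obs.voxel + 1e-9, 100.0)
        for _ in range(max_passes):
            for name in scan_params:
                lo, hi = d_bounds if name == "d_half" else _BOUNDS[name]

                def neg(x, name=name):
                    q = dict(params)
                    q[name] = x
                    return -self._cc(q)

                res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-4 if name == "magnification"
                                               else 1e-3})
                if -res.fun > self._cc(params):
                    params[name] = float(res.x)
                trace.append((name, params[name], self._cc(params)))
            cc_now = self._cc(params)
            if abs(cc_now - cc_prev) < tol:
                converged = True
                break
            cc_prev = cc_now
        cc_final = self._cc(params)
        if cc_final < cc0:   # never worse than the start
            params = {
                "b_envelope": start.b_envelope, "b_atomic": 0.0,
                "magnification": start.magnification,
                "d_half": start.filt.d_half if start.filt else None,
            }
            cc_final = cc0
        k, c = self._least_squares_scale(params)
        filt = FilterParams(params["d_half"], self.filter_order) \
            if params["d_half"] is not None else None
        imaging = ImagingModel(scale=abs(k) if k > 0 else 1.0,
                               b_envelope=params["b_envelope"],
                               magnification=params["magnification"],
                               filt=filt, offset=c)
        return ImagingFitResults(
            imaging=imaging, cc=cc_final, cc_start=cc0,
            mask_radius=self.mask_radius,
            n_atoms=int(np.sum(self.selection)) if self.selection is not None else len(self.model),
            converged=converged, trace=trace, fit_which=fit_which,
            b_atomic_shift=params["b_atomic"])


def refine_imaging(obs: DensityMap, model, fit_which=("d_half",),
                   mask_radius: float = 2.0, start: ImagingModel | None = None,
                   **kw) -> ImagingFitResults:
    """Functional wrapper over :class:`ImagingRefinement`."""
    return ImagingRefinement(obs, model, start=start, mask_radius=mask_radius,
                             **{k: v for k, v in kw.items()
                                if k in ("selection", "filter_order", "truncation")}
                             ).fit(fit_which,
                                   **{k: v for k, v in kw.items()
                                      if k in ("tol", "max_passes")})
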