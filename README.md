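# rsmap — real-space map/model analysis for high-resolution cryo-EM

As cryo-EM reconstructions push past ~1.5 Å, questions that used to be
academic become practical: what is the *model-referenced* resolution of a
map, how visible are hydrogens and ordered solvent really, how accurate were
the lower-resolution structures that came before, and can protonation states
(histidine tautomers) be argued from the chemistry of the model?  `rsmap` is
a toolkit for structural biologists who want to ask these questions of a
map/model pair — and to validate the machinery end-to-end on synthetic data
with known ground truth.

## What it computes

**Model-based resolution d½.**  The model's Coulombic potential is
synthesized from 5-Gaussian electron scattering factors (hydrogens
included), each atom broadened by its isotropic B, then passed through an
n-th order Butterworth low-pass filter

&nbsp;&nbsp;&nbsp;&nbsp;A(s) = [1 + (s/s_c)^(2n)]^(−1/2),&nbsp;&nbsp;
s_c = (1/d½)·3^(−1/(2n)),

parameterized by the resolution d½ at which the amplitude falls to one half
(n = 5 by default).  d½ — together with a scale, an envelope B and an
effective magnification — is refined to maximize the Pearson correlation
between observed and calculated potential over grid points within a mask
radius of the atoms (2.0 Å for sharpened maps, 1.8 Å for unsharpened, by
convention).

**FSC.**  Fourier shell correlation between independent half maps, one
shell per Fourier voxel, with the threshold crossing (0.143 by default)
found by linear interpolation.

**Atom-class observability.**  Occupancies of one class of atoms (protein
hydrogens, solvent oxygens, …) are titrated from 1 to 0 while the masked CC
is recorded over a fixed all-atom mask.  The occupancy that maximizes the
CC has a closed form in the titration inner products and estimates the
class's signal as a fraction of that expected from the model; ratios are
reported against side-chain carbons.

**Structure comparison.**  Deterministic atom pairing, inversion of
chemically (pseudo-)symmetric side-chain labels (Asp, Glu, Phe, Tyr, Arg,
Leu, Val, Asn, Gln) wherever it lowers the deviation, per-subset RMSDs with
Tukey-fence outliers (deviation > Q3 + 1.5·IQR), peptide-flip flagging, and
partitioning of an RMSD r between structures of nominal resolutions d_a,
d_b into independent resolution-proportional errors
e_a = r·d_a/√(d_a²+d_b²), e_b = r·d_b/√(d_a²+d_b²).

**Solvent & chemistry.**  Conservative water picking (unoccupied local map
maxima above a σ threshold with hydrogen-bonding potential), hydrogen-bond
enumeration with generous angular cut-offs, and histidine N1/N3/HisH⁺
tautomer calls from four chemical-rationale rules (carboxylate contact,
metal coordination, unambiguous donor/acceptor partner, steric clash).

**Synthetic data.**  Idealized toy models (helix / strand-pair / coil, with
riding hydrogens, waters, B-factors) and simulated maps with planted d½,
imaging parameters and white noise, plus perturbed model pairs with planted
outlier structure — every generator is a pure function of its spec and seed.

## Worked example

Simulate a map with a planted d½ of 2.0 Å at real-space SNR 1, then recover
the resolution both ways:

```bash
$ rsmap simulate --preset recovery-2.0A --seed 1 --out sim
wrote model + maps to sim/ (planted d_half = 2.0 Å)

$ rsmap fit-imaging sim/map.mrc sim/model.pdb --fit d_half --out fit
Imaging refinement results
======================================
scale k              1.00222
offset          -0.000616713
envelope B             0.000 A^2
...
d_half                 2.002 A
masked CC             0.9782
starting CC           0.9140
mask radius             2.00 A
atoms                    206
converged               True

$ rsmap fsc sim/half1.mrc sim/half2.mrc --out fsc
FSC_0.143 resolution: 2.002 Å
```

The real-space refinement recovers the planted filter resolution to
0.002 Å, and the half-map FSC crosses 0.143 at the same point — the
model-referenced and signal-to-noise views of resolution agree on this
synthetic map.  The masked CC of 0.98 reflects the noise level; on a
noise-free self-map it is 1.0.

Partitioning a 0.35 Å inter-model RMSD between structures at 1.56 Å and
2.8 Å nominal resolution:

```bash
$ rsmap partition-errors 0.35 1.56 2.8
0.17 0.31
```

i.e. estimated per-structure coordinate errors of 0.17 Å and 0.31 Å.

## Library surface

The refinement core follows the model/results idiom: build an
`ImagingRefinement(obs_map, model, ...)`, call `.fit(("d_half",
"b_envelope"))`, and read the returned `ImagingFitResults` (parameters,
masked CC, per-iteration trace, `summary()`).  Everything else —
`fsc_curve`, `class_signal_report`, `compare_models`, `pick_waters`,
`enumerate_hbonds`, `assess_his_tautomer`, `make_toy_model`,
`simulate_map`, `perturb_model` — is a plain function over `StructureModel`
and `DensityMap`.  See `docs/methods.md` for the science and the numerical
choices.
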