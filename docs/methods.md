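# Methods

This note documents the models, conventions and numerical choices behind
`rsmap`, and what the synthetic-data validation does and does not show.

## Potential synthesis

Electron scattering of a neutral atom is parameterized as the standard
five-Gaussian sum f(s) = Σᵢ aᵢ·exp(−bᵢ·s²/4) with s = 1/d in Å⁻¹ (the
coefficients ship in `rsmap/data/electron_scattering.tsv` and are verified
against gemmi's International-Tables table in the test suite).  With the
crystallographic B convention (Fourier attenuation exp(−B·s²/4)), the
real-space contribution of an atom with displacement parameter B and
occupancy q is

    ρ(r) = q · Σᵢ aᵢ (4π/(bᵢ+B))^{3/2} exp(−4π² r² / (bᵢ+B))

summed on the grid within a truncation radius of 3.0 + 0.1·√B Å (density
loss < 0.1% for B ≤ 60 Å²; configurable).  Hydrogen centers are nuclear
positions; no bond-shortening is applied.  The imaging filter and envelope
are applied afterwards to the whole grid in Fourier space; synthesis is
therefore exactly linear in per-atom occupancy and in the overall scale.

The Butterworth low-pass is A(s) = [1+(s/s_c)^{2n}]^{−1/2} with
s_c = (1/d½)·3^{−1/(2n)}, so that A = 1/2 exactly at s = 1/d½.  Order
n = 5 by default.  The filter is applied to amplitudes (not intensities);
the alternative is exposed nowhere because nothing downstream depends on
it — d½ is *defined* by half-amplitude attenuation.  A d½ beyond the grid's
Nyquist limit leaves the representable band essentially untouched and is
accepted (the filter is transparent there); an in-band filter on a grid
with voxel > d½/3 is refused as undersampled.

A plain B-factor sharpener (`sharpen`, multiplying amplitudes by
exp(+B·s²/4)) is provided as plumbing; it makes no claim to whiten noise.

## Imaging refinement

`ImagingRefinement` maximizes the Pearson correlation between observed and
calculated potential over grid points within a mask radius of the atoms
(default 2.0 Å; 1.8 Å is the usual choice against unsharpened maps).  The
linear scale and additive offset are profiled out in closed form — the CC
optimum is identical, which is why "least-squares scaling" and
"CC maximization" can be used interchangeably for these two parameters.
The remaining scalars are refined by cycles of bounded scalar line
searches (golden-section/Brent, derivative-free, deterministic), until the
CC improves by less than 1e−5 or 20 passes elapse.  Bounds: d½ ∈
[2·voxel, 100 Å], magnification ∈ [0.95, 1.05], envelope B ∈ [−100, 300] Å².
The result is never worse than the starting point by construction.

Envelope B, a uniform shift of all atomic B, and the filter all act
multiplicatively on the Fourier transform of the raw model potential, so
the raw synthesis is done once per magnification value and cached; a d½ or
envelope step costs one FFT pair.  Because a uniform atomic-B shift and
the envelope are *exactly* covariant (both multiply by exp(−ΔB·s²/4)),
requesting both — or both plus the scale — raises a `CovarianceError`
instead of silently exchanging them.  Envelope B and d½ are jointly
identifiable (a Gaussian and a 10th-power rolloff have different shapes);
the test suite confirms recovery of a planted pair from three distinct
starting points.

Magnification multiplies the calculated map's voxel size with the origin
held fixed, equivalent to scaling atom positions into grid coordinates by
1/m.  The experimental map is never resampled.

## FSC

One shell per Fourier voxel; per-shell normalized cross-correlation of the
half-map Fourier coefficients; threshold crossing (default 0.143) by
linear interpolation in (s, FSC); no crossing returns the Nyquist
resolution with a flag.  The resolution estimate can never be better than
2·voxel.

## Atom-class observability

Classes are backbone (N, CA, C, O, OXT), side-chain carbons, other
side-chain heavy atoms, protein hydrogens, solvent oxygens, solvent
hydrogens, and declared ions.  A titration fixes one mask built from all
atoms (2.0 Å) and sweeps a class's occupancy multiplier over
{1, 0.75, 0.5, 0.25, 0} (endpoints are the defining cases; the grid
density is a choice).  Because synthesis is linear, the calc map is
decomposed once into rest + class components and the sweep costs only
vector algebra.

Two summaries are reported.  The per-electron slope (least-squares slope
of CC vs occupancy divided by Σ Z over the class, H = 1, C = 6, N = 7,
O = 8) is the raw curve summary.  The *signal fraction* is the occupancy
α* that maximizes CC(α); writing the observation as O = k(R + βC) + noise,

    α* = (n0·r1 − n1·r0) / (n1·r1 − n0·c2)

(n0 = ⟨O,R⟩, n1 = ⟨O,C⟩, r0 = |R|², r1 = ⟨R,C⟩, c2 = |C|², all centered
over the mask) and α* = β exactly when the noise vanishes.  The slope is
*not* a usable cross-class signal measure: near a well-fit model CC
responds quadratically about the matching occupancy, so the slope mixes
the class's true signal with a normalization drag proportional to the
class's density power — on a noise-free self-map the slope-based
"per-electron ratio" of hydrogens to side-chain carbons is ≈ 0.2, not 1,
and for a genuinely attenuated class the slope can even change sign.  The
α* estimator has none of these pathologies (self-map → exactly 1 per
class; absent class → 0; 25%-strength class → 0.25), and is what the
class report's `signal_ratio` (vs side-chain carbons) uses.

The estimator assumes the model is complete apart from the titrated class;
a correlated *co-missing* class (e.g. solvent hydrogens absent together
with protein hydrogens) biases α* upward by a few hundredths at SNR 1.

## Structure comparison

Atoms pair on (chain, residue number, atom name); hydrogens are excluded
by default (older comparison partners typically lack them).  No
superposition is applied by default — deposited icosahedral capsid models
share one frame — but a Kabsch least-squares superposition is available
behind a flag.  Terminal atom pairs that are chemically symmetric
(Asp OD1/OD2, Glu OE1/OE2, Phe/Tyr CD/CE pairs, Arg NH1/NH2, Leu CD1/CD2,
Val CG1/CG2) or pseudo-symmetric (Asn OD1/ND2, Gln OE1/NE2 — a χ flip
nearly exchanges them) are swapped when that strictly lowers the residue's
squared deviation, so naming accidents do not inflate RMSDs.

Outliers are per-atom scalar deviations above Q3 + 1.5·IQR, with quartiles
by linear interpolation (the "type 7" convention) computed on each
subset's (all / backbone / Cα) own distribution.  RMSDs are reported
before and after removal.  An RMSD r between structures of nominal
resolutions d_a and d_b partitions into e_a = r·d_a/√(d_a²+d_b²) and
e_b = r·d_b/√(d_a²+d_b²) — the unique split with independent errors
(e_a² + e_b² = r²) proportional to resolution (e_a/e_b = d_a/d_b).

A peptide flip is flagged when a carbonyl O moves more than 2.0 Å while
both flanking Cα move less than 0.5 Å — the signature of a ~180° peptide
rotation modeled into a tubular backbone.

## Solvent and histidine chemistry

Waters are picked from local map maxima above 1.8 σ (σ is the standard
deviation over all voxels — the conventional "σ contour" reference),
farther than 2.2 Å from every modeled atom ("unoccupied"), and within
2.4–3.5 Å of a polar N/O atom or an already accepted water; peaks within
1.0 Å merge, keeping the higher.

Hydrogen bonds are all donor–acceptor N/O/S pairs with D···A ≤ 3.5 Å and,
when the donor hydrogen is modeled, D–H···A ≥ 90° — deliberately generous,
since strict angular ideals over-reject genuine bonds in models refined at
modest resolution.

Histidine tautomers: per ring nitrogen, evidence is collected as
(R1) a Glu/Asp carboxylate O within 3.0 Å → that N protonated (pKa
raised); (R2) a declared metal ion within 2.6 Å → that N deprotonated and
the *other* N protonated; (R3) an unambiguous donor (backbone or
Asn/Gln amide N) in H-bond range → that N accepts (deprotonated), an
unambiguous acceptor (backbone or amide carbonyl O) → that N donates
(protonated); (R4) a nonpolar carbon closer than 2.9 Å → no room for a
proton (deprotonated).  Precedence R2 > R1 > R3 > R4 (metal coordination
is the strongest geometric constraint; the rules themselves imply no
order).  A single surviving verdict per nitrogen maps onto N1 (H at N_δ),
N3 (H at N_ε) or HisH⁺ (both); conflicts or silence yield "ambiguous".
Since R4 only ever argues *against* a proton, HisH⁺ can never rest on
clash evidence.  Hydroxyl partners are treated as ambiguous (they can
donate or accept); ions are declared inputs — no typing is attempted.
The intrinsic ~4:1 N3:N1 preference of free histidine is background
chemistry and never enters the rules.  Map evidence (density at idealized
H positions) is intentionally outside this rule engine.

## Synthetic data

Toy chains are built from ideal internal coordinates (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; helix φ/ψ = −57/−47°, strand −139/135°, coil
from a small fixed table) over a repeating Ala/Ser/Asp/His pattern, with
riding hydrogens at ideal positions, waters placed 2.6–3.2 Å from polar
atoms, and B-factors drawn from N(10, 5²) Å² clipped at zero (a plausible
well-ordered-structure distribution; mean and spread are spec fields).
The strand-pair fold lays two extended strands side by side at sheet
spacing; it is a geometric stand-in, not a hydrogen-bond-perfect sheet.

Simulated maps are the filtered model potential plus white Gaussian
real-space noise.  The spec's `noise` parameter is the full-map noise σ
relative to the clean map's whole-box RMS; each half map receives √2×
that, so the full map (the half-map average) has exactly the nominal
noise.  The box-wide reference is deliberate: it keeps a nominal SNR
meaningful for Fourier statistics as well as masked real-space ones — for
a molecule occupying a few percent of the box, a mask-relative reference
of the same nominal value corresponds to several-fold worse Fourier SNR,
and the half-map FSC crossing then lands far below the planted filter
resolution rather than at it.

`perturb_model` displaces every atom isotropically with per-coordinate σ
= scale/√3, so the *scale is the expected 3-D RMS displacement* and the
measured RMSD against the original equals it in expectation; a random
fraction of atoms instead receives the outlier scale, and the planted
outlier flags are returned as ground truth.

What the synthetic validation shows: the estimators recover planted
imaging parameters, signal fractions and outlier structure under white
noise and an exactly correct model.  What it does not show: behavior
under colored (correlated) reconstruction noise, model incompleteness or
conformational heterogeneity, CTF residuals, or masking artifacts — real
maps have all of these, and the absolute tolerances measured here do not
transfer.

## Problem sizes and determinism

Validation runs use 6–60-residue toy models on 64³ grids at 0.5–0.8 Å
voxels — small enough that the full suite runs in seconds while every
code path (synthesis, FFT filters, refinement, titration, comparison,
picking) is exercised at realistic sampling rates.  Every stochastic step
takes an explicit seed; generators are pure functions of their spec, and
rerunning any command with the same resolved configuration reproduces its
outputs bit-identically.
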