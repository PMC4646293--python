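# Methods

## Relaxation fitting

Peak heights of a pseudo-3D relaxation series are modeled as
*I(t) = A·exp(−R·t)* and fitted by nonlinear least squares
(`scipy.optimize.curve_fit`, Trust Region Reflective with the rate bounded
positive). The two-parameter model deliberately omits an offset: peak-height
decays of inversion-recovery/spin-echo series decay to zero, and an offset is
not identifiable on the 8–12 point delay grids these experiments use
(T1: 10–1800 ms in 12 steps; T2: 20–160 ms in 8 steps; titration T1:
70–5000 ms in 10 steps). Initialization is the linear regression of log *I*
on *t* over points with positive intensity, which makes the fit
scale-equivariant and reliable across rates of at least 0.2–50 s⁻¹ on these
grids (property-tested). Standard errors come from the Jacobian-based
covariance at the optimum; a Monte-Carlo test (200 replicates, 2 %
multiplicative noise) confirms the reported rate stderr tracks the empirical
scatter within a factor of 1.5. No residual bootstrap is run by default.

The heteronuclear NOE is the plain ratio saturated/reference with first-order
error propagation |ratio|·√((σ_sat/sat)² + (σ_ref/ref)²). Negative ratios are
physical (fast internal motion) and preserved.

## Mobility segmentation

A residue is *rigid* when every available criterion passes: T2 ≤ 100 ms
(tumbling like a large, micelle-bound particle) and NOE ratio ≥ 0.5. The NOE
threshold is a design choice: the field's qualitative benchmarks are "close
to 0.8" for rigid backbone versus reduced/negative for flexible segments, so
0.5 separates the two regimes without claiming more precision than exists;
it is configurable. When a residue carries several atoms, the backbone amide
is authoritative. Maximal runs of rigid residues shorter than
`min_run_length` (default 3) are demoted to flexible, suppressing isolated
false positives; `rigid_runs` is recomputed from the final labels so the two
representations can never disagree. Residues without data are `unknown`.

## Solvent PRE and immersion depth

The PRE slope is extracted per proton by ordinary least squares of R1 against
Gd concentration over all titration points (≥ 3 concentrations including 0),
rather than pairwise differences — this uses all data and yields a defensible
slope stderr and r². Negative slopes are kept with a flag: they occur by
noise for fully solvent-exposed protons and are routed to the lower-only
restraint branch rather than treated as errors.

Depth conversion uses the closed form depth = (k/PRE)^⅓ − g with
g = 7.98 Å and k = 253 s⁻¹ mM⁻¹ Å³ (k's unit carries the s⁻¹ implied by the
PRE slope unit). This functional form is locked in by an oracle test: for
all eleven benchmark protons of the anchor peptide, radius 30 Å minus the
computed depth reproduces the published center distance to the printed
0.1 Å. Depth uncertainty is first-order propagation,
σ_depth = ⅓·(k/PRE)^⅓/PRE·σ_PRE, and a Monte-Carlo test confirms it within a
factor of 1.5 at 2 % intensity noise. The micelle radius is a configured
input (default 30 Å with peptide, 21 Å free), not computed inside the
pipeline — it is a measured constant of the sample. A Stokes–Einstein helper
(r = k_B·T/(6π·η·D)) converts a translational diffusion coefficient to a
hydrodynamic radius when needed.

Protons with PRE ≤ 0 have no finite depth under the model; they carry
sentinel values (depth −∞, distance +∞, rendered "> cutoff" in
human-readable output). Distances are reported at 0.1 Å in human-readable
output and full precision in machine output.

## Restraint generation

Distances within the 28 Å cutoff become bounded restraints
[r − 2, r + 2] Å at weight 0.30 relative to NOE restraints; beyond the
cutoff, lower-only restraints at max(cutoff, r − 2) Å; sentinel distances get
lower-only restraints at the cutoff. Whether the original lower bounds used
r − 2 or the cutoff is not documented anywhere we could anchor to, so the
conservative max() of the two is the default and both constants are
configurable. The weight is emitted as a per-restraint numeric column;
consumers without per-restraint weights should apply it as a class weight.
For export, the micelle center is materialized as atom `Q1` of a pseudo
residue `CEN` numbered one past the last peptide residue, because restraint
formats need a concrete atom pair; the convention is stated in the file
header. Restraints address attached protons only; no separate ¹⁵N/¹³C
treatment is attempted.

## Secondary chemical shifts

Deviations Δδ = δ_obs − δ_rc are computed for ¹³Cα, ¹³CO and ¹Hα against a
bundled Wishart-style random-coil table (provenance label
`wishart-style-builtin`; overridable by file — results should always state
which reference produced them). No temperature, pH or neighbor corrections
are applied; the analysis is a direct comparison. Classification first
smooths each nucleus with a centered moving average (default window 3,
shrinking at edges and gaps; window 1 disables smoothing), then calls helix
when every available deviation reaches `call_fraction` (default 0.5) of the
full-helix magnitudes (+2.6, +1.7, −0.38 ppm) with the right signs, sheet
analogously (−1.4, −1.4, +0.38 ppm), else coil; fewer than two nuclei give
`insufficient`. The fractional threshold exists because the published
magnitudes describe *fully formed* elements, while peptides form partial,
fraying structure. A 10⁻⁹ ppm slack keeps exact-boundary calls stable
against floating-point error.

## Synthetic data generator

The generator encodes the study conditions the analysis assumes:

* **Scenario** — the 34-residue anchor peptide (full-length numbering
  V10–K43; residues 18–39 are the published anchor sequence, residues 17 and
  40–43 are plausible filler as their identity is not printed in our
  sources). The eleven benchmark protons carry the depths implied by their
  published center distances at radius 30 Å; remaining anchor residues
  (Ser19–Cys30) draw a depth uniformly from [1, 8] Å once per seed; flanking
  termini are solvent-exposed and receive PRE = 0.6 s⁻¹ mM⁻¹ — larger than
  the surface value k/g³ ≈ 0.498, so they resolve beyond the 28 Å cutoff and
  exercise the lower-only branch. The rigid core (residues 20–32) has
  T2 = 80 ms and NOE 0.7; flanks T2 = 300 ms and NOE −0.1. Gly20–Gly24 is
  helical for shift simulation. Diamagnetic R1 values are deterministic in
  0.5–2 s⁻¹ (plausible backbone range; true per-residue values are not
  published).
* **Noise** — multiplicative Gaussian on intensities (peak heights scale
  with signal), additive Gaussian on shifts. One global seed is split into
  per-(atom, condition) substreams via CRC32, so adding an atom never
  changes another atom's noise, and all generators are pure functions of
  (scenario, design, noise, seed).

What the generator does **not** emulate: spectral lineshapes, peak overlap,
non-uniform-sampling artifacts, chemical exchange, Gd-induced micelle
perturbation, curved-interface corrections to the PRE model, or realistic
per-residue relaxation dispersion — passing tests demonstrate the
*analysis* recovers its own generating model, not that real spectra are this
clean. One knowing idealization: prolines are simulated with backbone-amide
observables they cannot have in reality, so that segmentation of the
contiguous rigid core is testable end to end.

## Problem sizes and numerical choices

Monte-Carlo tests use 200 replicates for stderr calibration and 20 replicate
seeds (6 concentrations × 10 delays per proton) for end-to-end depth
recovery; these sizes give stable medians while keeping the suite quick.
The noisy-recovery acceptance bar is a median center-distance error within
±0.5 Å per immersed proton at 2 % intensity noise. Fits are bounded to
R > 10⁻¹² s⁻¹; pre↔depth round-trips hold to 10⁻⁹ Å over the physical
range. Restraint files are byte-stable across runs (no timestamps).

## Known limitations

* The PRE depth model is a calibrated empirical form for a spherical
  micelle; it ignores partitioning of the paramagnet and interface curvature.
* Random-coil references vary between published tables by a few tenths of a
  ppm; absolute deviation bars therefore depend on the chosen table, which is
  why the classification is fractional and the provenance label travels with
  results.
* No model-free (Lipari–Szabo) analysis, rotational-diffusion tensors, or
  exchange modeling; T1/T2/NOE are used only descriptively for segmentation.
* NMR-STAR and spectrometer vendor formats are out of scope; TSV tables are
  the interchange unit.
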