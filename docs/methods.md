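# Methods

This note records the models, conventions and design choices behind
`csp-pocket`, in the spirit of a package methods appendix: what is assumed,
what the tunables mean, and what the synthetic benchmarks do and do not
demonstrate.

## 1. Chemical-shift-perturbation model

A two-state binding equilibrium between a ¹⁵N-labelled protein P and an
unlabelled ligand L is observed through a series of ¹H-¹⁵N HSQC spectra at
increasing molar ratios L:P. Each backbone amide contributes one cross-peak
whose behaviour depends on the exchange rate relative to the shift
difference Δω between free and bound forms:

* **slow exchange** (k_ex ≪ Δω): separate free and bound peaks with
  populations (1−f) and f, where f is the bound fraction; intermediate
  points show both peaks attenuated by exchange broadening;
* **fast exchange** (k_ex ≫ Δω): a single peak at the population-weighted
  position.

The combined CSP per residue is

    Δδ = sqrt((ΔδH² + (ΔδN / w)²) / 2),     w = 5 by default,

the root-mean-square of the proton shift change and the nitrogen change
scaled by the ratio of typical amide ¹⁵N to ¹H shift dispersions. `w` is a
parameter (`n_weight`) because other conventions (e.g. gyromagnetic-ratio
weights ≈ 0.10–0.14 applied without the /2) exist; all internal distances
use the same scaling so the choice is consistent end to end.

**Significance threshold.** The cutoff is `mean + k·sd` over the numeric
Δδ values with the *sample* (n−1) standard deviation — the conservative
choice at the ~100-residue scale — and `k = 1` by default. Residues are
selected by strict inequality (`Δδ > cutoff`). Two reporting subtleties:

* residues whose endpoint position had to be supplied from an external
  bound-state assignment (the NOESY-style route, see §2) are *excluded*
  from the mean/sd by default (`include_reassigned=False`) but are still
  compared against the cutoff and reported. Their extreme Δδ (here
  ≈0.5–0.75 ppm) would otherwise inflate the standard deviation enough to
  push the cutoff above genuinely perturbed residues; with the default the
  cutoff computed on the simulated defaults comes out at ≈0.097 ppm
  (measured by `scripts/acceptance.py`), i.e. at the ~0.1 ppm scale typical
  of such titrations. The flag restores the all-inclusive convention.
* residues with no computable endpoint CSP ("disappeared") are never
  imputed and never silently included in the significant list.

## 2. Peak tracking across the titration

Tracking is point-to-point: each residue's last observed position is
matched against the next point's peaks. Matching minimises the **total**
scaled distance `d = sqrt(Δh² + (Δn/w)²)` over all residue–peak pairs
(Hungarian algorithm), gated per axis by tolerances `tol_h`/`tol_n`
(defaults 0.04 ppm ¹H, 0.3 ppm ¹⁵N — several times the expected
point-to-point jitter, far below typical peak separations). Global
assignment rather than greedy matching makes the result provably the
minimum-total-distance assignment, which the test suite verifies against
exhaustive enumeration on small sets.

Continuity matters: only residues observed at the *previous* point are
eligible for strict matching. A residue whose peaks vanished (slow-exchange
broadening) re-enters by one of two rescue routes, both restricted to peaks
left unclaimed by the strict pass:

1. **relocation** — a wider proximity window (defaults 0.35 ppm ¹H,
   1.75 ppm ¹⁵N) around the last known position, modelling how a
   spectroscopist re-identifies a bound peak that reappears near the free
   position;
2. **bound-state re-assignment** — matching at the residue's position in a
   supplied bound-state shift table (strict tolerances). This mirrors the
   practice of assigning severely displaced bound peaks from a NOESY
   experiment on the saturated complex; endpoints recovered this way carry
   the `bound_ref` provenance label that drives the threshold exclusion of
   §1. When the supplied table also covers moderately displaced residues,
   it refines their matching too, but they keep the `relocated` label when
   their bound position lies within the relocation window — the label
   records whether external information was *necessary*, not whether it was
   used.

**Exchange classification.** A residue is *slow* if it is absent at ≥1
intermediate ratio in (0, saturation) while present at the final point, or
its endpoint came from a rescue route, or its final jump exceeds 3× the
scaled tracking tolerance; *fast* if present and strictly traceable at
every point; otherwise *undetermined* (notably: absent at the final point).

**Stoichiometry.** For each ratio, the mean Δδ versus the free reference is
taken over residues observable at that ratio; the plateau onset — the
smallest ratio after which every increment of the mean is below a tolerance
(default 0.005 ppm) — is reported as the stoichiometry. Using
observable-at-that-ratio residues (not only residues tracked at *every*
ratio) is deliberate: under slow exchange the plateau signature *is* the
reappearance of the perturbed residues at their final positions, and a
common-residue mean would be blind to it. Saturation below a 1:1 ratio is
flagged (excess protein or higher-order binding); a series that never
flattens reports the last ratio as a lower bound.

## 3. Homolog pocket comparison

Global (Needleman–Wunsch) alignment with affine gaps; defaults BLOSUM62,
gap open 10, extend 0.5, a gap of length L costing `open + (L−1)·extend`,
end gaps penalised. Sequence identity is reported over mutually non-gap
columns (the main convention; the alternative "over the shorter sequence"
denominators can be derived from the alignment object). The residue map is
the ordered set of mutually aligned columns; for the bundled Musashi
fixtures it is the constant shift-by-one correspondence (MSI2 residue k ↔
MSI1 residue k−1 over residues 21–104).

Superposition is the Kabsch/SVD least-squares rotation with the determinant
correction that excludes reflections, applied to centroid-centred mapped Cα
pairs; the RMSD is recomputed from the transformed coordinates because the
solver's internal residual loses precision to cancellation on near-exact
fits. Mapped pairs are restricted to a configurable structured core
(default residues 23–100) when structures are compared, since disordered
termini would dominate the residual. Pocket conservation reports the mapped
pairs significant on both sides and a Jaccard-style ratio (conserved /
mapped-with-either-side-significant); significant residues outside the
mapped range count as unshared.

Secondary-structure elements are configuration inputs (labelled inclusive
intervals; defaults carry the five β-strands and two α-helices of the
MSI2-RRM1 model), not computed from coordinates — the annotation exists to
summarise where a pocket clusters, not to predict structure.

## 4. Binding isotherms

**Saturation.** Signal model `y = f_min + (f_max − f_min)·b(x)` where b is
the exact 1:1 bound fraction with ligand depletion,

    bound = ((p + l + Kd) − sqrt((p + l + Kd)² − 4·p·l)) / 2,   b = bound/l.

The quadratic form is required because the probe is at ~2 nM, the same
order as the Kd; the naive hyperbola `p/(p+Kd)` is biased there (the
package exposes it as a comparison mode, and a test quantifies the bias).
Fitting is separable least squares: for fixed Kd the model is linear in
(f_min, f_max), solved in closed form, so Kd is found by a coarse log-grid
scan plus bounded 1-D refinement — immune to the starting-point failures of
joint 3-parameter optimisation. A curve whose dynamic range does not exceed
3× a trend-insensitive noise estimate (second differences) returns a
*no-binding* verdict instead of a meaningless Kd.

**Uncertainty.** Residual-resampling bootstrap, 500 replicates, seeded
(default seed 20171120). Residuals are rescaled by sqrt(n/(n−p)) to undo
the variance deflation of a p = 3 parameter fit, and the 95% interval is
`Kd·exp(±t₀.₉₇₅,ₙ₋ₚ · se(log Kd*))` — a bootstrap-SE interval with a
Student-t quantile, which holds near-nominal coverage at plate-assay sample
sizes where the plain percentile interval runs narrow. Measured calibration
(200 simulated curves, 1% noise): median relative Kd error ≈2–3%, interval
coverage ≈94–96% (`scripts/acceptance.py`).

**Competition.** Free protein in the one-protein/two-ligand equilibrium
solves `pf·(1 + L/(Kd_L+pf) + C/(Ki+pf)) = P`, a cubic in pf, by a
safeguarded bracketed root on [0, P] (machine-precision tolerances; the
tests cross-check against the closed-form cubic roots). The probe signal
uses the same linear envelope, fitted for Ki by the same separable search;
an empirical IC50 (midpoint crossing) is reported alongside. A flat curve
returns *no-displacement*.

Concentrations are nM throughout; file readers require an explicit unit
column and convert µM→nM rather than guessing.

## 5. What the synthetic data emulate — and what they do not

Defaults mirror the study conditions the package was designed around:
110 assigned residues numbered from 21, protein 80 µM, ratios 0, 0.3, 0.5,
0.7, 1.0, 1.3, slow exchange with Kd 10 nM, 19 pocket residues of which
seven are severely displaced (ΔδH 0.5–0.8 / ΔδN 2.5–4.0 ppm) and twelve
moderately (ΔδH 0.13–0.30 / ΔδN 0.65–1.5 ppm, weighted Δδ ≥ 0.13),
position noise σ_H 0.005 / σ_N 0.03 ppm, detection floor 0.25.

Free-state positions are generic backbone amide statistics (δH ~ N(8.3,
0.6), δN ~ N(119, 4), truncated to plausibility windows) — the goal is the
*statistical* structure of a crowded HSQC (peak density, chance overlap),
not the spectrum of any particular protein. Exchange broadening is modelled
purely as intensity loss, `1 − broadening·4f(1−f)` (maximal at
half-saturation, default broadening 0.8), applied to both members of a
pocket doublet; no lineshapes, relaxation or spin physics. Dropout is a
hard detection floor. Consequently, passing the recovery benchmarks shows
that the *analysis logic* is sound under realistic geometry and noise; it
does not certify performance against overlapped multiplets, titration
drift, temperature shifts, or assignment errors in real spectra.

The structure generator produces a compact 3.8 Å-step random chain with a
planted rigid transform and isotropic coordinate noise; for noise σ per
coordinate the expected superposition residual is √3·σ, which the noisy
benchmarks recover within 20%.

## 6. Numerical and degenerate-input conventions

* Parsers reject rather than repair: out-of-window shifts and atoms a
  residue type cannot carry (Gly Cβ, Pro amide H) are dropped with logged
  warnings; duplicate (residue, atom) rows are integrity errors.
* Numbering offsets act as a group (applying +a then +b equals +(a+b)) and
  the construct scale passes through zero, so tag constructs numbered from
  −3 renumber cleanly.
* The discriminant of the quadratic bound fraction is clamped at zero
  before the square root (it is non-negative analytically; rounding can
  make it −ε) and the fraction clipped to [0, 1].
* Assignment ties in peak matching are broken deterministically (cost
  matrix ordered by residue number); alignment ties follow the
  aligner's deterministic first-reported optimum.
* Collinear Cα sets superpose with a warning: the in-line rotation
  component is undetermined although the RMSD is still minimal.
* Fewer than 3 mapped atoms, fewer than 2 numeric CSPs, fewer than 5 curve
  points, or a titration without a ratio > 1 raise typed errors rather
  than returning extrapolations.

## 7. Problem sizes used by the shipped benchmarks

The default test suite and `scripts/acceptance.py` analyse 20 simulated
titrations (110 residues × 6 points each), 200 simulated binding curves
with 500 bootstrap replicates apiece, 1,000 short-sequence alignment pairs
against exhaustive enumeration, 10 noisy 75-atom superpositions against 100
random rotations each, and a 10×10×10 log-grid equilibrium comparison —
sizes chosen so the complete battery runs in a few minutes on one core
while keeping every Monte-Carlo margin far from its pass boundary.

## 8. Known limitations

* Intermediate exchange is not modelled or detected as such; residues in
  that regime will surface as `undetermined` or as implausible trajectories.
* Per-residue Kd estimation from fast-exchange trajectories is out of
  scope (the target system is slow-exchange).
* The Sparky reader covers the common `assignment w1 w2 [height]` dialect
  only; axis order is a flag (`w1 = ¹⁵N` by default) because peak lists do
  not declare it.
* NMR-STAR support is a read-only subset (the `Atom_chem_shift` loop);
  quoted values and multi-line fields are not handled.
* The relocation window trades recall against misassignment risk; in
  pathologically crowded regions a reappearing peak can still be matched to
  a wrong neighbour, exactly as in manual analysis. Supplying bound-state
  assignments removes most of that risk.
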