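# csp-pocket

Chemical-shift-perturbation (CSP) mapping of protein–ligand binding pockets
from ¹H-¹⁵N HSQC titrations, with cross-homolog pocket comparison and
binding-isotherm fitting. Built for the kind of study in which an
RNA-recognition motif (RRM) such as Musashi-2 RRM1 is titrated with a short
RNA, the perturbed residues define the binding pocket, and the pocket is
compared with that of a homolog (Musashi-1 RBD1) by sequence alignment and
Cα superposition.

## Who this is for

Structural biologists and NMR spectroscopists who have

* an assigned free-state backbone shift table (TSV or the `Atom_chem_shift`
  loop of an NMR-STAR/BMRB deposit),
* one Sparky-style 2D peak list per titration point,
* optionally: bound-state assignments for severely displaced peaks (e.g.
  from a ¹⁵N-edited NOESY of the saturated complex), homolog sequences
  (FASTA), structures (PDB), and fluorescence (FP / TR-FRET) binding-assay
  tables,

and want a reproducible path from those files to a ranked, thresholded
pocket call, an exchange-regime and stoichiometry assessment, a homolog
pocket-conservation report, and fitted dissociation constants.

## The computations at the core

**Weighted CSP.** For each residue with amide shifts in both states,

    Δδ = sqrt( (ΔδH² + (ΔδN / 5)²) / 2 )

with the conventional ¹⁵N scaling of 5 (exposed as `n_weight`). The
significance cutoff is `mean + k·sd` (sample standard deviation, `k = 1` by
default) over the numeric Δδ values; residues strictly above it are called
significant.

**Peak tracking.** Peaks are matched point-to-point by minimum total
distance in the scaled space `d = sqrt(Δh² + (Δn/5)²)` (Hungarian
assignment, per-axis tolerance gates). Slow-exchange residues that broaden
out at sub-stoichiometric ratios re-enter either through a wider proximity
("relocation") search when they reappear near their free position, or
through supplied bound-state assignments when they reappear far away.
Residues absent at intermediate ratios but present at saturation are
classified slow exchange; continuously traceable residues are fast.
The binding stoichiometry is the molar ratio at which the mean CSP stops
changing (plateau onset).

**Homolog comparison.** Needleman–Wunsch global alignment with affine gaps
(BLOSUM62, open 10, extend 0.5) gives a residue correspondence; mapped Cα
pairs are superposed by the Kabsch least-squares rotation (reflections
excluded) and pocket conservation is reported as conserved significant
pairs plus a Jaccard overlap on the mapped correspondence.

**Binding isotherms.** Saturation curves are fitted with the exact 1:1
ligand-depletion (quadratic) bound fraction — necessary because the probe
concentration (~2 nM) is comparable to the Kd — and competition curves with
the one-protein/two-ligand cubic equilibrium for Ki. Both are
`Model.fit() → Results` objects with `summary()`; Kd uncertainty comes from
a seeded residual-resampling bootstrap.

## Worked example

Simulate the default slow-exchange titration (110 residues, 19 planted
pocket residues, protein 80 µM, ligand:protein ratios 0–1.3, Kd 10 nM) and
analyse it end to end:

```python
from csp_pocket import (TitrationSimSpec, simulate_titration, track_peaks,
                        compute_csp, compute_threshold, select_significant)
from csp_pocket.csp_core import endpoint_table, profiles_by_ratio, assess_saturation

series, truth = simulate_titration(TitrationSimSpec(seed=7))
tracking = track_peaks(series, bound_reference=truth.bound_shifts)
endpoint, sources = endpoint_table(tracking, series.reference_assignments)
profile = compute_csp(series.reference_assignments, endpoint, endpoint_sources=sources)
threshold = compute_threshold(profile)
print(f"cutoff = {threshold.mean:.4f} + {threshold.sd:.4f} = {threshold.cutoff:.4f} ppm")
print("significant residues:", select_significant(profile, threshold))
sat = assess_saturation(profiles_by_ratio(tracking, series.reference_assignments))
print("stoichiometry:", sat.stoichiometry)
```

prints

```
cutoff = 0.0284 + 0.0683 = 0.0968 ppm
significant residues: [21, 22, 24, 25, 26, 27, 29, 30, 31, 32, 50, 61, 62, 63, 65, 66, 94, 95, 97]
stoichiometry: 1.0
```

— the cutoff lands at ≈0.1 ppm, every planted pocket residue is recovered
with no false positives, and the plateau of the mean CSP at a 1:1 molar
ratio reports the binding stoichiometry. A binding fit on a simulated
TR-FRET-style curve (probe 2 nM, Kd 2.07 nM, 1% noise):

```python
from csp_pocket import SaturationBindingModel
from csp_pocket.synthetic_data import simulate_saturation_curve

curve, _ = simulate_saturation_curve(2.07, probe_total=2.0, noise_frac=0.01, seed=42)
print(SaturationBindingModel(curve).fit().summary())
```

```
Saturation binding fit (1:1, ligand depletion)
======================================================
verdict        : binding
n points       : 12
probe total    : 2 nM
Kd             : 2.179 nM
95% CI (boot)  : [2.056, 2.308] nM
f_min / f_max  : 0.1022 / 1.003
residual SS    : 0.0002586
```

The fitted Kd of 2.18 nM recovers the planted 2.07 nM within the noise, and
the bootstrap interval quantifies the remaining uncertainty.

The same workflow runs from the shell over files:

```sh
csp-pocket simulate --seed 7 --out sim/
csp-pocket csp --config run.yaml      # or: map, fit, run-all
```

with a YAML configuration naming the inputs (see
`csp_pocket.pipeline.RunConfig` for every knob and its default).

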