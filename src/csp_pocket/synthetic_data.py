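"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be simulated here: HSQC titration
series under two-state slow or fast exchange, saturation and competition
binding curves, structure pairs for superposition tests, and the fixture
residue lists / correspondences of the two homologous RRM domains the
package was built around (Musashi-2 RRM1 and Musashi-1 RBD1).

The default :class:`TitrationSimSpec` mirrors the study conditions: 80 µM
protein observed at ligand:protein molar ratios 0, 0.3, 0.5, 0.7, 1.0 and
1.3, ~110 assigned residues numbered from 21, 19 pocket residues (seven of
them severely displaced), slow exchange with a Kd of 10 nM, and a peak
detection floor of 25% of the free-state intensity.

Free-state amide shifts are drawn from generic backbone statistics
(δH ~ N(8.3, 0.6) ppm, δN ~ N(119, 4) ppm); the goal is the statistical
structure of a crowded HSQC, not spectral realism for any one protein.
Intermediate-exchange broadening is modelled purely as intensity loss: both
members of a slow-exchange doublet are attenuated by
``1 − broadening · 4·f·(1−f)`` (maximal at 50% saturation), and any peak
below the detection floor is dropped. Everything is reproducible from the
seed; same seed, byte-identical serialised output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding_fit import (
    BindingCurve,
    bound_fraction_quadratic,
    bound_probe_fraction_competition,
)
from .csp_core import TitrationPoint, TitrationSeries, weighted_csp
from .errors import InputError
from .shift_io import (
    Peak2D,
    SequenceRecord,
    ShiftRecord,
    ShiftTable,
    StructureCA,
    write_shift_table,
    write_sparky_list,
)
from .structure_map import ResidueMap

# ---------------------------------------------------------------------------
# fixture residue lists of the two homologous RRMs
# ---------------------------------------------------------------------------

#: 19 residues of MSI2-RRM1 significantly perturbed at the 1:1 point
#: (G21 K22 F24 I25 G26 G27 S29 W30 Q31 T32 C50 S61 R62 G63 G65 F66 K94 V95 F97)
MSI2_SIGNIFICANT_19 = (21, 22, 24, 25, 26, 27, 29, 30, 31, 32, 50,
                       61, 62, 63, 65, 66, 94, 95, 97)

#: the 17-residue subset mapped onto the structured core (drops flexible G21, K22)
MSI2_SIGNIFICANT_17 = tuple(r for r in MSI2_SIGNIFICANT_19 if r not in (21, 22))

#: 17 residues of MSI1-RBD1 with pronounced CSPs in the published titration
#: (F23 I24 G25 G26 S28 W29 Q30 T31 M52 S60 R61 G62 G64 F65 K93 V94 F96)
MSI1_PRONOUNCED_17 = (23, 24, 25, 26, 28, 29, 30, 31, 52, 60,
                      61, 62, 64, 65, 93, 94, 96)

#: the seven severely displaced residues (bound positions required NOESY
#: re-assignment) and their one-residue-offset equivalents in MSI1-RBD1
MSI2_SEVERE_7 = (25, 27, 30, 61, 62, 65, 97)
MSI1_SEVERE_7 = (24, 26, 29, 60, 61, 64, 96)

#: secondary-structure elements of the MSI2-RRM1 model (inclusive intervals)
MSI2_SSE_RANGES = {
    "b1": (24, 26), "a1": (34, 43), "b2": (47, 52), "b3": (64, 69),
    "a2": (73, 81), "b4": (84, 86), "b5": (89, 96),
}

MSI2_STRUCTURED_CORE = (23, 100)


@dataclass
class ProteinFixtures:
    """Published residue lists and correspondences shipped as fixtures."""

    msi2_significant_19: tuple[int, ...]
    msi2_significant_17: tuple[int, ...]
    msi1_pronounced_17: tuple[int, ...]
    msi2_severe_7: tuple[int, ...]
    msi1_severe_7: tuple[int, ...]
    residue_map: ResidueMap          # MSI2 residue k ↔ MSI1 residue k−1
    sse_ranges: dict[str, tuple[int, int]]
    structured_core: tuple[int, int]
    sequences: tuple[SequenceRecord, SequenceRecord] | None = None


def make_fixture_protein() -> ProteinFixtures:
    """Fixture lists for the MSI2-RRM1 / MSI1-RBD1 pocket comparison.

    The residue correspondence is the constant shift-by-one map (MSI2
    residue k ↔ MSI1 residue k−1) over the aligned span. Real sequences are
    an optional user-supplied input and are not bundled.
    """
    return ProteinFixtures(
        msi2_significant_19=MSI2_SIGNIFICANT_19,
        msi2_significant_17=MSI2_SIGNIFICANT_17,
        msi1_pronounced_17=MSI1_PRONOUNCED_17,
        msi2_severe_7=MSI2_SEVERE_7,
        msi1_severe_7=MSI1_SEVERE_7,
        residue_map=ResidueMap.shift(21, 104, -1),
        sse_ranges=dict(MSI2_SSE_RANGES),
        structured_core=MSI2_STRUCTURED_CORE,
    )


# ---------------------------------------------------------------------------
# titration simulation
# ---------------------------------------------------------------------------

_AA_NO_PROLINE = "ACDEFGHIKLMNQRSTVWY"


def default_delta_bound() -> dict[int, tuple[float, float]]:
    """Planted bound-state offsets (ΔδH, ΔδN in ppm) for the default pocket.

    The seven severe residues get ΔδH 0.5–0.8 / ΔδN 2.5–4.0 (weighted Δδ
    ≈ 0.5–0.75, beyond any proximity search); the twelve moderate residues
    get ΔδH 0.13–0.30 / ΔδN 0.65–1.5 (weighted Δδ ≈ 0.13–0.30, recoverable
    by a wider relocation search near the free position).
    """
    offsets: dict[int, tuple[float, float]] = {}
    for i, res in enumerate(MSI2_SEVERE_7):
        offsets[res] = (0.5 + 0.05 * i, 2.5 + 0.25 * i)
    moderate = [r for r in MSI2_SIGNIFICANT_19 if r not in MSI2_SEVERE_7]
    for i, res in enumerate(moderate):
        sign = 1.0 if i % 2 == 0 else -1.0
        offsets[res] = (sign * (0.13 + 0.015 * i), sign * (0.65 + 0.07 * i))
    return offsets


@dataclass
class TitrationSimSpec:
    """Conditions of a simulated two-state HSQC titration."""

    n_residues: int = 110
    first_residue: int = 21
    pocket_residues: tuple[int, ...] = MSI2_SIGNIFICANT_19
    delta_bound: dict[int, tuple[float, float]] = field(default_factory=default_delta_bound)
    kd: float = 10.0                 # nM
    protein_total: float = 80.0      # µM
    ratios: tuple[float, ...] = (0.0, 0.3, 0.5, 0.7, 1.0, 1.3)
    exchange: str = "slow"           # slow | fast
    noise_sigma: tuple[float, float] = (0.005, 0.03)  # (ppm 1H, ppm 15N)
    detection_floor: float = 0.25    # fraction of free-state intensity
    broadening: float = 0.8          # max exchange-broadening intensity loss
    seed: int = 0

    def __post_init__(self) -> None:
        lo = self.first_residue
        hi = self.first_residue + self.n_residues - 1
        if not all(lo <= r <= hi for r in self.pocket_residues):
            raise InputError("pocket residues must lie within the simulated range")
        if not self.ratios or self.ratios[0] != 0.0:
            raise InputError("ratios must start at 0")
        if not 0 <= self.detection_floor < 1:
            raise InputError("detection_floor must be in [0, 1)")
        if self.exchange not in ("slow", "fast"):
            raise InputError("exchange must be 'slow' or 'fast'")
        missing = set(self.pocket_residues) - set(self.delta_bound)
        if missing:
            raise InputError(f"pocket residues without delta_bound offsets: {sorted(missing)}")

    @property
    def residue_numbers(self) -> list[int]:
        return list(range(self.first_residue, self.first_residue + self.n_residues))


@dataclass
class GroundTruth:
    """Machine-readable truth emitted alongside every simulated dataset."""

    pocket_residues: tuple[int, ...]
    kd: float
    stoichiometry: float
    true_csp: dict[int, float]              # weighted Δδ per residue
    free_shifts: ShiftTable | None = None
    bound_shifts: ShiftTable | None = None

    def to_dict(self) -> dict:
        return {
            "pocket_residues": list(self.pocket_residues),
            "kd_nM": self.kd,
            "stoichiometry": self.stoichiometry,
            "true_csp": {str(k): v for k, v in sorted(self.true_csp.items())},
        }


def simulate_titration(spec: TitrationSimSpec) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate a two-state binding titration observed as HSQC peak lists.

    Free amide positions are drawn once per residue; pocket residues acquire
    their planted offsets in the bound state. The bound fraction f at each
    molar ratio follows the exact 1:1 (ligand-depletion) equilibrium for the
    stated Kd and totals. Under slow exchange each pocket residue gives a
    free-position peak of intensity (1−f) and a bound-position peak of
    intensity f, both attenuated by exchange broadening and subject to the
    detection floor; under fast exchange a single peak sits at the
    population-weighted position. Gaussian position noise is added to every
    detected peak of every non-reference point.
    """
    rng = np.random.default_rng(spec.seed)
    warned = []
    for res in spec.pocket_residues:
        dh, dn = spec.delta_bound[res]
        if weighted_csp(dh, dn) < 3 * weighted_csp(spec.noise_sigma[0], spec.noise_sigma[1]):
            warned.append(res)
    if warned:
        import logging
        logging.getLogger(__name__).warning(
            "planted offsets below 3x noise for residues %s — unrecoverable by design",
            warned,
        )

    residues = spec.residue_numbers
    types = {r: _AA_NO_PROLINE[rng.integers(len(_AA_NO_PROLINE))] for r in residues}
    free_h = {r: _truncated_normal(rng, 8.3, 0.6, -2.0, 14.0) for r in residues}
    free_n = {r: _truncated_normal(rng, 119.0, 4.0, 90.0, 140.0) for r in residues}
    bound_h = dict(free_h)
    bound_n = dict(free_n)
    for res in spec.pocket_residues:
        dh, dn = spec.delta_bound[res]
        bound_h[res] = free_h[res] + dh
        bound_n[res] = free_n[res] + dn

    def table(h: dict, n: dict, label: str, ratio: float) -> ShiftTable:
        recs = []
        for r in residues:
            recs.append(ShiftRecord(r, types[r], "H", h[r]))
            recs.append(ShiftRecord(r, types[r], "N", n[r]))
        return ShiftTable(recs, state_label=label, molar_ratio=ratio)

    reference = table(free_h, free_n, "free", 0.0)
    bound_table = table(bound_h, bound_n, "bound", spec.ratios[-1])

    protein_nM = spec.protein_total * 1000.0
    sigma_h, sigma_n = spec.noise_sigma
    points = [TitrationPoint(0.0, peaks=[
        Peak2D(free_h[r], free_n[r], 1.0, assignment=None) for r in residues
    ])]
    for ratio in spec.ratios[1:]:
        ligand_nM = ratio * protein_nM
        # fraction of *protein* bound: normalise the complex by protein total
        f = bound_fraction_quadratic(ligand_nM, protein_nM, spec.kd)
        peaks: list[Peak2D] = []
        for r in residues:
            is_pocket = r in spec.pocket_residues
            if spec.exchange == "fast":
                h = free_h[r] + f * (bound_h[r] - free_h[r])
                n = free_n[r] + f * (bound_n[r] - free_n[r])
                _emit(peaks, rng, h, n, 1.0, sigma_h, sigma_n, spec.detection_floor)
            elif is_pocket:
                atten = max(1.0 - spec.broadening * 4.0 * f * (1.0 - f), 0.0)
                _emit(peaks, rng, free_h[r], free_n[r], (1.0 - f) * atten,
                      sigma_h, sigma_n, spec.detection_floor)
                _emit(peaks, rng, bound_h[r], bound_n[r], f * atten,
                      sigma_h, sigma_n, spec.detection_floor)
            else:
                # free and bound positions coincide: one full-intensity peak
                _emit(peaks, rng, free_h[r], free_n[r], 1.0,
                      sigma_h, sigma_n, spec.detection_floor)
        points.append(TitrationPoint(ratio, peaks=peaks))

    series = TitrationSeries(points, spec.protein_total, reference)
    truth = GroundTruth(
        pocket_residues=tuple(spec.pocket_residues),
        kd=spec.kd,
        stoichiometry=1.0,
        true_csp={
            r: (weighted_csp(*spec.delta_bound[r]) if r in spec.pocket_residues else 0.0)
            for r in residues
        },
        free_shifts=reference,
        bound_shifts=bound_table,
    )
    return series, truth


def _truncated_normal(rng, mu: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mu, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mu, lo), hi))


def _emit(peaks, rng, h, n, intensity, sigma_h, sigma_n, floor) -> None:
    if intensity < floor:
        return
    if sigma_h > 0 or sigma_n > 0:
        h = h + rng.normal(0.0, sigma_h)
        n = n + rng.normal(0.0, sigma_n)
    peaks.append(Peak2D(float(h), float(n), float(intensity), assignment=None))


def write_titration_dir(series: TitrationSeries, truth: GroundTruth,
                        outdir: str | Path) -> None:
    """Serialise a simulated series in the file formats the readers consume.

    Writes ``reference_shifts.tsv``, ``bound_shifts.tsv`` (when available),
    one Sparky ``ratio_<r>.list`` per titration point and
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_shift_table(series.reference_assignments, outdir / "reference_shifts.tsv")
    if truth.bound_shifts is not None:
        write_shift_table(truth.bound_shifts, outdir / "bound_shifts.tsv")
    for point in series.points:
        name = f"ratio_{point.molar_ratio:.2f}.list"
        write_sparky_list(point.as_peaks(), outdir / name)
    meta = truth.to_dict()
    meta["ratios"] = series.ratios
    meta["protein_total_uM"] = series.protein_total
    (outdir / "ground_truth.json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# binding-curve simulation
# ---------------------------------------------------------------------------

def default_saturation_grid() -> np.ndarray:
    """12-point log-spaced protein titration spanning the low-nM regime."""
    return np.geomspace(0.1, 500.0, 12)


def simulate_saturation_curve(
    kd: float,
    probe_total: float = 2.0,
    x: np.ndarray | None = None,
    f_min: float = 0.1,
    f_max: float = 1.0,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> tuple[BindingCurve, dict]:
    """Saturation curve from the ligand-depletion forward model + noise.

    Multiplicative Gaussian noise: ``y = clean · (1 + noise_frac·ε)``.
    """
    x = default_saturation_grid() if x is None else np.asarray(x, dtype=float)
    frac = bound_fraction_quadratic(x, probe_total, kd)
    clean = f_min + (f_max - f_min) * frac
    rng = np.random.default_rng(seed)
    y = clean * (1.0 + noise_frac * rng.standard_normal(len(x))) if noise_frac > 0 else clean
    curve = BindingCurve(x, y, probe_total)
    truth = {"kd_nM": kd, "f_min": f_min, "f_max": f_max, "noise_frac": noise_frac}
    return curve, truth


def simulate_competition_curve(
    ki: float,
    probe_kd: float = 2.0,
    probe_total: float = 2.0,
    protein_total: float = 10.0,
    c: np.ndarray | None = None,
    f_min: float = 0.1,
    f_max: float = 1.0,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> tuple[BindingCurve, dict]:
    """Displacement curve from the competitive (cubic) equilibrium + noise."""
    c = np.geomspace(0.1, 1e5, 12) if c is None else np.asarray(c, dtype=float)
    frac = bound_probe_fraction_competition(protein_total, probe_total, c, probe_kd, ki)
    clean = f_min + (f_max - f_min) * frac
    rng = np.random.default_rng(seed)
    y = clean * (1.0 + noise_frac * rng.standard_normal(len(c))) if noise_frac > 0 else clean
    curve = BindingCurve(c, y, probe_total)
    truth = {"ki_nM": ki, "probe_kd_nM": probe_kd, "protein_total_nM": protein_total,
             "f_min": f_min, "f_max": f_max}
    return curve, truth


# ---------------------------------------------------------------------------
# structure simulation
# ---------------------------------------------------------------------------

def simulate_structure_pair(
    n_atoms: int = 75,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureCA, StructureCA, dict]:
    """A compact Cα trace and its rigidly transformed (optionally noisy) copy.

    The first structure is a 3.8 Å-step random chain; the second is
    ``R·x + t`` plus isotropic Gaussian coordinate noise. The planted
    transform is returned as ground truth. With fewer than 3 or collinear
    points the rotation is not identifiable — callers get whatever least-
    squares transform fits best.
    """
    if n_atoms < 3:
        raise InputError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_atoms - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    # gentle compaction pull toward the origin keeps the chain globular
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        pull = -0.05 * coords[i - 1]
        coords[i] = coords[i - 1] + steps[i - 1] + pull
    if rotation is None:
        rotation = _random_rotation(rng)
    if translation is None:
        translation = rng.uniform(-20.0, 20.0, size=3)
    moved = coords @ np.asarray(rotation).T + np.asarray(translation)
    if noise_sigma > 0:
        moved = moved + rng.normal(0.0, noise_sigma, size=moved.shape)
    types = [_AA_NO_PROLINE[rng.integers(len(_AA_NO_PROLINE))] for _ in range(n_atoms)]
    a = StructureCA([(i + 1, types[i], *coords[i]) for i in range(n_atoms)], label="sim_a")
    b = StructureCA([(i + 1, types[i], *moved[i]) for i in range(n_atoms)], label="sim_b")
    truth = {"rotation": np.asarray(rotation), "translation": np.asarray(translation),
             "noise_sigma": noise_sigma}
    return a, b, truth


def _random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def write_structure_pdb(structure: StructureCA, path: str | Path,
                        chain: str = "A") -> None:
    """Write a Cα-only PDB file that :func:`shift_io.read_structure_ca` reads."""
    from .shift_io import _3TO1

    lines = []
    serial = 1
    three = {v: k for k, v in _3TO1.items()}
    for num, rtype, x, y, z in structure.residues:
        res3 = three.get(rtype, "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:>3s} {chain}{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C  "
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
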