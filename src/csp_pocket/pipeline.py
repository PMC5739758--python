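"""Run configuration and the three pipeline stages (csp / map / fit).

A :class:`RunConfig` collects every tunable of the pipeline with its
documented default and round-trips losslessly through YAML. The stage
runners consume it, log one line per stage with record counts, write
deterministic TSV/JSON reports (including provenance: config hash and
package version) and clean up partial outputs when a stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import binding_fit as bf
from . import csp_core as cc
from . import shift_io as sio
from . import structure_map as sm
from .errors import ConfigError, CspPocketError, InputError

logger = logging.getLogger(__name__)


@dataclass
class CspStageConfig:
    reference_shifts: str | None = None
    reference_dialect: str = "tsv"
    bound_shifts: str | None = None          # optional NOESY-style endpoint table
    peak_lists: list[list] = field(default_factory=list)  # [[ratio, path], ...]
    titration_dir: str | None = None         # shorthand for a simulated directory
    protein_total_uM: float = 80.0
    numbering_offset: int = 0
    sparky_axis_order: str = "nh"
    n_weight: float = 5.0
    k: float = 1.0
    include_reassigned: bool = False
    tol_h: float = 0.04
    tol_n: float = 0.3
    relocation_tol_h: float = 0.35
    relocation_tol_n: float = 1.75
    saturation_tolerance: float = 0.005
    compare_ratio: float | None = None       # default: first ratio >= 1


@dataclass
class MapStageConfig:
    fasta_a: str | None = None
    fasta_b: str | None = None
    first_residue_a: int = 1
    first_residue_b: int = 1
    structure_a: str | None = None
    structure_b: str | None = None
    chain_a: str = "A"
    chain_b: str = "A"
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    significant_a: list[int] = field(default_factory=list)
    significant_b: list[int] = field(default_factory=list)
    residue_map_offset: int | None = None    # use a constant-offset map instead of aligning
    map_range: list[int] | None = None       # [start_a, end_a] for the offset map
    sse_ranges: dict[str, list[int]] = field(default_factory=dict)
    structured_core: list[int] = field(default_factory=lambda: [23, 100])


@dataclass
class FitStageConfig:
    curve: str | None = None
    mode: str = "saturation"                 # saturation | competition
    probe_total_nM: float = 2.0
    probe_kd_nM: float | None = None         # competition only
    protein_total_nM: float | None = None    # competition only
    n_boot: int = 500
    depletion: bool = True


@dataclass
class RunConfig:
    seed: int = 20171120
    out_dir: str = "csp_pocket_out"
    csp: CspStageConfig = field(default_factory=CspStageConfig)
    map: MapStageConfig = field(default_factory=MapStageConfig)
    fit: FitStageConfig = field(default_factory=FitStageConfig)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        for name, sub in (("csp", CspStageConfig), ("map", MapStageConfig),
                          ("fit", FitStageConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                bad = set(kwargs[name]) - sub_known
                if bad:
                    raise ConfigError(f"unknown {name} config fields: {sorted(bad)}")
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "version": __version__,
                "seed": self.seed}


class _StageWriter:
    """Collects output files and removes them all if the stage fails."""

    def __init__(self, out_dir: Path) -> None:
        self.out_dir = out_dir
        self.written: list[Path] = []
        out_dir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.written.append(p)
        return p

    def rollback(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# stage: csp
# ---------------------------------------------------------------------------

@dataclass
class CspRunResult:
    profile: cc.CSPProfile
    threshold: cc.ThresholdResult
    significant: list[int]
    saturation: cc.SaturationCall
    exchange: dict[int, cc.ExchangeCall]
    tracking: cc.TrackingResult


def _load_series(cfg: CspStageConfig) -> tuple[cc.TitrationSeries, sio.ShiftTable | None]:
    if cfg.titration_dir:
        d = Path(cfg.titration_dir)
        reference = sio.read_shift_table(d / "reference_shifts.tsv", "tsv")
        bound = None
        if (d / "bound_shifts.tsv").exists():
            bound = sio.read_shift_table(d / "bound_shifts.tsv", "tsv",
                                         state_label="bound")
        lists = sorted(d.glob("ratio_*.list"))
        pairs = [(float(p.stem.split("_", 1)[1]), p) for p in lists]
    else:
        if not cfg.reference_shifts:
            raise ConfigError("csp stage: 'reference_shifts' is required")
        if not cfg.peak_lists:
            raise ConfigError("csp stage: 'peak_lists' is required")
        reference = sio.read_shift_table(cfg.reference_shifts, cfg.reference_dialect)
        bound = (sio.read_shift_table(cfg.bound_shifts, cfg.reference_dialect,
                                      state_label="bound")
                 if cfg.bound_shifts else None)
        pairs = [(float(r), Path(p)) for r, p in cfg.peak_lists]
    if cfg.numbering_offset:
        reference = sio.apply_numbering_offset(reference, cfg.numbering_offset)
        if bound is not None:
            bound = sio.apply_numbering_offset(bound, cfg.numbering_offset)
    points = [
        cc.TitrationPoint(ratio, peaks=sio.read_sparky_list(path, cfg.sparky_axis_order))
        for ratio, path in sorted(pairs)
    ]
    series = cc.TitrationSeries(points, cfg.protein_total_uM, reference)
    return series, bound


def run_csp(config: RunConfig) -> CspRunResult:
    """Track, compute CSPs, threshold, saturation and exchange; write reports."""
    cfg = config.csp
    writer = _StageWriter(Path(config.out_dir))
    try:
        series, bound = _load_series(cfg)
        logger.info("csp: loaded %d titration points, %d reference residues",
                    len(series.points), len(series.reference_assignments.residue_numbers))
        tracking = cc.track_peaks(
            series, cfg.tol_h, cfg.tol_n, n_weight=cfg.n_weight,
            relocation_tol=(cfg.relocation_tol_h, cfg.relocation_tol_n),
            bound_reference=bound,
        )
        endpoint, sources = cc.endpoint_table(
            tracking, series.reference_assignments, cfg.compare_ratio
        )
        profile = cc.compute_csp(
            series.reference_assignments, endpoint, n_weight=cfg.n_weight,
            endpoint_sources=sources, ratio_compared=endpoint.molar_ratio,
        )
        threshold = cc.compute_threshold(profile, k=cfg.k,
                                         include_reassigned=cfg.include_reassigned)
        profile.threshold = threshold
        significant = cc.select_significant(profile, threshold)
        per_ratio = cc.profiles_by_ratio(tracking, series.reference_assignments,
                                         n_weight=cfg.n_weight)
        saturation = cc.assess_saturation(per_ratio, cfg.saturation_tolerance)
        exchange = cc.classify_exchange(
            tracking, saturation_ratio=min(saturation.stoichiometry, 1.0) or 1.0,
            tol_h=cfg.tol_h, tol_n=cfg.tol_n, n_weight=cfg.n_weight,
        )
        logger.info("csp: %d/%d residues significant (cutoff %.4f ppm)",
                    len(significant), len(profile.records), threshold.cutoff)

        sio.write_report(profile, writer.path("csp_profile.tsv"), "tsv")
        summary = {
            "provenance": config.provenance(),
            "threshold": threshold.to_dict(),
            "significant": significant,
            "disappeared": profile.disappeared_residues,
            "saturation": saturation.to_dict(),
            "exchange_counts": _count_regimes(exchange),
            "exchange": {str(r): c.regime for r, c in sorted(exchange.items())},
        }
        sio.write_report(summary, writer.path("csp_summary.json"), "json")
        return CspRunResult(profile, threshold, significant, saturation,
                            exchange, tracking)
    except CspPocketError as exc:
        writer.rollback()
        raise type(exc)(f"csp stage: {exc}") from exc


def _count_regimes(exchange: dict[int, cc.ExchangeCall]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for call in exchange.values():
        counts[call.regime] = counts.get(call.regime, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# stage: map
# ---------------------------------------------------------------------------

@dataclass
class MapRunResult:
    alignment: sm.AlignmentResult | None
    residue_map: sm.ResidueMap
    superposition: sm.SuperpositionResult | None
    comparison: sm.PocketComparison
    sse_groups: dict[str, list[int]] | None


def run_map(config: RunConfig) -> MapRunResult:
    """Align, map residues, superpose (when structures given), compare pockets."""
    cfg = config.map
    writer = _StageWriter(Path(config.out_dir))
    try:
        alignment = None
        if cfg.residue_map_offset is not None:
            if not cfg.map_range:
                raise ConfigError("map stage: 'map_range' required with residue_map_offset")
            residue_map = sm.ResidueMap.shift(cfg.map_range[0], cfg.map_range[1],
                                              cfg.residue_map_offset)
        else:
            if not (cfg.fasta_a and cfg.fasta_b):
                raise ConfigError("map stage: 'fasta_a'/'fasta_b' required (or residue_map_offset)")
            seq_a = sio.read_fasta(cfg.fasta_a, cfg.first_residue_a)[0]
            seq_b = sio.read_fasta(cfg.fasta_b, cfg.first_residue_b)[0]
            alignment = sm.global_align(seq_a, seq_b, cfg.matrix, cfg.gap_open,
                                        cfg.gap_extend)
            residue_map = sm.map_equivalent_residues(alignment)
            logger.info("map: aligned %d columns, identity %.1f%%",
                        len(alignment.aligned_columns),
                        100 * alignment.identity_fraction)

        superposition = None
        if cfg.structure_a and cfg.structure_b:
            ca_a = sio.read_structure_ca(cfg.structure_a, cfg.chain_a)
            ca_b = sio.read_structure_ca(cfg.structure_b, cfg.chain_b)
            present = [
                (a, b) for a, b in residue_map.pairs
                if a in set(ca_a.residue_numbers) and b in set(ca_b.residue_numbers)
            ]
            core = cfg.structured_core
            present = [(a, b) for a, b in present if core[0] <= a <= core[1]]
            superposition = sm.superpose_kabsch(ca_a, ca_b, sm.ResidueMap(present))
            logger.info("map: superposed %d Cα pairs, rmsd %.2f Å",
                        superposition.n_atoms, superposition.rmsd)
        else:
            logger.info("map: structures absent, superposition skipped")

        comparison = sm.compare_pockets(list(cfg.significant_a),
                                        list(cfg.significant_b), residue_map)
        sse_groups = None
        if cfg.sse_ranges:
            ranges = {k: (v[0], v[1]) for k, v in cfg.sse_ranges.items()}
            labels = sm.annotate_sse(list(cfg.significant_a), ranges,
                                     tuple(cfg.structured_core))
            sse_groups = sm.group_by_sse(labels)

        report = {
            "provenance": config.provenance(),
            "alignment": alignment.to_dict() if alignment else None,
            "n_mapped_pairs": len(residue_map),
            "superposition": (superposition.to_dict() if superposition
                              else {"skipped": True}),
            "pocket_comparison": comparison.to_dict(),
            "sse_groups": sse_groups,
            "pymol_selection": sm.pymol_selection("pocket_a", list(cfg.significant_a)),
        }
        sio.write_report(report, writer.path("map_summary.json"), "json")
        sio.write_report(comparison, writer.path("conserved_pairs.tsv"), "tsv")
        return MapRunResult(alignment, residue_map, superposition, comparison,
                            sse_groups)
    except CspPocketError as exc:
        writer.rollback()
        raise type(exc)(f"map stage: {exc}") from exc


# ---------------------------------------------------------------------------
# stage: fit
# ---------------------------------------------------------------------------

def read_binding_curve(path: str | Path, probe_total_nM: float) -> bf.BindingCurve:
    """Read a binding-curve TSV with mandatory unit column.

    Columns: ``concentration  unit  signal`` where unit is ``nM`` or ``uM``
    (µM accepted); concentrations are converted to nM explicitly, never
    guessed.
    """
    xs, ys = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and not _is_float(parts[0]):
                continue
            if len(parts) < 3:
                raise InputError(f"{path}: line {lineno}: need concentration, unit, signal")
            conc = float(parts[0])
            unit = parts[1].strip()
            if unit in ("uM", "µM", "um"):
                conc *= 1000.0
            elif unit != "nM":
                raise InputError(f"{path}: line {lineno}: unknown unit {unit!r}")
            xs.append(conc)
            ys.append(float(parts[2]))
    return bf.BindingCurve(np.asarray(xs), np.asarray(ys), probe_total_nM)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def run_fit(config: RunConfig):
    """Fit the configured binding model and write a JSON report with verdict."""
    cfg = config.fit
    writer = _StageWriter(Path(config.out_dir))
    try:
        if not cfg.curve:
            raise ConfigError("fit stage: 'curve' is required")
        curve = read_binding_curve(cfg.curve, cfg.probe_total_nM)
        logger.info("fit: loaded %d points from %s", len(curve.x), cfg.curve)
        if cfg.mode == "saturation":
            model = bf.SaturationBindingModel(curve, depletion=cfg.depletion)
            results = model.fit(n_boot=cfg.n_boot, seed=config.seed)
        elif cfg.mode == "competition":
            if cfg.probe_kd_nM is None or cfg.protein_total_nM is None:
                raise ConfigError(
                    "fit stage: competition mode needs 'probe_kd_nM' and 'protein_total_nM'"
                )
            model = bf.CompetitionBindingModel(curve, cfg.probe_kd_nM,
                                               cfg.protein_total_nM)
            results = model.fit()
        else:
            raise ConfigError(f"fit stage: unknown mode {cfg.mode!r}")
        logger.info("fit: verdict %s", results.verdict)
        report = {"provenance": config.provenance(), "fit": results.to_dict()}
        sio.write_report(report, writer.path("binding_fit.json"), "json")
        return results
    except CspPocketError as exc:
        writer.rollback()
        raise type(exc)(f"fit stage: {exc}") from exc
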