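"""Chemical-shift-perturbation (CSP) analysis of an HSQC titration.

The workflow mirrors how an NMR titration of a ¹⁵N-labelled protein with an
unlabelled ligand is analysed in practice:

1. :func:`track_peaks` follows each assigned amide cross-peak from the free
   (reference) spectrum through the titration points, matching peaks between
   consecutive points by minimum total distance in scaled ppm space.
2. :func:`compute_csp` turns free vs end-point shift tables into a per-residue
   profile of ΔδH, ΔδN and the weighted combination
   ``Δδ = sqrt((ΔδH² + (ΔδN/w)²) / 2)`` with the conventional ¹⁵N weight
   ``w = 5``.
3. :func:`compute_threshold` places the significance cutoff at
   ``mean + k·sd`` (sample standard deviation) of the numeric Δδ values, and
   :func:`select_significant` returns the residues strictly above it.
4. :func:`classify_exchange` labels each residue slow or fast exchange from
   its tracking trajectory, and :func:`assess_saturation` locates the molar
   ratio at which the mean perturbation plateaus (the binding stoichiometry).

Slow exchange is the regime in which free and bound forms give separate
peaks: at sub-stoichiometric ligand the free peak loses intensity (and may
broaden below the detection limit) while the bound peak grows at a new
position, so a residue's trajectory is a disappearance followed by a
reappearance elsewhere. Moderately displaced bound peaks can be re-identified
by proximity (a wider *relocation* search); severely displaced ones cannot,
and are only recovered when an independently assigned bound-state shift table
(e.g. from a NOESY experiment on the saturated complex) is supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InputError, InsufficientDataError
from .shift_io import Peak2D, ShiftRecord, ShiftTable

logger = logging.getLogger(__name__)

DEFAULT_N_WEIGHT = 5.0

CSP_STATUSES = ("shifted", "relocated", "disappeared", "unassigned", "proline")


def weighted_csp(delta_h: float, delta_n: float, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Combined CSP  Δδ = sqrt((ΔδH² + (ΔδN/w)²)/2)."""
    return math.sqrt((delta_h ** 2 + (delta_n / n_weight) ** 2) / 2.0)


def scaled_distance(dh: float, dn: float, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Peak-matching distance  d = sqrt(Δh² + (Δn/w)²)  in scaled ppm space."""
    return math.hypot(dh, dn / n_weight)


# ---------------------------------------------------------------------------
# titration containers
# ---------------------------------------------------------------------------

@dataclass
class TitrationPoint:
    """One titration point: a molar ratio plus either a peak list or a shift table."""

    molar_ratio: float
    peaks: list[Peak2D] | None = None
    shifts: ShiftTable | None = None

    def __post_init__(self) -> None:
        if (self.peaks is None) == (self.shifts is None):
            raise InputError(
                f"titration point at ratio {self.molar_ratio}: exactly one of "
                "peaks/shifts must be populated"
            )
        if self.molar_ratio < 0:
            raise InputError("molar ratio must be >= 0")

    def as_peaks(self) -> list[Peak2D]:
        if self.peaks is not None:
            return self.peaks
        out = []
        for res in self.shifts.residue_numbers:
            h = self.shifts.get(res, "H")
            n = self.shifts.get(res, "N")
            if h is not None and n is not None:
                out.append(Peak2D(h.shift_ppm, n.shift_ppm, 1.0, assignment=res))
        return out


@dataclass
class TitrationSeries:
    """Ordered titration points; point 0 is the assigned free reference."""

    points: list[TitrationPoint]
    protein_total: float  # µM
    reference_assignments: ShiftTable

    def __post_init__(self) -> None:
        ratios = [p.molar_ratio for p in self.points]
        if not ratios or ratios[0] != 0.0:
            raise InputError("first titration point must have molar ratio 0")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise InputError("molar ratios must be strictly increasing")
        if self.protein_total <= 0:
            raise InputError("protein_total must be positive (µM)")

    @property
    def ratios(self) -> list[float]:
        return [p.molar_ratio for p in self.points]


# ---------------------------------------------------------------------------
# peak tracking
# ---------------------------------------------------------------------------

#: provenance of a residue's position at a titration point
SOURCE_REFERENCE = "reference"
SOURCE_TRACKED = "tracked"
SOURCE_RELOCATED = "relocated"
SOURCE_BOUND_REF = "bound_ref"


@dataclass(frozen=True)
class PeakObservation:
    present: bool
    h_ppm: float | None = None
    n_ppm: float | None = None
    source: str | None = None


@dataclass
class TrackingResult:
    """Per-residue trajectory across the titration points."""

    ratios: list[float]
    observations: dict[int, list[PeakObservation]]

    @property
    def residues(self) -> list[int]:
        return sorted(self.observations)

    def position_at(self, residue: int, point_index: int) -> tuple[float, float] | None:
        obs = self.observations[residue][point_index]
        return (obs.h_ppm, obs.n_ppm) if obs.present else None


def _assign(
    positions: dict[int, tuple[float, float]],
    peaks: Sequence[Peak2D],
    tol_h: float,
    tol_n: float,
    n_weight: float,
) -> dict[int, int]:
    """Minimum-total-distance assignment residue → peak index, gated per axis.

    Uses the Hungarian algorithm so the result coincides with exhaustive
    minimisation of the summed scaled distance; a peak is a candidate for a
    residue only if it lies within ``tol_h``/``tol_n`` of the residue's
    current position on each axis. Ties are deterministic (lower residue
    number first, by construction of the cost matrix ordering).
    """
    residues = sorted(positions)
    if not residues or not peaks:
        return {}
    big = 1e9
    cost = np.full((len(residues), len(peaks)), big)
    for i, res in enumerate(residues):
        h0, n0 = positions[res]
        for j, pk in enumerate(peaks):
            if abs(pk.h_ppm - h0) <= tol_h and abs(pk.n_ppm - n0) <= tol_n:
                cost[i, j] = scaled_distance(pk.h_ppm - h0, pk.n_ppm - n0, n_weight)
    rows, cols = linear_sum_assignment(cost)
    return {residues[i]: j for i, j in zip(rows, cols) if cost[i, j] < big}


def track_peaks(
    series: TitrationSeries,
    tol_h: float = 0.04,
    tol_n: float = 0.3,
    *,
    n_weight: float = DEFAULT_N_WEIGHT,
    relocation_tol: tuple[float, float] | None = (0.35, 1.75),
    bound_reference: ShiftTable | None = None,
) -> TrackingResult:
    """Follow every assigned residue through the titration.

    At each point, residues are first matched point-to-point from their last
    known position within (``tol_h``, ``tol_n``); residues left unmatched are
    then offered the *unclaimed* peaks inside the wider ``relocation_tol``
    window (how reappearing slow-exchange peaks near the free position are
    re-identified), and finally — if ``bound_reference`` assignments are
    supplied — unclaimed peaks within the strict tolerance of the residue's
    bound-state position (the NOESY-style re-assignment route for severely
    displaced peaks).
    """
    if tol_h <= 0 or tol_n <= 0:
        raise InputError("tracking tolerances must be positive")
    ref = series.reference_assignments
    obs: dict[int, list[PeakObservation]] = {}
    last_pos: dict[int, tuple[float, float]] = {}
    for res in ref.residue_numbers:
        h = ref.get(res, "H")
        n = ref.get(res, "N")
        if h is None or n is None:
            continue
        last_pos[res] = (h.shift_ppm, n.shift_ppm)
        obs[res] = [PeakObservation(True, h.shift_ppm, n.shift_ppm, SOURCE_REFERENCE)]
    if not obs:
        raise InputError("reference assignments contain no residue with both H and N")

    prev_present = set(last_pos)
    for point in series.points[1:]:
        peaks = point.as_peaks()
        # point-to-point continuity only holds for residues seen at the
        # previous point; residues that vanished re-enter via the rescue
        # passes below, never by strict matching from a stale position
        traceable = {r: last_pos[r] for r in prev_present}
        matched = _assign(traceable, peaks, tol_h, tol_n, n_weight)
        sources = {res: SOURCE_TRACKED for res in matched}
        claimed = set(matched.values())

        def _second_pass(candidates: dict[int, tuple[float, float]],
                         th: float, tn: float, tag: str) -> None:
            free_peaks_idx = [j for j in range(len(peaks)) if j not in claimed]
            sub = _assign(candidates, [peaks[j] for j in free_peaks_idx], th, tn, n_weight)
            for res, jj in sub.items():
                j = free_peaks_idx[jj]
                matched[res] = j
                sources[res] = tag
                claimed.add(j)

        if bound_reference is not None:
            # match residues that vanished against their known bound-state
            # positions. The provenance label distinguishes endpoints a
            # proximity search could also have re-identified (relocated)
            # from those only the external re-assignment recovers (bound_ref)
            bound_pos = {}
            reachable: set[int] = set()
            for res in obs:
                if res in matched:
                    continue
                h = bound_reference.get(res, "H")
                n = bound_reference.get(res, "N")
                if h is None or n is None:
                    continue
                bound_pos[res] = (h.shift_ppm, n.shift_ppm)
                if relocation_tol is not None:
                    h0, n0 = last_pos[res]
                    if (abs(h.shift_ppm - h0) <= relocation_tol[0]
                            and abs(n.shift_ppm - n0) <= relocation_tol[1]):
                        reachable.add(res)
            _second_pass(bound_pos, tol_h, tol_n, SOURCE_BOUND_REF)
            for res in reachable:
                if sources.get(res) == SOURCE_BOUND_REF:
                    sources[res] = SOURCE_RELOCATED
        if relocation_tol is not None:
            unmatched = {r: last_pos[r] for r in obs if r not in matched}
            _second_pass(unmatched, relocation_tol[0], relocation_tol[1],
                         SOURCE_RELOCATED)

        for res in obs:
            if res in matched:
                pk = peaks[matched[res]]
                obs[res].append(
                    PeakObservation(True, pk.h_ppm, pk.n_ppm, sources[res])
                )
                last_pos[res] = (pk.h_ppm, pk.n_ppm)
            else:
                obs[res].append(PeakObservation(False))
        prev_present = set(matched)

    return TrackingResult(ratios=series.ratios, observations=obs)


def endpoint_table(
    tracking: TrackingResult,
    reference: ShiftTable,
    ratio: float | None = None,
) -> tuple[ShiftTable, dict[int, str]]:
    """Assemble a bound-state shift table from the tracked positions at *ratio*.

    Defaults to the first ratio ≥ 1 (else the last point). Returns the table
    and a map residue → position source, used to mark relocated endpoints.
    """
    if ratio is None:
        ge_one = [r for r in tracking.ratios if r >= 1.0]
        ratio = ge_one[0] if ge_one else tracking.ratios[-1]
    if ratio not in tracking.ratios:
        raise InputError(f"ratio {ratio} not among tracked ratios {tracking.ratios}")
    idx = tracking.ratios.index(ratio)
    records: list[ShiftRecord] = []
    sources: dict[int, str] = {}
    for res, traj in tracking.observations.items():
        o = traj[idx]
        if not o.present:
            continue
        rtype = reference.residue_type(res) or "X"
        records.append(ShiftRecord(res, rtype, "H", o.h_ppm))
        records.append(ShiftRecord(res, rtype, "N", o.n_ppm))
        sources[res] = o.source
    return (
        ShiftTable(records, state_label="bound", molar_ratio=ratio),
        sources,
    )


# ---------------------------------------------------------------------------
# CSP profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSPRecord:
    residue_number: int
    delta_h: float | None
    delta_n: float | None
    delta_weighted: float | None
    status: str
    endpoint_source: str | None = None

    def __post_init__(self) -> None:
        if self.status not in CSP_STATUSES:
            raise InputError(f"unknown CSP status {self.status!r}")
        if self.status in ("shifted", "relocated"):
            if self.delta_weighted is None or self.delta_weighted < 0:
                raise InputError("numeric statuses require delta_weighted >= 0")
        elif self.delta_weighted is not None:
            raise InputError(f"status {self.status} must not carry delta values")


@dataclass(frozen=True)
class ThresholdResult:
    """Significance cutoff  mean + k·sd  over numeric Δδ values."""

    mean: float
    sd: float
    k: float
    cutoff: float
    n_used: int

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "k": self.k,
                "cutoff": self.cutoff, "n_used": self.n_used}


@dataclass
class CSPProfile:
    """Per-residue CSPs over a declared residue range, at one compared ratio."""

    records: list[CSPRecord]
    ratio_compared: float = 1.0
    threshold: ThresholdResult | None = None

    table_columns = ("residue", "delta_H", "delta_N", "delta_weighted", "status",
                     "significant")

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.residue_number)
        nums = [r.residue_number for r in self.records]
        if len(set(nums)) != len(nums):
            raise InputError("duplicate residue in CSP profile")

    def record(self, residue_number: int) -> CSPRecord | None:
        for r in self.records:
            if r.residue_number == residue_number:
                return r
        return None

    @property
    def numeric_records(self) -> list[CSPRecord]:
        return [r for r in self.records if r.delta_weighted is not None]

    @property
    def disappeared_residues(self) -> list[int]:
        return [r.residue_number for r in self.records if r.status == "disappeared"]

    def to_table(self) -> list[dict]:
        cutoff = self.threshold.cutoff if self.threshold else None
        rows = []
        for r in self.records:
            sig = (
                ""
                if cutoff is None or r.delta_weighted is None
                else str(r.delta_weighted > cutoff)
            )
            rows.append({
                "residue": r.residue_number,
                "delta_H": r.delta_h,
                "delta_N": r.delta_n,
                "delta_weighted": r.delta_weighted,
                "status": r.status,
                "significant": sig,
            })
        return rows

    def to_dict(self) -> dict:
        return {
            "ratio_compared": self.ratio_compared,
            "threshold": self.threshold.to_dict() if self.threshold else None,
            "records": self.to_table(),
        }


def compute_csp(
    free: ShiftTable,
    bound: ShiftTable,
    n_weight: float = DEFAULT_N_WEIGHT,
    residue_range: tuple[int, int] | None = None,
    endpoint_sources: Mapping[int, str] | None = None,
    ratio_compared: float = 1.0,
) -> CSPProfile:
    """Per-residue CSP profile between a free and a bound shift table.

    A residue is *shifted* (or *relocated*, when its endpoint position came
    from a relocation search or a bound-state re-assignment) if both states
    carry its H and N shifts; *disappeared* if only the free state does;
    *unassigned* if the free state lacks it; prolines, which have no backbone
    amide, are flagged *proline*.
    """
    if n_weight <= 0:
        raise InputError("n_weight must be positive")
    endpoint_sources = endpoint_sources or {}
    if residue_range is None:
        nums = free.residue_numbers
        if not nums:
            raise InputError("free shift table is empty")
        residue_range = (nums[0], nums[-1])
    shared = set(free.residue_numbers) & set(bound.residue_numbers)
    if not shared:
        raise InputError(
            "free and bound tables share no residues — numbering scales differ?"
        )
    records = []
    for res in range(residue_range[0], residue_range[1] + 1):
        rtype = free.residue_type(res) or bound.residue_type(res)
        if rtype == "P":
            records.append(CSPRecord(res, None, None, None, "proline"))
            continue
        fh, fn = free.get(res, "H"), free.get(res, "N")
        if fh is None or fn is None:
            records.append(CSPRecord(res, None, None, None, "unassigned"))
            continue
        bh, bn = bound.get(res, "H"), bound.get(res, "N")
        if bh is None or bn is None:
            records.append(CSPRecord(res, None, None, None, "disappeared"))
            continue
        dh = bh.shift_ppm - fh.shift_ppm
        dn = bn.shift_ppm - fn.shift_ppm
        source = endpoint_sources.get(res)
        status = "relocated" if source in (SOURCE_RELOCATED, SOURCE_BOUND_REF) else "shifted"
        records.append(
            CSPRecord(res, dh, dn, weighted_csp(dh, dn, n_weight), status, source)
        )
    return CSPProfile(records, ratio_compared=ratio_compared)


def compute_threshold(
    profile: CSPProfile,
    k: float = 1.0,
    include_reassigned: bool = False,
) -> ThresholdResult:
    """Cutoff = mean + k · sample standard deviation of the numeric Δδ values.

    ``include_reassigned=False`` (default) leaves residues whose endpoint had
    to be supplied from an external bound-state assignment out of the mean/sd
    (their extreme Δδ would otherwise dominate the statistics); they are still
    compared against the cutoff and reported.
    """
    values = [
        r.delta_weighted
        for r in profile.numeric_records
        if include_reassigned or r.endpoint_source != SOURCE_BOUND_REF
    ]
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >=2 numeric CSP values for a threshold, have {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ThresholdResult(mean=mean, sd=sd, k=k, cutoff=mean + k * sd,
                           n_used=len(values))


def select_significant(profile: CSPProfile, threshold: ThresholdResult) -> list[int]:
    """Residues with Δδ strictly above the cutoff, in ascending order.

    Residues whose peaks disappeared (no computable endpoint CSP) are never
    silently included; retrieve them via ``profile.disappeared_residues``.
    """
    out = [
        r.residue_number
        for r in profile.numeric_records
        if r.delta_weighted > threshold.cutoff
    ]
    if profile.disappeared_residues:
        logger.info(
            "%d residues disappeared and are excluded from the significant list: %s",
            len(profile.disappeared_residues), profile.disappeared_residues,
        )
    return sorted(out)


# ---------------------------------------------------------------------------
# exchange regime and stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeCall:
    residue_number: int
    regime: str  # slow | fast | undetermined
    evidence: str


def classify_exchange(
    tracking: TrackingResult,
    saturation_ratio: float = 1.0,
    *,
    tol_h: float = 0.04,
    tol_n: float = 0.3,
    n_weight: float = DEFAULT_N_WEIGHT,
) -> dict[int, ExchangeCall]:
    """Label each residue's exchange regime from its tracked trajectory.

    *slow*: absent at at least one intermediate ratio in (0, saturation) while
    present at the final point, or an endpoint recovered by relocation /
    bound-state re-assignment, or a final jump larger than 3× the tracking
    tolerance. *fast*: present and continuously traceable (every step within
    the strict tolerance) at every point. Otherwise *undetermined* — in
    particular a residue absent at the final point, whose endpoint CSP cannot
    be computed.
    """
    tol_scaled = scaled_distance(tol_h, tol_n, n_weight)
    calls: dict[int, ExchangeCall] = {}
    ratios = tracking.ratios
    for res, traj in tracking.observations.items():
        final = traj[-1]
        if not final.present:
            calls[res] = ExchangeCall(res, "undetermined", "absent at final ratio")
            continue
        absent_intermediate = any(
            (not o.present) and 0 < r < saturation_ratio
            for r, o in zip(ratios, traj)
        )
        relocated = final.source in (SOURCE_RELOCATED, SOURCE_BOUND_REF)
        jump = _final_jump(traj, n_weight)
        if absent_intermediate or relocated or (jump is not None and jump > 3 * tol_scaled):
            why = []
            if absent_intermediate:
                why.append("disappeared at intermediate ratio")
            if relocated:
                why.append(f"endpoint from {final.source}")
            if jump is not None and jump > 3 * tol_scaled:
                why.append(f"final jump {jump:.3f} > 3x tolerance")
            calls[res] = ExchangeCall(res, "slow", "; ".join(why))
            continue
        if all(o.present for o in traj) and all(
            o.source in (SOURCE_REFERENCE, SOURCE_TRACKED) for o in traj
        ):
            calls[res] = ExchangeCall(res, "fast", "continuously traceable")
        else:
            calls[res] = ExchangeCall(res, "undetermined", "gap in trajectory")
    return calls


def _final_jump(traj: Sequence[PeakObservation], n_weight: float) -> float | None:
    final = traj[-1]
    prev = [o for o in traj[:-1] if o.present]
    if not prev or not final.present:
        return None
    last = prev[-1]
    return scaled_distance(final.h_ppm - last.h_ppm, final.n_ppm - last.n_ppm, n_weight)


def profiles_by_ratio(
    tracking: TrackingResult,
    reference: ShiftTable,
    n_weight: float = DEFAULT_N_WEIGHT,
    residue_range: tuple[int, int] | None = None,
) -> dict[float, "CSPProfile"]:
    """CSP profile of every titration point versus the free reference."""
    out: dict[float, CSPProfile] = {}
    for ratio in tracking.ratios:
        table, sources = endpoint_table(tracking, reference, ratio)
        out[ratio] = compute_csp(
            reference, table, n_weight=n_weight, residue_range=residue_range,
            endpoint_sources=sources, ratio_compared=ratio,
        )
    return out


@dataclass
class SaturationCall:
    stoichiometry: float
    plateau_reached: bool
    per_ratio_mean_csp: list[tuple[float, float, int]]  # (ratio, mean Δδ, n residues)
    sub_stoichiometric: bool = False

    def to_dict(self) -> dict:
        return {
            "stoichiometry": self.stoichiometry,
            "plateau_reached": self.plateau_reached,
            "sub_stoichiometric": self.sub_stoichiometric,
            "per_ratio_mean_csp": [
                {"ratio": r, "mean_csp": m, "n": n} for r, m, n in self.per_ratio_mean_csp
            ],
        }


def assess_saturation(
    profiles_by_ratio: Mapping[float, CSPProfile] | Sequence[tuple[float, CSPProfile]],
    tolerance: float = 0.005,
) -> SaturationCall:
    """Find the molar ratio at which the mean CSP stops changing.

    ``profiles_by_ratio`` maps each titration ratio to the CSP profile of that
    point versus the free reference. The per-ratio statistic is the mean Δδ
    over residues with a numeric CSP at that ratio (residues broadened out at
    intermediate points re-enter the mean when they reappear — under slow
    exchange the observable plateau is precisely their reappearance at the
    bound position). The plateau onset is the smallest ratio after which every
    increment of the mean is below *tolerance*; it is reported as the binding
    stoichiometry.
    """
    items = sorted(
        profiles_by_ratio.items() if isinstance(profiles_by_ratio, Mapping)
        else profiles_by_ratio
    )
    if len(items) < 3 or items[-1][0] <= 1.0:
        raise InputError("need >=3 ratios including one above 1 to assess saturation")
    table = []
    for ratio, profile in items:
        vals = [r.delta_weighted for r in profile.numeric_records]
        mean = float(np.mean(vals)) if vals else math.nan
        table.append((ratio, mean, len(vals)))
    means = [m for _, m, _ in table]
    increments = [abs(b - a) for a, b in zip(means, means[1:])]
    onset_index: int | None = None
    for i in range(len(increments)):
        if all(d < tolerance for d in increments[i:]):
            onset_index = i
            break
    if onset_index is None:
        logger.warning("no plateau within the titration; stoichiometry is a lower bound")
        return SaturationCall(items[-1][0], False, table)
    stoich = items[onset_index][0]
    sub = stoich < 1.0 - 1e-9
    if sub:
        logger.warning(
            "saturation reached at sub-unity molar ratio %.2f — excess protein or "
            "higher-order stoichiometry", stoich,
        )
    return SaturationCall(stoich, True, table, sub_stoichiometric=sub)
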