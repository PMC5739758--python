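"""CSP computation, thresholding, tracking, exchange and stoichiometry."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csp_pocket import csp_core as cc
from csp_pocket.errors import InputError, InsufficientDataError
from csp_pocket.shift_io import Peak2D, ShiftRecord, ShiftTable

from conftest import make_table


# ---------------------------------------------------------------------------
# the weighted CSP formula
# ---------------------------------------------------------------------------

class TestWeightedCsp:
    @pytest.mark.parametrize("dh,dn,expected", [
        (0.0, 0.0, 0.0),
        (0.1, 0.5, 0.1),                      # sqrt((0.01 + 0.01)/2)
        (0.3, 0.0, math.sqrt(0.09 / 2.0)),    # 0.212132...
    ])
    def test_hand_evaluated_values(self, dh, dn, expected):
        assert cc.weighted_csp(dh, dn) == pytest.approx(expected, abs=1e-12)

    @given(dh=st.floats(-1, 1), dn=st.floats(-5, 5))
    @settings(max_examples=100, derandomize=True)
    def test_sign_flip_invariance_and_lower_bounds(self, dh, dn):
        v = cc.weighted_csp(dh, dn)
        assert v == pytest.approx(cc.weighted_csp(-dh, -dn), abs=1e-15)
        assert v >= abs(dh) / math.sqrt(2) - 1e-15
        assert v >= abs(dn) / (math.sqrt(2) * 5.0) - 1e-15

    def test_profile_from_tables(self, free_bound_pair):
        profile = cc.compute_csp(*free_bound_pair)
        assert profile.record(1).delta_weighted == pytest.approx(0.1, abs=1e-12)
        assert profile.record(2).delta_weighted == pytest.approx(0.212132034, abs=1e-8)
        assert profile.record(1).status == "shifted"

    def test_missing_bound_is_disappeared_and_missing_free_unassigned(self):
        free = make_table([(1, "G", "H", 8.0), (1, "G", "N", 110.0),
                           (2, "A", "H", 7.5), (2, "A", "N", 120.0)])
        bound = make_table([(1, "G", "H", 8.0), (1, "G", "N", 110.0),
                            (3, "K", "H", 8.8), (3, "K", "N", 125.0)], state="bound")
        profile = cc.compute_csp(free, bound, residue_range=(1, 3))
        assert profile.record(2).status == "disappeared"
        assert profile.record(3).status == "unassigned"

    def test_proline_flagged(self):
        free = make_table([(1, "G", "H", 8.0), (1, "G", "N", 110.0),
                           (2, "P", "N", 135.0)])
        bound = make_table([(1, "G", "H", 8.0), (1, "G", "N", 110.0)], state="bound")
        profile = cc.compute_csp(free, bound, residue_range=(1, 2))
        assert profile.record(2).status == "proline"

    def test_disjoint_numbering_is_input_error(self):
        free = make_table([(1, "G", "H", 8.0), (1, "G", "N", 110.0)])
        bound = make_table([(50, "G", "H", 8.0), (50, "G", "N", 110.0)])
        with pytest.raises(InputError, match="numbering"):
            cc.compute_csp(free, bound)


# ---------------------------------------------------------------------------
# threshold and significance
# ---------------------------------------------------------------------------

def _profile_from_values(values, statuses=None):
    records = []
    for i, v in enumerate(values, start=1):
        if v is None:
            records.append(cc.CSPRecord(i, None, None, None,
                                        (statuses or {}).get(i, "disappeared")))
        else:
            dh = v * math.sqrt(2)  # ΔδN = 0 ⇒ Δδ = |ΔδH|/√2 = v
            records.append(cc.CSPRecord(i, dh, 0.0, v, "shifted"))
    return cc.CSPProfile(records)


class TestThreshold:
    def test_constant_profile_degenerate(self):
        t = cc.compute_threshold(_profile_from_values([0.1] * 4))
        assert (t.mean, t.sd, t.cutoff) == (pytest.approx(0.1), 0.0, pytest.approx(0.1))

    def test_two_value_hand_computation(self):
        t = cc.compute_threshold(_profile_from_values([0.0, 0.2]), k=1)
        assert t.mean == pytest.approx(0.1, abs=1e-12)
        assert t.sd == pytest.approx(math.sqrt(0.02), abs=1e-12)  # n−1 denominator
        assert t.cutoff == pytest.approx(0.1 + math.sqrt(0.02), abs=1e-12)

    def test_k_zero_gives_mean(self):
        t = cc.compute_threshold(_profile_from_values([0.05, 0.1, 0.15]), k=0)
        assert t.cutoff == pytest.approx(t.mean)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            cc.compute_threshold(_profile_from_values([0.1]))

    def test_reassigned_endpoints_excluded_by_default(self):
        records = [cc.CSPRecord(i, 0.05 * math.sqrt(2), 0.0, 0.05, "shifted")
                   for i in range(1, 5)]
        records.append(cc.CSPRecord(9, 1.0, 0.0, cc.weighted_csp(1.0, 0.0),
                                    "relocated", endpoint_source="bound_ref"))
        profile = cc.CSPProfile(records)
        excl = cc.compute_threshold(profile)
        incl = cc.compute_threshold(profile, include_reassigned=True)
        assert excl.n_used == 4 and incl.n_used == 5
        assert excl.cutoff < incl.cutoff


class TestSelectSignificant:
    #: the 19 interface residues of the MSI2-RRM1 titration, used as planted truth
    POCKET_19 = (21, 22, 24, 25, 26, 27, 29, 30, 31, 32, 50,
                 61, 62, 63, 65, 66, 94, 95, 97)

    def test_planted_pocket_recovered_exactly(self):
        records = []
        for res in range(21, 112):
            v = 0.15 if res in self.POCKET_19 else 0.05
            records.append(cc.CSPRecord(res, v * math.sqrt(2), 0.0, v, "shifted"))
        profile = cc.CSPProfile(records)
        threshold = cc.ThresholdResult(mean=0.0, sd=0.0, k=1.0, cutoff=0.1, n_used=91)
        assert tuple(cc.select_significant(profile, threshold)) == self.POCKET_19

    def test_all_below_cutoff_empty(self):
        profile = _profile_from_values([0.01, 0.02, 0.03])
        t = cc.ThresholdResult(0.0, 0.0, 1.0, 0.5, 3)
        assert cc.select_significant(profile, t) == []

    def test_exactly_at_cutoff_excluded(self):
        profile = _profile_from_values([0.1, 0.2])
        t = cc.ThresholdResult(0.0, 0.0, 1.0, 0.1, 2)
        assert cc.select_significant(profile, t) == [2]

    def test_disappeared_not_silently_included(self):
        profile = _profile_from_values([0.3, None, 0.2])
        t = cc.ThresholdResult(0.0, 0.0, 1.0, 0.1, 2)
        assert cc.select_significant(profile, t) == [1, 3]
        assert profile.disappeared_residues == [2]


# ---------------------------------------------------------------------------
# peak tracking
# ---------------------------------------------------------------------------

def brute_force_assignment(positions, peaks, tol_h, tol_n, n_weight=5.0):
    """Exhaustive oracle: maximise matches, then minimise total scaled distance."""
    residues = sorted(positions)
    best = None
    for n_used in range(min(len(residues), len(peaks)), -1, -1):
        for res_subset in itertools.combinations(residues, n_used):
            for peak_perm in itertools.permutations(range(len(peaks)), n_used):
                total = 0.0
                ok = True
                for res, j in zip(res_subset, peak_perm):
                    h0, n0 = positions[res]
                    pk = peaks[j]
                    if abs(pk.h_ppm - h0) > tol_h or abs(pk.n_ppm - n0) > tol_n:
                        ok = False
                        break
                    total += cc.scaled_distance(pk.h_ppm - h0, pk.n_ppm - n0, n_weight)
                if ok:
                    cand = (-n_used, total, dict(zip(res_subset, peak_perm)))
                    if best is None or cand[:2] < best[:2]:
                        best = cand
        if best is not None and -best[0] == n_used:
            break  # no assignment with more matches exists
    return best[2] if best else {}


class TestTrackPeaks:
    def test_within_tolerance_matched(self):
        ref = make_table([(1, "G", "H", 8.00), (1, "G", "N", 120.0)])
        series = cc.TitrationSeries(
            [cc.TitrationPoint(0.0, shifts=ref),
             cc.TitrationPoint(1.0, peaks=[Peak2D(8.01, 120.1)])],
            80.0, ref)
        tr = cc.track_peaks(series, tol_h=0.05, tol_n=0.5)
        assert tr.observations[1][1].present

    def test_no_peak_within_tolerance_absent(self):
        ref = make_table([(1, "G", "H", 8.00), (1, "G", "N", 120.0)])
        series = cc.TitrationSeries(
            [cc.TitrationPoint(0.0, shifts=ref),
             cc.TitrationPoint(1.0, peaks=[Peak2D(9.50, 130.0)])],
            80.0, ref)
        tr = cc.track_peaks(series, tol_h=0.05, tol_n=0.5, relocation_tol=None)
        assert not tr.observations[1][1].present

    def test_closer_peak_wins(self):
        ref = make_table([(1, "G", "H", 8.00), (1, "G", "N", 120.0)])
        series = cc.TitrationSeries(
            [cc.TitrationPoint(0.0, shifts=ref),
             cc.TitrationPoint(1.0, peaks=[Peak2D(8.012, 120.0),   # d = 0.012
                                           Peak2D(8.010, 120.0)])],  # d = 0.010
            80.0, ref)
        tr = cc.track_peaks(series, tol_h=0.05, tol_n=0.5)
        assert tr.observations[1][1].h_ppm == 8.010

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_exhaustive_min_distance_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_res = int(rng.integers(1, 6))
        n_peaks = int(rng.integers(0, 6))
        positions = {i + 1: (float(rng.uniform(7, 9)), float(rng.uniform(110, 125)))
                     for i in range(n_res)}
        peaks = [Peak2D(float(rng.uniform(7, 9)), float(rng.uniform(110, 125)))
                 for _ in range(n_peaks)]
        tol_h, tol_n = 0.5, 3.0
        got = cc._assign(positions, peaks, tol_h, tol_n, 5.0)
        oracle = brute_force_assignment(positions, peaks, tol_h, tol_n)
        assert len(got) == len(oracle)
        total = sum(cc.scaled_distance(peaks[j].h_ppm - positions[r][0],
                                       peaks[j].n_ppm - positions[r][1], 5.0)
                    for r, j in got.items())
        total_oracle = sum(cc.scaled_distance(peaks[j].h_ppm - positions[r][0],
                                              peaks[j].n_ppm - positions[r][1], 5.0)
                           for r, j in oracle.items())
        assert total == pytest.approx(total_oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# exchange classification
# ---------------------------------------------------------------------------

def _mk_tracking(ratios, present_flags, positions=None, sources=None):
    obs = []
    for i, flag in enumerate(present_flags):
        if flag:
            h, n = (positions or {}).get(i, (8.0, 120.0))
            src = (sources or {}).get(i, "tracked" if i else "reference")
            obs.append(cc.PeakObservation(True, h, n, src))
        else:
            obs.append(cc.PeakObservation(False))
    return cc.TrackingResult(ratios=list(ratios), observations={1: obs})


class TestClassifyExchange:
    RATIOS = [0.0, 0.3, 0.5, 0.7, 1.0]

    def test_disappear_then_reappear_is_slow(self):
        tr = _mk_tracking(self.RATIOS, [1, 0, 0, 0, 1],
                          sources={4: "bound_ref"})
        assert cc.classify_exchange(tr)[1].regime == "slow"

    def test_continuous_drift_is_fast(self):
        positions = {i: (8.0 + 0.005 * i, 120.0 + 0.02 * i) for i in range(5)}
        tr = _mk_tracking(self.RATIOS, [1, 1, 1, 1, 1], positions=positions)
        assert cc.classify_exchange(tr)[1].regime == "fast"

    def test_absent_at_final_is_undetermined(self):
        tr = _mk_tracking(self.RATIOS, [1, 1, 1, 0, 0])
        assert cc.classify_exchange(tr)[1].regime == "undetermined"

    def test_large_final_jump_is_slow(self):
        positions = {i: (8.0, 120.0) for i in range(4)}
        positions[4] = (8.5, 122.0)  # far beyond 3× tolerance
        tr = _mk_tracking(self.RATIOS, [1, 1, 1, 1, 1], positions=positions)
        assert cc.classify_exchange(tr, tol_h=0.04, tol_n=0.3)[1].regime == "slow"


# ---------------------------------------------------------------------------
# saturation / stoichiometry
# ---------------------------------------------------------------------------

def _profiles_with_means(ratios, means):
    out = {}
    for ratio, mean in zip(ratios, means):
        recs = [cc.CSPRecord(i, mean * math.sqrt(2), 0.0, mean, "shifted")
                for i in (1, 2, 3)]
        out[ratio] = cc.CSPProfile(recs, ratio_compared=ratio)
    return out


class TestAssessSaturation:
    def test_plateau_at_unity(self):
        profiles = _profiles_with_means([0, 0.3, 0.5, 0.7, 1.0, 1.3],
                                        [0, 0.03, 0.05, 0.07, 0.10, 0.10])
        call = cc.assess_saturation(profiles, tolerance=0.005)
        assert call.stoichiometry == 1.0
        assert call.plateau_reached and not call.sub_stoichiometric

    def test_strictly_increasing_means_no_plateau(self):
        profiles = _profiles_with_means([0, 0.3, 0.5, 0.7, 1.0, 1.3],
                                        [0, 0.02, 0.04, 0.06, 0.08, 0.10])
        call = cc.assess_saturation(profiles, tolerance=0.005)
        assert not call.plateau_reached
        assert call.stoichiometry == 1.3  # lower bound

    def test_sub_stoichiometric_saturation_flagged(self):
        profiles = _profiles_with_means([0, 0.3, 0.5, 0.7, 1.0, 1.3],
                                        [0, 0.10, 0.10, 0.10, 0.10, 0.10])
        call = cc.assess_saturation(profiles, tolerance=0.005)
        assert call.stoichiometry == 0.3
        assert call.sub_stoichiometric

    def test_needs_a_ratio_above_one(self):
        profiles = _profiles_with_means([0, 0.3, 0.5], [0, 0.05, 0.05])
        with pytest.raises(InputError):
            cc.assess_saturation(profiles)
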