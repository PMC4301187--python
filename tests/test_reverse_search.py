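"""Reverse search semantics: RI window, strict threshold, conflict resolution."""

import numpy as np
import pytest

from gcident import MassSpectrum, Peak, cosine_score
from gcident.reverse_search import (
    PeakState,
    brute_force_reverse_search,
    reverse_search_all,
    reverse_search_entry,
)
from gcident.spectra import ScoringConfig

from conftest import make_entry

ENTRY_SPECTRUM = MassSpectrum({100: 500.0, 200: 300.0, 250: 100.0})


def peak(ri, spectrum=None, rt=None, sample_id="s1", state=PeakState.UNKNOWN):
    rt = rt if rt is not None else ri / 2
    p = Peak(
        sample_id=sample_id,
        rt_s=rt,
        apex_spectrum=spectrum if spectrum is not None else ENTRY_SPECTRUM,
        integ_begin_s=rt - 1,
        integ_end_s=rt + 1,
        ri=ri,
    )
    p.state = state
    return p


class TestReverseSearchEntry:
    def test_peaks_outside_window_are_not_candidates(self):
        entry = make_entry()  # reference RI 1551
        assert reverse_search_entry(entry, [peak(1537.0), peak(1565.0)]) is None

    def test_window_edge_is_inclusive(self):
        entry = make_entry()
        result = reverse_search_entry(entry, [peak(1538.0)])
        assert result is not None
        assert result.ri_difference == 13.0

    def test_score_exactly_at_threshold_not_assigned(self):
        entry = make_entry("E_(1TMS)_BP_RI:1000_db", MassSpectrum({100: 1.0}))
        # cosine = 1000 * 4 / sqrt(16+9) = 800 exactly, no penalty at dRI 0
        at_800 = peak(1000.0, MassSpectrum({100: 4.0, 200: 3.0}))
        assert reverse_search_entry(entry, [at_800]) is None
        assert at_800.state is PeakState.UNKNOWN
        above = peak(1000.0, MassSpectrum({100: 5.0, 200: 3.0}))
        result = reverse_search_entry(entry, [above])
        assert result is not None and result.penalized > 800

    def test_threshold_applies_to_penalized_score(self):
        entry = make_entry("E_(1TMS)_BP_RI:1000_db", MassSpectrum({100: 1.0}))
        # cosine 900 but dRI 6 -> 15% penalty -> 765 < 800
        p = peak(1006.0, MassSpectrum({100: 9.0, 200: np.sqrt(19.0)}))
        assert reverse_search_entry(entry, [p]) is None
        # at dRI 1 the same cosine survives: 900 > 800
        q = peak(1001.0, MassSpectrum({100: 9.0, 200: np.sqrt(19.0)}))
        assert reverse_search_entry(entry, [q]).penalized == pytest.approx(900, abs=1e-6)

    def test_accepted_and_locked_peaks_are_not_candidates(self):
        entry = make_entry()
        taken = peak(1551.0, state=PeakState.ACCEPTED)
        locked = peak(1552.0, state=PeakState.LOCKED)
        assert reverse_search_entry(entry, [taken, locked]) is None

    def test_planted_peak_beats_decoys(self):
        entry = make_entry()
        rng = np.random.default_rng(9)
        decoys = []
        for i in range(5):
            masses = rng.choice(np.arange(70, 400), 10, replace=False)
            spectrum = MassSpectrum({int(m): float(v) for m, v in zip(masses, rng.uniform(10, 999, 10))})
            if cosine_score(spectrum, entry.spectrum) >= 600:
                continue
            decoys.append(peak(1545.0 + i, spectrum))
        planted = peak(1552.0, entry.spectrum.scaled(7.3))
        result = reverse_search_entry(entry, decoys + [planted])
        assert result.peak is planted
        assert result.raw_cosine == pytest.approx(1000.0)
        assert planted.state is PeakState.PUTATIVE
        assert planted.assigned_entry == entry.raw_name

    def test_uncalibrated_peaks_rejected(self):
        entry = make_entry()
        bare = Peak(sample_id="s1", rt_s=10, apex_spectrum=ENTRY_SPECTRUM, integ_begin_s=9, integ_end_s=11)
        with pytest.raises(ValueError, match="calibrate"):
            reverse_search_entry(entry, [bare])


class TestReverseSearchAll:
    def test_entry_with_out_of_range_ri_gets_empty_group(self):
        entry = make_entry("Far_(1TMS)_BP_RI:3000_db", ENTRY_SPECTRUM)
        (group,) = reverse_search_all([entry], {"s1": [peak(1551.0)]})
        assert group.n_assigned == 0

    def test_conflict_resolved_toward_smaller_ri_difference(self):
        # identical spectra, reference RIs 20 units apart, single peak between
        a = make_entry("A_(1TMS)_BP_RI:1492_db", ENTRY_SPECTRUM)
        b = make_entry("B_(1TMS)_BP_RI:1512_db", ENTRY_SPECTRUM)
        shared = peak(1500.0)  # dRI 8 vs A, 12 vs B; same cosine 1000
        ga, gb = reverse_search_all([a, b], {"s1": [shared]})
        assert ga.n_assigned == 1 and ga.assignments["s1"].peak is shared
        assert gb.n_assigned == 0

    def test_loser_falls_back_to_next_best_peak(self):
        a = make_entry("A_(1TMS)_BP_RI:1500_db", ENTRY_SPECTRUM)
        b = make_entry("B_(1TMS)_BP_RI:1504_db", ENTRY_SPECTRUM)
        best = peak(1500.0)  # perfect for A (dRI 0), dRI 4 for B
        second = peak(1505.0, ENTRY_SPECTRUM.scaled(2.0))  # dRI 5 for A, 1 for B
        ga, gb = reverse_search_all([a, b], {"s1": [best, second]})
        assert ga.assignments["s1"].peak is best
        assert gb.assignments["s1"].peak is second

    def test_at_most_one_assignment_per_entry_per_sample(self):
        entry = make_entry()
        peaks = [peak(1545.0 + i, ENTRY_SPECTRUM.scaled(1 + i)) for i in range(8)]
        (group,) = reverse_search_all([entry], {"s1": peaks})
        assert group.n_assigned == 1
        assigned = [p for p in peaks if p.assigned_entry == entry.raw_name]
        assert len(assigned) == 1

    def test_raising_threshold_never_increases_assignments(self):
        rng = np.random.default_rng(17)
        library, samples = random_instance(rng)
        counts = []
        for threshold in (600.0, 800.0, 950.0):
            for peaks in samples.values():
                for p in peaks:
                    p.clear_assignment()
            groups = reverse_search_all(library, samples, ScoringConfig(score_threshold=threshold))
            counts.append(sum(g.n_assigned for g in groups))
        assert counts[0] >= counts[1] >= counts[2]


def random_instance(rng, n_entries=10, n_peaks=50):
    """A randomized search instance mixing true matches and decoys."""
    library = []
    for i in range(n_entries):
        masses = rng.choice(np.arange(70, 500), size=int(rng.integers(8, 20)), replace=False)
        spectrum = MassSpectrum({int(m): float(v) for m, v in zip(masses, rng.uniform(10, 999, len(masses)))})
        library.append(make_entry(f"E{i}_(1TMS)_BP_RI:{1000 + 90 * i}_db", spectrum))
    peaks = []
    for _ in range(n_peaks):
        entry = library[int(rng.integers(n_entries))]
        if rng.random() < 0.6:
            # a (possibly degraded) occurrence of a library metabolite
            spectrum = entry.spectrum.scaled(float(rng.uniform(0.5, 5)))
            if rng.random() < 0.5:
                extra = rng.choice(np.arange(70, 500), 3, replace=False)
                spectrum = spectrum + MassSpectrum(
                    {int(m): float(v) for m, v in zip(extra, rng.uniform(10, 400, 3))}
                )
            ri = entry.reference_ri + float(rng.uniform(-20, 20))
        else:
            masses = rng.choice(np.arange(70, 500), 12, replace=False)
            spectrum = MassSpectrum({int(m): float(v) for m, v in zip(masses, rng.uniform(10, 999, 12))})
            ri = float(rng.uniform(950, 2000))
        peaks.append(peak(ri, spectrum, rt=float(rng.uniform(0, 1000))))
    return library, {"s1": peaks}


def test_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        library, samples = random_instance(rng, n_entries=int(rng.integers(3, 11)), n_peaks=int(rng.integers(5, 51)))
        expected = brute_force_reverse_search(library, samples)
        for peaks in samples.values():
            for p in peaks:
                p.clear_assignment()
        groups = reverse_search_all(library, samples)
        got = {
            (g.entry.raw_name, sid): (a.penalized, a.peak.rt_s)
            for g in groups
            for sid, a in g.assignments.items()
        }
        assert set(got) == set(expected)
        for key, (pen, rt) in got.items():
            assert pen == pytest.approx(expected[key][0])
            assert rt == expected[key][1]
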