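"""Curation operations: fuse, duplicate, found/not-found, accept, lock."""

import numpy as np
import pytest

from gcident import MassSpectrum, Peak, cosine_score
from gcident.peak_editing import (
    EditLog,
    LockError,
    accept_group,
    accept_peak,
    apply_edit_script,
    duplicate,
    enable_edit,
    fuse,
    fuse_region,
    set_all_found,
    set_all_not_found,
    set_found,
    set_not_found,
)
from gcident.reverse_search import PeakGroup, PeakState, reverse_search_entry
from gcident.synthetic import generate_split_peak

from conftest import make_entry


def peak(ri, rt=None, spectrum=None, sample_id="s1", scans=(100, 110)):
    rt = rt if rt is not None else ri / 2
    return Peak(
        sample_id=sample_id,
        rt_s=rt,
        apex_spectrum=spectrum if spectrum is not None else MassSpectrum({100: 10.0, 200: 5.0}),
        integ_begin_s=rt - 2,
        integ_end_s=rt + 2,
        ri=ri,
        start_scan=scans[0],
        end_scan=scans[1],
    )


class TestFuse:
    def test_mean_ri_and_union_scan_range(self):
        left = peak(1500.0, rt=100.0, scans=(100, 110))
        right = peak(1510.0, rt=101.0, scans=(108, 120))
        peaks = [left, right]
        fused = fuse(peaks, left, right)
        assert fused.ri == 1505.0
        assert (fused.start_scan, fused.end_scan) == (100, 120)
        assert peaks == [fused]

    def test_spectrum_is_per_bin_sum_conserving_ion_content(self):
        left = peak(1500.0, spectrum=MassSpectrum({100: 10, 150: 4}))
        right = peak(1502.0, spectrum=MassSpectrum({150: 6, 200: 1}))
        total = left.apex_spectrum.total_intensity() + right.apex_spectrum.total_intensity()
        fused = fuse([left, right], left, right)
        assert fused.apex_spectrum == MassSpectrum({100: 10, 150: 10, 200: 1})
        assert fused.apex_spectrum.total_intensity() == pytest.approx(total)

    def test_argument_order_does_not_matter(self):
        left, right = peak(1500.0, rt=100.0), peak(1510.0, rt=105.0)
        fused = fuse([left, right], right, left)
        assert fused.ri == 1505.0

    def test_self_fusion_rejected(self):
        p = peak(1500.0)
        with pytest.raises(ValueError, match="itself"):
            fuse([p], p, p)

    def test_cross_sample_fusion_rejected(self):
        a, b = peak(1500.0, sample_id="s1"), peak(1502.0, sample_id="s2")
        with pytest.raises(ValueError, match="different samples"):
            fuse([a, b], a, b)

    def test_split_peak_restored_by_fusion(self):
        fx = generate_split_peak(seed=4)
        for half in (fx.left, fx.right):
            assert cosine_score(fx.entry.spectrum, half.apex_spectrum) < 800
        fused = fuse(fx.sample_peaks, fx.left, fx.right)
        assert cosine_score(fx.entry.spectrum, fused.apex_spectrum) > 950
        result = reverse_search_entry(fx.entry, fx.sample_peaks)
        assert result is not None and result.peak is fused


class TestFuseRegion:
    def samples(self):
        return {
            "a": [peak(1500.0, rt=100.0, sample_id="a"), peak(1504.0, rt=101.0, sample_id="a")],
            "b": [
                peak(1498.0, rt=99.0, sample_id="b"),
                peak(1502.0, rt=100.0, sample_id="b"),
                peak(1506.0, rt=101.0, sample_id="b"),
            ],
            "c": [peak(1503.0, rt=100.0, sample_id="c")],
        }

    def test_pairwise_fusion_counts(self):
        samples = self.samples()
        report = fuse_region(samples, 1495.0, 1510.0)
        assert report == {"a": 1, "b": 2, "c": 0}
        assert [len(p) for p in samples.values()] == [1, 1, 1]

    def test_out_of_window_peaks_untouched(self):
        samples = self.samples()
        fuse_region(samples, 1501.0, 1505.0)
        assert len(samples["b"]) == 3  # only one in-window peak in b
        assert len(samples["a"]) == 2  # only 1504 is inside

    def test_empty_window_is_noop(self):
        samples = self.samples()
        assert fuse_region(samples, 2000.0, 2010.0) == {"a": 0, "b": 0, "c": 0}

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="invalid RI window"):
            fuse_region(self.samples(), 1500.0, 1500.0)

    def test_locked_peak_skips_sample_with_warning(self):
        samples = self.samples()
        samples["a"][0].state = PeakState.LOCKED
        with pytest.warns(UserWarning, match="locked"):
            report = fuse_region(samples, 1495.0, 1510.0)
        assert report["a"] == 0 and report["b"] == 2


class TestDuplicate:
    def test_copy_is_unassigned_with_same_coordinates(self):
        p = peak(1500.0)
        p.state = PeakState.PUTATIVE
        p.assigned_entry = "X"
        peaks = [p]
        (copy,) = duplicate(peaks, [p])
        assert copy.rt_s == p.rt_s and copy.ri == p.ri
        assert (copy.start_scan, copy.end_scan) == (p.start_scan, p.end_scan)
        assert copy.state is PeakState.UNKNOWN and copy.assigned_entry is None
        assert len(peaks) == 2

    def test_shared_quant_mass_warning_names_mass(self):
        a = make_entry("A_(1TMS)_BP_RI:1500_db", quant_masses=(217, 100))
        b = make_entry("B_(1TMS)_BP_RI:1502_db", quant_masses=(217, 300))
        p = peak(1500.0)
        with pytest.warns(UserWarning, match="217"):
            duplicate([p], [p], source_entry=a, target_entry=b)

    def test_disjoint_quant_masses_no_warning(self, recwarn):
        a = make_entry("A_(1TMS)_BP_RI:1500_db", quant_masses=(100, 101))
        b = make_entry("B_(1TMS)_BP_RI:1502_db", quant_masses=(200, 201))
        p = peak(1500.0)
        duplicate([p], [p], source_entry=a, target_entry=b)
        assert not [w for w in recwarn if "share" in str(w.message)]


class TestFoundNotFound:
    def test_manual_assignment_bypasses_threshold(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db", MassSpectrum({100: 1.0}))
        weak = peak(1500.0, spectrum=MassSpectrum({100: 2.0, 300: 4.0, 310: 1.0}))
        group = PeakGroup(entry=entry)
        assignment = set_found(group, weak)
        assert assignment.raw_cosine < 800
        assert group.assignments["s1"] is assignment
        assert weak.state is PeakState.PUTATIVE

    def test_set_found_is_idempotent(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db")
        group = PeakGroup(entry=entry)
        p = peak(1500.0, spectrum=entry.spectrum)
        a1 = set_found(group, p)
        a2 = set_found(group, p)
        assert a1 is a2

    def test_not_found_then_found_restores_assignment(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db")
        group = PeakGroup(entry=entry)
        p = peak(1501.0, spectrum=entry.spectrum)
        first = set_found(group, p)
        set_not_found(group, "s1")
        assert group.assignments == {} and p.assigned_entry is None
        second = set_found(group, p)
        assert (second.entry_name, second.sample_id, second.raw_cosine, second.ri_difference) == (
            first.entry_name,
            first.sample_id,
            first.raw_cosine,
            first.ri_difference,
        )

    def test_set_all_found_uses_best_cosine_no_threshold(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db", MassSpectrum({100: 1.0}))
        good = peak(1501.0, spectrum=MassSpectrum({100: 5.0, 300: 1.0}), sample_id="sA")
        bad = peak(1499.0, spectrum=MassSpectrum({100: 1.0, 300: 5.0}), sample_id="sA")
        far = peak(1400.0, sample_id="sB")  # outside the RI window
        group = PeakGroup(entry=entry)
        with pytest.warns(UserWarning, match="sB"):
            report = set_all_found(group, {"sA": [good, bad], "sB": [far]})
        assert report == {"sA": True, "sB": False}
        assert group.assignments["sA"].peak is good

    def test_set_all_not_found_clears_every_sample(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db")
        group = PeakGroup(entry=entry)
        for sid in ("sA", "sB"):
            set_found(group, peak(1500.0, sample_id=sid))
        set_all_not_found(group)
        assert group.assignments == {}


class TestAcceptAndLock:
    def group_with_assignment(self, d_ri=3.5):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db", MassSpectrum({100: 1.0}))
        # cosine 900: dot=9, |A|=1, |B|=sqrt(81+19)=10
        p = peak(1500.0 + d_ri, spectrum=MassSpectrum({100: 9.0, 200: np.sqrt(19.0)}))
        group = PeakGroup(entry=entry)
        result = reverse_search_entry(entry, [p])
        assert result is not None
        group.assignments["s1"] = result
        return group, result

    def test_accept_removes_ri_penalty(self):
        group, assignment = self.group_with_assignment(d_ri=3.5)
        assert assignment.penalized == pytest.approx(855, abs=1e-6)
        accepted = accept_peak(group, "s1")
        assert accepted.peak.assigned_score == pytest.approx(900, abs=1e-6)
        assert accepted.peak.state is PeakState.ACCEPTED

    def test_accept_with_zero_ri_difference_keeps_score(self):
        group, assignment = self.group_with_assignment(d_ri=0.0)
        before = assignment.penalized
        accept_peak(group, "s1")
        assert assignment.peak.assigned_score == pytest.approx(before)

    def test_accept_is_idempotent(self):
        group, _ = self.group_with_assignment()
        a1 = accept_peak(group, "s1")
        a2 = accept_peak(group, "s1")
        assert a1 is a2 and a1.peak.assigned_score == pytest.approx(900, abs=1e-6)

    def test_locked_group_blocks_all_mutation(self):
        group, assignment = self.group_with_assignment()
        accept_group(group)
        p = assignment.peak
        assert p.state is PeakState.LOCKED
        with pytest.raises(LockError):
            fuse([p, peak(1501.0)], p, peak(1501.0))
        with pytest.raises(LockError):
            set_found(group, peak(1501.0))
        with pytest.raises(LockError):
            set_not_found(group, "s1")
        with pytest.raises(LockError):
            accept_peak(group, "s1")
        with pytest.raises(LockError):
            duplicate([p], [p])

    def test_enable_edit_unlocks(self):
        group, assignment = self.group_with_assignment()
        accept_group(group)
        enable_edit(group)
        assert assignment.peak.state is PeakState.ACCEPTED
        other = peak(1501.0)
        fused = fuse([assignment.peak, other], assignment.peak, other)
        assert fused.ri == pytest.approx((1503.5 + 1501.0) / 2)


class TestEditScript:
    def test_script_replay_and_log(self, tmp_path):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db", MassSpectrum({100: 1.0}))
        samples = {"s1": [peak(1500.0, rt=100.0, spectrum=MassSpectrum({100: 5.0}))]}
        group = PeakGroup(entry=entry)
        log = EditLog()
        script = [
            {"op": "set_found", "entry": entry.raw_name, "sample": "s1", "rt": 100.0},
            {"op": "accept_peak", "entry": entry.raw_name, "sample": "s1"},
            {"op": "accept_group", "entry": entry.raw_name},
        ]
        apply_edit_script([group], samples, script, log=log)
        assert group.locked and group.n_assigned == 1
        path = log.dump(tmp_path / "log.jsonl")
        assert len(path.read_text().splitlines()) == 3

    def test_unknown_operation_rejected(self):
        with pytest.raises(ValueError, match="unknown edit operation"):
            apply_edit_script([], {}, [{"op": "explode"}])

    def test_fuse_by_script_scrubs_dangling_assignment(self):
        entry = make_entry("E_(1TMS)_BP_RI:1500_db", MassSpectrum({100: 1.0}))
        p1 = peak(1500.0, rt=100.0, spectrum=MassSpectrum({100: 5.0}))
        p2 = peak(1502.0, rt=101.0, spectrum=MassSpectrum({100: 2.0}))
        samples = {"s1": [p1, p2]}
        group = PeakGroup(entry=entry)
        set_found(group, p1)
        apply_edit_script([group], samples, [{"op": "fuse", "sample": "s1", "rt_left": 100.0, "rt_right": 101.0}])
        assert group.assignments == {}
        assert len(samples["s1"]) == 1
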