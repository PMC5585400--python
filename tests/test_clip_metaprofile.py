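import numpy as np
import pytest

from tandem5ss.clip_metaprofile import (
    RELATIVE_POSITIONS,
    aggregate,
    extract_profile,
    metaprofile_report,
    section_argmax,
    write_metaprofiles,
)
from tandem5ss.event_classification import ClassifiedEvent
from tandem5ss.io_formats import CoverageTrack, TandemDonorEvent
from tandem5ss.synthetic_data import SimulationConfig, simulate_clip, simulate_events


def _plus_event(distal=1000, offset=11):
    return TandemDonorEvent("ev+", "chr1", "+", distal, distal + offset)


def _minus_event(distal=1000, offset=11):
    return TandemDonorEvent("ev-", "chr1", "-", distal, distal - offset)


def _r_index(r):
    return int(np.where(RELATIVE_POSITIONS == r)[0][0])


class TestExtractProfile:
    def test_single_base_density(self):
        ev = _plus_event()
        track = CoverageTrack([("chr1", ev.distal_donor - 25, ev.distal_donor - 24, 7.0)])
        prof = extract_profile(track, ev, "distal")
        assert prof.density[_r_index(-25)] == 1.0
        assert prof.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(prof.density) == 1

    def test_uniform_coverage(self):
        ev = _plus_event()
        track = CoverageTrack([("chr1", 0, 5000, 3.0)])
        prof = extract_profile(track, ev, "distal")
        assert np.allclose(prof.density, 1 / 400)

    def test_minus_strand_flip_brute_force(self):
        """A genomic peak downstream of a minus-strand donor lands at negative r."""
        ev = _minus_event()
        pos = ev.distal_donor + 30  # genomically downstream; exonic side on '-'
        track = CoverageTrack([("chr1", pos, pos + 1, 4.0)])
        prof = extract_profile(track, ev, "distal")
        # brute-force oracle: find r with coverage(anchor - r) > 0
        expected_r = [
            r for r in RELATIVE_POSITIONS if track.coverage("chr1", ev.distal_donor - r) > 0
        ]
        assert expected_r == [-30]
        assert prof.density[_r_index(-30)] == 1.0

    def test_zero_coverage_flagged(self):
        prof = extract_profile(CoverageTrack(), _plus_event(), "distal")
        assert prof.zero_coverage and prof.density is None

    def test_window_past_chromosome_start_rejected(self):
        ev = _plus_event(distal=100)
        with pytest.raises(ValueError, match="ev"):
            extract_profile(CoverageTrack(), ev, "distal")


class TestAggregate:
    def _delta_profile(self, r, event_id="e"):
        ev = TandemDonorEvent(event_id, "chr1", "+", 1000, 1011)
        track = CoverageTrack([("chr1", 1000 + r, 1000 + r + 1, 2.0)])
        return extract_profile(track, ev, "distal")

    def test_single_profile_mean_no_se(self):
        p = self._delta_profile(-10)
        meta = aggregate([p])
        np.testing.assert_array_equal(meta.mean, p.density)
        assert np.all(meta.se == 0)

    def test_two_disjoint_deltas_hand_computed(self):
        meta = aggregate([self._delta_profile(-10, "a"), self._delta_profile(40, "b")])
        i, j = _r_index(-10), _r_index(40)
        assert meta.mean[i] == pytest.approx(0.5)
        assert meta.mean[j] == pytest.approx(0.5)
        # sample SD of {0,1} is sqrt(0.5); SE = sqrt(0.5)/sqrt(2) = 0.5
        assert meta.se[i] == pytest.approx(0.5)
        assert meta.se[j] == pytest.approx(0.5)

    def test_mean_profile_sums_to_one(self):
        rng = np.random.default_rng(0)
        profiles = [self._delta_profile(int(rng.integers(-200, 200)), f"e{k}") for k in range(7)]
        meta = aggregate(profiles)
        assert meta.mean.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_coverage_excluded_and_counted(self):
        profiles = [self._delta_profile(-10), extract_profile(CoverageTrack(), _plus_event(), "distal")]
        meta = aggregate(profiles)
        assert meta.n_events == 1 and meta.n_excluded == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            aggregate([extract_profile(CoverageTrack(), _plus_event(), "distal")])


class TestSectionArgmax:
    def _rect_profile(self, center, width=30, event_id="e"):
        ev = TandemDonorEvent(event_id, "chr1", "+", 1000, 1011)
        lo = 1000 + center - width // 2
        track = CoverageTrack([("chr1", lo, lo + width, 5.0)])
        return extract_profile(track, ev, "distal")

    @pytest.mark.parametrize("center,expected_section", [(-25, 4), (75, 6), (-180, 1), (170, 8)])
    def test_rect_peak_section(self, center, expected_section):
        report = section_argmax([self._rect_profile(center)])
        ((_, section, tie),) = report.per_event
        assert section == expected_section and not tie
        # brute-force oracle over section sums
        raw = self._rect_profile(center).raw
        sums = [raw[50 * k : 50 * (k + 1)].sum() for k in range(8)]
        assert section == int(np.argmax(sums)) + 1

    def test_tie_flagged_lowest_section_wins(self):
        ev = TandemDonorEvent("e", "chr1", "+", 1000, 1011)
        track = CoverageTrack(
            [("chr1", 1000 - 175, 1000 - 174, 3.0), ("chr1", 1000 + 25, 1000 + 26, 3.0)]
        )
        report = section_argmax([extract_profile(track, ev, "distal")])
        ((_, section, tie),) = report.per_event
        assert section == 1 and tie

    def test_zero_events_excluded_from_histogram(self):
        report = section_argmax(
            [self._rect_profile(-25), extract_profile(CoverageTrack(), _plus_event(), "distal")]
        )
        assert report.histogram.sum() == 1 and report.n_excluded == 1
        assert report.section4_count == 1


class TestStrandEquivariance:
    def test_mirrored_minus_cohort_identical_profiles(self):
        """Mirroring all coordinates and flipping strand leaves profiles equal."""
        cfg = SimulationConfig(
            n_events=20, strand_mix=0.0, class_fractions=(1.0, 0.0, 0.0),
            peak_fraction=1.0, background_rate=0.5, seed=31,
        )
        events, truth = simulate_events(cfg)
        track = simulate_clip(events, truth, cfg)
        span = 10 ** int(np.ceil(np.log10(max(e.distal_donor for e in events) + 500)))
        mirrored_events = [
            TandemDonorEvent(e.event_id, e.chrom, "-", span - e.distal_donor, span - e.proximal_donor)
            for e in events
        ]
        mirrored_track = CoverageTrack(
            [(c, span - end + 1, span - start + 1, v) for c, start, end, v in track.records()]
        )
        for ev, mev in zip(events, mirrored_events):
            for anchor in ("distal", "proximal"):
                a = extract_profile(track, ev, anchor)
                b = extract_profile(mirrored_track, mev, anchor)
                np.testing.assert_array_equal(a.raw, b.raw)


class TestMetaprofileReport:
    def test_grid_and_peak_displacement(self, tmp_path):
        cfg = SimulationConfig(
            n_events=40, class_fractions=(1.0, 0.0, 0.0), peak_fraction=1.0,
            background_rate=0.0, seed=32, depth=500,
        )
        events, truth = simulate_events(cfg)
        track = simulate_clip(events, truth, cfg)
        classified = [ClassifiedEvent(e.event_id, "distal_activated", -0.4, 100.0) for e in events]
        grid = metaprofile_report(events, classified, track)
        meta_d, report_d = grid[("distal_activated", "distal")]
        assert meta_d.mean.sum() == pytest.approx(1.0, abs=1e-6)
        # peak mean density maximal inside [-50, 0) at the distal anchor
        peak_r = RELATIVE_POSITIONS[int(np.argmax(meta_d.mean))]
        assert -50 <= peak_r < 0
        # at the proximal anchor the same peak sits upstream by the 11-nt offset
        meta_p, _ = grid[("distal_activated", "proximal")]
        peak_r_prox = RELATIVE_POSITIONS[int(np.argmax(meta_p.mean))]
        assert peak_r_prox == peak_r - 11
        # empty class reported as absent, not an error
        assert grid[("proximal_activated", "distal")] == (None, None)
        written = write_metaprofiles(grid, tmp_path)
        assert len(written) == 4  # 2 files x 2 usable panels

    def test_flat_when_no_peaks(self):
        cfg = SimulationConfig(
            n_events=500, class_fractions=(1.0, 0.0, 0.0), peak_fraction=0.0,
            background_rate=5.0, seed=33,
        )
        events, truth = simulate_events(cfg)
        track = simulate_clip(events, truth, cfg)
        profiles = [extract_profile(track, e, "distal") for e in events]
        meta = aggregate(profiles)
        assert meta.mean.max() / meta.mean.min() < 2.0
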