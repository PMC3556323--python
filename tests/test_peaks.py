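"""Peak caller: closed-form z, input normalization, exhaustive-window
oracle, null subtraction and planted-signal recovery."""

import math
from bisect import bisect_left

import numpy as np
import pytest

from nrcistrome.intervals import GenomicInterval, interval_overlap
from nrcistrome.peaks import (
    PeakCall,
    PeakCallerParams,
    call_hotspots,
    normalize_input,
    read_peaks_bed,
    subtract_null_peaks,
    window_zscore,
    write_peaks_bed,
)
from nrcistrome.tracks import MappabilityTrack, TagTrack, mappable_bp



class TestWindowZscore:
    def test_expectation_gives_zero(self):
        assert window_zscore(7.5, 10_000, 7.5e-4) == pytest.approx(0.0)

    def test_closed_form_values(self):
        # p = 150/200000; 172 tags just clears the z=60 threshold, 7 does not
        assert window_zscore(172, 10_000, 7.5e-4) == pytest.approx(60.089, abs=1e-3)
        assert window_zscore(7, 10_000, 7.5e-4) == pytest.approx(-0.1826, abs=1e-4)

    def test_matches_direct_formula_everywhere(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = float(rng.integers(0, 500))
            N = int(rng.integers(1, 100_000))
            p = float(rng.uniform(1e-5, 0.99))
            expected = (n - N * p) / math.sqrt(N * p * (1 - p))
            assert window_zscore(n, N, p) == pytest.approx(expected, abs=1e-9)

    def test_zero_background_returns_zero(self):
        assert window_zscore(5, 0, 0.5) == 0.0

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_probability_rejected(self, p):
        with pytest.raises(ValueError):
            window_zscore(1, 10, p)

    def test_normal_approximation_matches_exact_binomial_tail(self):
        """For N*p >= 5 the z-score agrees with the z-equivalent of the exact
        binomial upper tail within the documented approximation tolerance."""
        from scipy import stats

        N, p = 20_000, 7.5e-4  # N*p = 15
        for n in (10, 15, 20, 25):  # z in about [-1.3, +2.6]
            z = window_zscore(n, N, p)
            # mid-P exact tail, mapped back to a normal quantile
            tail = stats.binom.sf(n, N, p) + 0.5 * stats.binom.pmf(n, N, p)
            z_exact = stats.norm.isf(tail)
            assert z == pytest.approx(z_exact, abs=0.25)


class TestNormalizeInput:
    def test_identity_when_totals_match(self):
        track = TagTrack.from_positions({"chr1": np.array([1, 2, 3])})
        scaled = normalize_input(track, 3)
        assert scaled.scale == pytest.approx(1.0)

    def test_halves_counts(self):
        track = TagTrack.from_positions({"chr1": np.arange(2_000)})
        scaled = normalize_input(track, 1_000)
        assert scaled.count_in(GenomicInterval("chr1", 0, 2_000)) == pytest.approx(1_000)
        assert scaled.effective_total == pytest.approx(1_000)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_input(TagTrack.from_positions({}), 100)


def _oracle_call(chip, input_scaled, mappability, params, chrom, chrom_len):
    """Exhaustive every-window scorer: plain-Python direct formula at every
    possible window start, then threshold and merge."""
    pos, counts = chip.positions(chrom)
    pos = pos.tolist()
    cum = np.concatenate([[0], np.cumsum(counts)])
    ipos, icounts = input_scaled.positions(chrom)
    ipos = ipos.tolist()
    icum = np.concatenate([[0], np.cumsum(icounts)])

    def count(track_pos, track_cum, lo, hi, scale=1.0):
        return (track_cum[bisect_left(track_pos, hi)] - track_cum[bisect_left(track_pos, lo)]) * scale

    retained = []
    w, half_bg = params.window_bp, params.background_bp // 2
    for s in range(0, chrom_len - w + 1):
        e = s + w
        chip_n = count(pos, cum, s, e)
        n = max(0.0, chip_n - count(ipos, icum, s, e, input_scaled.scale))
        center = s + w // 2
        bg_lo, bg_hi = max(0, center - half_bg), min(chrom_len, center + half_bg)
        N = count(pos, cum, bg_lo, bg_hi)
        mw = mappable_bp(GenomicInterval(chrom, s, e), mappability)
        mbg = mappable_bp(GenomicInterval(chrom, bg_lo, bg_hi), mappability)
        if mw == 0 or mbg == 0 or chip_n < params.min_window_tags:
            continue
        p = mw / mbg
        if not 0 < p < 1 or N == 0:
            continue
        z = (n - N * p) / math.sqrt(N * p * (1 - p))
        if z > params.z_threshold:
            retained.append((s, e, z))
    merged = []
    for s, e, z in retained:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], z)
        else:
            merged.append([s, e, z])
    return merged


def _toy_chromosome(seed, with_input, with_gap):
    rng = np.random.default_rng(seed)
    chrom_len = 10_000
    background = rng.integers(0, chrom_len, size=2_000)
    cluster1 = rng.integers(4_000, 4_060, size=160)
    cluster2 = rng.integers(7_800, 7_900, size=140)
    chip = TagTrack.from_positions(
        {"chr1": np.concatenate([background, cluster1, cluster2])}
    )
    if with_input:
        inp = TagTrack.from_positions(
            {"chr1": rng.integers(0, chrom_len, size=1_500)}
        )
        inp = normalize_input(inp, chip.total_tags)
    else:
        inp = TagTrack.from_positions({})
    blocks = (
        [GenomicInterval("chr1", 0, 3_000), GenomicInterval("chr1", 3_400, 10_000)]
        if with_gap
        else [GenomicInterval("chr1", 0, 10_000)]
    )
    mappability = MappabilityTrack.from_intervals(blocks)
    return chip, inp, mappability, chrom_len


class TestExhaustiveOracle:
    """Tag-anchored calling versus direct scoring of every 150 bp window.

    Anchoring candidates at tag positions cannot lower the maximum window
    score (shifting a window start to its first contained tag never drops
    tags), so the two scorers must retain the same enriched loci; the
    exhaustive scorer's merged regions may extend a few bp further left
    where sub-threshold starts precede the first tag.
    """

    @pytest.mark.parametrize("with_input,with_gap", [(False, False), (True, True)])
    def test_same_retained_loci(self, with_input, with_gap):
        chip, inp, mappability, chrom_len = _toy_chromosome(8, with_input, with_gap)
        params = PeakCallerParams(z_threshold=10.0)
        impl = call_hotspots(
            chip, inp, mappability, params, chrom_lengths={"chr1": chrom_len}
        )
        oracle = _oracle_call(chip, inp, mappability, params, "chr1", chrom_len)
        assert len(impl) == len(oracle)
        for pk, (s, e, z_max) in zip(impl, oracle):
            # implementation region nested in the oracle region, same peak z
            assert s <= pk.interval.start and pk.interval.end <= e
            assert interval_overlap(pk.interval, GenomicInterval("chr1", s, e)) > 0
            if not with_input:
                assert pk.z == pytest.approx(z_max, abs=1e-9)

    def test_chip_equals_input_gives_no_peaks(self):
        chip, _, mappability, chrom_len = _toy_chromosome(3, False, False)
        scaled = normalize_input(chip, chip.total_tags)
        peaks = call_hotspots(
            chip,
            scaled,
            mappability,
            PeakCallerParams(z_threshold=5.0),
            chrom_lengths={"chr1": chrom_len},
        )
        assert peaks == []

    def test_threshold_monotonicity(self):
        chip, inp, mappability, chrom_len = _toy_chromosome(9, False, False)
        lengths = {"chr1": chrom_len}
        lo = call_hotspots(chip, inp, mappability, PeakCallerParams(z_threshold=8.0), chrom_lengths=lengths)
        hi = call_hotspots(chip, inp, mappability, PeakCallerParams(z_threshold=15.0), chrom_lengths=lengths)
        assert len(hi) <= len(lo)
        for pk in hi:
            assert any(
                interval_overlap(pk.interval, other.interval) > 0 for other in lo
            )


class TestNullSubtraction:
    def _peak(self, start, end):
        return PeakCall(GenomicInterval("chr1", start, end), 10, 1000, 0.01, 70.0)

    def test_empty_null_list_is_identity(self):
        peaks = [self._peak(0, 150)]
        assert subtract_null_peaks(peaks, []) == peaks

    def test_single_bp_overlap_retained(self):
        peaks = [self._peak(100, 250)]
        nulls = [self._peak(249, 400)]
        assert subtract_null_peaks(peaks, nulls) == peaks

    def test_two_bp_overlap_removed(self):
        peaks = [self._peak(100, 250)]
        nulls = [self._peak(248, 400)]
        assert subtract_null_peaks(peaks, nulls) == []

    def test_subset_and_idempotent(self, small_genome, small_tracks):
        _, _, mappability, manifest = small_genome
        chip = small_tracks["chip_wt_veh"]
        nullc = small_tracks["chip_null_veh"]
        inp = small_tracks["input_wt"]
        lengths = manifest.chrom_lengths
        peaks = call_hotspots(
            chip, normalize_input(inp, chip.total_tags), mappability, chrom_lengths=lengths
        )
        null_peaks = call_hotspots(
            nullc, normalize_input(inp, nullc.total_tags), mappability, chrom_lengths=lengths
        )
        once = subtract_null_peaks(peaks, null_peaks)
        assert set(id(p) for p in once) <= set(id(p) for p in peaks)
        assert subtract_null_peaks(once, null_peaks) == once


class TestPlantedRecovery:
    def test_planted_sites_recovered_and_artifacts_removed(self, small_genome, small_tracks):
        _, _, mappability, manifest = small_genome
        chip = small_tracks["chip_wt_veh"]
        nullc = small_tracks["chip_null_veh"]
        inp = small_tracks["input_wt"]
        lengths = manifest.chrom_lengths
        peaks = call_hotspots(
            chip, normalize_input(inp, chip.total_tags), mappability, chrom_lengths=lengths
        )
        null_peaks = call_hotspots(
            nullc, normalize_input(inp, nullc.total_tags), mappability, chrom_lengths=lengths
        )
        filtered = subtract_null_peaks(peaks, null_peaks)
        active = [
            s
            for s in manifest.sites_for_condition("chip_wt_veh")
            if s.presence != "artifact"
        ]
        recovered = sum(
            1
            for s in active
            if any(interval_overlap(s.interval, pk.interval) > 0 for pk in filtered)
        )
        assert recovered / len(active) >= 0.9
        # every artifact-derived peak is excluded (>=2 bp overlap rule)
        for s in manifest.artifact_sites:
            assert not any(
                interval_overlap(s.interval, pk.interval) > 1 for pk in filtered
            )

    def test_output_deterministic_and_round_trips(self, tmp_path, small_genome, small_tracks):
        _, _, mappability, manifest = small_genome
        chip = small_tracks["chip_wt_veh"]
        inp = small_tracks["input_wt"]
        peaks = call_hotspots(
            chip,
            normalize_input(inp, chip.total_tags),
            mappability,
            chrom_lengths=manifest.chrom_lengths,
        )
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_peaks_bed(peaks, p1)
        write_peaks_bed(peaks, p2)
        assert p1.read_bytes() == p2.read_bytes()
        reread = read_peaks_bed(p1)
        assert [pk.interval for pk in reread] == [pk.interval for pk in peaks]
        assert [pk.N for pk in reread] == [pk.N for pk in peaks]
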