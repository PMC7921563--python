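"""RPF selection, distance spectra, periodograms, metagene profiles."""

import numpy as np
import pytest

from intactrna import SimConfig, simulate
from intactrna.ribosome import (
    DistanceSpectrum,
    RpfPlacement,
    distance_spectrum,
    metagene_profile,
    periodogram,
    select_rpfs,
)


class TestSelect:
    @pytest.mark.parametrize(
        "length,kept", [(25, False), (26, True), (29, True), (32, True), (33, False)]
    )
    def test_inclusive_window(self, length, kept):
        p = RpfPlacement("t", 0, length)
        assert (select_rpfs([p]) == [p]) == kept

    def test_random_lengths_match_predicate(self, rng):
        ps = [RpfPlacement("t", 0, int(l)) for l in rng.integers(20, 41, size=300)]
        assert select_rpfs(ps) == [p for p in ps if 26 <= p.length <= 32]


def brute_force_spectrum(placements, max_distance):
    """O(n^2) double loop over all read pairs, per transcript."""
    counts = [0] * (max_distance + 1)
    ps = list(placements)
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            if ps[i].transcript_id != ps[j].transcript_id:
                continue
            d = abs(ps[i].five_prime_pos - ps[j].five_prime_pos)
            if d <= max_distance:
                counts[d] += 1
    return tuple(counts)


class TestDistanceSpectrum:
    def test_single_pair(self):
        ps = [RpfPlacement("t", 10, 28), RpfPlacement("t", 13, 28)]
        spec = distance_spectrum(ps)
        assert spec.counts[3] == 1 and spec.total == 1

    def test_cross_transcript_never_counted(self):
        ps = [RpfPlacement("a", 10, 28), RpfPlacement("b", 13, 28)]
        assert distance_spectrum(ps).total == 0

    def test_coincident_distinct_reads_hit_zero(self):
        ps = [RpfPlacement("t", 10, 28)] * 3
        assert distance_spectrum(ps).counts[0] == 3  # C(3,2)

    def test_matches_brute_force_oracle(self, rng):
        ps = [
            RpfPlacement(f"t{int(t)}", int(p), 28)
            for t, p in zip(rng.integers(0, 5, size=500), rng.integers(0, 300, size=500))
        ]
        assert distance_spectrum(ps, 100).counts == brute_force_spectrum(ps, 100)

    def test_total_is_pairs_per_transcript(self, rng):
        """With max_distance >= transcript length the total is sum of n(n-1)/2."""
        from collections import Counter

        ps = [
            RpfPlacement(f"t{int(t)}", int(p), 28)
            for t, p in zip(rng.integers(0, 4, size=200), rng.integers(0, 80, size=200))
        ]
        spec = distance_spectrum(ps, max_distance=100)
        per_t = Counter(p.transcript_id for p in ps)
        assert spec.total == sum(n * (n - 1) // 2 for n in per_t.values())


class TestPeriodogram:
    def test_pure_period3_comb(self):
        counts = tuple(1 if d % 3 == 0 else 0 for d in range(99))
        res = periodogram(DistanceSpectrum(counts))
        assert res.dominant_period == pytest.approx(3.0)
        assert max(res.relative_density) == res.relative_density[
            int(np.argmax(res.density))
        ]

    def test_constant_spectrum_no_dominant_frequency(self):
        res = periodogram(DistanceSpectrum((5,) * 60))
        assert res.dominant_period is None

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            periodogram(DistanceSpectrum((0,) * 60))

    def test_relative_density_normalized_to_first_position(self, rng):
        counts = tuple(int(c) for c in rng.integers(0, 50, size=101))
        res = periodogram(DistanceSpectrum(counts))
        assert res.relative_density[0] == pytest.approx(1.0)

    def test_matches_direct_dft_oracle(self, rng):
        """Densities equal a hand-rolled DFT magnitude-squared to 1e-9."""
        for _ in range(10):
            counts = tuple(int(c) for c in rng.integers(0, 100, size=int(rng.integers(16, 128))))
            if not any(counts):
                continue
            res = periodogram(DistanceSpectrum(counts))
            x = np.array(counts, float) - np.mean(counts)
            n = len(x)
            for idx, k in enumerate(range(1, n // 2 + 1)):
                direct = (
                    np.sum(x * np.cos(2 * np.pi * k * np.arange(n) / n)) ** 2
                    + np.sum(x * np.sin(2 * np.pi * k * np.arange(n) / n)) ** 2
                ) / n
                assert res.density[idx] == pytest.approx(direct, abs=1e-9, rel=1e-9)


class TestPhasingDetection:
    def test_phased_rpfs_dominant_period_3(self):
        """>= 70% in-frame footprints yield a dominant period of 3 nt."""
        cfg = SimConfig(seed=5, rpf_in_frame_fraction=0.7)
        truth = simulate.simulate_reference(cfg)
        rpfs, _ = simulate.simulate_rpfs(truth, cfg)
        res = periodogram(distance_spectrum(select_rpfs(rpfs)))
        assert res.dominant_period == pytest.approx(3.0, abs=0.1)

    def test_uniform_rpfs_not_phased(self):
        """Uniform 5' ends give a dominant period of 3 at no more than
        chance rate across seeds."""
        hits = 0
        for seed in range(6):
            cfg = SimConfig(seed=100 + seed, rpf_in_frame_fraction=0.0)
            truth = simulate.simulate_reference(cfg)
            rpfs, _ = simulate.simulate_rpfs(truth, cfg)
            res = periodogram(distance_spectrum(select_rpfs(rpfs)))
            if res.dominant_period is not None and abs(res.dominant_period - 3.0) < 0.1:
                hits += 1
        assert hits <= 1


def brute_force_metagene(signals, cds_map, trim):
    """Independent rescale-and-trim implementation (explicit loops)."""
    rows, segs = [], []
    for tid, sig in signals.items():
        if tid not in cds_map:
            continue
        s, e = cds_map[tid]
        if not (0 < s < e < len(sig)):
            continue
        rows.append((list(sig[:s]), list(sig[s:e]), list(sig[e:])))
        segs.append((s, e - s, len(sig) - e))
    meds = [int(round(float(np.median([x[i] for x in segs])))) for i in range(3)]
    table = []
    for row in rows:
        full = []
        for seg, m in zip(row, meds):
            out = []
            for j in range(m):
                src = round(j * (len(seg) - 1) / (m - 1)) if m > 1 else 0
                out.append(seg[int(src)])
            full.extend(out)
        table.append(full)
    k = int(np.floor(trim * len(table)))
    profile = []
    for col in zip(*table):
        vals = sorted(col)
        vals = vals[k : len(vals) - k] if k else vals
        profile.append(sum(vals) / len(vals))
    return meds, profile


class TestMetagene:
    def test_identical_transcripts_identity(self):
        sig = list(range(30))
        signals = {f"t{i}": sig for i in range(3)}
        cds = {f"t{i}": (10, 22) for i in range(3)}
        prof = metagene_profile(signals, cds)
        assert list(prof.values) == pytest.approx(sig)
        assert prof.segment_lengths == (10, 12, 8)

    def test_textbook_trimmed_mean(self):
        """Values 1..10 at each position, trim 0.10 -> mean of 2..9 = 5.5."""
        signals = {f"t{i}": [float(i + 1)] * 9 for i in range(10)}
        cds = {f"t{i}": (3, 6) for i in range(10)}
        prof = metagene_profile(signals, cds, trim_fraction=0.10)
        assert all(v == pytest.approx(5.5) for v in prof.values)

    def test_transcript_without_orf_excluded(self):
        signals = {"a": [1.0] * 10, "b": [9.0] * 10}
        prof = metagene_profile(signals, {"a": (2, 8)})
        assert prof.n_transcripts == 1

    def test_matches_independent_oracle(self, rng):
        signals, cds = {}, {}
        for i in range(50):
            n = int(rng.integers(30, 120))
            signals[f"t{i}"] = rng.random(n).tolist()
            s = int(rng.integers(5, n // 3))
            e = int(rng.integers(s + 5, n - 5))
            cds[f"t{i}"] = (s, e)
        prof = metagene_profile(signals, cds, 0.10)
        meds, oracle = brute_force_metagene(signals, cds, 0.10)
        assert prof.segment_lengths == tuple(meds)
        assert list(prof.values) == pytest.approx(oracle)

    def test_invariant_under_reordering_and_duplication(self, rng):
        signals = {f"t{i}": rng.random(40).tolist() for i in range(8)}
        cds = {f"t{i}": (10, 30) for i in range(8)}
        base = metagene_profile(signals, cds, 0.0)
        rev = metagene_profile(dict(reversed(list(signals.items()))), cds, 0.0)
        dup = metagene_profile(
            {**signals, **{f"d{k}": v for k, v in signals.items()}},
            {**cds, **{f"d{k}": v for k, v in cds.items()}},
            0.0,
        )
        assert list(base.values) == pytest.approx(list(rev.values))
        assert list(base.values) == pytest.approx(list(dup.values))
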