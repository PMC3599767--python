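import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilemeta import find_candidate_ders, summarize_der
from tilemeta.regions import CandidateDER
from tilemeta.regression import ProbeStats

from conftest import make_matrix, make_annot


def stats_from_signs(signs):
    """ProbeStats whose slopes realize a sign pattern; 0 means zero slope,
    None an unusable probe."""
    slope = np.array([0.0 if s is None else float(s) for s in signs])
    usable = np.array([s is not None for s in signs])
    se2 = np.ones_like(slope)
    return ProbeStats(slope, se2, np.full(len(slope), 10), usable)


def default_coords(n, chrom="chr1", spacing=35):
    return np.array([chrom] * n, dtype=object), 100 + spacing * np.arange(n)


def brute_force_runs(signs, min_probes):
    """Independent O(n^2) enumeration of maximal same-sign runs."""
    n = len(signs)
    out = []
    for i in range(n):
        for j in range(i, n):
            seg = signs[i : j + 1]
            if 0 in seg or None in seg:
                continue
            if len(set(seg)) != 1:
                continue
            left_ok = i == 0 or signs[i - 1] != seg[0]
            right_ok = j == n - 1 or signs[j + 1] != seg[0]
            if left_ok and right_ok and j - i + 1 >= min_probes:
                out.append((i, j, seg[0]))
    return out


class TestFindCandidates:
    def test_hand_enumerated_pattern(self):
        signs = [1, 1, 1, -1, -1, 1, 0, 1, 1, 1, 1]
        chrom, pos = default_coords(len(signs))
        cands = find_candidate_ders(stats_from_signs(signs), chrom, pos, min_probes=3)
        assert [(c.first, c.last, c.direction) for c in cands] == [
            (0, 2, 1),
            (7, 10, 1),
        ]

    def test_all_positive_is_one_maximal_run(self):
        signs = [1] * 10
        chrom, pos = default_coords(10)
        cands = find_candidate_ders(stats_from_signs(signs), chrom, pos)
        assert len(cands) == 1
        assert cands[0].n_probes == 10

    def test_chromosome_break_splits_run(self):
        signs = [1, 1, 1]
        chrom = np.array(["chr1", "chr1", "chr2"], dtype=object)
        pos = np.array([100, 135, 100])
        cands = find_candidate_ders(stats_from_signs(signs), chrom, pos)
        assert cands == []

    def test_gap_break(self):
        signs = [1, 1, 1, 1, 1, 1]
        chrom, pos = default_coords(6)
        pos = pos.copy()
        pos[3:] += 10_000
        cands = find_candidate_ders(
            stats_from_signs(signs), chrom, pos, max_gap_bp=1000
        )
        assert [(c.first, c.last) for c in cands] == [(0, 2), (3, 5)]

    def test_unusable_probe_breaks_run(self):
        signs = [1, 1, 1, None, 1, 1, 1]
        chrom, pos = default_coords(7)
        cands = find_candidate_ders(stats_from_signs(signs), chrom, pos)
        assert [(c.first, c.last) for c in cands] == [(0, 2), (4, 6)]

    def test_min_probes_config_error(self):
        chrom, pos = default_coords(3)
        with pytest.raises(ValueError):
            find_candidate_ders(stats_from_signs([1, 1, 1]), chrom, pos, min_probes=1)

    @given(
        signs=st.lists(st.sampled_from([1, -1, 0]), min_size=1, max_size=200),
        min_probes=st.integers(2, 5),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_enumeration(self, signs, min_probes):
        chrom, pos = default_coords(len(signs))
        cands = find_candidate_ders(
            stats_from_signs(signs), chrom, pos, min_probes=min_probes
        )
        got = [(c.first, c.last, c.direction) for c in cands]
        assert got == brute_force_runs(signs, min_probes)

    @given(signs=st.lists(st.sampled_from([1, -1, 0]), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=100)
    def test_raising_min_probes_never_adds_candidates(self, signs):
        chrom, pos = default_coords(len(signs))
        sets = []
        for mp in (2, 3, 4):
            cands = find_candidate_ders(stats_from_signs(signs), chrom, pos, mp)
            sets.append({(c.first, c.last) for c in cands})
        assert sets[1] <= sets[0]
        assert sets[2] <= sets[1]

    def test_candidates_disjoint_and_sorted(self):
        rng = np.random.default_rng(3)
        signs = rng.choice([1, -1, 0], size=500, p=[0.45, 0.45, 0.1]).tolist()
        chrom, pos = default_coords(500)
        cands = find_candidate_ders(stats_from_signs(signs), chrom, pos)
        for a, b in zip(cands, cands[1:]):
            assert a.last < b.first


class TestSummarizeDer:
    def test_mean_and_signed_max(self):
        # per-probe group diffs 0.2, 0.4, 0.3
        diffs = np.array([0.2, 0.4, 0.3])
        values = np.zeros((3, 4))
        values[:, 2:] = diffs[:, None]
        matrix = make_matrix(values)
        cand = CandidateDER("chr1", 0, 2, 1)
        mean_diff, max_diff = summarize_der(cand, matrix, np.array([0, 0, 1, 1.0]))
        assert mean_diff == pytest.approx(0.3)
        assert max_diff == pytest.approx(0.4)

    def test_negative_direction_signed_max(self):
        diffs = np.array([-0.1, -0.5, -0.3])
        values = np.zeros((3, 4))
        values[:, 2:] = diffs[:, None]
        matrix = make_matrix(values)
        cand = CandidateDER("chr1", 0, 2, -1)
        mean_diff, max_diff = summarize_der(cand, matrix, np.array([0, 0, 1, 1.0]))
        assert mean_diff == pytest.approx(-0.3)
        assert max_diff == pytest.approx(-0.5)

    def test_all_equal_diffs(self):
        values = np.zeros((3, 4))
        values[:, 2:] = 0.2
        matrix = make_matrix(values)
        cand = CandidateDER("chr1", 0, 2, 1)
        mean_diff, max_diff = summarize_der(cand, matrix, np.array([0, 0, 1, 1.0]))
        assert mean_diff == pytest.approx(0.2)
        assert max_diff == pytest.approx(0.2)

    def test_continuous_phenotype_uses_slopes(self):
        values = np.zeros((3, 4))
        matrix = make_matrix(values)
        stats = ProbeStats(
            np.array([0.1, 0.3, 0.2]), np.ones(3), np.full(3, 4), np.ones(3, bool)
        )
        cand = CandidateDER("chr1", 0, 2, 1)
        mean_diff, max_diff = summarize_der(
            cand, matrix, np.array([0.5, 1.0, 2.0, 3.0]), stats
        )
        assert mean_diff == pytest.approx(0.2)
        assert max_diff == pytest.approx(0.3)
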