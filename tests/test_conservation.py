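"""Alignment, right-anchored stacking, identity profiles, conserved windows."""

import itertools

import numpy as np
import pytest

from crypticpts.conservation import (
    MISSING,
    ConservationProfile,
    conservation_profile,
    find_conserved_windows,
    motif_conservation,
    needleman_wunsch,
    stack_right_anchored,
)
from crypticpts.sequence_io import SequenceRecord
from crypticpts.synthetic_data import SimConfig, generate_locus, generate_ortholog_family

from conftest import random_nt


def brute_force_global_score(a, b, match, mismatch, gap):
    """Maximal score over all global alignments, by exhaustive recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestNeedlemanWunsch:
    def test_identity(self):
        a, b, score = needleman_wunsch("ACGT", "ACGT")
        assert (a, b, score) == ("ACGT", "ACGT", 4.0)

    def test_empty_vs_sequence(self):
        a, b, score = needleman_wunsch("ACGT", "")
        assert a == "ACGT" and b == "----" and score == -8.0

    def test_matches_brute_force_on_short_sequences(self, rng):
        for _ in range(120):
            la, lb = int(rng.integers(0, 7)), int(rng.integers(0, 7))
            a, b = random_nt(rng, la), random_nt(rng, lb)
            _, _, score = needleman_wunsch(a, b)
            assert score == brute_force_global_score(a, b, 1.0, -1.0, -2.0)

    def test_score_symmetry(self, rng):
        for _ in range(50):
            a = random_nt(rng, int(rng.integers(1, 30)))
            b = random_nt(rng, int(rng.integers(1, 30)))
            assert needleman_wunsch(a, b)[2] == needleman_wunsch(b, a)[2]

    def test_alignment_is_valid_and_scores_itself(self, rng):
        for _ in range(50):
            a = random_nt(rng, int(rng.integers(1, 25)))
            b = random_nt(rng, int(rng.integers(1, 25)))
            aa, bb, score = needleman_wunsch(a, b)
            assert aa.replace("-", "") == a and bb.replace("-", "") == b
            recomputed = sum(
                -2.0 if "-" in (x, y) else (1.0 if x == y else -1.0)
                for x, y in zip(aa, bb)
            )
            assert recomputed == score

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch("A", "A", match=-1.0)


class TestStacking:
    def test_padding(self):
        m = stack_right_anchored(
            [SequenceRecord("a", "ACG"), SequenceRecord("b", "TTACG")]
        )
        assert m.shape == (2, 5)
        assert "".join(m[0]) == MISSING * 2 + "ACG"
        assert "".join(m[1]) == "TTACG"

    def test_identical_sequences(self):
        m = stack_right_anchored([SequenceRecord(str(i), "ACGT") for i in range(4)])
        assert (m == m[0]).all()

    def test_planted_codons_column_aligned(self):
        config = SimConfig(seed=21)
        base, _ = generate_locus(config)
        orthologs, _ = generate_ortholog_family(base, config)
        m = stack_right_anchored(
            [SequenceRecord(o.gene_id, o.upstream_seq) for o in orthologs]
        )
        # indel-free: every row has the planted tandem anchor column range -63..-58
        width = m.shape[1]
        for row, o in zip(m, orthologs):
            assert "".join(row[width - 63 : width - 57]) == o.upstream_seq[-63:-57]


class TestProfile:
    def test_identical_rows_identity_one(self):
        m = stack_right_anchored([SequenceRecord(str(i), "ACGTAC") for i in range(5)])
        profile = conservation_profile(m)
        assert np.allclose(profile.identity, 1.0)
        assert list(profile.positions) == [-6, -5, -4, -3, -2, -1]

    def test_modal_fraction(self):
        m = np.array([list("A"), list("A"), list("C"), list("G")])
        profile = conservation_profile(m)
        assert profile.identity[0] == pytest.approx(0.5)

    def test_missing_excluded_from_both_counts(self):
        m = np.array([[MISSING], ["A"], ["A"], ["C"]])
        profile = conservation_profile(m)
        assert profile.identity[0] == pytest.approx(2 / 3)
        assert profile.coverage[0] == 3

    def test_row_permutation_invariance(self, rng):
        rows = [random_nt(rng, 40) for _ in range(6)]
        m1 = stack_right_anchored([SequenceRecord(str(i), r) for i, r in enumerate(rows)])
        perm = rng.permutation(6)
        m2 = m1[perm]
        p1, p2 = conservation_profile(m1), conservation_profile(m2)
        assert np.allclose(p1.identity, p2.identity, equal_nan=True)

    def test_planted_window_more_conserved_than_background(self):
        """Mean identity inside the low-substitution window exceeds outside."""
        inside_means, outside_means = [], []
        for seed in range(100):
            config = SimConfig(seed=seed, sub_rate_conserved=0.02, sub_rate_background=0.3)
            base, _ = generate_locus(config)
            fam, _ = generate_ortholog_family(base, config)
            m = stack_right_anchored(
                [SequenceRecord(o.gene_id, o.upstream_seq) for o in fam]
            )
            profile = conservation_profile(m)
            inside = (profile.positions >= -68) & (profile.positions <= -53)
            # exclude the consensus-constrained motif region from "outside"
            outside = (profile.positions < -100)
            inside_means.append(np.nanmean(profile.identity[inside]))
            outside_means.append(np.nanmean(profile.identity[outside]))
        assert np.mean(inside_means) > np.mean(outside_means)


class TestWindows:
    def test_single_full_window(self):
        profile = ConservationProfile(
            positions=np.arange(-30, 0),
            identity=np.ones(30),
            coverage=np.full(30, 5),
            n_seqs=5,
        )
        (w,) = find_conserved_windows(profile, min_identity=0.8, min_len=6)
        assert (w.start, w.end) == (-30, -1)

    def test_all_below_threshold(self):
        profile = ConservationProfile(
            positions=np.arange(-30, 0),
            identity=np.full(30, 0.5),
            coverage=np.full(30, 5),
            n_seqs=5,
        )
        assert find_conserved_windows(profile) == []

    def test_windows_satisfy_threshold_and_maximality(self, rng):
        for _ in range(50):
            n = 60
            identity = rng.random(n)
            profile = ConservationProfile(
                positions=np.arange(-n, 0),
                identity=identity,
                coverage=np.full(n, 4),
                n_seqs=4,
            )
            for w in find_conserved_windows(profile, min_identity=0.8, min_len=3):
                i0, i1 = w.start + n, w.end + n
                assert (identity[i0 : i1 + 1] >= 0.8).all()
                assert i0 == 0 or identity[i0 - 1] < 0.8
                assert i1 == n - 1 or identity[i1 + 1] < 0.8
                assert w.length >= 3

    def test_modal_recovery_of_planted_window(self):
        """Over 100 families, the modal window matches the planted block."""
        starts, ends = [], []
        for seed in range(1, 101):
            config = SimConfig(seed=seed)
            base, _ = generate_locus(config)
            fam, _ = generate_ortholog_family(base, config)
            m = stack_right_anchored(
                [SequenceRecord(o.gene_id, o.upstream_seq) for o in fam]
            )
            windows = find_conserved_windows(conservation_profile(m))
            best = max(
                (w for w in windows if w.start >= -80 and w.end <= -40),
                key=lambda w: w.length,
                default=None,
            )
            if best is not None:
                starts.append(best.start)
                ends.append(best.end)
        modal_start = max(set(starts), key=starts.count)
        modal_end = max(set(ends), key=ends.count)
        assert abs(modal_start - (-68)) <= 1
        assert abs(modal_end - (-53)) <= 1


class TestMotifConservation:
    def test_variant_peptides_all_conserved(self):
        config = SimConfig(seed=31, n_orthologs=6)
        base, _ = generate_locus(config)
        fam, _ = generate_ortholog_family(base, config)
        rows, fraction = motif_conservation(fam)
        assert fraction == 1.0
        assert len(rows) == 6
        peptides = {r["peptide"] for r in rows}
        assert all(len(p) == 9 for p in peptides)

    def test_ablated_half(self):
        config = SimConfig(seed=33, n_orthologs=6, sub_rate_background=0.0,
                           sub_rate_conserved=0.0)
        base, _ = generate_locus(config)
        fam, _ = generate_ortholog_family(base, config)
        # ablate the motif's first codon (R -> P breaks class 1) in half
        from crypticpts.start_codon_finder import substitute_codons

        ablated = [
            substitute_codons(o, [(-39, "CCA")]) if i < 3 else o
            for i, o in enumerate(fam)
        ]
        rows, fraction = motif_conservation(ablated)
        assert fraction == pytest.approx(0.5)
        assert fraction == sum(r["has_cryptic_pts2"] for r in rows) / len(rows)

    def test_zero_rates_identical_orthologs(self):
        config = SimConfig(seed=35, sub_rate_background=0.0, sub_rate_conserved=0.0)
        base, _ = generate_locus(config)
        fam, _ = generate_ortholog_family(base, config)
        assert all(o.upstream_seq == base.upstream_seq for o in fam)
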