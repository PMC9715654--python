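"""Scoring scheme, class-aware local alignment, and E-value statistics.

The production aligner is checked against two independent oracles: an
exhaustive enumeration of all gapped local pairings (tiny instances) and a
memoised top-down recursion over alignment moves (larger instances), plus a
cross-check against biotite's general-purpose aligner on a custom class
alphabet.
"""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from threadarch import (
    DegenerateQuery,
    align_local,
    build_scoring,
    calibrate_evalue,
    gen_observations,
    gen_proteome,
    search_proteome,
)
from threadarch.fingerprint import CLASS_LABELS
from threadarch.search import AA_INDEX, CLASS_INDEX, encode_query, encode_subject, fit_gumbel
from threadarch.synth import ObservationSpec, ProteomeSpec

from conftest import random_protein


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_local(q, s, S, gap_open, gap_extend):
    """Enumerate every order-preserving gapped pairing (tiny inputs only)."""
    m, n = len(q), len(s)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for qi in itertools.combinations(range(m), k):
            for sj in itertools.combinations(range(n), k):
                score = sum(S[q[a], s[b]] for a, b in zip(qi, sj))
                for t in range(k - 1):
                    a_gap = qi[t + 1] - qi[t] - 1
                    b_gap = sj[t + 1] - sj[t] - 1
                    if a_gap:
                        score -= gap_open + a_gap * gap_extend
                    if b_gap:
                        score -= gap_open + b_gap * gap_extend
                best = max(best, score)
    return best


def recursive_local(q, s, S, gap_open, gap_extend):
    """Memoised top-down recursion over alignment moves."""
    q, s = tuple(q), tuple(s)

    @lru_cache(maxsize=None)
    def end_at(i, j, state):
        # best score of a local alignment ending at column (i, j) in `state`
        if state == "M":
            prev = max(
                0.0,
                end_at(i - 1, j - 1, "M") if i > 0 and j > 0 else 0.0,
                end_at(i - 1, j - 1, "E") if i > 0 and j > 0 else 0.0,
                end_at(i - 1, j - 1, "F") if i > 0 and j > 0 else 0.0,
            )
            return prev + S[q[i], s[j]]
        if state == "E":  # gap consuming subject
            opts = []
            if j > 0:
                opts.append(end_at(i, j - 1, "M") - gap_open - gap_extend)
                opts.append(end_at(i, j - 1, "E") - gap_extend)
                opts.append(end_at(i, j - 1, "F") - gap_open - gap_extend)
            return max(opts, default=-math.inf)
        opts = []  # F: gap consuming query
        if i > 0:
            opts.append(end_at(i - 1, j, "M") - gap_open - gap_extend)
            opts.append(end_at(i - 1, j, "F") - gap_extend)
        return max(opts, default=-math.inf)

    best = 0.0
    for i in range(len(q)):
        for j in range(len(s)):
            best = max(best, end_at(i, j, "M"))
    return best


# ---------------------------------------------------------------------------
# Scoring


class TestBuildScoring:
    def test_closed_forms_uniform_background(self, scheme):
        assert scheme.score("ARO", "W") == pytest.approx(math.log2((1 / 3) / 0.05), abs=1e-9)
        assert scheme.score("ARO", "W") == pytest.approx(2.737, abs=1e-3)
        assert scheme.score("PRO", "P") == pytest.approx(math.log2(1 / 0.05), abs=1e-9)
        assert scheme.score("PRO", "P") == pytest.approx(4.322, abs=1e-3)
        assert scheme.score("PRO", "G") == -4.0

    def test_unk_row_zero(self, scheme):
        assert all(scheme.score("UNK", a) == 0.0 for a in "ACDEFGHIKLMNPQRSTVWY")

    def test_zero_background_rejected(self):
        bad = {a: 1 / 19 if a != "W" else 0.0 for a in "ACDEFGHIKLMNPQRSTVWY"}
        with pytest.raises(ValueError, match="W"):
            build_scoring(background=bad)

    def test_scale(self):
        doubled = build_scoring(scale=2.0)
        base = build_scoring()
        assert doubled.score("ARO", "W") == pytest.approx(2 * base.score("ARO", "W"))


# ---------------------------------------------------------------------------
# Alignment


class TestAlignLocal:
    def test_no_overlap_empty_alignment(self, scheme):
        aln = align_local(["PRO"], "G", scheme)
        assert aln.score == 0.0 and aln.is_empty

    def test_ungapped_toy_match(self, scheme):
        aln = align_local(["ARO", "PRO", "GLY"], "MFPGK", scheme)
        expected = scheme.score("ARO", "F") + scheme.score("PRO", "P") + scheme.score("GLY", "G")
        assert aln.score == pytest.approx(expected, abs=1e-9)
        assert aln.score == pytest.approx(11.381, abs=1e-3)
        assert aln.subject_span == (2, 4) and aln.query_span == (1, 3)
        # brute force over every gapped pairing agrees
        q, s = encode_query(["ARO", "PRO", "GLY"]), encode_subject("MFPGK")
        assert brute_force_local(q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend) == (
            pytest.approx(aln.score)
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, scheme, seed):
        """DP score equals the memoised exhaustive recursion, 50 seeded cases."""
        rng = np.random.default_rng(seed)
        labels = [CLASS_LABELS[i] for i in rng.integers(0, len(CLASS_LABELS), size=12)]
        subject = random_protein(rng, 30)
        aln = align_local(labels, subject, scheme)
        expect = recursive_local(
            encode_query(labels), encode_subject(subject),
            scheme.matrix, scheme.gap_open, scheme.gap_extend,
        )
        assert aln.score == pytest.approx(expect, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_tiny_brute_force(self, scheme, seed):
        rng = np.random.default_rng(100 + seed)
        labels = [CLASS_LABELS[i] for i in rng.integers(0, len(CLASS_LABELS), size=5)]
        subject = random_protein(rng, 8)
        aln = align_local(labels, subject, scheme)
        expect = brute_force_local(
            encode_query(labels), encode_subject(subject),
            scheme.matrix, scheme.gap_open, scheme.gap_extend,
        )
        assert aln.score == pytest.approx(expect, abs=1e-9)

    def test_biotite_cross_check(self, scheme):
        """Independent implementation (biotite, custom class alphabet) agrees."""
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        scale = 1000  # biotite substitution matrices are integer-valued
        class_alph = bseq.Alphabet(list(CLASS_LABELS))
        aa_alph = bseq.Alphabet(list("ACDEFGHIKLMNPQRSTVWY"))
        mat = balign.SubstitutionMatrix(
            class_alph, aa_alph, np.round(scheme.matrix * scale).astype(np.int32)
        )
        rng = np.random.default_rng(7)
        for _ in range(10):
            labels = [CLASS_LABELS[i] for i in rng.integers(0, len(CLASS_LABELS), size=10)]
            subject = random_protein(rng, 25)
            q = bseq.GeneralSequence(class_alph, labels)
            s = bseq.GeneralSequence(aa_alph, list(subject))
            ref = balign.align_optimal(
                q, s, mat,
                gap_penalty=(
                    -int(round((scheme.gap_open + scheme.gap_extend) * scale)),
                    -int(round(scheme.gap_extend * scale)),
                ),
                local=True,
            )[0].score
            ours = align_local(labels, subject, scheme).score
            assert round(ours * scale) == pytest.approx(ref, abs=scale // 100)

    def test_match_column_monotonicity(self, scheme):
        """Appending a class-consistent match column never lowers the score."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            labels = [CLASS_LABELS[i] for i in rng.integers(0, len(CLASS_LABELS), size=8)]
            subject = random_protein(rng, 20)
            base = align_local(labels, subject, scheme).score
            extended = align_local(labels + ["PRO"], subject + "P", scheme).score
            assert extended >= base - 1e-9

    def test_empty_inputs_rejected(self, scheme):
        with pytest.raises(ValueError):
            align_local([], "MKV", scheme)


# ---------------------------------------------------------------------------
# E-value calibration


class TestCalibration:
    def test_too_few_shuffles(self, scheme, target_sequence):
        proteome, _ = gen_proteome(ProteomeSpec(n_decoys=5, seed=0))
        obs = gen_observations(target_sequence, ObservationSpec(seed=0))
        from threadarch import build_query

        q = build_query(obs)
        with pytest.raises(ValueError, match="n_shuffles"):
            calibrate_evalue(q, proteome, scheme, n_shuffles=10)

    def test_gumbel_fit_recovers_scale(self):
        """ML fit on known Gumbel(μ=5, β=2) samples: λ=1/β within 10%."""
        rng = np.random.default_rng(0)
        samples = rng.gumbel(5.0, 2.0, size=500)
        loc, scale = fit_gumbel(samples)
        assert abs(1 / scale - 0.5) / 0.5 < 0.10
        assert abs(loc - 5.0) < 0.3

    def test_doubling_scores_halves_lambda(self):
        rng = np.random.default_rng(1)
        samples = rng.gumbel(10.0, 3.0, size=400)
        _, scale1 = fit_gumbel(samples)
        _, scale2 = fit_gumbel(2 * samples)
        assert 1 / scale2 == pytest.approx(0.5 / scale1, rel=0.02)

    def test_degenerate_fit(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.full(50, 3.0))

    def test_evalue_monotone_in_score(self, scheme, target_sequence):
        proteome, _ = gen_proteome(ProteomeSpec(n_decoys=30, seed=2))
        obs = gen_observations(target_sequence, ObservationSpec(seed=2))
        from threadarch import build_query

        cal = calibrate_evalue(build_query(obs), proteome, scheme, n_shuffles=40, seed=2)
        evs = [cal.evalue(s, 206, 10000) for s in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


# ---------------------------------------------------------------------------
# Ranked search


class TestSearchProteome:
    def test_self_match_is_perfect(self, scheme, target_sequence):
        from threadarch import build_query

        obs = gen_observations(
            target_sequence, ObservationSpec(emission=1.0, misassignment_rate=0.0, seed=0)
        )
        q = build_query(obs)
        proteome, _ = gen_proteome(ProteomeSpec(n_decoys=0, seed=0))
        hits = search_proteome(q, proteome, scheme, seed=0)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.subject_id == "target"
        assert hit.identity == 1.0
        assert hit.coverage >= 0.99

    def test_empty_proteome(self, scheme):
        assert search_proteome(DegenerateQuery(["ARO"]), [], scheme) == []

    def test_retrieval_degrades_with_misassignment(self, scheme, target_sequence):
        """Target score margin shrinks monotonically as class noise rises."""
        from threadarch import build_query

        rates = (0.0, 0.05, 0.15, 0.30)
        margins = []
        for rate in rates:
            per_seed = []
            for seed in range(5):
                proteome, _ = gen_proteome(ProteomeSpec(n_decoys=100, seed=seed))
                obs = gen_observations(
                    target_sequence, ObservationSpec(misassignment_rate=rate, seed=seed)
                )
                q = build_query(obs)
                hits = search_proteome(q, proteome, scheme, seed=seed, evalue_max=float("inf"))
                target_score = next(h.score for h in hits if h.subject_id == "target")
                best_decoy = max(h.score for h in hits if h.subject_id != "target")
                per_seed.append(target_score - best_decoy)
            margins.append(np.mean(per_seed))
        assert all(a > b for a, b in zip(margins, margins[1:]))
        assert margins[0] > 0  # noise-free: the target dominates outright
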