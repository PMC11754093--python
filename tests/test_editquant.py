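"""editquant: alignment, classification, profiles, windows, contexts, purity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deamscope.editquant import (
    ContextProfile,
    EditProfile,
    ReadClass,
    TargetDefinition,
    aggregate_library,
    align_global,
    build_position_profile,
    call_editing_window,
    classify_read,
    context_profile,
    ctot_profile,
    edit_type_matrix,
    indel_frequency,
    orient_and_align,
    quantify_target,
    revcomp,
    target_efficiency,
)
from deamscope.seqio import ConfigError, FormatError
from deamscope.synthdata import EditorSimConfig, LibrarySimConfig, \
    UNIFORM_CONTEXT, planted_rates, simulate_library, simulate_reads

from conftest import bruteforce_nw_score, random_dna


def make_target(spacer="ACCTCACGTGTATAGCAGCG", strand="+", flank=25, seed=5):
    rng = np.random.default_rng(seed)
    left, right = random_dna(rng, flank), random_dna(rng, flank)
    if strand == "+":
        amplicon = left + spacer + "TGG" + right
        start = flank
    else:
        amplicon = left + "CCA" + revcomp(spacer) + right
        start = flank + 3
    return TargetDefinition(target_id="t1", amplicon_seq=amplicon,
                            protospacer_start=start, protospacer_strand=strand)


class TestAlignGlobal:
    def test_identity(self):
        aln = align_global("ACGT", "ACGT")
        assert aln.score == 8
        assert not aln.has_gaps

    def test_single_deletion(self):
        aln = align_global("AGT", "ACGT")
        assert aln.score == 4  # 3 matches + 1 gap

    def test_mismatches_beat_gaps(self):
        assert align_global("AC", "GT").score == -2

    def test_non_dna_rejected_and_n_is_mismatch(self):
        with pytest.raises(FormatError):
            align_global("ACXG", "ACGT")
        assert align_global("ACNT", "ACGT").score == 2 * 3 - 1

    def test_matches_bruteforce_enumeration(self, rng):
        """NW score equals exhaustive enumeration on short random pairs."""
        for _ in range(120):
            a = random_dna(rng, int(rng.integers(1, 9)))
            b = random_dna(rng, int(rng.integers(1, 9)))
            assert align_global(a, b).score == bruteforce_nw_score(a, b), (a, b)

    def test_ungapping_recovers_inputs(self, rng):
        a, b = random_dna(rng, 12), random_dna(rng, 15)
        aln = align_global(b, a)
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_read.replace("-", "") == b


class TestOrientAndAlign:
    def test_reverse_complement_read_accepted(self):
        t = make_target()
        aln = orient_and_align(revcomp(t.amplicon_seq), t)
        assert aln is not None
        assert aln.orientation == "-"
        assert aln.aligned_read == t.amplicon_seq

    def test_random_read_discarded(self, rng):
        t = make_target()
        assert orient_and_align(random_dna(rng, 50), t) is None

    def test_planted_substitution_maps_to_its_position(self):
        t = make_target()
        i = t.amplicon_index(5)
        base = t.amplicon_seq[i]
        alt = "T" if base != "T" else "A"
        read = t.amplicon_seq[:i] + alt + t.amplicon_seq[i + 1:]
        aln = orient_and_align(read, t)
        observed, _ = aln.per_position()
        assert observed[i] == alt
        assert all(o == r for j, (o, r) in
                   enumerate(zip(observed, t.amplicon_seq)) if j != i)


class TestClassifyAndProfile:
    def test_perfect_read_is_reference(self):
        t = make_target()
        aln = orient_and_align(t.amplicon_seq, t)
        assert classify_read(aln, t) == ReadClass.REFERENCE

    def test_deletion_in_protospacer_is_indel(self):
        t = make_target()
        i = t.amplicon_index(5)
        read = t.amplicon_seq[:i] + t.amplicon_seq[i + 1:]
        aln = orient_and_align(read, t)
        assert classify_read(aln, t) == ReadClass.INDEL

    def test_single_substitution_is_substituted(self):
        t = make_target()
        i = t.amplicon_index(5)  # reference C at protospacer position 5
        assert t.amplicon_seq[i] == "C"
        read = t.amplicon_seq[:i] + "T" + t.amplicon_seq[i + 1:]
        aln = orient_and_align(read, t)
        assert classify_read(aln, t) == ReadClass.SUBSTITUTED

    def test_profile_counts_conserve_coverage(self):
        t = make_target()
        i = t.amplicon_index(5)
        reads = [t.amplicon_seq] * 9 + [
            t.amplicon_seq[:i] + "T" + t.amplicon_seq[i + 1:]]
        alns = [orient_and_align(r, t) for r in reads]
        prof = build_position_profile(alns, t)
        assert prof.n_reference == 9 and prof.n_substituted == 1
        cov = prof.coverage
        assert (cov == 10).all()
        assert prof.counts[i, 3] == 1  # T
        assert prof.counts[i, 1] == 9  # C
        assert (prof.counts.sum(axis=1) == prof.n_reference + prof.n_substituted).all()

    def test_zero_alignments_is_error(self):
        with pytest.raises(FormatError):
            build_position_profile([], make_target())


class TestCtotProfile:
    def test_half_edited_position(self):
        t = make_target()
        i = t.amplicon_index(5)
        reads = [t.amplicon_seq] * 50 + [
            t.amplicon_seq[:i] + "T" + t.amplicon_seq[i + 1:]] * 50
        prof = build_position_profile(
            [orient_and_align(r, t) for r in reads], t)
        ep = ctot_profile(prof, t)
        assert ep.f_ct[5] == pytest.approx(0.50)
        assert ep.n[5] == 100

    def test_minus_strand_g_to_a_maps_to_protospacer_c_to_t(self):
        """On a - strand target a protospacer C-to-T shows as amplicon G-to-A."""
        t = make_target(strand="-")
        assert t.protospacer_base(5) == "C"
        i = t.amplicon_index(5)
        assert t.amplicon_seq[i] == "G"
        edited = t.amplicon_seq[:i] + "A" + t.amplicon_seq[i + 1:]
        reads = [t.amplicon_seq] * 70 + [edited] * 30
        prof = build_position_profile(
            [orient_and_align(r, t) for r in reads], t)
        ep = ctot_profile(prof, t)
        assert ep.f_ct[5] == pytest.approx(0.30)

    def test_strand_metamorphic_equivalence(self, rng):
        """Quantifying a - strand target == quantifying the reverse-complemented
        amplicon as a + strand target."""
        t_minus = make_target(strand="-", seed=11)
        amp_rc = revcomp(t_minus.amplicon_seq)
        start_plus = len(amp_rc) - (t_minus.protospacer_start +
                                    t_minus.protospacer_len)
        t_plus = TargetDefinition(target_id="t1", amplicon_seq=amp_rc,
                                  protospacer_start=start_plus,
                                  protospacer_strand="+")
        assert t_plus.protospacer_seq == t_minus.protospacer_seq
        cfg = EditorSimConfig(base_rate=0.4, depth=400, seed=3)
        reads, _ = simulate_reads(t_minus, cfg)
        q_minus = quantify_target(reads, t_minus)
        q_plus = quantify_target(reads, t_plus)  # same reads, rc'd frame
        assert q_minus.edit_profile.f_ct == q_plus.edit_profile.f_ct

    def test_no_edits_gives_all_zero(self):
        t = make_target()
        prof = build_position_profile(
            [orient_and_align(t.amplicon_seq, t)] * 5, t)
        ep = ctot_profile(prof, t)
        assert all(v == 0.0 for v in ep.defined().values())


class TestEditingWindow:
    def _profile(self, f):
        return EditProfile(target_id="t", f_ct=dict(f),
                           f_cg={p: 0.0 for p in f}, f_ca={p: 0.0 for p in f},
                           n={p: 100 for p in f})

    def test_half_max_rule(self):
        ep = self._profile({2: 0.10, 4: 0.40, 5: 0.80, 6: 0.70, 8: 0.30})
        w = call_editing_window(ep)
        assert w.qualifying == frozenset({4, 5, 6})
        assert w.span == (4, 6)
        assert w.peak == 5
        assert w.label() == "C4-C6"

    def test_all_zero_is_empty_window(self):
        w = call_editing_window(self._profile({2: 0.0, 5: 0.0}))
        assert w.empty and w.peak is None

    def test_single_position(self):
        w = call_editing_window(self._profile({7: 0.2}))
        assert w.span == (7, 7) and w.peak == 7

    def test_undefined_everywhere_is_error(self):
        ep = EditProfile(target_id="t", f_ct={3: None}, f_cg={3: None},
                         f_ca={3: None}, n={3: 0})
        with pytest.raises(FormatError):
            call_editing_window(ep)

    @pytest.mark.parametrize("thr", [0.3, 0.5, 0.8])
    def test_raising_threshold_never_widens(self, thr):
        ep = self._profile({1: 0.15, 3: 0.5, 5: 0.9, 7: 0.45, 9: 0.2})
        low = call_editing_window(ep, rel_threshold=thr)
        high = call_editing_window(ep, rel_threshold=min(1.0, thr + 0.2))
        assert high.qualifying <= low.qualifying

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        f=st.dictionaries(st.integers(1, 20),
                          st.floats(0.0, 1.0, allow_nan=False), min_size=1),
        thr=st.floats(0.05, 1.0, allow_nan=False),
    )
    def test_window_properties_hold_for_arbitrary_profiles(self, f, thr):
        ep = self._profile(f)
        w = call_editing_window(ep, rel_threshold=thr)
        if w.empty:
            assert max(f.values()) < 0.01
            return
        m = max(f.values())
        assert f[w.peak] == m
        assert all(f[p] >= thr * m for p in w.qualifying)
        assert w.span[0] == min(w.qualifying) and w.span[1] == max(w.qualifying)
        tighter = call_editing_window(ep, rel_threshold=min(1.0, thr + 0.1))
        assert tighter.qualifying <= w.qualifying

    def test_peak_attains_maximum(self):
        ep = self._profile({2: 0.4, 5: 0.9, 8: 0.9})
        w = call_editing_window(ep)
        assert w.peak == 5  # smallest position on ties
        assert ep.f_ct[w.peak] == max(ep.defined().values())


def _quantified(target, cfg, seed=None):
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    reads, truth = simulate_reads(target, cfg, rng=rng)
    return quantify_target(reads, target), truth


class TestContextProfile:
    def test_context_assignment_uses_5prime_neighbour(self):
        t = make_target(spacer="AACTACGTACGTACGTACGT")
        assert t.context(3) == "AC"
        assert t.protospacer_base(3) == "C"

    def test_uniform_multipliers_give_equal_means(self):
        """Context-independent editor: four NC means agree within binomial error."""
        lib, _, _ = simulate_library(LibrarySimConfig(n_targets=30, seed=21))
        cfg = EditorSimConfig(base_rate=0.4,
                              window_shape={p: 1.0 for p in range(1, 21)},
                              context_multipliers=dict(UNIFORM_CONTEXT),
                              depth=600, seed=9)
        pairs = []
        for k, t in enumerate(lib):
            q, _ = _quantified(t, cfg, seed=1000 + k)
            pairs.append((t, q.edit_profile))
        ctx = context_profile(pairs, position_range=(1, 20))
        means = [m for m in ctx.means.values() if m is not None]
        assert len(means) == 4
        assert max(means) - min(means) < 0.04

    def test_tc_preferring_editor_ranks_tc_highest(self):
        """An eA3A-like TC-preferring editor dominates the TC context."""
        lib, _, _ = simulate_library(LibrarySimConfig(n_targets=30, seed=22))
        cfg = EditorSimConfig(
            base_rate=0.5, window_shape={p: 1.0 for p in range(1, 21)},
            context_multipliers={"AC": 0.05, "CC": 0.05, "GC": 0.05, "TC": 1.0},
            depth=600, seed=10)
        pairs = []
        for k, t in enumerate(lib):
            q, _ = _quantified(t, cfg, seed=2000 + k)
            pairs.append((t, q.edit_profile))
        ctx = context_profile(pairs, position_range=(1, 20))
        assert ctx.ranking()[0] == "TC"
        assert ctx.means["TC"] > 3 * max(
            ctx.means[c] for c in ("AC", "CC", "GC"))


class TestEditTypeMatrix:
    def _pairs(self, edits):
        """edits: list of (alt_base, count) applied at protospacer pos 5."""
        t = make_target()
        i = t.amplicon_index(5)
        reads = [t.amplicon_seq] * 10
        for alt, n in edits:
            reads += [t.amplicon_seq[:i] + alt + t.amplicon_seq[i + 1:]] * n
        prof = build_position_profile(
            [orient_and_align(r, t) for r in reads], t)
        return [(t, prof)]

    def test_pure_ctot(self):
        etm = edit_type_matrix(self._pairs([("T", 10)]))
        assert etm.proportions.loc["C", "T"] == pytest.approx(1.0)
        assert etm.proportions.values.sum() == pytest.approx(1.0)

    def test_mixed_channels(self):
        etm = edit_type_matrix(self._pairs([("T", 80), ("G", 20)]))
        assert etm.proportions.loc["C", "T"] == pytest.approx(0.8)
        assert etm.proportions.loc["C", "G"] == pytest.approx(0.2)

    def test_zero_events_flagged(self):
        etm = edit_type_matrix(self._pairs([]))
        assert etm.empty
        assert (etm.proportions.values == 0).all()

    def test_planted_minor_cg_channel_recovered(self):
        t = make_target()
        cfg = EditorSimConfig(base_rate=0.4, window_shape={5: 1.0},
                              cg_rate=0.05, depth=2000, seed=13)
        q, truth = _quantified(t, cfg)
        etm = edit_type_matrix([(t, q.profile)])
        # C->T events arise only inside the window (rate 0.4 at C5) while the
        # minor C->G channel fires at every reference C in the protospacer
        n_c = len(truth["planted_ct_rates"])
        expected_ct = sum(truth["planted_ct_rates"].values())
        expected_cg = 0.05 * n_c
        want = expected_cg / (expected_cg + expected_ct)
        n = etm.n_events
        sd = np.sqrt(want * (1 - want) / n)
        assert abs(etm.proportions.loc["C", "G"] - want) < 3 * sd


class TestIndelsAndAggregation:
    def test_indel_frequency_basics(self):
        assert indel_frequency([ReadClass.REFERENCE] * 10) == 0.0
        classes = [ReadClass.INDEL] * 5 + [ReadClass.REFERENCE] * 95
        assert indel_frequency(classes) == pytest.approx(0.05)
        with pytest.raises(FormatError):
            indel_frequency([ReadClass.DISCARDED])

    def test_planted_indel_rate_recovered(self):
        t = make_target()
        cfg = EditorSimConfig(base_rate=0.0, indel_rate=0.02,
                              depth=2000, seed=17)
        q, truth = _quantified(t, cfg)
        sd = np.sqrt(0.02 * 0.98 / 2000)
        assert abs(q.indel_frequency - 0.02) < 3 * sd

    def test_quartiles_use_linear_interpolation(self):
        quants = []
        t = make_target()
        for eff in (0.10, 0.20, 0.30, 0.40):
            i = t.amplicon_index(5)
            n_edit = int(eff * 100)
            reads = [t.amplicon_seq] * (100 - n_edit) + [
                t.amplicon_seq[:i] + "T" + t.amplicon_seq[i + 1:]] * n_edit
            quants.append(quantify_target(reads, t))
        stats = aggregate_library(quants)
        assert stats["median"] == pytest.approx(0.25)
        assert stats["q1"] == pytest.approx(0.175)
        assert stats["q3"] == pytest.approx(0.325)

    def test_identical_targets_mean_equals_median(self):
        t = make_target()
        q = quantify_target([t.amplicon_seq] * 10, t)
        stats = aggregate_library([q, q, q])
        assert stats["mean"] == stats["median"] == q.efficiency

    def test_planted_mean_recovered_across_library(self):
        lib, _, _ = simulate_library(LibrarySimConfig(n_targets=40, seed=33))
        cfg = EditorSimConfig(base_rate=0.4,
                              window_shape={p: 1.0 for p in range(1, 21)},
                              depth=400, seed=14)
        quants = []
        for k, t in enumerate(lib):
            rng = np.random.default_rng(3000 + k)
            reads, _ = simulate_reads(t, cfg, rng=rng)
            quants.append(quantify_target(reads, t,
                                          efficiency_method="mean_window"))
        stats = aggregate_library(quants)
        se = np.sqrt(0.4 * 0.6 / 400) / np.sqrt(len(lib))
        assert abs(stats["mean"] - 0.4) < 5 * se


class TestPlantedRateRecovery:
    def test_recovery_within_binomial_bound(self):
        """|f_hat - q| <= 3 sqrt(q(1-q)/n) at every planted position."""
        t = make_target()
        cfg = EditorSimConfig(base_rate=0.5, depth=1000, seed=19)
        q, truth = _quantified(t, cfg)
        for p, rate in truth["planted_ct_rates"].items():
            f = q.edit_profile.f_ct[p]
            bound = 3 * np.sqrt(max(rate * (1 - rate), 1e-9) / 1000) + 1e-9
            assert abs(f - rate) <= max(bound, 0.005), (p, f, rate)
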