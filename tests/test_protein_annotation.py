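"""Core classification, repeat/RiPP detection, duplicates, small-protein filter."""

import itertools
import random

import pytest

from bgcmine.fixtures import AMINO_ACIDS, RIPP_UNIT
from bgcmine.homology_search import AlignHit, DomainHit, MockEngine
from bgcmine.protein_annotation import (
    AnnotationConfig,
    CoreRule,
    annotate_window,
    classify_core,
    default_core_rules,
    detect_duplicates,
    detect_ripp_precursor,
    find_repeats,
    small_protein_filter,
)

from conftest import make_gene


def _hit(profile, score=100.0, query="g"):
    return DomainHit(query, profile, 1e-20, 1e-20, score)


class TestClassifyCore:
    def test_pyr4_family_is_terpene_cyclase_class(self):
        assert classify_core([_hit("Pyr4")]) == "terpene cyclase"

    def test_tailoring_profile_alone_is_not_core(self):
        assert classify_core([_hit("p450")]) is None
        assert classify_core([]) is None

    def test_rule_order_breaks_multi_rule_ties(self):
        hits = [_hit("PKS_KS"), _hit("Pyr4"), _hit("p450")]
        assert classify_core(hits) == "PKS"  # PKS rule listed first

    def test_nrps_needs_both_adenylation_and_condensation(self):
        assert classify_core([_hit("AMP-binding")]) is None
        assert classify_core([_hit("AMP-binding"), _hit("Condensation")]) == "NRPS"

    def test_min_bit_score_floor(self):
        rules = [CoreRule("PKS", frozenset({"PKS_KS"}), min_bit_score=120.0)]
        assert classify_core([_hit("PKS_KS", score=80.0)], rules) is None
        assert classify_core([_hit("PKS_KS", score=150.0)], rules) == "PKS"

    def test_rules_must_name_a_profile(self):
        with pytest.raises(ValueError):
            CoreRule("PKS", frozenset())


def _spaced(unit, copies, spacer="GSTVAQ"):
    return spacer + (unit + spacer) * copies


class TestFindRepeats:
    def test_three_exact_copies_one_family(self):
        protein = _spaced("WNDFYEHQMTCP", 3)
        families = find_repeats(protein)
        best = max(families, key=lambda f: len(f.occurrences))
        assert len(best.occurrences) >= 3
        starts = [s for s, _ in best.occurrences]
        texts = {protein[s : s + best.unit_length] for s in starts}
        assert len(texts) == 1  # identical units

    def test_polyalanine_has_identical_windows(self):
        families = find_repeats("A" * 300)
        assert families
        assert all(f.min_pairwise_identity == 1.0 for f in families)

    def test_random_sequence_has_no_triple_family(self):
        rng = random.Random(123)
        protein = "".join(rng.choice(AMINO_ACIDS) for _ in range(100))
        families = find_repeats(protein)
        assert all(len(f.occurrences) < 3 for f in families)

    def test_short_sequence_empty(self):
        assert find_repeats("MKT") == []


def _window_qualifies(seq, i, length):
    window = seq[i : i + length]
    if len(set(window)) < 3:
        return False
    return any(d in window for d in ("KK", "KR", "RK", "RR"))


def ripp_oracle(seq, min_len=10, min_identity=0.90, min_repeats=3):
    """Brute force over all unit lengths and window combinations.

    Materializes the full pairwise identity matrix of qualifying windows
    for every unit length and exhaustively searches all ascending window
    combinations — no screening heuristics.
    """
    import numpy as np

    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for length in range(min_len, n // min_repeats + 1):
        wins = [i for i in range(n - length + 1) if _window_qualifies(seq, i, length)]
        if len(wins) < min_repeats:
            continue
        mat = np.stack([arr[i : i + length] for i in wins])
        matches = (mat[:, None, :] == mat[None, :, :]).sum(axis=2)
        starts = np.array(wins)
        compatible = (matches + 1e-9 >= min_identity * length) & (
            np.abs(starts[:, None] - starts[None, :]) >= length
        )

        # a window in a valid k-set needs >= k-1 compatible partners
        viable = [int(i) for i in np.where(compatible.sum(axis=1) >= min_repeats - 1)[0]]
        if len(viable) < min_repeats:
            continue

        def extend(chosen, from_pos):
            if len(chosen) == min_repeats:
                return True
            for pos in range(from_pos, len(viable)):
                idx = viable[pos]
                if all(compatible[idx, m] for m in chosen):
                    if extend(chosen + [idx], pos + 1):
                        return True
            return False

        if extend([], 0):
            return True
    return False


class TestDetectRippPrecursor:
    def test_three_copies_with_basic_dipeptide(self):
        assert detect_ripp_precursor(_spaced(RIPP_UNIT, 3)) is True

    def test_two_copies_are_not_enough(self):
        assert detect_ripp_precursor(_spaced(RIPP_UNIT, 2)) is False

    def test_repeat_without_basic_dipeptide_fails(self):
        unit = "LLDKVAEILNGS"  # K present but no KK/KR/RK/RR
        assert detect_ripp_precursor(_spaced(unit, 3)) is False

    def test_polyalanine_fails_diversity(self):
        assert detect_ripp_precursor("A" * 300) is False

    def test_near_identical_repeats_at_ninety_percent(self):
        # 10-mers differing in one position: 9/10 = 90% identity, inclusive
        u1, u3 = "LKKDVAEING", "MKKDVAEING"
        protein = "GSTVAQ" + u1 + "GSTVAQ" + u3 + "GSTVAQ" + u1 + "GSTVAQ"
        assert detect_ripp_precursor(protein) is True

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        rng = random.Random(seed)
        n = rng.randint(30, 300)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(n))
        assert detect_ripp_precursor(seq) == ripp_oracle(seq)

    def test_matches_oracle_on_constructed_cases(self):
        cases = [
            _spaced(RIPP_UNIT, 3),
            _spaced(RIPP_UNIT, 2),
            _spaced("LLDKVAEILNGS", 3),
            "A" * 120,
            _spaced(RIPP_UNIT, 4),
            RIPP_UNIT * 3,  # no spacers: still three non-overlapping windows
        ]
        for seq in cases:
            assert detect_ripp_precursor(seq) == ripp_oracle(seq), seq


def _pair_hits(identity, coverage=80.0):
    return [
        AlignHit("g1", "g2", identity, coverage, 1e-30, 200),
        AlignHit("g2", "g1", identity, coverage, 1e-30, 200),
    ]


class TestDetectDuplicates:
    def test_close_pair_flags_both(self):
        flags = detect_duplicates(["g1", "g2", "g3"], _pair_hits(80.0))
        assert flags == {"g1": True, "g2": True, "g3": False}

    def test_boundary_just_below_fifty(self):
        flags = detect_duplicates(["g1", "g2"], _pair_hits(49.9))
        assert flags == {"g1": False, "g2": False}

    def test_coverage_floor_guards_domain_only_matches(self):
        flags = detect_duplicates(["g1", "g2"], _pair_hits(90.0, coverage=30.0))
        assert flags == {"g1": False, "g2": False}

    def test_symmetric_given_symmetric_hits(self):
        flags = detect_duplicates(["g1", "g2"], _pair_hits(65.0))
        assert flags["g1"] == flags["g2"] is True


class TestAnnotateWindow:
    def _index(self):
        class FakeIndex:
            def origin_of(self, pid):
                return pid.split("|")[0]

        return FakeIndex()

    def test_union_rule(self):
        genes = [
            make_gene("ref_only", 0, 750, index=0),
            make_gene("nothing", 1000, 1750, index=1),
            make_gene("ripp", 2000, 2300, protein=_spaced(RIPP_UNIT, 3), index=2),
        ]
        engine = MockEngine(
            reference_hits=[AlignHit("ref_only", "FBGC1|A", 30.0, 60.0, 1e-20, 200)]
        )
        anns = annotate_window(genes, engine, self._index())
        assert anns["ref_only"].is_biosynthetic and anns["ref_only"].core_category is None
        assert anns["ref_only"].best_ref == ("FBGC1|A", "FBGC1", 30.0)
        assert not anns["nothing"].is_biosynthetic
        assert anns["ripp"].is_ripp_pp and anns["ripp"].is_biosynthetic

    def test_reference_hits_below_thresholds_ignored(self):
        genes = [make_gene("g", 0, 750)]
        engine = MockEngine(
            reference_hits=[AlignHit("g", "FBGC1|A", 24.0, 90.0, 1e-20, 200)]
        )
        anns = annotate_window(genes, engine, self._index())
        assert anns["g"].best_ref is None
        assert not anns["g"].is_biosynthetic

    def test_usty_profile_detection(self):
        genes = [make_gene("g", 0, 750)]
        engine = MockEngine(domain_hits=[_hit("DUF3328", query="g")])
        anns = annotate_window(genes, engine, self._index())
        assert anns["g"].is_usty_like
        assert anns["g"].is_biosynthetic  # via the profile family hit

    def test_evidence_is_monotone(self):
        """Adding a hit never turns a biosynthetic verdict off."""
        genes = [make_gene("g", 0, 750)]
        base = annotate_window(genes, MockEngine(), self._index())
        more = annotate_window(
            genes,
            MockEngine(reference_hits=[AlignHit("g", "FBGC1|A", 55.0, 80.0, 1e-20, 200)]),
            self._index(),
        )
        assert not base["g"].is_biosynthetic
        assert more["g"].is_biosynthetic


class TestSmallProteinFilter:
    def _annotations(self, engine, genes):
        class FakeIndex:
            def origin_of(self, pid):
                return "FBGC1"

        return annotate_window(genes, engine, FakeIndex())

    def test_short_nonbiosynthetic_removed_boundary_inclusive(self):
        genes = [
            make_gene("short", 0, 453, protein="M" * 150, index=0),
            make_gene("exactly200", 1000, 1603, protein="M" * 200, index=1),
            make_gene("long", 2000, 2903, protein="M" * 300, index=2),
        ]
        anns = self._annotations(MockEngine(), genes)
        kept = small_protein_filter(genes, anns)
        assert [g.gene_id for g in kept] == ["exactly200", "long"]

    def test_short_ripp_candidate_retained(self):
        ripp = _spaced(RIPP_UNIT, 3)
        genes = [make_gene("ripp", 0, 3 * len(ripp) + 3, protein=ripp)]
        anns = self._annotations(MockEngine(), genes)
        assert small_protein_filter(genes, anns) == genes
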