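"""Window normalisation, branch encodings, folding, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import branchnet as bn
from branchnet.genomic_io import GenomicInterval, ReferenceGenome, ConservationTrack
from branchnet.preprocessing import (
    DatasetBundle,
    encode_sequence,
    encode_structure,
    extract_conservation,
    extract_sequence,
    fold_structure,
    normalize_interval,
    nussinov_fold,
    reduce_class,
    split_by_chromosome,
    split_random,
)

CHROM_LENGTHS = {"chr1": 10_000}


class TestNormalizeInterval:
    def test_extension_around_midpoint(self):
        iv = normalize_interval(GenomicInterval("chr1", 100, 120), 150, CHROM_LENGTHS)
        assert (iv.start, iv.end) == (35, 185)

    def test_already_at_length_unchanged(self):
        iv = normalize_interval(GenomicInterval("chr1", 100, 120), 20, CHROM_LENGTHS)
        assert (iv.start, iv.end) == (100, 120)

    def test_out_of_bounds_rejected_not_clipped(self):
        assert normalize_interval(GenomicInterval("chr1", 5, 15), 150, CHROM_LENGTHS) is None
        assert normalize_interval(GenomicInterval("chr1", 9990, 9999), 150, CHROM_LENGTHS) is None

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chromosome"):
            normalize_interval(GenomicInterval("chrX", 100, 120), 150, CHROM_LENGTHS)

    def test_result_always_window_long(self):
        for start, end in [(77, 78), (100, 301), (4000, 4001)]:
            iv = normalize_interval(GenomicInterval("chr1", start, end), 151, CHROM_LENGTHS)
            assert iv.length == 151


class TestExtractSequence:
    genome = ReferenceGenome({"chr1": "AACGT", "chr2": "AACG"})

    def test_plus_strand(self):
        assert extract_sequence(self.genome, GenomicInterval("chr1", 0, 4)) == "AACG"

    def test_minus_strand_reverse_complement(self):
        assert extract_sequence(self.genome, GenomicInterval("chr2", 0, 4, strand="-")) == "CGTT"

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_sequence(self.genome, GenomicInterval("chr1", 2, 7))


class TestEncodeSequence:
    def test_acgt_identity(self):
        np.testing.assert_array_equal(encode_sequence("ACGT"), np.eye(4))

    def test_n_is_zero_row_and_u_is_t(self):
        np.testing.assert_array_equal(encode_sequence("N"), [[0, 0, 0, 0]])
        np.testing.assert_array_equal(encode_sequence("U"), [[0, 0, 0, 1]])

    def test_illegal_character_errors(self):
        with pytest.raises(ValueError, match="encode"):
            encode_sequence("ACXG")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_reverse_complement_consistency(self, seq):
        """Encoding the '−' strand equals the row-reversed, A<->T / C<->G
        column-permuted '+' encoding."""
        genome = ReferenceGenome({"c": seq})
        iv_plus = GenomicInterval("c", 0, len(seq), strand="+")
        iv_minus = GenomicInterval("c", 0, len(seq), strand="-")
        enc_minus = encode_sequence(extract_sequence(genome, iv_minus))
        enc_plus = encode_sequence(extract_sequence(genome, iv_plus))
        np.testing.assert_array_equal(enc_minus, enc_plus[::-1][:, [3, 2, 1, 0]])


# ---------------------------------------------------------------------------
# Folding


def _enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Independent oracle: exhaustively enumerate every non-crossing set of
    admissible base pairs and return the maximum pair count."""
    s = seq.upper().replace("T", "U")
    pairable = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def structures(i, j):
        if i >= j:
            yield 0
            return
        yield from structures(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in pairable:
                for inner in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield 1 + inner + right

    return max(structures(0, len(s) - 1)) if s else 0


def _pair_count(db: str) -> int:
    return db.count("(")


class TestNussinovFold:
    @pytest.mark.parametrize("seq,expected_db", [
        ("AAAA", "...."),
        ("GAAAC", "(...)"),
        ("GGGAAACCC", "(((...)))"),
        ("NNNNNNNN", "........"),
    ])
    def test_known_structures(self, seq, expected_db):
        assert nussinov_fold(seq) == expected_db

    @given(st.text(alphabet="ACGU", min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_pair_count_matches_enumeration_oracle(self, seq):
        assert _pair_count(nussinov_fold(seq)) == _enumerate_max_pairs(seq)

    def test_deterministic_traceback(self):
        seq = "GCAUGGAUCGUA"
        assert nussinov_fold(seq) == nussinov_fold(seq)


class TestFoldStructure:
    def test_contract_balanced_and_length(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            db = fold_structure(seq, "builtin")
            assert len(db) == 30
            assert set(db) <= set("(.)")
            depth = np.cumsum([{"(": 1, ")": -1, ".": 0}[c] for c in db])
            assert (depth >= 0).all() and depth[-1] == 0

    def test_vienna_engine(self):
        db = fold_structure("GGGGAAAACCCC", "vienna")
        assert len(db) == 12 and set(db) <= set("(.)")

    def test_bad_engine_output_rejected(self):
        with pytest.raises(RuntimeError, match="invalid structure"):
            fold_structure("ACGU", engine=lambda s: s)  # wrong alphabet


class TestEncodeStructure:
    def test_bracket_one_hot(self):
        mat = encode_structure("(((...)))")
        np.testing.assert_array_equal(mat[:3], [[1, 0, 0]] * 3)
        np.testing.assert_array_equal(mat[3:6], [[0, 1, 0]] * 3)
        np.testing.assert_array_equal(mat[6:], [[0, 0, 1]] * 3)

    def test_empty_and_syntax_only(self):
        assert encode_structure("").shape == (0, 3)
        assert encode_structure("(.)").shape == (3, 3)  # min-loop violations are not its concern

    def test_illegal_character_errors(self):
        with pytest.raises(ValueError):
            encode_structure("(x)")


class TestExtractConservation:
    track = ConservationTrack({"chr1": {10: 0.5, 11: 1.5}})

    def test_covered_and_uncovered(self):
        np.testing.assert_array_equal(
            extract_conservation(self.track, GenomicInterval("chr1", 10, 12)),
            [[0.5], [1.5]])
        np.testing.assert_array_equal(
            extract_conservation(self.track, GenomicInterval("chr1", 100, 103)),
            np.zeros((3, 1)))

    def test_minus_strand_reversed(self):
        np.testing.assert_array_equal(
            extract_conservation(self.track, GenomicInterval("chr1", 10, 12, strand="-")),
            [[1.5], [0.5]])


# ---------------------------------------------------------------------------
# Balancing and splitting


def _dummy_samples(n, label="a", chrom="chr1"):
    vec = np.array([1.0, 0.0]) if label == "a" else np.array([0.0, 1.0])
    return [
        bn.EncodedSample({"sequence": np.zeros((4, 4))}, vec.copy(),
                         GenomicInterval(chrom, 10 * i, 10 * i + 4, label=label))
        for i in range(n)
    ]


class TestReduceClass:
    def test_ratio_and_absolute_reduction(self):
        samples = _dummy_samples(10_000)
        assert len(reduce_class(samples, ratio=0.5, seed=1)) == 5_000
        assert len(reduce_class(samples, n=5_000, seed=1)) == 5_000

    def test_no_upsampling(self):
        assert len(reduce_class(_dummy_samples(100), n=500, seed=1)) == 100

    def test_deterministic_and_order_preserving(self):
        samples = _dummy_samples(50)
        a = reduce_class(samples, ratio=0.4, seed=9)
        b = reduce_class(samples, ratio=0.4, seed=9)
        assert [s.source.start for s in a] == [s.source.start for s in b]
        starts = [s.source.start for s in a]
        assert starts == sorted(starts)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            reduce_class(_dummy_samples(5), seed=1)
        with pytest.raises(ValueError):
            reduce_class(_dummy_samples(5), ratio=1.5, seed=1)


class TestSplitRandom:
    def test_exact_sizes(self):
        samples = _dummy_samples(100, "a") + _dummy_samples(100, "b")
        bundle = split_random(samples, (0.70, 0.15, 0.10, 0.05), seed=1)
        sizes = {k: len(v) for k, v in bundle.subsets().items()}
        assert sizes == {"train": 140, "validation": 30, "evaluation": 20, "blackbox": 10}

    def test_stratification_within_one_sample(self):
        samples = _dummy_samples(100, "a") + _dummy_samples(60, "b")
        ratios = (0.5, 0.25, 0.15, 0.10)
        bundle = split_random(samples, ratios, seed=1)
        for subset, r in zip(bundle.subsets().values(), ratios):
            n_a = sum(s.source.label == "a" for s in subset)
            n_b = len(subset) - n_a
            # per-class floor rule keeps each subset's mix within 1 per class
            assert abs(n_a - r * 100) <= 1
            assert abs(n_b - r * 60) <= 1

    def test_all_train(self):
        samples = _dummy_samples(30)
        bundle = split_random(samples, (1, 0, 0, 0), seed=1)
        assert len(bundle.train) == 30
        assert not bundle.validation and not bundle.blackbox

    def test_same_seed_same_membership(self):
        samples = _dummy_samples(60, "a") + _dummy_samples(60, "b")
        key = lambda b: [(s.source.chrom, s.source.start) for s in b.train]
        assert key(split_random(samples, (0.7, 0.15, 0.1, 0.05), seed=5)) == \
            key(split_random(samples, (0.7, 0.15, 0.1, 0.05), seed=5))

    def test_empty_required_subset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            split_random(_dummy_samples(3), (0.4, 0.3, 0.2, 0.1), seed=1)

    def test_conservation_of_samples(self):
        samples = _dummy_samples(123, "a") + _dummy_samples(77, "b")
        bundle = split_random(samples, (0.7, 0.15, 0.1, 0.05), seed=2)
        assert sum(len(v) for v in bundle.subsets().values()) == 200


class TestSplitByChromosome:
    def _samples(self):
        return (_dummy_samples(5, "a", "chr1") + _dummy_samples(5, "a", "chr2")
                + _dummy_samples(5, "b", "chr3") + _dummy_samples(5, "b", "chr4"))

    def test_membership_matches_assignment(self):
        assignment = {"chr1": "train", "chr2": "train",
                      "chr3": "validation", "chr4": "evaluation"}
        bundle = split_by_chromosome(self._samples(), assignment)
        assert len(bundle.train) == 10 and len(bundle.validation) == 5
        assert len(bundle.evaluation) == 5 and not bundle.blackbox
        chrom_sets = [
            {s.source.chrom for s in subset}
            for subset in bundle.subsets().values() if subset
        ]
        for i, a in enumerate(chrom_sets):
            for b in chrom_sets[i + 1:]:
                assert not a & b

    def test_unassigned_chromosome_errors(self):
        with pytest.raises(ValueError, match="chr3"):
            split_by_chromosome(self._samples(), {"chr1": "train", "chr2": "validation",
                                                  "chr4": "evaluation"})


class TestBuildDataset:
    def test_sequence_only_shapes(self, seq_bundle):
        for samples in seq_bundle.subsets().values():
            for s in samples:
                assert set(s.branches) == {"sequence"}
                assert s.branches["sequence"].shape == (150, 4)
                assert s.label.sum() == 1

    def test_two_branch_shapes(self, small_fixture):
        cfg = bn.RunConfig()
        cfg.preprocessing.branches = ["sequence", "conservation"]
        bundle = bn.build_dataset(cfg, reference=small_fixture.genome,
                                  intervals=small_fixture.intervals,
                                  track=small_fixture.track)
        s = bundle.train[0]
        assert s.branches["sequence"].shape == (150, 4)
        assert s.branches["conservation"].shape == (150, 1)

    def test_structure_branch_end_to_end(self, small_fixture):
        cfg = bn.RunConfig()
        cfg.preprocessing.branches = ["sequence", "structure"]
        few = {label: ivs[:6] for label, ivs in small_fixture.intervals.items()}
        cfg.split.ratios = (0.5, 0.5, 0.0, 0.0)
        bundle = bn.build_dataset(cfg, reference=small_fixture.genome, intervals=few)
        assert bundle.train[0].branches["structure"].shape == (150, 3)
        assert (bundle.train[0].branches["structure"].sum(axis=1) == 1).all()

    def test_sample_conservation_with_rejections(self, small_fixture):
        # place one interval so close to the chromosome edge it must be dropped
        intervals = {k: list(v) for k, v in small_fixture.intervals.items()}
        intervals["positive"] = intervals["positive"] + [
            GenomicInterval("chr1", 2, 12, label="positive")
        ]
        cfg = bn.RunConfig()
        bundle = bn.build_dataset(cfg, reference=small_fixture.genome, intervals=intervals)
        total_in = sum(len(v) for v in intervals.values())
        total_out = sum(len(v) for v in bundle.subsets().values())
        assert total_out == total_in - 1  # exactly the edge interval rejected

    def test_archive_roundtrip(self, seq_bundle, tmp_path):
        path = tmp_path / "data.npz"
        seq_bundle.save(path, manifest=bn.RunConfig())
        loaded = DatasetBundle.load(path)
        assert loaded.class_names == seq_bundle.class_names
        for name, samples in seq_bundle.subsets().items():
            other = getattr(loaded, name)
            assert len(other) == len(samples)
            for a, b in zip(samples, other):
                np.testing.assert_array_equal(a.branches["sequence"], b.branches["sequence"])
                np.testing.assert_array_equal(a.label, b.label)
                assert a.source == b.source

    def test_reduction_applied_per_class(self, small_fixture):
        cfg = bn.RunConfig()
        cfg.preprocessing.reduce = {"positive": 0.5}
        bundle = bn.build_dataset(cfg, reference=small_fixture.genome,
                                  intervals=small_fixture.intervals)
        n_pos = sum(s.source.label == "positive"
                    for v in bundle.subsets().values() for s in v)
        n_neg = sum(s.source.label == "negative"
                    for v in bundle.subsets().values() for s in v)
        assert n_pos == 30 and n_neg == 60

    def test_fewer_than_two_classes_errors(self, small_fixture):
        cfg = bn.RunConfig()
        with pytest.raises(ValueError, match="2 class"):
            bn.build_dataset(cfg, reference=small_fixture.genome,
                             intervals={"positive": small_fixture.intervals["positive"]})
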