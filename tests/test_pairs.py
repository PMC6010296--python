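"""Read-pair classification, fragment assignment, and chimera evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transhic import (
    GenomeLayout,
    Mate,
    PairClass,
    PipelineConfig,
    ReadPairRecord,
    assign_fragment,
    classify_pair,
    estimate_chimeric_error,
    filter_pairs,
    split_ligation_read,
)
from transhic.simulate import SimulationSpec, simulate_read_pairs

from oracles import linear_scan_fragment


class TestSplitLigationRead:
    def test_split_keeps_one_half_site_each(self):
        assert split_ligation_read("AAAGATCGATCTTT", "GATCGATC") == [
            (0, "AAAGATC"),
            (7, "GATCTTT"),
        ]

    def test_no_signature_single_segment(self):
        assert split_ligation_read("AAAATTTT", "GATCGATC") == [(0, "AAAATTTT")]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            split_ligation_read("", "GATCGATC")

    def test_reconstruction_of_random_reads(self):
        """Rejoining the segments minus one half-site copy restores the read."""
        rng = np.random.default_rng(7)
        sig = "GATCGATC"
        half = len(sig) // 2
        bases = np.array(list("ACGT"))
        for _ in range(100):
            n = int(rng.integers(20, 80))
            read = "".join(rng.choice(bases, size=n))
            # avoid accidental earlier signature occurrences
            read = read.replace(sig, "ACGTACGT")
            pos = int(rng.integers(0, len(read) - 1))
            read = read[:pos] + sig + read[pos:]
            if read.find(sig) != pos:
                continue
            segs = split_ligation_read(read, sig)
            assert len(segs) == 2
            (o1, s1), (o2, s2) = segs
            assert (o1, o2) == (0, pos + half)
            assert s1 + s2[half:] == read[: pos + half] + read[pos + len(sig):]
            # both segments retain a half-site at the junction
            assert s1.endswith(sig[:half]) and s2.startswith(sig[half:])


class TestAssignFragment:
    @pytest.fixture
    def layout(self):
        return GenomeLayout([("c", 300)], sites={"c": np.array([100, 200])})

    def test_plus_strand_distance_to_high_end(self, layout):
        assert assign_fragment(layout, "c", 150, "+") == (1, 50)

    def test_boundary_position(self, layout):
        assert assign_fragment(layout, "c", 0, "+") == (0, 100)

    def test_minus_strand_distance_to_low_end(self, layout):
        assert assign_fragment(layout, "c", 150, "-") == (1, 50)
        assert assign_fragment(layout, "c", 250, "-") == (2, 50)

    def test_outside_chromosome_errors(self, layout):
        with pytest.raises(ValueError):
            assign_fragment(layout, "c", 300, "+")

    def test_against_linear_scan_oracle(self, toy_layout):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            chrom = str(rng.choice(toy_layout.names))
            pos = int(rng.integers(0, toy_layout.length(chrom)))
            strand = str(rng.choice(["+", "-"]))
            expected = linear_scan_fragment(
                toy_layout.sites[chrom], toy_layout.length(chrom), pos, strand
            )
            assert assign_fragment(toy_layout, chrom, pos, strand) == expected


def _mate(layout, chrom, pos, strand, mapq=40):
    frag, dist = assign_fragment(layout, chrom, pos, strand)
    return Mate(chrom, pos, strand, mapq, frag, dist)


def ten_record_fixture(layout):
    """2 low-MAPQ, 1 same-fragment, 2 dangling, 1 self-circle, 1 off-site,
    3 clean — each geometry unambiguous under the default thresholds."""
    mk = lambda *a, **k: _mate(layout, *a, **k)
    offsite1 = _mate(layout, "chrA", 0, "+")       # frag length 3000
    offsite2 = _mate(layout, "chrB", 4000, "+")    # frag length 5000
    assert offsite1.frag_end_dist + offsite2.frag_end_dist > 1200
    clean = [
        ReadPairRecord(mk("chrA", 2900, "+"), mk("chrB", 3900, "+")),
        ReadPairRecord(mk("chrA", 3050, "-"), mk("chrB", 8950, "+")),
        ReadPairRecord(mk("chrA", 2950, "+"), mk("chrB", 50, "-")),
    ]
    for rec in clean:
        assert rec.mate1.frag_end_dist + rec.mate2.frag_end_dist <= 1200
    return [
        ReadPairRecord(mk("chrA", 2900, "+", mapq=3), mk("chrB", 3900, "+")),
        ReadPairRecord(mk("chrA", 2900, "+"), mk("chrB", 3900, "+", mapq=0)),
        ReadPairRecord(mk("chrA", 3100, "+"), mk("chrA", 3200, "+")),  # same frag
        ReadPairRecord(mk("chrA", 1000, "+"), mk("chrA", 1500, "-")),  # inward 500
        ReadPairRecord(mk("chrB", 5000, "+"), mk("chrB", 5200, "-")),  # inward 200
        ReadPairRecord(mk("chrA", 1000, "-"), mk("chrA", 9000, "+")),  # outward 8k
        ReadPairRecord(offsite1, offsite2),
        *clean,
    ]


class TestClassifyPair:
    def test_same_fragment_same_orientation(self, sparse_layout, cfg):
        rec = ReadPairRecord(
            _mate(sparse_layout, "chrA", 3100, "+"),
            _mate(sparse_layout, "chrA", 3200, "+"),
        )
        assert classify_pair(rec, cfg) is PairClass.SAME_FRAGMENT

    def test_same_fragment_opposite_orientation_not_flagged(self, sparse_layout, cfg):
        rec = ReadPairRecord(
            _mate(sparse_layout, "chrA", 3100, "-"),
            _mate(sparse_layout, "chrA", 3200, "+"),
        )
        assert classify_pair(rec, cfg) is not PairClass.SAME_FRAGMENT

    def test_dangling_end(self, sparse_layout, cfg):
        rec = ReadPairRecord(
            _mate(sparse_layout, "chrA", 1000, "+"),
            _mate(sparse_layout, "chrA", 1500, "-"),
        )
        assert classify_pair(rec, cfg) is PairClass.DANGLING_END

    def test_unmapped_precedes_everything(self, cfg):
        rec = ReadPairRecord(
            Mate(None, 0, "+", 0), Mate("chrA", 10, "+", 40, 0, 10)
        )
        assert classify_pair(rec, cfg) is PairClass.UNMAPPED

    def test_mate_swap_invariance(self, sparse_layout, cfg):
        for rec in ten_record_fixture(sparse_layout):
            swapped = ReadPairRecord(rec.mate2, rec.mate1, rec.dup, rec.chim3)
            assert classify_pair(rec, cfg) == classify_pair(swapped, cfg)

    def test_ten_record_fixture_counts(self, sparse_layout, cfg):
        records = ten_record_fixture(sparse_layout)
        kept, stats = filter_pairs(records, cfg)
        assert len(kept) == 3
        assert stats.counts["low_mapq"] == 2
        assert stats.counts["same_fragment"] == 1
        assert stats.counts["dangling_end"] == 2
        assert stats.counts["self_circle"] == 1
        assert stats.counts["offsite_digestion"] == 1
        assert stats.counts["keep"] == 3
        assert sum(stats.counts.values()) == stats.total == 10


class TestFilterPairs:
    def test_empty_input(self, cfg):
        kept, stats = filter_pairs([], cfg)
        assert kept == [] and stats.total == 0

    def test_all_clean_library_kept_entirely(self, toy_layout, cfg):
        from transhic.simulate import ArtifactFractions

        spec = SimulationSpec(
            seed=2,
            n_read_pairs=300,
            artifact_fractions=ArtifactFractions(0, 0, 0, 0, 0, 0),
        )
        recs, labels = simulate_read_pairs(toy_layout, spec)
        assert set(labels) == {"keep"}
        kept, stats = filter_pairs(recs, cfg)
        assert len(kept) == 300 and stats.assigned_fraction == 1.0

    def test_planted_artifact_fractions_recovered_exactly(self, toy_layout, cfg):
        spec = SimulationSpec(seed=4, n_read_pairs=1000)
        recs, labels = simulate_read_pairs(toy_layout, spec)
        kept, stats = filter_pairs(recs, cfg)
        assert stats.assigned_fraction == pytest.approx(0.70)
        for rec, label in zip(recs, labels):
            assert classify_pair(rec, cfg).value == label

    def test_classes_partition_input(self, toy_layout, cfg):
        recs, _ = simulate_read_pairs(toy_layout, SimulationSpec(seed=6))
        _, stats = filter_pairs(recs, cfg)
        assert sum(stats.counts.values()) == stats.total == len(recs)


class TestChimericError:
    def test_inward_close_segment_is_not_an_error(self, cfg):
        rec = ReadPairRecord(
            Mate("c", 100, "+", 40, 0, 10),
            Mate("c", 5000, "-", 40, 1, 10),
            chim3=("c", 4500, "+"),
        )
        assert estimate_chimeric_error([rec], cfg) == 0.0

    def test_other_chromosome_segment_is_an_error(self, cfg):
        rec = ReadPairRecord(
            Mate("c", 100, "+", 40, 0, 10),
            Mate("c", 5000, "-", 40, 1, 10),
            chim3=("d", 4500, "+"),
        )
        assert estimate_chimeric_error([rec], cfg) == 1.0

    def test_no_evaluable_records_gives_nan(self, cfg):
        rec = ReadPairRecord(Mate("c", 0, "+", 40, 0, 1), Mate("c", 9, "+", 40, 1, 1))
        assert np.isnan(estimate_chimeric_error([rec], cfg))

    def test_planted_error_rate_recovered(self, toy_layout, cfg):
        spec = SimulationSpec(
            seed=8, n_read_pairs=1000, chimera_fraction=0.2, chimera_error_rate=0.05
        )
        recs, _ = simulate_read_pairs(toy_layout, spec)
        assert estimate_chimeric_error(recs, cfg) == pytest.approx(0.05)


@settings(max_examples=50, deadline=None)
@given(
    pos1=st.integers(0, 9_999),
    pos2=st.integers(0, 9_999),
    s1=st.sampled_from("+-"),
    s2=st.sampled_from("+-"),
    mapq=st.integers(0, 42),
)
def test_classification_is_total_and_swap_invariant(pos1, pos2, s1, s2, mapq):
    """Any well-formed pair gets exactly one class, regardless of mate order."""
    layout = GenomeLayout(
        [("chrA", 10_000)], sites={"chrA": np.array([3_000, 6_000])}
    )
    cfg = PipelineConfig()
    m1 = _mate(layout, "chrA", pos1, s1, mapq=mapq)
    m2 = _mate(layout, "chrA", pos2, s2)
    rec = ReadPairRecord(m1, m2)
    cls = classify_pair(rec, cfg)
    assert cls in PairClass
    assert classify_pair(ReadPairRecord(m2, m1), cfg) == cls
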