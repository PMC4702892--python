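"""Support, size, germline-subtraction and blacklist filters."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brehot import (
    FilterConfig,
    GenomeAssembly,
    filter_pipeline,
    filter_size,
    filter_support,
    subtract_blacklist,
    subtract_germline,
)

from conftest import random_records


class TestSupportFilter:
    def test_at_least_two_and_two_boundary(self, make_record):
        cfg = FilterConfig(min_discordant=2, min_softclip=2)
        kept = make_record(discordant=2, softclip=2)
        dropped = make_record(discordant=1, softclip=5)
        assert filter_support([kept, dropped], cfg) == [kept]

    def test_zero_thresholds_keep_everything(self, make_record):
        records = [make_record(discordant=d, softclip=s) for d in range(3) for s in range(3)]
        cfg = FilterConfig(min_discordant=0, min_softclip=0)
        assert filter_support(records, cfg) == records

    def test_grid_matches_brute_force(self, make_record):
        records = [
            make_record(discordant=d, softclip=s, pos=100 * (d * 4 + s + 1))
            for d in range(4)
            for s in range(3)
        ]
        cfg = FilterConfig(min_discordant=2, min_softclip=2)
        expected = [r for r in records if r.discordant_pairs >= 2 and r.softclip_reads >= 2]
        assert filter_support(records, cfg) == expected


class TestSizeFilter:
    def test_more_than_10mb_is_strict(self):
        big_genome = GenomeAssembly([("chr1", 20_000_000)])
        from conftest import random_records as _  # noqa: F401

        from brehot import AlterationRecord, Breakpoint

        def del_of_size(size):
            bp1 = Breakpoint(chrom="chr1", pos=0, sample_id="s", event_type="DEL", mate=("chr1", size))
            bp2 = Breakpoint(chrom="chr1", pos=size, sample_id="s", event_type="DEL", mate=("chr1", 0))
            return AlterationRecord(sample_id="s", event_type="DEL", bp1=bp1, bp2=bp2,
                                    discordant_pairs=2, softclip_reads=2)

        exactly, over = del_of_size(10_000_000), del_of_size(10_000_001)
        assert filter_size([exactly, over]) == [exactly]

    def test_interchromosomal_has_no_size_and_survives(self, make_record):
        tra = make_record(event_type="TRA_INTER", chrom="chr1", pos=10, mate_chrom="chr2", mate_pos=20)
        assert tra.size is None
        assert filter_size([tra], FilterConfig(max_size=0)) == [tra]

    def test_max_size_zero_degenerate(self, make_record):
        zero = make_record(pos=100, mate_pos=100)
        nonzero = make_record(pos=100, mate_pos=200)
        ins = make_record(event_type="INS", mate_pos=None)
        assert filter_size([zero, nonzero, ins], FilterConfig(max_size=0)) == [zero, ins]


class TestGermlineSubtraction:
    def test_match_within_tolerance_removed(self, make_record):
        cancer = make_record(pos=1000, mate_pos=5000)
        normal = make_record(sample_id="n", pos=1050, mate_pos=4990)
        assert subtract_germline([cancer], [normal], FilterConfig(germline_tolerance=100)) == []
        assert subtract_germline([cancer], [normal], FilterConfig(germline_tolerance=10)) == [cancer]

    def test_event_type_must_match(self, make_record):
        cancer = make_record(event_type="DEL", pos=1000, mate_pos=5000)
        normal = make_record(sample_id="n", event_type="INV", pos=1000, mate_pos=5000)
        assert subtract_germline([cancer], [normal]) == [cancer]

    def test_random_sets_match_all_pairs_oracle(self, genome):
        rng = np.random.default_rng(7)
        # narrow position range so matches actually occur
        small = GenomeAssembly([("chr1", 3_000), ("chr2", 3_000)])
        cancer = random_records(rng, small, 60, sample_id="c")
        normal = random_records(rng, small, 60, sample_id="n")
        cfg = FilterConfig(germline_tolerance=150)

        def matches(c, n):
            if c.event_type != n.event_type or (c.bp2 is None) != (n.bp2 is None):
                return False
            return all(
                cb.chrom == nb.chrom and abs(cb.pos - nb.pos) <= cfg.germline_tolerance
                for cb, nb in zip(c.breakpoints, n.breakpoints)
            )

        expected = [c for c in cancer if not any(matches(c, n) for n in normal)]
        assert subtract_germline(cancer, normal, cfg) == expected


class TestBlacklist:
    def test_half_open_containment(self, make_record):
        inside = make_record(pos=150, mate_pos=None, event_type="INS")
        at_end = make_record(pos=200, mate_pos=None, event_type="INS")
        blacklist = [("chr1", 100, 200)]
        assert subtract_blacklist([inside, at_end], blacklist) == [at_end]

    def test_empty_blacklist_keeps_all(self, make_record):
        records = [make_record(pos=p, mate_pos=None, event_type="INS") for p in (1, 2, 3)]
        assert subtract_blacklist(records, []) == records

    def test_random_instances_match_containment_oracle(self, genome):
        rng = np.random.default_rng(11)
        records = random_records(rng, genome, 80)
        blacklist = []
        for _ in range(15):
            chrom = genome.names[int(rng.integers(0, 2))]
            start = int(rng.integers(0, genome.length_of(chrom) - 1000))
            blacklist.append((chrom, start, start + int(rng.integers(1, 50_000))))
        expected = [
            r
            for r in records
            if not any(
                c == bp.chrom and s <= bp.pos < e
                for bp in r.breakpoints
                for c, s, e in blacklist
            )
        ]
        assert subtract_blacklist(records, blacklist) == expected


class TestFilterProperties:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 2**20),
        disc=st.integers(0, 6),
        soft=st.integers(0, 6),
        max_size=st.integers(0, 600_000),
    )
    def test_raising_thresholds_never_adds_survivors(self, seed, disc, soft, max_size):
        genome = GenomeAssembly([("chr1", 1_000_000), ("chr2", 500_000)])
        rng = np.random.default_rng(seed)
        records = random_records(rng, genome, 40)
        cfg = FilterConfig(min_discordant=disc, min_softclip=soft, max_size=max_size)
        tighter = FilterConfig(min_discordant=disc + 1, min_softclip=soft + 1,
                               max_size=max(0, max_size - 100_000))
        assert len(filter_support(records, tighter)) <= len(filter_support(records, cfg))
        assert len(filter_size(records, tighter)) <= len(filter_size(records, cfg))
        # survivors of the tighter config are a subset of the looser one's
        assert set(map(id, filter_support(records, tighter))) <= set(
            map(id, filter_support(records, cfg))
        )

    def test_filters_are_idempotent_and_preserve_order(self, genome):
        rng = np.random.default_rng(3)
        records = random_records(rng, genome, 50)
        cfg = FilterConfig()
        once = filter_support(filter_size(records, cfg), cfg)
        assert filter_support(filter_size(once, cfg), cfg) == once
        positions = [r.bp1.pos for r in once]
        original_order = [r.bp1.pos for r in records if r in once]
        assert positions == original_order

    def test_pipeline_reports_every_stage(self, genome, make_record):
        records = [make_record(pos=100 * i, mate_pos=100 * i + 50) for i in range(1, 6)]
        stages = filter_pipeline(records, FilterConfig(), [], [])
        assert list(stages) == ["support", "size", "germline", "blacklist"]
        assert stages["blacklist"] == records  # nothing to remove here
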