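import numpy as np
import pytest

from brehot import AlterationRecord, Breakpoint, BreakpointProfile, GenomeAssembly


@pytest.fixture
def genome():
    return GenomeAssembly([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def make_record():
    def _make(
        sample_id="s1",
        event_type="DEL",
        chrom="chr1",
        pos=1000,
        mate_pos=5000,
        mate_chrom=None,
        discordant=5,
        softclip=5,
    ):
        mate_chrom = mate_chrom or chrom
        mate = None if mate_pos is None else (mate_chrom, mate_pos)
        bp1 = Breakpoint(chrom=chrom, pos=pos, sample_id=sample_id, event_type=event_type, mate=mate)
        bp2 = None
        if mate is not None:
            bp2 = Breakpoint(
                chrom=mate_chrom, pos=mate_pos, sample_id=sample_id,
                event_type=event_type, mate=(chrom, pos),
            )
        return AlterationRecord(
            sample_id=sample_id, event_type=event_type, bp1=bp1, bp2=bp2,
            discordant_pairs=discordant, softclip_reads=softclip,
        )

    return _make


@pytest.fixture
def make_profile():
    def _make(sample_id, positions, chrom="chr1", event_type="DEL", cancer_type=""):
        bps = tuple(
            Breakpoint(
                chrom=c if isinstance(c, str) else chrom,
                pos=p,
                sample_id=sample_id,
                event_type=event_type,
            )
            for c, p in ((x if isinstance(x, tuple) else (chrom, x)) for x in positions)
        )
        return BreakpointProfile(sample_id=sample_id, breakpoints=bps, cancer_type=cancer_type)

    return _make


def random_records(rng, genome, n, sample_id="s"):
    """Random validated alteration records for oracle comparisons."""
    from brehot import EVENT_TYPES

    names = genome.names
    lengths = genome.lengths
    recs = []
    for i in range(n):
        ci = int(rng.integers(0, len(names)))
        pos = int(rng.integers(0, lengths[ci]))
        etype = EVENT_TYPES[int(rng.integers(0, len(EVENT_TYPES)))]
        if etype == "TRA_INTER" and len(names) > 1:
            oc = (ci + 1) % len(names)
            mate = (names[oc], int(rng.integers(0, lengths[oc])))
        elif etype == "INS":
            mate = None
        else:
            mate = (names[ci], int(rng.integers(0, lengths[ci])))
        bp1 = Breakpoint(chrom=names[ci], pos=pos, sample_id=sample_id, event_type=etype, mate=mate)
        bp2 = None
        if mate is not None:
            bp2 = Breakpoint(
                chrom=mate[0], pos=mate[1], sample_id=sample_id, event_type=etype,
                mate=(names[ci], pos),
            )
        recs.append(
            AlterationRecord(
                sample_id=sample_id, event_type=etype, bp1=bp1, bp2=bp2,
                discordant_pairs=int(rng.integers(0, 6)),
                softclip_reads=int(rng.integers(0, 6)),
            )
        )
    return recs
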