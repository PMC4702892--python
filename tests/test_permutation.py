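"""Permutation null, empirical p-values, and multiple-testing correction."""
import numpy as np
import pandas as pd
import pytest

from brehot import (
    GenomeAssembly,
    PermutationConfig,
    bh_adjust,
    empirical_pvalues,
    extend_breakpoints,
    permute_profiles,
    segment_by_boundaries,
)


def bh_step_up_oracle(p):
    """Independent Benjamini–Hochberg step-up: q_i = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPermuteProfiles:
    def test_counts_and_labels_conserved(self, make_profile):
        genome = GenomeAssembly([("chr1", 10_000), ("chr2", 5_000)])
        profiles = [make_profile(f"s{i}", list(range(100, 100 + 7 * (i + 1), 7))) for i in range(3)]
        rng = np.random.default_rng(5)
        permuted = permute_profiles(profiles, genome, rng)
        for before, after in zip(profiles, permuted):
            assert len(after) == len(before)
            assert after.sample_id == before.sample_id
            assert [b.event_type for b in after.breakpoints] == [
                b.event_type for b in before.breakpoints
            ]
            after.validate(genome)

    def test_fixed_seed_is_bit_reproducible(self, make_profile):
        genome = GenomeAssembly([("chr1", 10_000), ("chr2", 5_000)])
        profiles = [make_profile("s1", [10, 500, 900]), make_profile("s2", [20, 30])]
        a = permute_profiles(profiles, genome, np.random.default_rng(123))
        b = permute_profiles(profiles, genome, np.random.default_rng(123))
        assert a == b

    def test_chromosome_chosen_proportional_to_length(self, make_profile):
        genome = GenomeAssembly([("chr1", 200_000), ("chr2", 100_000)])  # 2:1
        n = 100_000
        profiles = [make_profile("s1", [0] * n)]
        permuted = permute_profiles(profiles, genome, np.random.default_rng(17))
        frac = sum(bp.chrom == "chr1" for bp in permuted[0].breakpoints) / n
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(frac - 2 / 3) <= 3 * se

    def test_within_chromosome_placement_preserves_chromosome(self, make_profile):
        genome = GenomeAssembly([("chr1", 10_000), ("chr2", 5_000)])
        profiles = [make_profile("s1", [("chr2", p) for p in (10, 20, 4_999)])]
        permuted = permute_profiles(profiles, genome, np.random.default_rng(2), "within_chromosome")
        assert all(bp.chrom == "chr2" for bp in permuted[0].breakpoints)


class TestEmpiricalPvalues:
    def test_pseudocount_formula(self, make_profile):
        # a bin whose observed score no permutation can reach gets p = 1/(n_perm+1)
        genome = GenomeAssembly([("chr1", 1_000_000)])
        profiles = [make_profile(f"s{i}", [500_000]) for i in range(5)]
        regions = pd.concat(
            [extend_breakpoints(p, 100, genome) for p in profiles], ignore_index=True
        )
        bins = segment_by_boundaries(regions, genome)
        cfg = PermutationConfig(n_perm=99, seed=0, flank=100)
        out = empirical_pvalues(bins, profiles, genome, cfg)
        # all 5 samples at one locus of a 1 Mb chromosome: permutations will not tie
        assert out.loc[out["tested"], "p_value"].iloc[0] == pytest.approx(1 / 100)

    def test_always_hit_bin_saturates_near_one(self, make_profile):
        # bin spanning nearly the whole genome is hit by every permutation
        genome = GenomeAssembly([("chr1", 1_000)])
        profiles = [make_profile("s1", [500]), make_profile("s2", [510])]
        regions = pd.concat(
            [extend_breakpoints(p, 600, genome) for p in profiles], ignore_index=True
        )
        bins = segment_by_boundaries(regions, genome)
        cfg = PermutationConfig(n_perm=50, seed=1, flank=600)
        out = empirical_pvalues(bins, profiles, genome, cfg)
        assert (out.loc[out["tested"], "p_value"] == 1.0).all()

    def test_matches_reference_reimplementation(self, make_profile):
        """Fast array path equals a slow object-level re-run of the same stream."""
        genome = GenomeAssembly([("chr1", 1_000)])
        profiles = [
            make_profile("s1", [100, 400, 800]),
            make_profile("s2", [120, 500, 900]),
        ]
        flank, n_perm, seed = 50, 200, 42
        regions = pd.concat(
            [extend_breakpoints(p, flank, genome) for p in profiles], ignore_index=True
        )
        bins = segment_by_boundaries(regions, genome)
        cfg = PermutationConfig(n_perm=n_perm, seed=seed, flank=flank)
        out = empirical_pvalues(bins, profiles, genome, cfg)

        # independent oracle: enumerate the same spawned substreams, relocate
        # via the public object API, extend, and count overlaps per bin by
        # brute force
        exceed = np.zeros(len(bins), dtype=int)
        children = np.random.SeedSequence(seed).spawn(n_perm)
        for child in children:
            rng = np.random.default_rng(child)
            permuted = permute_profiles(profiles, genome, rng)
            for i, row in enumerate(bins.itertuples(index=False)):
                hit_samples = set()
                for prof in permuted:
                    for bp in prof.breakpoints:
                        a, b = max(0, bp.pos - flank), min(1_000, bp.pos + flank + 1)
                        if a < row.end and b > row.start:
                            hit_samples.add(prof.sample_id)
                exceed[i] += len(hit_samples) >= row.score
        expected = (1 + exceed) / (n_perm + 1)
        tested = bins["tested"].to_numpy(bool)
        np.testing.assert_allclose(out["p_value"].to_numpy()[tested], expected[tested])
        assert np.isnan(out["p_value"].to_numpy()[~tested]).all()  # untested bins get no p

    def test_pvalues_bounded_by_pseudocount_floor(self, make_profile):
        genome = GenomeAssembly([("chr1", 50_000)])
        profiles = [make_profile(f"s{i}", [1_000 * i, 25_000]) for i in range(1, 5)]
        regions = pd.concat(
            [extend_breakpoints(p, 500, genome) for p in profiles], ignore_index=True
        )
        bins = segment_by_boundaries(regions, genome)
        cfg = PermutationConfig(n_perm=49, seed=9, flank=500)
        out = empirical_pvalues(bins, profiles, genome, cfg)
        p = out.loc[out["tested"], "p_value"]
        assert ((p >= 1 / 50) & (p <= 1.0)).all()


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_order_equivariance(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.001, 1.0, size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, size=m)
            np.testing.assert_allclose(bh_adjust(p), bh_step_up_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)
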