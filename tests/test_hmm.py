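"""Founder-haplotype HMM: state space, decoding, block calling."""

import numpy as np
import pytest

from dupincompat.genome import Chromosome, GenomeMap
from dupincompat.hmm import (
    HmmParams,
    backward_loglikelihood,
    call_blocks,
    decode_individual,
    decode_posteriors,
    emission_probabilities,
    enumerate_states,
    state_prior,
    transition_matrix,
)
from dupincompat.sim_ril import (
    CrossDesign,
    MISSING,
    _founders_at_markers,
    sample_founder_alleles,
    simulate_subpopulation,
)


class TestStateSpace:
    def test_four_founders_give_ten_canonical_states(self):
        states = enumerate_states(["b", "d", "a", "c"])
        assert states == [
            ("a", "a"), ("a", "b"), ("a", "c"), ("a", "d"),
            ("b", "b"), ("b", "c"), ("b", "d"),
            ("c", "c"), ("c", "d"),
            ("d", "d"),
        ]

    @pytest.mark.parametrize("n,expected", [(2, 3), (4, 10), (8, 36)])
    def test_state_count(self, n, expected):
        founders = [f"f{i}" for i in range(n)]
        assert len(enumerate_states(founders)) == expected

    def test_every_founder_appears_in_four_states(self):
        states = enumerate_states(list("abcd"))
        for f in "abcd":
            assert sum(f in s for s in states) == 4

    def test_duplicate_founders_error(self):
        with pytest.raises(ValueError):
            enumerate_states(["a", "a", "b", "c"])


def _random_instance(rng, n_markers, eps=0.05):
    founders = list("abcd")
    states = enumerate_states(founders)
    alleles = {f: rng.integers(0, 2, n_markers).astype(np.int8) for f in founders}
    obs = rng.integers(0, 3, n_markers).astype(np.int8)
    obs[rng.random(n_markers) < 0.2] = MISSING
    if (obs == MISSING).all():
        obs[0] = 1
    pos = np.sort(rng.uniform(0, 1.0, n_markers))
    params = HmmParams(error_rate=eps, residual_het=2.0 ** -5)
    return obs, alleles, pos, states, params


def brute_force_posteriors(obs, alleles, pos, states, params):
    """Independent oracle: sum prior x transitions x emissions over every
    state path, vectorized over the full path enumeration."""
    emis = emission_probabilities(obs, alleles, states, params)
    m, n = emis.shape
    prior = state_prior(states, params)
    d = np.diff(pos)
    trans = [transition_matrix(di, prior, params.switch_scale) for di in d]
    paths = np.stack(
        np.meshgrid(*[np.arange(n)] * m, indexing="ij"), axis=-1
    ).reshape(-1, m)
    w = prior[paths[:, 0]] * emis[0, paths[:, 0]]
    for t in range(1, m):
        w = w * trans[t - 1][paths[:, t - 1], paths[:, t]] * emis[t, paths[:, t]]
    total = w.sum()
    post = np.empty((m, n))
    for t in range(m):
        post[t] = np.bincount(paths[:, t], weights=w, minlength=n) / total
    return post


class TestDecoding:
    def test_error_free_matching_markers_give_confident_homozygote(self):
        founders = list("abcd")
        states = enumerate_states(founders)
        rng = np.random.default_rng(0)
        m = 30
        # informative panel: founder a distinct from the rest at every marker
        alleles = {"a": np.ones(m, dtype=np.int8)}
        for f in "bcd":
            alleles[f] = np.zeros(m, dtype=np.int8)
        obs = np.full(m, 2, dtype=np.int8)  # homozygous for a's allele
        pos = np.linspace(0, 0.5, m)
        post, _ = decode_posteriors(obs, alleles, pos, states, HmmParams(0.005))
        aa = states.index(("a", "a"))
        assert (post[:, aa] > 0.999).all()

    def test_uninformative_error_rate_returns_prior(self):
        rng = np.random.default_rng(1)
        obs, alleles, pos, states, _ = _random_instance(rng, 10)
        params = HmmParams(error_rate=0.5)
        post, _ = decode_posteriors(obs, alleles, pos, states, params)
        prior = state_prior(states, params)
        assert np.allclose(post, prior[None, :], atol=1e-12)

    def test_rows_sum_to_one_and_forward_backward_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            obs, alleles, pos, states, params = _random_instance(
                rng, int(rng.integers(2, 40))
            )
            post, ll_f = decode_posteriors(obs, alleles, pos, states, params)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
            ll_b = backward_loglikelihood(obs, alleles, pos, states, params)
            assert ll_f == pytest.approx(ll_b, rel=1e-9)

    def test_posteriors_match_exhaustive_path_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            obs, alleles, pos, states, params = _random_instance(
                rng, int(rng.integers(2, 6))
            )
            post, _ = decode_posteriors(obs, alleles, pos, states, params)
            oracle = brute_force_posteriors(obs, alleles, pos, states, params)
            assert np.max(np.abs(post - oracle)) < 1e-10

    def test_all_missing_observations_error(self):
        rng = np.random.default_rng(4)
        obs, alleles, pos, states, params = _random_instance(rng, 5)
        obs[:] = MISSING
        with pytest.raises(ValueError):
            decode_posteriors(obs, alleles, pos, states, params)


class TestCallBlocks:
    def _post_from_map(self, map_states, n_states=10, conf=0.97):
        m = len(map_states)
        post = np.full((m, n_states), (1 - conf) / (n_states - 1))
        post[np.arange(m), map_states] = conf
        return post

    def test_constant_state_single_block(self):
        states = enumerate_states(list("abcd"))
        pos = np.arange(10) * 100
        post = self._post_from_map([3] * 10)
        blocks = call_blocks(post, states, pos, "chr1", 1000)
        assert len(blocks) == 1
        assert blocks.iloc[0][["start", "end"]].tolist() == [0, 1000]

    def test_single_switch_boundary_at_marker_midpoint(self):
        states = enumerate_states(list("abcd"))
        pos = np.arange(10) * 100
        post = self._post_from_map([0] * 5 + [4] * 5)
        blocks = call_blocks(post, states, pos, "chr1", 1000)
        assert len(blocks) == 2
        assert blocks.iloc[0]["end"] == (pos[4] + pos[5]) // 2

    def test_single_marker_flip_absorbed(self):
        states = enumerate_states(list("abcd"))
        pos = np.arange(9) * 100
        post = self._post_from_map([0, 0, 0, 0, 5, 0, 0, 0, 0])
        blocks = call_blocks(post, states, pos, "chr1", 900, min_markers=2)
        assert len(blocks) == 1
        assert blocks.iloc[0]["state"] == "a|a"


class TestAccuracyOnSimulatedRils:
    def test_marker_accuracy_and_breakpoint_recall(self, founders):
        """F6 RILs with 0.5% genotyping error and 10% missingness decode to
        >= 99% correct marker states; >= 95% of resolvable true breakpoints
        (flanking truth runs at least min_markers long) are recovered within
        one marker interval.

        The marker panel cycles through the three balanced founder
        bipartitions so every founder pair is informative at two of every
        three consecutive markers, mirroring real panels selected for
        informativeness.
        """
        rng = np.random.default_rng(5)
        n_markers = 2000
        genome = GenomeMap(
            [Chromosome("chr1", 20_000_000, 1.0)],
            {"chr1": np.linspace(0, 20_000_000 - 1, n_markers, dtype=np.int64)},
        )
        splits = [(1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1)]
        alleles = {f: {"chr1": np.zeros(n_markers, dtype=np.int8)} for f in founders}
        for j in range(n_markers):
            for f, v in zip(founders, splits[j % 3]):
                alleles[f]["chr1"][j] = v
        design = CrossDesign("T", founders, selfing_generations=6, target_n=8)
        lines = simulate_subpopulation(
            design, alleles, [], genome, rng, error_rate=0.005, missing_rate=0.10
        )
        states = enumerate_states(founders)
        params = HmmParams(error_rate=0.005)
        positions = genome.markers["chr1"]
        n_correct = n_total = 0
        n_true_bp = n_found_bp = 0
        for ind in lines:
            truth = [
                tuple(sorted(pair))
                for pair in zip(
                    _founders_at_markers(ind.mosaic[0]["chr1"], positions),
                    _founders_at_markers(ind.mosaic[1]["chr1"], positions),
                )
            ]
            post, _ = decode_posteriors(
                ind.observed["chr1"],
                {f: alleles[f]["chr1"] for f in founders},
                genome.marker_morgans("chr1"),
                states,
                params,
            )
            called = [states[i] for i in post.argmax(axis=1)]
            n_correct += sum(c == t for c, t in zip(called, truth))
            n_total += len(truth)
            blocks = call_blocks(
                post, states, positions, "chr1", 20_000_000, min_markers=2
            )
            bp_called = blocks["end"].to_numpy()[:-1]
            # truth run length at each marker, for the resolvability filter
            run_id = np.cumsum(
                [0] + [truth[i] != truth[i - 1] for i in range(1, len(truth))]
            )
            run_len = np.bincount(run_id)
            for i in range(len(truth) - 1):
                if truth[i] != truth[i + 1]:
                    if min(run_len[run_id[i]], run_len[run_id[i + 1]]) < 2:
                        continue  # below the caller's min_markers resolution
                    n_true_bp += 1
                    lo = positions[max(i - 1, 0)]
                    hi = positions[min(i + 2, len(truth) - 1)]
                    if ((bp_called >= lo) & (bp_called <= hi)).any():
                        n_found_bp += 1
        assert n_correct / n_total >= 0.99
        assert n_true_bp > 0
        assert n_found_bp / n_true_bp >= 0.95

    def test_decode_individual_covers_genome(self, founders, small_genome, rng):
        alleles = sample_founder_alleles(small_genome, founders, rng)
        design = CrossDesign("T", founders, selfing_generations=4, target_n=1)
        (ind,) = simulate_subpopulation(design, alleles, [], small_genome, rng)
        blocks = decode_individual(ind, small_genome, alleles, founders)
        for c in small_genome.chromosomes:
            sub = blocks[blocks["chrom"] == c.id]
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == c.length_bp
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
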