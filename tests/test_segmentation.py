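"""Binning, emission construction, chain splitting, EM, Viterbi and linking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cphmm.io import CPG, CPH, SampleMeta
from cphmm.segmentation import (
    N, P, STATES, U, UNASSIGNED, GenomeMethylationStats, HmmSegmenter,
    emission_argmax_states, emission_matrix, fit_transitions, genome_stats,
    link_and_extract_dmrs, make_bins, posterior_theta, prior_mean, split_chains,
    sticky_transition_init, viterbi_decode,
)
from cphmm.simulate import simulate_hmm_bins

from conftest import bins_frame, small_table


def brute_force_viterbi(log_a, log_pi, log_e):
    """Exhaustive max over all 3^L paths; ties -> lexicographically smallest."""
    T = log_e.shape[0]
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(3), repeat=T):
        score = log_pi[path[0]] + log_e[0, path[0]]
        for t in range(1, T):
            score += log_a[path[t - 1], path[t]] + log_e[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path), best_score


def random_model(rng):
    a = rng.dirichlet(np.ones(3), size=3)
    pi = rng.dirichlet(np.ones(3))
    return np.log(a), np.log(pi)


class TestMakeBins:
    def test_tiling_of_540bp_chromosome(self, meta):
        table = small_table(meta, [("c", 0, "+", CPG, "CGG", 1, 2)])
        bins = make_bins(table, chrom_sizes={"c": 540})
        assert list(bins["start"]) == [0, 180, 360]
        assert list(bins["end"]) == [180, 360, 540]

    def test_detection_rule_is_strict(self, meta):
        rows = [("c", 0, "+", CPG, "CGG", 1, 11), ("c", 1, "+", CPH, "CAC", 1, 11),
                ("c", 180, "+", CPG, "CGG", 1, 10), ("c", 181, "+", CPH, "CAC", 1, 11)]
        bins = make_bins(small_table(meta, rows))
        assert list(bins["detected"]) == [True, False]

    def test_half_open_bin_boundary(self, meta):
        rows = [("c", 179, "+", CPH, "CAC", 1, 5), ("c", 180, "+", CPH, "CAC", 1, 7)]
        bins = make_bins(small_table(meta, rows))
        assert list(bins["cph_n"]) == [5, 7]


class TestGenomeStats:
    def test_median_and_pooled_ratio(self):
        bins = bins_frame([True] * 3)
        bins["cpg_m"] = [3, 6, 9]
        bins["cpg_n"] = 30
        bins[["cph_m", "cph_n"]] = [[1, 100], [3, 100], [2, 100]]
        st = genome_stats(bins)
        assert st.med_mg == pytest.approx(0.2)
        assert st.theta_u == pytest.approx(6 / 300)

    def test_identical_bins_raise_degenerate_error(self):
        bins = bins_frame([True] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            genome_stats(bins)

    def test_requires_two_detected_bins(self):
        bins = bins_frame([True, False, False])
        with pytest.raises(ValueError):
            genome_stats(bins)


def stats(theta_u=0.01, med_mg=0.5, sd_mg=0.2, sd_mh=0.02):
    return GenomeMethylationStats(theta_u, med_mg, sd_mg, sd_mh, n_detected=100)


class TestPriorMean:
    def test_at_median_both_states_equal_theta_u(self):
        st = stats()
        assert prior_mean(0.5, st, "P") == pytest.approx(0.01)
        assert prior_mean(0.5, st, "N") == pytest.approx(0.01)

    def test_one_sd_above_median_with_clamp(self):
        st = stats(theta_u=0.01, sd_mg=0.2, sd_mh=0.02)
        assert prior_mean(0.7, st, "P") == pytest.approx(0.03)
        # raw M_N = 0.01 - 0.02 = -0.01 -> clamped
        assert prior_mean(0.7, st, "N") == pytest.approx(1e-6)

    def test_sign_symmetry_below_median(self):
        st = stats()
        assert prior_mean(0.3, st, "P") < st.theta_u < prior_mean(0.3, st, "N")


class TestPosteriorTheta:
    def test_hand_computed_posterior_mean(self):
        # cph (3, 20), cpg_n 30, M 0.1 -> alpha 3, beta 27 -> 6/50
        assert posterior_theta(3, 20, 30, 0.1) == pytest.approx(0.12)

    def test_no_data_limit_is_pure_prior(self):
        assert posterior_theta(0, 0, 30, 0.1) == pytest.approx(0.1)

    def test_no_prior_limit_is_observed_ratio(self):
        assert posterior_theta(3, 20, 0, 0.1) == pytest.approx(3 / 20)


class TestEmissionMatrix:
    def make_bins_one(self, cph=(2, 10), cpg=(15, 30)):
        bins = bins_frame([True, True])
        bins[["cph_m", "cph_n"]] = [list(cph), [5, 100]]
        bins[["cpg_m", "cpg_n"]] = [list(cpg), [15, 30]]
        return bins

    def test_binomial_pmf_value(self):
        # force theta via a stats object: theta_hat for U is theta_u
        bins = self.make_bins_one()
        st = stats(theta_u=0.1)
        em = emission_matrix(bins, st)
        # Bin(2; 10, 0.1) = 45 * 0.01 * 0.9^8
        assert np.exp(em.log_e[0, U]) == pytest.approx(0.193710, abs=1e-6)

    def test_pmf_sums_to_one_over_outcomes(self):
        from scipy.stats import binom
        for n, theta in [(10, 0.1), (25, 0.01), (40, 0.5)]:
            total = np.exp(binom.logpmf(np.arange(n + 1), n, theta)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_state_nearest_observed_ratio_wins(self):
        bins = self.make_bins_one(cph=(1, 100), cpg=(27, 30))  # mG 0.9, high z
        st = stats(theta_u=0.05, sd_mh=0.04)
        em = emission_matrix(bins, st)
        # observed ratio 0.01 sits nearest theta_N -> N most likely
        assert em.theta[0, N] < em.theta[0, P]
        assert abs(em.theta[0, N] - 0.01) == min(
            abs(em.theta[0, s] - 0.01) for s in (P, N, U)
        )
        assert np.argmax(em.log_e[0]) == N

    def test_undetected_bins_are_uninformative(self):
        bins = bins_frame([True, True, False])
        bins.loc[0, "cph_m"] = 40
        em = emission_matrix(bins, stats())
        assert np.all(em.log_e[2] == 0.0)

    def test_alpha_beta_pseudocounts_sum_to_cpg_reads(self):
        bins = self.make_bins_one()
        em = emission_matrix(bins, stats())
        total = em.alpha[0] + em.beta[0]
        assert total == pytest.approx(bins["cpg_n"].iloc[0])


class TestSplitChains:
    def test_gap_longer_than_100kb_splits(self):
        detected = [True] * 10 + [False] * 600 + [True] * 10
        chains = split_chains(bins_frame(detected))
        assert chains == [(0, 10), (610, 620)]

    def test_90kb_gap_does_not_split(self):
        detected = [True] * 10 + [False] * 500 + [True] * 10
        chains = split_chains(bins_frame(detected))
        assert chains == [(0, 520)]

    def test_chromosomes_never_share_a_chain(self):
        b1 = bins_frame([True] * 5, chrom="chr1")
        b2 = bins_frame([True] * 5, chrom="chr2")
        bins = pd.concat([b1, b2], ignore_index=True)
        assert split_chains(bins) == [(0, 5), (5, 10)]

    def test_leading_and_trailing_undetected_trimmed(self):
        chains = split_chains(bins_frame([False, False, True, True, False]))
        assert chains == [(2, 4)]


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            T = int(rng.integers(1, 9))
            log_a, log_pi = random_model(rng)
            log_e = np.log(rng.dirichlet(np.ones(3), size=T))
            from cphmm._kernels import viterbi_log
            path, score = viterbi_log(log_a, log_pi, log_e)
            bf_path, bf_score = brute_force_viterbi(log_a, log_pi, log_e)
            assert score == pytest.approx(bf_score, abs=1e-9)
            assert np.array_equal(path, bf_path)

    def test_beats_random_paths(self):
        from cphmm._kernels import viterbi_log
        rng = np.random.default_rng(5)
        log_a, log_pi = random_model(rng)
        log_e = np.log(rng.dirichlet(np.ones(3), size=200))
        path, score = viterbi_log(log_a, log_pi, log_e)
        for _ in range(1000):
            alt = rng.integers(0, 3, size=200)
            alt_score = log_pi[alt[0]] + log_e[0, alt[0]] + sum(
                log_a[alt[t - 1], alt[t]] + log_e[t, alt[t]] for t in range(1, 200)
            )
            assert alt_score <= score + 1e-9

    def test_uniform_transitions_reduce_to_argmax(self):
        bins, _ = simulate_hmm_bins(np.eye(3) * 0.8 + 0.1, n_bins=300, seed=2)
        st = genome_stats(bins)
        em = emission_matrix(bins, st)
        from cphmm.segmentation import HmmModel
        uniform = HmmModel(STATES, np.full((3, 3), 1 / 3), np.full(3, 1 / 3))
        chains = split_chains(bins)
        v = viterbi_decode(chains, em, uniform)
        a = emission_argmax_states(em)
        in_chain = np.zeros(len(bins), dtype=bool)
        for i0, i1 in chains:
            in_chain[i0:i1] = True
        mask = in_chain & em.detected
        assert np.array_equal(v[mask], a[mask])

    def test_invariant_to_uniform_emission_rescaling(self):
        bins, _ = simulate_hmm_bins(np.eye(3) * 0.9 + 0.05, n_bins=200, seed=3)
        seg = HmmSegmenter().fit(bins)
        base = seg.predict(bins)
        shift = np.random.default_rng(0).normal(size=(len(bins), 1))
        from cphmm.segmentation import viterbi_decode as vd
        em = seg.emissions_
        em_shifted = type(em)(em.m_prior, em.alpha, em.beta, em.theta,
                              em.log_e + shift, em.detected)
        shifted = vd(seg.chains_, em_shifted, seg.model_)
        assert np.array_equal(base, shifted)


class TestEmissionArgmax:
    def test_argmax_and_tie_to_earlier_state(self):
        bins = bins_frame([True, True, False])
        em = emission_matrix(bins, stats())
        em.log_e[0] = np.log([0.2, 0.5, 0.3])
        em.log_e[1] = np.log([0.4, 0.4, 0.2])
        states = emission_argmax_states(em)
        assert states[0] == N
        assert states[1] == P          # exact tie -> P by state order
        assert states[2] == UNASSIGNED


class TestFitTransitions:
    def test_loglik_non_decreasing_and_rows_stochastic(self):
        bins, _ = simulate_hmm_bins(np.eye(3) * 0.9 + 0.05, n_bins=2000, seed=4)
        seg = HmmSegmenter().fit(bins)
        ll = [h["loglik"] for h in seg.em_history_]
        assert all(b >= a - 1e-6 for a, b in zip(ll, ll[1:]))
        assert np.allclose(seg.transition_.sum(axis=1), 1.0, atol=1e-12)
        assert seg.initial_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_terminates_by_tolerance(self):
        bins, _ = simulate_hmm_bins(np.eye(3) * 0.9 + 0.05, n_bins=2000, seed=4)
        seg = HmmSegmenter(tol=5e-4).fit(bins)
        assert seg.model_.converged
        assert seg.em_history_[-1]["delta"] < 5e-4

    def test_single_bin_chains_keep_initialization(self):
        log_e = [np.zeros((1, 3)), np.zeros((1, 3))]
        model = fit_transitions(log_e)
        assert np.allclose(model.transition, sticky_transition_init())

    def test_empty_chains_raise(self):
        with pytest.raises(ValueError):
            fit_transitions([])

    def test_recovers_known_transition_matrix(self):
        A = np.array([[0.98, 0.01, 0.01], [0.02, 0.96, 0.02], [0.05, 0.05, 0.90]])
        bins, _ = simulate_hmm_bins(A, n_bins=20_000, seed=11)
        seg = HmmSegmenter().fit(bins)
        assert np.abs(seg.transition_ - A).max() < 0.05


class TestLinking:
    def run(self, state_codes, detected=None):
        n = len(state_codes)
        bins = bins_frame([True] * n if detected is None else detected)
        states = np.array([{"P": P, "N": N, "U": U, ".": UNASSIGNED}[c]
                           for c in state_codes])
        return link_and_extract_dmrs(bins, states)

    def test_single_gap_bin_is_absorbed(self):
        segments, dmrs = self.run("NNPNN")
        n_segs = [s for s in segments if s.state == "N"]
        assert len(n_segs) == 1
        assert (n_segs[0].start, n_segs[0].end) == (0, 900)
        assert n_segs[0].n_gap_bins_absorbed == 1
        assert len(dmrs) == 1

    def test_three_bin_gap_is_not_linked(self):
        segments, dmrs = self.run("NNPPPNN")
        assert len(dmrs) == 2
        assert [(d.start, d.end) for d in dmrs] == [(0, 360), (900, 1260)]

    def test_all_p_gives_no_dmrs(self):
        _, dmrs = self.run("PPPPP")
        assert dmrs == []

    def test_two_bin_gap_links_and_unassigned_counts_as_gap(self):
        _, dmrs = self.run("NN..NN")
        assert [(d.start, d.end) for d in dmrs] == [(0, 1080)]

    def test_segments_do_not_overlap(self):
        segments, _ = self.run("PPNPPNNUPN")
        by_chrom = {}
        for s in segments:
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _)
                       in zip(spans, spans[1:]))


class TestEndToEnd:
    def test_viterbi_improves_on_emission_argmax_when_separated(self):
        """With informative emissions the full HMM dominates the per-bin
        argmax on accuracy, precision and recall of N detection."""
        from cphmm.simulate import (SimulationConfig, evaluate_precision_recall,
                                    run_single_benchmark)
        cfg = SimulationConfig(
            genome_length=2000 * 180, n_regions=5, region_len_range=(20, 40),
            mean_depth=60, cpg_per_bin_mean=10, cph_per_bin_mean=40,
            seed=5, add_noise=False,
        )
        res = run_single_benchmark(cfg)
        e, v = res["emission_only"], res["viterbi"]
        assert v.precision >= e.precision
        assert v.recall >= e.recall
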