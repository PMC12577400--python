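"""Bernoulli-HMM learning/decoding and chromatin-state coverage profiling."""

import itertools
import math

import numpy as np
import pytest

from coopreg.chromatin import (
    BinarizedTracks,
    ChromatinStateModel,
    Segmentation,
    binarize,
    decode,
    fit_hmm,
    group_states,
    match_states,
    poisson_threshold,
    posterior_marginals,
    state_coverage,
)
from coopreg.genome import Genome, GenomicInterval, SignalTrack
from coopreg.simulate import default_state_model, simulate_marks


# ---------------------------------------------------------------------------
# binarization


def poisson_tail_by_summation(mu: float, k: int) -> float:
    """P(X >= k) by direct summation of the Poisson pmf (independent oracle)."""
    total = 0.0
    for i in range(k):
        total += math.exp(-mu) * mu**i / math.factorial(i)
    return 1.0 - total


def test_poisson_threshold_matches_direct_tail_summation():
    for mu in (0.5, 1.0, 10.0):
        k = poisson_threshold(mu, 1e-4)
        assert poisson_tail_by_summation(mu, k) < 1e-4
        assert poisson_tail_by_summation(mu, k - 1) >= 1e-4


def test_binarize_constant_track_at_mean_is_zero():
    track = SignalTrack({"chr1": np.full(100, 10.0)}, bin_size=200)
    assert not binarize(track, 1e-4)["chr1"].any()


def test_binarize_mean_one_uses_tabulated_tail_threshold():
    # mean rate 1.0: smallest k with P(X>=k) < 1e-4 is 7 (tail at 6 is 5.9e-4)
    k = poisson_threshold(1.0, 1e-4)
    assert k == 7
    values = np.ones(1000)
    values[:10] = [4, 5, 5, 6, 6, 7, 8, 9, 10, 3]
    values[10] = 0.0  # keep mean at ~1
    track = SignalTrack({"chr1": values}, bin_size=200)
    mu = values.mean()
    expected = values >= poisson_threshold(mu, 1e-4)
    np.testing.assert_array_equal(binarize(track, 1e-4)["chr1"].astype(bool), expected)


def test_binarize_degenerate_threshold_flags_everything():
    track = SignalTrack({"chr1": np.arange(10, dtype=float)}, bin_size=200)
    assert binarize(track, 1.0)["chr1"].all()


def test_binarize_all_zero_track_warns_and_returns_zeros(caplog):
    track = SignalTrack({"chr1": np.zeros(50)}, bin_size=200)
    with caplog.at_level("WARNING"):
        out = binarize(track)
    assert not out["chr1"].any()
    assert any("all-zero" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# EM fitting


def test_fit_hmm_k1_closed_form():
    rng = np.random.default_rng(0)
    data = (rng.random((500, 2)) < [0.3, 0.7]).astype(np.uint8)
    tracks = BinarizedTracks(["m1", "m2"], {"chr1": data})
    model = fit_hmm(tracks, K=1, seed=0)
    np.testing.assert_allclose(model.emission[0], data.mean(axis=0), atol=1e-9)
    np.testing.assert_allclose(model.transition, [[1.0]])


def test_em_log_likelihood_monotone_nondecreasing():
    genome = Genome({"chr1": 100_000})
    truth = default_state_model(K=3, M=2)
    tracks, _ = simulate_marks(truth, genome, seed=5)
    model = fit_hmm(tracks, K=3, seed=1, max_iter=40)
    ll = np.array(model.log_likelihood_history)
    assert len(ll) > 2
    assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()


def test_fit_hmm_recovers_planted_two_state_model():
    genome = Genome({"chr1": 300_000})
    truth = default_state_model(K=2, M=2)
    tracks, _ = simulate_marks(truth, genome, seed=11)
    model = fit_hmm(tracks, K=2, seed=3)
    perm = match_states(truth.emission, model.emission)
    assert np.abs(model.emission[perm] - truth.emission).max() < 0.05
    assert np.abs(model.transition[np.ix_(perm, perm)] - truth.transition).max() < 0.1


def test_fit_hmm_warns_when_states_exceed_mark_combinations(caplog):
    data = np.zeros((50, 1), dtype=np.uint8)
    data[::2] = 1
    tracks = BinarizedTracks(["m"], {"chr1": data})
    with caplog.at_level("WARNING"):
        fit_hmm(tracks, K=4, seed=0, max_iter=5)
    assert any("collapse" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# decoding


def brute_force_posteriors(model: ChromatinStateModel, x: np.ndarray) -> np.ndarray:
    """Exact per-bin marginals by enumerating every state path (tiny n only)."""
    n, k = len(x), model.n_states
    post = np.zeros((n, k))
    for path in itertools.product(range(k), repeat=n):
        p = model.initial[path[0]]
        for t in range(1, n):
            p *= model.transition[path[t - 1], path[t]]
        for t, s in enumerate(path):
            for m in range(model.n_marks):
                e = model.emission[s, m]
                p *= e if x[t, m] else 1 - e
        for t, s in enumerate(path):
            post[t, s] += p
    return post / post.sum(axis=1, keepdims=True)


def test_posterior_marginals_match_path_enumeration():
    model = default_state_model(K=3, M=2, self_transition=0.8)
    rng = np.random.default_rng(7)
    x = (rng.random((8, 2)) < 0.5).astype(np.uint8)
    expected = brute_force_posteriors(model, x)
    np.testing.assert_allclose(posterior_marginals(model, x), expected, atol=1e-9)


def test_posterior_marginals_match_hmmlearn_categorical():
    hmm = pytest.importorskip("hmmlearn.hmm")
    model = default_state_model(K=3, M=2, self_transition=0.85)
    rng = np.random.default_rng(19)
    x = (rng.random((200, 2)) < 0.5).astype(np.uint8)
    # map the 2-mark alphabet onto 4 categorical symbols with product-Bernoulli
    # emission probabilities; posteriors must agree with our forward-backward
    combos = np.array(list(itertools.product((0, 1), repeat=2)))
    emission_cat = np.ones((3, 4))
    for ci, combo in enumerate(combos):
        for m, bit in enumerate(combo):
            e = model.emission[:, m]
            emission_cat[:, ci] *= np.where(bit, e, 1 - e)
    ref = hmm.CategoricalHMM(n_components=3, init_params="")
    ref.startprob_ = model.initial
    ref.transmat_ = model.transition
    ref.emissionprob_ = emission_cat
    symbols = (x[:, 0] * 2 + x[:, 1]).reshape(-1, 1)
    expected = ref.predict_proba(symbols)
    np.testing.assert_allclose(posterior_marginals(model, x), expected, atol=1e-8)


def test_posterior_rows_sum_to_one():
    model = default_state_model(K=4, M=3)
    rng = np.random.default_rng(2)
    x = (rng.random((300, 3)) < 0.4).astype(np.uint8)
    gamma = posterior_marginals(model, x)
    np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


def test_decode_recovers_planted_states_with_sharp_emissions():
    genome = Genome({"chr1": 200_000})
    truth = default_state_model(K=3, M=3)
    truth.emission = np.clip(truth.emission, 0.01, 0.99)
    truth.emission[truth.emission > 0.5] = 0.99
    truth.emission[truth.emission < 0.5] = 0.01
    tracks, true_seg = simulate_marks(truth, genome, seed=21)
    seg = decode(truth, tracks, genome=genome)
    total = correct = 0
    true_states = np.concatenate(
        [np.repeat([r[2] for r in true_seg.runs["chr1"]],
                   [(r[1] - r[0] + 199) // 200 for r in true_seg.runs["chr1"]])]
    )
    dec_states = np.concatenate(
        [np.repeat([r[2] for r in seg.runs["chr1"]],
                   [(r[1] - r[0] + 199) // 200 for r in seg.runs["chr1"]])]
    )
    accuracy = (true_states == dec_states).mean()
    assert accuracy >= 0.99


def test_decode_single_bin_chromosome_yields_one_run():
    model = default_state_model(K=2, M=1)
    tracks = BinarizedTracks(["mark1"], {"tiny": np.array([[1]], dtype=np.uint8)}, bin_size=200)
    genome = Genome({"tiny": 150})
    seg = decode(model, tracks, genome=genome)
    assert seg.runs["tiny"] == [(0, 150, seg.runs["tiny"][0][2])]


def test_decode_rejects_mark_mismatch():
    model = default_state_model(K=2, M=2)
    tracks = BinarizedTracks(["other"], {"chr1": np.zeros((5, 1), dtype=np.uint8)})
    with pytest.raises(ValueError, match="marks"):
        decode(model, tracks)


# ---------------------------------------------------------------------------
# coverage profiling


def per_base_coverage(peaks, seg):
    """Per-bp brute force: label every base of every peak by its state."""
    counts: dict[str, int] = {s: 0 for s in seg.state_labels}
    total = 0
    for p in peaks:
        for pos in range(p.start, p.end):
            for s, e, label in seg.runs[p.chrom]:
                if s <= pos < e:
                    counts[label] += 1
                    break
        total += len(p)
    return {k: v / total for k, v in counts.items()}, total


def test_state_coverage_split_peak_example():
    seg = Segmentation({"chr1": [(0, 50, "E1"), (50, 1000, "E2")]}, ["E1", "E2"])
    prof = state_coverage([GenomicInterval("chr1", 0, 100)], seg)
    assert prof.fractions == {"E1": 0.5, "E2": 0.5}
    assert prof.total_peak_bp == 100


def test_state_coverage_single_state_segmentation():
    seg = Segmentation({"chr1": [(0, 1000, "E1")]}, ["E1", "E2"])
    prof = state_coverage([GenomicInterval("chr1", 10, 60)], seg)
    assert prof.fractions == {"E1": 1.0, "E2": 0.0}


def test_state_coverage_empty_peaks_is_error():
    seg = Segmentation({"chr1": [(0, 1000, "E1")]}, ["E1"])
    with pytest.raises(ValueError, match="no peak bp"):
        state_coverage([], seg)


def test_state_coverage_matches_per_base_bruteforce(rng):
    labels = [f"E{i + 1}" for i in range(5)]
    for _ in range(10):
        bounds = np.sort(rng.choice(np.arange(200, 5000, 200), size=8, replace=False))
        bounds = [0, *bounds.tolist(), 5000]
        runs = [
            (bounds[i], bounds[i + 1], labels[rng.integers(5)])
            for i in range(len(bounds) - 1)
        ]
        seg = Segmentation({"chr1": runs}, labels)
        peaks = [
            GenomicInterval("chr1", s, s + int(rng.integers(1, 400)))
            for s in rng.integers(0, 4500, size=100)
        ]
        prof = state_coverage(peaks, seg)
        brute, total = per_base_coverage(peaks, seg)
        assert prof.total_peak_bp == total
        assert abs(sum(prof.fractions.values()) - 1.0) < 1e-9
        for label in labels:
            assert abs(prof.fractions[label] - brute[label]) < 1e-12


def test_whole_genome_peak_set_reproduces_genome_fraction():
    seg = Segmentation(
        {"chr1": [(0, 600, "E1"), (600, 1000, "E2")],
         "chr2": [(0, 500, "E2")]},
        ["E1", "E2"],
    )
    peaks = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr2", 0, 500)]
    prof = state_coverage(peaks, seg)
    assert prof.fractions == prof.genome_fraction


def test_segmentation_rejects_gaps_and_overlaps():
    with pytest.raises(ValueError):
        Segmentation({"chr1": [(0, 100, "E1"), (150, 200, "E2")]}, ["E1", "E2"])
    with pytest.raises(ValueError):
        Segmentation({"chr1": [(0, 100, "E1"), (50, 200, "E2")]}, ["E1", "E2"])


def test_group_states_sums_and_errors():
    seg = Segmentation({"chr1": [(0, 400, "E1"), (400, 700, "E2"), (700, 1000, "E3")]},
                       ["E1", "E2", "E3"])
    prof = state_coverage([GenomicInterval("chr1", 0, 1000)], seg)
    grouped = group_states(prof, {"E1": "promoter", "E2": "promoter", "E3": "enhancer"})
    assert grouped.fractions == pytest.approx({"promoter": 0.7, "enhancer": 0.3})
    assert sum(grouped.fractions.values()) == pytest.approx(sum(prof.fractions.values()))
    identity = group_states(prof, {s: s for s in prof.fractions})
    assert identity.fractions == pytest.approx(prof.fractions)
    with pytest.raises(ValueError, match="E3"):
        group_states(prof, {"E1": "promoter", "E2": "promoter"})
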