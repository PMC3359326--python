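"""Unit and property tests for the Dirichlet-multinomial observer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lookaway as lk
from lookaway.observer import TransitionPosterior


@pytest.mark.parametrize(
    "alphabet,counts,alpha,expected",
    [
        (lk.EXP1_ALPHABET, (0, 0), 1.0, (0.5, 0.5)),
        (lk.EXP2_ALPHABET, (0, 0, 0), 1.0, (1 / 3, 1 / 3, 1 / 3)),
        (lk.EXP1_ALPHABET, (4, 0), 1.0, (5 / 6, 1 / 6)),
        (lk.EXP1_ALPHABET, (2, 1), 0.5, (2.5 / 4, 1.5 / 4)),
    ],
)
def test_posterior_predictive_closed_form(alphabet, counts, alpha, expected):
    state = lk.PosteriorState(alphabet, counts=counts, alpha=alpha)
    np.testing.assert_allclose(lk.posterior_predictive(state), expected, rtol=1e-12)


@pytest.mark.parametrize(
    "counts,symbol,expected_bits",
    [
        ((4, 0), "present", -math.log2(5 / 6)),
        ((4, 0), "absent", math.log2(6)),
        ((0, 0), "present", 1.0),
        ((0, 0), "absent", 1.0),
    ],
)
def test_surprisal_examples(counts, symbol, expected_bits):
    state = lk.PosteriorState(lk.EXP1_ALPHABET, counts=counts)
    assert lk.surprisal(state, symbol) == pytest.approx(expected_bits, abs=1e-12)


def test_surprisal_natural_log_base():
    state = lk.PosteriorState(lk.EXP1_ALPHABET)
    assert lk.surprisal(state, "present", log_base=math.e) == pytest.approx(math.log(2))


def test_update_counts_and_exchangeability():
    state = lk.PosteriorState(lk.EXP1_ALPHABET)
    for _ in range(4):
        state = lk.update(state, "present")
    assert state.counts == (4, 0)
    batch = lk.PosteriorState(lk.EXP1_ALPHABET, counts=(4, 0))
    np.testing.assert_allclose(
        lk.posterior_predictive(state), lk.posterior_predictive(batch)
    )


def test_unknown_symbol_raises():
    state = lk.PosteriorState(lk.EXP1_ALPHABET)
    with pytest.raises(KeyError):
        lk.surprisal(state, "banana")
    with pytest.raises(KeyError):
        lk.update(state, "banana")


@pytest.mark.parametrize("bad_alpha", [0.0, -1.0])
def test_nonpositive_prior_strength_rejected(bad_alpha):
    with pytest.raises(ValueError):
        lk.PosteriorState(lk.EXP1_ALPHABET, alpha=bad_alpha)


def test_posterior_entropy_closed_form():
    # uniform density on the simplex has zero differential entropy
    assert lk.posterior_entropy(lk.PosteriorState(lk.EXP1_ALPHABET)) == pytest.approx(0.0)
    # Beta(2,1): ln B(2,1) + (3-2) psi(3) - (2-1) psi(2)
    from scipy.special import psi

    state = lk.PosteriorState(lk.EXP1_ALPHABET, counts=(1, 0))
    expected = math.log(0.5) + psi(3) - psi(2)
    assert lk.posterior_entropy(state) == pytest.approx(expected, abs=1e-12)


def test_posterior_entropy_monte_carlo_oracle(rng):
    """Differential entropy of Beta(2,1) estimated by Monte Carlo."""
    x = rng.beta(2, 1, size=400_000)
    mc = -np.mean(np.log(2 * x))  # density of Beta(2,1) is 2x
    state = lk.PosteriorState(lk.EXP1_ALPHABET, counts=(1, 0))
    assert lk.posterior_entropy(state) == pytest.approx(mc, abs=5e-3)


def test_entropy_strictly_decreases_with_consistent_evidence():
    state = lk.PosteriorState(lk.EXP1_ALPHABET)
    ents = [lk.posterior_entropy(state)]
    for _ in range(30):
        state = lk.update(state, "present")
        ents.append(lk.posterior_entropy(state))
    assert all(b < a for a, b in zip(ents, ents[1:]))


def test_sequence_complexity_all_same_symbol():
    trace = lk.sequence_complexity(["present"] * 5, lk.EXP1_ALPHABET)
    expected = [1.0] + [-math.log2(k / (k + 1)) for k in (2, 3, 4, 5)]
    np.testing.assert_allclose(trace.surprisal_bits, expected, atol=1e-12)
    assert np.all(np.diff(trace.surprisal_bits) < 0)


def test_sequence_complexity_examples():
    trace = lk.sequence_complexity(["present", "present", "absent"], lk.EXP1_ALPHABET)
    assert trace.surprisal_bits[2] == pytest.approx(2.0)  # predictive prob 1/4
    single = lk.sequence_complexity(["absent"], lk.EXP1_ALPHABET)
    assert single.surprisal_bits[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        lk.sequence_complexity([], lk.EXP1_ALPHABET)


def test_trace_internal_consistency():
    trace = lk.sequence_complexity(["A", "B", "A", "C", "C"], lk.EXP2_ALPHABET,
                                   mode="transitional")
    np.testing.assert_allclose(
        trace.surprisal_bits, -np.log2(trace.predictive_prob), atol=1e-12
    )
    assert len(trace) == 5
    assert list(trace.positions) == [1, 2, 3, 4, 5]


def test_transitional_first_event_scored_by_prior():
    trace = lk.sequence_complexity(["A", "A", "A"], lk.EXP2_ALPHABET, mode="transitional")
    assert trace.surprisal_bits[0] == pytest.approx(math.log2(3))
    # second event: transition row for A is still empty -> prior again
    assert trace.surprisal_bits[1] == pytest.approx(math.log2(3))
    # third event: one A->A transition observed
    assert trace.surprisal_bits[2] == pytest.approx(-math.log2(2 / 4))


def test_conditioning_blind_transitional_collapses_to_marginal():
    """A single shared transition row reproduces the marginal observer
    applied to the transition targets (events 2..n)."""
    seq = ["A", "B", "A", "C", "B", "B", "A"]
    tp = TransitionPosterior(lk.EXP2_ALPHABET, conditioning_blind=True)
    blind = []
    for sym in seq:
        if tp.previous_event is not None:
            blind.append(lk.surprisal(tp.row(tp.previous_event), sym))
        tp.observe(sym)
    marginal_on_targets = lk.sequence_complexity(seq[1:], lk.EXP2_ALPHABET, mode="marginal")
    np.testing.assert_allclose(blind, marginal_on_targets.surprisal_bits, atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    counts=st.lists(st.integers(0, 40), min_size=2, max_size=5),
    alpha=st.floats(0.05, 10.0),
)
def test_predictive_is_a_distribution(counts, alpha):
    alphabet = lk.EventAlphabet(tuple(f"s{i}" for i in range(len(counts))))
    state = lk.PosteriorState(alphabet, counts=tuple(counts), alpha=alpha)
    p = lk.posterior_predictive(state)
    assert abs(p.sum() - 1) < 1e-12
    assert np.all(p > 0) and np.all(p < 1)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.sampled_from("ABC"), min_size=1, max_size=15))
def test_relabeling_equivariance(seq):
    """Surprisal traces are invariant under a permutation of symbol labels."""
    perm = {"A": "B", "B": "C", "C": "A"}
    base = lk.sequence_complexity(seq, lk.EXP2_ALPHABET)
    relabeled = lk.sequence_complexity([perm[s] for s in seq], lk.EXP2_ALPHABET)
    np.testing.assert_allclose(base.surprisal_bits, relabeled.surprisal_bits, atol=1e-12)


def test_repeated_symbol_surprisal_monotone_30_events():
    state = lk.PosteriorState(lk.EXP2_ALPHABET)
    seen, unseen = [], []
    for _ in range(30):
        seen.append(lk.surprisal(state, "A"))
        unseen.append(lk.surprisal(state, "B"))
        state = lk.update(state, "A")
    assert all(b < a for a, b in zip(seen, seen[1:]))
    assert all(b > a for a, b in zip(unseen, unseen[1:]))
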