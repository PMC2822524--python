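"""Forward/backward/posterior DP checked against exhaustive path
enumeration, plus the row-wise restart and local Viterbi contracts."""

import numpy as np
import pytest

from _oracle import OracleResult
from conftest import random_dna, random_model

from profhmm.dp_engine import (
    RowBatch,
    Sequence,
    backward,
    forward,
    forward_rows,
    posterior_states,
    viterbi_local,
)
from profhmm.profile_model import DNA, build_plan7


def _deterministic_one_position():
    """Begin->M1 = 1, M1 emits A with prob 1, M1->End = 1."""
    m = build_plan7(1, DNA, local_mode=False)
    m.begin = np.array([1.0, 0.0, 0.0])
    m.match_emissions[0] = [1.0, 0.0, 0.0, 0.0]
    m.tmm[0], m.tmi[0], m.tmd[0] = 1.0, 0.0, 0.0
    return m


def test_single_path_likelihood_is_product_of_probabilities():
    m = _deterministic_one_position()
    assert forward(m, Sequence("s", "A")).log_likelihood == pytest.approx(0.0)
    m.match_emissions[0] = [0.5, 0.5, 0.0, 0.0]
    ll = forward(m, Sequence("s", "A")).log_likelihood
    assert ll == pytest.approx(np.log(0.5))


def test_backward_matches_forward_likelihood_on_deterministic_model():
    m = _deterministic_one_position()
    assert backward(m, Sequence("s", "A")).log_likelihood == pytest.approx(0.0)


@pytest.mark.parametrize("local", [False, True])
def test_forward_matches_enumeration_on_2_position_model(rng, local):
    m = random_model(rng, 2, local=local)
    oracle = OracleResult(m, "AC")
    got = forward(m, Sequence("s", "AC")).log_likelihood
    assert got == pytest.approx(np.log(oracle.likelihood), rel=1e-12)


def test_oracle_equivalence_randomized_suite(rng):
    """Forward, backward, posterior and the forward-backward identity all
    agree with exhaustive path enumeration on >= 200 random instances
    (models up to 3 positions, sequences up to 4 residues, both modes)."""
    checked = 0
    for case in range(200):
        n = int(rng.integers(1, 4))
        K = int(rng.integers(0, 5))
        local = bool(rng.integers(0, 2))
        m = random_model(rng, n, local=local)
        resid = random_dna(rng, K)
        oracle = OracleResult(m, resid)
        seq = Sequence(f"case{case}", resid)
        fwd = forward(m, seq)
        bwd = backward(m, seq)
        assert np.exp(fwd.log_likelihood) == pytest.approx(
            oracle.likelihood, rel=1e-10)
        assert np.exp(bwd.log_likelihood) == pytest.approx(
            oracle.likelihood, rel=1e-10)
        if K > 0 and oracle.likelihood > 0:
            pM, pI, pD = posterior_states(m, seq, fwd, bwd)
            np.testing.assert_allclose(pM[1:], oracle.post_M[1:],
                                       rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(pI[1:], oracle.post_I[1:],
                                       rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(pD, oracle.visit_D,
                                       rtol=1e-10, atol=1e-12)
            # emitting-state posteriors sum to 1 at every emitted residue
            np.testing.assert_allclose((pM + pI)[1:].sum(axis=1), 1.0,
                                       rtol=1e-10)
        checked += 1
    assert checked == 200


def test_forward_backward_identity_every_column(rng):
    """Sum over emitting states of alpha*beta equals the likelihood at
    every emitted-residue column (the forward-backward identity)."""
    for _ in range(20):
        n = int(rng.integers(1, 4))
        m = random_model(rng, n, local=bool(rng.integers(0, 2)))
        seq = Sequence("s", random_dna(rng, int(rng.integers(1, 5))))
        fwd, bwd = forward(m, seq), backward(m, seq)
        lhat = np.exp(fwd.log_likelihood + fwd.log_scale)
        per_col = (fwd.M * bwd.M + fwd.I * bwd.I).sum(axis=1)
        np.testing.assert_allclose(per_col[1:], lhat, rtol=1e-10)


def test_forward_rows_restart_equals_full_pass(rng):
    """Recomputing rows from any position reproduces the full forward
    pass; recomputing with no parameter change is bitwise identical."""
    m = random_model(rng, 5, local=True)
    seq = Sequence("s", random_dna(rng, 8))
    fwd = forward(m, seq)
    again = forward_rows(m, seq, fwd, from_position=1)
    assert again.log_likelihood == fwd.log_likelihood
    np.testing.assert_array_equal(again.M, fwd.M)

    restart = forward_rows(m, seq, fwd, from_position=3)
    np.testing.assert_array_equal(restart.M, fwd.M)
    np.testing.assert_array_equal(restart.I, fwd.I)
    np.testing.assert_array_equal(restart.D, fwd.D)


def test_forward_rows_after_local_parameter_change(rng):
    """Perturbing position p's parameters and recomputing rows from p
    equals a from-scratch forward pass on the perturbed model."""
    m = random_model(rng, 5, local=False)
    seq = Sequence("s", random_dna(rng, 7))
    fwd = forward(m, seq)
    m2 = m.copy()
    m2.match_emissions[2] = np.array([0.4, 0.3, 0.2, 0.1])
    m2.tmm[2], m2.tmi[2], m2.tmd[2] = 0.8, 0.1, 0.1
    scratch = forward(m2, seq)
    incremental = forward_rows(m2, seq, fwd, from_position=3)
    assert incremental.log_likelihood == pytest.approx(
        scratch.log_likelihood, abs=1e-12)
    np.testing.assert_allclose(incremental.M, scratch.M, rtol=1e-12)


def test_forward_rows_bad_position_raises(rng):
    m = random_model(rng, 3)
    seq = Sequence("s", "ACG")
    fwd = forward(m, seq)
    with pytest.raises(ValueError):
        forward_rows(m, seq, fwd, from_position=7)


def test_row_major_batch_equals_per_sequence(rng):
    """The batch engine (row-major fill) and the per-sequence API agree
    on likelihoods for mixed-length inputs."""
    m = random_model(rng, 4, local=True)
    seqs = [Sequence(f"s{i}", random_dna(rng, int(rng.integers(1, 9))))
            for i in range(6)]
    rb = RowBatch(m, seqs)
    rb.forward_fill()
    lls = rb.log_likelihoods()
    for s, ll in zip(seqs, lls):
        assert ll == pytest.approx(forward(m, s).log_likelihood, abs=1e-10)
    rb.backward_fill()
    np.testing.assert_allclose(rb.backward_likelihoods(), rb.likelihoods(),
                               rtol=1e-10)


def test_residue_outside_alphabet_names_position():
    m = build_plan7(2, DNA)
    with pytest.raises(ValueError, match="position 3"):
        forward(m, Sequence("s", "ACXA"))


def test_ambiguous_n_is_neutral(rng):
    """'N' emits with probability 1 from every emitting state, so the
    likelihood of 'ANC' equals summing over the middle residue with the
    background factored out consistently (checked against enumeration)."""
    m = random_model(rng, 2)
    oracle = OracleResult(m, "ANC")
    got = forward(m, Sequence("s", "ANC")).log_likelihood
    assert np.exp(got) == pytest.approx(oracle.likelihood, rel=1e-10)


# -- local Viterbi ---------------------------------------------------------


def _consensus_local_model(consensus: str, match=0.91):
    n = len(consensus)
    m = build_plan7(n, DNA, local_mode=True)
    for p, c in enumerate(consensus):
        e = np.full(4, (1 - match) / 3)
        e[DNA.index(c)] = match
        m.match_emissions[p] = e
    # trained-looking core transitions: mostly advance, rare early exit
    m.tmm[:], m.tmi[:], m.tmd[:], m.tmo[:] = 0.95, 0.02, 0.02, 0.01
    m.begin = np.array([0.5, 0.01, 0.49])
    m.z_cont, m.z_exit = 0.9, 0.1
    m.o_cont, m.o_exit = 0.9, 0.1
    return m


def test_viterbi_finds_embedded_consensus(rng):
    consensus = random_dna(rng, 30)
    m = _consensus_local_model(consensus)
    left = random_dna(rng, 57)
    right = random_dna(rng, 41)
    target = left + consensus + right
    hit = viterbi_local(m, Sequence("t", target))
    assert not hit.empty
    assert abs(hit.start - (len(left) + 1)) <= 2
    assert abs(hit.end - (len(left) + len(consensus))) <= 2
    assert hit.score > 10


def test_viterbi_score_beats_hand_constructed_path(rng):
    consensus = random_dna(rng, 12)
    m = _consensus_local_model(consensus)
    hit = viterbi_local(m, Sequence("t", consensus))
    # the all-match path through the full model is legal, so the optimum
    # must score at least as well
    hand = float(np.log(m.begin[0]))
    for p, c in enumerate(consensus):
        hand += np.log(m.match_emissions[p, DNA.index(c)] / 0.25)
        hand += np.log(m.tmm[p]) if p < len(consensus) - 1 else 0.0
    hand += np.log(m.tmm[-1] + m.tmd[-1] + m.tmo[-1])
    assert hit.score >= hand - 1e-9


def test_viterbi_empty_sequence_gives_empty_hit(rng):
    m = _consensus_local_model("ACGT")
    hit = viterbi_local(m, Sequence("t", ""))
    assert hit.empty


def test_viterbi_requires_local_mode(rng):
    m = random_model(rng, 3, local=False)
    with pytest.raises(ValueError):
        viterbi_local(m, Sequence("t", "ACGT"))
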