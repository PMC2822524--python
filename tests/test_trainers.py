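"""Expected counts against the path-enumeration oracle; M-step
arithmetic, flooring, convergence distance; EM/ECM monotonicity and
fixed-point behaviour of the training loops."""

import numpy as np
import pytest

from _oracle import OracleResult
from conftest import random_dna, random_model

from profhmm.dp_engine import RowBatch, Sequence, forward
from profhmm.profile_model import DNA, build_plan7, free_parameter_groups
from profhmm.trainers import (
    DegenerateUpdateError,
    Priors,
    TrainingConfig,
    bw_train,
    cbw_train,
    convergence_distance,
    expected_counts,
    floor_distribution,
    log_posterior,
    maximize,
)

LABELS = ["tmm", "tmi", "tmd", "tmo", "tim", "tii", "tdm", "tdd"]


def _oracle_counts(model, residues_list):
    """Aggregate oracle expected usages over a sequence set."""
    agg = {}
    for resid in residues_list:
        o = OracleResult(model, resid)
        for k, v in o.usage.items():
            agg[k] = agg.get(k, 0.0) + v
    return agg


def test_expected_counts_match_enumeration(rng):
    """Every expected count (emissions, all transitions, Begin and both
    flanking chains) equals the brute-force path-enumeration value."""
    for trial in range(12):
        n = int(rng.integers(1, 4))
        local = bool(rng.integers(0, 2))
        m = random_model(rng, n, local=local)
        seqs = [random_dna(rng, int(rng.integers(1, 5))) for _ in range(3)]
        counts = expected_counts(m, [Sequence(f"s{i}", r)
                                     for i, r in enumerate(seqs)])
        oracle = _oracle_counts(m, seqs)
        for p in range(n):
            for lab in LABELS:
                got = getattr(counts, lab[1:])[p]
                assert got == pytest.approx(oracle.get((lab, p), 0.0),
                                            rel=1e-9, abs=1e-12), (lab, p)
            for a in range(4):
                assert counts.match[p, a] == pytest.approx(
                    oracle.get(("em", p, a), 0.0), rel=1e-9, abs=1e-12)
        for a in range(4):
            assert counts.insert[a] == pytest.approx(
                oracle.get(("iem", a), 0.0), rel=1e-9, abs=1e-12)
        assert counts.begin[0] == pytest.approx(
            oracle.get("b_m", 0.0), rel=1e-9, abs=1e-12)
        assert counts.begin[1] == pytest.approx(
            oracle.get("b_d", 0.0), rel=1e-9, abs=1e-12)
        assert counts.begin[2] == pytest.approx(
            oracle.get("b_z", 0.0), rel=1e-9, abs=1e-12)
        assert counts.z[0] == pytest.approx(
            oracle.get("z_cont", 0.0), rel=1e-9, abs=1e-12)
        assert counts.z[1] == pytest.approx(
            oracle.get("z_exit", 0.0), rel=1e-9, abs=1e-12)
        assert counts.o[0] == pytest.approx(
            oracle.get("o_cont", 0.0), rel=1e-9, abs=1e-12)
        assert counts.o[1] == pytest.approx(
            oracle.get("o_exit", 0.0), rel=1e-9, abs=1e-12)


def test_per_sequence_counts_sum_to_aggregate(rng):
    m = random_model(rng, 3)
    seqs = [Sequence(f"s{i}", random_dna(rng, 5)) for i in range(4)]
    counts = expected_counts(m, seqs)
    # insertion visits = entries (M->I) plus self-loops (I->I)
    np.testing.assert_allclose(counts.per_seq_ins.sum(axis=0),
                               counts.mi + counts.ii, rtol=1e-9, atol=1e-12)
    singles = [expected_counts(m, [s]) for s in seqs]
    np.testing.assert_allclose(
        counts.per_seq_del.sum(axis=0),
        sum(c.per_seq_del[0] for c in singles), rtol=1e-9)


def test_deterministic_single_path_counts():
    """One sequence through an (almost) deterministic 2-position model
    gives unit match-emission counts along the path."""
    m = build_plan7(2, DNA)
    m.begin = np.array([1.0, 0.0, 0.0])
    m.match_emissions[0] = [1.0, 0.0, 0.0, 0.0]
    m.match_emissions[1] = [1.0, 0.0, 0.0, 0.0]
    m.tmm[:], m.tmi[:], m.tmd[:] = 1.0, 0.0, 0.0
    counts = expected_counts(m, [Sequence("s", "AA")])
    assert counts.match[0, 0] == pytest.approx(1.0)
    assert counts.match[1, 0] == pytest.approx(1.0)
    assert counts.mm[0] == pytest.approx(1.0)


# -- M-step ----------------------------------------------------------------


def test_maximize_add_one_arithmetic(rng):
    """Counts {A:3, C:1, G:0, T:0} with add-one pseudocounts give
    (4/8, 2/8, 1/8, 1/8)."""
    m = build_plan7(1, DNA)
    counts = expected_counts(m, [Sequence("s", "A")])
    counts.match[0] = [3.0, 1.0, 0.0, 0.0]
    new = maximize(m, counts, Priors.laplace(), floor=0.0)
    np.testing.assert_allclose(new.match_emissions[0],
                               [0.5, 0.25, 0.125, 0.125])


def test_maximize_zero_counts_uniform_pseudocounts(rng):
    m = build_plan7(1, DNA)
    counts = expected_counts(m, [Sequence("s", "A")])
    counts.match[0] = [0.0, 0.0, 0.0, 0.0]
    new = maximize(m, counts, Priors.laplace(), floor=0.0)
    np.testing.assert_allclose(new.match_emissions[0], [0.25] * 4)


def test_floor_distribution_enforced_and_proper():
    p = floor_distribution(np.array([1.0, 1e-9, 1e-12, 2.0]), 1e-5)
    assert p.sum() == pytest.approx(1.0)
    assert (p >= 1e-5 - 1e-15).all()
    with pytest.raises(DegenerateUpdateError):
        floor_distribution(np.zeros(4), 1e-5)


def test_floor_property_random_groups(rng):
    for _ in range(50):
        size = int(rng.integers(2, 6))
        raw = rng.gamma(0.1, size=size)
        p = floor_distribution(raw, 1e-5)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 1e-5 - 1e-15).all()


def test_convergence_distance_examples(rng):
    m = random_model(rng, 3)
    assert convergence_distance(m, m) == 0.0
    m2 = m.copy()
    m2.match_emissions[1] = [0.0, 1.0, 0.0, 0.0]
    m.match_emissions[1] = [1.0, 0.0, 0.0, 0.0]
    G = len(list(free_parameter_groups(m)))
    assert convergence_distance(m, m2) == pytest.approx(np.sqrt(2) / G)
    bad = random_model(rng, 4)
    with pytest.raises(ValueError):
        convergence_distance(m, bad)


# -- training loops --------------------------------------------------------


def _total_ll(model, seqs):
    return sum(forward(model, s).log_likelihood for s in seqs)


def test_bw_fixed_point_converges_immediately(rng):
    """A model already at its own MAP update converges in <= 2 iterations
    with distance ~ 0."""
    m = random_model(rng, 2)
    seqs = [Sequence(f"s{i}", random_dna(rng, 4)) for i in range(3)]
    cfg = TrainingConfig(algorithm="BW", priors=Priors.laplace(),
                         parameter_floor=1e-7, convergence_tol=1e-9,
                         max_iterations=200)
    trained, trace = bw_train(m, seqs, cfg)
    again, trace2 = bw_train(trained, seqs,
                             TrainingConfig(algorithm="BW",
                                            parameter_floor=1e-7,
                                            convergence_tol=1e-6,
                                            max_iterations=10))
    assert len(trace2) <= 2
    assert trace2.final.distance < 1e-6


def test_bw_concentrates_on_repeated_consensus(rng):
    """Training on many copies of one consensus drives match emissions
    onto the consensus residues."""
    consensus = "ACGTACGT"
    m = build_plan7(len(consensus), DNA)   # neutral start: uniform emissions
    seqs = [Sequence(f"s{i}", consensus) for i in range(50)]
    cfg = TrainingConfig(algorithm="BW", convergence_tol=1e-6,
                         max_iterations=300)
    trained, _ = bw_train(m, seqs, cfg)
    for p, c in enumerate(consensus):
        assert trained.match_emissions[p, DNA.index(c)] > 0.9


def test_training_is_deterministic(rng):
    m = random_model(rng, 3)
    seqs = [Sequence(f"s{i}", random_dna(rng, 6)) for i in range(5)]
    cfg = TrainingConfig(algorithm="CBW", max_iterations=5)
    m1, t1 = cbw_train(m, seqs, cfg)
    m2, t2 = cbw_train(m, seqs, cfg)
    np.testing.assert_array_equal(m1.match_emissions, m2.match_emissions)
    assert [r.log_posterior for r in t1] == [r.log_posterior for r in t2]


def test_bw_log_posterior_monotone_random_instances(rng):
    """EM monotonicity: the BW objective never decreases across
    iterations (slack 1e-8), on 10 random instances."""
    for _ in range(10):
        n = int(rng.integers(1, 5))
        m = random_model(rng, n, local=bool(rng.integers(0, 2)))
        seqs = [Sequence(f"s{i}", random_dna(rng, int(rng.integers(2, 7))))
                for i in range(4)]
        cfg = TrainingConfig(algorithm="BW", max_iterations=25,
                             convergence_tol=1e-9)
        _, trace = bw_train(m, seqs, cfg)
        lps = [r.log_posterior for r in trace]
        assert all(b >= a - 1e-8 for a, b in zip(lps, lps[1:]))


def test_cbw_log_posterior_monotone_per_conditional_update(rng):
    """ECM monotonicity: the objective is nondecreasing after every
    conditional update within a CBW sweep (slack 1e-8), on 10 random
    instances."""
    for _ in range(10):
        n = int(rng.integers(1, 4))
        m = random_model(rng, n, local=bool(rng.integers(0, 2)))
        seqs = [Sequence(f"s{i}", random_dna(rng, int(rng.integers(2, 6))))
                for i in range(3)]
        cfg = TrainingConfig(algorithm="CBW", max_iterations=4,
                             convergence_tol=1e-12)
        values = []

        def record(mstate):
            values.append(log_posterior(mstate, cfg.priors,
                                        _total_ll(mstate, seqs)))

        cbw_train(m, seqs, cfg, update_callback=record)
        assert all(b >= a - 1e-8 for a, b in zip(values, values[1:]))


def test_cbw_position_update_matches_bw_for_single_position(rng):
    """For a 1-position model the conditional update of the position
    group coincides with BW's update of that group (the conditioning set
    is empty for the position-specific parameters)."""
    m = random_model(rng, 1)
    seqs = [Sequence(f"s{i}", random_dna(rng, 3)) for i in range(3)]
    cfg = TrainingConfig(algorithm="BW", max_iterations=1,
                         convergence_tol=0.0)
    bw_model, _ = bw_train(m, seqs, cfg)
    captured = []
    cbw_train(m, seqs,
              TrainingConfig(algorithm="CBW", max_iterations=1,
                             convergence_tol=0.0),
              update_callback=lambda mm: captured.append(mm.copy()))
    first = captured[0]   # after the position-group update, before globals
    np.testing.assert_allclose(first.match_emissions,
                               bw_model.match_emissions, rtol=1e-9)
    np.testing.assert_allclose(
        [first.tmm[0], first.tmi[0], first.tmd[0]],
        [bw_model.tmm[0], bw_model.tmi[0], bw_model.tmd[0]], rtol=1e-9)


def test_cbw_converges_to_consensus_from_neutral_start(rng):
    """CBW on a noisy family from a neutral start recovers the consensus
    (argmax of match emissions) at every position and matches BW's
    solution quality on this easy instance."""
    truth = "ACGTTGCA"
    base = [list(truth) for _ in range(12)]
    for row in base:
        for j in range(len(row)):
            if rng.random() < 0.2:
                row[j] = "ACGT"[rng.integers(0, 4)]
    seqs = [Sequence(f"s{i}", "".join(r)) for i, r in enumerate(base)]
    start = build_plan7(len(truth), DNA)
    mb, _ = bw_train(start, seqs,
                     TrainingConfig(algorithm="BW", max_iterations=200,
                                    convergence_tol=1e-6))
    mc, _ = cbw_train(start, seqs,
                      TrainingConfig(algorithm="CBW", max_iterations=200,
                                     convergence_tol=1e-6))
    for p, c in enumerate(truth):
        assert int(np.argmax(mc.match_emissions[p])) == DNA.index(c)
    assert _total_ll(mc, seqs) == pytest.approx(_total_ll(mb, seqs), abs=1.0)


def test_cbw_dms_recovers_consensus_from_random_starts():
    """Training on 100 sequences from a 20-position truth profile at
    conservation .8 recovers the consensus residue (argmax of the match
    emissions, best sliding offset) at >= 90% of positions on average
    over 4 seeds.  Uses the neutral uniform-emission start (the start a
    practitioner would use for estimation; the fully random starts of
    the local-optima study are deliberately adversarial)."""
    from profhmm.profile_simulator import (
        TruthSpec, random_start_profile, sample_sequences,
        sample_true_profile)
    from profhmm.trainers import train

    def consensus_of(model):
        return "".join("ACGT"[i]
                       for i in np.argmax(model.match_emissions, axis=1))

    def best_offset_identity(a, b):
        best = 0
        for off in range(-3, 4):
            n = sum(1 for i, c in enumerate(a)
                    if 0 <= i + off < len(b) and b[i + off] == c)
            best = max(best, n)
        return best / len(a)

    rates = []
    for seed in range(4):
        truth, cons = sample_true_profile(TruthSpec(20, 0.8, seed=40 + seed))
        seqs = sample_sequences(truth, 100, seed=4000 + seed)
        start = random_start_profile(20, "simulation", seed=50 + seed,
                                     uniform_emissions=True)
        cfg = TrainingConfig.simulation(algorithm="CBW", use_dms=True,
                                        max_iterations=250)
        model, _ = train(start, seqs, cfg)
        rates.append(best_offset_identity(cons.residues,
                                          consensus_of(model)))
    assert np.mean(rates) >= 0.9, rates
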