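"""Simulation harness: "true" profiles, sampled families, random starts.

The controlled study draws a random consensus sequence (length 100 by
default), builds a "true" profile whose match emission at each position
puts a chosen *conservation level* c on the consensus residue and spreads
the remaining 1-c evenly over the other residues, then samples training
and test families from that profile by simulating the hidden chain.  A
family sampled at conservation .5 agrees with its consensus at about half
of its match positions, so c is a direct proxy for family divergence.

The true profile's transitions are high-fidelity (M->M .97, M->I .015,
M->D .015, gap extension .3) so sampled sequences stay near the consensus
length; only the emission construction is dictated by the study design.
Starting profiles for training draw their match emissions uniformly from
the probability simplex (Dirichlet(1,1,1,1)) — distinct random starts
with no residue bias — with regime-specific transitions: the documented
global-mode defaults for the simulation regime, the local-mode starting
table for the transposon regime.

``shuffle_sequence`` produces the composition-preserving random
permutations used to calibrate hit-score thresholds against a null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp_engine import Sequence
from .profile_model import DNA, Alphabet, InvalidModelError, ProfileHMM, build_plan7

__all__ = [
    "TruthSpec",
    "TRUE_PROFILE_TRANSITIONS",
    "sample_true_profile",
    "sample_sequences",
    "sample_with_paths",
    "mean_identity",
    "random_start_profile",
    "shuffle_sequence",
]

#: Transitions of simulated "true" profiles (documented defaults; the
#: study prescribes only the emission construction).
TRUE_PROFILE_TRANSITIONS = {
    "tmm": 0.97, "tmi": 0.015, "tmd": 0.015,
    "tim": 0.7, "tii": 0.3, "tdm": 0.7, "tdd": 0.3,
    "begin": (0.97, 0.03, 0.0),
}


@dataclass(frozen=True)
class TruthSpec:
    """Specification of one true profile: consensus length (100 in the
    study), conservation level in (1/|alphabet|, 1], and a seed."""

    consensus_length: int = 100
    conservation: float = 0.5
    seed: int = 0


def sample_true_profile(spec: TruthSpec, alphabet: Alphabet = DNA):
    """Draw a random consensus and build its true profile.

    Returns (profile, consensus sequence).  The match emission at each
    position is ``conservation`` on the consensus residue and
    ``(1 - conservation) / (|alphabet| - 1)`` on each other residue.
    """
    A = alphabet.size
    if not (1.0 / A < spec.conservation <= 1.0):
        raise InvalidModelError(
            f"conservation must lie in (1/{A}, 1], got {spec.conservation}")
    rng = np.random.default_rng(spec.seed)
    n = spec.consensus_length
    cons_idx = rng.integers(0, A, size=n)
    model = build_plan7(n, alphabet, local_mode=False)
    off = (1.0 - spec.conservation) / (A - 1)
    em = np.full((n, A), off)
    em[np.arange(n), cons_idx] = spec.conservation
    model.match_emissions = em
    t = TRUE_PROFILE_TRANSITIONS
    model.tmm[:], model.tmi[:], model.tmd[:] = t["tmm"], t["tmi"], t["tmd"]
    model.tim[:], model.tii[:] = t["tim"], t["tii"]
    model.tdm[:], model.tdd[:] = t["tdm"], t["tdd"]
    model.begin = np.array(t["begin"])
    consensus = Sequence("consensus",
                         "".join(alphabet.symbols[i] for i in cons_idx))
    return model, consensus


def _sample_path(model: ProfileHMM, rng):
    """Simulate one path through the model; returns (residue string,
    match records [(1-based position, residue)])."""
    symbols = model.alphabet.symbols
    A = len(symbols)
    n = model.n_positions
    out: list[str] = []
    matches: list[tuple[int, str]] = []

    def draw(probs):
        return int(rng.choice(len(probs), p=np.asarray(probs) / np.sum(probs)))

    state, pos = "B", 0
    while True:
        if state == "B":
            k = draw(model.begin)
            if k == 0:
                state, pos = "M", 0
            elif k == 1:
                state, pos = "D", 0
            else:
                state, pos = "Z", 0
        elif state == "Z":
            if pos == n:
                break
            if rng.random() < model.z_exit:
                state = "M"
            else:
                pos += 1
        elif state == "M":
            r = symbols[draw(model.match_emissions[pos])]
            out.append(r)
            matches.append((pos + 1, r))
            k = draw([model.tmm[pos], model.tmi[pos],
                      model.tmd[pos], model.tmo[pos]])
            if k == 3:
                state, pos = "O", pos + 1
            elif k == 1:
                state = "I"
            elif pos == n - 1:
                break                     # M_n -> End (advance targets)
            elif k == 0:
                state, pos = "M", pos + 1
            else:
                state, pos = "D", pos + 1
        elif state == "I":
            out.append(symbols[draw(model.insert_emissions)])
            if rng.random() < model.tim[pos]:
                if pos == n - 1:
                    break
                state, pos = "M", pos + 1
        elif state == "D":
            k = 0 if rng.random() < model.tdm[pos] else 1
            if pos == n - 1:
                break
            if k == 0:
                state, pos = "M", pos + 1
            else:
                state, pos = "D", pos + 1
        elif state == "O":
            if pos == n or rng.random() < model.o_exit:
                break
            pos += 1
    return "".join(out), matches


def sample_with_paths(model: ProfileHMM, n: int, seed: int = 0):
    """Sample n sequences, also returning each sequence's match-emission
    records [(1-based position, residue)] (which consensus position every
    emitted match residue aligns to)."""
    rng = np.random.default_rng(seed)
    seqs, paths = [], []
    for i in range(n):
        resid, matches = _sample_path(model, rng)
        seqs.append(Sequence(f"sim{i}", resid))
        paths.append(matches)
    return seqs, paths


def sample_sequences(model: ProfileHMM, n: int, seed: int = 0):
    """Sample n sequences from the model (reproducible under seed)."""
    return sample_with_paths(model, n, seed)[0]


def mean_identity(paths, consensus: Sequence) -> float:
    """Mean fraction of match-state emissions agreeing with the
    consensus residue at the aligned position."""
    total = agree = 0
    for matches in paths:
        for pos, r in matches:
            total += 1
            agree += r == consensus.residues[pos - 1]
    return agree / total if total else float("nan")


def random_start_profile(length: int, regime: str = "simulation",
                         seed: int = 0, alphabet: Alphabet = DNA,
                         uniform_emissions: bool = False) -> ProfileHMM:
    """A random starting profile for training.

    Match emissions are drawn uniformly from the probability simplex
    (Dirichlet(1,...,1)); insert emissions are even.  In the simulation
    regime the whole profile is uniformly distributed — the per-position
    transition groups are drawn from the simplex as well, so starting
    points carry no alignment information and expose the estimation
    algorithms to the local-optimum landscape the study probes.  The
    transposon regime instead uses the local-mode starting transition
    table with random match emissions.  ``uniform_emissions`` gives the
    degenerate exactly-even emission start with default transitions.
    """
    if regime not in ("simulation", "transposon"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    model = build_plan7(length, alphabet,
                        local_mode=(regime == "transposon"))
    if uniform_emissions:
        return model
    A = alphabet.size
    model.match_emissions = rng.dirichlet(np.ones(A), size=length)
    if regime == "simulation":
        core = rng.dirichlet(np.ones(3), size=length)
        model.tmm[:], model.tmi[:], model.tmd[:] = core.T
        model.tim, model.tii = rng.dirichlet(np.ones(2), size=length).T
        model.tdm, model.tdd = rng.dirichlet(np.ones(2), size=length).T
        bm, bd = rng.dirichlet(np.ones(2))
        model.begin = np.array([bm, bd, 0.0])
    return model


def shuffle_sequence(seq: Sequence, seed: int = 0) -> Sequence:
    """Uniform random permutation of the residues (composition exactly
    preserved); used to build null targets for threshold calibration."""
    rng = np.random.default_rng(seed)
    arr = np.array(list(seq.residues))
    rng.shuffle(arr)
    return Sequence(f"{seq.id}|shuffled", "".join(arr))
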