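"""Forward, backward, posterior and Viterbi dynamic programming.

The recursions run over a lattice indexed by *column* ``c`` (the number of
residues consumed so far, 0..K) and model position ``p`` (0-based).  They
can be filled time-major (column by column) or state-major (row by row):
because the Plan 7 transition kernel is banded under the canonical state
ordering, a row depends only on the previous position's rows and on the
same row at the previous column, so rows can be recomputed independently
from any position onward.  The row-major orientation is what makes the
conditional (position-at-a-time) trainer as cheap as a full Baum-Welch
iteration.

Numerical regime: multiplicative per-column scaling with *constant* scale
factors equal to the inverse background probability (|alphabet| per real
residue, 1 for the neutral ambiguity 'N').  Emission probabilities enter
the recursion as odds ratios against a uniform background, which keeps
values near 1 for typical sequences and — unlike likelihood-dependent
scaling — leaves previously computed rows valid when a single position's
parameters change.  Reported log-likelihoods are natural logs.  Sequences
up to a few thousand residues are safe in this regime; genome-scale
scanning uses the log-space Viterbi instead.

Conventions for the flanking deletion chains (local mode): the DeletionIn
chain is traversed entirely at column 0 (flanking insertions are
disallowed, so nothing can be emitted before the first Match); entering
the Match state at 0-based position p via DeletionIn costs
``begin[2] * z_cont**p * z_exit``.  The DeletionOut chain is transparent
to the likelihood (it reaches End with probability 1) and is accounted
for in the End sum and in the expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_model import Alphabet, ProfileHMM

__all__ = [
    "Sequence",
    "DPResult",
    "RowBatch",
    "LocalAlignment",
    "forward",
    "backward",
    "forward_rows",
    "posterior_states",
    "viterbi_local",
]


@dataclass(frozen=True)
class Sequence:
    """A named residue string over the model's alphabet ('N' allowed)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DPResult:
    """Scaled DP values over (state, column).

    ``M``/``I``/``D`` have shape (K+1, n); ``end`` has shape (K+1,).
    Values are scaled: multiplying a forward value at column c by
    ``exp(-log_scale * c / K)``-style factors reconstructs the joint
    probability; concretely the per-column factors are |alphabet| for each
    real residue and 1 for 'N', and ``log_scale`` is their total log.
    ``log_likelihood`` is the natural-log sequence likelihood.
    """

    kind: str                    # "forward" | "backward"
    M: np.ndarray
    I: np.ndarray
    D: np.ndarray
    end: np.ndarray | None
    scale_factors: np.ndarray    # per-column multiplicative factors, length K+1
    log_likelihood: float

    @property
    def log_scale(self) -> float:
        return float(np.sum(np.log(self.scale_factors)))


def _entry_m(model: ProfileHMM) -> np.ndarray:
    """Entry mass from Begin (column 0) into M at each 0-based position:
    direct Begin->M1 plus the DeletionIn chain."""
    n = model.n_positions
    ent = model.begin[2] * model.z_exit * model.z_cont ** np.arange(n)
    ent[0] += model.begin[0]
    return ent


def _o_expectations(model: ProfileHMM):
    """Per entry position p: expected DeletionOut continue and exit uses
    for a path leaving M_p through the DeletionOut chain."""
    n = model.n_positions
    rem = n - 1 - np.arange(n)          # deletable positions after p
    oc = model.o_cont
    with np.errstate(divide="ignore"):
        if oc in (0.0, 1.0):
            e_cont = np.where(rem > 0, oc * rem, 0.0) if oc == 1.0 else np.zeros(n)
        else:
            e_cont = oc * (1 - oc ** rem) / (1 - oc)
    e_exit = 1.0 - oc ** rem
    return e_cont, e_exit


class RowBatch:
    """Row-major forward/backward engine over a batch of sequences.

    Holds padded, encoded sequences and the scaled DP lattices.  All
    arrays are (S, T, n) with T = max length + 1.  The public per-sequence
    functions (:func:`forward`, :func:`backward`, ...) wrap a batch of
    size one; the trainers drive the batch interface directly.
    """

    def __init__(self, model: ProfileHMM, seqs: list[Sequence]):
        self.alphabet = model.alphabet
        A = self.alphabet.size
        self.S = len(seqs)
        enc_list = [self.alphabet.encode(s.residues) for s in seqs]
        self.lengths = np.array([len(e) for e in enc_list], dtype=np.int64)
        self.T = int(self.lengths.max(initial=0)) + 1
        # -2 marks padding beyond a sequence's end
        self.enc = np.full((self.S, self.T - 1), -2, dtype=np.int64)
        for s, e in enumerate(enc_list):
            self.enc[s, : len(e)] = e
        # per-column scale factors: A for a real residue, 1 for 'N'/pad
        self.col_scale = np.ones((self.S, self.T))
        self.col_scale[:, 1:][self.enc >= 0] = float(A)
        self.log_scale = np.log(self.col_scale).sum(axis=1)
        # indicator of each sequence's final column
        self.endi = np.zeros((self.S, self.T))
        self.endi[np.arange(self.S), self.lengths] = 1.0
        self.set_model(model)
        n = self.n
        shape = (self.S, self.T, n)
        self.aM = np.zeros(shape)
        self.aI = np.zeros(shape)
        self.aD = np.zeros(shape)
        self.bM = np.zeros(shape)
        self.bI = np.zeros(shape)
        self.bD = np.zeros(shape)

    # -- model-dependent caches -------------------------------------------

    def set_model(self, model: ProfileHMM) -> None:
        self.model = model
        self.n = model.n_positions
        A = self.alphabet.size
        # scaled insert emissions per column: odds vs uniform background
        si = np.zeros((self.S, self.T))
        valid = self.enc >= 0
        si[:, 1:][valid] = (A * model.insert_emissions)[self.enc[valid]]
        si[:, 1:][self.enc == -1] = 1.0
        self.si = si
        self.refresh_match_rows()
        self.ent_m = _entry_m(model)

    def refresh_match_rows(self, positions=None) -> None:
        """Recompute the scaled match-emission lattice for the given
        0-based positions (all by default)."""
        model, A = self.model, self.alphabet.size
        if positions is None:
            sm = np.zeros((self.S, self.T, self.n))
            valid = self.enc >= 0
            scaled = A * model.match_emissions            # (n, A)
            sm[:, 1:, :][valid] = scaled.T[self.enc[valid]]
            sm[:, 1:, :][self.enc == -1] = 1.0
            self.sm = sm
        else:
            for p in np.atleast_1d(positions):
                col = np.zeros((self.S, self.T))
                valid = self.enc >= 0
                col[:, 1:][valid] = (A * model.match_emissions[p])[self.enc[valid]]
                col[:, 1:][self.enc == -1] = 1.0
                self.sm[:, :, p] = col

    # -- forward ----------------------------------------------------------

    def forward_row(self, p: int) -> None:
        """Fill forward rows (M, I, D) at 0-based position p from rows
        p-1 (and Begin/DeletionIn for p = 0)."""
        m = self.model
        # D_p: silent, same-column recursion over positions
        if p == 0:
            self.aD[:, :, 0] = 0.0
            self.aD[:, 0, 0] = m.begin[1]
        else:
            self.aD[:, :, p] = (self.aM[:, :, p - 1] * m.tmd[p - 1]
                                + self.aD[:, :, p - 1] * m.tdd[p - 1])
        # M_p: emitting, previous-column inputs
        x = np.zeros((self.S, self.T))
        if self.T > 1:
            x[:, 1] = self.ent_m[p]
        if p > 0:
            x[:, 1:] += (self.aM[:, :-1, p - 1] * m.tmm[p - 1]
                         + self.aI[:, :-1, p - 1] * m.tim[p - 1]
                         + self.aD[:, :-1, p - 1] * m.tdm[p - 1])
        self.aM[:, :, p] = self.sm[:, :, p] * x
        # I_p: first-order recurrence along columns
        aI = self.aI[:, :, p]
        aI[:, 0] = 0.0
        aMp, si = self.aM[:, :, p], self.si
        tmi, tii = m.tmi[p], m.tii[p]
        for c in range(1, self.T):
            aI[:, c] = si[:, c] * (aMp[:, c - 1] * tmi + aI[:, c - 1] * tii)

    def forward_fill(self, p_start: int = 0) -> None:
        for p in range(p_start, self.n):
            self.forward_row(p)

    def end_values(self) -> np.ndarray:
        """Scaled End-state mass per (sequence, column)."""
        m, n = self.model, self.n
        end = self.aM @ m.tmo
        end += (self.aM[:, :, n - 1] * (m.tmm[n - 1] + m.tmd[n - 1])
                + self.aI[:, :, n - 1] * m.tim[n - 1]
                + self.aD[:, :, n - 1] * (m.tdm[n - 1] + m.tdd[n - 1]))
        # fully deleted paths (relevant only for the empty sequence)
        end[:, 0] += m.begin[2] * m.z_cont ** n
        return end

    def likelihoods(self) -> np.ndarray:
        """Scaled likelihood per sequence (End mass at each final column)."""
        return (self.end_values() * self.endi).sum(axis=1)

    def log_likelihoods(self) -> np.ndarray:
        lhat = self.likelihoods()
        if np.any(lhat <= 0):
            bad = int(np.argmax(lhat <= 0))
            raise FloatingPointError(
                f"sequence {bad} has zero likelihood under the model")
        return np.log(lhat) - self.log_scale

    # -- backward ---------------------------------------------------------

    def backward_row(self, p: int) -> None:
        """Fill backward rows at position p from rows p+1 (I first, then
        D, then M; only I needs a column loop)."""
        m, n, T = self.model, self.n, self.T
        last = p == n - 1
        smn = self.sm[:, :, p + 1] if not last else None
        bI = self.bI[:, :, p]
        bI[:, T - 1] = m.tim[p] * self.endi[:, T - 1] if last else 0.0
        if last:
            adv = m.tim[p] * self.endi          # I_n -> End
            for c in range(T - 2, -1, -1):
                bI[:, c] = adv[:, c] + m.tii[p] * self.si[:, c + 1] * bI[:, c + 1]
        else:
            bMn = self.bM[:, :, p + 1]
            for c in range(T - 2, -1, -1):
                bI[:, c] = (m.tim[p] * smn[:, c + 1] * bMn[:, c + 1]
                            + m.tii[p] * self.si[:, c + 1] * bI[:, c + 1])
        if last:
            self.bD[:, :, p] = (m.tdm[p] + m.tdd[p]) * self.endi
            self.bM[:, :, p] = ((m.tmm[p] + m.tmd[p] + m.tmo[p]) * self.endi)
            self.bM[:, :-1, p] += (m.tmi[p] * self.si[:, 1:] * bI[:, 1:])
        else:
            bMn = self.bM[:, :, p + 1]
            adv = np.zeros((self.S, self.T))
            adv[:, :-1] = smn[:, 1:] * bMn[:, 1:]
            self.bD[:, :, p] = m.tdm[p] * adv + m.tdd[p] * self.bD[:, :, p + 1]
            bM = m.tmm[p] * adv + m.tmd[p] * self.bD[:, :, p + 1] \
                + m.tmo[p] * self.endi
            bM[:, :-1] += m.tmi[p] * self.si[:, 1:] * bI[:, 1:]
            self.bM[:, :, p] = bM

    def backward_fill(self) -> None:
        for p in range(self.n - 1, -1, -1):
            self.backward_row(p)

    def backward_likelihoods(self) -> np.ndarray:
        """Scaled likelihood recovered from the backward lattice."""
        m = self.model
        if self.T == 1:
            return (m.begin[1] * self.bD[:, 0, 0]
                    + m.begin[2] * m.z_cont ** self.n)
        lhat = (self.ent_m * self.sm[:, 1, :] * self.bM[:, 1, :]).sum(axis=1)
        lhat += m.begin[1] * self.bD[:, 0, 0]
        lhat += m.begin[2] * m.z_cont ** self.n * self.endi[:, 0]
        # empty sequences contribute through column-0 End mass only
        empty = self.lengths == 0
        if np.any(empty):
            lhat[empty] = (m.begin[1] * self.bD[empty, 0, 0]
                           + m.begin[2] * m.z_cont ** self.n)
        return lhat


# -- public per-sequence operations ---------------------------------------


def _single(model: ProfileHMM, seq: Sequence) -> RowBatch:
    return RowBatch(model, [seq])


def _fwd_result(rb: RowBatch) -> DPResult:
    end = rb.end_values()[0]
    lhat = float((end * rb.endi[0]).sum())
    ll = float(np.log(lhat) - rb.log_scale[0]) if lhat > 0 else -np.inf
    return DPResult("forward", rb.aM[0].copy(), rb.aI[0].copy(),
                    rb.aD[0].copy(), end.copy(), rb.col_scale[0].copy(), ll)


def forward(model: ProfileHMM, seq: Sequence) -> DPResult:
    """Scaled forward pass; ``log_likelihood`` is the natural-log
    probability of the sequence under the model."""
    rb = _single(model, seq)
    rb.forward_fill()
    return _fwd_result(rb)


def backward(model: ProfileHMM, seq: Sequence) -> DPResult:
    """Scaled backward pass; its ``log_likelihood`` is recovered from the
    column-0 entry masses and equals the forward value."""
    rb = _single(model, seq)
    rb.backward_fill()
    lhat = float(rb.backward_likelihoods()[0])
    ll = float(np.log(lhat) - rb.log_scale[0]) if lhat > 0 else -np.inf
    return DPResult("backward", rb.bM[0].copy(), rb.bI[0].copy(),
                    rb.bD[0].copy(), None, rb.col_scale[0].copy(), ll)


def forward_rows(model: ProfileHMM, seq: Sequence, fwd: DPResult,
                 from_position: int) -> DPResult:
    """Recompute forward rows from 1-based model position
    ``from_position`` onward, reusing earlier rows of ``fwd`` untouched.

    Used after a parameter change confined to positions >= from_position:
    the banded ordering guarantees earlier rows are unaffected.
    """
    n = model.n_positions
    if not 1 <= from_position <= n:
        raise ValueError(f"from_position {from_position} outside 1..{n}")
    if fwd.M.shape != (len(seq.residues) + 1, n):
        raise ValueError("forward lattice does not match model/sequence shape")
    rb = _single(model, seq)
    p0 = from_position - 1
    rb.aM[0, :, :p0] = fwd.M[:, :p0]
    rb.aI[0, :, :p0] = fwd.I[:, :p0]
    rb.aD[0, :, :p0] = fwd.D[:, :p0]
    rb.forward_fill(p_start=p0)
    return _fwd_result(rb)


def posterior_states(model: ProfileHMM, seq: Sequence, fwd: DPResult,
                     bwd: DPResult):
    """Posterior occupancy per (state, column) given the sequence.

    Returns (post_M, post_I, post_D): for every emitted residue position
    c >= 1, ``post_M[c] + post_I[c]`` sums to 1 over states (the residue
    was emitted by exactly one Match or Insertion state); ``post_D`` is
    the probability that the silent Deletion state was visited with c
    residues consumed.
    """
    if fwd.kind != "forward" or bwd.kind != "backward":
        raise ValueError("posterior_states needs one forward and one backward result")
    if fwd.M.shape != bwd.M.shape:
        raise ValueError("forward/backward lattices have mismatched shapes")
    K = len(seq.residues)
    if fwd.M.shape[0] != K + 1:
        raise ValueError("lattices were computed for a different sequence")
    lhat = np.exp(fwd.log_likelihood + fwd.log_scale)
    post_M = fwd.M * bwd.M / lhat
    post_I = fwd.I * bwd.I / lhat
    post_D = fwd.D * bwd.D / lhat
    return post_M, post_I, post_D


# -- local Viterbi ---------------------------------------------------------

_ROLE_PRIORITY = {"M": 0, "D": 1, "I": 2}


@dataclass
class LocalAlignment:
    """Best local hit of a profile against a sequence.

    ``score`` is the natural-log odds of the aligned segment against the
    background model (the profile's insert emission distribution);
    ``start``/``end`` are 1-based inclusive coordinates on the sequence;
    ``path`` lists (role, 1-based model position) along the alignment.
    ``empty`` is True when the sequence had no alignable content.
    """

    score: float = -np.inf
    start: int = 0
    end: int = 0
    path: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.path


def viterbi_local(model: ProfileHMM, seq: Sequence) -> LocalAlignment:
    """Maximum-probability local alignment (log-odds scored).

    Local in the sequence (unaligned flanks are scored by the background)
    and local in the model through the DeletionIn/DeletionOut chains.
    Tie-break: Match preferred over Deletion over Insertion, then lower
    model position.  Requires a local-mode model.
    """
    if not model.local_mode:
        raise ValueError("viterbi_local requires a local-mode model")
    K, n = len(seq.residues), model.n_positions
    if K == 0:
        return LocalAlignment()
    enc = model.alphabet.encode(seq.residues)
    bg = model.insert_emissions
    with np.errstate(divide="ignore"):
        lem = np.log(model.match_emissions) - np.log(bg)      # (n, A)
        lem = np.hstack([lem, np.zeros((n, 1))])              # 'N' -> 0
        lsi = np.log(model.insert_emissions) - np.log(bg)
        lsi = np.append(lsi, 0.0)
        ltmm, ltmi, ltmd = np.log(model.tmm), np.log(model.tmi), np.log(model.tmd)
        ltim, ltii = np.log(model.tim), np.log(model.tii)
        ltdm, ltdd = np.log(model.tdm), np.log(model.tdd)
        lstart = np.log(_entry_m(model))
        # exit cost: leave from M_p through DeletionOut (mass 1 to End);
        # the last position may also exit through its advance transitions
        lexit = np.log(model.tmo.copy())
        lexit[n - 1] = np.log(model.tmo[n - 1] + model.tmm[n - 1]
                              + model.tmd[n - 1])

    NEG = -np.inf
    vM = np.full((K + 1, n), NEG)
    vI = np.full((K + 1, n), NEG)
    vD = np.full((K + 1, n), NEG)
    # backpointers: 0 start, 1 from M, 2 from I, 3 from D
    ptrM = np.zeros((K + 1, n), dtype=np.int8)
    ptrI = np.zeros((K + 1, n), dtype=np.int8)
    ptrD = np.zeros((K + 1, n), dtype=np.int8)

    for c in range(1, K + 1):
        e = lem[:, enc[c - 1]]
        # M: start fresh at any column, or extend from column c-1
        cand = np.full((4, n), NEG)
        cand[0] = lstart
        cand[1, 1:] = vM[c - 1, :-1] + ltmm[:-1]
        cand[3, 1:] = vD[c - 1, :-1] + ltdm[:-1]
        cand[2, 1:] = vI[c - 1, :-1] + ltim[:-1]
        best = np.argmax(cand, axis=0)        # ties: start < M < I < D order
        # enforce documented tie-break M > D > I among equals
        top = cand[best, np.arange(n)]
        prefer = np.where((cand[3] >= top) & (best == 2), 3, best)
        vM[c] = e + cand[prefer, np.arange(n)]
        ptrM[c] = prefer
        si = lsi[enc[c - 1]]
        im = vM[c - 1] + ltmi
        ii = vI[c - 1] + ltii
        useM = im >= ii
        vI[c] = si + np.where(useM, im, ii)
        ptrI[c] = np.where(useM, 1, 2)
        # D: same-column recursion
        for p in range(n):
            if p == 0:
                vD[c, 0] = NEG
                continue
            dm = vM[c, p - 1] + ltmd[p - 1]
            dd = vD[c, p - 1] + ltdd[p - 1]
            if dm >= dd:
                vD[c, p], ptrD[c, p] = dm, 1
            else:
                vD[c, p], ptrD[c, p] = dd, 3

    ends = vM[1:, :] + lexit            # end the hit after a Match
    flat = int(np.argmax(ends))
    c_end, p_end = 1 + flat // n, flat % n
    score = float(ends[c_end - 1, p_end])
    if not np.isfinite(score):
        return LocalAlignment()

    # traceback
    path = []
    role, c, p = "M", c_end, p_end
    while True:
        path.append((role, p + 1))
        if role == "M":
            ptr = ptrM[c, p]
            if ptr == 0:
                break
            c, p, role = c - 1, p - 1, {1: "M", 2: "I", 3: "D"}[ptr]
        elif role == "I":
            ptr = ptrI[c, p]
            c, role = c - 1, {1: "M", 2: "I"}[ptr]
        else:  # D, silent
            ptr = ptrD[c, p]
            p, role = p - 1, {1: "M", 3: "D"}[ptr]
    path.reverse()
    n_emitted = sum(1 for role, _ in path if role in "MI")
    start = c_end - n_emitted + 1
    return LocalAlignment(score=score, start=start, end=c_end, path=path)
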