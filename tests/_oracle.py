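"""Brute-force path-enumeration oracle for tiny profile HMM instances.

Independent of the package's dynamic programming code: walks the model's
state graph recursively, enumerating every legal hidden path that emits a
given sequence, and accumulates exact path probabilities, per-parameter
expected usages, and per-emission posteriors.  Only feasible for models
with a few positions and sequences of a few residues.
"""

from collections import defaultdict

import numpy as np


def enumerate_paths(model, residues: str):
    """Yield (probability, usages, emitters) over all complete paths.

    ``usages`` is a Counter of parameter labels; ``emitters`` is a tuple
    of (role, 0-based position) for each emitted residue in order.
    """
    enc = model.alphabet.encode(residues)
    n = model.n_positions
    K = len(enc)
    out = []

    def em_prob(vec, x):
        return 1.0 if x == -1 else float(vec[x])

    def go(state, tau, prob, uses, emitters):
        if prob == 0.0:
            return
        role = state[0]
        if role == "End":
            if tau == K:
                out.append((prob, uses, tuple(emitters)))
            return
        if role == "B":
            go(("M", 0), tau, prob * model.begin[0], uses + [("b_m",)], emitters)
            go(("D", 0), tau, prob * model.begin[1], uses + [("b_d",)], emitters)
            go(("Z", 0), tau, prob * model.begin[2], uses + [("b_z",)], emitters)
            return
        if role == "Z":
            j = state[1]
            if j == n:
                go(("End",), tau, prob, uses, emitters)
                return
            go(("M", j), tau, prob * model.z_exit, uses + [("z_exit",)], emitters)
            go(("Z", j + 1), tau, prob * model.z_cont, uses + [("z_cont",)], emitters)
            return
        if role == "O":
            j = state[1]
            if j == n:
                go(("End",), tau, prob, uses, emitters)
                return
            go(("End",), tau, prob * model.o_exit, uses + [("o_exit",)], emitters)
            go(("O", j + 1), tau, prob * model.o_cont, uses + [("o_cont",)], emitters)
            return
        if role == "M":
            p = state[1]
            if tau == K:
                return
            x = enc[tau]
            e = em_prob(model.match_emissions[p], x)
            prob = prob * e
            uses = uses + [("em", p, int(x))]
            emitters = emitters + [("M", p)]
            tau += 1
            last = p == n - 1
            mnext = ("End",) if last else ("M", p + 1)
            dnext = ("End",) if last else ("D", p + 1)
            go(mnext, tau, prob * model.tmm[p], uses + [("tmm", p)], emitters)
            go(("I", p), tau, prob * model.tmi[p], uses + [("tmi", p)], emitters)
            go(dnext, tau, prob * model.tmd[p], uses + [("tmd", p)], emitters)
            go(("O", p + 1), tau, prob * model.tmo[p], uses + [("tmo", p)], emitters)
            return
        if role == "I":
            p = state[1]
            if tau == K:
                return
            x = enc[tau]
            e = em_prob(model.insert_emissions, x)
            prob = prob * e
            uses = uses + [("iem", int(x))]
            emitters = emitters + [("I", p)]
            tau += 1
            last = p == n - 1
            mnext = ("End",) if last else ("M", p + 1)
            go(mnext, tau, prob * model.tim[p], uses + [("tim", p)], emitters)
            go(("I", p), tau, prob * model.tii[p], uses + [("tii", p)], emitters)
            return
        if role == "D":
            p = state[1]
            last = p == n - 1
            mnext = ("End",) if last else ("M", p + 1)
            dnext = ("End",) if last else ("D", p + 1)
            uses2 = uses + [("dvisit", p)]
            go(mnext, tau, prob * model.tdm[p], uses2 + [("tdm", p)], emitters)
            go(dnext, tau, prob * model.tdd[p], uses2 + [("tdd", p)], emitters)
            return
        raise AssertionError(state)

    go(("B",), 0, 1.0, [], [])
    return out


class OracleResult:
    """Exact likelihood, expected usages and posteriors for one
    (model, sequence) instance."""

    def __init__(self, model, residues: str):
        paths = enumerate_paths(model, residues)
        self.likelihood = sum(p for p, _, _ in paths)
        K = len(residues)
        n = model.n_positions
        usage = defaultdict(float)
        post_M = np.zeros((K + 1, n))
        post_I = np.zeros((K + 1, n))
        visit_D = np.zeros((K + 1, n))
        for prob, uses, emitters in paths:
            for u in uses:
                usage[u if len(u) > 1 else u[0]] += prob
            for tau, (role, p) in enumerate(emitters, start=1):
                (post_M if role == "M" else post_I)[tau, p] += prob
            self._replay_deletions(model, uses, visit_D, prob)
        if self.likelihood > 0:
            for arr in (post_M, post_I, visit_D):
                arr /= self.likelihood
            self.usage = {k: v / self.likelihood for k, v in usage.items()}
        else:
            self.usage = {}
        self.post_M, self.post_I, self.visit_D = post_M, post_I, visit_D

    @staticmethod
    def _replay_deletions(model, uses, visit_D, prob):
        """Walk the recorded usage labels, tracking how many residues had
        been consumed when each Deletion state was visited."""
        consumed = 0
        for u in uses:
            if u[0] in ("em", "iem"):
                consumed += 1
            elif u[0] == "dvisit":
                visit_D[consumed, u[1]] += prob

    def count(self, label) -> float:
        return self.usage.get(label, 0.0)
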