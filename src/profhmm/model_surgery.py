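"""Dynamic Model Surgery: on-line structural correction during training.

Parameter estimation for profile HMMs is notorious for local optima in
which the model's positions are *misaligned* against the family: a
position that most sequences delete should not exist, and a point where
most sequences insert residues marks a missing position.  Dynamic Model
Surgery watches the expected insertion/deletion usage per position while
the Baum-Welch or conditional updates are being computed, and edits the
model immediately: if more than a fraction ``nu_insert`` of the sequences
have expected insertion counts exceeding a threshold ``xi`` at position
j, a new position is added after j; if more than ``nu_delete`` of the
sequences have expected deletion counts exceeding ``xi`` at j, position j
is removed.  Because structural edits can oscillate (insert one sweep,
delete it back the next), ``xi`` escalates whenever a cycle is detected:
by a fixed increment ``epsilon``, or adaptively by the minimal amount
that changes at least one exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_model import ProfileHMM

__all__ = [
    "SurgeryConfig",
    "PositionUsage",
    "SurgeryState",
    "position_usage",
    "decide_actions",
    "apply_surgery",
    "detect_cycle_and_escalate",
]


@dataclass
class SurgeryConfig:
    """Thresholds for Dynamic Model Surgery.

    The simulation regime uses ``xi0=.01``, ``epsilon=.005`` and
    ``nu_insert = nu_delete = .5``; the transposon regime uses
    ``xi0=.1``, ``nu_insert=.1``, ``nu_delete=.9`` with adaptive
    escalation (the data show many more deletions than insertions, so the
    deletion trigger must be much stricter).
    """

    xi0: float = 0.01
    epsilon: float = 0.005
    nu_insert: float = 0.5
    nu_delete: float = 0.5
    escalation: str = "fixed"          # "fixed" | "adaptive"
    cycle_memory: int = 20
    #: surgery decisions are evaluated only at iterations whose parameter
    #: distance has dropped below this (diffuse early-training posteriors
    #: make usage fractions meaningless; see docs/methods.md)
    stability_threshold: float = 0.005
    #: a proposal touching more than this fraction of the positions means
    #: xi sits in the posterior noise floor: escalate instead of editing
    noise_fraction: float = 0.5
    #: once this many consecutive surgery events leave the model length
    #: inside a +-1 band, the structure is considered settled and surgery
    #: stops for the rest of the run (lets training reach convergence)
    settle_events: int = 6

    def __post_init__(self):
        if self.xi0 <= 0:
            raise ValueError("xi0 must be positive")
        if not (0 < self.nu_insert < 1 and 0 < self.nu_delete < 1):
            raise ValueError("nu thresholds must lie in (0, 1)")
        if self.escalation not in ("fixed", "adaptive"):
            raise ValueError(f"unknown escalation mode {self.escalation!r}")


@dataclass
class PositionUsage:
    """Per-position exceedance fractions: f_ins[j] is the fraction of
    sequences whose expected insertion count at position j exceeds xi,
    f_del[j] the same for deletions."""

    f_ins: np.ndarray
    f_del: np.ndarray


def position_usage(counts, xi: float) -> PositionUsage:
    """Exceedance fractions from per-sequence expected counts.

    ``counts`` is an :class:`~profhmm.trainers.ExpectedCounts` (or any
    object with ``per_seq_ins`` / ``per_seq_del`` arrays of shape
    (sequences, positions))."""
    ins = getattr(counts, "per_seq_ins", None)
    dele = getattr(counts, "per_seq_del", None)
    if ins is None or dele is None:
        raise ValueError("per-sequence expected counts are required for DMS")
    return PositionUsage(f_ins=(ins > xi).mean(axis=0),
                         f_del=(dele > xi).mean(axis=0))


def decide_actions(usage: PositionUsage, config: SurgeryConfig) -> list:
    """Ordered surgery actions: ('insert_after', j) where f_ins[j] >
    nu_insert, ('delete', j) where f_del[j] > nu_delete (1-based j).

    When both trigger at one position the two edits cancel: removing the
    position and adding one in its place is a net no-op, so no action is
    taken there.  This matters with diffuse early-training posteriors,
    where both usage fractions exceed the threshold at nearly every
    position: cancelling leaves the model to keep estimating (surgery
    then fires only where the evidence is one-sided), where a
    deletion-wins rule would amputate the whole model in the first
    sweeps.  Actions are ordered by descending position so indices stay
    valid as they are applied."""
    n = len(usage.f_ins)
    actions = []
    triggered = {j for j in range(n) if usage.f_del[j] > config.nu_delete}
    ins_trig = {j for j in range(n) if usage.f_ins[j] > config.nu_insert}
    insertions = ins_trig - triggered
    # conflicted positions cancel; never delete every position
    deletions = triggered - ins_trig
    if len(deletions) == n and n > 0:
        deletions.discard(int(np.argmin(usage.f_del)))
    for j in range(n):
        if j in deletions:
            actions.append(("delete", j + 1))
        elif j in insertions:
            actions.append(("insert_after", j + 1))
    actions.sort(key=lambda a: -a[1])
    return actions


def apply_surgery(model: ProfileHMM, actions, dp_state=None, seq=None,
                  emission_init: np.ndarray | None = None):
    """Apply surgery actions, returning (new model, repaired forward DP).

    An inserted position copies its source position's transition group
    and starts with a neutral (prior-mean, uniform) match emission — or
    ``emission_init`` when given.  A deleted position's arrays are simply
    removed; its neighbours' transitions then span the gap.  When a
    forward :class:`~profhmm.dp_engine.DPResult` and its sequence are
    supplied, rows strictly before the earliest affected position are
    reused untouched and later rows recomputed.
    """
    from .dp_engine import RowBatch, _fwd_result  # local import: no cycle

    new = model.copy()
    earliest = None
    arrays = ["tmm", "tmi", "tmd", "tmo", "tim", "tii", "tdm", "tdd"]
    for kind, j in actions:
        n = new.n_positions
        if not 1 <= j <= n:
            raise ValueError(f"surgery site {j} outside 1..{n}")
        i = j - 1
        if kind == "delete":
            if n == 1:
                raise ValueError("cannot delete the only position of a model")
            new.match_emissions = np.delete(new.match_emissions, i, axis=0)
            for name in arrays:
                setattr(new, name, np.delete(getattr(new, name), i))
            earliest = j if earliest is None else min(earliest, j)
        elif kind == "insert_after":
            A = new.alphabet.size
            em = (np.full(A, 1.0 / A) if emission_init is None
                  else np.asarray(emission_init, dtype=float))
            new.match_emissions = np.insert(new.match_emissions, i + 1,
                                            em, axis=0)
            for name in arrays:
                arr = getattr(new, name)
                setattr(new, name, np.insert(arr, i + 1, arr[i]))
            earliest = j + 1 if earliest is None else min(earliest, j + 1)
        elif kind == "reinit":
            # delete + insert composed: a fresh neutral emission replaces
            # the misaligned position, transitions kept
            A = new.alphabet.size
            new.match_emissions[i] = (np.full(A, 1.0 / A)
                                      if emission_init is None
                                      else np.asarray(emission_init, float))
            earliest = j if earliest is None else min(earliest, j)
        else:
            raise ValueError(f"unknown surgery action {kind!r}")

    repaired = None
    if dp_state is not None and seq is not None:
        p0 = 1 if earliest is None else earliest
        rb = RowBatch(new, [seq])
        keep = p0 - 1
        rb.aM[0, :, :keep] = dp_state.M[:, :keep]
        rb.aI[0, :, :keep] = dp_state.I[:, :keep]
        rb.aD[0, :, :keep] = dp_state.D[:, :keep]
        rb.forward_fill(p_start=keep)
        repaired = _fwd_result(rb)
    return new, repaired


def detect_cycle_and_escalate(history, xi: float, config: SurgeryConfig,
                              per_seq_counts: np.ndarray | None = None):
    """Return the possibly-escalated xi given a structural history.

    ``history`` is a sequence of structural signatures (model length,
    actions tuple) for recent iterations, most recent last.  A cycle is a
    return to a previously seen model length while actions are still
    firing: surgery that makes progress moves the length monotonically,
    so a revisited length means the edits are churning (inserting and
    deleting back and forth without net structural progress).  Fixed
    mode adds ``epsilon``; adaptive mode raises xi to the smallest
    per-sequence expected count strictly above it (the minimal amount
    that changes an exceedance fraction).
    """
    if len(history) < 2:
        return xi
    current = history[-1]
    if not current[1]:
        return xi
    window = [sig[0] for sig in history[-config.cycle_memory - 1:-1]]
    if current[0] not in window:
        return xi
    if config.escalation == "fixed" or per_seq_counts is None:
        return xi + config.epsilon
    above = per_seq_counts[per_seq_counts > xi]
    return float(above.min()) if above.size else xi + config.epsilon


@dataclass
class SurgeryState:
    """Mutable DMS state carried across training iterations: the current
    threshold xi and the structural-signature history since the last
    escalation."""

    config: SurgeryConfig
    xi: float = field(default=None)
    history: list = field(default_factory=list)
    event_lengths: list = field(default_factory=list)
    frozen: bool = False

    def __post_init__(self):
        if self.xi is None:
            self.xi = self.config.xi0

    def note_event(self, model_length: int) -> None:
        """Track lengths at surgery events; freeze structural editing
        once the length has stopped moving."""
        self.event_lengths.append(model_length)
        k = self.config.settle_events
        recent = self.event_lengths[-k:]
        if len(recent) == k and max(recent) - min(recent) <= 1:
            self.frozen = True

    def observe(self, model_length: int, actions,
                per_seq_counts: np.ndarray | None = None) -> bool:
        """Record this iteration's structural signature; escalate xi on a
        detected cycle.  Returns True when an escalation happened."""
        self.history.append((model_length, tuple(sorted(actions))))
        new_xi = detect_cycle_and_escalate(self.history, self.xi,
                                           self.config, per_seq_counts)
        if new_xi != self.xi:
            self.xi = new_xi
            self.history.clear()
            return True
        if len(self.history) > self.config.cycle_memory:
            del self.history[0]
        return False

    def escalate(self, per_seq_counts: np.ndarray | None = None) -> None:
        """Force one escalation step (used when a proposal lands in the
        posterior noise floor)."""
        if self.config.escalation == "fixed" or per_seq_counts is None:
            self.xi += self.config.epsilon
        else:
            above = per_seq_counts[per_seq_counts > self.xi]
            self.xi = (float(above.min()) if above.size
                       else self.xi + self.config.epsilon)
        self.history.clear()
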