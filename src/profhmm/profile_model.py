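"""Plan 7 profile HMM data model.

A profile HMM represents a sequence family as a chain of ``n`` ancestral
*positions*.  Each position ``p`` carries three states: Match (``M_p``,
emits one residue from a position-specific distribution), Insertion
(``I_p``, emits from a shared background-like distribution and may
self-loop), and Deletion (``D_p``, silent).  The Plan 7 topology forbids
direct Insertion<->Deletion transitions, leaving seven transitions per
position triple (M->M, M->I, M->D, I->M, I->I, D->M, D->D).

Two bookkeeping states flank the core chain, giving ``3n + 4`` states in
total.  In *local* mode they act as DeletionIn / DeletionOut chains: a hit
may enter the model at any position (silently deleting the prefix through
DeletionIn) and leave early (deleting the suffix through DeletionOut).
In global mode their entry probabilities are zero and every path traverses
all ``n`` positions.  Flanking insertions are disallowed in both modes.

Transition parameters are stored per position as length-``n`` arrays.  At
the last position the "advance" targets fold onto End: ``tmm[n-1]`` is
M_n->End, ``tmd[n-1]`` also reaches End (there is no D_{n+1}), ``tim[n-1]``
is I_n->End and ``tdm[n-1]``/``tdd[n-1]`` both reach End.  The DeletionIn
chain is parameterised by a single (continue, exit) pair: entering it at
Begin places it "before position 1"; each continue step deletes one
position, and exit enters the Match state at the position reached.
DeletionOut mirrors this after an early Match exit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "ProfileHMM",
    "StateOrdering",
    "InvalidModelError",
    "build_plan7",
    "canonical_ordering",
    "transition_edges",
    "max_advancing_offset",
    "validate",
    "free_parameter_groups",
]

#: Local-mode starting transition values (transposon-regime defaults).
LOCAL_DEFAULTS = {
    "tmm": 0.095, "tmi": 0.0025, "tmd": 0.0025, "tmo": 0.9,
    "tim": 0.5, "tii": 0.5, "tdm": 0.5, "tdd": 0.5,
    "begin": (0.09, 0.01, 0.9),       # Begin -> (M1, D1, DeletionIn)
    "flank": (0.9999, 0.0001),        # DeletionIn/Out (continue, exit)
}

#: Global-mode defaults (the training data moves them; any proper
#: distribution works as a start).
GLOBAL_DEFAULTS = {
    "tmm": 0.95, "tmi": 0.025, "tmd": 0.025, "tmo": 0.0,
    "tim": 0.5, "tii": 0.5, "tdm": 0.5, "tdd": 0.5,
    "begin": (0.95, 0.05, 0.0),
    "flank": (0.9999, 0.0001),        # inert: zero entry probability
}


class InvalidModelError(ValueError):
    """Raised when a profile HMM cannot be built or used as requested."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet (case-insensitive by default)."""

    symbols: str = "ACGT"
    case_insensitive: bool = True

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidModelError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, residue: str) -> int:
        r = residue.upper() if self.case_insensitive else residue
        return self.symbols.index(r)

    def encode(self, residues: str) -> np.ndarray:
        """Encode a residue string to integer codes; 'N' maps to -1
        (neutral ambiguity, emitted with probability 1 by every state)."""
        s = residues.upper() if self.case_insensitive else residues
        lookup = {c: i for i, c in enumerate(self.symbols)}
        out = np.empty(len(s), dtype=np.int64)
        for i, c in enumerate(s):
            if c in lookup:
                out[i] = lookup[c]
            elif c == "N":
                out[i] = -1
            else:
                raise ValueError(
                    f"residue {c!r} at position {i + 1} is not in alphabet "
                    f"{self.symbols!r}"
                )
        return out


DNA = Alphabet("ACGT")


@dataclass
class ProfileHMM:
    """Full parameter set of a Plan 7 profile HMM.

    Attributes
    ----------
    match_emissions : (n, A) array, rows sum to 1
    insert_emissions : (A,) array, shared across positions
    tmm..tdd : (n,) arrays, per-position out-transition probabilities
        (see module docstring for last-position folding)
    begin : (3,) array, Begin -> (M1, D1, DeletionIn)
    z_cont, z_exit : DeletionIn chain continue/exit probabilities
    o_cont, o_exit : DeletionOut chain continue/exit probabilities
    local_mode : whether the flanking deletion chains are reachable
    """

    alphabet: Alphabet
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    tmm: np.ndarray
    tmi: np.ndarray
    tmd: np.ndarray
    tmo: np.ndarray
    tim: np.ndarray
    tii: np.ndarray
    tdm: np.ndarray
    tdd: np.ndarray
    begin: np.ndarray
    z_cont: float = 0.9999
    z_exit: float = 0.0001
    o_cont: float = 0.9999
    o_exit: float = 0.0001
    local_mode: bool = False
    flanking_insertion_allowed: bool = False
    #: escape hatch for representing hand-edited, off-topology transitions;
    #: always empty for models built by this package (validate() flags them)
    extra_transitions: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.match_emissions.shape[0]

    def copy(self) -> "ProfileHMM":
        kw = {
            f: (getattr(self, f).copy() if isinstance(getattr(self, f), np.ndarray)
                else getattr(self, f))
            for f in self.__dataclass_fields__
        }
        kw["extra_transitions"] = dict(self.extra_transitions)
        return ProfileHMM(**kw)

    # -- convenience views used by the trainers ---------------------------

    def m_out(self, p: int) -> np.ndarray:
        """Out-transition distribution of M_{p+1} (0-based p)."""
        return np.array([self.tmm[p], self.tmi[p], self.tmd[p], self.tmo[p]])

    def set_m_out(self, p: int, probs: np.ndarray) -> None:
        self.tmm[p], self.tmi[p], self.tmd[p], self.tmo[p] = probs


@dataclass(frozen=True)
class State:
    role: str       # Begin | DeletionIn | Match | Insertion | Deletion | DeletionOut | End
    position: int   # 1-based model position; 0 for non-positional states


@dataclass(frozen=True)
class StateOrdering:
    """Canonical banded ordering: Begin, DeletionIn, (M_p, I_p, D_p) for
    p = 1..n, DeletionOut, End."""

    states: tuple

    def index(self, role: str, position: int = 0) -> int:
        return self.states.index(State(role, position))

    def __len__(self) -> int:
        return len(self.states)


def build_plan7(n_positions: int, alphabet: Alphabet = DNA,
                local_mode: bool = False) -> ProfileHMM:
    """Build a Plan 7 profile with the default starting parameters.

    Local mode uses the transposon-study starting values (M->DeletionOut
    .9, M->M .095, M->I .0025, M->D .0025; Begin -> DeletionIn .9 / M1 .09
    / D1 .01; flanking chains continue .9999 / exit .0001; insertion and
    deletion gap extend/end both .5).  Global mode uses documented
    uniform-ish defaults.  Emissions start uniform in both modes.
    """
    if n_positions < 1:
        raise InvalidModelError(f"n_positions must be >= 1, got {n_positions}")
    d = LOCAL_DEFAULTS if local_mode else GLOBAL_DEFAULTS
    n, A = n_positions, alphabet.size
    ones = np.ones(n)
    model = ProfileHMM(
        alphabet=alphabet,
        match_emissions=np.full((n, A), 1.0 / A),
        insert_emissions=np.full(A, 1.0 / A),
        tmm=ones * d["tmm"], tmi=ones * d["tmi"],
        tmd=ones * d["tmd"], tmo=ones * d["tmo"],
        tim=ones * d["tim"], tii=ones * d["tii"],
        tdm=ones * d["tdm"], tdd=ones * d["tdd"],
        begin=np.array(d["begin"], dtype=float),
        z_cont=d["flank"][0], z_exit=d["flank"][1],
        o_cont=d["flank"][0], o_exit=d["flank"][1],
        local_mode=local_mode,
    )
    return model


def canonical_ordering(model: ProfileHMM) -> StateOrdering:
    """The banded state ordering: Begin, DeletionIn, per-position M/I/D,
    DeletionOut, End (3n + 4 states)."""
    states = [State("Begin", 0), State("DeletionIn", 0)]
    for p in range(1, model.n_positions + 1):
        states += [State("Match", p), State("Insertion", p), State("Deletion", p)]
    states += [State("DeletionOut", 0), State("End", 0)]
    return StateOrdering(tuple(states))


def transition_edges(model: ProfileHMM):
    """Enumerate the model's transitions as (from_state, to_state, prob).

    The flanking deletion chains appear in collapsed form: a self-loop
    (advancing chain coverage by one position) plus the boundary edges
    Begin->DeletionIn, DeletionIn->M1, M_p->DeletionOut, DeletionOut->End.
    On a global-mode model all flanking edges carry probability zero, so
    the nonzero edge set is exactly the banded Plan 7 core.
    """
    n = model.n_positions
    B, Z = State("Begin", 0), State("DeletionIn", 0)
    O, E = State("DeletionOut", 0), State("End", 0)
    M = lambda p: State("Match", p)
    I = lambda p: State("Insertion", p)
    D = lambda p: State("Deletion", p)

    edges = [
        (B, M(1), model.begin[0]),
        (B, D(1), model.begin[1]),
        (B, Z, model.begin[2]),
        (Z, Z, model.z_cont if model.begin[2] > 0 else 0.0),
        (Z, M(1), model.z_exit if model.begin[2] > 0 else 0.0),
        (O, O, model.o_cont if np.any(model.tmo > 0) else 0.0),
        (O, E, model.o_exit if np.any(model.tmo > 0) else 0.0),
    ]
    for p in range(1, n + 1):
        i = p - 1
        mnext = M(p + 1) if p < n else E
        dnext = D(p + 1) if p < n else E
        edges += [
            (M(p), mnext, model.tmm[i]),
            (M(p), I(p), model.tmi[i]),
            (M(p), dnext, model.tmd[i]),
            (M(p), O, model.tmo[i]),
            (I(p), mnext, model.tim[i]),
            (I(p), I(p), model.tii[i]),
            (D(p), mnext, model.tdm[i]),
            (D(p), dnext, model.tdd[i]),
        ]
    for (a, b), prob in model.extra_transitions.items():
        edges.append((a, b, prob))
    return edges


def max_advancing_offset(model: ProfileHMM) -> int:
    """Max (j - i) over nonzero, non-self transitions under the canonical
    ordering.  Plan 7's banded structure gives 5 (M_p -> D_{p+1})."""
    ordering = canonical_ordering(model)
    best = 0
    for a, b, prob in transition_edges(model):
        if prob <= 0 or a == b:
            continue
        best = max(best, ordering.index(b.role, b.position)
                   - ordering.index(a.role, a.position))
    return best


def _check_dist(report, where, vec, tol):
    s = float(np.sum(vec))
    if abs(s - 1.0) > tol:
        report.append(f"normalization: {where} sums to {s!r}")
    if np.any(np.asarray(vec) < 0):
        report.append(f"normalization: {where} has negative entries")


def validate(model: ProfileHMM, floor: float | None = None,
             tol: float = 1e-9) -> list:
    """Report every violated invariant (empty list iff the model is valid).

    Checks each emission vector and out-transition group for normalization,
    optionally that all free parameters respect ``floor``, and that no
    off-topology (e.g. Insertion<->Deletion) transitions are present.
    """
    report: list[str] = []
    n = model.n_positions
    if n < 1:
        report.append("topology: model has no positions")
        return report
    for p in range(n):
        _check_dist(report, f"match emission at position {p + 1}",
                    model.match_emissions[p], tol)
    _check_dist(report, "insert emission", model.insert_emissions, tol)
    for p in range(n):
        _check_dist(report, f"M out-group at position {p + 1}",
                    [model.tmm[p], model.tmi[p], model.tmd[p], model.tmo[p]], tol)
        _check_dist(report, f"I out-group at position {p + 1}",
                    [model.tim[p], model.tii[p]], tol)
        _check_dist(report, f"D out-group at position {p + 1}",
                    [model.tdm[p], model.tdd[p]], tol)
    _check_dist(report, "Begin out-group", model.begin, tol)
    _check_dist(report, "DeletionIn group", [model.z_cont, model.z_exit], tol)
    _check_dist(report, "DeletionOut group", [model.o_cont, model.o_exit], tol)
    if not model.local_mode:
        if model.begin[2] != 0.0:
            report.append("topology: global-mode model enters DeletionIn")
        if np.any(model.tmo != 0.0):
            report.append("topology: global-mode model enters DeletionOut")
    if model.flanking_insertion_allowed:
        report.append("topology: flanking insertions are not supported")
    allowed_pairs = {
        ("Begin", "Match"), ("Begin", "Deletion"), ("Begin", "DeletionIn"),
        ("DeletionIn", "DeletionIn"), ("DeletionIn", "Match"),
        ("Match", "Match"), ("Match", "Insertion"), ("Match", "Deletion"),
        ("Match", "DeletionOut"), ("Match", "End"),
        ("Insertion", "Match"), ("Insertion", "Insertion"), ("Insertion", "End"),
        ("Deletion", "Match"), ("Deletion", "Deletion"), ("Deletion", "End"),
        ("DeletionOut", "DeletionOut"), ("DeletionOut", "End"),
    }
    for (a, b), prob in model.extra_transitions.items():
        if prob > 0 and (a.role, b.role) not in allowed_pairs:
            report.append(f"topology: forbidden transition {a.role}->{b.role}")
    if floor is not None:
        for name, group in free_parameter_groups(model):
            g = np.asarray(group, dtype=float)
            if np.any(g < floor - 1e-15):
                report.append(f"floor: {name} has a parameter below {floor}")
    return report


def free_parameter_groups(model: ProfileHMM):
    """Yield (name, values) for every free multinomial parameter group.

    The per-position groups are the match emission and the M/I/D
    out-transition groups; the state-independent groups are the insert
    emission, the Begin group and (local mode) the flanking chains.  In
    global mode the structurally-zero flanking entries are not free.
    """
    n = model.n_positions
    for p in range(n):
        yield (f"match_emission[{p + 1}]", model.match_emissions[p])
    for p in range(n):
        if model.local_mode:
            yield (f"M_out[{p + 1}]",
                   np.array([model.tmm[p], model.tmi[p], model.tmd[p], model.tmo[p]]))
        else:
            yield (f"M_out[{p + 1}]",
                   np.array([model.tmm[p], model.tmi[p], model.tmd[p]]))
        yield (f"I_out[{p + 1}]", np.array([model.tim[p], model.tii[p]]))
        yield (f"D_out[{p + 1}]", np.array([model.tdm[p], model.tdd[p]]))
    yield ("insert_emission", model.insert_emissions)
    if model.local_mode:
        yield ("begin", model.begin)
        yield ("deletion_in", np.array([model.z_cont, model.z_exit]))
        yield ("deletion_out", np.array([model.o_cont, model.o_exit]))
    else:
        yield ("begin", model.begin[:2])
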