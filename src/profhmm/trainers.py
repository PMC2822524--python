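"""Baum-Welch and Conditional Baum-Welch parameter estimation.

Both trainers maximise the (Dirichlet-smoothed) posterior of a Plan 7
profile HMM given a set of unaligned sequences.

Baum-Welch (BW) is classical EM: a full forward-backward pass yields
expected usage counts for every emission and transition, and all
parameter groups are re-estimated at once from (counts + pseudocounts),
normalised, floored and renormalised.

Conditional Baum-Welch (CBW) is the ECM variant: each model position's
parameter group (its match emission plus its M/I/D out-transitions) is
re-estimated *conditionally*, holding every other group at its current
value, sweeping positions in ascending order and finishing with the
state-independent parameters (insert emission, Begin, flanking chains).
The banded state ordering makes this as cheap as one BW iteration:
forward rows are recomputed incrementally as the sweep advances (rows
before the active position depend only on already-updated groups, and
backward rows after it only on not-yet-updated groups), and the
per-sequence likelihood needed to normalise the counts comes from a cut
identity at the active row — every path either matches position p,
deletes it through D_p, or bypasses it through a flanking chain.

Each conditional update is an exact ECM step, so the log-posterior is
nondecreasing after every one of them (up to the parameter floor, which
rarely binds).  Convergence is declared when the average Euclidean
distance of all free parameter groups between successive iterations
drops below ``convergence_tol`` (1e-5 in the simulation regime, 1e-7 in
the transposon regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dp_engine import RowBatch, Sequence
from .model_surgery import (
    SurgeryConfig,
    SurgeryState,
    apply_surgery,
    decide_actions,
    position_usage,
)
from .profile_model import (
    LOCAL_DEFAULTS,
    ProfileHMM,
    free_parameter_groups,
)

__all__ = [
    "ExpectedCounts",
    "Priors",
    "TrainingConfig",
    "TraceRecord",
    "TrainingTrace",
    "DegenerateUpdateError",
    "expected_counts",
    "maximize",
    "floor_distribution",
    "convergence_distance",
    "log_posterior",
    "bw_train",
    "cbw_train",
    "train",
]


class DegenerateUpdateError(ValueError):
    """A parameter group had zero total weight (no counts, no prior)."""


@dataclass
class ExpectedCounts:
    """Expected usage counts from one E-step.

    Per-position arrays have length n; ``match`` is (n, A).  The
    per-sequence insertion/deletion count matrices (S, n) are retained
    for Dynamic Model Surgery.  ``begin`` is ordered (M1, D1, DeletionIn),
    ``z``/``o`` are (continue, exit) for the flanking chains.
    """

    match: np.ndarray
    insert: np.ndarray
    mm: np.ndarray
    mi: np.ndarray
    md: np.ndarray
    mo: np.ndarray
    im: np.ndarray
    ii: np.ndarray
    dm: np.ndarray
    dd: np.ndarray
    begin: np.ndarray
    z: np.ndarray
    o: np.ndarray
    per_seq_ins: np.ndarray
    per_seq_del: np.ndarray
    log_likelihoods: np.ndarray


@dataclass
class Priors:
    """Dirichlet pseudocounts per parameter-group type.

    Scalars broadcast over the group; the default of 1 everywhere is the
    add-one (Laplace) prior.  The transposon regime uses the local-mode
    starting values as transition pseudocounts, scaled by the initial
    profile length to reflect their use at every position.
    """

    match: float | np.ndarray = 1.0
    insert: float | np.ndarray = 1.0
    m_out: float | np.ndarray = 1.0
    i_out: float | np.ndarray = 1.0
    d_out: float | np.ndarray = 1.0
    begin: float | np.ndarray = 1.0
    z: float | np.ndarray = 1.0
    o: float | np.ndarray = 1.0

    @classmethod
    def laplace(cls) -> "Priors":
        return cls()

    @classmethod
    def transposon(cls, initial_length: int) -> "Priors":
        """Weak Dirichlet priors for the transposon regime: Laplace on
        match emissions; other groups centred on their starting values,
        transitions scaled by the initial profile length."""
        d = LOCAL_DEFAULTS
        s = float(initial_length)
        return cls(
            match=1.0,
            insert=np.full(4, 0.25),
            m_out=np.array([d["tmm"], d["tmi"], d["tmd"], d["tmo"]]) * s,
            i_out=np.array([d["tim"], d["tii"]]) * s,
            d_out=np.array([d["tdm"], d["tdd"]]) * s,
            begin=np.array(d["begin"]),
            z=np.array(d["flank"]) * s,
            o=np.array(d["flank"]) * s,
        )

    def for_group(self, name: str, size: int) -> np.ndarray:
        key = {"match_emission": "match", "insert_emission": "insert",
               "M_out": "m_out", "I_out": "i_out", "D_out": "d_out",
               "begin": "begin", "deletion_in": "z", "deletion_out": "o"}[
                   name.split("[")[0]]
        val = getattr(self, key)
        arr = np.broadcast_to(np.asarray(val, dtype=float), (size,)).copy() \
            if np.ndim(val) == 0 else np.asarray(val, dtype=float)[:size]
        if arr.shape != (size,):
            raise ValueError(f"prior for {name} has wrong size")
        return arr


@dataclass
class TrainingConfig:
    """Algorithm choice, priors, floors, DMS thresholds and stopping
    rules for one training run."""

    algorithm: str = "BW"              # "BW" | "CBW"
    use_dms: bool = False
    priors: Priors = field(default_factory=Priors)
    parameter_floor: float = 1e-5
    convergence_tol: float = 1e-5
    max_iterations: int = 300
    seed: int = 0
    surgery: SurgeryConfig = field(default_factory=SurgeryConfig)

    def __post_init__(self):
        if self.algorithm not in ("BW", "CBW"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0 < self.parameter_floor < 0.25:
            raise ValueError("parameter_floor must lie in (0, 1/|alphabet|)")

    @classmethod
    def simulation(cls, algorithm="CBW", use_dms=True, seed=0,
                   max_iterations=300) -> "TrainingConfig":
        """Simulation-study settings: Laplace priors, tol 1e-5, DMS with
        xi starting at .01 escalating by .005, nu = .5."""
        return cls(algorithm=algorithm, use_dms=use_dms, seed=seed,
                   priors=Priors.laplace(), convergence_tol=1e-5,
                   max_iterations=max_iterations,
                   surgery=SurgeryConfig(xi0=0.01, epsilon=0.005,
                                         nu_insert=0.5, nu_delete=0.5,
                                         escalation="fixed"))

    @classmethod
    def transposon(cls, initial_length: int, algorithm="CBW", use_dms=True,
                   seed=0, max_iterations=300) -> "TrainingConfig":
        """Transposon-study settings: starting-value priors scaled by the
        initial length, tol 1e-7, DMS with xi starting at .1, nu_insert
        .1 / nu_delete .9, adaptive escalation."""
        return cls(algorithm=algorithm, use_dms=use_dms, seed=seed,
                   priors=Priors.transposon(initial_length),
                   convergence_tol=1e-7, max_iterations=max_iterations,
                   surgery=SurgeryConfig(xi0=0.1, nu_insert=0.1,
                                         nu_delete=0.9,
                                         escalation="adaptive"))


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    log_likelihood: float
    log_posterior: float
    distance: float
    model_length: int
    dms_actions: tuple = ()
    xi: float | None = None


@dataclass
class TrainingTrace:
    records: list = field(default_factory=list)

    def append(self, rec: TraceRecord) -> None:
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def final(self) -> TraceRecord:
        return self.records[-1]


# -- E-step ----------------------------------------------------------------


def _one_hot(rb: RowBatch) -> np.ndarray:
    A = rb.alphabet.size
    oh = np.zeros((rb.S, rb.T, A))
    s_idx, c_idx = np.nonzero(rb.enc >= 0)
    oh[s_idx, c_idx + 1, rb.enc[s_idx, c_idx]] = 1.0
    return oh


def _counts_from_batch(rb: RowBatch) -> ExpectedCounts:
    """Full expected counts from filled forward and backward lattices."""
    m, n, S, T = rb.model, rb.n, rb.S, rb.T
    lhat = rb.likelihoods()
    if np.any(lhat <= 0):
        raise FloatingPointError("a sequence has zero likelihood")
    w = 1.0 / lhat
    oh = _one_hot(rb)

    gM = rb.aM * rb.bM * w[:, None, None]
    gI = rb.aI * rb.bI * w[:, None, None]
    match = np.einsum("scp,sca->pa", gM, oh)
    insert = np.einsum("scp,sca->a", gI, oh)
    per_seq_ins = gI.sum(axis=1)
    per_seq_del = (rb.aD * rb.bD * w[:, None, None]).sum(axis=1)

    AW = rb.aM * w[:, None, None]
    IW = rb.aI * w[:, None, None]
    DW = rb.aD * w[:, None, None]
    endi = rb.endi
    AWend = np.einsum("scp,sc->p", AW, endi)
    IWend = np.einsum("scp,sc->p", IW, endi)
    DWend = np.einsum("scp,sc->p", DW, endi)
    adv = rb.sm[:, 1:, :] * rb.bM[:, 1:, :]          # (S, T-1, n)
    sib = rb.si[:, 1:, None] * rb.bI[:, 1:, :]

    mm = np.empty(n); md = np.empty(n); im = np.empty(n)
    dm = np.empty(n); dd = np.empty(n)
    if n > 1:
        mm[:-1] = m.tmm[:-1] * np.einsum(
            "scp,scp->p", AW[:, :-1, :-1], adv[:, :, 1:])
        im[:-1] = m.tim[:-1] * np.einsum(
            "scp,scp->p", IW[:, :-1, :-1], adv[:, :, 1:])
        dm[:-1] = m.tdm[:-1] * np.einsum(
            "scp,scp->p", DW[:, :-1, :-1], adv[:, :, 1:])
        md[:-1] = m.tmd[:-1] * np.einsum(
            "scp,scp->p", AW[:, :, :-1], rb.bD[:, :, 1:])
        dd[:-1] = m.tdd[:-1] * np.einsum(
            "scp,scp->p", DW[:, :, :-1], rb.bD[:, :, 1:])
    mm[-1] = m.tmm[-1] * AWend[-1]
    md[-1] = m.tmd[-1] * AWend[-1]
    im[-1] = m.tim[-1] * IWend[-1]
    dm[-1] = m.tdm[-1] * DWend[-1]
    dd[-1] = m.tdd[-1] * DWend[-1]
    mi = m.tmi * np.einsum("scp,scp->p", AW[:, :-1, :], sib)
    ii = m.tii * np.einsum("scp,scp->p", IW[:, :-1, :], sib)
    mo = m.tmo * AWend

    # Begin and flanking chains (all entered at column 0)
    if T > 1:
        bmc = m.begin[0] * float((rb.sm[:, 1, 0] * rb.bM[:, 1, 0] * w).sum())
        zent = m.begin[2] * m.z_exit * m.z_cont ** np.arange(n)
        zterm = zent[None, :] * rb.sm[:, 1, :] * rb.bM[:, 1, :] * w[:, None]
    else:
        bmc = 0.0
        zterm = np.zeros((S, n))
    zrunoff = m.begin[2] * m.z_cont ** n * endi[:, 0] * w
    bdc = m.begin[1] * float((rb.bD[:, 0, 0] * w).sum())
    bzc = float(zterm.sum() + zrunoff.sum())
    zc = float((np.arange(n) * zterm).sum() + n * zrunoff.sum())
    ze = float(zterm.sum())

    from .dp_engine import _o_expectations
    e_cont, e_exit = _o_expectations(m)
    enter_o = m.tmo * AWend
    oc = float((enter_o * e_cont).sum())
    oe = float((enter_o * e_exit).sum())

    return ExpectedCounts(
        match=match, insert=insert, mm=mm, mi=mi, md=md, mo=mo,
        im=im, ii=ii, dm=dm, dd=dd,
        begin=np.array([bmc, bdc, bzc]), z=np.array([zc, ze]),
        o=np.array([oc, oe]),
        per_seq_ins=per_seq_ins, per_seq_del=per_seq_del,
        log_likelihoods=rb.log_likelihoods(),
    )


def expected_counts(model: ProfileHMM, seqs: list[Sequence]) -> ExpectedCounts:
    """One full E-step: expected emission/transition usage counts over a
    sequence set, with per-sequence insertion/deletion counts retained."""
    if not seqs:
        raise ValueError("expected_counts requires at least one sequence")
    rb = RowBatch(model, seqs)
    rb.forward_fill()
    rb.backward_fill()
    return _counts_from_batch(rb)


# -- M-step ----------------------------------------------------------------


def floor_distribution(p: np.ndarray, floor: float) -> np.ndarray:
    """Normalise, then enforce a minimum value on every entry while
    keeping the distribution proper (small entries are pinned at the
    floor and the remainder rescaled; iterated until stable)."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DegenerateUpdateError("parameter group has zero total weight")
    p = p / total
    if floor <= 0:
        return p
    if floor * len(p) >= 1.0:
        raise ValueError("floor too large for the group size")
    for _ in range(len(p) + 1):
        low = p < floor
        if not low.any():
            return p
        k = int(low.sum())
        p = np.where(low, floor, p * (1.0 - k * floor) / p[~low].sum())
    return p


def _update(counts, pseudo, floor) -> np.ndarray:
    return floor_distribution(np.asarray(counts, dtype=float) + pseudo, floor)


def maximize(model: ProfileHMM, counts: ExpectedCounts, priors: Priors,
             floor: float = 1e-5) -> ProfileHMM:
    """MAP M-step: every free group becomes (counts + pseudocounts)
    normalised, floored at ``floor`` and renormalised."""
    new = model.copy()
    n = model.n_positions
    pm = priors.for_group("match_emission", model.alphabet.size)
    for p in range(n):
        new.match_emissions[p] = _update(counts.match[p], pm, floor)
        if model.local_mode:
            pr = priors.for_group("M_out", 4)
            new.set_m_out(p, _update(
                [counts.mm[p], counts.mi[p], counts.md[p], counts.mo[p]],
                pr, floor))
        else:
            pr = priors.for_group("M_out", 3)
            mm, mi, md = _update(
                [counts.mm[p], counts.mi[p], counts.md[p]], pr, floor)
            new.tmm[p], new.tmi[p], new.tmd[p], new.tmo[p] = mm, mi, md, 0.0
        new.tim[p], new.tii[p] = _update(
            [counts.im[p], counts.ii[p]], priors.for_group("I_out", 2), floor)
        new.tdm[p], new.tdd[p] = _update(
            [counts.dm[p], counts.dd[p]], priors.for_group("D_out", 2), floor)
    new.insert_emissions = _update(
        counts.insert, priors.for_group("insert_emission", model.alphabet.size),
        floor)
    if model.local_mode:
        new.begin = _update(counts.begin, priors.for_group("begin", 3), floor)
        new.z_cont, new.z_exit = _update(
            counts.z, priors.for_group("deletion_in", 2), floor)
        new.o_cont, new.o_exit = _update(
            counts.o, priors.for_group("deletion_out", 2), floor)
    else:
        bm, bd = _update(counts.begin[:2], priors.for_group("begin", 2), floor)
        new.begin = np.array([bm, bd, 0.0])
    return new


def convergence_distance(old: ProfileHMM, new: ProfileHMM) -> float:
    """Average over free parameter groups of the Euclidean norm of each
    group's change (the convergence statistic; scale-stable under DMS
    length changes)."""
    old_groups = list(free_parameter_groups(old))
    new_groups = list(free_parameter_groups(new))
    if len(old_groups) != len(new_groups):
        raise ValueError("models have different parameter shapes")
    total = 0.0
    for (na, ga), (nb, gb) in zip(old_groups, new_groups):
        if na != nb or len(ga) != len(gb):
            raise ValueError(f"parameter group mismatch: {na} vs {nb}")
        total += float(np.linalg.norm(np.asarray(ga) - np.asarray(gb)))
    return total / len(old_groups)


def log_posterior(model: ProfileHMM, priors: Priors,
                  total_log_likelihood: float) -> float:
    """The training objective: log-likelihood plus the Dirichlet
    pseudocount term sum(pseudo * log theta) over all free groups."""
    term = 0.0
    for name, group in free_parameter_groups(model):
        pseudo = priors.for_group(name, len(group))
        term += float(np.dot(pseudo, np.log(np.asarray(group, dtype=float))))
    return total_log_likelihood + term


# -- training loops --------------------------------------------------------


def _dms_step(model, counts_like, state, config, per_seq_all):
    """Shared DMS cadence: decide from this iteration's usage, apply,
    observe for cycle escalation.  Returns (model, actions).

    A proposal touching more than ``noise_fraction`` of the positions
    means xi is below the posterior noise floor (genuine misalignments
    are sparse and have near-unit expected counts): the threshold is
    escalated instead of editing.  Surgery stops for the rest of the run
    once the model length has settled."""
    if state.frozen:
        return model, []
    usage = position_usage(counts_like, state.xi)
    actions = decide_actions(usage, config.surgery)
    n = model.n_positions
    if len(actions) > max(2, int(config.surgery.noise_fraction * n)):
        state.escalate(per_seq_all)
        return model, []
    if actions:
        model, _ = apply_surgery(model, actions)
        state.note_event(model.n_positions)
    state.observe(model.n_positions, actions, per_seq_all)
    return model, actions


class _PerSeq:
    """Minimal carrier of per-sequence counts for position_usage."""

    def __init__(self, ins, dele):
        self.per_seq_ins = ins
        self.per_seq_del = dele


def bw_train(model: ProfileHMM, seqs: list[Sequence],
             config: TrainingConfig):
    """Baum-Welch training (optionally with Dynamic Model Surgery).

    Returns (trained model, trace).  Each trace record reports the
    objective at the parameters used for that iteration's E-step.
    """
    if not seqs or max(len(s) for s in seqs) == 0:
        raise ValueError("training requires nonempty sequences")
    model = model.copy()
    rb = RowBatch(model, seqs)
    trace = TrainingTrace()
    state = SurgeryState(config.surgery) if config.use_dms else None
    for it in range(1, config.max_iterations + 1):
        rb.set_model(model)
        rb.forward_fill()
        rb.backward_fill()
        counts = _counts_from_batch(rb)
        ll = float(counts.log_likelihoods.sum())
        lp = log_posterior(model, config.priors, ll)
        new_model = maximize(model, counts, config.priors,
                             config.parameter_floor)
        dist = convergence_distance(model, new_model)
        model = new_model
        actions = ()
        xi = None
        if state is not None:
            xi = state.xi
            if dist < config.surgery.stability_threshold:
                per_all = np.concatenate([counts.per_seq_ins.ravel(),
                                          counts.per_seq_del.ravel()])
                model, acts = _dms_step(model, counts, state, config, per_all)
                actions = tuple(acts)
                if actions:
                    rb = RowBatch(model, seqs)
        trace.append(TraceRecord(it, ll, lp, dist, model.n_positions,
                                 actions, xi))
        if dist < config.convergence_tol and not actions:
            break
    return model, trace


def cbw_train(model: ProfileHMM, seqs: list[Sequence],
              config: TrainingConfig, update_callback=None):
    """Conditional Baum-Welch training (optionally with DMS).

    Sweeps positions 1..n in ascending order, re-estimating each
    position's parameter group conditionally on all others with
    incrementally recomputed forward rows, then updates the
    state-independent parameters.  ``update_callback(model)`` is invoked
    after every conditional update (used to verify per-update
    monotonicity on small instances).

    Returns (trained model, trace).
    """
    if not seqs or max(len(s) for s in seqs) == 0:
        raise ValueError("training requires nonempty sequences")
    model = model.copy()
    rb = RowBatch(model, seqs)
    trace = TrainingTrace()
    state = SurgeryState(config.surgery) if config.use_dms else None
    floor = config.parameter_floor
    pr = config.priors
    A = model.alphabet.size

    for it in range(1, config.max_iterations + 1):
        rb.set_model(model)
        rb.forward_fill()
        rb.backward_fill()
        lls = rb.log_likelihoods()
        ll = float(lls.sum())
        lp = log_posterior(model, pr, ll)
        old = model.copy()
        n, S, T = rb.n, rb.S, rb.T
        oh = _one_hot(rb)
        endi = rb.endi
        per_ins = np.zeros((S, n))
        per_del = np.zeros((S, n))

        # flanking-chain bypass masses for the likelihood cut
        if T > 1:
            zent = model.begin[2] * model.z_exit * model.z_cont ** np.arange(n)
            zterm = zent[None, :] * rb.sm[:, 1, :] * rb.bM[:, 1, :]
        else:
            zterm = np.zeros((S, n))
        zrunoff = model.begin[2] * model.z_cont ** n * endi[:, 0]
        rev = np.cumsum(zterm[:, ::-1], axis=1)[:, ::-1]
        zsuf = np.zeros((S, n))
        if n > 1:
            zsuf[:, :-1] = rev[:, 1:]
        obp = np.zeros(S)

        for p in range(n):
            rb.forward_row(p)
            aMp, aIp, aDp = rb.aM[:, :, p], rb.aI[:, :, p], rb.aD[:, :, p]
            bMp, bIp, bDp = rb.bM[:, :, p], rb.bI[:, :, p], rb.bD[:, :, p]
            lhat = ((aMp * bMp + aDp * bDp).sum(axis=1)
                    + zsuf[:, p] + zrunoff + obp)
            if np.any(lhat <= 0):
                raise FloatingPointError("zero likelihood during CBW sweep")
            w = 1.0 / lhat
            gM = aMp * bMp * w[:, None]
            em = np.einsum("sc,sca->a", gM, oh)
            gI = aIp * bIp * w[:, None]
            per_ins[:, p] = gI.sum(axis=1)
            per_del[:, p] = (aDp * bDp * w[:, None]).sum(axis=1)

            AWp = aMp * w[:, None]
            IWp = aIp * w[:, None]
            DWp = aDp * w[:, None]
            endw = float((AWp * endi).sum())
            last = p == n - 1
            if last:
                mm_c = model.tmm[p] * endw
                md_c = model.tmd[p] * endw
                im_c = model.tim[p] * float((IWp * endi).sum())
                dend = float((DWp * endi).sum())
                dm_c = model.tdm[p] * dend
                dd_c = model.tdd[p] * dend
            else:
                adv = rb.sm[:, 1:, p + 1] * rb.bM[:, 1:, p + 1]
                mm_c = model.tmm[p] * float((AWp[:, :-1] * adv).sum())
                md_c = model.tmd[p] * float((AWp * rb.bD[:, :, p + 1]).sum())
                im_c = model.tim[p] * float((IWp[:, :-1] * adv).sum())
                dm_c = model.tdm[p] * float((DWp[:, :-1] * adv).sum())
                dd_c = model.tdd[p] * float((DWp * rb.bD[:, :, p + 1]).sum())
            sib = rb.si[:, 1:] * bIp[:, 1:]
            mi_c = model.tmi[p] * float((AWp[:, :-1] * sib).sum())
            ii_c = model.tii[p] * float((IWp[:, :-1] * sib).sum())
            mo_c = model.tmo[p] * endw

            # conditional M-step for this position's group
            model.match_emissions[p] = _update(
                em, pr.for_group("match_emission", A), floor)
            if model.local_mode:
                model.set_m_out(p, _update([mm_c, mi_c, md_c, mo_c],
                                           pr.for_group("M_out", 4), floor))
            else:
                mm2, mi2, md2 = _update([mm_c, mi_c, md_c],
                                        pr.for_group("M_out", 3), floor)
                model.tmm[p], model.tmi[p], model.tmd[p] = mm2, mi2, md2
            model.tim[p], model.tii[p] = _update(
                [im_c, ii_c], pr.for_group("I_out", 2), floor)
            model.tdm[p], model.tdd[p] = _update(
                [dm_c, dd_c], pr.for_group("D_out", 2), floor)

            # refresh this position's forward rows under the new group
            rb.refresh_match_rows(p)
            rb.forward_row(p)
            obp = model.o_cont * (
                obp + (rb.aM[:, :, p] * endi).sum(axis=1) * model.tmo[p])
            if update_callback is not None:
                update_callback(model)

        # state-independent parameters, conditional on the new groups
        rb.backward_fill()
        counts = _counts_from_batch(rb)
        model.insert_emissions = _update(
            counts.insert, pr.for_group("insert_emission", A), floor)
        if model.local_mode:
            model.begin = _update(counts.begin, pr.for_group("begin", 3), floor)
            model.z_cont, model.z_exit = _update(
                counts.z, pr.for_group("deletion_in", 2), floor)
            model.o_cont, model.o_exit = _update(
                counts.o, pr.for_group("deletion_out", 2), floor)
        else:
            bm, bd = _update(counts.begin[:2], pr.for_group("begin", 2), floor)
            model.begin = np.array([bm, bd, 0.0])
        rb.set_model(model)
        if update_callback is not None:
            update_callback(model)

        dist = convergence_distance(old, model)
        actions = ()
        xi = None
        if state is not None:
            xi = state.xi
            if dist < config.surgery.stability_threshold:
                per_all = np.concatenate([per_ins.ravel(), per_del.ravel()])
                model, acts = _dms_step(model, _PerSeq(per_ins, per_del),
                                        state, config, per_all)
                actions = tuple(acts)
                if actions:
                    rb = RowBatch(model, seqs)
        trace.append(TraceRecord(it, ll, lp, dist, model.n_positions,
                                 actions, xi))
        if dist < config.convergence_tol and not actions:
            break
    return model, trace


def train(model: ProfileHMM, seqs: list[Sequence], config: TrainingConfig):
    """Dispatch on ``config.algorithm``."""
    fn = bw_train if config.algorithm == "BW" else cbw_train
    return fn(model, seqs, config)
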