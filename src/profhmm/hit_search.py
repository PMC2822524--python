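"""Shuffle-calibrated local hit search with a trained profile.

A local-mode profile is scanned against a target sequence by repeatedly
extracting the best local Viterbi alignment, recording it when its
log-odds score clears a threshold, masking its span with 'N' (neutral:
zero log-odds contribution) and rescanning until nothing above the
threshold remains.  Hits are therefore non-overlapping per strand; the
reverse strand is scanned on the reverse complement with coordinates
mapped back to the forward strand.

The score threshold is calibrated empirically against a null: the target
is shuffled (composition-preserving), the shuffled sequence is cut into
non-overlapping windows of twice the model length, and the best local
score in each window forms the null score sample.  The threshold is the
smallest score such that strictly greater scores make up at most
``top_fraction`` (default 5%) of the null sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dp_engine import LocalAlignment, Sequence, viterbi_local
from .profile_model import ProfileHMM

__all__ = [
    "Hit",
    "as_search_model",
    "threshold_from_scores",
    "empirical_threshold",
    "scan",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMP)[::-1]


@dataclass
class Hit:
    """One profile hit on a target: 1-based inclusive forward-strand
    coordinates, strand, log-odds score, and a pairwise alignment as
    (consensus row, annotation row, target row)."""

    target_id: str
    start: int
    end: int
    strand: str
    score: float
    alignment: tuple = field(default=("", "", ""))

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit start must not exceed end")


def as_search_model(model: ProfileHMM, exit_prob: float = 0.01,
                    begin=(0.50, 0.01, 0.49),
                    flank_cont: float = 0.9) -> ProfileHMM:
    """Convert a trained profile into a local-mode search model.

    Keeps the trained emissions and core transitions (M-out rescaled to
    make room for a mild per-position DeletionOut exit) and installs
    scanning-friendly flanking parameters: entry anywhere through the
    DeletionIn chain at a small per-position cost, exit anywhere at
    ``exit_prob``.  Training-time flanking probabilities are shaped by
    the training set's coverage, not by what makes a good scanner, so
    scanning always goes through this conversion for global-mode models
    (and may re-apply it to local-mode ones).
    """
    new = model.copy()
    core = np.vstack([new.tmm, new.tmi, new.tmd])
    core = core / core.sum(axis=0) * (1.0 - exit_prob)
    new.tmm, new.tmi, new.tmd = core[0], core[1], core[2]
    new.tmo = np.full(new.n_positions, exit_prob)
    new.begin = np.asarray(begin, dtype=float)
    new.z_cont = new.o_cont = flank_cont
    new.z_exit = new.o_exit = 1.0 - flank_cont
    new.local_mode = True
    return new


def threshold_from_scores(scores, top_fraction: float = 0.05) -> float:
    """Smallest observed score such that strictly greater scores comprise
    at most ``top_fraction`` of the sample."""
    s = np.sort(np.asarray(list(scores), dtype=float))[::-1]
    if s.size == 0:
        raise ValueError("no scores to calibrate a threshold from")
    k = int(np.floor(top_fraction * s.size))
    return float(s[min(k, s.size - 1)])


def empirical_threshold(model: ProfileHMM, shuffled_target: Sequence,
                        top_fraction: float = 0.05):
    """Calibrate the hit-score threshold on a shuffled target.

    Returns (threshold, null scores).  With no scorable windows a
    sentinel accept-all threshold (-inf) is returned with a warning.
    """
    window = max(2 * model.n_positions, 50)
    resid = shuffled_target.residues
    scores = []
    for lo in range(0, max(len(resid), 1), window):
        chunk = resid[lo:lo + window]
        if not chunk:
            continue
        aln = viterbi_local(model, Sequence(f"w{lo}", chunk))
        if not aln.empty:
            scores.append(aln.score)
    if not scores:
        warnings.warn("no hits on the shuffled target; accepting all hits")
        return float("-inf"), []
    return threshold_from_scores(scores, top_fraction), scores


def _consensus(model: ProfileHMM) -> str:
    return "".join(model.alphabet.symbols[i]
                   for i in np.argmax(model.match_emissions, axis=1))


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _alignment_rows(model: ProfileHMM, aln: LocalAlignment,
                    segment: str) -> tuple:
    """Render a Viterbi path as (consensus row, annotation row, target
    row); annotation: space = match, 'i' transition, 'v' transversion,
    '-' gap (cross_match-style)."""
    cons = _consensus(model)
    top, mid, bot = [], [], []
    t = 0
    for role, pos in aln.path:
        if role == "M":
            c, r = cons[pos - 1], segment[t]
            t += 1
            top.append(c)
            bot.append(r)
            if c == r.upper():
                mid.append(" ")
            elif (c, r.upper()) in _TRANSITIONS:
                mid.append("i")
            else:
                mid.append("v")
        elif role == "I":
            top.append("-")
            mid.append("-")
            bot.append(segment[t])
            t += 1
        else:  # deletion
            top.append(cons[pos - 1])
            mid.append("-")
            bot.append("-")
    return "".join(top), "".join(mid), "".join(bot)


def _scan_strand(model, resid, target_id, threshold, strand, max_hits):
    K = len(resid)
    work = list(resid)
    hits = []
    while len(hits) < max_hits:
        aln = viterbi_local(model, Sequence(target_id, "".join(work)))
        if aln.empty or aln.score < threshold:
            break
        segment = resid[aln.start - 1:aln.end]
        rows = _alignment_rows(model, aln, segment)
        if strand == "+":
            start, end = aln.start, aln.end
        else:
            start, end = K - aln.end + 1, K - aln.start + 1
        hits.append(Hit(target_id, start, end, strand, aln.score, rows))
        work[aln.start - 1:aln.end] = "N" * (aln.end - aln.start + 1)
    return hits


def scan(model: ProfileHMM, target: Sequence, threshold: float,
         both_strands: bool = False, max_hits: int = 1000) -> list:
    """All non-overlapping hits scoring at least ``threshold``.

    Greedy best-hit-and-mask per strand; hits are returned sorted by
    forward start coordinate.  Requires a local-mode model.
    """
    hits = _scan_strand(model, target.residues, target.id, threshold,
                        "+", max_hits)
    if both_strands:
        hits += _scan_strand(model, reverse_complement(target.residues),
                             target.id, threshold, "-", max_hits)
    return sorted(hits, key=lambda h: (h.start, h.strand))
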