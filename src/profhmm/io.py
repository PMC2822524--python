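"""Readers and writers: FASTA, profile serialization, training traces,
hit tables, fragment maps, and the HMMER2-style export.

The profile format is a flat, versioned key-value text format storing
every probability vector at full precision (`repr` of float64), so a
serialize -> parse round trip reproduces the model bit for bit.

The HMMER2-style export prepares a local-mode profile for FS-style
search conventions: the null model emission distribution is the
profile's insert emission distribution, the null-model termination and
inter-hit loop termination probabilities are both .25, and every other
probability transfers unchanged, encoded as integer scores
round(1000 * log2(p / null)) in the usual score style.  The target is
semantic fidelity (probabilities recoverable from the document, and the
document stable under parse -> render), not byte compatibility with any
historical hmmbuild output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dp_engine import Sequence
from .hit_search import Hit
from .profile_model import Alphabet, ProfileHMM
from .trainers import TraceRecord, TrainingTrace
from .transitive_eval import GenomeFragment

__all__ = [
    "read_fasta", "write_fasta", "filter_by_length",
    "write_profile", "read_profile",
    "write_trace", "read_trace",
    "write_hits", "read_hits",
    "write_fragments", "read_fragments",
    "export_hmmer2", "parse_hmmer2",
    "RunConfig",
]

PROFILE_FORMAT_VERSION = 1


# -- FASTA -----------------------------------------------------------------


def read_fasta(path) -> list[Sequence]:
    """Read FASTA records (multi-line bodies supported), preserving
    order and ids and upper-casing residues."""
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise ValueError(f"{path}: empty FASTA file (line 1)")
        if not first[1].startswith(">"):
            raise ValueError(
                f"{path}: malformed FASTA header at line {first[0]}")
    records = list(SeqIO.parse(path, "fasta"))
    return [Sequence(r.id, str(r.seq).upper()) for r in records]


def write_fasta(seqs, path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    SeqIO.write(records, path, "fasta")


def filter_by_length(seqs, min_length: int) -> list[Sequence]:
    """Keep sequences of at least ``min_length`` residues, stable order
    (the transposon study keeps elements of >= 150 residues)."""
    return [s for s in seqs if len(s) >= min_length]


# -- profile serialization -------------------------------------------------


def _vec(v) -> str:
    return " ".join(repr(float(x)) for x in np.atleast_1d(v))


def write_profile(model: ProfileHMM, path) -> None:
    n = model.n_positions
    lines = [f"# profhmm profile format v{PROFILE_FORMAT_VERSION}",
             f"alphabet: {model.alphabet.symbols}",
             f"length: {n}",
             f"local_mode: {str(model.local_mode).lower()}",
             f"begin: {_vec(model.begin)}",
             f"deletion_in: {_vec([model.z_cont, model.z_exit])}",
             f"deletion_out: {_vec([model.o_cont, model.o_exit])}",
             f"insert_emissions: {_vec(model.insert_emissions)}"]
    for p in range(n):
        lines.append(f"match_emissions {p + 1}: "
                     f"{_vec(model.match_emissions[p])}")
    for p in range(n):
        t = [model.tmm[p], model.tmi[p], model.tmd[p], model.tmo[p],
             model.tim[p], model.tii[p], model.tdm[p], model.tdd[p]]
        lines.append(f"transitions {p + 1}: {_vec(t)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("# profhmm profile format v"):
        raise ValueError(f"{path}: not a profhmm profile file")
    version = int(lines[0].rsplit("v", 1)[1])
    if version != PROFILE_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported profile format v{version}")
    kv = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        key, _, val = ln.partition(":")
        kv[key.strip()] = val.strip()
    alphabet = Alphabet(kv["alphabet"])
    n = int(kv["length"])
    floats = lambda s: np.array([float(x) for x in s.split()])
    em = np.vstack([floats(kv[f"match_emissions {p + 1}"]) for p in range(n)])
    trans = np.vstack([floats(kv[f"transitions {p + 1}"]) for p in range(n)])
    begin = floats(kv["begin"])
    z = floats(kv["deletion_in"])
    o = floats(kv["deletion_out"])
    return ProfileHMM(
        alphabet=alphabet, match_emissions=em,
        insert_emissions=floats(kv["insert_emissions"]),
        tmm=trans[:, 0].copy(), tmi=trans[:, 1].copy(),
        tmd=trans[:, 2].copy(), tmo=trans[:, 3].copy(),
        tim=trans[:, 4].copy(), tii=trans[:, 5].copy(),
        tdm=trans[:, 6].copy(), tdd=trans[:, 7].copy(),
        begin=begin, z_cont=float(z[0]), z_exit=float(z[1]),
        o_cont=float(o[0]), o_exit=float(o[1]),
        local_mode=kv["local_mode"] == "true",
    )


# -- training trace --------------------------------------------------------

_TRACE_COLS = ["iteration", "log_likelihood", "log_posterior", "distance",
               "model_length", "dms_actions", "xi"]


def write_trace(trace: TrainingTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRACE_COLS) + "\n")
        for r in trace:
            actions = ";".join(f"{kind}@{site}" for kind, site in r.dms_actions)
            fh.write("\t".join([
                str(r.iteration), repr(r.log_likelihood),
                repr(r.log_posterior), repr(r.distance),
                str(r.model_length), actions or "-",
                repr(r.xi) if r.xi is not None else "-",
            ]) + "\n")


def read_trace(path) -> TrainingTrace:
    trace = TrainingTrace()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRACE_COLS:
            raise ValueError(f"{path}: not a profhmm trace file")
        for ln in fh:
            it, ll, lp, dist, length, actions, xi = ln.rstrip("\n").split("\t")
            acts = tuple()
            if actions != "-":
                acts = tuple((k, int(s)) for k, s in
                             (a.split("@") for a in actions.split(";")))
            trace.append(TraceRecord(
                int(it), float(ll), float(lp), float(dist), int(length),
                acts, None if xi == "-" else float(xi)))
    return trace


# -- hits ------------------------------------------------------------------


def write_hits(hits, path, alignments: bool = False) -> None:
    """Tabular hits (id, start, end, strand, score); with
    ``alignments``, cross_match-style alignment blocks follow as
    comment lines."""
    with open(path, "w") as fh:
        fh.write("target_id\tstart\tend\tstrand\tscore\n")
        for h in hits:
            fh.write(f"{h.target_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                     f"{h.score!r}\n")
            if alignments and any(h.alignment):
                for row in h.alignment:
                    fh.write(f"# {row}\n")


def read_hits(path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "target_id\tstart\tend\tstrand\tscore":
            raise ValueError(f"{path}: not a profhmm hits file")
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            tid, start, end, strand, score = ln.rstrip("\n").split("\t")
            hits.append(Hit(tid, int(start), int(end), strand, float(score)))
    return hits


# -- fragment maps ---------------------------------------------------------


def write_fragments(fragments, path) -> None:
    cols = ["a_id", "a_start", "a_end", "a_strand", "row_a",
            "b_id", "b_start", "b_end", "b_strand", "row_b"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for f in fragments:
            fh.write("\t".join(str(getattr(f, c)) for c in cols) + "\n")


def read_fragments(path) -> list[GenomeFragment]:
    frags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["a_id", "a_start"]:
            raise ValueError(f"{path}: not a fragment map file")
        for ln in fh:
            if not ln.strip():
                continue
            v = ln.rstrip("\n").split("\t")
            frags.append(GenomeFragment(
                v[0], int(v[1]), int(v[2]), v[3], v[4],
                v[5], int(v[6]), int(v[7]), v[8], v[9]))
    return frags


# -- HMMER2-style export ---------------------------------------------------


def _score(p: float, null: float = 1.0) -> str:
    if p <= 0:
        return "*"
    return str(int(round(1000.0 * np.log2(p / null))))


def _unscore(s: str, null: float = 1.0) -> float:
    if s == "*":
        return 0.0
    return null * 2.0 ** (int(s) / 1000.0)


def export_hmmer2(model: ProfileHMM, name: str = "profhmm_model") -> str:
    """Serialize a local-mode profile in an HMMER2-style score document
    (see module docstring for the conventions)."""
    if not model.local_mode:
        raise ValueError("HMMER2-style export supports local-mode models only")
    n = model.n_positions
    null = model.insert_emissions
    lines = [
        "HMMER2.0  [profhmm]",
        f"NAME  {name}",
        f"LENG  {n}",
        f"ALPH  Nucleic",
        "NULE  " + " ".join(f"{p:.6f}" for p in null),
        "NULT  0.250000",
        "LOOPT 0.250000",
        "BEGIN " + " ".join(_score(p) for p in model.begin),
        "ZCHN  " + " ".join(_score(p) for p in (model.z_cont, model.z_exit)),
        "OCHN  " + " ".join(_score(p) for p in (model.o_cont, model.o_exit)),
        "HMM      A     C     G     T",
    ]
    for p in range(n):
        mrow = " ".join(_score(model.match_emissions[p, a], null[a])
                        for a in range(4))
        trow = " ".join(_score(x) for x in (
            model.tmm[p], model.tmi[p], model.tmd[p], model.tmo[p],
            model.tim[p], model.tii[p], model.tdm[p], model.tdd[p]))
        lines.append(f"{p + 1:>5} M: {mrow}  T: {trow}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def parse_hmmer2(text: str) -> dict:
    """Decode an exported document back to probabilities (to printed
    precision).  Returns a dict with keys name, length, null,
    null_termination, loop_termination, begin, z, o, match_emissions,
    transitions (n x 8)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines[0].startswith("HMMER2.0"):
        raise ValueError("not an HMMER2-style document")
    doc: dict = {}
    pos_rows = []
    for ln in lines[1:]:
        tag = ln.split()[0]
        rest = ln.split()[1:]
        if tag == "NAME":
            doc["name"] = rest[0]
        elif tag == "LENG":
            doc["length"] = int(rest[0])
        elif tag == "NULE":
            doc["null"] = np.array([float(x) for x in rest])
        elif tag == "NULT":
            doc["null_termination"] = float(rest[0])
        elif tag == "LOOPT":
            doc["loop_termination"] = float(rest[0])
        elif tag == "BEGIN":
            doc["begin"] = np.array([_unscore(s) for s in rest])
        elif tag == "ZCHN":
            doc["z"] = np.array([_unscore(s) for s in rest])
        elif tag == "OCHN":
            doc["o"] = np.array([_unscore(s) for s in rest])
        elif tag in ("ALPH", "HMM", "//"):
            continue
        else:
            pos_rows.append(ln)
    null = doc["null"]
    em = np.zeros((doc["length"], 4))
    tr = np.zeros((doc["length"], 8))
    for ln in pos_rows:
        parts = ln.split()
        p = int(parts[0]) - 1
        m_scores = parts[2:6]
        t_scores = parts[7:15]
        em[p] = [_unscore(s, null[a]) for a, s in enumerate(m_scores)]
        tr[p] = [_unscore(s) for s in t_scores]
    doc["match_emissions"] = em
    doc["transitions"] = tr
    return doc


def render_hmmer2(doc: dict) -> str:
    """Re-render a parsed document (export -> parse -> render is
    byte-identical)."""
    model = ProfileHMM(
        alphabet=Alphabet("ACGT"),
        match_emissions=doc["match_emissions"],
        insert_emissions=doc["null"],
        tmm=doc["transitions"][:, 0], tmi=doc["transitions"][:, 1],
        tmd=doc["transitions"][:, 2], tmo=doc["transitions"][:, 3],
        tim=doc["transitions"][:, 4], tii=doc["transitions"][:, 5],
        tdm=doc["transitions"][:, 6], tdd=doc["transitions"][:, 7],
        begin=doc["begin"], z_cont=doc["z"][0], z_exit=doc["z"][1],
        o_cont=doc["o"][0], o_exit=doc["o"][1], local_mode=True)
    return export_hmmer2(model, name=doc["name"])


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Serializable description of one CLI run: a run is reproducible
    from its config file and seeds alone."""

    subcommand: str
    options: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)
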