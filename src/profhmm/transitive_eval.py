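"""Transitive pileups and transitive pairwise alignments.

Two elements found on different genomes can be compared *transitively*
through a genome-genome fragment alignment: stacking element-A, genome-A,
genome-B and element-B rows column by column (a transitive pileup), then
dropping the genome rows leaves an implied pairwise alignment between the
two elements.  Columns where the genome-genome alignment itself is gapped
cannot possibly align transitively: element residues there are shown in
lowercase, gap symbols as dots '.' instead of dashes, and such *dot-gap*
columns are excluded from all statistics.  The remaining columns are
classified as match, transition (purine<->purine A<->G or
pyrimidine<->pyrimidine C<->T), transversion, or gap; the comparison
score of an alignment is matches + transitions (transitions being the
chemically favoured substitutions, they count as evidence of homology
alongside exact matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeFragment",
    "Pileup",
    "TransitiveAlignment",
    "HitSummary",
    "classify_pair",
    "build_pileup",
    "transitive_align",
    "evaluate_hitsets",
    "render_transitive",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def classify_pair(a: str, b: str) -> str:
    """Classify two aligned residues: match / transition / transversion.

    Case-folded; 'N' against anything counts as the conservative
    transversion class.  Gap characters are rejected (gaps are classified
    at column level, not residue level).
    """
    a, b = a.upper(), b.upper()
    if a in "-." or b in "-.":
        raise ValueError("classify_pair takes residues, not gap characters")
    if a == "N" or b == "N":
        return "transversion"
    if a == b:
        return "match"
    if {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass
class GenomeFragment:
    """One fragment of a genome-genome alignment (chain/net style).

    Coordinates are 1-based inclusive on the forward strand of each
    genome.  ``row_a``/``row_b`` are equal-length gapped alignment rows;
    a '-' strand means the row traverses that genome's forward
    coordinates in reverse (reverse-complemented residues).
    """

    a_id: str
    a_start: int
    a_end: int
    a_strand: str
    row_a: str
    b_id: str
    b_start: int
    b_end: int
    b_strand: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("fragment rows must be column-aligned")
        for row, start, end, name in ((self.row_a, self.a_start, self.a_end, "A"),
                                      (self.row_b, self.b_start, self.b_end, "B")):
            span = end - start + 1
            bases = sum(1 for c in row if c != "-")
            if bases != span:
                raise ValueError(
                    f"fragment {name} row has {bases} residues for a "
                    f"{span}-base interval")

    def key(self):
        return (self.a_id, self.a_start, self.a_end, self.a_strand,
                self.b_id, self.b_start, self.b_end, self.b_strand)


@dataclass
class Pileup:
    """Column-aligned rows: element A, genome A, genome B, element B.
    Element rows are lowercase at dot-gap columns (where the genome-
    genome alignment is gapped) and '-'/'.' where the element is absent."""

    elem_a: str
    gen_a: str
    gen_b: str
    elem_b: str

    @property
    def n_columns(self) -> int:
        return len(self.gen_a)


def _covers(hit, genome_id: str, pos: int) -> bool:
    return hit.target_id == genome_id and hit.start <= pos <= hit.end


def _overlaps(hit, genome_id, start, end) -> bool:
    return hit.target_id == genome_id and hit.start <= end and hit.end >= start


def build_pileup(hit_a, hit_b, fragment: GenomeFragment) -> Pileup:
    """Project two hits through a genome-genome fragment.

    Element rows carry the genome residue wherever the hit covers that
    genome position within the fragment; lowercase marks columns that
    cannot align transitively because the other genome is gapped there.
    Hits that do not overlap the fragment give an empty pileup.
    """
    if not (_overlaps(hit_a, fragment.a_id, fragment.a_start, fragment.a_end)
            and _overlaps(hit_b, fragment.b_id, fragment.b_start,
                          fragment.b_end)):
        return Pileup("", "", "", "")
    ea, eb = [], []
    pos_a = fragment.a_start if fragment.a_strand != "-" else fragment.a_end
    pos_b = fragment.b_start if fragment.b_strand != "-" else fragment.b_end
    step_a = 1 if fragment.a_strand != "-" else -1
    step_b = 1 if fragment.b_strand != "-" else -1
    for ca, cb in zip(fragment.row_a, fragment.row_b):
        dot = ca == "-" or cb == "-"
        if ca == "-":
            ea.append(".")
        else:
            covered = _covers(hit_a, fragment.a_id, pos_a)
            ea.append((ca.lower() if dot else ca.upper()) if covered else
                      ("." if dot else "-"))
            pos_a += step_a
        if cb == "-":
            eb.append(".")
        else:
            covered = _covers(hit_b, fragment.b_id, pos_b)
            eb.append((cb.lower() if dot else cb.upper()) if covered else
                      ("." if dot else "-"))
            pos_b += step_b
    return Pileup("".join(ea), fragment.row_a, fragment.row_b, "".join(eb))


@dataclass
class TransitiveAlignment:
    """Implied pairwise alignment between two elements, with per-column
    classes and the dot-gap-excluded tallies.  ``score`` is matches +
    transitions."""

    elem_a: str
    elem_b: str
    classes: tuple
    matches: int = 0
    transitions: int = 0
    transversions: int = 0
    gaps: int = 0
    dot_gaps: int = 0
    ambiguous: int = 0      # diagnostic: 'N'-involving comparisons

    @property
    def score(self) -> int:
        return self.matches + self.transitions


def transitive_align(pileup: Pileup) -> TransitiveAlignment:
    """Drop the genome rows and classify every column.

    Dot-gap columns (genome-genome gap) are excluded from all tallies;
    remaining columns are match/transition/transversion when both
    elements have residues, otherwise gap.
    """
    classes = []
    tally = {"match": 0, "transition": 0, "transversion": 0,
             "gap": 0, "dot-gap": 0}
    ambiguous = 0
    for ea, eb, ga, gb in zip(pileup.elem_a, pileup.elem_b,
                              pileup.gen_a, pileup.gen_b):
        if ga == "-" or gb == "-":
            classes.append("dot-gap")
            tally["dot-gap"] += 1
            continue
        if ea in "-." or eb in "-.":
            classes.append("gap")
            tally["gap"] += 1
            continue
        cls = classify_pair(ea, eb)
        if "N" in (ea.upper(), eb.upper()):
            ambiguous += 1
        classes.append(cls)
        tally[cls] += 1
    return TransitiveAlignment(
        elem_a=pileup.elem_a, elem_b=pileup.elem_b, classes=tuple(classes),
        matches=tally["match"], transitions=tally["transition"],
        transversions=tally["transversion"], gaps=tally["gap"],
        dot_gaps=tally["dot-gap"], ambiguous=ambiguous)


@dataclass
class HitSummary:
    """Totals over all transitive alignments of two hit sets."""

    n_alignments: int = 0
    matches: int = 0
    transitions: int = 0
    transversions: int = 0
    gaps: int = 0
    alignments: list = field(default_factory=list)

    @property
    def score(self) -> int:
        return self.matches + self.transitions


def evaluate_hitsets(hits_a, hits_b, fragments,
                     deduplicate: bool = True) -> HitSummary:
    """One transitive alignment per (hit A, hit B, fragment) triple with
    mutual overlap; totals are sums over them.  A hit pair aligning
    through several fragments contributes once per fragment; duplicate
    triples (by coordinates) are collapsed when ``deduplicate``."""
    summary = HitSummary()
    seen = set()
    for frag in fragments:
        for ha in hits_a:
            if not _overlaps(ha, frag.a_id, frag.a_start, frag.a_end):
                continue
            for hb in hits_b:
                if not _overlaps(hb, frag.b_id, frag.b_start, frag.b_end):
                    continue
                key = ((ha.target_id, ha.start, ha.end),
                       (hb.target_id, hb.start, hb.end), frag.key())
                if deduplicate and key in seen:
                    continue
                seen.add(key)
                ta = transitive_align(build_pileup(ha, hb, frag))
                summary.n_alignments += 1
                summary.matches += ta.matches
                summary.transitions += ta.transitions
                summary.transversions += ta.transversions
                summary.gaps += ta.gaps
                summary.alignments.append(ta)
    return summary


_ANNOT = {"match": " ", "transition": "i", "transversion": "v",
          "gap": "-", "dot-gap": "."}


def render_transitive(ta: TransitiveAlignment, width: int = 60,
                      name_a: str = "elementA", name_b: str = "elementB") -> str:
    """Text rendering: element rows with a middle annotation row
    (space/i/v/-/.), wrapped, with a statistics footer computed after
    removing dot-gap columns."""
    mid = "".join(_ANNOT[c] for c in ta.classes)
    blocks = []
    for lo in range(0, len(mid), width):
        blocks.append("\n".join([
            f"{name_a:>10} {ta.elem_a[lo:lo + width]}",
            f"{'':>10} {mid[lo:lo + width]}",
            f"{name_b:>10} {ta.elem_b[lo:lo + width]}",
        ]))
    stats = (f"matches: {ta.matches}  transitions: {ta.transitions}  "
             f"transversions: {ta.transversions}  gaps: {ta.gaps}  "
             f"score: {ta.score}")
    return "\n\n".join(blocks + [stats]) + "\n"
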