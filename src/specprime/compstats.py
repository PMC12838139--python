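"""Sequence characterisation: base composition and uncorrected p-distances.

Composition is reported overall and per codon position (classed from each
record's own frame offset on the ungapped sequence, never from alignment
columns).  Distances follow the uncorrected p-distance model with pairwise
deletion: per pair, only sites with unambiguous non-gap bases in both rows
are compared, and gaps/ambiguities are missing data rather than a fifth
character state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .profile import Alignment, alignment_from_rows, species_consensus
from .seqio import SeqRecord, UNAMBIGUOUS

POSITION_CLASSES = ("all", "pos1", "pos2", "pos3")


@dataclass(frozen=True)
class CompositionRow:
    """Percent base composition for one species x position class."""

    species: str
    position_class: str  # "all" | "pos1" | "pos2" | "pos3"
    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    gc_pct: float
    counted_bases: int


@dataclass(frozen=True)
class CompositionTable:
    rows: tuple[CompositionRow, ...]

    def get(self, species: str, position_class: str = "all") -> CompositionRow:
        for row in self.rows:
            if row.species == species and row.position_class == position_class:
                return row
        raise KeyError(f"no composition row for ({species!r}, {position_class!r})")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric species x species p-distance matrix with pairwise-deletion
    denominators (comparable-site counts)."""

    labels: tuple[str, ...]
    p: tuple[tuple[float, ...], ...]
    n_sites: tuple[tuple[int, ...], ...]

    def get(self, a: str, b: str) -> float:
        return self.p[self.labels.index(a)][self.labels.index(b)]

    def pairs(self) -> list[tuple[str, str, float]]:
        """Upper-triangle pairs (a, b, p)."""
        out = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                out.append((a, self.labels[j], self.p[i][j]))
        return out


def _count_composition(chunks: Sequence[str]) -> tuple[dict[str, int], int]:
    counts = {b: 0 for b in "ACGT"}
    for chunk in chunks:
        for base in chunk:
            if base in UNAMBIGUOUS:
                counts[base] += 1
    return counts, sum(counts.values())


def _row(species: str, cls: str, counts: dict[str, int], denom: int) -> CompositionRow:
    if denom == 0:
        return CompositionRow(species, cls, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    pct = {b: 100.0 * counts[b] / denom for b in "ACGT"}
    return CompositionRow(species, cls, pct["A"], pct["T"], pct["G"], pct["C"],
                          pct["G"] + pct["C"], denom)


def base_composition(records: Sequence[SeqRecord],
                     by_codon_position: bool = True) -> CompositionTable:
    """Base composition per species, overall and (optionally) per codon position.

    Percentages are taken over unambiguous A/C/G/T only; ambiguity codes are
    excluded from numerator and denominator alike.  When splitting by codon
    position, each record contributes its complete codons after its own
    frame offset (any trailing partial codon is ignored for the positional
    rows but still counted in the ``all`` row).
    """
    by_species: dict[str, list[SeqRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)

    rows: list[CompositionRow] = []
    for species, recs in by_species.items():
        counts_all, denom_all = _count_composition([r.sequence for r in recs])
        rows.append(_row(species, "all", counts_all, denom_all))
        if not by_codon_position:
            continue
        for pos in (0, 1, 2):
            chunks = []
            for rec in recs:
                body = rec.sequence[rec.frame_offset:]
                n_full = len(body) // 3
                chunks.append(body[pos: 3 * n_full: 3])
            counts, denom = _count_composition(chunks)
            rows.append(_row(species, f"pos{pos + 1}", counts, denom))
    return CompositionTable(rows=tuple(rows))


def _pairwise_p(seq_a: str, seq_b: str) -> tuple[float, int]:
    mismatches = 0
    comparable = 0
    for x, y in zip(seq_a, seq_b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return float("nan"), 0
    return mismatches / comparable, comparable


def p_distance_matrix(alignment: Alignment,
                      collapse: Literal["per_record", "per_species_consensus"]
                      = "per_species_consensus") -> DistanceMatrix:
    """Uncorrected p-distance matrix with pairwise deletion.

    ``per_species_consensus`` first collapses each species to its
    majority-rule consensus (ties become ``N`` and are thereby deleted
    pairwise); ``per_record`` keeps one row per input record.
    """
    if len(alignment.rows) < 2:
        raise ValueError("p_distance_matrix requires >= 2 rows")
    if collapse == "per_species_consensus":
        labels = alignment.species
        seqs = [species_consensus(alignment, sp) for sp in labels]
    elif collapse == "per_record":
        labels = tuple(rec_id for rec_id, _, _ in alignment.rows)
        seqs = [seq for _, _, seq in alignment.rows]
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")

    n = len(labels)
    p = [[0.0] * n for _ in range(n)]
    sites = [[0] * n for _ in range(n)]
    for i in range(n):
        sites[i][i] = sum(1 for b in seqs[i] if b in UNAMBIGUOUS)
        for j in range(i + 1, n):
            pij, nij = _pairwise_p(seqs[i], seqs[j])
            if nij == 0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) has zero comparable sites"
                )
            p[i][j] = p[j][i] = pij
            sites[i][j] = sites[j][i] = nij
    return DistanceMatrix(labels=tuple(labels),
                          p=tuple(tuple(r) for r in p),
                          n_sites=tuple(tuple(r) for r in sites))


def records_to_trivial_alignment(records: Sequence[SeqRecord]) -> Alignment:
    """Treat equal-length ungapped records as already aligned (no indels)."""
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("records differ in length; run codon_aware_align first")
    return alignment_from_rows((r.id, r.species, r.sequence) for r in records)
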