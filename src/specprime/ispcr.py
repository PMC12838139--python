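"""In-silico PCR: mismatch-tolerant binding-site search with a 3'-extension
block, amplicon prediction, and single/mixed-template specificity matrices.

A primer binds wherever its total mismatch count does not exceed
``max_mismatch`` AND its 3'-terminal block (default: the last two bases) is a
perfect match — encoding the observation that even a single mismatch at the
primer's 3' terminus markedly inhibits polymerase extension.  Ambiguous
template bases count as mismatches (conservative).  Semantics are strictly
presence/absence: template dose in a mixture is carried through as an
annotation and never changes whether a band is predicted.

Coordinates are 1-based inclusive on the + strand of the template; amplicon
spans include both primer footprints (gel-size convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .design import PrimerPair
from .seqio import PrimerTableRow, SeqRecord, UNAMBIGUOUS, reverse_complement

MAX_AMPLICON_SCAN = 3000


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str  # "+" | "-"
    three_prime_position: int  # 1-based template coordinate of the primer 3' base
    mismatch_total: int
    mismatches_in_3prime_block: int

    def __post_init__(self) -> None:
        if not self.mismatch_total >= self.mismatches_in_3prime_block >= 0:
            raise ValueError("mismatch counts inconsistent")


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int  # 1-based inclusive, + strand
    end: int
    length: int
    forward_site: BindingSite
    reverse_site: BindingSite

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("length inconsistent with span")


@dataclass(frozen=True)
class MatrixCell:
    """One primer-pair x template-set outcome."""

    amplicon_count: int
    amplicon_lengths: tuple[int, ...]
    template_dose: tuple[tuple[str, int], ...] = ()  # (species, copies) annotation

    @property
    def positive(self) -> bool:
        return self.amplicon_count > 0


@dataclass(frozen=True)
class SpecificityMatrix:
    """Rows: primer pairs (by target species). Columns: template sets."""

    pair_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    cells: tuple[tuple[MatrixCell, ...], ...]  # [pair][column]
    column_members: tuple[tuple[str, ...], ...]  # species making up each column

    def cell(self, pair_label: str, column_label: str) -> MatrixCell:
        return self.cells[self.pair_labels.index(pair_label)][
            self.column_labels.index(column_label)]


def _mismatches(primer: str, window: str) -> list[bool]:
    """Per-position mismatch flags, primer 5'->3' vs the already-oriented window."""
    return [w not in UNAMBIGUOUS or p != w for p, w in zip(primer, window)]


def find_binding_sites(primer: str, template: SeqRecord, max_mismatch: int = 3,
                       block_size: int = 2) -> list[BindingSite]:
    """All qualifying binding sites of *primer* on both strands of *template*.

    A site qualifies iff total mismatches <= *max_mismatch* and the primer's
    3'-terminal *block_size* bases match perfectly.
    """
    primer = primer.upper()
    seq = template.sequence
    n, m = len(seq), len(primer)
    if m > n:
        return []
    sites: list[BindingSite] = []
    for start in range(n - m + 1):
        window = seq[start: start + m]
        # + strand: primer lies along the + strand, 3' end at start+m (1-based)
        flags = _mismatches(primer, window)
        total = sum(flags)
        block = sum(flags[m - block_size:])
        if total <= max_mismatch and block == 0:
            sites.append(BindingSite(template.id, "+", start + m, total, block))
        # - strand: primer anneals to the + strand; its 3' end maps to start+1
        flags = _mismatches(primer, reverse_complement(window))
        total = sum(flags)
        block = sum(flags[m - block_size:])
        if total <= max_mismatch and block == 0:
            sites.append(BindingSite(template.id, "-", start + 1, total, block))
    sites.sort(key=lambda s: (s.three_prime_position, s.strand))
    return sites


def _pair_sequences(pair: "PrimerPair | Sequence[PrimerTableRow]") -> tuple[str, str]:
    if isinstance(pair, PrimerPair):
        return pair.forward.sequence, pair.reverse.sequence
    rows = list(pair)
    if len(rows) != 2:
        raise ValueError("expected exactly two primer table rows (forward, reverse)")
    fwd = next((r for r in rows if r.orientation == "forward"), None)
    rev = next((r for r in rows if r.orientation == "reverse"), None)
    if fwd is None or rev is None:
        raise ValueError("primer rows must contain one forward and one reverse oligo")
    return fwd.sequence, rev.sequence


def predict_amplicons(pair: "PrimerPair | Sequence[PrimerTableRow]",
                      templates: Sequence[SeqRecord], max_mismatch: int = 3,
                      block_size: int = 2,
                      max_amplicon_scan: int = MAX_AMPLICON_SCAN
                      ) -> list[AmpliconPrediction]:
    """All amplicons formed by a + strand forward site and a - strand reverse
    site with 0 < length <= *max_amplicon_scan*, ordered by template then start."""
    fwd, rev = _pair_sequences(pair)
    out: list[AmpliconPrediction] = []
    for template in templates:
        f_sites = [s for s in find_binding_sites(fwd, template, max_mismatch, block_size)
                   if s.strand == "+"]
        r_sites = [s for s in find_binding_sites(rev, template, max_mismatch, block_size)
                   if s.strand == "-"]
        for fs in f_sites:
            start = fs.three_prime_position - len(fwd) + 1
            for rs in r_sites:
                end = rs.three_prime_position + len(rev) - 1
                length = end - start + 1
                if 0 < length <= max_amplicon_scan and fs.three_prime_position < rs.three_prime_position:
                    out.append(AmpliconPrediction(template.id, start, end, length, fs, rs))
    out.sort(key=lambda a: (a.template_id, a.start, a.end))
    return out


def default_mixtures(species: Sequence[str]) -> dict[str, dict[str, int]]:
    """The validation mixture panel: per target species, a '+' mock community
    with all species present and a '-' community of the three non-targets,
    plus the 1:1:1:1 .. 1:4:4:4 gradient series (target : each non-target)."""
    mixtures: dict[str, dict[str, int]] = {"mix_all": {sp: 1 for sp in species}}
    for target in species:
        others = [sp for sp in species if sp != target]
        mixtures[f"mix_minus_{target}"] = {sp: 1 for sp in others}
        for k in (1, 2, 3, 4):
            dose = {target: 1}
            dose.update({sp: k for sp in others})
            mixtures[f"gradient_{target}_1to{k}"] = dose
    return mixtures


def specificity_matrix(pairs: Mapping[str, "PrimerPair | Sequence[PrimerTableRow]"],
                       species_templates: Mapping[str, Sequence[SeqRecord]],
                       mixtures: Mapping[str, Mapping[str, int]] | None = None,
                       max_mismatch: int = 3, block_size: int = 2
                       ) -> SpecificityMatrix:
    """Amplification outcomes of each pair against single-species columns and
    named template mixtures.

    *pairs* maps target-species label -> primer pair.  Copy counts in a
    mixture only annotate template dose; presence/absence of a band depends
    solely on which species are present (a mixture cell is the union of its
    member species' cells).
    """
    species = list(species_templates)
    if mixtures is None:
        mixtures = default_mixtures(species)
    for name, dose in mixtures.items():
        unknown = set(dose) - set(species)
        if unknown:
            raise ValueError(f"mixture {name!r} names unknown species {sorted(unknown)}")

    single_cols = [(sp, {sp: 1}) for sp in species]
    mixture_cols = list(mixtures.items())
    all_cols = single_cols + mixture_cols

    pair_labels = tuple(pairs)
    cells: list[tuple[MatrixCell, ...]] = []
    for label in pair_labels:
        pair = pairs[label]
        per_species: dict[str, list[AmpliconPrediction]] = {
            sp: predict_amplicons(pair, species_templates[sp], max_mismatch, block_size)
            for sp in species
        }
        row: list[MatrixCell] = []
        for _, dose in all_cols:
            amps: list[AmpliconPrediction] = []
            for sp in dose:
                amps.extend(per_species[sp])
            lengths = tuple(sorted(a.length for a in amps))
            row.append(MatrixCell(len(amps), lengths,
                                  tuple(sorted(dose.items()))))
        cells.append(tuple(row))
    return SpecificityMatrix(
        pair_labels=pair_labels,
        column_labels=tuple(name for name, _ in all_cols),
        cells=tuple(cells),
        column_members=tuple(tuple(sorted(dose)) for _, dose in all_cols),
    )
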