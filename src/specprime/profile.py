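"""Codon-aware alignment and per-column variability profiling.

The marker is a protein-coding gene with a conserved reading frame, so
alignment operates in codon units: pairwise global alignment (Gotoh affine
gaps) over codons, joined progressively.  Gaps therefore occur in runs whose
lengths are multiples of three, mirroring the codon-length indels seen between
full-length coding sequences of related species.

Column coordinates are 1-based and inclusive everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import GAP, SeqRecord, UNAMBIGUOUS

#: Per-codon gap penalties on a +1/-1 per-nucleotide identity scale.
#: A run of L gap codons costs GAP_OPEN + GAP_EXTEND * (L - 1).
GAP_OPEN = 8.0
GAP_EXTEND = 2.0


@dataclass(frozen=True)
class Alignment:
    """Column-indexed multiple alignment of species-labelled sequences."""

    rows: tuple[tuple[str, str, str], ...]  # (record id, species, gapped sequence)
    n_columns: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        for rec_id, _, seq in self.rows:
            if len(seq) != self.n_columns:
                raise ValueError(
                    f"row {rec_id!r} has length {len(seq)} != n_columns {self.n_columns}"
                )

    @property
    def species(self) -> tuple[str, ...]:
        """Species labels in first-occurrence order."""
        seen: dict[str, None] = {}
        for _, sp, _ in self.rows:
            seen.setdefault(sp)
        return tuple(seen)

    def rows_for(self, species: str) -> list[tuple[str, str, str]]:
        return [row for row in self.rows if row[1] == species]

    def column(self, coord: int) -> tuple[str, ...]:
        """Bases at a 1-based column, one per row."""
        return tuple(seq[coord - 1] for _, _, seq in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column summary: base counts per species, polymorphism, diagnosticity."""

    coord: int  # 1-based
    counts: dict[str, dict[str, int]]  # species -> {A,C,G,T,gap,ambiguous}
    has_gap_or_ambiguous: bool
    is_polymorphic: bool
    diagnostic_for: str | None


@dataclass(frozen=True)
class SiteProfile:
    """Column-wise profile of an alignment."""

    columns: tuple[ColumnProfile, ...]
    species: tuple[str, ...]
    n_rows: int

    @property
    def polymorphic_coords(self) -> tuple[int, ...]:
        return tuple(c.coord for c in self.columns if c.is_polymorphic)


@dataclass(frozen=True)
class WindowScore:
    """A (possibly merged) alignment interval scored by polymorphic-site density."""

    start: int  # 1-based inclusive
    end: int
    density: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end precedes start")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density outside [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# codon-aware alignment
# ---------------------------------------------------------------------------

def _codon_units(record: SeqRecord) -> tuple[str, list[str], str]:
    """Split a record into (frame prefix, complete codons, trailing partial)."""
    seq = record.sequence
    prefix = seq[: record.frame_offset]
    body = seq[record.frame_offset:]
    n_full = len(body) // 3
    codons = [body[3 * i: 3 * i + 3] for i in range(n_full)]
    suffix = body[3 * n_full:]
    return prefix, codons, suffix


def _codon_score(a: str, b: str) -> float:
    """Summed per-nucleotide identity (+1 match / -1 mismatch) of two codons."""
    return sum(1.0 if x == y else -1.0 for x, y in zip(a, b))


def _profile_column_score(column: Sequence[str], codon: str) -> float:
    """Mean codon score of *codon* against a profile column; gap units score 0."""
    total = 0.0
    n = 0
    for unit in column:
        if unit == GAP * 3:
            continue
        total += _codon_score(unit, codon)
        n += 1
    return total / n if n else 0.0


def _gotoh(n_rows: int, n_cols: int, score):
    """Affine-gap global alignment (maximising) over abstract units.

    ``score(i, j)`` scores pairing unit ``i`` of A (0-based) with unit ``j``
    of B.  Returns the traceback as a list of (i or None, j or None) pairs and
    the optimal score.
    """
    neg = float("-inf")
    M = [[neg] * (n_cols + 1) for _ in range(n_rows + 1)]
    Ix = [[neg] * (n_cols + 1) for _ in range(n_rows + 1)]  # gap in B (consume A)
    Iy = [[neg] * (n_cols + 1) for _ in range(n_rows + 1)]  # gap in A (consume B)
    M[0][0] = 0.0
    for i in range(1, n_rows + 1):
        Ix[i][0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, n_cols + 1):
        Iy[0][j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    for i in range(1, n_rows + 1):
        for j in range(1, n_cols + 1):
            s = score(i - 1, j - 1)
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - GAP_OPEN, Ix[i - 1][j] - GAP_EXTEND)
            Iy[i][j] = max(M[i][j - 1] - GAP_OPEN, Iy[i][j - 1] - GAP_EXTEND)

    # Traceback; deterministic preference M > Ix > Iy on exact ties.
    i, j = n_rows, n_cols
    state = max((M[i][j], "M"), (Ix[i][j], "X"), (Iy[i][j], "Y"),
                key=lambda t: (t[0], {"M": 2, "X": 1, "Y": 0}[t[1]]))[1]
    best = max(M[i][j], Ix[i][j], Iy[i][j])
    path: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            s = score(i - 1, j - 1)
            prev = max((M[i - 1][j - 1], "M"), (Ix[i - 1][j - 1], "X"),
                       (Iy[i - 1][j - 1], "Y"),
                       key=lambda t: (t[0], {"M": 2, "X": 1, "Y": 0}[t[1]]))[1]
            path.append((i - 1, j - 1))
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            path.append((i - 1, None))
            if i - 1 == 0 and j == 0:
                i, state = i - 1, "M"
            elif abs(Ix[i][j] - (M[i - 1][j] - GAP_OPEN)) < 1e-9 and M[i - 1][j] > float("-inf"):
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "X"
        else:  # "Y"
            path.append((None, j - 1))
            if j - 1 == 0 and i == 0:
                j, state = j - 1, "M"
            elif abs(Iy[i][j] - (M[i][j - 1] - GAP_OPEN)) < 1e-9 and M[i][j - 1] > float("-inf"):
                j, state = j - 1, "M"
            else:
                j, state = j - 1, "Y"
    path.reverse()
    return path, best


def pairwise_codon_align(a: list[str], b: list[str]) -> tuple[list[str], list[str], float]:
    """Global affine-gap alignment of two codon lists.

    Returns the two gapped codon lists (gap unit ``---``) and the score.
    """
    path, best = _gotoh(len(a), len(b), lambda i, j: _codon_score(a[i], b[j]))
    ga: list[str] = []
    gb: list[str] = []
    for i, j in path:
        ga.append(a[i] if i is not None else GAP * 3)
        gb.append(b[j] if j is not None else GAP * 3)
    return ga, gb, best


def _pairwise_identity(a: list[str], b: list[str]) -> float:
    """Nucleotide identity fraction over the pairwise codon alignment."""
    ga, gb, _ = pairwise_codon_align(a, b)
    match = 0
    total = 0
    for ca, cb in zip(ga, gb):
        for x, y in zip(ca, cb):
            total += 1
            if x == y and x != GAP:
                match += 1
    return match / total if total else 0.0


def codon_aware_align(records: Sequence[SeqRecord]) -> Alignment:
    """Progressive multiple alignment in codon units.

    The first input record seeds the alignment; remaining records join in
    order of decreasing pairwise identity to that seed (ties: input order).
    Each joining sequence is aligned against the running profile with the
    same affine per-codon gap penalties as the pairwise engine.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("codon_aware_align requires at least 2 records")
    units = []
    for rec in records:
        prefix, codons, suffix = _codon_units(rec)
        if not codons:
            raise ValueError(f"record {rec.id!r} shorter than one codon after frame trim")
        units.append((rec, prefix, codons, suffix))

    seed = units[0]
    rest = units[1:]
    idents = [_pairwise_identity(seed[2], u[2]) for u in rest]
    order = sorted(range(len(rest)), key=lambda k: (-idents[k], k))

    # rows of gapped codon units, parallel to `joined`
    joined = [seed]
    prof_rows: list[list[str]] = [list(seed[2])]
    for k in order:
        rec_u = rest[k]
        codons = rec_u[2]
        n_prof = len(prof_rows[0])
        cols = [tuple(r[c] for r in prof_rows) for c in range(n_prof)]
        path, _ = _gotoh(n_prof, len(codons),
                         lambda i, j: _profile_column_score(cols[i], codons[j]))
        new_rows: list[list[str]] = [[] for _ in prof_rows]
        new_row: list[str] = []
        for i, j in path:
            for r, nr in zip(prof_rows, new_rows):
                nr.append(r[i] if i is not None else GAP * 3)
            new_row.append(codons[j] if j is not None else GAP * 3)
        prof_rows = new_rows + [new_row]
        joined.append(rec_u)

    # flank padding: frame-offset prefixes right-aligned, partial-codon
    # suffixes left-aligned, so ungapping each row recovers its input exactly
    pre_w = max(len(u[1]) for u in joined)
    suf_w = max(len(u[3]) for u in joined)
    out_rows = []
    for (rec, prefix, _, suffix), row in zip(joined, prof_rows):
        gapped = (GAP * (pre_w - len(prefix)) + prefix
                  + "".join(row)
                  + suffix + GAP * (suf_w - len(suffix)))
        out_rows.append((rec.id, rec.species, gapped))
    n_columns = pre_w + 3 * len(prof_rows[0]) + suf_w
    return Alignment(rows=tuple(out_rows), n_columns=n_columns)


def alignment_from_rows(rows: Iterable[tuple[str, str, str]]) -> Alignment:
    """Build an Alignment from pre-aligned (id, species, gapped seq) rows."""
    rows = tuple(rows)
    if not rows:
        raise ValueError("no rows")
    return Alignment(rows=rows, n_columns=len(rows[0][2]))


# ---------------------------------------------------------------------------
# site profiling
# ---------------------------------------------------------------------------

_CLASSES = ("A", "C", "G", "T", "gap", "ambiguous")


def _classify(base: str) -> str:
    if base == GAP:
        return "gap"
    if base in UNAMBIGUOUS:
        return base
    return "ambiguous"


def site_profile(alignment: Alignment) -> SiteProfile:
    """Per-column base counts, polymorphism flags and diagnostic-base calls.

    A column is polymorphic when >= 2 distinct unambiguous bases occur across
    rows.  A column is diagnostic for species S when every S row carries one
    unambiguous base, every non-S row carries one *other* shared unambiguous
    base, and the column contains no gap or ambiguity; such columns guarantee
    a true mismatch against every non-target template.
    """
    species = alignment.species
    columns: list[ColumnProfile] = []
    for coord in range(1, alignment.n_columns + 1):
        counts: dict[str, dict[str, int]] = {
            sp: dict.fromkeys(_CLASSES, 0) for sp in species
        }
        bases_by_species: dict[str, set[str]] = {sp: set() for sp in species}
        unambiguous: set[str] = set()
        dirty = False
        for _, sp, seq in alignment.rows:
            base = seq[coord - 1]
            cls = _classify(base)
            counts[sp][cls] += 1
            if cls in ("gap", "ambiguous"):
                dirty = True
            else:
                unambiguous.add(base)
                bases_by_species[sp].add(base)
        is_poly = len(unambiguous) >= 2
        diagnostic: str | None = None
        if is_poly and not dirty:
            for sp in species:
                own = bases_by_species[sp]
                others = set().union(*(bases_by_species[o] for o in species if o != sp))
                if len(own) == 1 and len(others) == 1 and own != others:
                    diagnostic = sp
                    break
        columns.append(ColumnProfile(coord, counts, dirty, is_poly, diagnostic))
    return SiteProfile(columns=tuple(columns), species=species, n_rows=len(alignment.rows))


def diagnostic_sites(profile: SiteProfile, target: str) -> list[int]:
    """Ascending 1-based columns diagnostic for *target*."""
    if target not in profile.species:
        raise ValueError(
            f"unknown species {target!r}; available: {', '.join(profile.species)}"
        )
    return [c.coord for c in profile.columns if c.diagnostic_for == target]


def hypervariable_windows(profile: SiteProfile, window: int = 100, step: int = 10,
                          min_density: float = 0.15) -> list[WindowScore]:
    """Sliding-window polymorphism density scan with merge of overlapping hits.

    All windows of *window* columns advancing by *step* whose polymorphic-site
    density reaches *min_density* are kept; overlapping hits are merged and the
    merged span rescored over its full width.  Sorted by descending density,
    then ascending start.
    """
    n = len(profile.columns)
    if not 1 <= window <= n:
        raise ValueError(f"window {window} outside [1, {n}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    poly = [1 if c.is_polymorphic else 0 for c in profile.columns]
    cum = [0]
    for v in poly:
        cum.append(cum[-1] + v)

    def density(start: int, end: int) -> float:  # 1-based inclusive
        return (cum[end] - cum[start - 1]) / (end - start + 1)

    hits: list[tuple[int, int]] = []
    for start in range(1, n - window + 2, step):
        end = start + window - 1
        if density(start, end) >= min_density:
            hits.append((start, end))
    merged: list[list[int]] = []
    for start, end in hits:  # hits are start-sorted
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    scored = [WindowScore(s, e, density(s, e)) for s, e in merged]
    return sorted(scored, key=lambda w: (-w.density, w.start))


def species_consensus(alignment: Alignment, species: str) -> str:
    """Majority-rule consensus row for one species (ties -> ``N``).

    Gaps win a column only by strict majority; ambiguity codes never vote.
    """
    rows = alignment.rows_for(species)
    if not rows:
        raise ValueError(
            f"unknown species {species!r}; available: {', '.join(alignment.species)}"
        )
    out = []
    for coord in range(1, alignment.n_columns + 1):
        votes: dict[str, int] = {}
        for _, _, seq in rows:
            base = seq[coord - 1]
            if base in UNAMBIGUOUS or base == GAP:
                votes[base] = votes.get(base, 0) + 1
        if not votes:
            out.append("N")
            continue
        top = max(votes.values())
        winners = sorted(b for b, v in votes.items() if v == top)
        out.append(winners[0] if len(winners) == 1 else "N")
    return "".join(out)
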