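"""Reading and writing external representations.

Plain and aligned FASTA, the primer table (TSV), and deterministic TSV/JSON
reports.  Species labels are explicit metadata carried on each record, taken
from a ``species=`` token in the FASTA header, an explicit id-to-species map,
or the full header text — never inferred from sequence content.

All report coordinates are 1-based and inclusive on the alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: IUPAC DNA codes (unambiguous + ambiguity). Gaps are only legal in aligned FASTA.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC DNA string (gap-preserving)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid records."""


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class SeqRecord:
    """One species-labelled DNA sequence (a marker coding region).

    Parameters
    ----------
    id : str
        Unique record identifier within a set.
    species : str
        Non-empty species label; the assay is defined per named species.
    sequence : str
        IUPAC DNA, stored uppercase, no gaps.
    frame_offset : int
        Position of the first complete codon (0, 1 or 2).
    """

    id: str
    species: str
    sequence: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.species:
            raise ValidationError(f"record {self.id!r}: species label must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"record {self.id!r}: sequence must be non-empty")
        for pos, base in enumerate(seq, start=1):
            if base not in IUPAC_DNA:
                raise ValidationError(
                    f"record {self.id!r}: non-IUPAC character {base!r} at position {pos}"
                )
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"record {self.id!r}: frame_offset must be 0, 1 or 2")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerTableRow:
    """One oligo of a published primer pair, 5'->3' on its own strand."""

    primer_name: str
    target_species: str
    orientation: str  # "forward" | "reverse"
    sequence: str

    def __post_init__(self) -> None:
        orient = self.orientation.lower()
        if orient not in ("forward", "reverse"):
            raise ValidationError(
                f"primer {self.primer_name!r}: orientation {self.orientation!r} "
                "not accepted (accepted tokens: forward, reverse)"
            )
        object.__setattr__(self, "orientation", orient)
        seq = self.sequence.upper()
        if len(seq) < 10:
            raise ValidationError(
                f"primer {self.primer_name!r}: sequence length {len(seq)} < 10"
            )
        for pos, base in enumerate(seq, start=1):
            if base not in IUPAC_DNA:
                raise ValidationError(
                    f"primer {self.primer_name!r}: non-IUPAC character {base!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)


def _species_from_header(rec_id: str, description: str,
                         species_map: Mapping[str, str] | None) -> str:
    for token in description.split():
        if token.startswith("species="):
            return token[len("species="):]
    if species_map and rec_id in species_map:
        return species_map[rec_id]
    return description.strip() or rec_id


def read_fasta(path: str | Path,
               species_map: Mapping[str, str] | None = None) -> list[SeqRecord]:
    """Read a FASTA file into validated, species-labelled records.

    Species are taken from a ``species=`` header token when present, else from
    *species_map*, else from the full header line.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - Biopython is permissive
        raise FastaParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        species = _species_from_header(rec.id, rec.description, species_map)
        seq = str(rec.seq)
        if GAP in seq:
            raise ValidationError(
                f"record {rec.id!r}: gap character in plain FASTA input "
                "(use read_aligned_fasta for aligned input)"
            )
        records.append(SeqRecord(id=rec.id, species=species, sequence=seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with ``species=`` header tokens, 60-column wrapped."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id} species={rec.species}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_aligned_fasta(path: str | Path,
                       species_map: Mapping[str, str] | None = None
                       ) -> list[tuple[str, str, str]]:
    """Read aligned FASTA; returns (id, species, gapped_sequence) rows.

    ``-`` is the only accepted gap character; rows must share one length.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = _species_from_header(rec.id, rec.description, species_map)
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base != GAP and base not in IUPAC_DNA:
                raise ValidationError(
                    f"record {rec.id!r}: non-IUPAC character {base!r} at position {pos}"
                )
        rows.append((rec.id, species, seq))
    if not rows:
        raise FastaParseError(f"{path}: no FASTA records found")
    lengths = {len(seq) for _, _, seq in rows}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: aligned rows have unequal lengths {sorted(lengths)}")
    return rows


def write_aligned_fasta(rows: Iterable[tuple[str, str, str]], path: str | Path,
                        width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec_id, species, seq in rows:
            fh.write(f">{rec_id} species={species}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


PRIMER_TABLE_COLUMNS = ("name", "species", "orientation", "sequence")


def read_primer_table(path: str | Path) -> list[PrimerTableRow]:
    """Read a primer table TSV with header ``name species orientation sequence``."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: missing header row")
    header = tuple(lines[0].split("\t"))
    if header != PRIMER_TABLE_COLUMNS:
        raise ValidationError(
            f"{path}: header {header} != expected {PRIMER_TABLE_COLUMNS}"
        )
    rows: list[PrimerTableRow] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 tab-separated fields")
        name, species, orientation, sequence = parts
        rows.append(PrimerTableRow(name, species, orientation, sequence))
    return rows


def write_primer_table(rows: Iterable[PrimerTableRow], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(PRIMER_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write(f"{row.primer_name}\t{row.target_species}\t"
                     f"{row.orientation}\t{row.sequence}\n")


def format_float(x: float, decimals: int = 4) -> str:
    """Fixed float formatting used by every report writer (determinism)."""
    return f"{x:.{decimals}f}"


def write_tsv(path: str | Path, header: Sequence[str],
              rows: Iterable[Sequence[object]],
              comment_lines: Sequence[str] = ()) -> None:
    """Write a TSV report: optional ``#`` comment header, fixed column order."""
    path = Path(path)
    with path.open("w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                format_float(v) if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def write_json_report(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
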