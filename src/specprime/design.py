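"""Species-specific primer candidate enumeration, scoring, pairing and ranking.

Design follows four principles: target the most variable region of the
marker, keep amplicons within a configured size band, avoid regions of high
homology to non-target species, and minimise hairpin/dimer structure.  On top
of these, every candidate must carry a species-diagnostic nucleotide in its
3'-terminal window (by default the 3'-terminal base itself), so that every
non-target template presents a terminal mismatch that blocks polymerase
extension.

The melting temperature model is a nearest-neighbour enthalpy/entropy
summation over the unified dinucleotide parameter set with terminal
initiation and duplex-symmetry terms, a monovalent-salt entropy correction
(0.368 * (N-1) * ln[Na+] cal/(mol K)) and total-strand concentration C taken
as C/4 in the melting condition:

    Tm = dH / (dS_salt + R * ln(C/4)) - 273.15

Structure screening uses integer match-run heuristics (longest perfect
Watson-Crick stem or duplex run), not free-energy minimisation: the screening
is qualitative, as in interactive design tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .profile import Alignment, SiteProfile, WindowScore, diagnostic_sites, species_consensus
from .seqio import GAP, UNAMBIGUOUS, reverse_complement

R_GAS = 1.987  # cal/(mol K)

#: Unified nearest-neighbour parameters: 5'->3' dinucleotide -> (dH kcal/mol,
#: dS cal/(mol K)).  Ten unique stacks; the reverse-complement stack shares
#: the same values.
_NN_UNIQUE = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
NN_PARAMS: dict[str, tuple[float, float]] = {}
for _step, _hs in _NN_UNIQUE.items():
    NN_PARAMS[_step] = _hs
    NN_PARAMS[reverse_complement(_step)] = _hs

#: Terminal initiation terms (dH kcal/mol, dS cal/(mol K)) per duplex end.
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
#: Self-complementary duplex symmetry correction.
SYMMETRY = (0.0, -1.4)


def melting_temperature(sequence: str, salt_mM: float = 50.0,
                        primer_conc_nM: float = 500.0) -> float:
    """Nearest-neighbour duplex melting temperature in degrees Celsius."""
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError(f"sequence length {len(seq)} < 8")
    if any(b not in UNAMBIGUOUS for b in seq):
        raise ValueError("melting_temperature requires unambiguous A/C/G/T")
    d_h = 0.0
    d_s = 0.0
    for end in (seq[0], seq[-1]):
        h, s = INIT_AT if end in "AT" else INIT_GC
        d_h += h
        d_s += s
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i: i + 2]]
        d_h += h
        d_s += s
    if seq == reverse_complement(seq):
        d_h += SYMMETRY[0]
        d_s += SYMMETRY[1]
    d_s += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    conc = primer_conc_nM * 1e-9
    return 1000.0 * d_h / (d_s + R_GAS * math.log(conc / 4.0)) - 273.15


def _complementary(a: str, b: str) -> bool:
    return (a, b) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def structure_scores(sequence: str, min_loop: int = 3) -> tuple[int, int]:
    """(hairpin_score, self_dimer_score) integer match-run heuristics.

    hairpin_score: longest perfect Watson-Crick stem closable with a loop of
    at least *min_loop* nt.  self_dimer_score: longest contiguous
    complementary run of the sequence against itself in antiparallel
    orientation over all ungapped offsets.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError(f"sequence length {len(seq)} < 8")
    n = len(seq)
    hairpin = 0
    # left arm starts at i, right arm ends at j (pairing seq[i] with seq[j])
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            length = 0
            # pairing (i+length, j-length) must leave >= min_loop unpaired bases
            while (i + length < j - length - min_loop
                   and _complementary(seq[i + length], seq[j - length])):
                length += 1
            hairpin = max(hairpin, length)
    return hairpin, cross_dimer_score(seq, seq)


def cross_dimer_score(seq_a: str, seq_b: str) -> int:
    """Longest contiguous complementary run between two primers.

    Computed as the longest common contiguous match between ``seq_a`` and the
    reverse complement of ``seq_b`` over all ungapped offsets (i.e. the
    longest perfect antiparallel duplex the two oligos can form).
    """
    a = seq_a.upper()
    b = reverse_complement(seq_b.upper())
    best = 0
    for offset in range(-(len(b) - 1), len(a)):
        run = 0
        for i in range(len(a)):
            j = i - offset
            if 0 <= j < len(b) and a[i] == b[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


@dataclass(frozen=True)
class DesignConfig:
    """Design constraints and scoring weights.

    Lengths in nt, temperatures in degrees Celsius, GC in percent,
    salt in mM monovalent cation, primer concentration in nM.
    """

    primer_length_range: tuple[int, int] = (18, 24)
    amplicon_length_range: tuple[int, int] = (550, 800)
    tm_range: tuple[float, float] = (50.0, 62.0)
    max_pair_tm_diff: float = 3.0
    gc_range: tuple[float, float] = (35.0, 65.0)
    diagnostic_3prime_window: int = 5
    strict_terminal: bool = True
    min_nontarget_mismatches: int = 2
    max_hairpin: int = 4
    max_self_dimer: int = 8
    max_cross_dimer: int = 8
    monovalent_salt_mM: float = 50.0
    primer_conc_nM: float = 500.0
    restrict_to_windows: bool = True
    top_n: int = 3
    w_tm: float = 1.0
    w_diagnostic: float = 2.0
    w_specificity: float = 1.0
    w_structure: float = 0.5

    def __post_init__(self) -> None:
        for name in ("primer_length_range", "amplicon_length_range",
                     "tm_range", "gc_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered: {lo} > {hi}")
        if self.diagnostic_3prime_window < 1:
            raise ValueError("diagnostic_3prime_window must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        """Read ``key = value`` overrides; ranges as ``lo,hi``."""
        kwargs = {}
        fields = {f: cls.__dataclass_fields__[f] for f in cls.__dataclass_fields__}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _parse_config_value(key, value)
        return cls(**kwargs)


def _parse_config_value(key: str, value: str):
    if key.endswith("_range"):
        lo, hi = (v.strip() for v in value.split(","))
        caster = int if key in ("primer_length_range", "amplicon_length_range") else float
        return (caster(lo), caster(hi))
    if key in ("strict_terminal", "restrict_to_windows"):
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"bad boolean for {key}: {value!r}")
    if key in ("diagnostic_3prime_window", "min_nontarget_mismatches",
               "max_hairpin", "max_self_dimer", "max_cross_dimer", "top_n"):
        return int(value)
    return float(value)


@dataclass(frozen=True)
class PrimerCandidate:
    """A designed oligo with thermodynamic, structural and diagnostic annotations.

    ``sequence`` is always 5'->3' on the primer's own strand; a reverse
    candidate is therefore the reverse complement of the target consensus
    over its alignment span.  ``diagnostic_offsets`` are distances from the
    3'-terminal base (0 = terminal).
    """

    sequence: str
    orientation: str  # "forward" | "reverse"
    target_species: str
    alignment_span: tuple[int, int]  # 1-based inclusive columns
    tm: float
    gc: float
    diagnostic_offsets: tuple[int, ...]
    hairpin_score: int
    self_dimer_score: int
    nontarget_min_mismatches: int = -1  # -1 until specificity_profile runs
    nontarget_3prime_mismatch: bool = False

    @property
    def three_prime_column(self) -> int:
        return self.alignment_span[1] if self.orientation == "forward" \
            else self.alignment_span[0]


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    predicted_amplicon_length: int
    tm_diff: float
    cross_dimer_score: int
    composite_score: float
    rank: int = 0


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _template_strand(candidate: PrimerCandidate) -> str:
    """Candidate sequence laid on the + strand of the alignment (5'->3')."""
    if candidate.orientation == "forward":
        return candidate.sequence
    return reverse_complement(candidate.sequence)


def _three_prime_window_cols(candidate: PrimerCandidate, window: int) -> range:
    start, end = candidate.alignment_span
    if candidate.orientation == "forward":
        return range(max(start, end - window + 1), end + 1)
    return range(start, min(end, start + window - 1) + 1)


def specificity_profile(candidate: PrimerCandidate, alignment: Alignment,
                        config: DesignConfig | None = None) -> PrimerCandidate:
    """Annotate a candidate with worst-case mismatch counts vs non-targets.

    For every non-target row, counts total mismatches of the primer against
    the row over its span (row gaps/ambiguities count as mismatches) and
    whether at least one mismatch falls inside the 3'-terminal window; the
    stored aggregates are the minimum mismatch count over non-target rows and
    whether *every* non-target row has a 3'-window mismatch.
    """
    config = config or DesignConfig()
    start, end = candidate.alignment_span
    plus = _template_strand(candidate)
    window_cols = set(_three_prime_window_cols(candidate, config.diagnostic_3prime_window))
    min_mm: int | None = None
    all_3p = True
    for _, sp, seq in alignment.rows:
        if sp == candidate.target_species:
            continue
        total = 0
        in_3p = 0
        for col in range(start, end + 1):
            base = seq[col - 1]
            expected = plus[col - start]
            mismatch = base not in UNAMBIGUOUS or base != expected
            if mismatch:
                total += 1
                if col in window_cols:
                    in_3p += 1
        min_mm = total if min_mm is None else min(min_mm, total)
        if in_3p == 0:
            all_3p = False
    if min_mm is None:  # no non-target rows
        min_mm, all_3p = 0, False
    return replace(candidate, nontarget_min_mismatches=min_mm,
                   nontarget_3prime_mismatch=all_3p)


def validate_candidate(candidate: PrimerCandidate, config: DesignConfig) -> bool:
    """Independent re-check that a candidate satisfies every config constraint."""
    length = len(candidate.sequence)
    lo, hi = config.primer_length_range
    if not lo <= length <= hi:
        return False
    if not config.tm_range[0] <= candidate.tm <= config.tm_range[1]:
        return False
    if not config.gc_range[0] <= candidate.gc <= config.gc_range[1]:
        return False
    if candidate.hairpin_score > config.max_hairpin:
        return False
    if candidate.self_dimer_score > config.max_self_dimer:
        return False
    offsets = set(candidate.diagnostic_offsets)
    if not offsets & set(range(config.diagnostic_3prime_window)):
        return False
    if config.strict_terminal and 0 not in offsets:
        return False
    if candidate.nontarget_min_mismatches < config.min_nontarget_mismatches:
        return False
    if not candidate.nontarget_3prime_mismatch:
        return False
    return True


def enumerate_candidates(alignment: Alignment, target: str,
                         windows: Sequence[WindowScore] | None = None,
                         config: DesignConfig | None = None,
                         profile: SiteProfile | None = None
                         ) -> list[PrimerCandidate]:
    """All primer candidates for *target* passing every design constraint.

    Candidates are substrings of the target-species majority consensus lying
    inside the hypervariable windows (both orientations).  A span containing
    a gap or any ambiguous consensus base is disqualified outright.
    """
    from .profile import site_profile as _site_profile

    config = config or DesignConfig()
    if profile is None:
        profile = _site_profile(alignment)
    diag = set(diagnostic_sites(profile, target))
    if not diag:
        warnings.warn(f"no diagnostic sites for species {target!r}; "
                      "no candidates can be designed", stacklevel=2)
        return []
    consensus = species_consensus(alignment, target)

    if config.restrict_to_windows:
        if windows is None:
            raise ValueError("windows required when restrict_to_windows is set")
        spans = [(w.start, w.end) for w in windows]
    else:
        spans = [(1, alignment.n_columns)]

    lo, hi = config.primer_length_range
    out: list[PrimerCandidate] = []
    seen: set[tuple[str, int, int]] = set()
    for w_start, w_end in spans:
        for start in range(w_start, w_end + 1):
            for length in range(lo, hi + 1):
                end = start + length - 1
                if end > w_end:
                    break
                span_seq = consensus[start - 1: end]
                if any(b not in UNAMBIGUOUS for b in span_seq):
                    continue
                for orientation in ("forward", "reverse"):
                    cand = _build_candidate(span_seq, orientation, target,
                                            (start, end), diag, config)
                    if cand is None:
                        continue
                    key = (orientation, start, end)
                    if key in seen:
                        continue
                    seen.add(key)
                    cand = specificity_profile(cand, alignment, config)
                    if validate_candidate(cand, config):
                        out.append(cand)
    out.sort(key=lambda c: (c.alignment_span, c.orientation))
    return out


def _build_candidate(span_seq: str, orientation: str, target: str,
                     span: tuple[int, int], diag: set[int],
                     config: DesignConfig) -> PrimerCandidate | None:
    start, end = span
    if orientation == "forward":
        primer = span_seq
        offsets = tuple(sorted(end - col for col in diag if start <= col <= end))
    else:
        primer = reverse_complement(span_seq)
        offsets = tuple(sorted(col - start for col in diag if start <= col <= end))
    in_window = [o for o in offsets if o < config.diagnostic_3prime_window]
    if not in_window:
        return None
    if config.strict_terminal and 0 not in in_window:
        return None
    gc = gc_percent(primer)
    if not config.gc_range[0] <= gc <= config.gc_range[1]:
        return None
    tm = melting_temperature(primer, config.monovalent_salt_mM, config.primer_conc_nM)
    if not config.tm_range[0] <= tm <= config.tm_range[1]:
        return None
    hairpin, self_dimer = structure_scores(primer)
    if hairpin > config.max_hairpin or self_dimer > config.max_self_dimer:
        return None
    return PrimerCandidate(
        sequence=primer, orientation=orientation, target_species=target,
        alignment_span=span, tm=tm, gc=gc, diagnostic_offsets=offsets,
        hairpin_score=hairpin, self_dimer_score=self_dimer,
    )


def _nongap_cumsum(consensus: str) -> list[int]:
    cum = [0]
    for b in consensus:
        cum.append(cum[-1] + (b != GAP))
    return cum


def pair_and_rank(candidates: Sequence[PrimerCandidate], alignment: Alignment,
                  config: DesignConfig | None = None,
                  top_n: int | None = None) -> list[PrimerPair]:
    """Pair forward x reverse candidates, score, and rank deterministically.

    composite_score = w_tm * (Tm closeness to the configured midpoint)
                    + w_diagnostic * (3'-window diagnostic-site count, both primers)
                    + w_specificity * (worst-case non-target mismatches)
                    - w_structure * (hairpin + self-dimer + cross-dimer scores).

    Sorted by descending score, then ascending amplicon start column, then
    ascending amplicon length (a total order independent of input order).
    """
    config = config or DesignConfig()
    if top_n is None:
        top_n = config.top_n
    if not candidates:
        return []
    targets = {c.target_species for c in candidates}
    if len(targets) != 1:
        raise ValueError("pair_and_rank expects candidates for a single target species")
    target = targets.pop()
    forwards = [c for c in candidates if c.orientation == "forward"]
    reverses = [c for c in candidates if c.orientation == "reverse"]
    midpoint = (config.tm_range[0] + config.tm_range[1]) / 2.0
    # amplicon length on the ungapped target consensus, both footprints included
    cum = _nongap_cumsum(species_consensus(alignment, target))

    pairs: list[PrimerPair] = []
    for f in forwards:
        for r in reverses:
            if f.alignment_span[1] >= r.alignment_span[0]:
                continue
            length = cum[r.alignment_span[1]] - cum[f.alignment_span[0] - 1]
            lo, hi = config.amplicon_length_range
            if not lo <= length <= hi:
                continue
            tm_diff = abs(f.tm - r.tm)
            if tm_diff > config.max_pair_tm_diff:
                continue
            cross = cross_dimer_score(f.sequence, r.sequence)
            if cross > config.max_cross_dimer:
                continue
            w = config.diagnostic_3prime_window
            n_diag = (sum(1 for o in f.diagnostic_offsets if o < w)
                      + sum(1 for o in r.diagnostic_offsets if o < w))
            closeness = -(abs(f.tm - midpoint) + abs(r.tm - midpoint)) / 2.0
            spec = min(f.nontarget_min_mismatches, r.nontarget_min_mismatches)
            structure = f.hairpin_score + f.self_dimer_score \
                + r.hairpin_score + r.self_dimer_score + cross
            score = (config.w_tm * closeness + config.w_diagnostic * n_diag
                     + config.w_specificity * spec - config.w_structure * structure)
            pairs.append(PrimerPair(f, r, length, tm_diff, cross, score))
    pairs.sort(key=lambda p: (-p.composite_score, p.forward.alignment_span[0],
                              p.predicted_amplicon_length,
                              p.reverse.alignment_span[0]))
    ranked = [replace(p, rank=i + 1) for i, p in enumerate(pairs[:top_n])]
    return ranked
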