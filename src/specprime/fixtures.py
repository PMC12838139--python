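"""Seeded synthetic marker-family generator with planted diagnostic sites.

Emulates the statistical structure of a small family of congeneric
protein-coding mitochondrial marker sequences: ~1545 nt coding sequences,
strong A+T bias (strongest at third, then first codon positions), mean
pairwise p-distance near 0.19 with substitutions concentrated in a mid-gene
hypervariable interval, and a known set of planted species-diagnostic
columns per species.  No indels are generated (alignment is exercised
separately on constructed indel cases), so sequence coordinates coincide
with alignment columns.

Substitutions never create an in-frame stop codon, keeping codon-position
composition realistic for a functional coding gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SeqRecord

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Per-codon-position A+T fractions chosen so their mean is the configured
#: overall at_fraction (positions 1 and 3 AT-enriched, position 2 balanced).
_POSITION_AT_WEIGHTS = (1.10, 0.76, 1.14)
#: Within A+T, A vs T split; within G+C, G is the rarer base.
_A_OF_AT = 0.48
_G_OF_GC = 0.42


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a synthetic species family.

    target_p is the desired mean pairwise p-distance; hotspot_share of the
    substitution events fall inside the hotspot interval (1-based, inclusive,
    in nucleotide coordinates).
    """

    n_species: int = 4
    n_codons: int = 515
    target_p: float = 0.19
    at_fraction: float = 0.70
    hotspot: tuple[int, int] = (600, 1300)
    hotspot_share: float = 0.7
    planted_diagnostic_per_species: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_p <= 0.75:
            raise ValueError("target_p outside [0, 0.75]")
        if not 0.0 <= self.hotspot_share <= 1.0:
            raise ValueError("hotspot_share outside [0, 1]")
        lo, hi = self.hotspot
        if not 1 <= lo <= hi <= 3 * self.n_codons:
            raise ValueError("hotspot outside the sequence")
        n_hotspot = hi - lo + 1
        if self.n_species * self.planted_diagnostic_per_species > n_hotspot:
            raise ValueError(
                f"{self.n_species * self.planted_diagnostic_per_species} planted "
                f"sites do not fit in a {n_hotspot}-column hotspot"
            )

    @property
    def n_sites(self) -> int:
        return 3 * self.n_codons


def _raw_position_freqs(at_fraction: float, scale: float = 1.0) -> list[np.ndarray]:
    freqs = []
    for w in _POSITION_AT_WEIGHTS:
        at = min(at_fraction * w * scale, 0.97)
        gc = 1.0 - at
        freqs.append(np.array([
            at * _A_OF_AT,            # A
            gc * (1.0 - _G_OF_GC),    # C
            gc * _G_OF_GC,            # G
            at * (1.0 - _A_OF_AT),    # T
        ]))
    return freqs


def _conditional_at(freqs: list[np.ndarray]) -> float:
    """Expected A+T fraction of a codon drawn from *freqs* given it is not a stop.

    Stop codons are AT-rich, so conditioning on stop-free codons depresses
    the realised A+T below the nominal stationary value; calibration below
    compensates for exactly this."""
    total_p = 0.0
    total_at = 0.0
    for i1, b1 in enumerate(BASES):
        for i2, b2 in enumerate(BASES):
            for i3, b3 in enumerate(BASES):
                if b1 + b2 + b3 in STOP_CODONS:
                    continue
                p = freqs[0][i1] * freqs[1][i2] * freqs[2][i3]
                total_p += p
                total_at += p * sum(b in "AT" for b in (b1, b2, b3)) / 3.0
    return total_at / total_p


def _mutated_at(freqs: list[np.ndarray]) -> float:
    """Expected A+T fraction of a site after a forced-different substitution.

    Redrawing from the stationary mix conditioned on differing from the
    current base is GC-enriching relative to the stationary A+T fraction
    (the likelier AT bases exclude themselves more often)."""
    out = 0.0
    for f in freqs:
        at = 0.0
        for i, b in enumerate(BASES):
            alt = np.delete(f, i)
            alt_bases = np.delete(BASES, i)
            at += f[i] * sum(p for p, bb in zip(alt, alt_bases) if bb in "AT") / alt.sum()
        out += at / len(freqs)
    return out


def _position_freqs(at_fraction: float, mutation_load: float = 0.0) -> list[np.ndarray]:
    """Stationary A/C/G/T frequencies per codon position, calibrated so the
    expected realised A+T fraction equals *at_fraction* after conditioning on
    stop-free codons and after the expected per-lineage substitution load."""
    def realised(scale: float) -> float:
        freqs = _raw_position_freqs(at_fraction, scale)
        anc = _conditional_at(freqs)
        return (1.0 - mutation_load) * anc + mutation_load * _mutated_at(freqs)

    lo, hi = 0.8, 1.6
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if realised(mid) < at_fraction:
            lo = mid
        else:
            hi = mid
    return _raw_position_freqs(at_fraction, (lo + hi) / 2.0)


def _calibrate_rates(spec: SyntheticFamilySpec,
                     planted_set: set[int]) -> np.ndarray:
    """Per-site mutation probability achieving target_p with the hotspot share.

    Planted diagnostic columns are excluded from random substitution but each
    contributes a fixed 2/n_species to the mean pairwise p (one lineage
    differs from all others), so the random rates are calibrated to make the
    *total* expected mean pairwise distance hit target_p."""
    n = spec.n_sites
    lo, hi = spec.hotspot
    n_hot = hi - lo + 1
    n_cold = n - n_hot
    if spec.target_p == 0:
        return np.zeros(n)
    hot_rate = spec.hotspot_share / n_hot
    cold_rate = (1.0 - spec.hotspot_share) / n_cold if n_cold else 0.0
    rel = np.full(n, cold_rate)
    rel[lo - 1: hi] = hot_rate
    if planted_set:
        rel[[c - 1 for c in planted_set]] = 0.0
    rel /= rel.max()
    planted_term = len(planted_set) * (2.0 / spec.n_species) / n

    def realized(scale: float) -> float:
        q = np.clip(scale * rel, 0.0, 0.95)
        per_site = 2 * q * (1 - q) + (2.0 / 3.0) * q * q
        return float(per_site.sum() / n) + planted_term

    if realized(0.95) <= spec.target_p:
        return np.clip(0.95 * rel, 0.0, 0.95)
    lo_s, hi_s = 0.0, 0.95
    for _ in range(80):  # bisection on the scale factor
        mid = (lo_s + hi_s) / 2.0
        if realized(mid) < spec.target_p:
            lo_s = mid
        else:
            hi_s = mid
    return np.clip(((lo_s + hi_s) / 2.0) * rel, 0.0, 0.95)


def _codon_of(seq: np.ndarray, site: int) -> str:
    start = 3 * (site // 3)
    return "".join(seq[start: start + 3])


def _mutate_site(seq: np.ndarray, site: int, rng: np.random.Generator,
                 freqs: list[np.ndarray]) -> None:
    """Substitute one site, drawing from the position's stationary frequencies
    restricted to bases that differ and do not create a stop codon."""
    pos = site % 3
    current = seq[site]
    weights = freqs[pos].copy()
    order = np.argsort(-weights)  # try likelier bases first, deterministically
    choices = []
    probs = []
    for k in order:
        base = BASES[k]
        if base == current:
            continue
        seq[site] = base
        if _codon_of(seq, site) not in STOP_CODONS:
            choices.append(base)
            probs.append(weights[k])
    seq[site] = current
    if not choices:
        return
    probs = np.array(probs) / np.sum(probs)
    seq[site] = rng.choice(np.array(choices), p=probs)


def generate_family(spec: SyntheticFamilySpec
                    ) -> tuple[list[SeqRecord], dict[str, list[int]]]:
    """Generate a species family plus the planted diagnostic-column truth.

    Returns (records, truth) where truth maps species label -> sorted list of
    planted diagnostic columns (1-based nucleotide coordinates).  Same spec
    (including seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites

    # planted diagnostic columns: disjoint across species, inside the hotspot
    lo, hi = spec.hotspot
    hotspot_cols = np.arange(lo, hi + 1)
    n_plant = spec.n_species * spec.planted_diagnostic_per_species
    planted = rng.choice(hotspot_cols, size=n_plant, replace=False)
    species_labels = [f"sp{i + 1}" for i in range(spec.n_species)]
    truth = {
        sp: sorted(int(c) for c in
                   planted[i * spec.planted_diagnostic_per_species:
                           (i + 1) * spec.planted_diagnostic_per_species])
        for i, sp in enumerate(species_labels)
    }
    planted_set = {c for cols in truth.values() for c in cols}

    # independent per-lineage substitutions, hotspot-concentrated
    rates = _calibrate_rates(spec, planted_set)
    freqs = _position_freqs(spec.at_fraction, mutation_load=float(rates.mean()))

    # ancestral sequence, stop-free in frame
    ancestor = np.empty(n, dtype="<U1")
    for codon_i in range(spec.n_codons):
        while True:
            codon = [rng.choice(BASES, p=freqs[pos]) for pos in range(3)]
            if "".join(codon) not in STOP_CODONS:
                break
        ancestor[3 * codon_i: 3 * codon_i + 3] = codon

    lineages = []
    for _ in species_labels:
        seq = ancestor.copy()
        hit = rng.random(n) < rates
        for site in np.flatnonzero(hit):
            if (site + 1) in planted_set:
                continue  # planted columns are set explicitly below
            _mutate_site(seq, int(site), rng, freqs)
        lineages.append(seq)

    # force the one-species-differs pattern at every planted column
    for sp_i, sp in enumerate(species_labels):
        for col in truth[sp]:
            site = col - 1
            shared = _diagnostic_pair(lineages, site, sp_i, rng, freqs)
            if shared is None:
                continue
            shared_base, target_base = shared
            for k, seq in enumerate(lineages):
                seq[site] = target_base if k == sp_i else shared_base
    # verify plants (stop-avoidance can in principle reject every base pair;
    # regenerate the truth entry as absent rather than emit a false truth)
    for sp_i, sp in enumerate(species_labels):
        truth[sp] = [
            col for col in truth[sp]
            if all(lineages[k][col - 1] == lineages[(sp_i + 1) % spec.n_species][col - 1]
                   for k in range(spec.n_species) if k != sp_i)
            and lineages[sp_i][col - 1] != lineages[(sp_i + 1) % spec.n_species][col - 1]
        ]

    records = [
        SeqRecord(id=f"{sp}_1", species=sp, sequence="".join(seq))
        for sp, seq in zip(species_labels, lineages)
    ]
    return records, truth


def _diagnostic_pair(lineages: list[np.ndarray], site: int, target_i: int,
                     rng: np.random.Generator, freqs: list[np.ndarray]
                     ) -> tuple[str, str] | None:
    """Pick (shared_base, target_base), distinct, creating no stop in any lineage."""
    pos = site % 3
    weights = freqs[pos]

    def stop_free(base: str, which: list[int]) -> bool:
        for k in which:
            seq = lineages[k]
            old = seq[site]
            seq[site] = base
            bad = _codon_of(seq, site) in STOP_CODONS
            seq[site] = old
            if bad:
                return False
        return True

    def weighted_draw(legal: list[str]) -> str:
        idx = [list(BASES).index(b) for b in legal]
        p = weights[idx] / weights[idx].sum()
        return str(rng.choice(np.array(legal), p=p))

    others = [k for k in range(len(lineages)) if k != target_i]
    legal_shared = [b for b in BASES if stop_free(b, others)]
    # stationary-weighted draws keep planted columns composition-neutral
    while legal_shared:
        shared = weighted_draw(legal_shared)
        legal_shared.remove(shared)
        legal_target = [b for b in BASES
                        if b != shared and stop_free(b, [target_i])]
        if legal_target:
            return shared, weighted_draw(legal_target)
    return None
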