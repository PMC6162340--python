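"""V-gene template annotation and per-mutation stop-codon risk.

An immunoglobulin heavy-chain variable-region (V) gene is represented as an
in-frame nucleotide template together with its complementarity-determining
region (CDR) intervals.  Somatic hypermutation (SHM) does not hit the gene
uniformly: mutations are concentrated in CDRs and at short degenerate AID
hotspot motifs (classically RGYW and its reverse-complement partner WRCY).
This module partitions the template into weighted enrichment regions and
computes, by exhaustive enumeration of single-nucleotide substitutions, the
probability ``q`` that one random point mutation creates a premature stop
codon (TAA/TAG/TGA).

A codon whose single substitutions can terminate the gene in exactly one way
carries a risk of 1/9 (1/3 chance the mutation lands in the critical position
times 1/3 chance it is the critical base change); a "doubly at risk" codon
carries 2/9.  Nothing here hard-codes those two classes — risk is whatever
enumeration yields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STOP_CODONS",
    "VGeneTemplate",
    "Region",
    "RegionPartition",
    "CodonRisk",
    "CodonRiskProfile",
    "DEFAULT_MOTIF_PATTERNS",
    "DEFAULT_REGION_WEIGHTS",
    "find_hotspot_motifs",
    "merge_intervals",
    "partition_regions",
    "codon_stop_risk",
    "position_stop_risk",
    "template_stop_probability_per_mutation",
    "risk_profile",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"

#: IUPAC degenerate nucleotide codes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Classic AID hotspot motifs on the coding strand.
DEFAULT_MOTIF_PATTERNS = ("RGYW", "WRCY")

#: Region classes and their default SHM enrichment weights.  CDRs are
#: mutated 5x, hotspot-motif regions 2x; a motif inside a CDR composes
#: multiplicatively (10x) by default.
DEFAULT_REGION_WEIGHTS: Mapping[str, float] = {
    "FR_plain": 1.0,
    "FR_motif": 2.0,
    "CDR_plain": 5.0,
    "CDR_motif": 10.0,
}

REGION_CLASSES = tuple(DEFAULT_REGION_WEIGHTS)


def _validate_intervals(intervals: Sequence[tuple[int, int]], length: int,
                        what: str) -> list[tuple[int, int]]:
    out = []
    prev_end = -1
    for start, end in intervals:
        if not (0 <= start < end <= length):
            raise ValueError(f"{what} interval [{start}, {end}) outside [0, {length})")
        if start < prev_end:
            raise ValueError(f"{what} intervals overlap or are unsorted at [{start}, {end})")
        prev_end = end
        out.append((int(start), int(end)))
    return out


@dataclass(frozen=True)
class VGeneTemplate:
    """An in-frame V-gene nucleotide template (reading frame offset 0).

    Parameters
    ----------
    id : str
        Sequence identifier.
    seq : str
        Nucleotide sequence over A/C/G/T; length must be a multiple of 3 and
        the translation must contain no stop codon.
    cdr_intervals : sequence of (start, end)
        CDR locations, 0-based half-open nucleotide coordinates, sorted and
        non-overlapping.
    """

    id: str
    seq: str
    cdr_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(f"template length {len(seq)} is not a positive multiple of 3")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"template contains non-ACGT symbols: {sorted(bad)}")
        for i in range(0, len(seq), 3):
            if seq[i:i + 3] in STOP_CODONS:
                raise ValueError(f"template contains stop codon {seq[i:i+3]} at codon {i // 3 + 1}")
        object.__setattr__(
            self, "cdr_intervals",
            tuple(_validate_intervals(self.cdr_intervals, len(seq), "CDR")),
        )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> str:
        """Codon at 0-based codon ``index``."""
        return self.seq[3 * index:3 * index + 3]


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    region_class: str
    weight: float

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.weight <= 0:
            raise ValueError("region weight must be positive")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionPartition:
    """A tiling of ``[0, L)`` into weighted enrichment regions."""

    regions: tuple[Region, ...]
    length: int

    def __post_init__(self):
        pos = 0
        for r in self.regions:
            if r.start != pos:
                raise ValueError(f"partition has a gap or overlap at position {pos}")
            pos = r.end
        if pos != self.length:
            raise ValueError(f"partition covers [0, {pos}) but template length is {self.length}")

    def position_weights(self) -> list[float]:
        """Per-nucleotide enrichment weight, length L."""
        w = []
        for r in self.regions:
            w.extend([r.weight] * r.size)
        return w

    @classmethod
    def uniform(cls, length: int) -> "RegionPartition":
        return cls((Region(0, length, "FR_plain", 1.0),), length)


def _pattern_matches_at(seq: str, pattern: str, i: int) -> bool:
    for j, sym in enumerate(pattern):
        if seq[i + j] not in IUPAC[sym]:
            return False
    return True


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals; returns sorted list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_hotspot_motifs(template: VGeneTemplate,
                        motif_patterns: Sequence[str] = DEFAULT_MOTIF_PATTERNS,
                        ) -> list[tuple[int, int]]:
    """Locate AID hotspot motif matches on the forward strand.

    Patterns use IUPAC degenerate codes.  Overlapping matches (within or
    across patterns) are merged into single intervals.
    """
    for pat in motif_patterns:
        bad = set(pat.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in pattern {pat!r}")
    seq = template.seq
    hits: list[tuple[int, int]] = []
    for pat in motif_patterns:
        pat = pat.upper()
        k = len(pat)
        for i in range(len(seq) - k + 1):
            if _pattern_matches_at(seq, pat, i):
                hits.append((i, i + k))
    return merge_intervals(hits)


def _membership_array(intervals: Sequence[tuple[int, int]], length: int) -> list[bool]:
    inside = [False] * length
    for s, e in intervals:
        for i in range(s, e):
            inside[i] = True
    return inside


def partition_regions(template: VGeneTemplate,
                      motif_intervals: Sequence[tuple[int, int]] = (),
                      weights: Mapping[str, float] = DEFAULT_REGION_WEIGHTS,
                      ) -> RegionPartition:
    """Classify every template position by CDR/motif membership.

    Membership is the cross product {FR, CDR} x {plain, motif}; contiguous
    runs of the same class become one region.  The resulting regions tile
    ``[0, L)`` exactly.
    """
    L = template.length
    _validate_intervals(sorted(motif_intervals), L, "motif")
    missing = set(REGION_CLASSES) - set(weights)
    if missing:
        raise ValueError(f"weights missing for region classes: {sorted(missing)}")
    in_cdr = _membership_array(template.cdr_intervals, L)
    in_motif = _membership_array(merge_intervals(motif_intervals), L)
    classes = []
    for i in range(L):
        if in_cdr[i]:
            classes.append("CDR_motif" if in_motif[i] else "CDR_plain")
        else:
            classes.append("FR_motif" if in_motif[i] else "FR_plain")
    regions = []
    start = 0
    for i in range(1, L + 1):
        if i == L or classes[i] != classes[start]:
            cls = classes[start]
            regions.append(Region(start, i, cls, float(weights[cls])))
            start = i
    return RegionPartition(tuple(regions), L)


def codon_stop_risk(codon: str) -> tuple[int, float]:
    """Number (and /9 probability) of single-nucleotide substitutions of
    ``codon`` that yield a stop codon.

    Enumerates all 9 single-base variants; a codon that is itself a stop is
    rejected (the template invariant excludes internal stops).
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(BASES):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"codon {codon} is itself a stop codon")
    count = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            if codon[:pos] + base + codon[pos + 1:] in STOP_CODONS:
                count += 1
    return count, count / 9.0


def position_stop_risk(seq: str, position: int) -> float:
    """Probability that a substitution at ``position`` (uniform over the 3
    alternative bases) turns the enclosing codon into a stop codon."""
    codon_start = 3 * (position // 3)
    codon = seq[codon_start:codon_start + 3]
    offset = position - codon_start
    n = 0
    for base in BASES:
        if base == codon[offset]:
            continue
        if codon[:offset] + base + codon[offset + 1:] in STOP_CODONS:
            n += 1
    return n / 3.0


def template_stop_probability_per_mutation(template: VGeneTemplate,
                                           partition: RegionPartition | None = None,
                                           ) -> float:
    """Probability ``q`` that one point mutation creates a premature stop.

    The mutated position is drawn proportionally to the region enrichment
    weights and the substituted base uniformly over the three alternatives:

        q = sum_i w_i * c_i / sum_i w_i

    where ``c_i`` is the fraction of the 3 substitutions at position ``i``
    that produce a stop codon.  With all weights equal this reduces to the
    unweighted mean codon risk (sum of codon risk counts / 9, divided by the
    number of codons).
    """
    if partition is None:
        partition = RegionPartition.uniform(template.length)
    if partition.length != template.length:
        raise ValueError("partition length does not match template")
    weights = partition.position_weights()
    num = 0.0
    den = 0.0
    for i, w in enumerate(weights):
        num += w * position_stop_risk(template.seq, i)
        den += w
    return num / den


@dataclass(frozen=True)
class CodonRisk:
    index: int            # 0-based codon index
    codon: str
    risk_count: int
    risk_probability: float
    region_class: str     # class of the codon's first nucleotide


@dataclass(frozen=True)
class CodonRiskProfile:
    template_id: str
    codons: tuple[CodonRisk, ...]
    q: float = field(default=float("nan"))

    def to_records(self) -> list[dict]:
        return [
            {
                "codon_index": c.index + 1,  # 1-based in reports
                "codon": c.codon,
                "risk_count": c.risk_count,
                "risk_probability": c.risk_probability,
                "region_class": c.region_class,
            }
            for c in self.codons
        ]

    def to_json(self) -> str:
        return json.dumps(
            {"template_id": self.template_id, "q": self.q, "codons": self.to_records()},
            indent=2,
        )


def risk_profile(template: VGeneTemplate,
                 partition: RegionPartition | None = None) -> CodonRiskProfile:
    """Per-codon stop-risk table plus the weighted template probability q."""
    if partition is None:
        partition = RegionPartition.uniform(template.length)
    pos_class = []
    for r in partition.regions:
        pos_class.extend([r.region_class] * r.size)
    codons = []
    for idx in range(template.n_codons):
        codon = template.codon(idx)
        count, prob = codon_stop_risk(codon)
        codons.append(CodonRisk(idx, codon, count, prob, pos_class[3 * idx]))
    q = template_stop_probability_per_mutation(template, partition)
    return CodonRiskProfile(template.id, tuple(codons), q)
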