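"""Seed-match scanning: find and classify miRNA target sites in a 3′-UTR.

The seed is the miRNA subsequence at positions 2–7 (6mer seed) or 2–8
(7mer seed), counted 1-based from the 5′ end. A target site is a UTR
window that is the exact Watson–Crick reverse complement of a seed, in
one of four canonical classes:

========  =============================================================
6mer      match to positions 2–7 only
7mer-A1   6mer match followed (3′ on the UTR) by an A opposite position 1
7mer-m8   match extended through position 8
8mer      7mer-m8 match plus the A opposite position 1
========  =============================================================

The A of the A1 classes is the literal UTR nucleotide A, not
complementarity to the miRNA's first residue. G:U wobbles and mismatch
seeds are not matched. Only the maximal class of each window is
reported; overlapping sites are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import DataError
from .io_formats import NucSequence, reverse_complement

MIN_MIRNA_LENGTH = 8


class SiteType(str, Enum):
    SIX_MER = "6mer"
    SEVEN_MER_A1 = "7mer-A1"
    SEVEN_MER_M8 = "7mer-m8"
    EIGHT_MER = "8mer"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: span of the seed-match region on the UTR, per class
SITE_LENGTHS = {
    SiteType.SIX_MER: 6,
    SiteType.SEVEN_MER_A1: 7,
    SiteType.SEVEN_MER_M8: 7,
    SiteType.EIGHT_MER: 8,
}


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5′→3′, strict RNA alphabet, at least 8 nt."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < MIN_MIRNA_LENGTH:
            raise DataError(
                f"miRNA {self.name!r} is {len(self.residues)} nt; "
                f"at least {MIN_MIRNA_LENGTH} required"
            )
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise DataError(
                f"miRNA {self.name!r}: residues outside {{A,C,G,U}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TargetSite:
    """One seed match on a UTR, in 0-based half-open UTR coordinates.

    ``[start, end)`` covers the whole matched region including the A of
    the A1 classes, so ``end - start`` is 6, 7 or 8 by class.
    """

    utr_id: str
    mirna_name: str
    start: int
    end: int
    site_type: SiteType
    percentile: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        expected = SITE_LENGTHS[self.site_type]
        if self.end - self.start != expected:
            raise DataError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )


def seed_of(mirna: MiRNA, span: tuple[int, int] = (2, 8)) -> str:
    """Seed subsequence of the miRNA over 1-based positions ``span``.

    Only spans (2, 7) (6-nt seed) and (2, 8) (7-nt seed) are meaningful
    here, but any in-range 1-based inclusive span is returned.
    """
    lo, hi = span
    if not (1 <= lo <= hi <= len(mirna)):
        raise DataError(f"seed span {span} out of range for {len(mirna)}-nt miRNA")
    return mirna.residues[lo - 1 : hi]


def seed_match(mirna: MiRNA, span: tuple[int, int] = (2, 8)) -> str:
    """UTR motif matched by the seed: reverse complement of :func:`seed_of`."""
    return reverse_complement(seed_of(mirna, span))


def find_sites(utr: NucSequence, mirna: MiRNA) -> list[TargetSite]:
    """All maximal-class seed matches of ``mirna`` in ``utr``.

    Returned in order of start coordinate. ``N`` in the UTR never
    matches. Overlapping sites are all reported; each window is reported
    once, under its maximal class.
    """
    m6 = seed_match(mirna, (2, 7))  # 6 nt
    m7 = seed_match(mirna, (2, 8))  # 7 nt: complement of position 8, then m6
    m8_first = m7[0]
    seq = utr.residues
    n = len(seq)
    sites: list[TargetSite] = []

    for j in range(0, n - 6 + 1):
        if seq[j : j + 6] != m6:
            continue
        has_m8 = j > 0 and seq[j - 1] == m8_first
        if has_m8:
            # reported from the m7 window start; skip here to avoid duplicates
            continue
        has_a1 = j + 6 < n and seq[j + 6] == "A"
        if has_a1:
            sites.append(
                TargetSite(utr.id, mirna.name, j, j + 7, SiteType.SEVEN_MER_A1)
            )
        else:
            sites.append(TargetSite(utr.id, mirna.name, j, j + 6, SiteType.SIX_MER))

    for i in range(0, n - 7 + 1):
        if seq[i : i + 7] != m7:
            continue
        has_a1 = i + 7 < n and seq[i + 7] == "A"
        if has_a1:
            sites.append(TargetSite(utr.id, mirna.name, i, i + 8, SiteType.EIGHT_MER))
        else:
            sites.append(
                TargetSite(utr.id, mirna.name, i, i + 7, SiteType.SEVEN_MER_M8)
            )

    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def count_matches(sequence: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``sequence``, overlaps counted."""
    if not motif:
        raise DataError("empty motif")
    count = 0
    pos = sequence.find(motif)
    while pos != -1:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count
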