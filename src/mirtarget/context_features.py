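"""Sequence-context features of a target site.

Three determinants of site efficacy in the context-score tradition:

* **AU content** — weighted fraction of A/U in the flanks of the seed
  match; AU-rich context correlates with site accessibility. Position i
  (1 = adjacent to the site, counted outward on each side) carries
  weight 1/(i+1); the value is the weight sum over A/U positions divided
  by the weight sum over available positions.
* **UTR position** — distance from the site midpoint to the nearer UTR
  end, capped; sites near either UTR end repress more strongly.
* **3′ pairing** — contribution of supplementary pairing between the
  miRNA 3′ half (positions ≥ 9) and the 15 nt of UTR immediately 5′ of
  the seed match. The best run of contiguous Watson–Crick pairs over
  candidate register offsets is scored: 1.0 per paired position falling
  in miRNA 13–16, 0.5 elsewhere, minus 0.5 per offset step away from
  the seed-adjacent register, floored at 0.

The exact weights live in the constants block below and are this
package's committed interpretation of the context-score lineage.
"""

from __future__ import annotations

import logging

from .errors import DataError
from .io_formats import NucSequence
from .site_scanner import MiRNA, TargetSite
from .thermodynamics import can_pair

logger = logging.getLogger(__name__)

# -- constants block (context-score weights) --------------------------------
AU_WINDOW = 30              # nt considered on each side of the site
AU_WEIGHT_OFFSET = 1        # weight of position i is 1 / (i + AU_WEIGHT_OFFSET)
UTR_POSITION_CAP = 1500     # nt
PAIRING_REGION = 15         # nt of UTR 5' of the seed match searched
PAIRING_CORE = (13, 16)     # miRNA positions (1-based, inclusive) worth 1.0
PAIRING_BASE_WEIGHT = 0.5   # other miRNA positions
PAIRING_OFFSET_PENALTY = 0.5
PAIRING_MAX_OFFSET = 8      # candidate register displacements, each way
# ---------------------------------------------------------------------------


def au_content(utr: NucSequence, site: TargetSite, window: int = AU_WINDOW) -> float:
    """Weighted A/U fraction of the site flanks, in [0, 1]."""
    if not (0 <= site.start < site.end <= len(utr)):
        raise DataError(f"site [{site.start},{site.end}) outside UTR {utr.id!r}")
    seq = utr.residues
    num = 0.0
    den = 0.0
    for i in range(1, window + 1):
        weight = 1.0 / (i + AU_WEIGHT_OFFSET)
        up = site.start - i          # i nt 5' of the site
        down = site.end - 1 + i      # i nt 3' of the site
        if up >= 0:
            den += weight
            if seq[up] in "AU":
                num += weight
        if down < len(seq):
            den += weight
            if seq[down] in "AU":
                num += weight
    if den == 0.0:
        logger.warning(
            "site [%d,%d) on %s has no flanking sequence; AU content set to 0",
            site.start, site.end, utr.id,
        )
        return 0.0
    return num / den


def utr_position(utr: NucSequence, site: TargetSite, cap: int = UTR_POSITION_CAP) -> float:
    """Distance (nt) from the site midpoint to the nearer UTR end, capped."""
    if not (0 <= site.start < site.end <= len(utr)):
        raise DataError(f"site [{site.start},{site.end}) outside UTR {utr.id!r}")
    mid = (site.start + site.end) / 2.0
    dist = min(mid, len(utr) - mid)
    return float(min(dist, cap))


def three_prime_pairing(
    mirna: MiRNA, utr: NucSequence, site: TargetSite,
    region: int = PAIRING_REGION,
) -> float:
    """Supplementary-pairing score of the miRNA 3′ half, ≥ 0.

    The UTR region immediately 5′ of the seed match (up to ``region``
    nt, truncated at the UTR start) is aligned antiparallel against
    miRNA positions 9..end. In the zero-offset register, miRNA position
    9 faces the UTR nucleotide adjacent to the seed match; positive and
    negative offsets slide the miRNA 3′ half along the region.
    """
    if not (0 <= site.start < site.end <= len(utr)):
        raise DataError(f"site [{site.start},{site.end}) outside UTR {utr.id!r}")
    tail = mirna.residues[8:]  # miRNA positions 9..end, 5'->3'
    if not tail:
        return 0.0
    lo = max(0, site.start - region)
    upstream = utr.residues[lo : site.start]
    if not upstream:
        return 0.0
    # antiparallel: walk the UTR region 3'->5' while walking the miRNA tail 5'->3'
    target = upstream[::-1]
    best = 0.0
    for offset in range(-PAIRING_MAX_OFFSET, PAIRING_MAX_OFFSET + 1):
        run_score = 0.0
        run = 0.0
        for t_idx in range(len(target)):
            m_idx = t_idx - offset  # index into tail; 0 == miRNA position 9
            if 0 <= m_idx < len(tail) and can_pair(tail[m_idx], target[t_idx]):
                mirna_pos = 9 + m_idx  # 1-based miRNA numbering
                weight = (
                    1.0
                    if PAIRING_CORE[0] <= mirna_pos <= PAIRING_CORE[1]
                    else PAIRING_BASE_WEIGHT
                )
                run += weight
                run_score = max(run_score, run)
            else:
                run = 0.0
        score = run_score - PAIRING_OFFSET_PENALTY * abs(offset)
        best = max(best, score)
    return max(0.0, best)
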