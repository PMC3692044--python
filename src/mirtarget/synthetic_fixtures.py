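"""Deterministic generators for synthetic test inputs.

Everything here is a pure function of its arguments including the seed:
random UTRs, UTRs with planted seed matches of known class and position
(on backgrounds scrubbed of spurious matches), alignments evolved on a
tree with per-region rate scales (conserved windows get λ < 1), and
feature/response tables for exercising the linear repression model.

These generators define the ground truth the test suite checks against;
they emulate sequence composition and neutral/conserved substitution,
not realistic UTR evolution (no indels, no realignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conservation import SubstitutionModel
from .errors import DataError
from .io_formats import NucSequence, PhyloTree, SpeciesAlignment
from .site_scanner import (
    MiRNA,
    SITE_LENGTHS,
    SiteType,
    TargetSite,
    find_sites,
    seed_match,
)
from .scoring_model import FEATURE_DIRECTIONS, LinearModel, predict

NUCLEOTIDES = "ACGU"
_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: plausible raw-value ranges per feature for synthetic training tables
FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "dg_duplex": (-30.0, 0.0),
    "dg_binding": (-32.0, 0.0),
    "dg_seed_duplex": (-12.0, 0.0),
    "dg_seed_binding": (-13.0, 0.0),
    "dg_open": (0.0, 15.0),
    "dg_total": (-30.0, 10.0),
    "prob_binomial": (0.0, 1.0),
    "prob_exact": (0.0, 1.0),
    "utr_position": (0.0, 1500.0),
    "bls": (0.0, 5.0),
    "phylop_score": (-3.0, 6.0),
    "au_content": (0.0, 1.0),
    "three_prime_pairing": (0.0, 8.0),
    "site_count": (1.0, 6.0),
}


def gen_utr(
    length: int,
    base_composition=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    utr_id: str = "utr",
) -> NucSequence:
    """I.i.d. random UTR of the given length and composition."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise DataError("base composition must be 4 nonnegative values summing to 1")
    if length < 0:
        raise DataError("length must be >= 0")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp)
    return NucSequence(id=utr_id, residues="".join(NUCLEOTIDES[c] for c in codes))


def _match_string(mirna: MiRNA, site_type: SiteType) -> str:
    """Exact UTR string of one site class for this miRNA."""
    m6 = seed_match(mirna, (2, 7))
    m7 = seed_match(mirna, (2, 8))
    return {
        SiteType.SIX_MER: m6,
        SiteType.SEVEN_MER_A1: m6 + "A",
        SiteType.SEVEN_MER_M8: m7,
        SiteType.EIGHT_MER: m7 + "A",
    }[site_type]


def plant_sites(
    utr: NucSequence,
    mirna: MiRNA,
    positions: list[int],
    site_types: list[SiteType],
    seed: int = 0,
) -> tuple[NucSequence, list[TargetSite]]:
    """Write exact seed matches into a UTR and return the truth table.

    The background is scrubbed so the returned UTR contains no seed
    match of this miRNA other than the planted ones, and planted sites
    cannot be upgraded or absorbed by their neighborhood (no spurious A
    after a 6mer/7mer-m8, no position-8 complement before a 6mer).
    Positions must be non-overlapping and in bounds.
    """
    if len(positions) != len(site_types):
        raise DataError("positions and site_types must have equal length")
    spans = sorted(
        (pos, pos + SITE_LENGTHS[st]) for pos, st in zip(positions, site_types)
    )
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        # keep a 1-nt guard so class-guard edits never touch a neighbor site
        if s2 < e1 + 1:
            raise DataError(f"planted sites overlap or touch: [{s1},{e1}) and [{s2},{e2})")
    if spans and (spans[0][0] < 0 or spans[-1][1] > len(utr)):
        raise DataError("planted site out of UTR bounds")

    rng = np.random.default_rng(seed)
    residues = list(utr.residues)
    m7 = seed_match(mirna, (2, 8))
    m8_first = m7[0]
    truth: list[TargetSite] = []
    protected: set[int] = set()
    for pos, st in zip(positions, site_types):
        text = _match_string(mirna, st)
        residues[pos : pos + len(text)] = text
        protected.update(range(pos, pos + len(text)))
        end = pos + len(text)
        # guard positions: the nucleotide before a 6mer/7mer-A1 must not
        # extend the match through position 8, and the nucleotide after a
        # 6mer/7mer-m8 must not be the A of an A1 upgrade. Guard bases are
        # drawn from {A, m8-complement}-free choices and then protected so
        # the background scrub cannot reintroduce a violation.
        if pos > 0 and st in (SiteType.SIX_MER, SiteType.SEVEN_MER_A1):
            if residues[pos - 1] == m8_first:
                residues[pos - 1] = _guard_base({m8_first, "A"}, rng)
            protected.add(pos - 1)
        if st in (SiteType.SIX_MER, SiteType.SEVEN_MER_M8) and end < len(residues):
            if residues[end] == "A":
                residues[end] = _guard_base({m8_first, "A"}, rng)
            protected.add(end)
        truth.append(TargetSite(utr.id, mirna.name, pos, pos + len(text), st))

    # scrub spurious 6mer matches in the background (every site class
    # contains the 6mer core, so killing stray 6mers kills all classes)
    m6 = seed_match(mirna, (2, 7))
    for _ in range(10 * max(1, len(residues))):
        seq = "".join(residues)
        hit = _spurious_hit(seq, m6, truth)
        if hit is None:
            break
        # mutate one unprotected position inside the stray match
        candidates = [p for p in range(hit, hit + 6) if p not in protected]
        if not candidates:
            raise DataError("cannot scrub background without touching a planted site")
        p = int(rng.choice(candidates))
        residues[p] = _other_base(residues[p], rng)
    else:
        raise DataError("background scrub did not converge")
    return NucSequence(id=utr.id, residues="".join(residues)), truth


def _other_base(base: str, rng) -> str:
    choices = [c for c in NUCLEOTIDES if c != base]
    return choices[int(rng.integers(len(choices)))]


def _guard_base(excluded: set[str], rng) -> str:
    choices = [c for c in NUCLEOTIDES if c not in excluded]
    return choices[int(rng.integers(len(choices)))]


def _spurious_hit(seq: str, m6: str, truth: list[TargetSite]) -> int | None:
    planted_starts = set()
    for site in truth:
        # the 6mer core sits one position in for classes matching m8
        offset = 1 if site.site_type in (SiteType.SEVEN_MER_M8, SiteType.EIGHT_MER) else 0
        planted_starts.add(site.start + offset)
    pos = seq.find(m6)
    while pos != -1:
        if pos not in planted_starts:
            return pos
        pos = seq.find(m6, pos + 1)
    return None


def gen_planted_fixture(
    mirna: MiRNA,
    length: int = 200,
    n_sites: int = 2,
    seed: int = 0,
) -> tuple[NucSequence, list[TargetSite]]:
    """Convenience: random UTR with n planted sites of random classes."""
    rng = np.random.default_rng(seed)
    utr = gen_utr(length, seed=int(rng.integers(2**31)), utr_id=f"utr_seed{seed}")
    types = [
        list(SiteType)[int(rng.integers(4))] for _ in range(n_sites)
    ]
    # spread sites with >= 12 nt spacing
    slot = length // max(1, n_sites)
    positions = [i * slot + int(rng.integers(max(1, slot - 12))) for i in range(n_sites)]
    positions = [min(p, length - 8) for p in positions]
    return plant_sites(utr, mirna, positions, types, seed=int(rng.integers(2**31)))


def gen_alignment(
    tree: PhyloTree,
    root_seq: NucSequence,
    model: SubstitutionModel | None = None,
    window_scales: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
    ref_species: str | None = None,
) -> SpeciesAlignment:
    """Evolve a root sequence down a tree; gap-free leaf alignment.

    ``window_scales`` maps half-open regions of the root sequence to a
    rate multiplier λ (λ < 1 simulates negative selection, λ = 0 freezes
    the window); unlisted positions evolve at λ = 1. No indels.
    """
    model = model or SubstitutionModel("JC69")
    rng = np.random.default_rng(seed)
    n = len(root_seq)
    lam = np.ones(n)
    if window_scales:
        for (lo, hi), scale in window_scales.items():
            if scale < 0:
                raise DataError("rate scale must be >= 0")
            if not (0 <= lo <= hi <= n):
                raise DataError(f"window [{lo},{hi}) outside root sequence")
            lam[lo:hi] = scale
    root_codes = np.array([_INDEX[c] for c in root_seq.residues])

    leaf_rows: dict[str, str] = {}

    def evolve(parent_codes: np.ndarray, node) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            codes = parent_codes.copy()
            # per-position branch length t * lambda; group identical lambdas
            for scale in np.unique(lam):
                idx = np.nonzero(lam == scale)[0]
                if idx.size == 0 or t * scale == 0:
                    continue
                P = model.transition_matrix(t * float(scale))
                cum = P.cumsum(axis=1)
                u = rng.random(idx.size)
                codes[idx] = (u[:, None] < cum[codes[idx]]).argmax(axis=1)
            if child.is_leaf():
                leaf_rows[child.taxon.label] = "".join(
                    NUCLEOTIDES[c] for c in codes
                )
            else:
                evolve(codes, child)

    evolve(root_codes, tree.tree.seed_node)
    ref = ref_species or tree.leaf_labels()[0]
    return SpeciesAlignment(rows=leaf_rows, ref_species=ref)


def gen_repression_dataset(
    model: LinearModel,
    n_pairs: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table + noisy linear response for model-fitting tests.

    Features are drawn uniformly from :data:`FEATURE_RANGES`; the
    response is the model prediction plus Gaussian noise of the given
    standard deviation.
    """
    if n_pairs < 1:
        raise DataError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in model.coefficients:
        lo, hi = FEATURE_RANGES.get(name, (0.0, 1.0))
        cols[name] = rng.uniform(lo, hi, size=n_pairs)
    features = pd.DataFrame(cols)
    clean = np.array(
        [predict(model, dict(zip(features.columns, row))) for row in features.to_numpy()]
    )
    response = clean + rng.normal(0.0, noise_sd, size=n_pairs)
    return features, response


def noise_sd_for_r2(model: LinearModel, r2: float) -> float:
    """Noise s.d. giving a target generative R² for uniform features.

    Features are independent uniforms over :data:`FEATURE_RANGES`, so
    the signal variance is Σ βᵢ²·(hiᵢ−loᵢ)²/12 and
    R² = Var(signal) / (Var(signal) + σ²).
    """
    if not (0 < r2 < 1):
        raise DataError("target R^2 must be in (0, 1)")
    var_signal = sum(
        coef**2 * (FEATURE_RANGES.get(name, (0.0, 1.0))[1]
                   - FEATURE_RANGES.get(name, (0.0, 1.0))[0]) ** 2 / 12.0
        for name, coef in model.coefficients.items()
    )
    return float(np.sqrt(var_signal * (1.0 - r2) / r2))


def demo_true_model() -> LinearModel:
    """The generative model used by shipped synthetic demo datasets."""
    return LinearModel(
        intercept=-0.05,
        coefficients={
            "dg_duplex": 0.012,
            "dg_open": 0.010,
            "dg_seed_binding": 0.020,
            "prob_exact": 0.25,
            "bls": -0.06,
            "phylop_score": -0.04,
            "au_content": -0.30,
            "utr_position": 0.00012,
            "three_prime_pairing": -0.02,
        },
        label="synthetic demo generator",
    )
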