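"""Over-representation of seed matches under an order-1 Markov model.

A UTR carrying more copies of a seed match than its own nucleotide
composition predicts is a candidate for selection on targeting. The UTR
composition is modeled as a first-order Markov chain fitted to the UTR
itself, and the probability of seeing at least the observed number *n*
of seed matches in a sequence of the same length is computed either

* with a binomial approximation (``p_over`` "binomial"): each of the
  L − k + 1 windows matches independently with the stationary motif
  probability, or
* exactly (``p_over`` "exact"): a product automaton of the
  Knuth–Morris–Pratt matching automaton (failure-function construction,
  so self-overlapping motifs are handled correctly), the last emitted
  nucleotide (to condition Markov transitions) and the occurrence count
  truncated at *n*, advanced L steps by the transition matrix.

Occurrences are counted with overlaps: "AAA" contains two copies of
"AA". Small p_over means over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError
from .io_formats import NucSequence
from .site_scanner import MiRNA, count_matches, seed_match

NUCLEOTIDES = "ACGU"
_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


@dataclass
class MarkovModel:
    """Order-1 Markov chain over {A, C, G, U}.

    ``initial`` is the start distribution, ``transition[i, j]`` the
    probability of nucleotide j following nucleotide i.
    """

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise DataError("MarkovModel needs a 4-vector and a 4x4 matrix")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise DataError("negative probabilities in Markov model")
        if abs(self.initial.sum() - 1) > 1e-9:
            raise DataError("initial distribution does not sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise DataError("transition rows do not sum to 1")

    @classmethod
    def uniform(cls) -> "MarkovModel":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25))


@dataclass
class OverrepResult:
    """Observed seed-match count and its chance probability."""

    observed_n: int
    p_over: float
    method: str


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def fit_markov(seq: NucSequence | str) -> MarkovModel:
    """Fit initial and transition probabilities to one sequence.

    ``N`` positions are excised before fitting. The initial distribution
    is the mononucleotide frequency; the transition matrix is the
    normalized dinucleotide count matrix, with all-zero rows replaced by
    the uniform distribution.
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    clean = residues.replace("N", "")
    if len(clean) < 2:
        raise DataError("need at least 2 non-N residues to fit a Markov model")
    codes = _encode(clean)
    initial = np.bincount(codes, minlength=4).astype(float)
    initial /= initial.sum()
    trans = np.zeros((4, 4))
    np.add.at(trans, (codes[:-1], codes[1:]), 1.0)
    rowsum = trans.sum(axis=1, keepdims=True)
    uniform_rows = rowsum[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(rowsum > 0, trans / rowsum, 0.25)
    trans[uniform_rows] = 0.25
    return MarkovModel(initial=initial, transition=trans)


def motif_prob(model: MarkovModel, motif: str) -> float:
    """Probability that a window drawn from the chain equals ``motif``."""
    if not motif:
        raise DataError("empty motif")
    if "N" in motif:
        raise DataError("motif must be N-free")
    codes = _encode(motif)
    p = model.initial[codes[0]]
    for a, b in zip(codes[:-1], codes[1:]):
        p *= model.transition[a, b]
    return float(p)


def pover_binomial(model: MarkovModel, motif: str, L: int, n: int) -> float:
    """P(X ≥ n) with X ~ Binomial(L − k + 1, motif_prob).

    An approximation that ignores window overlap correlations; good for
    long sequences and non-self-overlapping motifs.
    """
    if n < 0:
        raise DataError("occurrence count n must be >= 0")
    k = len(motif)
    if L < k:
        raise DataError(f"sequence length {L} shorter than motif ({k} nt)")
    if n == 0:
        return 1.0
    windows = L - k + 1
    p = motif_prob(model, motif)
    return float(stats.binom.sf(n - 1, windows, p))


def _kmp_automaton(motif: str) -> np.ndarray:
    """DFA ``delta[state, symbol] -> state`` over states 0..k.

    State s = length of the longest motif prefix that is a suffix of the
    emitted text. Entering state k signals an occurrence; transitions
    out of k continue from its failure state so overlapping occurrences
    are counted.
    """
    k = len(motif)
    codes = _encode(motif)
    # failure function
    fail = np.zeros(k + 1, dtype=np.int64)
    for q in range(2, k + 1):
        s = fail[q - 1]
        while s > 0 and codes[s] != codes[q - 1]:
            s = fail[s]
        fail[q] = s + 1 if codes[s] == codes[q - 1] else 0
    delta = np.zeros((k + 1, 4), dtype=np.int64)
    for s in range(k + 1):
        for c in range(4):
            if s < k and codes[s] == c:
                delta[s, c] = s + 1
            elif s == 0:
                delta[s, c] = 0
            else:
                delta[s, c] = delta[fail[s], c]
    return delta


def occurrence_distribution(
    model: MarkovModel, motif: str, L: int, max_count: int
) -> np.ndarray:
    """Distribution of the overlap-counted occurrence number after L
    emitted nucleotides, with counts ≥ ``max_count`` lumped together.

    Returns a vector of length ``max_count + 1`` summing to 1.
    """
    if "N" in motif or not motif:
        raise DataError("motif must be nonempty and N-free")
    k = len(motif)
    if L < 1:
        raise DataError("sequence length must be >= 1")
    delta = _kmp_automaton(motif)
    n_states = k + 1
    nc = max_count + 1
    # joint distribution over (automaton state, last symbol, count)
    dist = np.zeros((n_states, 4, nc))
    for c in range(4):
        s = delta[0, c]
        cnt = 1 if s == k else 0
        dist[s, c, min(cnt, max_count)] += model.initial[c]
    for _ in range(L - 1):
        new = np.zeros_like(dist)
        for s in range(n_states):
            block = dist[s]  # (4, nc)
            if not block.any():
                continue
            for c in range(4):
                s2 = delta[s, c]
                inc = 1 if s2 == k else 0
                contrib = block * model.transition[:, c][:, None]  # (4, nc)
                col = contrib.sum(axis=0)  # over previous symbol
                if inc and nc > 1:
                    shifted = np.empty_like(col)
                    shifted[1:] = col[:-1]
                    shifted[0] = 0.0
                    shifted[-1] += col[-1]
                    col = shifted
                new[s2, c] += col
        dist = new
    return dist.sum(axis=(0, 1))


def pover_exact(model: MarkovModel, motif: str, L: int, n: int) -> float:
    """Exact P(at least n overlap-counted occurrences in L nt)."""
    if n < 0:
        raise DataError("occurrence count n must be >= 0")
    k = len(motif)
    if L < k:
        raise DataError(f"sequence length {L} shorter than motif ({k} nt)")
    if n == 0:
        return 1.0
    if n > L - k + 1:
        return 0.0
    dist = occurrence_distribution(model, motif, L, max_count=n)
    return float(dist[n])


def pover_feature(
    utr: NucSequence,
    mirna: MiRNA,
    method: str = "exact",
    seed_span: tuple[int, int] = (2, 8),
) -> OverrepResult:
    """Over-representation p-value of the miRNA's seed match in one UTR.

    The observed count n is the overlap-counted number of seed-match
    occurrences (``N`` breaks the scan; windows containing N never
    match); the Markov model is fitted to the UTR itself.
    """
    if method not in ("binomial", "exact"):
        raise DataError(f"unknown method {method!r}")
    motif = seed_match(mirna, seed_span)
    n = count_matches(utr.residues, motif)
    if n == 0:
        return OverrepResult(observed_n=0, p_over=1.0, method=method)
    model = fit_markov(utr)
    L = len(utr.residues.replace("N", ""))
    fn = pover_binomial if method == "binomial" else pover_exact
    if L < len(motif):
        return OverrepResult(observed_n=n, p_over=1.0, method=method)
    return OverrepResult(observed_n=n, p_over=fn(model, motif, L, n), method=method)
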