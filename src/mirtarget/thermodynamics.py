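"""Free-energy features of the miRNA–target interaction.

Six features, all in kcal/mol at 37 °C:

* ``dg_duplex`` — minimum free energy of intermolecular hybridization of
  the full miRNA against the target region (site plus a bounded upstream
  window that accommodates 3′ pairing).
* ``dg_binding`` — ensemble (partition-function) hybridization free
  energy, −RT·ln Z over all intermolecular structures of the pair.
* ``dg_seed_duplex`` / ``dg_seed_binding`` — the same two quantities
  restricted to miRNA positions 1–8 against the seed-match region.
* ``dg_open`` — site accessibility: the free-energy cost of forcing the
  site unpaired in the UTR, G(constrained) − G(unconstrained), both
  ensemble free energies over a window of the UTR around the site.
* ``dg_total`` — ``dg_duplex + dg_open``.

The default :class:`NNBackend` is a self-contained nearest-neighbor
model: hybrid and fold energies are sums of dinucleotide stack terms
from a shipped table, an affine penalty for interior loops and bulges, a
duplex initiation term and terminal AU/GU penalties; single-strand folds
additionally pay a per-pair entropic cost. Minimum free energies come
from exhaustive dynamic programming and ensemble energies from the
standard inside (partition-function) recursion. Any object satisfying
:class:`EnergyBackend` can be substituted.

Conventions: hybridization energies are capped at 0.0 (a destabilizing
duplex means no interaction); ``N`` never pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Protocol, Sequence

import numpy as np

from .errors import DataError
from .io_formats import NucSequence
from .site_scanner import MiRNA, TargetSite

#: gas constant × 310.15 K, kcal/mol
RT_37C = 0.0019872041 * 310.15

_PAIRABLE = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)
_WEAK_PAIRS = frozenset([("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")])

DEFAULT_OPEN_FLANK = 70  # nt each side of the site for dg_open
DEFAULT_UPSTREAM_EXTENSION = 15  # nt of UTR upstream of the site for dg_duplex


def can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRABLE


@dataclass
class NearestNeighborTable:
    """Stack energies and loop/initiation terms at 37 °C.

    ``stack_energies`` is keyed by two adjacent pairs
    ``((top1, bottom1), (top2, bottom2))`` for the step
    5′-t1·t2-3′ / 3′-b1·b2-5′ and is closed under reading the helix from
    the other strand. ``loop_penalties`` maps the total number of
    unpaired nucleotides in an interior loop or bulge to its cost.
    """

    stack_energies: dict[tuple[tuple[str, str], tuple[str, str]], float]
    duplex_init: float
    au_end_penalty: float
    loop_penalties: dict[int, float]
    ss_pair_cost: float
    max_loop: int
    min_hairpin: int

    def stack(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        return self.stack_energies[(p1, p2)]

    def end_penalty(self, pair: tuple[str, str]) -> float:
        return self.au_end_penalty if pair in _WEAK_PAIRS else 0.0


def load_nn_table(path=None) -> NearestNeighborTable:
    """Load the nearest-neighbor table (default: the shipped TSV)."""
    if path is None:
        ref = resources.files("mirtarget.data").joinpath("nn_stacks.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params: dict[str, float] = {}
    stacks: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "param" and len(fields) == 3:
            params[fields[1]] = float(fields[2])
        elif fields[0] == "stack" and len(fields) == 4:
            p1 = (fields[1][0], fields[1][1])
            p2 = (fields[2][0], fields[2][1])
            dg = float(fields[3])
            stacks[(p1, p2)] = dg
            # same physical step read from the other strand, 5'->3'
            sym = ((p2[1], p2[0]), (p1[1], p1[0]))
            stacks.setdefault(sym, dg)
        else:
            raise DataError(f"nearest-neighbor table line {lineno}: cannot parse {line!r}")
    for p1 in _PAIRABLE:
        for p2 in _PAIRABLE:
            if (p1, p2) not in stacks:
                raise DataError(f"nearest-neighbor table misses stack {p1}/{p2}")
    loop_base = params["loop_base"]
    loop_per_nt = params["loop_per_nt"]
    max_loop = int(params["max_loop"])
    loops = {k: loop_base + loop_per_nt * k for k in range(1, max_loop + 1)}
    return NearestNeighborTable(
        stack_energies=stacks,
        duplex_init=params["duplex_init"],
        au_end_penalty=params["au_end_penalty"],
        loop_penalties=loops,
        ss_pair_cost=params["ss_pair_cost"],
        max_loop=max_loop,
        min_hairpin=int(params["min_hairpin"]),
    )


class EnergyBackend(Protocol):
    """Contract every energy engine must satisfy (37 °C, kcal/mol)."""

    def duplex_mfe(self, a: str, b: str) -> float: ...

    def duplex_ensemble(self, a: str, b: str) -> float: ...

    def ensemble_free_energy(
        self, seq: str, unpaired: Iterable[int] = ()
    ) -> float: ...


class NNBackend:
    """Self-contained nearest-neighbor energy engine (see module docs)."""

    def __init__(self, table: NearestNeighborTable | None = None):
        self.table = table or load_nn_table()
        t = self.table
        self._loop_cost = np.full(t.max_loop + 2, np.inf)
        for k, v in t.loop_penalties.items():
            self._loop_cost[k] = v

    # -- duplex (intermolecular only) ------------------------------------

    def _duplex_arrays(self, a: str, b: str):
        """Per-cell pairability, stack weights and end penalties."""
        la, lb = len(a), len(b)
        pairable = np.zeros((la, lb), dtype=bool)
        endpen = np.zeros((la, lb))
        for i in range(la):
            for j in range(lb):
                if can_pair(a[i], b[j]):
                    pairable[i, j] = True
                    endpen[i, j] = self.table.end_penalty((a[i], b[j]))
        return pairable, endpen

    def _gap_cost(self, di: int, dj: int) -> float:
        unpaired = (di - 1) + (dj - 1)
        if unpaired == 0:
            raise AssertionError("adjacent pairs are a stack, not a loop")
        if unpaired > self.table.max_loop:
            return math.inf
        return self.table.loop_penalties[unpaired]

    def _duplex_dp(self, a: str, b: str):
        """Shared DP sweep: returns (M, Q, endpen).

        ``M[i, j]`` is the minimum energy of a hybrid whose 3′-most pair
        (on ``a``) is (i, j), including initiation and the left-end
        penalty; ``Q[i, j]`` is the corresponding Boltzmann sum.
        """
        t = self.table
        la, lb = len(a), len(b)
        pairable, endpen = self._duplex_arrays(a, b)
        M = np.full((la, lb), np.inf)
        Q = np.zeros((la, lb))
        # precomputed exp(-loop cost / RT) indexed by [di, dj]
        max_d = t.max_loop + 1
        loop_e = np.full((max_d + 2, max_d + 2), np.inf)
        for di in range(1, max_d + 2):
            for dj in range(1, max_d + 2):
                if (di, dj) != (1, 1):
                    un = (di - 1) + (dj - 1)
                    if un <= t.max_loop:
                        loop_e[di, dj] = t.loop_penalties[un]
        loop_w = np.exp(-loop_e / RT_37C)
        for i in range(la):
            for j in range(lb - 1, -1, -1):
                if not pairable[i, j]:
                    continue
                best = t.duplex_init + endpen[i, j]
                zsum = math.exp(-best / RT_37C)
                if i > 0 and j < lb - 1:
                    i0 = max(0, i - max_d - 1)
                    j1 = min(lb, j + max_d + 2)
                    sub_m = M[i0:i, j + 1 : j1]
                    sub_q = Q[i0:i, j + 1 : j1]
                    di_v = i - np.arange(i0, i)
                    dj_v = np.arange(j + 1, j1) - j
                    wl = loop_w[np.ix_(di_v, dj_v)]
                    cl = loop_e[np.ix_(di_v, dj_v)]
                    if pairable[i - 1, j + 1]:
                        st = t.stack((a[i - 1], b[j + 1]), (a[i], b[j]))
                        cl = cl.copy()
                        wl = wl.copy()
                        cl[-1, 0] = st
                        wl[-1, 0] = math.exp(-st / RT_37C)
                    with np.errstate(invalid="ignore"):
                        cand = np.min(sub_m + cl)
                    if cand < best:
                        best = cand
                    zsum += float(np.sum(sub_q * wl))
                M[i, j] = best
                Q[i, j] = zsum
        return M, Q, endpen, pairable

    def duplex_mfe(self, a: str, b: str) -> float:
        """Minimum hybridization free energy, capped at 0.0."""
        if not a or not b:
            raise DataError("duplex requires two nonempty sequences")
        M, _, endpen, pairable = self._duplex_dp(a, b)
        if not pairable.any():
            return 0.0
        vals = M[pairable] + endpen[pairable]
        return float(min(0.0, vals.min()))

    def duplex_ensemble(self, a: str, b: str) -> float:
        """−RT·ln Z over all hybrids (incl. the empty one), hence ≤ 0."""
        if not a or not b:
            raise DataError("duplex requires two nonempty sequences")
        _, Q, endpen, pairable = self._duplex_dp(a, b)
        z = 1.0 + float(np.sum(Q[pairable] * np.exp(-endpen[pairable] / RT_37C)))
        return -RT_37C * math.log(z)

    # -- single-strand folding (for site accessibility) ------------------

    def ensemble_free_energy(self, seq: str, unpaired: Iterable[int] = ()) -> float:
        """Ensemble free energy of one strand; ``unpaired`` positions are
        forced single-stranded. Always ≤ 0 (the open chain is a state)."""
        t = self.table
        n = len(seq)
        blocked = set(unpaired)
        if n == 0:
            return 0.0
        w_pair = math.exp(-t.ss_pair_cost / RT_37C)
        # Zb[i, j]: partition over structures of [i, j] where (i, j) pair;
        # Z[i, j]: over all structures of [i, j]. Stored dense, j >= i.
        Z = np.ones((n + 2, n + 2))
        Zb = np.zeros((n + 2, n + 2))
        ok = np.zeros((n, n), dtype=bool)
        stack_w = np.ones((n, n))
        for i in range(n):
            if i in blocked or seq[i] == "N":
                continue
            for j in range(i + t.min_hairpin + 1, n):
                if j in blocked:
                    continue
                if can_pair(seq[i], seq[j]):
                    ok[i, j] = True
                    if i + 1 < j - 1 and can_pair(seq[i + 1], seq[j - 1]):
                        st = t.stack((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
                        stack_w[i, j] = math.exp(-st / RT_37C)
        for span in range(t.min_hairpin + 1, n):
            for i in range(0, n - span):
                j = i + span
                if ok[i, j]:
                    inner = Z[i + 1, j - 1]
                    zb = w_pair * (inner + (stack_w[i, j] - 1.0) * Zb[i + 1, j - 1])
                    Zb[i, j] = zb
                # Z[i, j] = unpaired-i case + sum over partners k of i
                ks = np.nonzero(ok[i, i : j + 1])[0]
                acc = Z[i + 1, j]
                if ks.size:
                    kabs = ks + i
                    acc += float(np.dot(Zb[i, kabs], Z[kabs + 1, j]))
                Z[i, j] = acc
        return -RT_37C * math.log(float(Z[0, n - 1]))


_DEFAULT_BACKEND: NNBackend | None = None


def default_backend() -> NNBackend:
    global _DEFAULT_BACKEND
    if _DEFAULT_BACKEND is None:
        _DEFAULT_BACKEND = NNBackend()
    return _DEFAULT_BACKEND


@dataclass
class SiteEnergies:
    """The six free-energy features of one target site, kcal/mol."""

    dg_duplex: float
    dg_binding: float
    dg_seed_duplex: float
    dg_seed_binding: float
    dg_open: float

    @property
    def dg_total(self) -> float:
        return dg_total(self)


def _residues(x) -> str:
    return x.residues if hasattr(x, "residues") else str(x)


def dg_duplex(mirna, target_region, backend: EnergyBackend | None = None) -> float:
    """MFE of intermolecular hybridization (≤ 0; 0 means no stable duplex)."""
    backend = backend or default_backend()
    return backend.duplex_mfe(_residues(mirna), _residues(target_region))


def dg_binding(mirna, target_region, backend: EnergyBackend | None = None) -> float:
    """Ensemble hybridization free energy −RT·ln Z (≤ dg_duplex)."""
    backend = backend or default_backend()
    return backend.duplex_ensemble(_residues(mirna), _residues(target_region))


def _seed_region(utr: NucSequence, site: TargetSite) -> str:
    return utr.residues[site.start : site.end]


def dg_seed_duplex(
    mirna: MiRNA, utr: NucSequence, site: TargetSite,
    backend: EnergyBackend | None = None,
) -> float:
    """dg_duplex restricted to miRNA positions 1–8 vs the site region."""
    return dg_duplex(mirna.residues[:8], _seed_region(utr, site), backend)


def dg_seed_binding(
    mirna: MiRNA, utr: NucSequence, site: TargetSite,
    backend: EnergyBackend | None = None,
) -> float:
    """dg_binding restricted to miRNA positions 1–8 vs the site region."""
    return dg_binding(mirna.residues[:8], _seed_region(utr, site), backend)


def dg_open(
    utr: NucSequence,
    site: TargetSite,
    flank: int = DEFAULT_OPEN_FLANK,
    backend: EnergyBackend | None = None,
) -> float:
    """Accessibility cost G(site forced unpaired) − G(unconstrained) ≥ 0.

    Both ensemble free energies are computed over the UTR window
    ``[site.start − flank, site.end + flank]`` clamped to the UTR.
    """
    if not (0 <= site.start < site.end <= len(utr)):
        raise DataError(f"site [{site.start},{site.end}) outside UTR {utr.id!r}")
    backend = backend or default_backend()
    lo = max(0, site.start - flank)
    hi = min(len(utr), site.end + flank)
    window = utr.residues[lo:hi]
    constrained = range(site.start - lo, site.end - lo)
    g_unc = backend.ensemble_free_energy(window)
    g_con = backend.ensemble_free_energy(window, unpaired=constrained)
    delta = g_con - g_unc
    if delta < -1e-9:
        raise AssertionError(f"dg_open came out negative: {delta}")
    return max(0.0, delta)


def dg_total(e: SiteEnergies) -> float:
    """Exactly ``dg_duplex + dg_open``."""
    return e.dg_duplex + e.dg_open


def site_energies(
    utr: NucSequence,
    mirna: MiRNA,
    site: TargetSite,
    flank: int = DEFAULT_OPEN_FLANK,
    upstream: int = DEFAULT_UPSTREAM_EXTENSION,
    backend: EnergyBackend | None = None,
) -> SiteEnergies:
    """All free-energy features of one site.

    The duplex target region is the site extended ``upstream`` nt toward
    the UTR 5′ end, leaving room for pairing against the miRNA 3′ half.
    """
    backend = backend or default_backend()
    region = utr.residues[max(0, site.start - upstream) : site.end]
    return SiteEnergies(
        dg_duplex=dg_duplex(mirna, region, backend),
        dg_binding=dg_binding(mirna, region, backend),
        dg_seed_duplex=dg_seed_duplex(mirna, utr, site, backend),
        dg_seed_binding=dg_seed_binding(mirna, utr, site, backend),
        dg_open=dg_open(utr, site, flank, backend),
    )
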