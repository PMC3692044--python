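"""Evolutionary features of target sites.

Two complementary views of conservation:

* **BLS** (branch length score): the summed branch length of the
  minimal subtree connecting the species in which the seed match is
  present — the evolutionary time during which the site existed.
* **phyloP-style LRT**: negative-selection test on the site columns. A
  site-specific scale factor λ multiplies every branch length of the
  neutral tree; λ̂ is estimated by maximum likelihood (Felsenstein
  pruning) and compared with λ = 1 by a likelihood-ratio test. λ̂ < 1
  means the site accumulates fewer substitutions than the neutral
  expectation (conservation), λ̂ > 1 acceleration. The reported score is
  −log10 of the one-sided p-value, signed positive for conservation.

The neutral substitution model is JC69 by default; HKY85 is available.
Alignment rows for species absent from the tree are ignored with a
warning; tree leaves without an alignment row are pruned from the
likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from .errors import DataError, OptimizationError
from .io_formats import GAP, PhyloTree, SpeciesAlignment
from .site_scanner import TargetSite

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"
_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

LAMBDA_BOUNDS = (1e-4, 10.0)


@dataclass
class SubstitutionModel:
    """Nucleotide substitution model: JC69 or HKY85.

    Branch lengths are in expected substitutions per site, so the rate
    matrix is scaled to unit expected rate at equilibrium.
    """

    kind: str = "JC69"
    frequencies: np.ndarray | None = None
    kappa: float = 2.0  # HKY transition/transversion rate ratio

    def __post_init__(self) -> None:
        if self.kind not in ("JC69", "HKY85"):
            raise DataError(f"unknown substitution model {self.kind!r}")
        if self.kind == "JC69":
            self.frequencies = np.full(4, 0.25)
        else:
            if self.frequencies is None:
                self.frequencies = np.full(4, 0.25)
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            if abs(self.frequencies.sum() - 1) > 1e-9 or (self.frequencies <= 0).any():
                raise DataError("HKY85 frequencies must be positive and sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """Normalized rate matrix Q (rows sum to 0, unit mean rate)."""
        pi = self.frequencies
        if self.kind == "JC69":
            q = np.full((4, 4), 1.0 / 3.0)
            np.fill_diagonal(q, -1.0)
            return q
        # HKY85: transitions A<->G (0,2) and C<->U (1,3)
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if {i, j} in ({0, 2}, {1, 3}):
                    rate *= self.kappa
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(q))
        return q / mean_rate

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); closed form for JC69, expm for HKY85."""
        if t < 0:
            raise DataError("negative branch length")
        if self.kind == "JC69":
            e = math.exp(-4.0 * t / 3.0)
            same = 0.25 + 0.75 * e
            diff = 0.25 - 0.25 * e
            p = np.full((4, 4), diff)
            np.fill_diagonal(p, same)
            return p
        return linalg.expm(self.rate_matrix() * t)


@dataclass
class ConservationResult:
    """BLS and phyloP-style outputs for one site."""

    bls: float
    phylop_p: float
    phylop_score: float
    lam: float | None = None


# ---------------------------------------------------------------------------
# site presence and BLS


def site_presence(
    aln: SpeciesAlignment, site: TargetSite, seed_match: str, slop: int = 2
) -> set[str]:
    """Species whose aligned region contains the seed match exactly.

    The site's ungapped reference coordinates are mapped to alignment
    columns; each species' gap-stripped subsequence over those columns,
    extended by ``slop`` columns on each side to tolerate alignment
    jitter, is searched for the exact match string.
    """
    ref_len = len(aln.ref_ungapped())
    if not (0 <= site.start < site.end <= ref_len):
        raise DataError(
            f"site [{site.start},{site.end}) outside reference row "
            f"({ref_len} nt ungapped)"
        )
    cols = aln.ref_coord_to_column()
    lo = max(0, cols[site.start] - slop)
    hi = min(aln.n_columns, cols[site.end - 1] + 1 + slop)
    present: set[str] = set()
    for species, row in aln.rows.items():
        segment = row[lo:hi].replace(GAP, "")
        if seed_match in segment:
            present.add(species)
    return present


def bls(tree: PhyloTree, present: set[str], normalize: bool = False) -> float:
    """Branch length of the minimal subtree connecting ``present``.

    0.0 for zero or one species. With ``normalize`` the value is divided
    by the total tree length.
    """
    leaves = set(tree.leaf_labels())
    missing = present - leaves
    if missing:
        raise DataError(f"species not in tree: {sorted(missing)}")
    if len(present) <= 1:
        return 0.0
    mrca = tree.tree.mrca(taxon_labels=sorted(present))
    total = 0.0
    seen: set[int] = set()
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label not in present:
            continue
        node = leaf
        while node is not mrca:
            if id(node) in seen:
                break
            seen.add(id(node))
            total += node.edge.length or 0.0
            node = node.parent_node
    if normalize:
        tl = tree.total_length()
        return total / tl if tl > 0 else 0.0
    return total


# ---------------------------------------------------------------------------
# Felsenstein pruning and the phyloP-style LRT


def _flatten_tree(tree: PhyloTree, keep: set[str]):
    """Postorder node arrays restricted to leaves in ``keep``.

    Returns (postorder list of (children-indices, branch-length),
    leaf-label → index). The tree is logically pruned: internal nodes
    with a single retained child collapse into the child's branch.
    """
    nodes = []
    index: dict[str, int] = {}

    def visit(node) -> tuple[int, float] | None:
        if node.is_leaf():
            label = node.taxon.label
            if label not in keep:
                return None
            nodes.append(([], label))
            index[label] = len(nodes) - 1
            return (len(nodes) - 1, node.edge.length or 0.0)
        kept = [r for r in (visit(c) for c in node.child_nodes()) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child_idx, blen = kept[0]
            return (child_idx, blen + (node.edge.length or 0.0))
        nodes.append((kept, None))
        return (len(nodes) - 1, node.edge.length or 0.0)

    root = visit(tree.tree.seed_node)
    if root is None:
        raise DataError("no tree leaves retained")
    return nodes, index, root[0]


def _columns_matrix(columns: SpeciesAlignment, species: list[str]) -> np.ndarray:
    """Integer matrix (n_species × n_cols); −1 encodes gap/N (missing)."""
    mat = np.full((len(species), columns.n_columns), -1, dtype=np.int64)
    for i, sp in enumerate(species):
        for j, ch in enumerate(columns.rows[sp]):
            mat[i, j] = _INDEX.get(ch, -1)
    return mat


def felsenstein_loglik(
    tree: PhyloTree,
    columns: SpeciesAlignment,
    model: SubstitutionModel,
    scale: float = 1.0,
) -> float:
    """Pruning-algorithm log-likelihood of independent alignment columns,
    with every branch length multiplied by ``scale``.

    Species present in only one of tree/alignment are dropped (with a
    warning for alignment rows absent from the tree). Gap/N cells are
    treated as missing data.
    """
    if scale <= 0:
        raise DataError("branch scale must be positive")
    tree_leaves = set(tree.leaf_labels())
    aln_species = set(columns.rows)
    extra = aln_species - tree_leaves
    if extra:
        logger.warning("alignment rows ignored (absent from tree): %s", sorted(extra))
    keep = tree_leaves & aln_species
    if not keep:
        raise DataError("no species shared between tree and alignment")
    nodes, leaf_index, root_idx = _flatten_tree(tree, keep)
    mat_species = [l for _, l in nodes if isinstance(l, str)]
    mat = _columns_matrix(columns, mat_species)
    ncols = mat.shape[1]
    partial: list[np.ndarray] = [None] * len(nodes)  # type: ignore[list-item]
    leaf_row = 0
    for idx, (children, label) in enumerate(nodes):
        if isinstance(label, str):
            lik = np.zeros((ncols, 4))
            obs = mat[leaf_row]
            leaf_row += 1
            missing = obs < 0
            lik[missing, :] = 1.0
            lik[np.arange(ncols)[~missing], obs[~missing]] = 1.0
            partial[idx] = lik
        else:
            lik = np.ones((ncols, 4))
            for child_idx, blen in children:
                p = model.transition_matrix(blen * scale)
                lik = lik * (partial[child_idx] @ p.T)
            partial[idx] = lik
    root_lik = partial[root_idx]
    site_probs = root_lik @ model.frequencies
    if (site_probs <= 0).any():
        raise DataError("zero likelihood column (conflicting states on a zero-length tree?)")
    return float(np.log(site_probs).sum())


def phylop_score(
    tree: PhyloTree,
    columns: SpeciesAlignment,
    neutral: SubstitutionModel | None = None,
) -> ConservationResult:
    """phyloP-style likelihood-ratio conservation test on site columns.

    λ̂ (branch scale) is optimized in [1e-4, 10]; the LRT statistic
    2·(ℓ(λ̂) − ℓ(1)) is referred to χ²₁ halved for the one-sided
    alternative in the fitted direction. ``phylop_p`` is the one-sided
    conservation p-value (uniform under neutrality); ``phylop_score`` is
    −log10 of the directional p-value, positive for λ̂ < 1 (conserved),
    negative for λ̂ > 1 (accelerated), 0 at λ̂ = 1. The BLS field is not
    filled here (it needs the presence set); it is set to NaN.
    """
    neutral = neutral or SubstitutionModel("JC69")
    shared = set(tree.leaf_labels()) & set(columns.rows)
    if len(shared) < 2:
        raise DataError("phyloP test needs >= 2 species with data")

    def nll(lam: float) -> float:
        return -felsenstein_loglik(tree, columns, neutral, scale=lam)

    res = minimize_scalar(
        nll, bounds=LAMBDA_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise OptimizationError(f"branch-scale optimization failed: {res.message}")
    lam = float(res.x)
    ll_hat = -float(res.fun)
    ll_null = felsenstein_loglik(tree, columns, neutral, scale=1.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll_null))
    tail = 0.5 * stats.chi2.sf(lrt, df=1)  # one-sided directional p
    if lrt < 1e-10:
        p_cons, score = 1.0, 0.0
    elif lam < 1.0:
        p_cons = tail
        score = -math.log10(max(tail, 1e-300))
    else:
        p_cons = 1.0 - tail
        score = math.log10(max(tail, 1e-300))
    return ConservationResult(
        bls=float("nan"), phylop_p=p_cons, phylop_score=score, lam=lam
    )


def conservation_features(
    tree: PhyloTree,
    aln: SpeciesAlignment,
    site: TargetSite,
    seed_match: str,
    neutral: SubstitutionModel | None = None,
    normalize_bls: bool = False,
) -> ConservationResult:
    """BLS + phyloP-style test for one site on a supplied alignment."""
    present = site_presence(aln, site, seed_match)
    present &= set(tree.leaf_labels())
    score = bls(tree, present, normalize=normalize_bls)
    cols = aln.ref_coord_to_column()
    lo, hi = cols[site.start], cols[site.end - 1] + 1
    window = SpeciesAlignment(
        rows={sp: row[lo:hi] for sp, row in aln.rows.items()},
        ref_species=aln.ref_species,
    )
    result = phylop_score(tree, window, neutral)
    result.bls = score
    return result
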