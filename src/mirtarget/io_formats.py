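"""Readers and writers for the standard formats the package touches.

Single home for coordinate and alphabet conventions:

* Sequences are stored in the RNA alphabet ``{A, C, G, U, N}``; DNA input
  is converted on read (``T`` → ``U``). ``N`` is permitted and never pairs
  or matches anything downstream.
* All coordinates are 0-based, half-open, both internally and in BED
  output. 1-based coordinates appear only in human-readable messages.
* BED output is in UTR-local space: ``chrom`` is the UTR id; no genome
  liftover is attempted.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import dendropy
from Bio import SeqIO

from .errors import DataError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(residues: str) -> str:
    """Reverse complement in RNA space (``N`` maps to ``N``)."""
    return residues.translate(_COMPLEMENT)[::-1]


def _normalize_residues(raw: str, *, allow_gaps: bool = False) -> str:
    seq = raw.upper().replace("T", "U")
    allowed = RNA_ALPHABET | {GAP} if allow_gaps else RNA_ALPHABET
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise DataError(
                f"illegal residue {ch!r} at position {pos + 1} (1-based)"
            )
    return seq


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence in the RNA alphabet.

    Parameters
    ----------
    id
        Record identifier (FASTA header word).
    residues
        Uppercase RNA residues over ``{A, C, G, U, N}``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise DataError(
                f"record {self.id!r}: residues outside RNA alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path, alphabet_policy: str = "dna_to_rna") -> list[NucSequence]:
    """Read a FASTA file into :class:`NucSequence` records, in file order.

    ``T`` residues are converted to ``U`` (policy ``dna_to_rna``, the only
    one supported). Duplicate ids and residues outside ``{A,C,G,U,N,T}``
    are hard errors.
    """
    if alphabet_policy != "dna_to_rna":
        raise ValueError(f"unknown alphabet policy: {alphabet_policy!r}")
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            residues = _normalize_residues(str(rec.seq))
        except DataError as exc:
            raise DataError(f"record {rec.id!r}: {exc}") from None
        records.append(NucSequence(id=rec.id, residues=residues))
    return records


def write_fasta(records: Iterable[NucSequence], out: TextIO, width: int = 60) -> None:
    for rec in records:
        out.write(f">{rec.id}\n")
        for i in range(0, len(rec.residues), width):
            out.write(rec.residues[i : i + width] + "\n")


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths (substitutions/site).

    Thin wrapper over a :class:`dendropy.Tree` that enforces the package's
    invariants: every non-root branch carries a nonnegative length, leaf
    labels are unique, and there are at least two leaves.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        leaves = self.leaf_labels()
        if len(leaves) < 2:
            raise DataError("tree must have at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            raise DataError("leaf labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise DataError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'!r}"
                )
            if edge.length < 0:
                raise DataError(f"negative branch length {edge.length}")

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def total_length(self) -> float:
        return sum(
            e.length
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node and e.length is not None
        )

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required on all non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"malformed newick: {exc}") from None
    tree.is_rooted = True
    return PhyloTree(tree=tree)


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


@dataclass
class SpeciesAlignment:
    """Orthologous UTR alignment: species name → gapped RNA row.

    All rows have equal length; ``ref_species`` must be present. The
    ungapped reference row is the reference UTR in whose coordinates
    target sites are expressed.
    """

    rows: dict[str, str]
    ref_species: str

    def __post_init__(self) -> None:
        if self.ref_species not in self.rows:
            raise DataError(
                f"reference species {self.ref_species!r} absent from alignment"
            )
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise DataError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ref_ungapped(self) -> str:
        return self.rows[self.ref_species].replace(GAP, "")

    def ref_coord_to_column(self) -> list[int]:
        """Column index of each ungapped reference position."""
        cols = []
        for col, ch in enumerate(self.rows[self.ref_species]):
            if ch != GAP:
                cols.append(col)
        return cols


def read_alignment(path, ref_species: str) -> SpeciesAlignment:
    """Read an aligned multi-FASTA (rows keyed by species name)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DataError(f"duplicate species {rec.id!r} in alignment {path}")
        rows[rec.id] = _normalize_residues(str(rec.seq), allow_gaps=True)
    if not rows:
        raise DataError(f"empty alignment file {path}")
    return SpeciesAlignment(rows=rows, ref_species=ref_species)


def write_bed(sites: Sequence, out: TextIO) -> None:
    """Write target sites as BED6 in UTR-local coordinates.

    name is ``<miRNA>|<site type>``; score is the site's percentile scaled
    to 0–1000 (0 when no percentile has been attached); strand is ``+``
    (3′-UTRs are scanned in sense orientation only).
    """
    for site in sites:
        pct = getattr(site, "percentile", None)
        score = 0 if pct is None else int(round(pct * 10))
        out.write(
            f"{site.utr_id}\t{site.start}\t{site.end}\t"
            f"{site.mirna_name}|{site.site_type}\t{score}\t+\n"
        )


def write_csv(rows: Sequence[Mapping[str, object]], out: TextIO) -> None:
    """Write report rows as RFC-4180 CSV with a header row.

    All rows must share one key set; the first row fixes column order.
    """
    rows = list(rows)
    if not rows:
        return
    fields = list(rows[0].keys())
    fieldset = set(fields)
    for i, row in enumerate(rows):
        if set(row.keys()) != fieldset:
            raise DataError(
                f"row {i} has inconsistent fields: "
                f"{sorted(set(row.keys()) ^ fieldset)}"
            )
    writer = csv.DictWriter(out, fieldnames=fields, lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)


def csv_string(rows: Sequence[Mapping[str, object]]) -> str:
    buf = io.StringIO()
    write_csv(rows, buf)
    return buf.getvalue()
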