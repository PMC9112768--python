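"""File formats and core containers for the toolkit.

Handles plain FASTA (seed/extant sequences), aligned FASTA (reference and
predicted MSAs), Newick trees, and the trinucleotide rate-matrix table used by
the sequence simulator.  Every other module goes through this layer.

Rate-matrix table dialect
-------------------------
A 65-line tab-separated table: a header row naming the 64 target triplets in
lexicographic order, then one row per source triplet (64 rows) giving the rate
of the source→target change per generation.  Only cells where the two triplets
differ at exactly the centre base may be non-zero (three valid targets per
source).  On read the matrix is normalised so that the mean total mutation
rate over the 64 source triplets equals 1 — the simulator's abstract "average
substitution rate of 1" — unless ``normalize=False``.

Conventions: coordinates are 0-based half-open throughout the package;
sequences are upper-cased on input and restricted to A/C/G/T/N (plus '-' in
alignments).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .tree_sim import Phylogeny, PhyloNode

__all__ = [
    "SeqRecord",
    "Msa",
    "TripletRateMatrix",
    "FormatError",
    "BASES",
    "TRIPLETS",
    "read_fasta",
    "write_fasta",
    "read_msa_fasta",
    "write_msa_fasta",
    "read_newick",
    "write_newick",
    "read_rate_matrix",
    "write_rate_matrix",
]

BASES = "ACGT"
#: all 64 trinucleotides in lexicographic order
TRIPLETS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
_TRIPLET_INDEX = {t: i for i, t in enumerate(TRIPLETS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_SEQ_ALPHABET = set("ACGTN")
_MSA_ALPHABET = _SEQ_ALPHABET | {"-"}


class FormatError(ValueError):
    """Raised on malformed input files or containers."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over A/C/G/T/N (upper case)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("SeqRecord id must be non-empty")
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _header_line_numbers(path) -> dict[str, int]:
    """Map FASTA record ids to the 1-based line number of their header."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rid = line[1:].split(None, 1)[0].strip() if line[1:].strip() else ""
                out.setdefault(rid, lineno)
    return out


def _parse_fasta(path, *, aligned: bool):
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA near line 1: {exc}") from exc
    if not raw:
        raise FormatError(f"{path}: no FASTA records found")
    lines = _header_line_numbers(path)
    alphabet = _MSA_ALPHABET if aligned else _SEQ_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in raw:
        where = f"{path} line {lines.get(rec.id, '?')}"
        if not rec.id:
            raise FormatError(f"{where}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{where}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{where}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - alphabet
        if bad:
            what = "gap/invalid" if "-" in bad and not aligned else "invalid"
            raise FormatError(
                f"{where}: record {rec.id!r} contains {what} characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def read_fasta(path) -> list[SeqRecord]:
    """Read unaligned FASTA; gap characters are rejected."""
    return [SeqRecord(rid, seq) for rid, seq in _parse_fasta(path, aligned=False)]


def write_fasta(records: list[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# multiple sequence alignments
# ---------------------------------------------------------------------------

class Msa:
    """An ordered gapped alignment over {A,C,G,T,N,-} keyed by sequence id.

    Invariants: all rows share the same length, ungapping any row yields a
    valid sequence, and no column is entirely gaps.
    """

    def __init__(self, rows: list[tuple[str, str]], *, drop_all_gap_columns: bool = False):
        if not rows:
            raise FormatError("Msa requires at least one row")
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate row ids in Msa: {dupes}")
        lengths = {len(r[1]) for r in rows}
        if len(lengths) != 1:
            ncols = len(rows[0][1])
            bad = [rid for rid, row in rows if len(row) != ncols]
            raise FormatError(f"ragged alignment rows for ids: {bad}")
        rows = [(rid, row.upper()) for rid, row in rows]
        for rid, row in rows:
            bad = set(row) - _MSA_ALPHABET
            if bad:
                raise FormatError(f"row {rid!r} contains invalid characters {sorted(bad)}")
            if not row.replace("-", ""):
                raise FormatError(f"row {rid!r} is entirely gaps")
        if drop_all_gap_columns:
            keep = [
                c for c in range(len(rows[0][1]))
                if any(row[c] != "-" for _, row in rows)
            ]
            rows = [(rid, "".join(row[c] for c in keep)) for rid, row in rows]
        else:
            for c in range(len(rows[0][1])):
                if all(row[c] == "-" for _, row in rows):
                    raise FormatError(f"column {c} consists entirely of gaps")
        self.rows: list[tuple[str, str]] = rows
        self._by_id = dict(rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self._by_id[rid]

    def ungapped(self, rid: str) -> str:
        return self._by_id[rid].replace("-", "")

    def ungapped_records(self) -> list[SeqRecord]:
        return [SeqRecord(rid, row.replace("-", "")) for rid, row in self.rows]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Msa):
            return NotImplemented
        return self.rows == other.rows

    def __repr__(self) -> str:  # pragma: no cover
        return f"Msa({self.nrows} rows x {self.ncols} cols)"


def read_msa_fasta(path, *, drop_all_gap_columns: bool = False) -> Msa:
    """Read an aligned FASTA file; ragged rows raise listing offending ids."""
    return Msa(_parse_fasta(path, aligned=True), drop_all_gap_columns=drop_all_gap_columns)


def write_msa_fasta(msa: Msa, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: PhyloNode, dnode) -> None:
        for child in node.children:
            dchild = dnode.new_child(edge_length=child.branch_length)
            if child.is_leaf:
                dchild.taxon = taxa.new_taxon(child.name)
            else:
                dchild.label = child.name
            build(child, dchild)

    root = dtree.seed_node
    root.label = tree.root.name
    if tree.root.is_leaf:
        root.taxon = taxa.new_taxon(tree.root.name)
    build(tree.root, root)
    return dtree


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    counter = itertools.count()

    def name_of(dnode) -> str:
        if dnode.taxon is not None and dnode.taxon.label:
            return dnode.taxon.label
        if dnode.label:
            return dnode.label
        return f"_internal{next(counter)}"

    def build(dnode, parent: PhyloNode | None) -> PhyloNode:
        bl = dnode.edge.length
        if parent is not None and bl is None:
            raise FormatError(f"node {name_of(dnode)!r} is missing a branch length")
        node = PhyloNode(
            name=name_of(dnode),
            branch_length=None if parent is None else float(bl),
            parent=parent,
        )
        for dchild in dnode.child_nodes():
            node.children.append(build(dchild, node))
        return node

    root = build(dtree.seed_node, None)
    tree = Phylogeny(root)
    tree.validate()
    return tree


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree; branch lengths required off-root."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny, path) -> None:
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()
    with open(path, "w") as fh:
        fh.write(text + "\n")


# ---------------------------------------------------------------------------
# triplet rate matrix
# ---------------------------------------------------------------------------

@dataclass
class TripletRateMatrix:
    """Per-generation centre-base substitution rates with 1 bp flanking context.

    ``rates[i, b]`` is the rate at which source triplet ``TRIPLETS[i]`` mutates
    its centre base to ``BASES[b]``; cells where ``BASES[b]`` equals the centre
    base are structurally zero.
    """

    rates: np.ndarray  # shape (64, 4)
    _marginal_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (64, 4):
            raise FormatError(f"rate array must be (64, 4), got {self.rates.shape}")
        if np.any(self.rates < 0):
            i, b = np.argwhere(self.rates < 0)[0]
            raise FormatError(
                f"negative rate at {TRIPLETS[i]}->{TRIPLETS[i][0]}{BASES[b]}{TRIPLETS[i][2]}"
            )
        for i, trip in enumerate(TRIPLETS):
            c = _BASE_INDEX[trip[1]]
            if self.rates[i, c] != 0.0:
                raise FormatError(f"diagonal (no-change) cell {trip}->{trip} must be zero")

    # -- lookups -----------------------------------------------------------
    def rate(self, source: str, target_center: str) -> float:
        return float(self.rates[_TRIPLET_INDEX[source], _BASE_INDEX[target_center]])

    def total_rate(self, source: str) -> float:
        return float(self.rates[_TRIPLET_INDEX[source]].sum())

    def mean_total_rate(self) -> float:
        return float(self.rates.sum(axis=1).mean())

    def context_rates(self, left: str | None, center: str, right: str | None) -> np.ndarray:
        """Target-base rate vector for a site, marginalising unknown flanks.

        ``left``/``right`` may be None (sequence edge) or 'N'; either case
        averages over the four possible flanking bases.  A centre base of 'N'
        is immutable (zero vector): N is never mutated from or to.
        """
        lkey = left if left in _BASE_INDEX else "*"
        rkey = right if right in _BASE_INDEX else "*"
        key = (lkey, center, rkey)
        cached = self._marginal_cache.get(key)
        if cached is not None:
            return cached
        if center not in _BASE_INDEX:
            vec = np.zeros(4)
        else:
            lefts = BASES if lkey == "*" else lkey
            rights = BASES if rkey == "*" else rkey
            acc = np.zeros(4)
            n = 0
            for l in lefts:
                for r in rights:
                    acc += self.rates[_TRIPLET_INDEX[l + center + r]]
                    n += 1
            vec = acc / n
        self._marginal_cache[key] = vec
        return vec

    def normalized(self) -> "TripletRateMatrix":
        """Scale so the mean total rate over the 64 source triplets is 1."""
        mean = self.mean_total_rate()
        if mean <= 0:
            raise FormatError("cannot normalize an all-zero rate matrix")
        return TripletRateMatrix(self.rates / mean)


def read_rate_matrix(path, *, normalize: bool = True) -> TripletRateMatrix:
    """Read the 65-line TSV dialect and validate every one of the 64x64 cells."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse rate-matrix TSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing_rows = [t for t in TRIPLETS if t not in df.index]
    missing_cols = [t for t in TRIPLETS if t not in df.columns]
    if missing_rows or missing_cols:
        raise FormatError(
            f"{path}: missing triplets rows={missing_rows[:3]} cols={missing_cols[:3]}"
        )
    table = df.loc[TRIPLETS, TRIPLETS].to_numpy(dtype=float)
    rates = np.zeros((64, 4))
    for i, src in enumerate(TRIPLETS):
        for j, tgt in enumerate(TRIPLETS):
            val = table[i, j]
            if val == 0.0:
                continue
            if val < 0:
                raise FormatError(f"{path}: negative rate in cell {src}->{tgt}")
            same_flanks = src[0] == tgt[0] and src[2] == tgt[2]
            if not same_flanks:
                raise FormatError(
                    f"{path}: cell {src}->{tgt} changes a flanking base (must be zero)"
                )
            if src[1] == tgt[1]:
                raise FormatError(f"{path}: diagonal cell {src}->{tgt} must be zero")
            rates[i, _BASE_INDEX[tgt[1]]] = val
    matrix = TripletRateMatrix(rates)
    return matrix.normalized() if normalize else matrix


def write_rate_matrix(matrix: TripletRateMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + TRIPLETS) + "\n")
        for i, src in enumerate(TRIPLETS):
            cells = []
            for tgt in TRIPLETS:
                if src[0] == tgt[0] and src[2] == tgt[2] and src[1] != tgt[1]:
                    cells.append(f"{matrix.rates[i, _BASE_INDEX[tgt[1]]]:.12g}")
                else:
                    cells.append("0")
            fh.write("\t".join([src] + cells) + "\n")
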