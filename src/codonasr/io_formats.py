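"""Sequence and tree containers plus FASTA / Newick / TSV state-table I/O.

All pipeline stages exchange three containers defined here: the validated
:class:`SequenceRecord`, the rectangular :class:`Alignment`, and the rooted
:class:`Tree` (parent-array representation with branch lengths in expected
substitutions per site).  FASTA parsing is backed by Bio.SeqIO and Newick by
dendropy; validation (alphabets, duplicate ids, missing branch lengths) is
applied on top so that malformed input fails loudly at the boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA = "dna"
PROTEIN = "protein"
BINARY = "binary"

_ALPHABETS = {
    DNA: frozenset("ACGTN-"),
    PROTEIN: frozenset("ACDEFGHIKLMNPQRSTVWYX*-"),
    BINARY: frozenset("01"),
}

GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence over a declared alphabet.

    Sequences are upper-cased on construction; DNA 'U' is mapped to 'T'
    with a logged warning (RNA input is tolerated but normalised).
    """

    id: str
    seq: str
    alphabet: str = DNA

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}: empty or contains whitespace")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seq = self.seq.upper()
        if self.alphabet == DNA and "U" in seq:
            logger.warning("sequence %s: mapping RNA 'U' to 'T'", self.id)
            seq = seq.replace("U", "T")
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        allowed = _ALPHABETS[self.alphabet]
        for pos, c in enumerate(seq, start=1):
            if c not in allowed:
                raise ValueError(
                    f"sequence {self.id!r}: character {c!r} at position {pos} "
                    f"is not in the {self.alphabet} alphabet"
                )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered set of equal-length sequences over one alphabet."""

    records: list[SequenceRecord]
    alphabet: str = DNA

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dup}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def __contains__(self, seq_id: str) -> bool:
        return any(r.id == seq_id for r in self.records)

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string, one character per row."""
        return "".join(r.seq[j] for r in self.records)

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n_rows, n_columns)."""
        return np.array([list(r.seq) for r in self.records])


def parse_fasta(text: str, alphabet: str = DNA) -> list[SequenceRecord]:
    """Parse FASTA text into validated records.

    The header token before the first whitespace becomes the id.  Raises
    ``ValueError`` on empty input, duplicate ids, or characters outside the
    declared alphabet (naming the offending character and 1-based position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), alphabet=alphabet))
    if not records:
        raise ValueError("no FASTA records found in input")
    return records


def read_fasta(path: str | Path, alphabet: str = DNA) -> list[SequenceRecord]:
    return parse_fasta(Path(path).read_text(), alphabet=alphabet)


def write_fasta(records: Iterable[SequenceRecord], path_or_handle, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips through :func:`parse_fasta`)."""
    own = isinstance(path_or_handle, (str, Path))
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        for r in records:
            handle.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                handle.write(r.seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def fasta_string(records: Iterable[SequenceRecord], width: int = 60) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Rooted tree in parent-array form.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root),
    ``lengths[i]`` the branch length of the edge above node ``i`` (0.0 at the
    root), ``names[i]`` the leaf label or internal-node label.  Unlabelled
    internal nodes are auto-named ``node<k>`` in preorder so downstream
    posterior tables always have stable node ids.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str | None]

    children: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        if self.lengths.size != n or len(self.names) != n:
            raise ValueError("parent, lengths and names must have equal length")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.children = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self.children[p].append(i)
        # connectivity/acyclicity: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while self.parent[j] != -1:
                j = int(self.parent[j])
                seen += 1
                if seen > n:
                    raise ValueError("cycle detected in tree")
        leaf_names = [self.names[i] for i in self.leaves()]
        if any(nm is None for nm in leaf_names):
            raise ValueError("every leaf must be labelled")
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf labels")
        self._autoname_internals()

    def _autoname_internals(self) -> None:
        taken = {nm for nm in self.names if nm}
        k = 1
        for i in self.preorder():
            if self.children[i] and not self.names[i]:
                while f"node{k}" in taken:
                    k += 1
                self.names[i] = f"node{k}"
                taken.add(self.names[i])

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves()]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def find(self, name: str) -> int:
        for i, nm in enumerate(self.names):
            if nm == name:
                return i
        raise KeyError(f"no node named {name!r}")

    # -- dendropy bridge ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        names: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    logger.warning("missing branch length treated as 0")
                    lengths[i] = 0.0
                else:
                    lengths[i] = float(nd.edge.length)
            if nd.taxon is not None:
                names[i] = nd.taxon.label
            elif nd.label:
                names[i] = str(nd.label)
        return cls(parent=parent, lengths=lengths, names=names)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for i in self.preorder():
            if i == self.root:
                nd = dtree.seed_node
            else:
                nd = dendropy.Node()
                dnodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.lengths[i])
            dnodes[i] = nd
            if self.is_leaf(i):
                nd.taxon = taxa.new_taxon(self.names[i])
            elif self.names[i]:
                nd.label = self.names[i]
        return dtree

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf(i):
                base = self.names[i]
            else:
                inner = ",".join(fmt(c) for c in self.children[i])
                base = f"({inner}){self.names[i] or ''}"
            if i == self.root:
                return base
            return f"{base}:{self.lengths[i]:.12g}"

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.lengths.copy(), list(self.names))


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Branch lengths are preserved to full precision; missing lengths default
    to 0 with a logged warning.  Internal-node support labels become node
    labels, never lengths.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick statement")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return Tree.from_dendropy(dtree)


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root (or re-root) the tree on the edge leading to the outgroup leaf.

    The outgroup edge is split at its midpoint.  Under a reversible model the
    placement along that edge does not affect marginal posteriors elsewhere.
    """
    dtree = tree.to_dendropy()
    taxon = dtree.taxon_namespace.get_taxon(outgroup)
    if taxon is None:
        raise KeyError(f"outgroup {outgroup!r} not found among leaves")
    node = dtree.find_node_with_taxon_label(outgroup)
    length = node.edge.length or 0.0
    dtree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    dtree.suppress_unifurcations()
    return Tree.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Posterior state tables (TSV)
# ---------------------------------------------------------------------------


def write_state_table(table, path: str | Path) -> None:
    """Write a posterior table as TSV: node, site, state, probability.

    One row per (node, site, state) with probability > 0; probabilities are
    printed at 6 decimals minimum.  Tab-delimited, UTF-8, '.' decimals.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tsite\tstate\tprobability\n")
        for ni, node in enumerate(table.node_ids):
            for si in range(table.probs.shape[1]):
                for xi, state in enumerate(table.states):
                    p = table.probs[ni, si, xi]
                    if p > 0:
                        fh.write(f"{node}\t{si + 1}\t{state}\t{p:.6f}\n")


def read_state_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_state_table` into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"node": str, "state": str})
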