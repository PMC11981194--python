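"""Empirical-Bayes marginal ancestral reconstruction and variant calling.

The reconstruction is marginal (per node), not joint: for every internal
node v, site s and state x the posterior P(x | data) is computed from the
downward partial likelihoods (data below v) and the upward complementary
partials (data elsewhere plus the root prior), with model parameters held
fixed.  Rate mixtures are handled the standard empirical-Bayes way — the
per-category posteriors are averaged with the per-site category posterior
weights, and the invariant-site class contributes its own term.

Indels are reconstructed separately on a binary presence/absence recoding of
the same alignment under the two-state JC2 model with branch lengths taken
as-is.  Nucleotide and indel posteriors are then combined per codon: the
probability of a codon is the product of its three nucleotide posteriors,
and a codon is called a gap at a node when its mean gap posterior exceeds
0.5 (the MAP decision on the binary state).  Residue posteriors sum the
renormalised codon posteriors over synonymous codons, and ambiguity is
called at the residue level: every state with posterior above the threshold
(default 0.3) becomes a candidate, and candidate combinations across the
positions of interest are enumerated as alternative ancestral variants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import BINARY, DNA, GAP, PROTEIN, Alignment, SequenceRecord, Tree, root_with_outgroup
from .phylo_models import (
    SubstitutionModel,
    _pruning_pass,
    build_model,
    encode_alignment,
)
from .seqprep import CodonAlignment

logger = logging.getLogger(__name__)

AA_STATES = tuple(sorted(set(standard_dna_table.forward_table.values()))) + (GAP,)
CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")


@dataclass
class PosteriorTable:
    """Posterior state probabilities P[node, site, state].

    Rows normalise to 1 per (node, site) within numerical tolerance; sites
    are 1-based in all serialised output.
    """

    node_ids: list[str]
    states: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.node_ids), self.probs.shape[1], len(self.states)):
            raise ValueError("probs must have shape (n_nodes, n_sites, n_states)")

    @property
    def n_sites(self) -> int:
        return self.probs.shape[1]

    def node(self, node_id: str) -> np.ndarray:
        return self.probs[self.node_ids.index(node_id)]

    def map_states(self, node_id: str) -> str:
        """MAP state string for one node (ties broken by state order)."""
        P = self.node(node_id)
        return "".join(self.states[i] for i in P.argmax(axis=1))


def _up_pass(tree: Tree, model: SubstitutionModel, pr, ci: int):
    """Upward partials for category ``ci`` (complement of the down pass)."""
    n_sites = pr.down[ci][tree.root].shape[0]
    k = model.n_states
    up = [None] * tree.n_nodes
    up_scale = [None] * tree.n_nodes
    up[tree.root] = np.broadcast_to(model.freqs, (n_sites, k)).copy()
    up_scale[tree.root] = np.zeros(n_sites)
    tiny = np.finfo(float).tiny
    for v in tree.preorder():
        kids = tree.children[v]
        for c in kids:
            prod = up[v].copy()
            sc = up_scale[v].copy()
            for s in kids:
                if s != c:
                    prod = prod * pr.messages[ci][s]
                    sc = sc + pr.down_logscale[ci][s]
            out = prod @ pr.transition[ci][c]
            m = np.maximum(out.max(axis=1), tiny)
            up[c] = out / m[:, None]
            up_scale[c] = sc + np.log(m)
    return up, up_scale


def marginal_asr(
    tree: Tree,
    aln: Alignment | CodonAlignment,
    model: SubstitutionModel,
    outgroup: str | None = None,
) -> PosteriorTable:
    """Marginal (empirical-Bayes) ancestral state posteriors.

    Requires a rooted tree; an unrooted input (root with more than two
    children) must come with an ``outgroup`` leaf name used to place the
    root.  Posteriors are reported for internal nodes of the rooted tree.
    """
    if isinstance(aln, CodonAlignment):
        aln = aln.alignment
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup)
    elif len(tree.children[tree.root]) > 2:
        # Under a reversible model internal-node marginals are invariant to
        # the root position, so a multifurcating "root" is usable as given.
        logger.warning(
            "tree root is multifurcating and no outgroup was declared; "
            "treating the supplied root node as the rooting point"
        )
    codes = encode_alignment(tree, aln, model)
    pr = _pruning_pass(tree, codes, model)
    n_sites = aln.n_columns
    k = model.n_states
    ncat = model.n_categories

    # per-site mixture weights over categories (+ invariant class)
    parts = np.log(model.weights)[:, None] + pr.site_loglik  # (ncat, S)
    if model.p_inv > 0:
        l_inv = pr.const_ok @ model.freqs
        with np.errstate(divide="ignore"):
            inv_part = np.log(model.p_inv) + np.log(l_inv)
        parts = np.vstack([np.log1p(-model.p_inv) + parts, inv_part[None, :]])
    m = parts.max(axis=0)
    w = np.exp(parts - m[None, :])
    w /= w.sum(axis=0)[None, :]  # (ncat[+1], S)

    internals = tree.internal_nodes()
    post = np.zeros((len(internals), n_sites, k))
    for ci in range(ncat):
        up, _ = _up_pass(tree, model, pr, ci)
        for vi, v in enumerate(internals):
            J = up[v] * pr.down[ci][v]
            tot = J.sum(axis=1)
            tot[tot == 0] = 1.0
            post[vi] += w[ci][:, None] * (J / tot[:, None])
    if model.p_inv > 0:
        l_inv = pr.const_ok @ model.freqs
        safe = np.where(l_inv > 0, l_inv, 1.0)
        inv_post = (pr.const_ok * model.freqs[None, :]) / safe[:, None]
        for vi in range(len(internals)):
            post[vi] += w[-1][:, None] * inv_post
    node_ids = [tree.names[v] for v in internals]
    return PosteriorTable(node_ids=node_ids, states=model.states, probs=post)


def recode_binary(aln: Alignment | CodonAlignment) -> Alignment:
    """Recode an alignment column-wise to gap presence/absence.

    '0' marks a non-gap character and '1' a gap, following the convention of
    binary indel matrices for reconstruction.
    """
    if isinstance(aln, CodonAlignment):
        aln = aln.alignment
    records = [
        SequenceRecord(
            id=r.id,
            seq="".join("1" if c == GAP else "0" for c in r.seq),
            alphabet=BINARY,
        )
        for r in aln.records
    ]
    return Alignment(records=records, alphabet=BINARY)


def indel_asr(
    tree: Tree,
    aln: Alignment | CodonAlignment,
    jc2: SubstitutionModel | None = None,
    outgroup: str | None = None,
) -> PosteriorTable:
    """Marginal ancestral reconstruction of gap presence/absence.

    The alignment is recoded to binary states and reconstructed under the
    two-state equal-rate JC2 model.  Branch lengths of the supplied tree are
    used exactly as given — never re-optimised on the binary data.
    """
    if jc2 is None:
        jc2 = build_model("JC2")
    if jc2.n_states != 2:
        raise ValueError("indel reconstruction requires a two-state model")
    binary = recode_binary(aln)
    return marginal_asr(tree, binary, jc2, outgroup=outgroup)


@dataclass
class CodonPosteriorTable:
    """Per-codon posteriors from combining nucleotide and indel ASR.

    ``raw[n, c, j]`` is the product of the three nucleotide posteriors of
    codon ``CODONS[j]`` at codon site ``c`` (products need not sum to one);
    ``norm`` is the renormalised distribution.  ``gap_called`` marks codon
    sites whose mean gap posterior exceeded the gap threshold — there the
    gap state supersedes all codon states.
    """

    node_ids: list[str]
    raw: np.ndarray
    norm: np.ndarray
    gap_prob: np.ndarray
    gap_called: np.ndarray
    codons: tuple[str, ...] = CODONS

    @property
    def n_codon_sites(self) -> int:
        return self.raw.shape[1]


def combine_codon(
    nuc: PosteriorTable,
    indel: PosteriorTable,
    gap_threshold: float = 0.5,
) -> CodonPosteriorTable:
    """Combine nucleotide and indel posteriors into codon posteriors.

    The probability of each codon is the product of the posteriors of its
    three nucleotides.  A codon site is called a gap at a node when the mean
    posterior of the gap state over its three columns exceeds
    ``gap_threshold`` (default 0.5, the MAP decision on the binary state).
    """
    if nuc.node_ids != indel.node_ids:
        raise ValueError("nucleotide and indel tables cover different node sets")
    if nuc.n_sites != indel.n_sites:
        raise ValueError("nucleotide and indel tables cover different site sets")
    if nuc.n_sites % 3 != 0:
        raise ValueError("nucleotide table length is not divisible by 3 (frame mismatch)")
    gap_state = indel.states.index("1")
    n_nodes = len(nuc.node_ids)
    n_codons = nuc.n_sites // 3
    P = nuc.probs.reshape(n_nodes, n_codons, 3, len(nuc.states))
    raw = np.einsum("nca,ncb,ncd->ncabd", P[:, :, 0], P[:, :, 1], P[:, :, 2])
    raw = raw.reshape(n_nodes, n_codons, 64)
    tot = raw.sum(axis=2)
    safe = np.where(tot > 0, tot, 1.0)
    norm = raw / safe[:, :, None]
    gap_prob = indel.probs[:, :, gap_state].reshape(n_nodes, n_codons, 3).mean(axis=2)
    return CodonPosteriorTable(
        node_ids=list(nuc.node_ids),
        raw=raw,
        norm=norm,
        gap_prob=gap_prob,
        gap_called=gap_prob > gap_threshold,
    )


def residue_posteriors(codons: CodonPosteriorTable) -> tuple[PosteriorTable, np.ndarray]:
    """Amino-acid (+ gap) posteriors from renormalised codon posteriors.

    P(aa) sums the synonymous codons of the standard genetic code; at
    gap-called sites the gap state takes probability 1.  Stop-codon mass is
    returned separately (and warned about when non-negligible) so that
    P(aa) + P(gap) + P(stop) conserves to 1.
    """
    n_nodes, n_sites, _ = codons.norm.shape
    aa_index = {aa: i for i, aa in enumerate(AA_STATES)}
    probs = np.zeros((n_nodes, n_sites, len(AA_STATES)))
    stop_mass = np.zeros((n_nodes, n_sites))
    for j, codon in enumerate(codons.codons):
        aa = standard_dna_table.forward_table.get(codon)
        if aa is None:  # stop codon
            stop_mass += codons.norm[:, :, j]
        else:
            probs[:, :, aa_index[aa]] += codons.norm[:, :, j]
    gap_col = aa_index[GAP]
    called = codons.gap_called
    probs[called] = 0.0
    probs[:, :, gap_col][called] = 1.0
    stop_mass[called] = 0.0
    worst = float(stop_mass.max()) if stop_mass.size else 0.0
    if worst > 0.05:
        logger.warning("ancestral stop-codon posterior mass up to %.3f detected", worst)
    table = PosteriorTable(node_ids=list(codons.node_ids), states=AA_STATES, probs=probs)
    return table, stop_mass


@dataclass(frozen=True)
class InterfaceRegion:
    """A contiguous run of interface residues in reference numbering."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.label}: start {self.start} > end {self.end}")

    def positions(self) -> list[int]:
        return list(range(self.start, self.end + 1))


@dataclass(frozen=True)
class AncestralVariant:
    label: str
    residues: str  # one character per queried position
    states: tuple[str, ...]
    joint_probability: float


@dataclass
class AncestralVariantSet:
    node: str
    positions: list[int]  # 1-based residue sites in the posterior table
    variants: list[AncestralVariant] = field(default_factory=list)


def _node_tag(node_id: str) -> str:
    return node_id[4:] if node_id.startswith("node") else node_id


def call_variants(
    residues: PosteriorTable,
    node: str,
    positions: Sequence[int],
    threshold: float = 0.3,
    max_variants: int = 16,
) -> AncestralVariantSet:
    """Enumerate alternative ancestral residue combinations at a node.

    At each queried position every state with posterior strictly greater
    than ``threshold`` is a candidate (the ambiguity rule); a position where
    no state clears the threshold contributes its single MAP state with a
    warning.  Variants are the Cartesian product of candidates, ordered by
    descending joint probability (product of the chosen-state posteriors)
    and truncated at ``max_variants``.  Labels are ``anc<node>.<rank>``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if not positions:
        raise ValueError("empty position list")
    P = residues.node(node)
    candidates: list[list[tuple[str, float]]] = []
    for pos in positions:
        if not 1 <= pos <= residues.n_sites:
            raise IndexError(f"position {pos} outside table with {residues.n_sites} sites")
        col = P[pos - 1]
        cands = [
            (residues.states[i], float(col[i]))
            for i in np.argsort(col)[::-1]
            if col[i] > threshold
        ]
        if not cands:
            imax = int(col.argmax())
            logger.warning(
                "node %s position %d: no state exceeds p=%.2f; using MAP state %s (p=%.3f)",
                node, pos, threshold, residues.states[imax], col[imax],
            )
            cands = [(residues.states[imax], float(col[imax]))]
        candidates.append(cands)
    combos = []
    for choice in itertools.product(*candidates):
        states = tuple(s for s, _ in choice)
        joint = float(np.prod([p for _, p in choice]))
        combos.append((states, joint))
    combos.sort(key=lambda c: (-c[1], c[0]))
    n_total = len(combos)
    if n_total > max_variants:
        logger.warning(
            "node %s: %d candidate variants truncated to %d", node, n_total, max_variants
        )
        combos = combos[:max_variants]
    tag = _node_tag(node)
    variants = [
        AncestralVariant(
            label=f"anc{tag}.{k}",
            residues="".join(states),
            states=states,
            joint_probability=joint,
        )
        for k, (states, joint) in enumerate(combos, start=1)
    ]
    return AncestralVariantSet(node=node, positions=list(positions), variants=variants)


def posterior_table_from_tsv(path) -> PosteriorTable:
    """Rebuild a :class:`PosteriorTable` from a written state-table TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"node": str, "state": str})
    node_ids = list(dict.fromkeys(df["node"]))
    states = tuple(sorted(df["state"].unique()))
    n_sites = int(df["site"].max())
    probs = np.zeros((len(node_ids), n_sites, len(states)))
    n_idx = {n: i for i, n in enumerate(node_ids)}
    s_idx = {s: i for i, s in enumerate(states)}
    for node, site, state, p in df.itertuples(index=False):
        probs[n_idx[node], site - 1, s_idx[state]] = p
    return PosteriorTable(node_ids=node_ids, states=states, probs=probs)


def map_reference_positions(
    aln: Alignment, reference_id: str, positions: Sequence[int]
) -> list[int]:
    """Translate reference residue numbers to alignment columns (1-based).

    The k-th non-gap character of the reference row corresponds to its
    alignment column; requested indices beyond the reference length raise.
    """
    if reference_id not in aln:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    row = aln[reference_id].seq
    residue_to_column: list[int] = []
    for j, c in enumerate(row, start=1):
        if c != GAP:
            residue_to_column.append(j)
    out = []
    for pos in positions:
        if not 1 <= pos <= len(residue_to_column):
            raise IndexError(
                f"position {pos} beyond reference {reference_id!r} "
                f"({len(residue_to_column)} residues)"
            )
        out.append(residue_to_column[pos - 1])
    return out
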