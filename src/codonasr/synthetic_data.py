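"""Synthetic data with recorded ancestral truth for end-to-end testing.

The generators emulate the statistical structure of a helper-NLR coding
dataset: a random bifurcating tree, codon sequences evolved along it under a
reversible nucleotide model with among-site rate variation, whole-codon gap
presence/absence evolving under an independent two-state process, ordinal
0–7 HR score datasets, and toy two-chain complexes with contacts known by
construction.  Every internal node's true sequence and presence states are
recorded so reconstruction accuracy can be measured exactly.

Substitutions are simulated with exponential waiting times under the rate
matrix; a proposed substitution that would create an in-frame stop codon is
discarded (the chain holds its state while time advances), i.e. the process
is thinned away from stop codons at every node.  This keeps simulated CDS
frame-clean at arbitrary branch lengths, mimicking the purifying selection
that keeps real coding sequences free of premature stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DNA, GAP, Alignment, SequenceRecord, Tree
from .phylo_models import NUC_STATES, SubstitutionModel, build_model
from .seqprep import STOP_CODONS, CodonAlignment
from .stats_tests import HRScoreDataset
from .structure_contacts import AtomRecord

logger = logging.getLogger(__name__)


def default_nucleotide_model() -> SubstitutionModel:
    """The generator's default: HKY85 with a 4-category free-rate mixture.

    kappa = 2.0, base frequencies (0.3, 0.2, 0.2, 0.3) — AT-rich as typical
    for plant nuclear coding sequence — and rates (0.2, 0.6, 1.2, 2.0) at
    equal weights to emulate among-site rate heterogeneity.
    """
    return build_model(
        "HKY85",
        frequencies=(0.3, 0.2, 0.2, 0.3),
        kappa=2.0,
        rate_categories=[(0.2, 0.25), (0.6, 0.25), (1.2, 0.25), (2.0, 0.25)],
    )


def simulate_tree(n_taxa: int, mean_branch_length: float = 0.05, seed: int | None = None) -> Tree:
    """Random bifurcating tree by uniform coalescent-style joins.

    Branch lengths are i.i.d. exponential with the given mean (expected
    substitutions per site).  Leaves are named t1..tn; deterministic for a
    given seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if mean_branch_length <= 0:
        raise ValueError("mean branch length must be > 0")
    rng = np.random.default_rng(seed)
    total = 2 * n_taxa - 1
    parent = np.full(total, -1, dtype=int)
    lengths = np.zeros(total)
    names: list[str | None] = [f"t{i + 1}" for i in range(n_taxa)] + [None] * (n_taxa - 1)
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        lengths[a] = rng.exponential(mean_branch_length)
        lengths[b] = rng.exponential(mean_branch_length)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(parent=parent, lengths=lengths, names=names)


@dataclass
class SimulationTruth:
    """Complete record of one simulated history."""

    tree: Tree
    sequences: dict[str, str]  # aligned (gap-masked) sequence at every node
    presence: dict[str, np.ndarray]  # per-codon presence at every node
    site_categories: np.ndarray  # rate-category index per nucleotide site (-1 = invariant)
    params: dict
    seed: int | None
    rejected_stop_jumps: int = 0

    def root_name(self) -> str:
        return self.tree.names[self.tree.root]


def _sample_root_codons(rng, freqs: np.ndarray, n_codons: int) -> np.ndarray:
    """Root nucleotide states drawn from the equilibrium, avoiding stops."""
    out = np.empty(3 * n_codons, dtype=np.int64)
    for c in range(n_codons):
        while True:
            trio = rng.choice(4, size=3, p=freqs)
            codon = "".join(NUC_STATES[i] for i in trio)
            if codon not in STOP_CODONS:
                out[3 * c : 3 * c + 3] = trio
                break
    return out


def _evolve_branch(
    rng,
    seq: np.ndarray,
    rates: np.ndarray,
    Q: np.ndarray,
    t: float,
) -> tuple[np.ndarray, int]:
    """Evolve a codon sequence along one branch (thinned away from stops)."""
    child = seq.copy()
    rejected = 0
    n_codons = child.size // 3
    stop_codes = {tuple(NUC_STATES.index(c) for c in s) for s in STOP_CODONS}
    for c in range(n_codons):
        sl = slice(3 * c, 3 * c + 3)
        codon = child[sl].copy()
        r = rates[sl]
        elapsed = 0.0
        while True:
            lam = np.array([-Q[codon[i], codon[i]] * r[i] for i in range(3)])
            total = lam.sum()
            if total <= 0:
                break  # all three sites invariant
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                break
            pos = rng.choice(3, p=lam / total)
            row = Q[codon[pos]].copy()
            row[codon[pos]] = 0.0
            target = rng.choice(4, p=row / row.sum())
            proposal = codon.copy()
            proposal[pos] = target
            if tuple(proposal) in stop_codes:
                rejected += 1  # thinning: time advances, state holds
                continue
            codon = proposal
        child[sl] = codon
    return child, rejected


def _presence_transition(gain: float, loss: float, t: float) -> np.ndarray:
    """2-state presence/absence kernel; state 0 = present, 1 = absent."""
    tot = gain + loss
    if tot == 0:
        return np.eye(2)
    decay = np.exp(-tot * t)
    p_stat_absent = loss / tot
    P = np.empty((2, 2))
    P[0, 1] = p_stat_absent * (1 - decay)
    P[0, 0] = 1 - P[0, 1]
    P[1, 0] = (gain / tot) * (1 - decay)
    P[1, 1] = 1 - P[1, 0]
    return P


def simulate_evolution(
    tree: Tree,
    n_codons: int,
    model: SubstitutionModel | None = None,
    indel_rates: tuple[float, float] = (2.0, 0.2),
    seed: int | None = None,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve codon sequences with whole-codon indels along the tree.

    ``indel_rates`` is (gain, loss): the absent->present and
    present->absent rates of the per-codon two-state process, per unit
    branch length.  The root is fully present with nucleotides drawn from
    the model equilibrium avoiding stop codons; each nucleotide site draws a
    rate category once (shared across the whole tree), and invariant sites
    evolve at rate zero.  Returns the leaf alignment (gaps where a codon is
    absent) and the full :class:`SimulationTruth`.
    """
    if model is None:
        model = default_nucleotide_model()
    if model.states != NUC_STATES:
        raise ValueError("simulation requires a nucleotide model")
    gain, loss = indel_rates
    if gain < 0 or loss < 0:
        raise ValueError("indel rates must be >= 0")
    rng = np.random.default_rng(seed)
    n_sites = 3 * n_codons

    # per-site rate category, fixed across the tree; -1 marks invariant sites
    cats = rng.choice(model.n_categories, size=n_sites, p=model.weights)
    if model.p_inv > 0:
        cats[rng.random(n_sites) < model.p_inv] = -1
    site_rates = np.where(cats >= 0, model.rates[np.maximum(cats, 0)], 0.0)

    seqs: dict[int, np.ndarray] = {}
    present: dict[int, np.ndarray] = {}
    root = tree.root
    seqs[root] = _sample_root_codons(rng, model.freqs, n_codons)
    present[root] = np.ones(n_codons, dtype=bool)
    rejected = 0
    for v in tree.preorder():
        if v == root:
            continue
        t = float(tree.lengths[v])
        seqs[v], rej = _evolve_branch(rng, seqs[tree.parent[v]], site_rates, model.Q, t)
        rejected += rej
        P = _presence_transition(gain, loss, t)
        parent_absent = (~present[tree.parent[v]]).astype(int)
        absent = rng.random(n_codons) < P[parent_absent, 1]
        present[v] = ~absent
    if rejected:
        logger.info("rejected %d stop-creating substitution events", rejected)

    def render(v: int) -> str:
        chars = []
        for c in range(n_codons):
            if present[v][c]:
                chars.append("".join(NUC_STATES[i] for i in seqs[v][3 * c : 3 * c + 3]))
            else:
                chars.append(GAP * 3)
        return "".join(chars)

    sequences = {tree.names[v]: render(v) for v in range(tree.n_nodes)}
    presence = {tree.names[v]: present[v] for v in range(tree.n_nodes)}
    leaf_records = [
        SequenceRecord(id=tree.names[v], seq=sequences[tree.names[v]], alphabet=DNA)
        for v in tree.leaves()
    ]
    aln = CodonAlignment(alignment=Alignment(records=leaf_records, alphabet=DNA))
    truth = SimulationTruth(
        tree=tree,
        sequences=sequences,
        presence=presence,
        site_categories=cats,
        params={
            "n_codons": n_codons,
            "model": model.name,
            "indel_gain": gain,
            "indel_loss": loss,
        },
        seed=seed,
        rejected_stop_jumps=rejected,
    )
    return aln, truth


def simulate_hr_scores(
    group_specs: Mapping[str, tuple[int, Sequence[float]]],
    seed: int | None = None,
) -> HRScoreDataset:
    """Draw i.i.d. ordinal HR scores per treatment group.

    ``group_specs`` maps a treatment label to (n_spots, distribution over
    scores 0..7).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, np.ndarray] = {}
    for label, (n, probs) in group_specs.items():
        p = np.asarray(probs, dtype=float)
        if p.size != 8 or np.any(p < 0) or abs(p.sum() - 1) > 1e-8:
            raise ValueError(f"group {label!r}: distribution must be a simplex over 0..7")
        groups[label] = rng.choice(8, size=n, p=p / p.sum())
    return HRScoreDataset(groups=groups)


def make_toy_complex(
    n_contact_residues: int,
    spacing: float = 8.0,
    contact_distance: float = 3.0,
    start_residue: int = 153,
    residue_step: int = 1,
    chain_a: str = "A",
    chain_b: str = "B",
) -> list[AtomRecord]:
    """Two opposed chains with contacts known by construction.

    Chain A places one CA atom per residue along the x axis at ``spacing``
    Å intervals, numbered from ``start_residue`` in steps of
    ``residue_step``; chain B mirrors each atom at ``contact_distance`` Å
    across.  With spacing larger than the contact window, exactly the
    opposed pairs are contacts.
    """
    if n_contact_residues < 0:
        raise ValueError("n_contact_residues must be >= 0")
    atoms: list[AtomRecord] = []
    for i in range(n_contact_residues):
        x = i * spacing
        num = start_residue + i * residue_step
        atoms.append(AtomRecord(chain_a, num, "ALA", "CA", "C", x, 0.0, 0.0))
        atoms.append(AtomRecord(chain_b, 500 + i, "GLY", "CA", "C", x, contact_distance, 0.0))
    return atoms
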