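"""Exhaustive-enumeration reference for likelihoods and marginal posteriors.

For trees small enough to enumerate every joint assignment of states to the
internal nodes, the site likelihood and the per-node marginal posteriors can
be computed directly from the joint distribution:

    P(assignment, data) = pi(root) * prod_edges P_parent->child(t)

summed over rate categories with their weights, plus the invariant-site
class (in which the entire tree holds one constant state).  This is
deliberately independent of the pruning code path: it loops over explicit
assignments and transition-matrix entries and serves as the oracle the fast
implementation is validated against on trees of up to a handful of leaves.
"""

from __future__ import annotations

import itertools

import numpy as np

from .io_formats import Alignment, Tree
from .phylo_models import SubstitutionModel, transition_matrix
from .asr_engine import PosteriorTable


def brute_force_marginals(
    tree: Tree, aln: Alignment, model: SubstitutionModel
) -> tuple[PosteriorTable, np.ndarray]:
    """Marginal posteriors and per-site log-likelihoods by full enumeration.

    Missing leaf characters (gaps/ambiguity) are summed out, which for a
    row-stochastic kernel contributes a factor of one.  Only feasible for
    trees with a few internal nodes; intended as a test oracle.
    """
    k = model.n_states
    idx = model.state_index()
    internals = tree.internal_nodes()
    leaves = tree.leaves()
    n_sites = aln.n_columns
    leaf_codes = {
        v: [idx.get(c, -1) for c in aln[tree.names[v]].seq] for v in leaves
    }
    P_cat = [
        {v: transition_matrix(model, float(tree.lengths[v]), float(r))
         for v in range(tree.n_nodes) if v != tree.root}
        for r in model.rates
    ]
    pos = {v: i for i, v in enumerate(internals)}
    post = np.zeros((len(internals), n_sites, k))
    site_ll = np.zeros(n_sites)
    for s in range(n_sites):
        numer = np.zeros((len(internals), k))
        denom = 0.0
        for ci in range(model.n_categories):
            w = model.weights[ci] * (1.0 - model.p_inv)
            P = P_cat[ci]
            for assign in itertools.product(range(k), repeat=len(internals)):
                prob = model.freqs[assign[pos[tree.root]]]
                for v in internals:
                    if v == tree.root:
                        continue
                    prob *= P[v][assign[pos[tree.parent[v]]], assign[pos[v]]]
                for v in leaves:
                    x = leaf_codes[v][s]
                    if x >= 0:
                        prob *= P[v][assign[pos[tree.parent[v]]], x]
                contrib = w * prob
                denom += contrib
                for v in internals:
                    numer[pos[v], assign[pos[v]]] += contrib
        if model.p_inv > 0:
            for x in range(k):
                if all(leaf_codes[v][s] in (-1, x) for v in leaves):
                    contrib = model.p_inv * model.freqs[x]
                    denom += contrib
                    numer[:, x] += contrib
        site_ll[s] = np.log(denom)
        post[:, s, :] = numer / denom
    table = PosteriorTable(
        node_ids=[tree.names[v] for v in internals],
        states=model.states,
        probs=post,
    )
    return table, site_ll
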