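"""Reversible substitution models and Felsenstein pruning on a fixed topology.

The model family covers the nucleotide patterns JC69, K80, HKY85, TIM3 and
GTR plus the two-state JC2 used for gap presence/absence, each optionally
combined with free rate categories (FreeRate-style mixtures such as R4) and
an invariant-site proportion.  Rate matrices are built as q_ij = s_ij * pi_j
and scaled so one unit of branch length equals one expected substitution per
site at equilibrium, averaged over the rate mixture and the invariant class.

Transition matrices use the symmetric eigendecomposition of
pi^{1/2} Q pi^{-1/2}; reversibility guarantees a real spectrum, so P(t) is
exact to machine precision with no Pade scaling-and-squaring.

The pruning pass is vectorised across alignment sites and carries per-site
log scaling factors, so likelihoods stay finite for long alignments.  The
same pass exposes the downward partials and upward (complementary) partials
that marginal ancestral reconstruction consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import BINARY, DNA, Alignment, Tree

logger = logging.getLogger(__name__)

NUC_STATES = ("A", "C", "G", "T")
BIN_STATES = ("0", "1")

# exchangeability key order for nucleotide models
_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
_PAIR_KEYS = tuple(a + b for a, b in _PAIRS)

MODEL_NAMES = ("JC69", "K80", "HKY85", "TIM3", "GTR", "JC2")


@dataclass
class SubstitutionModel:
    """A time-reversible CTMC over ``states`` with a rate mixture.

    ``rates``/``weights`` define the among-site rate categories (already
    normalised so that ``(1 - p_inv) * sum(w * r) == 1``); ``p_inv`` is the
    proportion of invariant sites.
    """

    name: str
    states: tuple[str, ...]
    exchangeabilities: np.ndarray  # symmetric, zero diagonal
    freqs: np.ndarray
    rates: np.ndarray
    weights: np.ndarray
    p_inv: float
    Q: np.ndarray = field(init=False, repr=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        k = len(self.states)
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if S.shape != (k, k) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric k x k")
        if np.any(S[~np.eye(k, dtype=bool)] <= 0):
            raise ValueError("exchangeabilities must be positive (irreducibility)")
        if pi.shape != (k,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be a strictly positive simplex")
        pi = pi / pi.sum()
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or np.any(r <= 0) or np.any(w <= 0):
            raise ValueError("rate categories must have positive rates and weights")
        w = w / w.sum()
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))  # expected rate at equilibrium
        Q = Q / mu
        # normalise the mixture so the overall expected rate is 1
        mix = (1.0 - self.p_inv) * np.sum(w * r)
        r = r / mix
        self.freqs = pi
        self.rates = r
        self.weights = w
        self.Q = Q
        # symmetric eigendecomposition for the exact matrix exponential
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self._eig = (lam, V * (1.0 / sq)[:, None], V * sq[:, None])

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


def transition_matrix(model: SubstitutionModel, t: float, r: float = 1.0) -> np.ndarray:
    """P(r*t) = exp(Q r t): row-stochastic transition kernel."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if r <= 0:
        raise ValueError("category rate must be > 0")
    lam, left, right = model._eig
    P = (left * np.exp(lam * r * t)[None, :]) @ right.T
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _resolve_exchangeabilities(
    name: str, exchangeabilities, kappa: float | None
) -> np.ndarray:
    """Build the symmetric 4x4 exchangeability matrix for a named pattern."""
    vals: dict[str, float]
    if name == "JC69":
        vals = {k: 1.0 for k in _PAIR_KEYS}
    elif name in ("K80", "HKY85"):
        if kappa is None:
            kappa = 2.0 if exchangeabilities is None else None
        if kappa is None:
            raise ValueError(f"{name} requires a kappa (transition/transversion) parameter")
        vals = {"AC": 1.0, "AG": kappa, "AT": 1.0, "CG": 1.0, "CT": kappa, "GT": 1.0}
    elif name in ("TIM3", "GTR"):
        if exchangeabilities is None:
            raise ValueError(f"{name} requires explicit exchangeabilities {list(_PAIR_KEYS)}")
        if isinstance(exchangeabilities, dict):
            vals = {k: float(exchangeabilities[k]) for k in _PAIR_KEYS}
        else:
            seq = list(exchangeabilities)
            if len(seq) != 6:
                raise ValueError("expected 6 exchangeabilities in order " + ",".join(_PAIR_KEYS))
            vals = dict(zip(_PAIR_KEYS, map(float, seq)))
        if name == "TIM3":
            # TIM3 ties: AC = CG and AT = GT
            if abs(vals["AC"] - vals["CG"]) > 1e-9 or abs(vals["AT"] - vals["GT"]) > 1e-9:
                raise ValueError("TIM3 requires AC == CG and AT == GT exchangeabilities")
    else:
        raise ValueError(f"unknown nucleotide model {name!r}")
    S = np.zeros((4, 4))
    idx = {s: i for i, s in enumerate(NUC_STATES)}
    for (a, b), key in zip(_PAIRS, _PAIR_KEYS):
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = vals[key]
    return S


def build_model(
    name: str,
    frequencies: Sequence[float] | None = None,
    exchangeabilities=None,
    kappa: float | None = None,
    rate_categories: Sequence[tuple[float, float]] | None = None,
    p_inv: float = 0.0,
) -> SubstitutionModel:
    """Construct a named substitution model.

    ``rate_categories`` is a list of (rate, weight) pairs (e.g. four pairs
    for an R4 FreeRate mixture); omitted means a single unit-rate category.
    JC69 and JC2 force equal frequencies.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    cats = list(rate_categories) if rate_categories else [(1.0, 1.0)]
    rates = np.array([c[0] for c in cats], dtype=float)
    weights = np.array([c[1] for c in cats], dtype=float)
    if name == "JC2":
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        return SubstitutionModel(
            name=name,
            states=BIN_STATES,
            exchangeabilities=S,
            freqs=np.array([0.5, 0.5]),
            rates=rates,
            weights=weights,
            p_inv=p_inv,
        )
    if name in ("JC69", "K80"):
        freqs = np.full(4, 0.25)
        if frequencies is not None and not np.allclose(frequencies, 0.25):
            raise ValueError(f"{name} requires equal base frequencies")
    else:
        if frequencies is None:
            raise ValueError(f"{name} requires base frequencies (A, C, G, T)")
        freqs = np.asarray(frequencies, dtype=float)
    S = _resolve_exchangeabilities(name, exchangeabilities, kappa)
    return SubstitutionModel(
        name=name,
        states=NUC_STATES,
        exchangeabilities=S,
        freqs=freqs,
        rates=rates,
        weights=weights,
        p_inv=p_inv,
    )


def model_from_config(config: dict, aln: Alignment | None = None) -> SubstitutionModel:
    """Build a model from a config mapping (e.g. parsed YAML).

    Recognised keys: ``name`` (required), ``frequencies`` (list or the
    string "empirical", which requires ``aln``), ``kappa``,
    ``exchangeabilities`` (list of 6 or mapping), ``rate_categories``
    (list of [rate, weight] pairs), ``p_inv``.  All resolved parameters are
    echoed to the log for reproducibility.
    """
    name = config["name"]
    freqs = config.get("frequencies")
    if isinstance(freqs, str):
        if freqs != "empirical":
            raise ValueError(f"unknown frequencies spec {freqs!r}")
        if aln is None:
            raise ValueError("empirical frequencies require an alignment")
        freqs = empirical_frequencies(aln).tolist()
    cats = config.get("rate_categories")
    if cats is not None:
        cats = [(float(r), float(w)) for r, w in cats]
    model = build_model(
        name,
        frequencies=freqs,
        exchangeabilities=config.get("exchangeabilities"),
        kappa=config.get("kappa"),
        rate_categories=cats,
        p_inv=float(config.get("p_inv", 0.0)),
    )
    logger.info(
        "model %s: freqs=%s rates=%s weights=%s p_inv=%.4f",
        model.name,
        np.round(model.freqs, 4).tolist(),
        np.round(model.rates, 4).tolist(),
        np.round(model.weights, 4).tolist(),
        model.p_inv,
    )
    return model


def empirical_frequencies(aln: Alignment, states: tuple[str, ...] = NUC_STATES) -> np.ndarray:
    """Observed state frequencies over the alignment (missing data ignored)."""
    counts = np.zeros(len(states))
    idx = {s: i for i, s in enumerate(states)}
    for rec in aln.records:
        for c in rec.seq:
            if c in idx:
                counts[idx[c]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no countable states")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Pruning machinery
# ---------------------------------------------------------------------------


def encode_alignment(tree: Tree, aln: Alignment, model: SubstitutionModel) -> np.ndarray:
    """Leaf state codes aligned to tree node indices.

    Returns an integer array of shape (n_nodes, n_sites); -1 marks missing
    data (gap, N, X or any symbol outside the model states) and rows for
    internal nodes.  Raises if the leaf set does not match the alignment ids.
    """
    leaf_ids = set(tree.leaf_names())
    aln_ids = set(aln.ids)
    if leaf_ids != aln_ids:
        missing = sorted(leaf_ids - aln_ids)
        extra = sorted(aln_ids - leaf_ids)
        raise ValueError(
            f"tree/alignment mismatch: missing from alignment {missing}, "
            f"not in tree {extra}"
        )
    idx = model.state_index()
    codes = np.full((tree.n_nodes, aln.n_columns), -1, dtype=np.int64)
    for i in tree.leaves():
        seq = aln[tree.names[i]].seq
        codes[i] = [idx.get(c, -1) for c in seq]
    return codes


@dataclass
class PruningResult:
    """Per-category partials and scaling factors from one pruning pass.

    ``down[c][v]`` has shape (n_sites, k): P(data below v | state at v),
    scaled per site with cumulative log-scales in ``down_logscale[c][v]``.
    ``site_loglik[c]`` is the per-site log-likelihood of category ``c``.
    """

    down: list[np.ndarray]
    down_logscale: list[np.ndarray]
    messages: list[np.ndarray]  # msg[c][v] = down[v] @ P_v.T (same scale as down[v])
    site_loglik: np.ndarray  # (n_categories, n_sites)
    const_ok: np.ndarray  # (n_sites, k) indicator for the invariant class
    transition: list[list[np.ndarray | None]]  # per category, per node P-matrix


def _pruning_pass(tree: Tree, codes: np.ndarray, model: SubstitutionModel) -> PruningResult:
    n_nodes, n_sites = codes.shape
    k = model.n_states
    post = tree.postorder()
    ncat = model.n_categories

    # invariant-class indicator: site is compatible with constant state x
    const_ok = np.ones((n_sites, k))
    for v in tree.leaves():
        leaf = np.ones((n_sites, k))
        obs = codes[v] >= 0
        leaf[obs] = 0.0
        leaf[np.nonzero(obs)[0], codes[v][obs]] = 1.0
        const_ok *= leaf

    down_all, scale_all, msg_all, P_all = [], [], [], []
    site_ll = np.empty((ncat, n_sites))
    tiny = np.finfo(float).tiny
    for ci in range(ncat):
        r = model.rates[ci]
        down = [None] * n_nodes
        scale = [None] * n_nodes
        msgs = [None] * n_nodes
        Ps: list[np.ndarray | None] = [None] * n_nodes
        for v in post:
            if tree.is_leaf(v):
                L = np.ones((n_sites, k))
                obs = codes[v] >= 0
                L[obs] = 0.0
                L[np.nonzero(obs)[0], codes[v][obs]] = 1.0
                down[v] = L
                scale[v] = np.zeros(n_sites)
            else:
                L = np.ones((n_sites, k))
                sc = np.zeros(n_sites)
                for c in tree.children[v]:
                    L = L * msgs[c]
                    sc = sc + scale[c]
                m = np.maximum(L.max(axis=1), tiny)
                down[v] = L / m[:, None]
                scale[v] = sc + np.log(m)
            if v != tree.root:
                P = transition_matrix(model, float(tree.lengths[v]), float(r))
                Ps[v] = P
                msgs[v] = down[v] @ P.T
        root = tree.root
        lik = down[root] @ model.freqs
        site_ll[ci] = np.log(np.maximum(lik, tiny)) + scale[root]
        down_all.append(down)
        scale_all.append(scale)
        msg_all.append(msgs)
        P_all.append(Ps)
    return PruningResult(
        down=down_all,
        down_logscale=scale_all,
        messages=msg_all,
        site_loglik=site_ll,
        const_ok=const_ok,
        transition=P_all,
    )


@dataclass
class SiteLikelihoodResult:
    per_site: np.ndarray
    total: float


def _mixture_site_loglik(model: SubstitutionModel, pr: PruningResult) -> np.ndarray:
    """Combine per-category log-likelihoods with the invariant class."""
    parts = np.log(model.weights)[:, None] + pr.site_loglik
    if model.p_inv > 0:
        l_inv = pr.const_ok @ model.freqs
        with np.errstate(divide="ignore"):
            inv_part = np.log(model.p_inv) + np.log(l_inv)
        parts = np.vstack([np.log1p(-model.p_inv) + parts, inv_part[None, :]])
    m = parts.max(axis=0)
    return m + np.log(np.exp(parts - m[None, :]).sum(axis=0))


def site_likelihoods(tree: Tree, aln: Alignment, model: SubstitutionModel) -> SiteLikelihoodResult:
    """Felsenstein pruning log-likelihood per site and in total.

    Gaps and ambiguity codes are missing data (partial vector of ones); the
    likelihood mixes over rate categories and the invariant-site class.
    """
    codes = encode_alignment(tree, aln, model)
    pr = _pruning_pass(tree, codes, model)
    per_site = _mixture_site_loglik(model, pr)
    return SiteLikelihoodResult(per_site=per_site, total=float(per_site.sum()))


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 100,
    bounds: tuple[float, float] = (1e-8, 10.0),
) -> Tree:
    """Coordinate-ascent branch-length optimisation on a fixed topology.

    One bounded scalar search per branch per sweep; terminates when a full
    sweep improves the total log-likelihood by less than ``tol``.  The
    log-likelihood is non-decreasing across sweeps by construction (a
    proposed branch length is kept only if it does not lower it).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    work = tree.copy()
    codes = encode_alignment(work, aln, model)

    def total_ll() -> float:
        pr = _pruning_pass(work, codes, model)
        return float(_mixture_site_loglik(model, pr).sum())

    current = total_ll()
    branches = [v for v in range(work.n_nodes) if v != work.root]
    for sweep in range(max_sweeps):
        start = current
        for v in branches:
            old = work.lengths[v]

            def neg_ll(t: float, _v: int = v) -> float:
                work.lengths[_v] = t
                return -total_ll()

            res = minimize_scalar(neg_ll, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-10})
            if -res.fun >= current:
                work.lengths[v] = float(res.x)
                current = -res.fun
            else:
                work.lengths[v] = old
        if current - start < tol:
            return work
    logger.warning("branch-length optimisation did not converge in %d sweeps", max_sweeps)
    return work
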