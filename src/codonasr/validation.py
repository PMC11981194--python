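"""Self-checks that recompute the package's correctness guarantees.

Each function runs an experiment from scratch — simulating inputs, running
the implementation, and measuring agreement with an independent reference
(closed form, exhaustive enumeration, or recorded simulation truth).  They
back both the acceptance test suite and the reproduction script, and are
deliberately small enough to run on one CPU in a few minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .asr_engine import combine_codon, indel_asr, marginal_asr, recode_binary, residue_posteriors
from .bruteforce import brute_force_marginals
from .io_formats import Alignment, SequenceRecord, root_with_outgroup
from .phylo_models import build_model, optimize_branch_lengths, site_likelihoods, transition_matrix
from .seqprep import (
    REASON_INTERNAL_STOP,
    REASON_LENGTH,
    REASON_NOT_MULTIPLE_OF_THREE,
    filter_cds,
)
from .stats_tests import exact_permutation_p, permutation_test
from .synthetic_data import default_nucleotide_model, simulate_evolution, simulate_hr_scores, simulate_tree
from .conservation import information_matrix
from .io_formats import PROTEIN


def _random_alignment(rng, ids, n_sites, gap_frac=0.1):
    records = []
    for name in ids:
        chars = rng.choice(list("ACGT"), size=n_sites)
        mask = rng.random(n_sites) < gap_frac
        chars = np.where(mask, "-", chars)
        records.append(SequenceRecord(id=name, seq="".join(chars)))
    return Alignment(records)


def _oracle_models():
    return [
        build_model("JC69"),
        build_model("HKY85", frequencies=(0.3, 0.2, 0.2, 0.3), kappa=2.5),
        build_model("JC2"),
    ]


def asr_oracle_deviation(seed: int, n_instances: int = 200, n_sites: int = 20) -> dict:
    """Max |posterior - enumeration| over random small-tree instances.

    Rotates through JC69, HKY85 and (via the binary indel path) JC2 on
    random trees with 3–5 leaves.  Also records the max deviation of the
    pruning per-site log-likelihood from the enumeration value.
    """
    rng = np.random.default_rng(seed)
    models = _oracle_models()
    nuc_dev = indel_dev = lik_dev = 0.0
    for i in range(n_instances):
        model = models[i % len(models)]
        tree = simulate_tree(int(rng.integers(3, 6)), 0.2, seed=int(rng.integers(2**31)))
        aln = _random_alignment(rng, tree.leaf_names(), n_sites)
        if model.name == "JC2":
            post = indel_asr(tree, aln, model)
            oracle, site_ll = brute_force_marginals(tree, recode_binary(aln), model)
            indel_dev = max(indel_dev, float(np.abs(post.probs - oracle.probs).max()))
            lik = site_likelihoods(tree, recode_binary(aln), model)
        else:
            post = marginal_asr(tree, aln, model)
            oracle, site_ll = brute_force_marginals(tree, aln, model)
            nuc_dev = max(nuc_dev, float(np.abs(post.probs - oracle.probs).max()))
            lik = site_likelihoods(tree, aln, model)
        lik_dev = max(lik_dev, float(np.abs(lik.per_site - site_ll).max()))
    return {
        "marginal_dev": nuc_dev,
        "indel_dev": indel_dev,
        "loglik_dev": lik_dev,
        "n": n_instances,
    }


def reroot_invariance(seed: int, n_instances: int = 10) -> dict:
    """Max change of the total log-likelihood across three root positions."""
    rng = np.random.default_rng(seed)
    model = build_model("HKY85", frequencies=(0.3, 0.2, 0.2, 0.3), kappa=2.0)
    worst = 0.0
    for _ in range(n_instances):
        tree = simulate_tree(6, 0.1, seed=int(rng.integers(2**31)))
        aln = _random_alignment(rng, tree.leaf_names(), 30, gap_frac=0.05)
        ref = site_likelihoods(tree, aln, model).total
        for og in tree.leaf_names()[:3]:
            alt = site_likelihoods(root_with_outgroup(tree, og), aln, model).total
            worst = max(worst, abs(alt - ref))
    return {"max_dev": worst, "n": n_instances}


def jc69_kernel_error(n_points: int = 200) -> dict:
    """Max deviation of the JC69 diagonal from 1/4 + 3/4 exp(-4rt/3)."""
    model = build_model("JC69")
    worst = 0.0
    for rt in np.linspace(1e-4, 5.0, n_points):
        P = transition_matrix(model, float(rt))
        expected = 0.25 + 0.75 * np.exp(-4.0 * rt / 3.0)
        worst = max(worst, float(np.abs(np.diag(P) - expected).max()))
    return {"max_err": worst, "n": n_points}


def jc_branch_mle_error(seed: int, n_sites: int = 600) -> dict:
    """|MLE - closed form| for the 2-taxon JC distance.

    Two sequences differing at a random draw of sites give the observed
    mismatch fraction p_hat; the branch-length MLE must equal
    -3/4 ln(1 - 4 p_hat / 3).
    """
    rng = np.random.default_rng(seed)
    from .io_formats import parse_newick

    base = rng.choice(list("ACGT"), size=n_sites)
    other = base.copy()
    n_diff = int(0.15 * n_sites)
    sites = rng.choice(n_sites, size=n_diff, replace=False)
    for s in sites:
        other[s] = rng.choice([c for c in "ACGT" if c != base[s]])
    aln = Alignment(
        [SequenceRecord("a", "".join(base)), SequenceRecord("b", "".join(other))]
    )
    p_hat = np.mean(base != other)
    expected = -0.75 * np.log(1.0 - 4.0 * p_hat / 3.0)
    tree = parse_newick("(a:0.05,b:0.05);")
    opt = optimize_branch_lengths(tree, aln, build_model("JC69"), tol=1e-10)
    fitted = float(sum(opt.lengths[i] for i in opt.leaves()))
    return {"abs_err": abs(fitted - expected), "fitted": fitted,
            "expected": expected, "n": n_sites}


@dataclass
class RecoveryResult:
    residue_pct: float
    indel_pct: float
    n_codons: int


def recovery_experiment(seed: int, scale: float = 1.0, n_taxa: int = 32,
                        n_codons: int = 300) -> RecoveryResult:
    """MAP ancestral recovery against recorded simulation truth.

    Simulates the study conditions (default generator model, mean branch
    length 0.05 scaled by ``scale``), runs the full reconstruction pipeline
    and scores the MAP root residues and root presence/absence calls
    against the truth.
    """
    tree = simulate_tree(n_taxa, 0.05 * scale, seed=seed)
    aln, truth = simulate_evolution(tree, n_codons, seed=seed + 1)
    model = default_nucleotide_model()
    nuc = marginal_asr(tree, aln, model)
    ind = indel_asr(tree, aln)
    codons = combine_codon(nuc, ind)
    residues, _ = residue_posteriors(codons)
    root = truth.root_name()
    true_seq = truth.sequences[root]
    true_res = [
        str(Seq(true_seq[i : i + 3]).translate()) if "-" not in true_seq[i : i + 3] else "-"
        for i in range(0, len(true_seq), 3)
    ]
    map_res = residues.map_states(root)
    residue_pct = 100.0 * float(np.mean([a == b for a, b in zip(map_res, true_res)]))
    gap_state = ind.states.index("1")
    pres_map = ind.node(root)[:, gap_state].reshape(n_codons, 3).mean(axis=1) <= 0.5
    indel_pct = 100.0 * float(np.mean(pres_map == truth.presence[root]))
    return RecoveryResult(residue_pct=residue_pct, indel_pct=indel_pct, n_codons=n_codons)


def permutation_agreement(seed: int, B: int = 10_000) -> dict:
    """Monte-Carlo vs exact enumeration on small two-group score fixtures.

    All fixtures keep C(n, n_a) <= 10^4 so the exact p is enumerable;
    returns the worst |p_mc - p_exact| in Monte-Carlo standard-error units.
    """
    rng = np.random.default_rng(seed)
    fixtures = [
        ([7, 7, 7], [0, 0, 0]),
        ([0, 1, 3, 5, 7], [2, 4, 6, 6, 7]),
        ([1, 1, 2, 2, 3], [3, 4, 5, 5]),
        ([5, 6, 7, 7, 6], [5, 6, 7, 7, 5]),
    ]
    for _ in range(4):
        n_a, n_b = rng.integers(3, 8, size=2)
        fixtures.append(
            (rng.integers(0, 8, size=n_a).tolist(), rng.integers(0, 8, size=n_b).tolist())
        )
    worst = 0.0
    for a, b in fixtures:
        exact = exact_permutation_p(a, b, max_assignments=10_000)
        mc = permutation_test(a, b, B=B, seed=int(rng.integers(2**31)))
        se = float(np.sqrt(max(exact.p * (1 - exact.p), 1e-12) / B))
        dev = abs(mc.p - exact.p)
        # the +1 correction shifts p by at most 1/(B+1); fold it in
        worst = max(worst, max(dev - 1.0 / (B + 1), 0.0) / se if se > 0 else 0.0)
    return {"max_se_units": worst, "n": len(fixtures), "B": B}


def null_type1_rate(seed: int, n_sims: int = 2000, n_per_group: int = 12,
                    B: int = 999, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the permutation test under the null.

    Both groups draw i.i.d. from the same 0–7 score distribution; the
    rejection rate at ``alpha`` should sit inside the binomial 99% band.
    """
    null_probs = [0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.10, 0.05]
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        data = simulate_hr_scores(
            {"a": (n_per_group, null_probs), "b": (n_per_group, null_probs)},
            seed=int(rng.integers(2**31)),
        )
        r = permutation_test(data["a"], data["b"], B=B, seed=int(rng.integers(2**31)))
        if r.p <= alpha:
            rejections += 1
    rate = rejections / n_sims
    half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / n_sims)
    return {
        "rate": rate,
        "n": n_sims,
        "lower": alpha - half_width,
        "upper": alpha + half_width,
    }


def cds_filter_demo() -> dict:
    """Filter a 12-record CDS fixture with known violations.

    Returns the kept/rejected counts and the number of records whose fate
    differs from the hand-derived expectation (0 when semantics are exact).
    """
    records = [
        SequenceRecord("ok1", "ATGGCAGGT"),
        SequenceRecord("ok2", "ATGGCAGGTTGA"),
        SequenceRecord("int_stop", "ATGTAAGGGTGA"),
        SequenceRecord("frame", "ATGGCAG"),
        SequenceRecord("short", "ATG"),
        SequenceRecord("short_after_strip", "ATGTAA"),
        SequenceRecord("long", "ATGGCAGGTGCAGCA"),
        SequenceRecord("ok3", "ATGAATTGGGCC"),
        SequenceRecord("int_stop2", "TGATGATGATGA"),
        SequenceRecord("frame2", "ATGGCAGG"),
        SequenceRecord("ok4", "ATGNNNGGT"),
        SequenceRecord("ok5", "ATGGCAGGATAG"),
    ]
    expected_kept = ["ok1", "ok2", "ok3", "ok4", "ok5"]
    expected_rejected = {
        "int_stop": REASON_INTERNAL_STOP,
        "int_stop2": REASON_INTERNAL_STOP,
        "frame": REASON_NOT_MULTIPLE_OF_THREE,
        "frame2": REASON_NOT_MULTIPLE_OF_THREE,
        "short": REASON_LENGTH,
        "short_after_strip": REASON_LENGTH,
        "long": REASON_LENGTH,
    }
    _, report = filter_cds(records, min_len=6, max_len=12)
    mismatches = int(report.kept != expected_kept)
    mismatches += sum(
        1 for i, r in report.rejected if expected_rejected.get(i) != r
    )
    mismatches += abs(len(report.rejected) - len(expected_rejected))
    return {
        "kept": len(report.kept),
        "rejected": len(report.rejected),
        "mismatches": mismatches,
        "n": len(records),
    }


def information_closed_forms() -> dict:
    """Information content of a fully conserved and a uniform protein column."""
    conserved = Alignment(
        [SequenceRecord(f"s{i}", "A", alphabet=PROTEIN) for i in range(20)],
        alphabet=PROTEIN,
    )
    uniform = Alignment(
        [SequenceRecord(f"s{i}", aa, alphabet=PROTEIN)
         for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")],
        alphabet=PROTEIN,
    )
    m1 = information_matrix(conserved)
    m2 = information_matrix(uniform)
    return {
        "conserved_bits": float(m1.loc[1, "A"]),
        "uniform_bits": float(m2.loc[1].max()),
        "n": 20,
    }
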