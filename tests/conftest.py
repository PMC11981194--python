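import numpy as np
import pytest

from codonasr import (
    Alignment,
    SequenceRecord,
    build_model,
    parse_newick,
    simulate_evolution,
    simulate_tree,
)


@pytest.fixture
def jc69():
    return build_model("JC69")


@pytest.fixture
def jc2():
    return build_model("JC2")


@pytest.fixture
def hky():
    return build_model("HKY85", frequencies=(0.3, 0.2, 0.2, 0.3), kappa=2.5)


@pytest.fixture
def cherry_tree():
    """Two leaves hanging off the root."""
    return parse_newick("(a:0.1,b:0.2);")


@pytest.fixture
def five_leaf_tree():
    return parse_newick("(((a:0.1,b:0.15):0.05,c:0.2):0.1,(d:0.07,e:0.12):0.18);")


def random_alignment(rng, ids, n_sites, alphabet_chars="ACGT", gap_frac=0.0):
    records = []
    for name in ids:
        chars = rng.choice(list(alphabet_chars), size=n_sites)
        if gap_frac > 0:
            mask = rng.random(n_sites) < gap_frac
            chars[mask] = "-"
        records.append(SequenceRecord(id=name, seq="".join(chars)))
    return Alignment(records)


@pytest.fixture
def small_simulation():
    """16-taxon simulated codon dataset with recorded truth (fixed seed)."""
    tree = simulate_tree(16, 0.05, seed=7)
    aln, truth = simulate_evolution(tree, 60, seed=8)
    return tree, aln, truth
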