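import numpy as np
import pytest

from convsel.io import SequenceRecord
from convsel.substmodels import dayhoff_model
from convsel.trees import parse_newick

AAS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def dayhoff():
    return dayhoff_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture()
def five_taxon_tree():
    return parse_newick("(((A:0.12,B:0.3):0.08,C:0.2):0.1,(D:0.15,E:0.25):0.18);")


def random_protein_records(taxa, n_sites, rng):
    return [
        SequenceRecord(t, "".join(rng.choice(list(AAS), n_sites))) for t in taxa
    ]


def simulate_protein_on_tree(tree, model, n_sites, rng):
    """Direct CTMC simulation of amino-acid data (independent of the
    package's simulator; used to build realistic test alignments)."""
    states = {tree.root: rng.choice(20, size=n_sites, p=model.freqs)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = model.transition_matrix(tree.nodes[v].length)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_sites)
        parent = states[tree.nodes[v].parent]
        states[v] = np.minimum((cum[parent] < u[:, None]).sum(axis=1), 19)
    recs = [
        SequenceRecord(n.name, "".join(AAS[s] for s in states[n.index]))
        for n in tree.nodes
        if n.is_tip
    ]
    return recs, states
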