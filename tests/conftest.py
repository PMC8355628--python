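"""Shared fixtures: a small deterministic reference pair and the bundled one."""

import numpy as np
import pytest

from paramotif.refs import Motif, MotifSet, ReferencePair, find_motifs
from paramotif.simulate import synthetic_reference_pair

TOY_SITES = (60, 170, 280, 390, 500)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def toy_pair():
    """600 bp gene/pseudogene pair differing at five well-spaced sites."""
    for attempt in range(20):
        rng = np.random.default_rng(424 + attempt)
        gene = _random_seq(rng, 600)
        pseudo = list(gene)
        for pos in TOY_SITES:
            pseudo[pos] = "ACGT"[("ACGT".index(pseudo[pos]) + 1) % 4]
        pair = ReferencePair("toyG", gene, "toyP", "".join(pseudo))
        motifs = find_motifs(pair, k=11)
        if len(motifs.gene) == len(motifs.pseudo) == len(TOY_SITES):
            return pair
    raise RuntimeError("could not build toy pair")


@pytest.fixture(scope="session")
def toy_motifs(toy_pair):
    return find_motifs(toy_pair, k=11)


@pytest.fixture(scope="session")
def bundled():
    """The package's bundled synthetic 6 kb / 30-motif reference pair."""
    return synthetic_reference_pair()


def make_motif_set(gene_positions, pseudo_positions=(), k=11):
    """A coordinate-only motif set for group/cluster logic tests.

    Sequences are placeholders; operations under test use only ids,
    positions and k.
    """
    gene = [Motif(i + 1, "gene", "A" * k, p, k // 2) for i, p in enumerate(gene_positions)]
    pseudo = [Motif(i + 1, "pseudo", "C" * k, p, k // 2) for i, p in enumerate(pseudo_positions)]
    return MotifSet(gene, pseudo, k)
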