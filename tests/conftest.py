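import numpy as np
import pytest

from n15quant import chemcore as cc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_heavy_ion():
    """The carbamidomethylated VALEACVQAR [M+H]+ heavy ion used as the
    worked composition example throughout the docs."""
    return cc.PeptideIon(
        "VALEACVQAR", cc.parse_modifications("Carbamidomethyl@6"), charge=1, channel="heavy"
    )


@pytest.fixture
def worked_heavy_comp(worked_heavy_ion):
    return cc.build_composition(worked_heavy_ion)


def random_small_composition(rng, max_atoms=12, labeled=True):
    """A random composition with at most ``max_atoms`` atoms for the
    brute-force enumeration oracle."""
    elements = ["C", "H", "N", "O", "S"]
    counts = {}
    remaining = int(rng.integers(1, max_atoms + 1))
    for el in rng.permutation(elements):
        if remaining == 0:
            break
        n = int(rng.integers(0, remaining + 1))
        if n:
            counts[el] = n
            remaining -= n
    if not counts:
        counts = {"C": 1}
    n_n = counts.get("N", 0)
    n_lab = int(rng.integers(0, n_n + 1)) if labeled else 0
    return cc.ElementalComposition(counts, n_labeled_N=n_lab, n_unlabeled_N=n_n - n_lab)


def random_tryptic_sequence(rng, min_len=6, max_len=16):
    pool = "ACDEFGHIKLMNPQRSTVWY"
    length = int(rng.integers(min_len, max_len))
    body = "".join(pool[i] for i in rng.integers(0, len(pool), length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")
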