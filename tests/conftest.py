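import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from khscan import build_exchange_classes, bundled_ranking, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def classes(code):
    return build_exchange_classes(code)


@pytest.fixture(scope="session")
def ranking(code):
    """The packaged (synthetic, Grantham-ordered) exchangeability ranking."""
    return bundled_ranking(code)


@pytest.fixture(scope="session")
def shuffled_ranking(code, classes):
    """A seeded random permutation of 1..75 over the correct class set."""
    rng = np.random.default_rng(20240917)
    perm = rng.permutation(classes.n_classes) + 1
    return classes.with_ranks(
        {pair: int(perm[i]) for i, pair in enumerate(classes.classes)},
        provenance="test permutation",
    )


def random_codon_alignment(rng, n_codons, code, p_sub=0.05, p_gap=0.0, p_n=0.0):
    """A random pairwise alignment: seq_b is seq_a with random point edits."""
    from khscan import CodonAlignment

    sense = code.sense_codons
    nts = "ACGT"
    a = list(rng.choice(sense, size=n_codons))
    b = []
    for codon in a:
        cb = codon
        if rng.random() < p_sub:
            pos = rng.integers(3)
            alt = [x for x in nts if x != cb[pos]][rng.integers(3)]
            cb = cb[:pos] + alt + cb[pos + 1 :]
            if rng.random() < 0.15:  # occasional second hit in the same codon
                pos = rng.integers(3)
                alt = [x for x in nts if x != cb[pos]][rng.integers(3)]
                cb = cb[:pos] + alt + cb[pos + 1 :]
        b.append(cb)
    a_s, b_s = list("".join(a)), list("".join(b))
    for i in range(len(a_s)):
        u = rng.random()
        if u < p_gap:
            (a_s if rng.random() < 0.5 else b_s)[i] = "-"
        elif u < p_gap + p_n:
            (a_s if rng.random() < 0.5 else b_s)[i] = "N"
    return CodonAlignment("rnd", "".join(a_s), "".join(b_s))
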