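"""Grantham (1974) physicochemical distance between amino acids.

Used to construct the packaged default exchangeability ranking: the 75
elementary amino-acid change classes ordered by increasing Grantham
distance, so the physicochemically most similar pair gets rank 1.  This is
a synthetic stand-in for a measured evolutionary exchangeability index;
any user-supplied ranking TSV takes precedence in the pipeline.

D(a, b) = [alpha*(c_a - c_b)^2 + beta*(p_a - p_b)^2 + gamma*(v_a - v_b)^2]^(1/2)

with composition c, polarity p and molecular volume v per residue and
weights alpha = 1.833, beta = 0.1018, gamma = 0.000399.
"""

from __future__ import annotations

import math

from .reference_data import ExchangeClassTable, GeneticCode, build_exchange_classes, standard_code

ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399

# residue -> (composition, polarity, volume), Grantham 1974 Table 1
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.00, 8.1, 31.0),
    "R": (0.65, 10.5, 124.0),
    "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0),
    "C": (2.75, 5.5, 55.0),
    "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "L": (0.00, 4.9, 111.0),
    "K": (0.33, 11.3, 119.0),
    "M": (0.00, 5.7, 105.0),
    "F": (0.00, 5.2, 132.0),
    "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
    "V": (0.00, 5.9, 84.0),
}


def grantham_distance(aa1: str, aa2: str) -> float:
    c1, p1, v1 = PROPERTIES[aa1]
    c2, p2, v2 = PROPERTIES[aa2]
    return math.sqrt(ALPHA * (c1 - c2) ** 2 + BETA * (p1 - p2) ** 2 + GAMMA * (v1 - v2) ** 2)


def grantham_ranking(code: GeneticCode | None = None) -> ExchangeClassTable:
    """Rank the elementary exchange classes by increasing Grantham distance.

    Ties (none occur under the standard code at double precision) would be
    broken by lexicographic pair order for determinism.
    """
    code = code or standard_code()
    table = build_exchange_classes(code)
    ordered = sorted(table.classes, key=lambda p: (grantham_distance(*sorted(p)), sorted(p)))
    rank = {pair: i + 1 for i, pair in enumerate(ordered)}
    return table.with_ranks(
        rank,
        provenance="synthetic ranking: elementary classes ordered by Grantham (1974) distance",
    )
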