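"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions, deliberately avoiding the
package's own tables and accumulation strategy: codons are translated via
Biopython, neighbors enumerated in place, sites accumulated as exact
rationals column by column, and Fisher p-values obtained by full
hypergeometric enumeration with integer combinatorics.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
NTS = "ACGT"
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def translate(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


def enumerate_elementary_pairs() -> set[frozenset[str]]:
    """All unordered amino-acid pairs reachable by one nucleotide change."""
    pairs = set()
    for n1 in NTS:
        for n2 in NTS:
            for n3 in NTS:
                codon = n1 + n2 + n3
                if codon in _STOPS:
                    continue
                for pos in range(3):
                    for alt in NTS:
                        if alt == codon[pos]:
                            continue
                        other = codon[:pos] + alt + codon[pos + 1 :]
                        if other in _STOPS:
                            continue
                        a, b = translate(codon), translate(other)
                        if a != b:
                            pairs.add(frozenset((a, b)))
    return pairs


def site_weights_for_codon(codon: str, kappa: Fraction):
    """(syn, {aa_pair: weight}, stop) site weights of one codon, exact."""
    w_ts = kappa / (kappa + 2)
    w_tv = Fraction(1, 1) / (kappa + 2)
    syn = Fraction(0)
    by_pair: dict[frozenset, Fraction] = {}
    stop = Fraction(0)
    aa = translate(codon)
    for pos in range(3):
        for alt in NTS:
            if alt == codon[pos]:
                continue
            nb = codon[:pos] + alt + codon[pos + 1 :]
            w = w_ts if _TS[codon[pos]] == alt else w_tv
            if nb in _STOPS:
                stop += w
            elif translate(nb) == aa:
                syn += w
            else:
                pair = frozenset((aa, translate(nb)))
                by_pair[pair] = by_pair.get(pair, Fraction(0)) + w
    return syn, by_pair, stop


def syn_steps_pathways(codon_a: str, codon_b: str) -> Fraction:
    """Mean synonymous steps over stop-free minimal pathways."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    totals = []
    for order in permutations(diffs):
        cur = codon_a
        steps = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                steps += 1
            cur = nxt
        if ok:
            totals.append(steps)
    return Fraction(sum(totals), len(totals)) if totals else Fraction(0)


def brute_force_counts(seq_a: str, seq_b: str, kappa: float, rank_of):
    """Column-by-column N/L counting from the definitions.

    ``rank_of(aa1, aa2)`` maps an elementary pair to its class rank.
    Returns a dict with exact-Fraction Ns/Ls/Ni/Li plus integer tallies.
    """
    kap = Fraction(kappa)
    ns = Fraction(0)
    ni: dict[int, Fraction] = {}
    n_total = 0
    n_nonelem = 0
    used_a, used_b = [], []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(ch not in NTS for ch in ca + cb):
            continue  # gap or ambiguity in the column
        if ca in _STOPS or cb in _STOPS:
            continue
        used_a.append(ca)
        used_b.append(cb)
        diffs = [j for j in range(3) if ca[j] != cb[j]]
        if not diffs:
            continue
        aa1, aa2 = translate(ca), translate(cb)
        if len(diffs) == 1:
            if aa1 == aa2:
                ns += 1
            else:
                r = rank_of(aa1, aa2)
                ni[r] = ni.get(r, Fraction(0)) + 1
                n_total += 1
        else:
            if aa1 == aa2:
                ns += syn_steps_pathways(ca, cb)
            else:
                n_nonelem += 1
                n_total += 1
                ns += syn_steps_pathways(ca, cb)
    ls = Fraction(0)
    li: dict[int, Fraction] = {}
    stop_w = Fraction(0)
    for seq in ("".join(used_a), "".join(used_b)):
        for i in range(0, len(seq), 3):
            syn, by_pair, stop = site_weights_for_codon(seq[i : i + 3], kap)
            ls += syn
            stop_w += stop
            for pair, w in by_pair.items():
                r = rank_of(*sorted(pair))
                li[r] = li.get(r, Fraction(0)) + w
    half = Fraction(1, 2)
    return {
        "ns": ns,
        "ls": ls * half,
        "ni": ni,
        "li": {r: v * half for r, v in li.items()},
        "stop_weight": stop_w * half,
        "n_aa_changes_total": n_total,
        "n_nonelementary": n_nonelem,
        "n_codons_used": len(used_a),
    }


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration: sum of P(tables) <= P(obs).

    Margins fixed at (a+b, c+d, a+c); probabilities from integer binomial
    coefficients, compared with a tiny relative tolerance to absorb float
    representation of the observed probability.
    """
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if p <= p_obs or abs(p - p_obs) <= p_obs * Fraction(1, 10**7):
            total += p
    return float(min(total, Fraction(1)))
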