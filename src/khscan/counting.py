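"""Codon-change classification, site counting, and kappa estimation.

Substitutions (N) and mutation-opportunity sites (L) are tallied per
exchange class with kappa-weighted site counting: each codon position
contributes one site unit, split kappa/(kappa+2) to its transition
neighbor and 1/(kappa+2) to each of the two transversion neighbors.  Site
weights falling on stop-codon neighbors are excluded (recorded as
``stop_weight``) and not renormalized.

All N/L bookkeeping is exact rational arithmetic (``fractions.Fraction``),
so results are independent of accumulation order and identical across
implementations; callers convert to float at the rates layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations

from .alignment_io import CodonAlignment
from .reference_data import (
    NUCLEOTIDES,
    STOP,
    TRANSITION,
    ExchangeClassTable,
    GeneticCode,
    codon_neighbors,
)

#: codon families fourfold degenerate at position 3 are detected from the code


@dataclass(frozen=True)
class ChangeClassification:
    """Outcome of comparing one aligned codon pair."""

    kind: str  # identical | synonymous | elementary | nonelementary_aa_change |
    #            multihit_synonymous | stop_involving
    n_diffs: int
    aa_pair: frozenset[str] | None = None
    class_rank: int | None = None
    is_transition: bool | None = None  # single-diff changes only


@dataclass
class SubstitutionCounts:
    """Observed substitutions and mutation-opportunity sites for one gene.

    ``ni``/``li`` are indexed by class rank (1-based key).  Values are exact
    rationals; use :meth:`ns_float` etc. or plain ``float()`` for output.
    """

    ns: Fraction = Fraction(0)
    ls: Fraction = Fraction(0)
    ni: dict[int, Fraction] = field(default_factory=dict)
    li: dict[int, Fraction] = field(default_factory=dict)
    stop_weight: Fraction = Fraction(0)
    n_aa_changes_total: int = 0
    n_nonelementary: int = 0
    n_codons_used: int = 0

    def na(self) -> Fraction:
        """Total elementary nonsynonymous substitutions (sum over classes)."""
        return sum(self.ni.values(), Fraction(0))

    def la(self) -> Fraction:
        """Total elementary nonsynonymous sites."""
        return sum(self.li.values(), Fraction(0))

    def pooled(self, ranks: list[int]) -> tuple[Fraction, Fraction]:
        n = sum((self.ni.get(r, Fraction(0)) for r in ranks), Fraction(0))
        l = sum((self.li.get(r, Fraction(0)) for r in ranks), Fraction(0))
        return n, l

    def add(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        """Pool two count sets (used for supergene concatenation)."""
        out = SubstitutionCounts(
            ns=self.ns + other.ns,
            ls=self.ls + other.ls,
            stop_weight=self.stop_weight + other.stop_weight,
            n_aa_changes_total=self.n_aa_changes_total + other.n_aa_changes_total,
            n_nonelementary=self.n_nonelementary + other.n_nonelementary,
            n_codons_used=self.n_codons_used + other.n_codons_used,
        )
        for r in set(self.ni) | set(other.ni):
            out.ni[r] = self.ni.get(r, Fraction(0)) + other.ni.get(r, Fraction(0))
        for r in set(self.li) | set(other.li):
            out.li[r] = self.li.get(r, Fraction(0)) + other.li.get(r, Fraction(0))
        return out


@dataclass(frozen=True)
class KappaEstimate:
    """Transition/transversion rate ratio from fourfold-degenerate sites.

    ``source`` records how the value was obtained: ``"k80"`` (closed form),
    ``"capped"`` (Q=0 with P>0), ``"default"`` (no informative sites), or a
    policy label such as ``"global"``/``"fixed"`` set by the caller.
    """

    kappa: float
    n_4fold_sites: int = 0
    P: float = 0.0
    Q: float = 0.0
    source: str = "k80"


DEFAULT_KAPPA = 2.0
KAPPA_CAP = 50.0


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(nt not in NUCLEOTIDES for nt in codon):
        raise ValueError(f"not an unambiguous DNA triplet: {codon!r}")


def classify_codon_change(
    codon_a: str,
    codon_b: str,
    code: GeneticCode,
    table: ExchangeClassTable,
) -> ChangeClassification:
    """Classify the difference between two aligned, ungapped codons.

    Single-nucleotide amino-acid changes between sense codons are
    *elementary* and carry the rank of their exchange class; codon pairs
    differing at 2–3 positions with differing amino acids are counted as one
    non-elementary change with no class.
    """
    _check_codon(codon_a)
    _check_codon(codon_b)
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    n = len(diffs)
    if code.is_stop(codon_a) or code.is_stop(codon_b):
        return ChangeClassification(kind="stop_involving", n_diffs=n)
    if n == 0:
        return ChangeClassification(kind="identical", n_diffs=0)
    aa_a, aa_b = code.translate(codon_a), code.translate(codon_b)
    is_ts = TRANSITION[codon_a[diffs[0]]] == codon_b[diffs[0]] if n == 1 else None
    if aa_a == aa_b:
        kind = "synonymous" if n == 1 else "multihit_synonymous"
        return ChangeClassification(kind=kind, n_diffs=n, is_transition=is_ts)
    pair = frozenset((aa_a, aa_b))
    if n == 1:
        return ChangeClassification(
            kind="elementary", n_diffs=1, aa_pair=pair,
            class_rank=table.rank_of(aa_a, aa_b), is_transition=is_ts,
        )
    return ChangeClassification(kind="nonelementary_aa_change", n_diffs=n, aa_pair=pair)


class SiteWeights:
    """Per-codon site-weight table for a fixed kappa, code and class table.

    For each sense codon the single site unit of each position is split
    kappa/(kappa+2) : 1/(kappa+2) : 1/(kappa+2) over its three neighbors and
    routed to the synonymous pool, the neighbor's exchange class, or the
    stop-opportunity weight.  Weights are exact rationals: kappa (a float)
    is taken exactly as p/q, so every weight is an integer numerator over
    the common denominator D = p + 2q, and site totals are accumulated as
    integers.
    """

    def __init__(self, kappa: float, code: GeneticCode, table: ExchangeClassTable):
        if kappa <= 0:
            raise ValueError(f"kappa must be positive, got {kappa}")
        self.kappa = kappa
        k = Fraction(kappa)
        p, q = k.numerator, k.denominator
        self.denom = p + 2 * q  # per-position denominator; per site unit is q*3... see below
        # weight of the transition neighbor is p/(p+2q); each transversion q/(p+2q)
        self.w_ts = Fraction(p, self.denom)
        self.w_tv = Fraction(q, self.denom)
        self.per_codon: dict[str, tuple[int, dict[int, int], int]] = {}
        for codon in code.sense_codons:
            aa = code.translate(codon)
            ls = 0
            li: dict[int, int] = {}
            stop_w = 0
            for nb in codon_neighbors(codon):
                pos = next(i for i in range(3) if codon[i] != nb[i])
                w = p if TRANSITION[codon[pos]] == nb[pos] else q
                aa2 = code.translate(nb)
                if aa2 == STOP:
                    stop_w += w
                elif aa2 == aa:
                    ls += w
                else:
                    r = table.rank_of(aa, aa2)
                    li[r] = li.get(r, 0) + w
            self.per_codon[codon] = (ls, li, stop_w)


def count_sites(
    seq: str,
    kappa: float,
    code: GeneticCode,
    table: ExchangeClassTable,
    weights: SiteWeights | None = None,
) -> tuple[Fraction, dict[int, Fraction], Fraction]:
    """Kappa-weighted synonymous, per-class, and stop-opportunity sites.

    ``seq`` is an ungapped, in-frame codon sequence; a stop codon anywhere
    raises naming its position.  Returns ``(Ls, {rank: Li}, stop_weight)``
    with ``Ls + sum(Li) + stop_weight == 3 * n_codons`` exactly.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    w = weights if weights is not None and weights.kappa == kappa else SiteWeights(kappa, code, table)
    ls = 0
    li: dict[int, int] = {}
    stop_w = 0
    per_codon = w.per_codon
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        entry = per_codon.get(codon)
        if entry is None:
            _check_codon(codon)
            raise ValueError(f"stop codon {codon} at codon position {i // 3}")
        c_ls, c_li, c_stop = entry
        ls += c_ls
        stop_w += c_stop
        for r, cw in c_li.items():
            li[r] = li.get(r, 0) + cw
    d = w.denom
    return (Fraction(ls, d), {r: Fraction(v, d) for r, v in li.items()}, Fraction(stop_w, d))


def _synonymous_steps_multihit(codon_a: str, codon_b: str, code: GeneticCode) -> Fraction:
    """Pathway-averaged synonymous step count for a multi-diff synonymous pair.

    Minimal mutational pathways are the orderings of the differing positions;
    pathways passing through a stop codon are excluded.  Returns the mean
    number of synonymous steps over the remaining pathways (0 if every
    pathway hits a stop, which cannot happen between sense codons of the
    same amino acid under the standard code for 2-diff pairs).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    totals: list[int] = []
    for order in permutations(diffs):
        current = codon_a
        syn_steps = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(nxt) == code.translate(current):
                syn_steps += 1
            current = nxt
        if ok:
            totals.append(syn_steps)
    if not totals:
        return Fraction(0)
    return Fraction(sum(totals), len(totals))


def count_substitutions(
    aln: CodonAlignment,
    code: GeneticCode,
    table: ExchangeClassTable,
    kappa: float | KappaEstimate = DEFAULT_KAPPA,
    weights: SiteWeights | None = None,
) -> SubstitutionCounts:
    """Count substitutions and sites over the usable columns of an alignment.

    Columns containing gaps/ambiguity in either codon, or a stop codon, are
    skipped.  Single-difference columns increment Ns or the elementary class
    of their amino-acid pair; multi-difference columns with differing amino
    acids count as one non-elementary change; multi-difference synonymous
    columns credit Ns with the pathway-averaged number of synonymous steps.
    L values are the mean of :func:`count_sites` over the two sequences.
    """
    kap = kappa.kappa if isinstance(kappa, KappaEstimate) else float(kappa)
    w = weights if weights is not None and weights.kappa == kap else SiteWeights(kap, code, table)
    sense = w.per_codon  # membership doubles as a validity/stop check
    out = SubstitutionCounts()
    seq_a_used: list[str] = []
    seq_b_used: list[str] = []
    for codon_a, codon_b in aln.iter_codons():
        if codon_a == codon_b:
            if codon_a in sense:  # identical, valid, non-stop: usable, no change
                seq_a_used.append(codon_a)
                seq_b_used.append(codon_b)
                out.n_codons_used += 1
                continue
            if aln.is_skippable(codon_a, codon_b):
                continue
            cls = classify_codon_change(codon_a, codon_b, code, table)
            if cls.kind == "stop_involving":
                continue
            raise AssertionError("unreachable")  # pragma: no cover
        if aln.is_skippable(codon_a, codon_b):
            continue
        cls = classify_codon_change(codon_a, codon_b, code, table)
        if cls.kind == "stop_involving":
            continue
        seq_a_used.append(codon_a)
        seq_b_used.append(codon_b)
        out.n_codons_used += 1
        if cls.kind == "synonymous":
            out.ns += 1
        elif cls.kind == "elementary":
            out.ni[cls.class_rank] = out.ni.get(cls.class_rank, Fraction(0)) + 1
            out.n_aa_changes_total += 1
        elif cls.kind == "nonelementary_aa_change":
            out.n_nonelementary += 1
            out.n_aa_changes_total += 1
            # synonymous steps on the mutational pathways still feed Ns
            out.ns += _synonymous_steps_multihit(codon_a, codon_b, code)
        elif cls.kind == "multihit_synonymous":
            out.ns += _synonymous_steps_multihit(codon_a, codon_b, code)
    if out.n_codons_used == 0:
        raise ValueError(f"gene {aln.gene_id}: no usable codon columns")
    ls_a, li_a, stop_a = count_sites("".join(seq_a_used), kap, code, table, weights=w)
    ls_b, li_b, stop_b = count_sites("".join(seq_b_used), kap, code, table, weights=w)
    half = Fraction(1, 2)
    out.ls = (ls_a + ls_b) * half
    out.stop_weight = (stop_a + stop_b) * half
    for r in set(li_a) | set(li_b):
        out.li[r] = (li_a.get(r, Fraction(0)) + li_b.get(r, Fraction(0))) * half
    return out


def _fourfold_families(code: GeneticCode) -> set[str]:
    """First-two-nucleotide prefixes whose codon box is fourfold degenerate."""
    fams = set()
    for n1 in NUCLEOTIDES:
        for n2 in NUCLEOTIDES:
            aas = {code.translate(n1 + n2 + n3) for n3 in NUCLEOTIDES}
            if len(aas) == 1 and STOP not in aas:
                fams.add(n1 + n2)
    return fams


def k80_kappa(P: float, Q: float) -> float:
    """Kimura two-parameter closed-form kappa from difference proportions.

    kappa = [-1/2 ln(1-2P-Q) + 1/4 ln(1-2Q)] / [-1/4 ln(1-2Q)].
    Raises on saturation (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        raise ValueError(f"saturated difference proportions: P={P}, Q={Q}")
    denom = -0.25 * math.log(1 - 2 * Q)
    num = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
    if denom == 0.0:
        raise ZeroDivisionError("Q == 0: kappa undefined")
    return num / denom


def fourfold_differences(aln: CodonAlignment, code: GeneticCode) -> tuple[int, int, int]:
    """(n_sites, n_transitions, n_transversions) at comparable fourfold sites.

    A third-position site is comparable when both codons share identical
    first two nucleotides, that codon box is fourfold degenerate, and no
    gap/ambiguity is present in the column.
    """
    fams = _fourfold_families(code)
    n = ts = tv = 0
    for codon_a, codon_b in aln.iter_codons():
        if aln.is_skippable(codon_a, codon_b):
            continue
        if codon_a[:2] != codon_b[:2] or codon_a[:2] not in fams:
            continue
        n += 1
        a3, b3 = codon_a[2], codon_b[2]
        if a3 != b3:
            if TRANSITION[a3] == b3:
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def estimate_kappa(aln: CodonAlignment, code: GeneticCode) -> KappaEstimate:
    """Estimate kappa from fourfold-degenerate third codon positions (K80).

    With no observed differences the estimator is uninformative and the
    default kappa (2.0) is returned; with transitions but no transversions
    kappa is undefined and capped at 50.  Saturation raises.
    """
    n, ts, tv = fourfold_differences(aln, code)
    return kappa_from_fourfold(n, ts, tv)


def kappa_from_fourfold(n_sites: int, n_ts: int, n_tv: int) -> KappaEstimate:
    """Kappa estimate from pooled fourfold-site difference counts."""
    if n_sites == 0:
        return KappaEstimate(kappa=DEFAULT_KAPPA, n_4fold_sites=0, source="default")
    P = n_ts / n_sites
    Q = n_tv / n_sites
    if P == 0 and Q == 0:
        return KappaEstimate(kappa=DEFAULT_KAPPA, n_4fold_sites=n_sites, P=0.0, Q=0.0,
                             source="default")
    if Q == 0:
        return KappaEstimate(kappa=KAPPA_CAP, n_4fold_sites=n_sites, P=P, Q=0.0, source="capped")
    kappa = k80_kappa(P, Q)
    # numerically P slightly above the Q=2P neutral line can give kappa<=0
    if kappa <= 0:
        kappa = min(max(kappa, 1e-6), KAPPA_CAP)
    return KappaEstimate(kappa=kappa, n_4fold_sites=n_sites, P=P, Q=Q, source="k80")
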