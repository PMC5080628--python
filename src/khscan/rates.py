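"""Jukes–Cantor-corrected rates K_s, K_i, cumulative K_i*, K_a, K_h and
Fisher's exact significance for the rate ratios.

Cumulative rates pool counts first and correct the pooled proportion
(rather than averaging per-class distances), which makes K_75* exactly the
standard K_a computed from pooled nonsynonymous counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

from scipy import stats

from .counting import KappaEstimate, SubstitutionCounts
from .reference_data import ExchangeClassTable


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance -(3/4) ln(1 - (4/3) p).

    Defined for 0 <= p < 0.75; saturation (p >= 0.75) raises.
    """
    p = float(p)
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise ValueError(f"saturated proportion p={p} >= 0.75")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _round_half_away(x: float) -> int:
    return math.floor(x + 0.5) if x >= 0 else -math.floor(-x + 0.5)


def fisher_ratio_test(
    n1: float, l1: float, n2: float, l2: float, sided: str = "two"
) -> float:
    """Fisher's exact test comparing two substitutions-per-site proportions.

    Builds the 2x2 table [[N1, round(L1)-N1], [N2, round(L2)-N2]] with sites
    rounded half-away-from-zero (substitution counts likewise when they are
    fractional).  ``sided`` is ``"two"`` (probability-ordering two-sided
    mass) or ``"greater"`` (N1/L1 > N2/L2 alternative).
    """
    a = _round_half_away(float(n1))
    c = _round_half_away(float(n2))
    b = _round_half_away(float(l1)) - a
    d = _round_half_away(float(l2)) - c
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in 2x2 table [[{a},{b}],[{c},{d}]]")
    alternative = {"two": "two-sided", "greater": "greater"}[sided]
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


@dataclass
class RateEstimates:
    """Corrected substitution rates and significance for one gene/supergene.

    ``ki``/``kistar`` are keyed by class rank; entries are None when the
    class (or pooled) site total is zero.  ``ka`` is ``kistar[n_classes]``
    and ``kh`` is ``kistar[h_cutoff_rank]`` by construction.
    """

    kappa: float
    ks: float | None
    ki: dict[int, float | None] = field(default_factory=dict)
    kistar: dict[int, float | None] = field(default_factory=dict)
    ka: float | None = None
    kh: float | None = None
    ka_ks: float | None = None
    kh_ks: float | None = None
    p_ka_ks: float | None = None
    p_kh_ks: float | None = None
    nh: float = 0.0
    lh: float = 0.0
    na: float = 0.0
    la: float = 0.0


def compute_rates(
    counts: SubstitutionCounts,
    kappa: KappaEstimate | float,
    table: ExchangeClassTable,
    h_cutoff_rank: int = 10,
    fisher_sided: str = "two",
) -> RateEstimates:
    """Turn N/L counts into K_s, per-class K_i, cumulative K_i*, K_a, K_h.

    K_i*[i] = JC( sum_{rank<=i} N_j / sum_{rank<=i} L_j ); ratios to K_s and
    their Fisher p-values are attached when K_s is defined and positive.
    """
    if not table.is_ranked:
        raise ValueError("exchange-class table must be ranked")
    kap = kappa.kappa if isinstance(kappa, KappaEstimate) else float(kappa)
    n_classes = table.n_classes

    def _jc_or_none(n: Fraction, l: Fraction) -> float | None:
        # zero sites or a saturated proportion (>= 0.75, possible for rare
        # classes with tiny fractional site pools) -> rate undefined
        if l <= 0 or n / l >= Fraction(3, 4):
            return None
        return jukes_cantor(n / l)

    ks = _jc_or_none(counts.ns, counts.ls)
    ki: dict[int, float | None] = {}
    for r in range(1, n_classes + 1):
        ki[r] = _jc_or_none(counts.ni.get(r, Fraction(0)), counts.li.get(r, Fraction(0)))

    kistar: dict[int, float | None] = {}
    cum_n = Fraction(0)
    cum_l = Fraction(0)
    for r in range(1, n_classes + 1):
        cum_n += counts.ni.get(r, Fraction(0))
        cum_l += counts.li.get(r, Fraction(0))
        kistar[r] = _jc_or_none(cum_n, cum_l)

    nh, lh = counts.pooled(list(range(1, h_cutoff_rank + 1)))
    na, la = counts.pooled(list(range(1, n_classes + 1)))

    est = RateEstimates(
        kappa=kap, ks=ks, ki=ki, kistar=kistar,
        ka=kistar[n_classes], kh=kistar[h_cutoff_rank],
        nh=float(nh), lh=float(lh), na=float(na), la=float(la),
    )
    if ks is not None and ks > 0:
        if est.ka is not None:
            est.ka_ks = est.ka / ks
            est.p_ka_ks = fisher_ratio_test(na, la, counts.ns, counts.ls, sided=fisher_sided)
        if est.kh is not None:
            est.kh_ks = est.kh / ks
            est.p_kh_ks = fisher_ratio_test(nh, lh, counts.ns, counts.ls, sided=fisher_sided)
    return est
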