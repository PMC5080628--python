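"""Per-gene screening pipeline: filters, PSG calls, K_s distribution, and
the supergene "twofold approximation" regression.

A gene passes the screen when it survives the divergence filters
(K_a <= 0.05, 0.005 <= K_s <= 0.08) and shows K_h/K_s > 1 with Fisher's
exact p below threshold; such genes are flagged candidate positively
selected genes (PSGs).  To examine the K_h/K_s vs K_a/K_s relationship in
genes of different divergence, genes with K_a > 0 are sorted by K_a and
pooled 100 at a time into "supergenes" whose counts are summed before rates
are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import RESULT_COLUMNS, CodonAlignment
from .counting import (
    DEFAULT_KAPPA,
    KappaEstimate,
    SiteWeights,
    SubstitutionCounts,
    count_substitutions,
    fourfold_differences,
    kappa_from_fourfold,
)
from .rates import RateEstimates, compute_rates
from .reference_data import ExchangeClassTable, GeneticCode, standard_code

#: genes need at least this many comparable fourfold sites for a per-gene kappa
MIN_4FOLD_SITES = 50


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and policies of the screen.

    Divergence filters remove genes whose rate estimates are unreliable for
    the exact test: too diverged (K_a > ka_max or K_s > ks_max, multiple
    hits start to dominate) or too similar (K_s < ks_min, no information).
    """

    ka_max: float = 0.05
    ks_max: float = 0.08
    ks_min: float = 0.005
    p_threshold: float = 0.05
    h_cutoff_rank: int = 10
    bin_size: int = 100
    fisher_sided: str = "two"  # "two" | "greater"
    kappa_policy: str = "per-gene"  # "per-gene" | "global" | "fixed:<X>"

    def __post_init__(self) -> None:
        if not (0 < self.ks_min < self.ks_max):
            raise ValueError("require 0 < ks_min < ks_max")
        if self.h_cutoff_rank < 1:
            raise ValueError("h_cutoff_rank must be >= 1")
        if self.fisher_sided not in {"two", "greater"}:
            raise ValueError(f"unknown fisher_sided {self.fisher_sided!r}")


@dataclass
class GeneResult:
    """One row of the per-gene result table."""

    gene_id: str
    species_a: str
    species_b: str
    counts: SubstitutionCounts
    rates: RateEstimates
    filtered: bool = False
    filter_reason: str | None = None
    is_psg: bool = False

    def to_row(self) -> dict:
        r, c = self.rates, self.counts
        return {
            "gene_id": self.gene_id,
            "species_a_id": self.species_a,
            "species_b_id": self.species_b,
            "Ns": float(c.ns), "Ls": float(c.ls),
            "Nh": r.nh, "Lh": r.lh, "Na": r.na, "La": r.la,
            "kappa": r.kappa, "Ks": r.ks, "Ka": r.ka, "Kh": r.kh,
            "Ka_Ks": r.ka_ks, "Kh_Ks": r.kh_ks,
            "p_Ka_Ks": r.p_ka_ks, "p_Kh_Ks": r.p_kh_ks,
            "n_nonelementary": c.n_nonelementary,
            "filtered": self.filtered,
            "filter_reason": self.filter_reason,
            "is_psg": self.is_psg,
        }


@dataclass
class SupergeneSet:
    """Pooled counts/rates of consecutive K_a-ranked 100-gene bins."""

    counts: list[SubstitutionCounts]
    rates: list[RateEstimates]
    n_genes_used: int
    n_genes_dropped: int
    bin_size: int
    slope: float | None = None


def apply_filters(rates: RateEstimates, config: ScreenConfig) -> tuple[bool, str | None]:
    """Divergence-filter verdict; the first violated predicate names the reason."""
    if rates.ks is None:
        return True, "ks_undefined"
    if rates.ka is not None and rates.ka > config.ka_max:
        return True, "ka_gt_max"
    if rates.ks > config.ks_max:
        return True, "ks_gt_max"
    if rates.ks < config.ks_min:
        return True, "ks_lt_min"
    return False, None


def call_psg(rates: RateEstimates, filtered: bool, config: ScreenConfig) -> bool:
    """Candidate PSG: unfiltered, K_h/K_s > 1, and exact-test p < threshold."""
    return (
        not filtered
        and rates.kh_ks is not None
        and rates.kh_ks > 1
        and rates.p_kh_ks is not None
        and rates.p_kh_ks < config.p_threshold
    )


def _resolve_kappa(
    aln: CodonAlignment,
    code: GeneticCode,
    config: ScreenConfig,
    global_kappa: KappaEstimate | None,
    ffd: tuple[int, int, int] | None = None,
) -> KappaEstimate:
    policy = config.kappa_policy
    if policy.startswith("fixed:"):
        return KappaEstimate(kappa=float(policy.split(":", 1)[1]), source="fixed")
    if policy == "global":
        if global_kappa is None:
            raise ValueError("global kappa requested but not supplied")
        return global_kappa
    # per-gene with fallback to global, then to the default
    n, ts, tv = ffd if ffd is not None else fourfold_differences(aln, code)
    if n >= MIN_4FOLD_SITES:
        return kappa_from_fourfold(n, ts, tv)
    if global_kappa is not None:
        return replace(global_kappa, source="global")
    return KappaEstimate(kappa=DEFAULT_KAPPA, n_4fold_sites=n, source="default")


def analyze_gene(
    aln: CodonAlignment,
    table: ExchangeClassTable,
    config: ScreenConfig = ScreenConfig(),
    code: GeneticCode | None = None,
    global_kappa: KappaEstimate | None = None,
    weights_cache: dict | None = None,
    ffd: tuple[int, int, int] | None = None,
) -> GeneResult:
    """Counts -> kappa -> rates -> p-values -> filter/PSG flags for one gene."""
    code = code or standard_code()
    kappa = _resolve_kappa(aln, code, config, global_kappa, ffd=ffd)
    weights = None
    if weights_cache is not None:
        weights = weights_cache.get(kappa.kappa)
        if weights is None:
            weights = SiteWeights(kappa.kappa, code, table)
            weights_cache[kappa.kappa] = weights
    counts = count_substitutions(aln, code, table, kappa=kappa, weights=weights)
    rates = compute_rates(counts, kappa, table,
                          h_cutoff_rank=config.h_cutoff_rank,
                          fisher_sided=config.fisher_sided)
    filtered, reason = apply_filters(rates, config)
    psg = call_psg(rates, filtered, config)
    return GeneResult(
        gene_id=aln.gene_id, species_a=aln.species_a, species_b=aln.species_b,
        counts=counts, rates=rates, filtered=filtered, filter_reason=reason,
        is_psg=psg,
    )


def run_screen(
    alignments: Iterable[CodonAlignment],
    table: ExchangeClassTable,
    config: ScreenConfig = ScreenConfig(),
    code: GeneticCode | None = None,
    log=None,
) -> list[GeneResult]:
    """Screen a gene cohort; deterministic given inputs and config.

    With the default per-gene kappa policy, genes short of fourfold sites
    fall back to a global kappa pooled over the whole cohort.
    """
    code = code or standard_code()
    alns = list(alignments)
    if not alns:
        raise ValueError("no alignments supplied")
    # pooled fourfold differences over all genes -> global fallback kappa
    ffds = [fourfold_differences(aln, code) for aln in alns]
    tot_n = sum(f[0] for f in ffds)
    tot_ts = sum(f[1] for f in ffds)
    tot_tv = sum(f[2] for f in ffds)
    global_kappa = kappa_from_fourfold(tot_n, tot_ts, tot_tv)
    cache: dict = {}
    results = [
        analyze_gene(aln, table, config, code=code, global_kappa=global_kappa,
                     weights_cache=cache, ffd=ffd)
        for aln, ffd in zip(alns, ffds)
    ]
    if log is not None:
        n_filtered = sum(r.filtered for r in results)
        n_ka = sum(1 for r in results if r.rates.ka_ks is not None and r.rates.ka_ks > 1)
        n_psg = sum(r.is_psg for r in results)
        log(f"screened {len(results)} genes: {n_filtered} filtered, "
            f"{n_ka} with Ka/Ks>1, {n_psg} candidate PSGs "
            f"(global kappa {global_kappa.kappa:.3f} from {tot_n} fourfold sites)")
    return results


def results_to_table(results: Sequence[GeneResult]) -> pd.DataFrame:
    """Per-gene results as a DataFrame with the fixed column order."""
    ids = [r.gene_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in results")
    return pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)


def build_supergenes(
    results: Sequence[GeneResult],
    table: ExchangeClassTable,
    config: ScreenConfig = ScreenConfig(),
) -> SupergeneSet:
    """Pool K_a-sorted genes into fixed-size bins and recompute rates.

    Genes with undefined or zero K_a are excluded; the remainder are sorted
    by K_a descending (ties broken by gene_id for determinism), pooled in
    bins of ``config.bin_size`` by summing their N and L counts, and the
    trailing remainder is dropped.  The twofold regression slope over the
    supergenes is attached.
    """
    eligible = [r for r in results if r.rates.ka is not None and r.rates.ka > 0]
    if len(eligible) < config.bin_size:
        raise ValueError(
            f"need at least {config.bin_size} genes with Ka > 0, have {len(eligible)}")
    eligible.sort(key=lambda r: (-r.rates.ka, r.gene_id))
    n_bins = len(eligible) // config.bin_size
    pooled_counts: list[SubstitutionCounts] = []
    pooled_rates: list[RateEstimates] = []
    for b in range(n_bins):
        members = eligible[b * config.bin_size : (b + 1) * config.bin_size]
        acc = members[0].counts
        for m in members[1:]:
            acc = acc.add(m.counts)
        mean_kappa = float(np.mean([m.rates.kappa for m in members]))
        pooled_counts.append(acc)
        pooled_rates.append(
            compute_rates(acc, mean_kappa, table,
                          h_cutoff_rank=config.h_cutoff_rank,
                          fisher_sided=config.fisher_sided))
    sset = SupergeneSet(
        counts=pooled_counts, rates=pooled_rates,
        n_genes_used=n_bins * config.bin_size,
        n_genes_dropped=len(eligible) - n_bins * config.bin_size,
        bin_size=config.bin_size,
    )
    try:
        sset.slope = twofold_regression(sset)
    except ValueError:
        sset.slope = None
    return sset


def twofold_regression(supergenes: SupergeneSet, intercept: bool = False) -> float:
    """Least-squares slope of K_h/K_s on K_a/K_s over the supergenes.

    Through the origin by default (slope = sum(xy)/sum(x^2)); with
    ``intercept=True`` an ordinary two-parameter fit is used and the slope
    returned.  A slope near 2 is the "twofold approximation" pattern.
    """
    xy = [(r.ka_ks, r.kh_ks) for r in supergenes.rates
          if r.ka_ks is not None and r.kh_ks is not None]
    if len(xy) < 2:
        raise ValueError(f"need >= 2 supergenes with defined ratios, have {len(xy)}")
    x = np.array([p[0] for p in xy])
    y = np.array([p[1] for p in xy])
    if intercept:
        if np.ptp(x) == 0:
            raise ValueError("degenerate fit: all Ka/Ks identical")
        slope, _ = np.polyfit(x, y, 1)
        return float(slope)
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate fit: all Ka/Ks zero")
    return float(np.dot(x, y) / sxx)


def summarize_ks(
    results: Sequence[GeneResult] | pd.DataFrame,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Histogram of defined K_s values; returns (counts, edges, modal midpoint).

    The modal midpoint is the center of the most populated bin (ties go to
    the lowest bin); None when no gene has a defined K_s.
    """
    if isinstance(results, pd.DataFrame):
        ks = results["Ks"].dropna().to_numpy(dtype=float)
    else:
        ks = np.array([r.rates.ks for r in results if r.rates.ks is not None], dtype=float)
    if ks.size == 0:
        return np.array([], dtype=int), np.array([]), None
    hi = max(float(ks.max()), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(ks, bins=edges)
    modal = int(np.argmax(counts))
    midpoint = float((edges[modal] + edges[modal + 1]) / 2)
    return counts, edges, midpoint
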