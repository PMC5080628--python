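"""Mutation–selection codon-pair simulator.

Generates pairwise ortholog alignments by evolving two lineages
independently from a common ancestral sequence (a star tree of two).
Mutation proposals at each codon position occur with transition :
transversion rates kappa : 1 (per target), scaled so that a neutral site
accrues ``branch_length`` expected substitutions per lineage; synonymous
proposals are always accepted, nonsynonymous proposals with the acceptance
probability (omega) of their elementary exchange class, and stop-creating
proposals are rejected.  The pairwise divergence is therefore about
2 * branch_length, so branch_length = 0.01 emulates the K_s ~ 0.02 regime
of very recently diverged species pairs.

Every accepted event is logged per gene, giving an exact truth table
against which the counting engine can be verified at low divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import CodonAlignment
from .reference_data import (
    NUCLEOTIDES,
    STOP,
    TRANSITION,
    ExchangeClassTable,
    GeneticCode,
    standard_code,
)


def omega_bands(
    omega_high: float,
    omega_low: float,
    h_ranks: int = 10,
    n_classes: int = 75,
) -> dict[int, float]:
    """Acceptance probabilities: omega_high for ranks 1..h_ranks, omega_low after."""
    return {r: (omega_high if r <= h_ranks else omega_low) for r in range(1, n_classes + 1)}


@dataclass
class SimulationConfig:
    """Parameters of the codon-pair generator.

    ``branch_length`` is expected neutral substitutions per site per
    lineage; ``omega_by_rank`` maps each class rank to its acceptance
    probability (default: neutral, all 1).  ``codon_frequencies`` is a map
    codon -> probability over sense codons (default uniform).
    """

    n_codons: int = 500
    kappa_true: float = 2.0
    branch_length: float = 0.01
    omega_by_rank: dict[int, float] = field(default_factory=dict)
    codon_frequencies: dict[str, float] | None = None
    seed: int = 0
    n_genes: int = 1

    def __post_init__(self) -> None:
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        if self.kappa_true <= 0:
            raise ValueError("kappa_true must be positive")
        if self.branch_length < 0:
            raise ValueError("branch_length must be non-negative")
        if any(w < 0 for w in self.omega_by_rank.values()):
            raise ValueError("acceptance probabilities must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class GeneTruth:
    """Realized (accepted) substitution events for one simulated gene."""

    gene_id: str
    ns_true: int = 0
    ni_true: dict[int, int] = field(default_factory=dict)
    n_events: int = 0
    n_multihit_codons: int = 0  # codons with >=2 accepted events across both lineages

    @property
    def na_true(self) -> int:
        return sum(self.ni_true.values())


class _Engine:
    """Precomputed proposal/acceptance tables for one (code, table, config)."""

    def __init__(self, code: GeneticCode, table: ExchangeClassTable, cfg: SimulationConfig):
        self.code = code
        self.table = table
        self.sense = code.sense_codons
        n_classes = table.n_classes
        omega = {r: 1.0 for r in range(1, n_classes + 1)}
        omega.update(cfg.omega_by_rank)
        # omega > 1 (positive selection) is handled by thinning from a
        # dominating proposal intensity M = max(1, max omega): proposals run
        # M times faster and every acceptance probability is divided by M,
        # which leaves neutral (omega=1) classes exactly calibrated
        self.boost = max(1.0, max(omega.values(), default=1.0))
        # fate: ("stop", 0) | ("syn", p_accept) | ("aa", p_accept, class rank)
        self.fate: dict[str, str | tuple] = {}
        for codon in self.sense:
            aa = code.translate(codon)
            for pos in range(3):
                for nt in NUCLEOTIDES:
                    if nt == codon[pos]:
                        continue
                    nb = codon[:pos] + nt + codon[pos + 1 :]
                    aa2 = code.translate(nb)
                    if aa2 == STOP:
                        self.fate[codon + nb] = ("stop", 0.0)
                    elif aa2 == aa:
                        self.fate[codon + nb] = ("syn", 1.0 / self.boost)
                    else:
                        r = table.rank_of(aa, aa2)
                        self.fate[codon + nb] = ("aa", omega[r] / self.boost, r)
        # ancestral codon distribution
        if cfg.codon_frequencies is None:
            self.anc_codons = self.sense
            self.anc_probs = np.full(len(self.sense), 1.0 / len(self.sense))
        else:
            items = sorted(cfg.codon_frequencies.items())
            bad = [c for c, _ in items if c not in set(self.sense)]
            if bad:
                raise ValueError(f"codon_frequencies contains non-sense codons: {bad}")
            total = sum(p for _, p in items)
            self.anc_codons = [c for c, _ in items]
            self.anc_probs = np.array([p / total for _, p in items])
        self.p_transition = cfg.kappa_true / (cfg.kappa_true + 2.0)


def _evolve_lineage(
    codons: list[str],
    engine: _Engine,
    branch_length: float,
    rng: np.random.Generator,
    truth: GeneTruth,
    events_per_codon: np.ndarray,
) -> list[str]:
    # proposal events per codon ~ Poisson(3 * branch_length * boost): per
    # position the total proposal rate is the neutral substitution rate
    # times the dominating factor for omega > 1 classes
    n_events = rng.poisson(3.0 * branch_length * engine.boost, size=len(codons))
    out = list(codons)
    for idx in np.nonzero(n_events)[0]:
        codon = out[idx]
        for _ in range(n_events[idx]):
            pos = rng.integers(3)
            cur = codon[pos]
            if rng.random() < engine.p_transition:
                nt = TRANSITION[cur]
            else:
                choices = [n for n in NUCLEOTIDES if n != cur and n != TRANSITION[cur]]
                nt = choices[rng.integers(2)]
            nb = codon[:pos] + nt + codon[pos + 1 :]
            fate = engine.fate[codon + nb]
            if fate[0] == "stop":
                continue
            if fate[0] == "syn":
                p_acc = fate[1]
                if p_acc >= 1.0 or rng.random() < p_acc:
                    codon = nb
                    truth.ns_true += 1
                    truth.n_events += 1
                    events_per_codon[idx] += 1
            else:
                _, p_acc, rank = fate
                if p_acc >= 1.0 or rng.random() < p_acc:
                    codon = nb
                    truth.ni_true[rank] = truth.ni_true.get(rank, 0) + 1
                    truth.n_events += 1
                    events_per_codon[idx] += 1
        out[idx] = codon
    return out


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(gene_index,)))


def simulate_pair(
    config: SimulationConfig,
    code: GeneticCode | None = None,
    table: ExchangeClassTable | None = None,
    gene_index: int = 0,
    gene_id: str | None = None,
    _engine: _Engine | None = None,
) -> tuple[CodonAlignment, GeneTruth]:
    """Simulate one ortholog pair; returns the alignment and its event log.

    Reproducible: the random stream is derived from ``(config.seed,
    gene_index)``, so cohorts are order-independent.
    """
    from .reference_data import build_exchange_classes

    code = code or standard_code()
    if table is None:
        base = build_exchange_classes(code)
        table = base.with_ranks({p: i + 1 for i, p in enumerate(base.classes)})
    engine = _engine or _Engine(code, table, config)
    rng = _gene_rng(config.seed, gene_index)
    gid = gene_id or f"g{gene_index:05d}"
    truth = GeneTruth(gene_id=gid)
    anc_idx = rng.choice(len(engine.anc_codons), size=config.n_codons, p=engine.anc_probs)
    ancestor = [engine.anc_codons[i] for i in anc_idx]
    events = np.zeros(config.n_codons, dtype=int)
    tip_a = _evolve_lineage(ancestor, engine, config.branch_length, rng, truth, events)
    tip_b = _evolve_lineage(ancestor, engine, config.branch_length, rng, truth, events)
    truth.n_multihit_codons = int(np.sum(events >= 2))
    aln = CodonAlignment(
        gene_id=gid, seq_a="".join(tip_a), seq_b="".join(tip_b),
        species_a="sim_a", species_b="sim_b",
    )
    return aln, truth


def simulate_cohort(
    config: SimulationConfig,
    code: GeneticCode | None = None,
    table: ExchangeClassTable | None = None,
) -> tuple[list[CodonAlignment], list[GeneTruth]]:
    """Simulate ``config.n_genes`` independent ortholog pairs plus truth logs."""
    from .reference_data import build_exchange_classes

    code = code or standard_code()
    if table is None:
        base = build_exchange_classes(code)
        table = base.with_ranks({p: i + 1 for i, p in enumerate(base.classes)})
    engine = _Engine(code, table, config)
    alns: list[CodonAlignment] = []
    truths: list[GeneTruth] = []
    for g in range(config.n_genes):
        aln, truth = simulate_pair(config, code=code, table=table, gene_index=g,
                                   _engine=engine)
        alns.append(aln)
        truths.append(truth)
    return alns, truths
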