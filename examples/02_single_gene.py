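"""Analyze one ortholog pair: counts, rates, exact test, screening flags.

Simulates a single 500-codon ortholog pair in which the 10 most
exchangeable classes evolve at twice the neutral rate (omega_h = 2) while
all other replacements are strongly constrained (omega_l = 0.1), then runs
the per-gene K_h analysis.  Expect K_h/K_s around 2 and K_a/K_s well below
1 — the situation where the classical K_a/K_s test misses the signal.
"""

from khscan import ScreenConfig, SimulationConfig, analyze_gene, bundled_ranking, simulate_pair
from khscan.simulate import omega_bands

ranking = bundled_ranking()
cfg = SimulationConfig(
    n_codons=500,
    branch_length=0.03,  # pairwise Ks ~ 0.06, inside the screen's filter window
    seed=14,
    omega_by_rank=omega_bands(omega_high=2.0, omega_low=0.1, h_ranks=10),
)
aln, truth = simulate_pair(cfg, table=ranking)
result = analyze_gene(aln, ranking, ScreenConfig(kappa_policy="fixed:2.0"))

r = result.rates
c = result.counts
print(f"gene {result.gene_id}: {c.n_codons_used} codons, "
      f"{float(c.ns):.1f} synonymous and {int(c.na())} elementary changes "
      f"({c.n_nonelementary} non-elementary)")
print(f"Ks   = {r.ks:.4f}   (synonymous rate, Jukes-Cantor corrected)")
print(f"Ka   = {r.ka:.4f}   (= K75*, all elementary classes pooled)")
print(f"Kh   = {r.kh:.4f}   (= K10*, the 10 most exchangeable classes)")
print(f"Ka/Ks = {r.ka_ks:.3f} (p = {r.p_ka_ks:.4f})")
print(f"Kh/Ks = {r.kh_ks:.3f} (p = {r.p_kh_ks:.4f})")
print(f"filtered: {result.filtered}  candidate PSG: {result.is_psg}")
print("Kh/Ks is well above 1 with a small p while Ka/Ks stays below 1: the "
      "selection signal in the exchangeable classes is diluted out of Ka by "
      "the constrained classes, which is exactly what K_h is built to avoid.")
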