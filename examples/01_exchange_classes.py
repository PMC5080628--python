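"""Enumerate the 75 elementary amino-acid change classes and their ranking.

An elementary change is an amino-acid difference reachable by a single
nucleotide substitution between sense codons.  The packaged ranking orders
the classes from most to least exchangeable (rank 1 = most exchangeable);
K_h pools the substitutions of the top 10 classes.
"""

from khscan import build_exchange_classes, bundled_ranking, standard_code

code = standard_code()
classes = build_exchange_classes(code)
print(f"elementary amino-acid change classes under the {code.name} code: "
      f"{classes.n_classes}")

ranking = bundled_ranking(code)
print(f"ranking provenance: {ranking.provenance}")
top = sorted(ranking.rank.items(), key=lambda kv: kv[1])[:10]
print("the 10 most exchangeable classes (these define K_h):")
for pair, rank in top:
    a, b = sorted(pair)
    print(f"  rank {rank:2d}: {a} <-> {b}")
# Lys<->Arg is a classic high-exchangeability pair; Met<->Tyr needs 2 nt
# changes and therefore is not an elementary class at all.
print("Lys/Arg elementary:", ("K", "R") in ranking)
print("Met/Tyr elementary:", ("M", "Y") in ranking)
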