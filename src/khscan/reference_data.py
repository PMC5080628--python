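"""Genetic code, elementary exchange classes, and the exchangeability ranking.

An *elementary* amino-acid change is a difference between two amino acids
that can be produced by a single nucleotide substitution between sense
codons.  Under the standard genetic code there are exactly 75 such unordered
amino-acid pairs.  Ranking them from most to least exchangeable partitions
nonsynonymous evolution into classes whose cumulative rates (K_i*) underlie
the K_h statistic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: transition partner for each nucleotide (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table; stop codons map to ``'*'``."""

    codon_to_aa: dict[str, str]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.codon_to_aa)}")

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    @property
    def sense_codons(self) -> list[str]:
        return [c for c, aa in sorted(self.codon_to_aa.items()) if aa != STOP]

    @property
    def amino_acids(self) -> set[str]:
        return {aa for aa in self.codon_to_aa.values() if aa != STOP}


def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (from Biopython's table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for c in table.stop_codons:
        mapping[c] = STOP
    return GeneticCode(codon_to_aa=mapping, name="standard")


def codon_neighbors(codon: str) -> Iterable[str]:
    """All 9 codons one nucleotide substitution away, in canonical order.

    Order: position 0..2, alternative nucleotide in ``ACGT`` order.
    """
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield codon[:pos] + nt + codon[pos + 1 :]


@dataclass
class ExchangeClassTable:
    """The elementary amino-acid change classes, optionally ranked.

    ``classes`` holds unordered pairs (frozensets of two one-letter amino
    acids).  ``rank`` maps each pair to an integer 1..n from most (1) to
    least (n) exchangeable; it may be empty for an unranked table.
    """

    classes: list[frozenset[str]]
    rank: dict[frozenset[str], int] = field(default_factory=dict)
    provenance: str = ""

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def is_ranked(self) -> bool:
        return bool(self.rank)

    def rank_of(self, aa1: str, aa2: str) -> int:
        return self.rank[frozenset((aa1, aa2))]

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in set(self.classes)

    def with_ranks(self, rank: dict[frozenset[str], int], provenance: str = "") -> "ExchangeClassTable":
        table = ExchangeClassTable(classes=list(self.classes), rank=dict(rank),
                                   provenance=provenance or self.provenance)
        table._validate_ranks()
        return table

    def _validate_ranks(self) -> None:
        pairs = set(self.classes)
        ranked = set(self.rank)
        missing = pairs - ranked
        if missing:
            raise ValueError(f"ranking is missing pair(s): {_fmt_pairs(missing)}")
        extra = ranked - pairs
        if extra:
            raise ValueError(f"ranking contains non-elementary pair(s): {_fmt_pairs(extra)}")
        n = len(self.classes)
        if sorted(self.rank.values()) != list(range(1, n + 1)):
            raise ValueError(f"ranks must be a permutation of 1..{n}")


def _fmt_pairs(pairs: Iterable[frozenset[str]]) -> str:
    return ", ".join("{" + ",".join(sorted(p)) + "}" for p in sorted(pairs, key=sorted))


def build_exchange_classes(code: GeneticCode) -> ExchangeClassTable:
    """Enumerate all elementary amino-acid change classes of a genetic code.

    A pair {A1, A2} is elementary when some sense codon of A1 differs from
    some sense codon of A2 at exactly one nucleotide position.  Returns an
    unranked table; the standard code yields exactly 75 classes.
    """
    pairs: set[frozenset[str]] = set()
    for codon in code.sense_codons:
        aa = code.translate(codon)
        for nb in codon_neighbors(codon):
            aa2 = code.translate(nb)
            if aa2 != STOP and aa2 != aa:
                pairs.add(frozenset((aa, aa2)))
    return ExchangeClassTable(classes=sorted(pairs, key=sorted),
                              provenance=f"enumerated from {code.name} code")


def load_ei_ranking(path: str | Path, code: GeneticCode | None = None) -> ExchangeClassTable:
    """Load an exchangeability ranking from a TSV file.

    Format: optional ``#`` comment lines, a header line, then one row per
    class with columns ``aa1  aa2  rank`` (one-letter amino acids).  The pair
    set must equal the elementary classes of ``code`` and the ranks must be a
    permutation of 1..n; violations are rejected naming the offending pair.
    """
    code = code or standard_code()
    expected = build_exchange_classes(code)
    path = Path(path)
    rank: dict[frozenset[str], int] = {}
    provenance_lines: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                provenance_lines.append(line.lstrip("# "))
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.lower() for f in fields[:3]] != ["aa1", "aa2", "rank"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'aa1\\taa2\\trank', got {line!r}")
                header_seen = True
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            aa1, aa2, r = fields[0].strip(), fields[1].strip(), fields[2].strip()
            pair = frozenset((aa1, aa2))
            if len(pair) != 2:
                raise ValueError(f"{path}:{lineno}: pair {{{aa1},{aa2}}} is not two distinct amino acids")
            if pair in rank:
                raise ValueError(f"{path}:{lineno}: duplicate pair {{{','.join(sorted(pair))}}}")
            if pair not in set(expected.classes):
                raise ValueError(
                    f"{path}:{lineno}: pair {{{','.join(sorted(pair))}}} is not reachable by a "
                    f"single-nucleotide change between sense codons")
            try:
                rank[pair] = int(r)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: rank {r!r} is not an integer") from None
    provenance = "; ".join(provenance_lines) or str(path)
    return expected.with_ranks(rank, provenance=provenance)


def bundled_ranking(code: GeneticCode | None = None) -> ExchangeClassTable:
    """The packaged default exchangeability ranking.

    This is a synthetic stand-in ranking: the 75 elementary pairs ordered by
    Grantham (1974) physicochemical distance, most similar first (see
    :mod:`khscan.grantham` and the data file header).  Supply a measured
    exchangeability ranking via :func:`load_ei_ranking` for production use.
    """
    ref = importlib.resources.files("khscan") / "data" / "ei_ranking_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_ei_ranking(path, code=code)
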