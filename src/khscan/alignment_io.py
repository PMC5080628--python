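"""Reading pairwise in-frame codon alignments; writing result tables.

Input alignments are 2-record FASTA files (or a manifest TSV pointing at
them).  Alignment production itself (ortholog calling, MUSCLE + codon
back-translation) happens upstream; this module only validates frame and
gap structure and exposes the codon columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

GAP_CHARS = set("-.")
AMBIGUOUS = set("NnXx")

RESULT_COLUMNS = [
    "gene_id", "species_a_id", "species_b_id",
    "Ns", "Ls", "Nh", "Lh", "Na", "La",
    "kappa", "Ks", "Ka", "Kh", "Ka_Ks", "Kh_Ks", "p_Ka_Ks", "p_Kh_Ks",
    "n_nonelementary", "filtered", "filter_reason", "is_psg",
]
_FLOAT_COLUMNS = ["Ns", "Ls", "Nh", "Lh", "Na", "La", "kappa",
                  "Ks", "Ka", "Kh", "Ka_Ks", "Kh_Ks", "p_Ka_Ks", "p_Kh_Ks"]


@dataclass
class CodonAlignment:
    """A validated pairwise, in-frame codon alignment."""

    gene_id: str
    seq_a: str
    seq_b: str
    species_a: str = "a"
    species_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"gene {self.gene_id}: sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})")
        if len(self.seq_a) % 3:
            raise ValueError(
                f"gene {self.gene_id}: alignment length {len(self.seq_a)} "
                f"is not a multiple of 3")
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()

    @property
    def n_columns(self) -> int:
        return len(self.seq_a) // 3

    def iter_codons(self) -> Iterator[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]

    @staticmethod
    def is_skippable(codon_a: str, codon_b: str) -> bool:
        """True when either codon contains a gap or ambiguity character.

        Such columns are wholly excluded from both substitution and site
        counting, keeping N and L consistent.
        """
        chars = set(codon_a) | set(codon_b)
        return bool(chars & GAP_CHARS) or bool(chars & AMBIGUOUS)

    def validate_gaps(self, strict: bool = False) -> None:
        """Optionally reject gap runs whose length is not a multiple of 3."""
        if not strict:
            return
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            run = 0
            for pos, ch in enumerate(seq + "X"):
                if ch in GAP_CHARS:
                    run += 1
                elif run:
                    if run % 3:
                        raise ValueError(
                            f"gene {self.gene_id}: {name} gap run of length {run} "
                            f"ending at position {pos} is not codon-aligned")
                    run = 0


def read_codon_alignment(
    path: str | Path,
    gene_id: str | None = None,
    strict_gaps: bool = False,
) -> CodonAlignment:
    """Read a 2-record aligned FASTA into a :class:`CodonAlignment`.

    Record ids become the species labels; ``gene_id`` defaults to the file
    stem.  Rejects files with a record count other than 2, unequal lengths,
    or lengths not divisible by 3.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    aln = CodonAlignment(
        gene_id=gene_id or path.stem,
        seq_a=str(records[0].seq),
        seq_b=str(records[1].seq),
        species_a=records[0].id,
        species_b=records[1].id,
    )
    aln.validate_gaps(strict=strict_gaps)
    return aln


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Read a ``gene_id <TAB> path`` manifest; relative paths resolve against it."""
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].strip().lower() == "gene_id":
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene_id\\tpath'")
            p = Path(fields[1])
            if not p.is_absolute():
                p = path.parent / p
            entries.append((fields[0], p))
    return entries


def iter_alignments(
    source: str | Path,
    strict_gaps: bool = False,
) -> Iterator[CodonAlignment]:
    """Yield alignments from a directory of FASTA files or a manifest TSV."""
    source = Path(source)
    if source.is_dir():
        paths = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in {".fa", ".fasta", ".fna"})
        for p in paths:
            yield read_codon_alignment(p, strict_gaps=strict_gaps)
    else:
        for gene_id, p in read_manifest(source):
            yield read_codon_alignment(p, gene_id=gene_id, strict_gaps=strict_gaps)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if isinstance(value, (int,)):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_results(table: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a per-gene result table as TSV, floats at 6 significant digits.

    Undefined values (None/NaN) are written as ``NA``; booleans as
    ``true``/``false``.  An optional ``#`` comment header carries the run
    manifest reference.
    """
    if table.empty:
        raise ValueError("result table is empty")
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in table.iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], keep_default_na=False)
    for col in ("filtered", "is_psg"):
        if df[col].dtype != bool:  # pandas may already parse true/false
            df[col] = df[col].map({"true": True, "false": False})
    df["filter_reason"] = df["filter_reason"].replace("", None)
    df["filter_reason"] = df["filter_reason"].where(df["filter_reason"].notna(), None)
    for col in _FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_counts(counts_by_gene: dict, n_classes: int, path: str | Path,
                 comment: str | None = None) -> None:
    """Write raw per-gene N/L counts (needed to pool supergenes later).

    Columns: gene_id, Ns, Ls, then Ni_1..Ni_k and Li_1..Li_k by class rank.
    """
    path = Path(path)
    ranks = list(range(1, n_classes + 1))
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        header = (["gene_id", "Ns", "Ls", "n_nonelementary", "n_codons_used"]
                  + [f"Ni_{r}" for r in ranks] + [f"Li_{r}" for r in ranks])
        fh.write("\t".join(header) + "\n")
        for gene_id, c in counts_by_gene.items():
            row = [gene_id, f"{float(c.ns):.10g}", f"{float(c.ls):.10g}",
                   str(c.n_nonelementary), str(c.n_codons_used)]
            row += [f"{float(c.ni.get(r, 0)):.10g}" for r in ranks]
            row += [f"{float(c.li.get(r, 0)):.10g}" for r in ranks]
            fh.write("\t".join(row) + "\n")


def read_counts(path: str | Path) -> dict:
    """Read a counts TSV back into per-gene :class:`SubstitutionCounts`."""
    from fractions import Fraction

    from .counting import SubstitutionCounts

    df = pd.read_csv(path, sep="\t", comment="#")
    ranks = sorted(int(c.split("_", 1)[1]) for c in df.columns if c.startswith("Ni_"))
    out: dict[str, SubstitutionCounts] = {}
    for _, row in df.iterrows():
        c = SubstitutionCounts(
            ns=Fraction(str(row["Ns"])),
            ls=Fraction(str(row["Ls"])),
            n_nonelementary=int(row["n_nonelementary"]),
            n_codons_used=int(row["n_codons_used"]),
        )
        for r in ranks:
            ni = Fraction(str(row[f"Ni_{r}"]))
            li = Fraction(str(row[f"Li_{r}"]))
            if ni:
                c.ni[r] = ni
            if li:
                c.li[r] = li
        out[str(row["gene_id"])] = c
    return out
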