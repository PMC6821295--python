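"""Recoding of proteins/CDS into a target code, and codon-usage tables.

Fail-safe codes designate a single sense codon per amino acid, so recoding
a protein is deterministic: each residue maps to its designated codon and
the CDS ends with the code's designated stop.  For target codes with
degenerate blocks (e.g. recoding back into the Standard Code) a codon-
choice rule applies: the most frequent codon of the block in a supplied
usage table, falling back to the first in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import GeneticCode, all_codons

__all__ = [
    "CodonUsage",
    "recode_protein",
    "recode_cds",
    "codon_usage",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class CodonUsage:
    """Codon counts over a CDS collection, with derived frequencies."""

    counts: dict[str, int]
    codon_length: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {c: 0.0 for c in self.counts}
        return {c: k / tot for c, k in self.counts.items()}

    @property
    def distinct_codons_used(self) -> int:
        return sum(1 for k in self.counts.values() if k > 0)

    def to_tsv(self, path: str | Path | None = None) -> str:
        freqs = self.frequencies
        lines = ["codon\tcount\tfrequency"]
        for codon in all_codons(self.codon_length):
            lines.append(f"{codon}\t{self.counts[codon]}\t{freqs[codon]:.6g}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def __add__(self, other: "CodonUsage") -> "CodonUsage":
        if self.codon_length != other.codon_length:
            raise ValueError("codon lengths differ")
        return CodonUsage(
            {c: self.counts[c] + other.counts[c] for c in self.counts},
            self.codon_length,
        )


def _designated_codon(
    code: GeneticCode, amino_acid: str, usage: CodonUsage | None
) -> str:
    block = code.codons_for(amino_acid)
    if not block:
        raise ValueError(
            f"amino acid {amino_acid} is not encoded by code {code.name!r}"
        )
    if len(block) == 1 or usage is None:
        return block[0]
    return max(block, key=lambda c: (usage.counts.get(c, 0), -block.index(c)))


def recode_protein(
    protein: str,
    target_code: GeneticCode,
    usage: CodonUsage | None = None,
    stop_codon: str | None = None,
) -> str:
    """Encode a protein into ``target_code``'s designated codons plus a stop."""
    stops = target_code.stop_codons
    if not stops:
        raise ValueError(f"code {target_code.name!r} has no stop codon")
    stop = stop_codon if stop_codon is not None else stops[0]
    if stop not in stops:
        raise ValueError(f"{stop} is not a stop codon of {target_code.name!r}")
    out = []
    for aa in protein.strip().upper():
        out.append(_designated_codon(target_code, aa, usage))
    out.append(stop)
    return "".join(out)


def recode_cds(
    cds_or_protein: str,
    target_code: GeneticCode,
    source_code: GeneticCode | None = None,
    usage: CodonUsage | None = None,
) -> str:
    """Recode a CDS (translated under ``source_code``) or a raw protein.

    The result translates under ``target_code`` to the same protein and
    uses only the target's designated sense codons plus one stop.
    """
    seq = cds_or_protein.strip().upper()
    if source_code is not None:
        protein = source_code.translate(seq)
    else:
        protein = seq
    return recode_protein(protein, target_code, usage)


def codon_usage(cds_set: Iterable[str], k: int = 3) -> CodonUsage:
    """Tabulate codon counts over a collection of coding sequences."""
    counts = dict.fromkeys(all_codons(k), 0)
    for cds in cds_set:
        seq = cds.strip().upper().replace("T", "U")
        if len(seq) % k:
            raise ValueError(
                f"CDS length {len(seq)} is not a multiple of codon length {k}"
            )
        for i in range(0, len(seq), k):
            counts[seq[i : i + k]] += 1
    return CodonUsage(counts, k)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (description, sequence) pairs."""
    return [
        (rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (description, sequence) pairs as wrapped FASTA."""
    seqrecs = []
    for desc, seq in records:
        name = desc.split()[0] if desc else "seq"
        seqrecs.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")
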