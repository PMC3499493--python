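"""Sequence I/O and quality control for COI barcode records.

Barcode records travel as FASTA with headers of the form
``accession|Genus species`` (underscores in the species name are accepted
and normalized to spaces).  Quality control mirrors standard barcode
screening: an ungapped-length floor (the usual NUMT proxy for the ~655 bp
COI amplicon) and a stop-codon check under the vertebrate mitochondrial
genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "BarcodeRecord",
    "AlignedSet",
    "QcReport",
    "FastaHeaderError",
    "read_fasta",
    "write_fasta",
    "qc_filter",
    "translate_ok",
    "consensus_sequence",
]

GAP_CHARS = frozenset("-.")

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

# IUPAC nucleotide ambiguity codes, keyed by the set of bases they cover.
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("AC"): "M", frozenset("GT"): "K",
    frozenset("AT"): "W", frozenset("CG"): "S",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


class FastaHeaderError(ValueError):
    """Raised for a FASTA header that does not follow ``accession|Genus species``."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One labeled barcode sequence.

    ``species`` is the full binomial ("Genus species"); ``genus`` is derived
    from its first token.  ``provenance`` distinguishes sequences generated
    by the study at hand ("novel") from public-database records ("database").
    """

    accession: str
    species: str
    sequence: str
    provenance: str = "novel"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.species.split()) < 2:
            raise ValueError(
                f"species {self.species!r} must be a binomial (>=2 tokens)"
            )
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if self.provenance not in ("novel", "database"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in GAP_CHARS)


@dataclass(frozen=True)
class AlignedSet:
    """An ordered collection of records sharing one alignment length."""

    records: Tuple[BarcodeRecord, ...]
    aligned_length: int

    @classmethod
    def from_records(cls, records: Iterable[BarcodeRecord]) -> "AlignedSet":
        recs = tuple(records)
        if not recs:
            raise ValueError("an aligned set needs at least one record")
        length = len(recs[0].sequence)
        for r in recs:
            if len(r.sequence) != length:
                raise ValueError(
                    f"{r.accession}: length {len(r.sequence)} != {length}; "
                    "sequences must be pre-aligned"
                )
        return cls(records=recs, aligned_length=length)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, accessions: Iterable[str]) -> "AlignedSet":
        keep = set(accessions)
        return AlignedSet.from_records(
            r for r in self.records if r.accession in keep
        )


@dataclass
class QcReport:
    """Outcome of quality-control filtering.

    ``kept`` holds accessions that passed; ``rejected`` maps accession to a
    reason in {"empty", "too_short", "internal_stop"}.  Together they cover
    the input exactly once.
    """

    kept: List[str] = field(default_factory=list)
    rejected: Dict[str, str] = field(default_factory=dict)


def _parse_header(header: str) -> Tuple[str, str]:
    if "|" not in header:
        raise FastaHeaderError(
            f"header {header!r} lacks the 'accession|Genus species' pipe"
        )
    accession, _, label = header.partition("|")
    accession = accession.strip()
    species = " ".join(label.replace("_", " ").split())
    if not accession:
        raise FastaHeaderError(f"header {header!r} has an empty accession")
    if len(species.split()) < 2:
        raise FastaHeaderError(
            f"header {header!r} has no binomial species name after the pipe"
        )
    return accession, species


def read_fasta(path, provenance: str = "novel") -> List[BarcodeRecord]:
    """Read barcode records from FASTA, parsing ``accession|Genus species`` headers.

    Entry order is preserved and sequences are uppercased.  Malformed headers
    and duplicate accessions raise :class:`FastaHeaderError` / ``ValueError``
    naming the offender.
    """
    records: List[BarcodeRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, species = _parse_header(entry.description)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(
            BarcodeRecord(
                accession=accession,
                species=species,
                sequence=str(entry.seq).upper(),
                provenance=provenance,
            )
        )
    return records


def write_fasta(records: Iterable[BarcodeRecord], path, width: int = 70) -> None:
    """Write records as FASTA with ``accession|Genus species`` headers.

    Round-trips losslessly through :func:`read_fasta` on
    (accession, species, sequence).
    """
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(f">{r.accession}|{r.species}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def translate_ok(sequence: str) -> bool:
    """True iff some forward reading frame has no internal mitochondrial stop.

    The check uses the vertebrate mitochondrial code (stops TAA, TAG, AGA,
    AGG).  Gaps are removed first; codons containing ambiguity codes
    translate to unknown and never count as stops.  A stop in the final
    complete codon of a frame is terminal, not internal.  Barcode amplicons
    have primer-fixed orientation, so reverse frames are not examined.
    """
    seq = "".join(c for c in sequence.upper() if c not in GAP_CHARS)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon after gap removal")
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        if not any(c in MITO_STOPS for c in codons[:-1]):
            return True
    return False


def qc_filter(
    records: Sequence[BarcodeRecord], min_length: int = 600
) -> QcReport:
    """Apply the barcode quality filters and report the outcome per record.

    A record is kept when its ungapped length strictly exceeds ``min_length``
    and at least one forward frame is free of internal stop codons.  All
    failures land in the report; nothing raises.  Filtering a kept set again
    changes nothing (idempotence).
    """
    report = QcReport()
    for r in records:
        n = r.ungapped_length
        if n == 0:
            report.rejected[r.accession] = "empty"
        elif n <= min_length:
            report.rejected[r.accession] = "too_short"
        elif not translate_ok(r.sequence):
            report.rejected[r.accession] = "internal_stop"
        else:
            report.kept.append(r.accession)
    return report


def consensus_sequence(records: Sequence[BarcodeRecord]) -> str:
    """Strict-majority consensus of one species' aligned records.

    Per column, the unique plurality base among {A,C,G,T} wins; ties emit
    the IUPAC code covering the tied bases.  Columns with no unambiguous
    base emit '-' when fully gapped, otherwise 'N'.
    """
    if not records:
        raise ValueError("consensus of an empty record set is undefined")
    species = {r.species for r in records}
    if len(species) > 1:
        raise ValueError(f"mixed species input: {sorted(species)}")
    aligned = AlignedSet.from_records(records)
    out = []
    for col in zip(*(r.sequence for r in aligned)):
        counts = {b: 0 for b in "ACGT"}
        for c in col:
            if c in counts:
                counts[c] += 1
        top = max(counts.values())
        if top == 0:
            out.append("-" if all(c in GAP_CHARS for c in col) else "N")
            continue
        winners = frozenset(b for b, k in counts.items() if k == top)
        out.append(_IUPAC[winners])
    return "".join(out)
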