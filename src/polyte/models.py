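"""Core domain types shared across the pipeline.

The central object is :class:`TranscriptModel`: one mature mRNA stored 5'→3'
as an RNA string together with the coordinates of its main coding sequence.
Everything upstream of ``cds_start`` is the 5'UTR, everything from ``cds_end``
on is the 3'UTR.  Coordinates are 0-based half-open throughout the package;
GFF3 export converts to 1-based inclusive at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
START_CODON = "AUG"


def as_rna(sequence: str) -> str:
    """Uppercase a nucleotide string and transcribe DNA T to RNA U."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: RNA sequence plus main-ORF coordinates.

    Parameters
    ----------
    transcript_id : str
        Unique transcript identifier.
    sequence : str
        Nucleotide sequence 5'→3'.  DNA input (T) is accepted and is
        transcribed to U on construction.
    cds_start : int
        0-based inclusive position of the A of the main-ORF AUG.
    cds_end : int
        0-based exclusive end of the main ORF (one past the stop codon).
    gene_id : str
        Parent gene identifier (defaults to the transcript id).
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    gene_id: str = ""

    def __post_init__(self) -> None:
        seq = as_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not self.gene_id:
            object.__setattr__(self, "gene_id", self.transcript_id)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-ACGU characters in sequence: {sorted(bad)}"
            )
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        if seq[self.cds_start : self.cds_start + 3] != START_CODON:
            raise ValueError(
                f"{self.transcript_id}: CDS does not start with AUG "
                f"(found {seq[self.cds_start:self.cds_start + 3]!r})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def regions(self) -> dict[str, tuple[int, int]]:
        """Canonical non-overlapping partition: 5'UTR / CDS / 3'UTR."""
        return {
            "five_prime_UTR": (0, self.cds_start),
            "CDS": (self.cds_start, self.cds_end),
            "three_prime_UTR": (self.cds_end, len(self.sequence)),
        }
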