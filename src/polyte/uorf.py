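"""Upstream ORF discovery, start-codon mutagenesis, frameshift translation.

A uORF is any open reading frame whose AUG lies in the 5'UTR, upstream of the
main start codon.  uORFs that terminate before the main AUG are
``contained_in_utr``; those whose first in-frame stop lies at or beyond the
main AUG overlap the CDS, either in the same reading frame
(``overlapping_in_frame``) or, more interestingly for translational control,
in a different one (``overlapping_out_of_frame``) — the configuration in
which a scanning ribosome that initiates at the uORF terminates inside the
main ORF without producing the main protein.

Only AUG starts are scanned by default.  Near-cognate starts (CUG/GUG/UUG)
can be enabled with ``start_codons`` for sensitivity analyses; no minimum
uORF length is imposed (an AUG immediately followed by a stop counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .models import START_CODON, STOP_CODONS, TranscriptModel, as_rna

_STANDARD_TABLE = CodonTable.unambiguous_rna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

CONTAINED = "contained_in_utr"
OVERLAP_OUT_OF_FRAME = "overlapping_out_of_frame"
OVERLAP_IN_FRAME = "overlapping_in_frame"


@dataclass(frozen=True)
class UORF:
    """One upstream ORF.

    ``stop_end`` is the 0-based exclusive end of the stop codon, or ``None``
    when no in-frame stop occurs before the transcript end.  ``n_codons``
    includes the stop codon when present, otherwise counts the complete
    codons available.  ``frame_vs_cds`` is ``(start - cds_start) mod 3``:
    0 means the uORF reads in the main-ORF frame.
    """

    transcript_id: str
    start: int
    stop_end: int | None
    n_codons: int
    frame_vs_cds: int
    overlap_class: str


@dataclass(frozen=True)
class TranslationOutcome:
    """Result of naive 5'→3' triplet translation from position 0.

    ``premature_stop_codon_index`` is the 1-based codon index of the first
    stop, or ``None`` if no stop occurs within the sequence.
    """

    protein: str
    premature_stop_codon_index: int | None


def _walk_orf(sequence: str, start: int) -> tuple[int | None, int]:
    """Walk triplets from ``start`` to the first stop codon.

    Returns ``(stop_end, n_codons)`` with ``stop_end`` None if the sequence
    ends before an in-frame stop; ``n_codons`` then counts complete codons.
    """
    pos = start
    n = 0
    while pos + 3 <= len(sequence):
        n += 1
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos + 3, n
        pos += 3
    return None, n


def find_uorfs(
    t: TranscriptModel, start_codons: Sequence[str] = (START_CODON,)
) -> list[UORF]:
    """Discover every uORF initiating in the 5'UTR of ``t``.

    One UORF is emitted per start codon whose first base lies in
    ``[0, cds_start)``.  Extension proceeds in triplets past ``cds_start``
    if needed, until the first in-frame stop or the transcript end.
    Results are sorted by start position.
    """
    seq = t.sequence
    out: list[UORF] = []
    starts = {as_rna(c) for c in start_codons}
    for i in range(t.cds_start):
        if seq[i : i + 3] not in starts:
            continue
        stop_end, n_codons = _walk_orf(seq, i)
        frame = (i - t.cds_start) % 3
        if stop_end is not None and stop_end <= t.cds_start:
            klass = CONTAINED
        elif frame != 0:
            klass = OVERLAP_OUT_OF_FRAME
        else:
            klass = OVERLAP_IN_FRAME
        out.append(
            UORF(
                transcript_id=t.transcript_id,
                start=i,
                stop_end=stop_end,
                n_codons=n_codons,
                frame_vs_cds=frame,
                overlap_class=klass,
            )
        )
    return out


def mutate_start_codon(
    t: TranscriptModel, uorf: UORF, replacement: str = "UAA"
) -> TranscriptModel:
    """Replace a uORF's AUG with ``replacement`` (default UAA).

    Returns a new :class:`TranscriptModel`; CDS coordinates are unchanged.
    The edit window is checked for newly created AUG trigrams — any
    replacement whose trailing A abuts a downstream UG (even UAA) would
    silently introduce a new uORF start — and raises ``ValueError`` instead.
    """
    replacement = as_rna(replacement)
    if len(replacement) != 3:
        raise ValueError(f"replacement must be a codon, got {replacement!r}")
    if t.sequence[uorf.start : uorf.start + 3] != START_CODON:
        raise ValueError(
            f"{t.transcript_id}: position {uorf.start} is not an AUG "
            f"(found {t.sequence[uorf.start:uorf.start + 3]!r})"
        )
    seq = t.sequence[: uorf.start] + replacement + t.sequence[uorf.start + 3 :]
    # any AUG trigram overlapping the edited window would be a new uORF start
    lo = max(0, uorf.start - 2)
    hi = min(len(seq) - 3, uorf.start + 2)
    for i in range(lo, hi + 1):
        if seq[i : i + 3] == START_CODON:
            raise ValueError(
                f"replacement {replacement!r} creates a new AUG at {i}"
            )
    return TranscriptModel(
        transcript_id=t.transcript_id,
        sequence=seq,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
        gene_id=t.gene_id,
    )


def translate(rna: str) -> TranslationOutcome:
    """Translate from position 0 in triplets until the first stop or the end."""
    rna = as_rna(rna)
    protein = []
    codon_index = 0
    for pos in range(0, len(rna) - 2, 3):
        codon = rna[pos : pos + 3]
        codon_index += 1
        if codon in STOP_CODONS:
            return TranslationOutcome("".join(protein), codon_index)
        protein.append(GENETIC_CODE[codon])
    return TranslationOutcome("".join(protein), None)


def apply_indel_and_translate(
    cds: str, pos: int, del_len: int
) -> TranslationOutcome:
    """Delete ``del_len`` bases at ``pos`` from a CDS and translate the result.

    Models a CRISPR-style small deletion: a deletion whose length is not a
    multiple of 3 shifts the reading frame downstream of ``pos`` and
    typically creates a premature stop codon, truncating the protein.

    Raises ``ValueError`` if the CDS does not start with AUG, the deletion
    falls outside the sequence, or the deletion removes initiator-AUG bases.
    """
    cds = as_rna(cds)
    if cds[:3] != START_CODON:
        raise ValueError(f"CDS does not start with AUG (found {cds[:3]!r})")
    if not (0 <= pos and pos + del_len <= len(cds)):
        raise ValueError(
            f"deletion [{pos}, {pos + del_len}) outside CDS of length {len(cds)}"
        )
    if del_len < 0:
        raise ValueError("del_len must be >= 0")
    if del_len > 0 and pos < 3:
        raise ValueError("deletion removes initiator AUG bases")
    return translate(cds[:pos] + cds[pos + del_len :])
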