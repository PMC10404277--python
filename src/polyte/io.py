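"""Readers and writers for the pipeline's file contracts.

Formats: FASTA (transcripts, via Biopython), GFF3 (1-based inclusive) plus
a BED-like TSV mirror (0-based half-open) for region annotations, TSV count
matrices with a library-design table, TSV spike-in references, TSV RPF
records with optional SAM import/export (transcript-space, via pysam), and
TSV luciferase well tables.

Writers accept an optional ``header`` string that is emitted as ``# ...``
comment lines; readers skip comments.  No timestamps are written anywhere,
so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import TranscriptModel, as_rna
from .normalize import CountMatrix


def _comment_lines(header: str | None) -> str:
    if not header:
        return ""
    return "".join(f"# {line}\n" for line in header.splitlines())


def _write_tsv(df: pd.DataFrame, path, header: str | None, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_lines(header))
        df.to_csv(fh, sep="\t", index=index)


# --------------------------------------------------------------------------
# transcripts and annotations


def write_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=f"gene={t.gene_id}")
        for t in transcripts
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Transcript id → RNA sequence (DNA T transcribed to U on read)."""
    return {
        rec.id: as_rna(str(rec.seq)) for rec in SeqIO.parse(os.fspath(path), "fasta")
    }


def read_transcripts(fasta_path, annotation_path) -> list[TranscriptModel]:
    """Assemble TranscriptModels from a FASTA plus a region annotation table."""
    seqs = read_fasta(fasta_path)
    ann = read_regions_tsv(annotation_path)
    out = []
    for tx_id, seq in seqs.items():
        cds = ann[(ann["transcript_id"] == tx_id) & (ann["feature"] == "CDS")]
        if len(cds) != 1:
            raise ValueError(f"{tx_id}: expected exactly one CDS annotation")
        out.append(
            TranscriptModel(
                tx_id, seq, int(cds["start0"].iloc[0]), int(cds["end0"].iloc[0])
            )
        )
    return out


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(annotations: pd.DataFrame, path, source: str = "polyte") -> None:
    """Write region annotations as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotations.iterrows():
            attrs = f"ID={row['transcript_id']}:{row['name']}"
            fh.write(
                "\t".join(
                    [
                        row["transcript_id"],
                        source,
                        row["feature"],
                        str(int(row["start0"]) + 1),
                        str(int(row["end0"])),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 back into the internal 0-based half-open table."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, dtype={"start": int, "end": int}
    )
    name = df["attributes"].str.split(":", n=1).str[1].fillna(df["type"])
    return pd.DataFrame(
        {
            "transcript_id": df["seqid"],
            "feature": df["type"],
            "start0": df["start"] - 1,
            "end0": df["end"],
            "name": name,
        }
    )


def write_regions_tsv(annotations: pd.DataFrame, path, header: str | None = None) -> None:
    """BED-like TSV mirror of the annotation table (0-based half-open)."""
    _write_tsv(annotations, path, header, index=False)


def read_regions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --------------------------------------------------------------------------
# count matrices


def write_count_matrix(cm: CountMatrix, path, header: str | None = None) -> None:
    df = cm.counts.copy()
    df.insert(0, "is_spikein", cm.is_spikein.astype(int))
    df.index.name = "id"
    _write_tsv(df, path, header, index=True)


def read_count_matrix(path) -> CountMatrix:
    """Read a count matrix TSV, validating that every cell is a count.

    A non-integer or negative cell raises ``ValueError`` naming the file,
    row id and library column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col="id")
    if "is_spikein" not in df.columns:
        raise ValueError(f"{path}: missing is_spikein column")
    flags = df.pop("is_spikein").astype(bool)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-integer count at row {row!r}, column {col!r} "
                f"(value {df.loc[row, col]!r})"
            )
        df[col] = numeric.astype("int64")
    return CountMatrix(df, flags)


def write_matrix_tsv(df: pd.DataFrame, path, header: str | None = None) -> None:
    """Plain real-valued matrix (e.g. normalized counts), id-indexed."""
    out = df.copy()
    out.index.name = "id"
    _write_tsv(out, path, header, index=True)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="id")


def write_library_design(design: pd.DataFrame, path, header: str | None = None) -> None:
    _write_tsv(design, path, header, index=False)


def read_library_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_spikein_reference(ref: pd.Series, path, header: str | None = None) -> None:
    _write_tsv(ref.rename("input_amount").rename_axis("spike_id").reset_index(), path, header, index=False)


def read_spikein_reference(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    ref = df.set_index("spike_id")["input_amount"].astype(float)
    if (ref <= 0).any():
        raise ValueError(f"{path}: spike-in amounts must be positive")
    return ref


def write_size_factors(factors: pd.Series, path, header: str | None = None) -> None:
    _write_tsv(
        factors.rename("size_factor").rename_axis("library_id").reset_index(),
        path, header, index=False,
    )


# --------------------------------------------------------------------------
# RPF records


def write_rpf_tsv(reads: pd.DataFrame, path, header: str | None = None) -> None:
    _write_tsv(reads[["transcript_id", "start", "length"]], path, header, index=False)


def read_rpf_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df[["transcript_id", "start", "length"]].astype(
        {"start": "int64", "length": "int64"}
    )


def write_rpf_sam(
    reads: pd.DataFrame, transcripts: Sequence[TranscriptModel], path
) -> None:
    """Export RPF records as transcript-space SAM alignments."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": t.transcript_id, "LN": len(t.sequence)} for t in transcripts
        ],
    }
    seqs = {t.transcript_id: t.sequence.replace("U", "T") for t in transcripts}
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"rpf{i:07d}"
            a.reference_name = row.transcript_id
            a.reference_start = int(row.start)
            a.cigarstring = f"{int(row.length)}M"
            a.query_sequence = seqs[row.transcript_id][
                int(row.start) : int(row.start) + int(row.length)
            ]
            a.mapping_quality = 255
            a.flag = 0
            out.write(a)


def read_rpf_sam(path) -> pd.DataFrame:
    """Import transcript-space SAM/BAM alignments as RPF records."""
    rows = {"transcript_id": [], "start": [], "length": []}
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            rows["transcript_id"].append(rec.reference_name)
            rows["start"].append(rec.reference_start)
            rows["length"].append(rec.reference_length)
    return pd.DataFrame(rows).astype({"start": "int64", "length": "int64"})


# --------------------------------------------------------------------------
# luciferase tables


def read_luciferase(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df[["construct_id", "replicate", "renilla", "firefly"]]


def write_luciferase(df: pd.DataFrame, path, header: str | None = None) -> None:
    _write_tsv(df, path, header, index=False)
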