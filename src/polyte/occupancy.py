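"""Relative ribosome-occupancy profiles from ribosome-protected fragments.

Ribo-seq footprints (RPFs) arrive as transcript-space alignment records
``(transcript_id, start, length)``.  After the standard 28–32 nt size
selection, per-base raw density is accumulated by full-footprint coverage
counting (every base under a footprint gets +1) and normalized so the
profile over the transcript sums to 1 — the relative ribosome occupancy.
Summing the profile over annotated intervals (uORFs, CDS, UTRs) yields
region occupancy proportions that can be compared between genotypes.

A 5'-end counting mode (`how="five_prime"`) is available for sensitivity
analysis; coverage counting is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .models import TranscriptModel

RPF_COLUMNS = ("transcript_id", "start", "length")

#: default footprint size-selection window, inclusive on both ends
RPF_MIN_LEN = 28
RPF_MAX_LEN = 32


def validate_rpf(reads: pd.DataFrame) -> pd.DataFrame:
    """Check an RPF record table for the required columns and sane values."""
    missing = set(RPF_COLUMNS) - set(reads.columns)
    if missing:
        raise ValueError(f"RPF table missing columns: {sorted(missing)}")
    if len(reads) and ((reads["start"] < 0).any() or (reads["length"] < 1).any()):
        raise ValueError("RPF records must have start >= 0 and length >= 1")
    return reads


def filter_rpf_by_length(
    reads: pd.DataFrame, min_len: int = RPF_MIN_LEN, max_len: int = RPF_MAX_LEN
) -> pd.DataFrame:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive both ends)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    validate_rpf(reads)
    keep = (reads["length"] >= min_len) & (reads["length"] <= max_len)
    return reads.loc[keep].reset_index(drop=True)


@dataclass
class OccupancyProfile:
    """Per-base relative ribosome occupancy on one transcript.

    ``density`` has one entry per base and sums to 1 when any read is
    present; a zero-read input yields an all-zero profile with
    ``is_empty=True``, which comparison utilities exclude rather than
    propagate as NaN.
    """

    transcript_id: str
    density: np.ndarray
    is_empty: bool = False


def occupancy_profile(
    reads: pd.DataFrame, t: TranscriptModel, how: str = "coverage"
) -> OccupancyProfile:
    """Build the relative-occupancy profile of ``t`` from its RPF records.

    Raw density at base b is the number of footprints covering b
    (``how="coverage"``) or the number of footprints starting at b
    (``how="five_prime"``); the profile is raw density divided by its sum.
    """
    if how not in ("coverage", "five_prime"):
        raise ValueError(f"unknown counting mode {how!r}")
    validate_rpf(reads)
    n = len(t.sequence)
    mine = reads.loc[reads["transcript_id"] == t.transcript_id]
    if len(mine) == 0:
        return OccupancyProfile(t.transcript_id, np.zeros(n), is_empty=True)
    starts = mine["start"].to_numpy(dtype=np.int64)
    lengths = mine["length"].to_numpy(dtype=np.int64)
    if (starts < 0).any() or (starts + lengths > n).any():
        raise ValueError(
            f"{t.transcript_id}: RPF record out of transcript bounds (len {n})"
        )
    if how == "coverage":
        # difference-array coverage: +1 at start, -1 past the footprint end
        delta = np.zeros(n + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, starts + lengths, -1.0)
        raw = np.cumsum(delta[:-1])
    else:
        raw = np.zeros(n)
        np.add.at(raw, starts, 1.0)
    return OccupancyProfile(t.transcript_id, raw / raw.sum())


def region_occupancy(
    p: OccupancyProfile, regions: Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """Sum profile density over labeled half-open intervals.

    Overlapping regions (e.g. an out-of-frame uORF extending into the CDS
    versus the CDS itself) are each summed independently and may
    double-count shared bases; proportions over a non-overlapping partition
    of the transcript sum to 1.
    """
    n = len(p.density)
    out: dict[str, float] = {}
    for label, (start, end) in regions.items():
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"region {label!r} [{start}, {end}) outside transcript of length {n}"
            )
        if start == end:
            warnings.warn(f"region {label!r} is empty; proportion set to 0")
            out[label] = 0.0
        else:
            out[label] = float(p.density[start:end].sum())
    return out


def compare_occupancy(
    a: Mapping[str, float], b: Mapping[str, float], eps: float = 1e-6
) -> pd.DataFrame:
    """Per-region occupancy difference and log2 ratio between two conditions.

    Returns a DataFrame indexed by region with columns ``diff`` (a - b) and
    ``log2_ratio`` (log2((a+eps)/(b+eps)), the pseudo-proportion eps guarding
    empty regions).
    """
    if set(a) != set(b):
        raise ValueError(
            f"region label mismatch: {sorted(set(a) ^ set(b))}"
        )
    labels = list(a)
    av = np.array([a[l] for l in labels], dtype=float)
    bv = np.array([b[l] for l in labels], dtype=float)
    return pd.DataFrame(
        {"diff": av - bv, "log2_ratio": np.log2((av + eps) / (bv + eps))},
        index=pd.Index(labels, name="region"),
    )
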