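"""Spike-in size factors and count normalization.

Synthetic spike-in RNAs (ERCC-style) are added in equal known amounts to
every RNA sample before library construction, so after sequencing the ratio
count/input_amount for a spike-in species estimates the library's capture ×
depth scale.  The per-library size factor is the median of those ratios
across species (robust to individual dropouts), rescaled so the geometric
mean over libraries is 1; dividing counts by the factors puts all libraries
on a common absolute scale — the property that makes between-fraction TE
ratios meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("control", "mutant")
FRACTIONS = ("total", "monosome", "polysome")


@dataclass
class CountMatrix:
    """Gene/spike × library count matrix with a per-row spike-in flag.

    ``counts`` is a DataFrame (rows: gene or spike ids, columns: library
    ids).  Values are non-negative; integer for raw counts, real after
    normalization.
    """

    counts: pd.DataFrame
    is_spikein: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate row ids in count matrix")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate library ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative values in count matrix")
        self.is_spikein = self.is_spikein.reindex(self.counts.index)
        if self.is_spikein.isna().any():
            raise ValueError("is_spikein flag missing for some rows")
        self.is_spikein = self.is_spikein.astype(bool)

    @property
    def genes(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spikein]

    @property
    def spikes(self) -> pd.DataFrame:
        return self.counts.loc[self.is_spikein]


def validate_library_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a library design table (library_id, genotype, fraction, replicate)."""
    required = {"library_id", "genotype", "fraction", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"library design missing columns: {sorted(missing)}")
    if design["library_id"].duplicated().any():
        raise ValueError("duplicate library_id in design")
    key = design[["genotype", "fraction", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (genotype, fraction, replicate) in design")
    return design


def libraries_for(design: pd.DataFrame, genotype: str, fraction: str) -> list[str]:
    """Library ids for one genotype × fraction cell, ordered by replicate."""
    sub = design[(design["genotype"] == genotype) & (design["fraction"] == fraction)]
    return list(sub.sort_values("replicate")["library_id"])


def compute_size_factors(
    counts: CountMatrix | pd.DataFrame,
    ref: pd.Series,
    min_count: int = 5,
) -> pd.Series:
    """Median-of-ratios size factors from spike-in counts.

    For each library j, ``factor_j = median_i(count_ij / input_amount_i)``
    over the spike-in species i that reach ``min_count`` in every library
    (a common species set, so the median is over the same ratios
    everywhere); factors are then rescaled to geometric mean 1.

    Parameters
    ----------
    counts : CountMatrix or DataFrame
        A CountMatrix (its spike rows are used) or a DataFrame of spike-in
        counts only.
    ref : Series
        Known input amount per spike id.  Spikes absent from ``ref`` are
        ignored.
    min_count : int
        Ratio-stability guard: species below this count in any library are
        excluded.  A library in which fewer than 3 species pass raises an
        error naming the library.
    """
    spikes = counts.spikes if isinstance(counts, CountMatrix) else counts
    ref = ref.astype(float)
    if (ref <= 0).any():
        raise ValueError("spike-in input amounts must be positive")
    common = spikes.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("no spike-in rows match the reference")
    spikes = spikes.loc[common]
    passing = spikes >= min_count
    for lib in spikes.columns:
        if passing[lib].sum() < 3:
            raise ValueError(
                f"library {lib!r}: fewer than 3 spike-ins reach min_count={min_count}"
            )
    keep = passing.all(axis=1)
    if keep.sum() < 3:
        raise ValueError(
            f"fewer than 3 spike-ins reach min_count={min_count} in every library"
        )
    ratios = spikes.loc[keep].div(ref.loc[keep], axis=0)
    factors = ratios.median(axis=0)
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean -> 1
    factors.name = "size_factor"
    return factors


def normalize_counts(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> CountMatrix | pd.DataFrame:
    """Divide every library's counts by its size factor.

    Spike-in rows are retained (still flagged) when a CountMatrix is given.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = set(df.columns) - set(factors.index)
    if missing:
        raise ValueError(f"no size factor for libraries: {sorted(missing)}")
    if (factors.loc[list(df.columns)] <= 0).any():
        raise ValueError("size factors must be positive")
    norm = df.div(factors.loc[df.columns], axis=1)
    if isinstance(counts, CountMatrix):
        return CountMatrix(norm, counts.is_spikein.copy())
    return norm
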