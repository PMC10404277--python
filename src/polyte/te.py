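"""Translation efficiency from polysome fractions, and NB differential expression.

Translation efficiency (TE) for a gene is the ratio of its spike-in
normalized polysome-fraction abundance to its monosome-fraction abundance —
a proxy for how heavily the transcript is ribosome-loaded.  Per-replicate
TE values within a condition are combined by geometric mean (the natural
average for ratios) before the between-genotype ratio is taken:

    TE_g            = (poly_g + c) / (mono_g + c)
    TE log2FC       = log2(TE_mutant / TE_control)
    RNA log2FC      = log2((mean total_mut + c) / (mean total_ctl + c))

with pseudocount c (default 1.0 on normalized counts).  A gene is called
translationally up/down-regulated when |TE log2FC| exceeds its threshold
while |RNA log2FC| stays below its own — i.e. ribosome loading changes
without a matching change in transcript abundance.  Inequalities are
strict at the thresholds.

The differential-expression stage is a minimal negative-binomial exact
test: a single method-of-moments dispersion is pooled across genes
(Var = mu + alpha*mu^2), and per gene the two genotype sums are compared
conditionally on their total under the null of equal means, summing the
probabilities of outcomes no more likely than the observed one.  P-values
are Benjamini–Hochberg adjusted and calls require both FDR and |log2FC|
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .normalize import libraries_for, validate_library_design

TE_UP = "TE_up"
TE_DOWN = "TE_down"
TE_UNCHANGED = "unchanged"

#: fixed column order of the TE result table, for diff-stable output
TE_COLUMNS = ("gene_id", "te_control", "te_mutant", "te_log2fc", "rna_log2fc", "te_class")
DE_COLUMNS = ("gene_id", "log2fc", "p_value", "fdr", "de_class")


def _geomean(df: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(df).mean(axis=1))


def compute_te(
    norm_polysome: pd.DataFrame | pd.Series,
    norm_monosome: pd.DataFrame | pd.Series,
    pseudocount: float = 1.0,
    method: str = "per_replicate_geomean",
) -> pd.Series:
    """Per-gene TE for one condition.

    With replicate matrices (genes × libraries), ``per_replicate_geomean``
    (default) takes the geometric mean of per-replicate (poly+c)/(mono+c)
    ratios; ``pooled`` averages normalized counts across replicates first
    and takes a single ratio.  Series inputs are treated as one replicate.
    """
    if isinstance(norm_polysome, pd.Series):
        norm_polysome = norm_polysome.to_frame()
    if isinstance(norm_monosome, pd.Series):
        norm_monosome = norm_monosome.to_frame()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (norm_polysome.to_numpy() < 0).any() or (norm_monosome.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if pseudocount == 0 and (
        (norm_polysome.to_numpy() == 0).any() or (norm_monosome.to_numpy() == 0).any()
    ):
        raise ValueError("pseudocount 0 requires strictly positive counts")
    if norm_polysome.shape[1] != norm_monosome.shape[1]:
        raise ValueError("polysome and monosome replicate counts differ")
    poly = norm_polysome + pseudocount
    mono = norm_monosome + pseudocount
    if method == "per_replicate_geomean":
        ratios = poly.to_numpy() / mono.to_numpy()
        te = np.exp(np.log(ratios).mean(axis=1))
        return pd.Series(te, index=norm_polysome.index, name="te")
    if method == "pooled":
        te = poly.mean(axis=1) / mono.mean(axis=1)
        te.name = "te"
        return te
    raise ValueError(f"unknown TE method {method!r}")


def te_log2fc(te_mutant: pd.Series, te_control: pd.Series) -> pd.Series:
    """log2 ratio of mutant to control TE."""
    out = np.log2(te_mutant / te_control)
    out.name = "te_log2fc"
    return out


def rna_log2fc(
    norm_total_mutant: pd.DataFrame,
    norm_total_control: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2 ratio of mean normalized total-RNA abundance, mutant over control."""
    out = np.log2(
        (norm_total_mutant.mean(axis=1) + pseudocount)
        / (norm_total_control.mean(axis=1) + pseudocount)
    )
    out.name = "rna_log2fc"
    return out


def classify_te_change(
    te_lfc, rna_lfc, te_threshold: float = 1.0, rna_threshold: float = 1.0
):
    """Classify TE changes: TE_up / TE_down / unchanged.

    TE_up  iff te_lfc >  te_threshold and |rna_lfc| < rna_threshold;
    TE_down iff te_lfc < -te_threshold and |rna_lfc| < rna_threshold;
    otherwise unchanged.  Strict inequalities: values exactly at a
    threshold are unchanged.
    """
    if te_threshold <= 0 or rna_threshold <= 0:
        raise ValueError("thresholds must be positive")
    scalar = np.isscalar(te_lfc)
    te_arr = np.atleast_1d(np.asarray(te_lfc, dtype=float))
    rna_arr = np.atleast_1d(np.asarray(rna_lfc, dtype=float))
    quiet_rna = np.abs(rna_arr) < rna_threshold
    out = np.where(
        (te_arr > te_threshold) & quiet_rna,
        TE_UP,
        np.where((te_arr < -te_threshold) & quiet_rna, TE_DOWN, TE_UNCHANGED),
    )
    if scalar:
        return str(out[0])
    if isinstance(te_lfc, pd.Series):
        return pd.Series(out, index=te_lfc.index, name="te_class")
    return out


def te_table(
    norm_counts: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 1.0,
    te_threshold: float = 1.0,
    rna_threshold: float = 1.0,
    method: str = "per_replicate_geomean",
    control: str = "control",
    mutant: str = "mutant",
) -> pd.DataFrame:
    """Full per-gene TE result table for a 2-genotype × 3-fraction design."""
    validate_library_design(design)
    cols = {
        (g, f): libraries_for(design, g, f)
        for g in (control, mutant)
        for f in ("total", "monosome", "polysome")
    }
    for key, libs in cols.items():
        if not libs:
            raise ValueError(f"no libraries for {key}")
    te_ctl = compute_te(
        norm_counts[cols[(control, "polysome")]],
        norm_counts[cols[(control, "monosome")]],
        pseudocount,
        method,
    )
    te_mut = compute_te(
        norm_counts[cols[(mutant, "polysome")]],
        norm_counts[cols[(mutant, "monosome")]],
        pseudocount,
        method,
    )
    te_lfc = te_log2fc(te_mut, te_ctl)
    rna_lfc = rna_log2fc(
        norm_counts[cols[(mutant, "total")]],
        norm_counts[cols[(control, "total")]],
        pseudocount,
    )
    out = pd.DataFrame(
        {
            "gene_id": norm_counts.index,
            "te_control": te_ctl.to_numpy(),
            "te_mutant": te_mut.to_numpy(),
            "te_log2fc": te_lfc.to_numpy(),
            "rna_log2fc": rna_lfc.to_numpy(),
            "te_class": classify_te_change(
                te_lfc, rna_lfc, te_threshold, rna_threshold
            ).to_numpy(),
        }
    )
    return out[list(TE_COLUMNS)]


# ---------------------------------------------------------------------------
# negative-binomial differential expression


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: pd.Series
) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    Within each group the sample mean and variance estimate mu and
    mu + alpha*mu^2; alpha is the ratio of summed excess variance to summed
    squared means, pooled over genes and groups, floored at a small
    positive value (quasi-Poisson data would otherwise give alpha <= 0).
    """
    num = 0.0
    den = 0.0
    for g in groups.unique():
        sub = counts.loc[:, groups[groups == g].index]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        num += float((v - m).sum())
        den += float((m**2).sum())
    if den == 0:
        raise ValueError("all-zero count matrix")
    return max(num / den, 1e-8)


def nb_exact_test_pvalue(
    s_a: int, s_b: int, n_a: int, n_b: int, alpha: float
) -> float:
    """Exact conditional NB test of equal per-library means.

    Group sums of i.i.d. NB(mu, alpha) libraries are NB with size n/alpha;
    conditioning on the total, the p-value sums P(K = k | T) over all
    splits k no more probable than the observed one.  (For NB with a
    common dispersion this conditional law is free of mu — a negative
    hypergeometric — but it is evaluated here through the two marginal
    pmfs, which is numerically equivalent.)
    """
    total = int(s_a + s_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    p = 1.0 / (1.0 + alpha * mu)
    k = np.arange(total + 1)
    logf = nbinom.logpmf(k, n_a / alpha, p) + nbinom.logpmf(total - k, n_b / alpha, p)
    f = np.exp(logf - logf.max())
    f_obs = f[int(s_a)]
    return float(f[f <= f_obs * (1.0 + 1e-10)].sum() / f.sum())


def differential_expression(
    norm_total: pd.DataFrame,
    design: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
    control: str = "control",
    mutant: str = "mutant",
    fraction: str = "total",
) -> pd.DataFrame:
    """NB exact-test differential expression, mutant vs control.

    ``norm_total`` holds normalized counts (genes × libraries); values are
    rounded to integers for the exact test.  Genes with zero counts in all
    libraries are dropped (their log2FC is ill-defined).  Requires at least
    2 replicates per genotype.

    Returns a DataFrame with columns gene_id, log2fc, p_value, fdr,
    de_class (up / down / ns).
    """
    validate_library_design(design)
    ctl_libs = libraries_for(design, control, fraction)
    mut_libs = libraries_for(design, mutant, fraction)
    if len(ctl_libs) < 2 or len(mut_libs) < 2:
        raise ValueError(
            "differential expression needs >= 2 replicates per genotype "
            "(dispersion inestimable otherwise)"
        )
    counts = norm_total[ctl_libs + mut_libs].round().astype(np.int64)
    counts = counts.loc[counts.sum(axis=1) > 0]
    groups = pd.Series(
        [control] * len(ctl_libs) + [mutant] * len(mut_libs),
        index=ctl_libs + mut_libs,
    )
    alpha = estimate_common_dispersion(counts, groups)
    s_ctl = counts[ctl_libs].sum(axis=1).to_numpy()
    s_mut = counts[mut_libs].sum(axis=1).to_numpy()
    pvals = np.array(
        [
            nb_exact_test_pvalue(a, b, len(ctl_libs), len(mut_libs), alpha)
            for a, b in zip(s_ctl, s_mut)
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    lfc = np.log2(
        (s_mut / len(mut_libs) + pseudocount) / (s_ctl / len(ctl_libs) + pseudocount)
    )
    de_class = np.where(
        (fdr < fdr_threshold) & (lfc > lfc_threshold),
        "up",
        np.where((fdr < fdr_threshold) & (lfc < -lfc_threshold), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "de_class": de_class,
        }
    )
    return out[list(DE_COLUMNS)]
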