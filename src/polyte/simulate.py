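"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the study designs the pipeline consumes:

* transcriptomes — random transcripts (5'UTR / CDS / 3'UTR) in which uORFs
  of a requested kind (contained in the UTR, or overlapping the CDS out of
  frame) are planted explicitly while accidental upstream AUGs are masked
  by rejection sampling, so the planted annotation is the complete truth;
* fraction count matrices — a 2-genotype × 3-fraction (total / monosome /
  polysome) × replicate design with ERCC-like spike-ins, negative-binomial
  noise (Var = mu + alpha*mu^2), planted TE and RNA-abundance log2
  fold-changes, and per-library scale factors;
* RPF read sets — transcript-space ribosome footprints whose start
  positions are drawn region-wise with chosen weights, emulating a
  redistribution of ribosome occupancy between a uORF and the main CDS.

A planted TE log2FC of delta is split symmetrically: polysome loading
x 2^(+delta/2) and monosome loading x 2^(-delta/2) in the mutant, so total
RNA abundance is untouched unless an RNA effect is planted as well.  All
generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import START_CODON, STOP_CODONS, TranscriptModel
from .normalize import CountMatrix, validate_library_design
from .uorf import CONTAINED, OVERLAP_OUT_OF_FRAME, UORF, find_uorfs

_BASES = np.array(list("ACGU"))
_NON_STOP_NON_START = [
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in STOP_CODONS and a + b + c != START_CODON
]
_STOPS = sorted(STOP_CODONS)

#: default RPF length distribution: uniform on 25-35 nt so that the
#: standard 28-32 nt size selection is exercised non-trivially
DEFAULT_RPF_LENGTH_DIST = {l: 1.0 / 11.0 for l in range(25, 36)}


@dataclass
class SimulationDesign:
    """Parameters of a fraction-count simulation.

    ``dispersion`` is the NB dispersion alpha in Var = mu + alpha*mu^2;
    at alpha = 0 counts equal the rounded expected means (no sampling),
    which makes planted truths exactly recoverable.  ``noise="poisson"``
    ignores the dispersion and draws Poisson counts instead.
    """

    genotypes: Sequence[str] = ("control", "mutant")
    fractions: Sequence[str] = ("total", "monosome", "polysome")
    replicates_per_condition: int = 2
    mean_depth: float = 500.0
    dispersion: float = 0.05
    te_effects: Mapping[str, float] = field(default_factory=dict)
    rna_effects: Mapping[str, float] = field(default_factory=dict)
    library_scale_factors: Mapping[str, float] = field(default_factory=dict)
    spikein_unit_counts: float = 1.0
    noise: str = "nb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if any(v <= 0 for v in self.library_scale_factors.values()):
            raise ValueError("library scale factors must be > 0")
        if self.noise not in ("nb", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def library_ids(self) -> list[str]:
        return [
            f"{g}_{f}_rep{r}"
            for g in self.genotypes
            for f in self.fractions
            for r in range(1, self.replicates_per_condition + 1)
        ]


def make_spikein_reference(
    n_species: int = 92, span_log2: float = 8.0, total_amount: float = 1e4
) -> pd.Series:
    """ERCC-like spike-in reference: geometrically spaced input amounts.

    ``n_species`` species span ``span_log2`` doublings and are scaled so
    the amounts sum to ``total_amount`` (arbitrary consistent unit); with
    ``SimulationDesign.spikein_unit_counts = 1`` the expected total spike
    count per unit-scale library is then ``total_amount``.
    """
    if n_species < 1 or total_amount <= 0:
        raise ValueError("need n_species >= 1 and total_amount > 0")
    amounts = 2.0 ** np.linspace(0.0, span_log2, n_species)
    amounts *= total_amount / amounts.sum()
    ids = [f"SPIKE_{i:03d}" for i in range(1, n_species + 1)]
    return pd.Series(amounts, index=pd.Index(ids, name="spike_id"), name="input_amount")


# ---------------------------------------------------------------------------
# transcriptome generation


def _random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _scan_aug(utr: str) -> list[int]:
    return [i for i in range(len(utr) - 2) if utr[i : i + 3] == START_CODON]


def _plant_contained(rng: np.random.Generator, utr: list[str], lo: int, hi: int) -> int:
    """Write AUG + body + stop into utr[lo:hi); returns the uORF start."""
    space = hi - lo
    n_codons = int(rng.integers(2, min(space // 3, 8) + 1))
    start = lo + int(rng.integers(0, space - 3 * n_codons + 1))
    codons = [START_CODON]
    codons += [
        _NON_STOP_NON_START[j]
        for j in rng.integers(0, len(_NON_STOP_NON_START), size=n_codons - 2)
    ]
    codons.append(_STOPS[rng.integers(0, 3)])
    utr[start : start + 3 * n_codons] = list("".join(codons))
    return start


def _plant_overlapping(rng: np.random.Generator, utr: list[str], lo: int) -> int | None:
    """Plant an out-of-frame AUG in the UTR 3' region; returns the start.

    The distance d from the AUG to the CDS start satisfies d >= 4 and
    d mod 3 != 0 (d = 3 would put the uORF in the main-ORF frame); all
    complete uORF-frame codons inside the UTR are made non-stop so the
    uORF runs past the main start codon.  When the UTR allows it, d >= 24
    is preferred so the uORF has a substantial UTR-resident span (several
    codons upstream of the main AUG, the configuration of known long
    CDS-overlapping uORFs) rather than being a bare AUG abutting the CDS.
    """
    utr_len = len(utr)
    feasible = [d for d in range(4, utr_len - lo + 1) if d % 3 != 0]
    if not feasible:
        return None
    prefer = [d for d in feasible if d >= 24]
    pool = prefer or feasible
    d = int(pool[rng.integers(0, len(pool))])
    start = utr_len - d
    utr[start : start + 3] = list(START_CODON)
    pos = start + 3
    while pos + 3 <= utr_len:
        utr[pos : pos + 3] = list(
            _NON_STOP_NON_START[rng.integers(0, len(_NON_STOP_NON_START))]
        )
        pos += 3
    return start


def _build_utr5(
    rng: np.random.Generator, utr_len: int, requests: Sequence[str]
) -> tuple[str, list[tuple[int, str]]] | None:
    """One attempt at a 5'UTR with exactly the requested planted uORFs.

    Returns ``(utr, [(start, kind), ...])`` or None when the attempt
    produced accidental AUGs or in-frame stops that break a requested kind
    (the caller resamples; editing bases instead would bias composition).
    """
    utr = list(_random_utr(rng, utr_len))
    planted: list[tuple[int, str]] = []
    overlap_req = [k for k in requests if k == OVERLAP_OUT_OF_FRAME]
    contained_req = [k for k in requests if k == CONTAINED]
    hi = utr_len
    if overlap_req:
        start = _plant_overlapping(rng, utr, lo=6 if contained_req else 0)
        if start is None:
            return None
        planted.append((start, OVERLAP_OUT_OF_FRAME))
        hi = start
    for _ in contained_req:
        if hi < 6:
            return None
        start = _plant_contained(rng, utr, lo=0, hi=hi)
        planted.append((start, CONTAINED))
        hi = start
    utr_str = "".join(utr)
    if sorted(_scan_aug(utr_str)) != sorted(s for s, _ in planted):
        return None
    return utr_str, sorted(planted)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """AUG + random non-stop codons + stop; length 3*n_codons."""
    codons = [START_CODON]
    body = rng.integers(0, len(_NON_STOP_NON_START), size=n_codons - 2)
    codons += [_NON_STOP_NON_START[j] for j in body]
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def generate_transcriptome(
    n_genes: int,
    utr5_len_range: tuple[int, int] = (30, 120),
    cds_codons_range: tuple[int, int] = (50, 200),
    uorf_spec: Sequence[Mapping[str, str]] | None = None,
    utr3_len_range: tuple[int, int] = (40, 100),
    seed: int = 0,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Random transcripts with optionally planted uORFs.

    ``uorf_spec`` is a list of requests ``{"gene_id": ..., "kind": ...}``
    with kind in {"contained_in_utr"/"contained",
    "overlapping_out_of_frame"}; a gene may carry one of each (the
    two-uORF 5'UTR configuration).  5'UTRs contain no AUG other than the
    planted starts, so ``find_uorfs`` recovers exactly the planted set.

    Returns the transcripts and an annotation table (transcript_id,
    feature, start0, end0, name) in 0-based half-open coordinates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi, what in (
        (*utr5_len_range, "utr5_len_range"),
        (*cds_codons_range, "cds_codons_range"),
        (*utr3_len_range, "utr3_len_range"),
    ):
        if lo > hi or lo < 0:
            raise ValueError(f"empty or negative {what}: ({lo}, {hi})")
    if cds_codons_range[0] < 2:
        raise ValueError("CDS needs at least 2 codons (start + stop)")
    kinds_by_gene: dict[str, list[str]] = {}
    alias = {"contained": CONTAINED, CONTAINED: CONTAINED, OVERLAP_OUT_OF_FRAME: OVERLAP_OUT_OF_FRAME}
    for req in uorf_spec or []:
        kind = alias.get(req["kind"])
        if kind is None:
            raise ValueError(f"unknown uORF kind {req['kind']!r}")
        kinds_by_gene.setdefault(req["gene_id"], []).append(kind)
    min_utr = {0: utr5_len_range[0], 1: 6, 2: 12}
    for gid, kinds in kinds_by_gene.items():
        if len(kinds) > 2 or kinds.count(CONTAINED) > 1 or kinds.count(OVERLAP_OUT_OF_FRAME) > 1:
            raise ValueError(f"{gid}: at most one uORF of each kind is supported")
        if utr5_len_range[1] < min_utr[len(kinds)]:
            raise ValueError(
                f"{gid}: requested uORFs infeasible with 5'UTR length "
                f"<= {utr5_len_range[1]} (need >= {min_utr[len(kinds)]})"
            )

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes)))
    transcripts: list[TranscriptModel] = []
    ann_rows: list[dict] = []
    for i in range(1, n_genes + 1):
        gene_id = f"gene{i:0{width}d}"
        tx_id = f"{gene_id}.t1"
        kinds = kinds_by_gene.get(gene_id, [])
        need = min_utr[len(kinds)]
        utr5_len = int(rng.integers(max(utr5_len_range[0], need), utr5_len_range[1] + 1))
        n_codons = int(rng.integers(cds_codons_range[0], cds_codons_range[1] + 1))
        utr3_len = int(rng.integers(utr3_len_range[0], utr3_len_range[1] + 1))
        cds = _random_cds(rng, n_codons)
        for _ in range(500):
            built = _build_utr5(rng, utr5_len, kinds)
            if built is None:
                continue
            utr5, planted = built
            seq = utr5 + cds + _random_utr(rng, utr3_len)
            t = TranscriptModel(tx_id, seq, utr5_len, utr5_len + len(cds), gene_id)
            found = {u.start: u.overlap_class for u in find_uorfs(t)}
            if found == {s: k for s, k in planted}:
                break
        else:  # pragma: no cover - bounded resampling failed
            raise RuntimeError(f"{gene_id}: could not plant requested uORFs")
        transcripts.append(t)
        for feat, (a, b) in t.regions().items():
            ann_rows.append(
                {"transcript_id": tx_id, "feature": feat, "start0": a, "end0": b, "name": feat}
            )
        for j, u in enumerate(find_uorfs(t), start=1):
            end = u.stop_end if u.stop_end is not None else len(t)
            ann_rows.append(
                {
                    "transcript_id": tx_id,
                    "feature": "uORF",
                    "start0": u.start,
                    "end0": end,
                    "name": f"uORF{j}:{u.overlap_class}",
                }
            )
    annotations = pd.DataFrame(
        ann_rows, columns=["transcript_id", "feature", "start0", "end0", "name"]
    )
    return transcripts, annotations


# ---------------------------------------------------------------------------
# fraction count matrices


def expected_fraction_means(
    gene_ids: Sequence[str], design: SimulationDesign
) -> pd.DataFrame:
    """Closed-form expected counts per gene × library (no spike-ins)."""
    mutant = design.genotypes[1] if len(design.genotypes) > 1 else None
    lib_ids = design.library_ids()
    mu = np.empty((len(gene_ids), len(lib_ids)))
    for j, lib in enumerate(lib_ids):
        geno, frac, _rep = lib.rsplit("_", 2)
        scale = design.library_scale_factors.get(lib, 1.0)
        for i, g in enumerate(gene_ids):
            base = design.mean_depth
            if geno == mutant:
                base *= 2.0 ** design.rna_effects.get(g, 0.0)
                delta = design.te_effects.get(g, 0.0)
                if frac == "polysome":
                    base *= 2.0 ** (delta / 2.0)
                elif frac == "monosome":
                    base *= 2.0 ** (-delta / 2.0)
            mu[i, j] = base * scale
    return pd.DataFrame(mu, index=pd.Index(gene_ids, name="id"), columns=lib_ids)


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, design: SimulationDesign
) -> np.ndarray:
    if design.noise == "poisson":
        return rng.poisson(mu)
    if design.dispersion == 0:
        return np.rint(mu).astype(np.int64)
    lam = rng.gamma(1.0 / design.dispersion, design.dispersion * mu)
    return rng.poisson(lam)


def generate_fraction_counts(
    transcripts: Sequence[TranscriptModel] | Sequence[str],
    design: SimulationDesign,
    spikein_ref: pd.Series | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the full fraction count matrix plus its library design table.

    Gene expected counts follow the planted-effect model in the module
    docstring; spike-in expected counts are ``input_amount x scale_factor
    x spikein_unit_counts``, independent of genotype and fraction (equal
    amounts are added to every sample).
    """
    gene_ids = [
        t.gene_id if isinstance(t, TranscriptModel) else str(t) for t in transcripts
    ]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng(design.seed)
    mu_genes = expected_fraction_means(gene_ids, design)
    lib_ids = list(mu_genes.columns)
    blocks = [mu_genes]
    flags = [pd.Series(False, index=mu_genes.index)]
    if spikein_ref is not None:
        if set(spikein_ref.index) & set(gene_ids):
            raise ValueError("spike ids must be disjoint from gene ids")
        scales = np.array([design.library_scale_factors.get(l, 1.0) for l in lib_ids])
        mu_spikes = pd.DataFrame(
            np.outer(spikein_ref.to_numpy() * design.spikein_unit_counts, scales),
            index=spikein_ref.index,
            columns=lib_ids,
        )
        blocks.append(mu_spikes)
        flags.append(pd.Series(True, index=mu_spikes.index))
    mu_all = pd.concat(blocks)
    counts = pd.DataFrame(
        _draw_counts(rng, mu_all.to_numpy(), design),
        index=mu_all.index,
        columns=lib_ids,
    )
    lib_design = pd.DataFrame(
        [
            {
                "library_id": lib,
                "genotype": lib.rsplit("_", 2)[0],
                "fraction": lib.rsplit("_", 2)[1],
                "replicate": int(lib.rsplit("_", 2)[2].removeprefix("rep")),
            }
            for lib in lib_ids
        ]
    )
    validate_library_design(lib_design)
    return CountMatrix(counts, pd.concat(flags)), lib_design


# ---------------------------------------------------------------------------
# luciferase well tables


def generate_luciferase_table(
    construct_effects: Mapping[str, float],
    n_replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic dual-luciferase wells with planted relative activities.

    Each well draws an independent transfection scale (lognormal, CV 0.3)
    applied to both channels — the nuisance the Renilla/Firefly ratio is
    meant to cancel — plus per-channel lognormal measurement noise with
    coefficient of variation ``cv``.  The planted effect multiplies the
    Renilla channel only, so a construct's expected relative activity
    equals its entry in ``construct_effects``.
    """
    if n_replicates < 1 or cv < 0:
        raise ValueError("need n_replicates >= 1 and cv >= 0")
    if any(e <= 0 for e in construct_effects.values()):
        raise ValueError("construct effects must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for cid in construct_effects:
        for r in range(1, n_replicates + 1):
            transfection = rng.lognormal(0.0, np.sqrt(np.log1p(0.3**2)))
            firefly = 1e4 * transfection * rng.lognormal(0.0, sigma)
            renilla = (
                5e3 * construct_effects[cid] * transfection * rng.lognormal(0.0, sigma)
            )
            rows.append(
                {"construct_id": cid, "replicate": r,
                 "renilla": renilla, "firefly": firefly}
            )
    return pd.DataFrame(rows, columns=["construct_id", "replicate", "renilla", "firefly"])


# ---------------------------------------------------------------------------
# RPF read sets


def generate_rpf_reads(
    transcript: TranscriptModel,
    regions: Mapping[str, tuple[int, int]],
    region_weights: Mapping[str, float],
    n_reads: int,
    length_dist: Mapping[int, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw transcript-space RPF records with region-weighted start positions.

    Each read samples a region by weight and a length from ``length_dist``
    (default uniform 25–35 nt); its start is uniform over the region,
    truncated so the footprint fits the transcript.  Returns a DataFrame
    (transcript_id, start, length).
    """
    if length_dist is None:
        length_dist = DEFAULT_RPF_LENGTH_DIST
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    weights = {k: v for k, v in region_weights.items() if v > 0}
    if weights and abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("region weights must sum to 1")
    lengths = sorted(length_dist)
    lprobs = np.array([length_dist[l] for l in lengths], dtype=float)
    if (lprobs < 0).any() or abs(lprobs.sum() - 1.0) > 1e-9 or min(lengths) < 1:
        raise ValueError("length_dist must be a distribution over lengths >= 1")
    n = len(transcript.sequence)
    for label in weights:
        if label not in regions:
            raise ValueError(f"weighted region {label!r} not in regions")
        a, b = regions[label]
        if not (0 <= a < b <= n):
            raise ValueError(f"region {label!r} [{a}, {b}) invalid for length {n}")
        for l in lengths:
            if length_dist[l] > 0 and min(b - 1, n - l) < a:
                raise ValueError(
                    f"region {label!r} too short for footprint length {l}"
                )
    rng = np.random.default_rng(seed)
    labels = sorted(weights)
    if n_reads and not labels:
        raise ValueError("no region with positive weight")
    if not n_reads:
        return pd.DataFrame(
            {"transcript_id": pd.Series(dtype=str),
             "start": pd.Series(dtype=np.int64),
             "length": pd.Series(dtype=np.int64)}
        )
    which = rng.choice(len(labels), size=n_reads, p=[weights[l] for l in labels])
    ls = np.asarray(lengths, dtype=np.int64)[
        rng.choice(len(lengths), size=n_reads, p=lprobs)
    ]
    a = np.array([regions[l][0] for l in labels], dtype=np.int64)[which]
    b = np.array([regions[l][1] for l in labels], dtype=np.int64)[which]
    hi = np.minimum(b - 1, n - ls)
    starts = rng.integers(a, hi + 1)
    return pd.DataFrame(
        {
            "transcript_id": transcript.transcript_id,
            "start": starts.astype(np.int64),
            "length": ls,
        }
    )
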