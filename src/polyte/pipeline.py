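"""End-to-end orchestration: simulate → normalize → TE/DE → uORF → occupancy → reporter.

A run is driven by a single config mapping (YAML file or dict) merged over
:data:`DEFAULT_CONFIG`.  Every source of randomness derives from one root
seed: stage k uses ``SeedSequence([root_seed, k])`` with the fixed stage
order of :data:`STAGES`, so reruns with the same config are byte-identical
and stages can be toggled without shifting each other's seeds.  Each output
TSV carries a ``#`` header echoing the tool version and stage parameters;
the run manifest (stage status, outputs, parameter echo, seed echo) is
written as JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, occupancy as occ, reporter as rep, te as te_mod
from .normalize import compute_size_factors, normalize_counts
from .simulate import (
    SimulationDesign,
    generate_fraction_counts,
    generate_luciferase_table,
    generate_rpf_reads,
    generate_transcriptome,
    make_spikein_reference,
)
from .uorf import find_uorfs

log = logging.getLogger("polyte")

STAGES = ("simulate", "normalize", "te", "de", "uorf", "occupancy", "reporter")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "simulate": {
        "n_genes": 60,
        "utr5_len_range": [30, 120],
        "cds_codons_range": [50, 150],
        "mean_depth": 300.0,
        "dispersion": 0.05,
        "replicates": 2,
        "te_effects": {},
        "rna_effects": {},
        "scale_factors": {},
        "n_spikeins": 92,
        "spikein_span_log2": 8.0,
        "spikein_total_amount": 1e4,
        "focal_gene": None,  # default: first gene; gets both uORF kinds
        "rpf_reads": 4000,
        "rpf_weights_control": {"uORF1": 0.15, "uORF2": 0.55, "CDS": 0.25,
                                "three_prime_UTR": 0.05},
        "rpf_weights_mutant": {"uORF1": 0.15, "uORF2": 0.25, "CDS": 0.55,
                               "three_prime_UTR": 0.05},
        "luciferase_effects": {"NC": 1.0, "utr_wt": 0.4, "utr_uaa": 0.8},
        "luciferase_replicates": 3,
        "luciferase_cv": 0.05,
    },
    "normalize": {"min_count": 5},
    "te": {"pseudocount": 1.0, "te_threshold": 1.0, "rna_threshold": 1.0,
           "method": "per_replicate_geomean"},
    "de": {"fdr_threshold": 0.05, "lfc_threshold": 1.0, "pseudocount": 1.0},
    "uorf": {},
    "occupancy": {"min_len": 28, "max_len": 32, "how": "coverage", "eps": 1e-6},
    "reporter": {"control_id": "NC", "equal_var": True},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides over the defaults."""
    cfg = _deep_merge(DEFAULT_CONFIG, {})
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _deep_merge(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([root, stage index])."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % 2**31)


def _header(stage: str, params: dict) -> str:
    echo = json.dumps(params, sort_keys=True, default=str)
    return f"polyte {__version__}\nstage={stage}\nparams={echo}"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, outdir) -> dict:
    """Execute enabled stages in dependency order; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config["seed"],
        "stages": {},
    }
    state: dict = {"outdir": outdir}
    for stage in STAGES:
        if not config["stages"].get(stage, False):
            continue
        params = dict(config.get(stage, {}))
        seed = stage_seed(config["seed"], stage)
        log.info("[%s] starting (seed=%d)", stage, seed)
        try:
            outputs = _STAGE_FUNCS[stage](config, params, seed, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seed": seed,
            "params": params,
            "outputs": [Path(p).name for p in outputs],
        }
        log.info("[%s] done", stage)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config, p, seed, state):
    out = state["outdir"]
    focal_idx = 1
    width = max(3, len(str(p["n_genes"])))
    focal = p["focal_gene"] or f"gene{focal_idx:0{width}d}"
    uorf_spec = [
        {"gene_id": focal, "kind": "contained"},
        {"gene_id": focal, "kind": "overlapping_out_of_frame"},
    ]
    transcripts, annotations = generate_transcriptome(
        p["n_genes"],
        tuple(p["utr5_len_range"]),
        tuple(p["cds_codons_range"]),
        uorf_spec,
        seed=seed,
    )
    design = SimulationDesign(
        replicates_per_condition=p["replicates"],
        mean_depth=p["mean_depth"],
        dispersion=p["dispersion"],
        te_effects=dict(p["te_effects"]),
        rna_effects=dict(p["rna_effects"]),
        library_scale_factors=dict(p["scale_factors"]),
        seed=seed,
    )
    ref = make_spikein_reference(
        p["n_spikeins"], p["spikein_span_log2"], p["spikein_total_amount"]
    )
    cm, lib_design = generate_fraction_counts(transcripts, design, ref)
    focal_t = next(t for t in transcripts if t.gene_id == focal)
    regions = _focal_regions(focal_t)
    rpf = {}
    for cond, wkey in (("control", "rpf_weights_control"), ("mutant", "rpf_weights_mutant")):
        weights = dict(p[wkey])
        rpf[cond] = generate_rpf_reads(
            focal_t, regions, weights, p["rpf_reads"],
            seed=seed + (0 if cond == "control" else 1),
        )
    luc = generate_luciferase_table(
        dict(p["luciferase_effects"]),
        n_replicates=p["luciferase_replicates"],
        cv=p["luciferase_cv"],
        seed=seed,
    )
    hdr = _header("simulate", p)
    io.write_fasta(transcripts, out / "transcripts.fasta")
    io.write_gff3(annotations, out / "annotations.gff3")
    io.write_regions_tsv(annotations, out / "annotations.tsv", hdr)
    io.write_count_matrix(cm, out / "counts.tsv", hdr)
    io.write_library_design(lib_design, out / "library_design.tsv", hdr)
    io.write_spikein_reference(ref, out / "spikein_reference.tsv", hdr)
    io.write_rpf_tsv(rpf["control"], out / "rpf_control.tsv", hdr)
    io.write_rpf_tsv(rpf["mutant"], out / "rpf_mutant.tsv", hdr)
    io.write_luciferase(luc, out / "luciferase.tsv", hdr)
    state.update(
        transcripts=transcripts, annotations=annotations, counts=cm,
        lib_design=lib_design, spikein_ref=ref, focal=focal_t,
        rpf=rpf, luciferase=luc,
    )
    return [out / n for n in (
        "transcripts.fasta", "annotations.gff3", "annotations.tsv", "counts.tsv",
        "library_design.tsv", "spikein_reference.tsv", "rpf_control.tsv",
        "rpf_mutant.tsv", "luciferase.tsv",
    )]


def _focal_regions(t) -> dict[str, tuple[int, int]]:
    regions = dict(t.regions())
    for j, u in enumerate(find_uorfs(t), start=1):
        end = u.stop_end if u.stop_end is not None else len(t)
        regions[f"uORF{j}"] = (u.start, end)
    return regions


def _require(state, key, stage, hint):
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} needs {hint}; enable the producing stage or "
            "provide the file via config paths"
        )
    return state[key]


def _stage_normalize(config, p, seed, state):
    out = state["outdir"]
    cm = _load_or(state, "counts", config, "counts", io.read_count_matrix)
    ref = _load_or(state, "spikein_ref", config, "spikein_reference",
                   io.read_spikein_reference)
    factors = compute_size_factors(cm, ref, min_count=p["min_count"])
    norm = normalize_counts(cm, factors)
    hdr = _header("normalize", p)
    io.write_size_factors(factors, out / "size_factors.tsv", hdr)
    io.write_matrix_tsv(norm.counts, out / "normalized_counts.tsv", hdr)
    state.update(size_factors=factors, normalized=norm)
    return [out / "size_factors.tsv", out / "normalized_counts.tsv"]


def _load_or(state, key, config, path_key, reader):
    if key in state:
        return state[key]
    path = config.get("paths", {}).get(path_key)
    if path is None:
        raise RuntimeError(
            f"no in-memory {key!r} and no paths.{path_key} in config"
        )
    value = reader(path)
    state[key] = value
    return value


def _stage_te(config, p, seed, state):
    out = state["outdir"]
    norm = _require(state, "normalized", "te", "normalized counts")
    lib_design = _load_or(state, "lib_design", config, "library_design",
                          io.read_library_design)
    table = te_mod.te_table(
        norm.genes, lib_design,
        pseudocount=p["pseudocount"], te_threshold=p["te_threshold"],
        rna_threshold=p["rna_threshold"], method=p["method"],
    )
    io.write_regions_tsv(table, out / "te_results.tsv", _header("te", p))
    state["te_table"] = table
    return [out / "te_results.tsv"]


def _stage_de(config, p, seed, state):
    out = state["outdir"]
    norm = _require(state, "normalized", "de", "normalized counts")
    lib_design = _load_or(state, "lib_design", config, "library_design",
                          io.read_library_design)
    table = te_mod.differential_expression(
        norm.genes, lib_design,
        fdr_threshold=p["fdr_threshold"], lfc_threshold=p["lfc_threshold"],
        pseudocount=p["pseudocount"],
    )
    io.write_regions_tsv(table, out / "de_results.tsv", _header("de", p))
    state["de_table"] = table
    return [out / "de_results.tsv"]


def _stage_uorf(config, p, seed, state):
    out = state["outdir"]
    transcripts = _load_or(
        state, "transcripts", config, "transcripts",
        lambda path: io.read_transcripts(path, config["paths"]["annotations"]),
    )
    rows = []
    for t in transcripts:
        for j, u in enumerate(find_uorfs(t), start=1):
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "name": f"uORF{j}",
                    "start0": u.start,
                    "end0": u.stop_end if u.stop_end is not None else len(t),
                    "n_codons": u.n_codons,
                    "frame_vs_cds": u.frame_vs_cds,
                    "overlap_class": u.overlap_class,
                    "has_stop": u.stop_end is not None,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["transcript_id", "name", "start0", "end0", "n_codons",
                 "frame_vs_cds", "overlap_class", "has_stop"],
    )
    io.write_regions_tsv(table, out / "uorf_annotations.tsv", _header("uorf", p))
    gff = pd.DataFrame(
        {
            "transcript_id": table["transcript_id"],
            "feature": "uORF",
            "start0": table["start0"],
            "end0": table["end0"],
            "name": table["name"] + ":" + table["overlap_class"],
        }
    )
    io.write_gff3(gff, out / "uorf_annotations.gff3")
    state["uorf_table"] = table
    return [out / "uorf_annotations.tsv", out / "uorf_annotations.gff3"]


def _stage_occupancy(config, p, seed, state):
    out = state["outdir"]
    focal = _require(state, "focal", "occupancy", "a focal transcript")
    rpf = state.get("rpf")
    if rpf is None:
        paths = config.get("paths", {})
        rpf = {
            "control": io.read_rpf_tsv(paths["rpf_control"]),
            "mutant": io.read_rpf_tsv(paths["rpf_mutant"]),
        }
    regions = _focal_regions(focal)
    hdr = _header("occupancy", p)
    profile_rows, region_occ = [], {}
    for cond, reads in rpf.items():
        kept = occ.filter_rpf_by_length(reads, p["min_len"], p["max_len"])
        prof = occ.occupancy_profile(kept, focal, how=p["how"])
        region_occ[cond] = occ.region_occupancy(prof, regions)
        profile_rows.append(
            pd.DataFrame(
                {
                    "transcript_id": focal.transcript_id,
                    "condition": cond,
                    "pos0": np.arange(len(prof.density)),
                    "density": prof.density,
                }
            )
        )
    profiles = pd.concat(profile_rows, ignore_index=True)
    io.write_regions_tsv(profiles, out / "occupancy_profiles.tsv", hdr)
    occ_table = pd.DataFrame(region_occ).rename_axis("region").reset_index()
    io.write_regions_tsv(occ_table, out / "region_occupancy.tsv", hdr)
    comparison = occ.compare_occupancy(
        region_occ["mutant"], region_occ["control"], eps=p["eps"]
    ).reset_index()
    io.write_regions_tsv(comparison, out / "occupancy_comparison.tsv", hdr)
    state["occupancy_comparison"] = comparison.set_index("region")
    return [out / "occupancy_profiles.tsv", out / "region_occupancy.tsv",
            out / "occupancy_comparison.tsv"]


def _stage_reporter(config, p, seed, state):
    out = state["outdir"]
    luc = _load_or(state, "luciferase", config, "luciferase", io.read_luciferase)
    rel = rep.relative_luciferase(luc, p["control_id"])
    tests = rep.compare_constructs_to_control(
        rel, p["control_id"], equal_var=p["equal_var"]
    )
    hdr = _header("reporter", p)
    io.write_regions_tsv(rel, out / "relative_activity.tsv", hdr)
    io.write_regions_tsv(tests, out / "reporter_tests.tsv", hdr)
    state.update(relative_activity=rel, reporter_tests=tests)
    return [out / "relative_activity.tsv", out / "reporter_tests.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "te": _stage_te,
    "de": _stage_de,
    "uorf": _stage_uorf,
    "occupancy": _stage_occupancy,
    "reporter": _stage_reporter,
}
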