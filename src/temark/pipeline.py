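"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate -> call-promoters -> classify-mods ->
enrich -> age -> distance on a single :class:`RunConfig`, writing each
stage's TSV outputs plus a run manifest (config hash, seed, versions,
per-stage row counts) into the output directory.  Every source of
randomness receives a substream derived deterministically from the run
seed and a stage/library name, so identical (config, seed) runs produce
identical files and adding a library does not perturb the others.

The stages are also available as file-based functions (used by the CLI)
that read whatever a previous stage wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_distance import (
    age_density_correlation,
    distance_bin_profile,
    distance_records,
    subfamily_age_table,
)
from .enrichment import (
    class_enrichment,
    enrichment_table,
    family_age_correlation,
    family_interval_sets,
    pool_libraries,
    records_frame,
)
from .io_formats import TagLibrary, write_table, write_tags
from .models import GenomeModel
from .promoters import (
    call_presence,
    classify_modifications,
    count_tags_in_intervals,
    define_promoters,
)
from .simulate import (
    EnrichmentSpec,
    GenomeConfig,
    PromoterMark,
    RegionBias,
    SubfamilyConfig,
    apply_expression_effects,
    generate_genome,
    generate_tags,
    substream,
    write_genome,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "call-promoters", "classify-mods", "enrich", "age", "distance"]


@dataclass
class RunConfig:
    """Everything one run needs: the synthetic inputs and analysis parameters."""

    genome: GenomeConfig
    spec: EnrichmentSpec
    alpha: float = 0.05
    background: str = "both"  # global | local | both
    window_bp: int = 1_000_000
    bin_bp: int = 10_000
    max_distance: int = 200_000
    unique_only: bool = True
    log_scale_expression: bool = False
    age_families: tuple[str, ...] = ("Alu", "L1")
    promoter_up: int = 1000
    promoter_down: int = 200


def demo_config() -> RunConfig:
    """The bundled demo study conditions (see :mod:`temark.configs`)."""
    from .configs import demo_enrichment_spec, demo_genome_config

    return RunConfig(
        genome=demo_genome_config(),
        spec=demo_enrichment_spec(),
        log_scale_expression=True,
    )


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
               .generate_state(1)[0] & 0x7FFFFFFF)


# --- config (de)serialisation --------------------------------------------

def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["age_families"] = list(config.age_families)
    d["genome"]["chromosomes"] = [list(c) for c in config.genome.chromosomes]
    spec = d["spec"]
    spec["family_fold"] = _fold_nest(config.spec.family_fold)
    spec["subfamily_fold"] = _fold_nest(config.spec.subfamily_fold)
    spec["gene_proximity"] = {m: list(v) for m, v in config.spec.gene_proximity.items()}
    spec["region_bias"] = [dataclasses.asdict(b) for b in config.spec.region_bias]
    return d


def _fold_nest(table: dict[tuple[str, str], float]) -> dict:
    out: dict[str, dict[str, float]] = {}
    for (group, mod), fold in table.items():
        out.setdefault(group, {})[mod] = fold
    return out


def _fold_flat(nested: dict) -> dict[tuple[str, str], float]:
    return {(g, m): float(f) for g, mods in (nested or {}).items() for m, f in mods.items()}


def config_from_dict(d: dict) -> RunConfig:
    g = dict(d["genome"])
    g["chromosomes"] = [(str(c), int(l)) for c, l in g["chromosomes"]]
    g["families"] = {
        fam: {sub: SubfamilyConfig(**cfg) for sub, cfg in subs.items()}
        for fam, subs in (g.get("families") or {}).items()
    }
    genome = GenomeConfig(**g)
    s = dict(d["spec"])
    s["family_fold"] = _fold_flat(s.get("family_fold"))
    s["subfamily_fold"] = _fold_flat(s.get("subfamily_fold"))
    s["promoter_marks"] = {m: PromoterMark(**v) for m, v in (s.get("promoter_marks") or {}).items()}
    s["gene_proximity"] = {m: tuple(v) for m, v in (s.get("gene_proximity") or {}).items()}
    s["region_bias"] = [RegionBias(**b) for b in (s.get("region_bias") or [])]
    spec = EnrichmentSpec(**s)
    rest = {k: v for k, v in d.items() if k not in ("genome", "spec")}
    if "age_families" in rest:
        rest["age_families"] = tuple(rest["age_families"])
    return RunConfig(genome=genome, spec=spec, **rest)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- in-memory pipeline ---------------------------------------------------

@dataclass
class RunResult:
    genome: GenomeModel
    libraries: dict[str, TagLibrary]
    calls: pd.DataFrame
    classification: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]  # background kind -> 228-row table
    class_records: dict[str, list]  # background kind -> EnrichmentRecord list
    family_age: pd.DataFrame
    subfamily_age: pd.DataFrame
    age_correlations: pd.DataFrame
    distance: pd.DataFrame
    distance_bins: pd.DataFrame
    distance_correlations: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _corr_row(corr, **labels) -> dict:
    return {**labels, "coefficient": corr.coefficient, "n": corr.n,
            "t": corr.t, "p": corr.p, "method": corr.method}


def run_all(config: RunConfig, seed: int, outdir=None) -> RunResult:
    """Run every stage on one config; optionally write all outputs under outdir."""
    backgrounds = ["global", "local"] if config.background == "both" else [config.background]
    rows: dict[str, int] = {}

    # -- simulate
    genome = generate_genome(config.genome, _stage_seed(seed, "genome"))
    genome = apply_expression_effects(genome, config.spec)
    libraries = {
        mod: generate_tags(genome, config.spec, mod, seed) for mod in config.spec.modifications
    }
    rows["simulate"] = len(genome.te_insertions) + len(genome.genes)
    logger.info("simulate: %d TEs, %d genes, %d libraries, %d tags total",
                len(genome.te_insertions), len(genome.genes), len(libraries),
                sum(l.total_count for l in libraries.values()))

    # -- call-promoters
    promoters = define_promoters(genome.genes, genome.chrom_sizes,
                                 up=config.promoter_up, down=config.promoter_down)
    n_tests = max(1, len(promoters) * len(libraries))
    calls_by_mod = {}
    for mod, lib in libraries.items():
        counts = count_tags_in_intervals(lib, promoters)
        calls_by_mod[mod] = call_presence(counts, promoters, lib, genome.genome_length,
                                          alpha=config.alpha, n_tests=n_tests)
    calls = pd.concat(calls_by_mod.values(), ignore_index=True)
    rows["call-promoters"] = len(calls)

    # -- classify-mods
    classification = classify_modifications(calls_by_mod, genome.genes,
                                            log_scale=config.log_scale_expression)
    rows["classify-mods"] = len(classification)

    # -- enrich
    family_sets = family_interval_sets(genome.te_insertions)
    enr_frames: dict[str, pd.DataFrame] = {}
    class_recs: dict[str, list] = {}
    fam_age_rows = []
    for kind in backgrounds:
        recs = enrichment_table(
            libraries, family_sets, genome.genome_length,
            chrom_sizes=genome.chrom_sizes, te_insertions=genome.te_insertions,
            background=kind, alpha=config.alpha, window_bp=config.window_bp,
            seed=_stage_seed(seed, f"localbg-{kind}"))
        enr_frames[kind] = records_frame(recs)
        crecs = class_enrichment(
            libraries, classification, family_sets, genome.genome_length,
            chrom_sizes=genome.chrom_sizes, te_insertions=genome.te_insertions,
            background=kind, alpha=config.alpha, window_bp=config.window_bp,
            seed=_stage_seed(seed, f"localbg-class-{kind}"))
        class_recs[kind] = crecs
        for klass in ("active", "repressive"):
            corr = family_age_correlation(crecs, klass)
            fam_age_rows.append(_corr_row(corr, klass=klass, background_kind=kind))
    family_age = pd.DataFrame(fam_age_rows)
    rows["enrich"] = sum(len(f) for f in enr_frames.values())

    # -- age
    klass_of = dict(zip(classification["modification"], classification["klass"]))
    active_pool = pool_libraries([libraries[m] for m in libraries if klass_of[m] == "active"], "active")
    repressive_pool = pool_libraries(
        [libraries[m] for m in libraries if klass_of[m] == "repressive"], "repressive")
    subfam = subfamily_age_table(genome.te_insertions, active_pool, repressive_pool,
                                 families=config.age_families)
    age_rows = []
    for fam in config.age_families:
        sub = subfam[subfam["family"] == fam]
        for klass in ("active", "repressive"):
            corr = age_density_correlation(sub, klass)
            age_rows.append(_corr_row(corr, family=fam, klass=klass))
    age_correlations = pd.DataFrame(age_rows)
    rows["age"] = len(subfam)

    # -- distance
    dist = distance_records(genome.te_insertions, genome.genes, active_pool, repressive_pool,
                            families=config.age_families, unique_only=config.unique_only)
    bin_frames, dist_rows = [], []
    for fam in config.age_families:
        sub = dist[dist["family"] == fam]
        for klass in ("active", "repressive"):
            profile = distance_bin_profile(sub, klass, bin_bp=config.bin_bp,
                                           max_distance=config.max_distance)
            bins = profile.bins.copy()
            bins.insert(0, "klass", klass)
            bins.insert(0, "family", fam)
            bin_frames.append(bins)
            if profile.correlation is not None:
                dist_rows.append(_corr_row(profile.correlation, family=fam, klass=klass))
    distance_bins = pd.concat(bin_frames, ignore_index=True)
    distance_correlations = pd.DataFrame(dist_rows)
    rows["distance"] = len(dist)

    manifest = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "temark_version": __version__,
        "stages": [{"name": s, "rows": rows[s]} for s in STAGES],
    }

    result = RunResult(
        genome=genome, libraries=libraries, calls=calls, classification=classification,
        enrichment=enr_frames, class_records=class_recs, family_age=family_age,
        subfamily_age=subfam, age_correlations=age_correlations, distance=dist,
        distance_bins=distance_bins, distance_correlations=distance_correlations,
        manifest=manifest,
    )
    if outdir is not None:
        write_results(result, config, Path(outdir))
    return result


def write_results(result: RunResult, config: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(result.genome, outdir)
    tagdir = outdir / "tags"
    tagdir.mkdir(exist_ok=True)
    for mod, lib in result.libraries.items():
        write_tags(lib, tagdir / f"{mod}.bed")
    save_config(config, outdir / "config.yaml")
    write_table(result.calls, outdir / "calls.tsv")
    write_table(result.classification, outdir / "classification.tsv")
    for kind, frame in result.enrichment.items():
        write_table(frame, outdir / f"enrichment_{kind}.tsv")
        write_table(records_frame(result.class_records[kind]),
                    outdir / f"class_enrichment_{kind}.tsv")
    write_table(result.family_age, outdir / "family_age_correlation.tsv")
    write_table(result.subfamily_age, outdir / "subfamily_age.tsv")
    write_table(result.age_correlations, outdir / "age_correlations.tsv")
    write_table(result.distance, outdir / "distance_records.tsv")
    write_table(result.distance_bins, outdir / "distance_bins.tsv")
    write_table(result.distance_correlations, outdir / "distance_correlations.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
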