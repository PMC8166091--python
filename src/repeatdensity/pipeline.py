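"""End-to-end orchestration: scan -> classify -> intersect -> profile -> compare.

A run is driven by a :class:`RunConfig` (YAML on disk or built in code),
executes the stages in order, writes every intermediate table, and ends
with a JSON + text report whose numbers are all recomputable from the
emitted TSVs. Reruns on the same inputs are identical modulo the report
timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import compare_classes, densities_by_class
from .errors import ConfigError, RepeatDensityError, StageError
from .expression import GeneClassification, classify_genes, filter_by_pvalue, intersect
from .io import read_annotation, read_expression, read_fasta, write_repeats_bed
from .profile import gene_bin_profile, gene_window_density, group_density_profile, make_window
from .scanner import scan_genome

logger = logging.getLogger(__name__)

_PATH_KEYS = ("genome", "annotation", "expr1", "expr2", "groups")


@dataclass
class RunConfig:
    """Paths plus every analysis parameter; defaults mirror the study design."""

    genome: str | None = None
    annotation: str | None = None
    expr1: str | None = None
    expr2: str | None = None
    groups: str | None = None
    out_dir: str = "repeatdensity_out"
    experiment1_id: str = "experiment1"
    experiment2_id: str = "experiment2"
    annotation_dialect: str = "tsv"
    bases: tuple[str, ...] = ("A", "T")
    min_len: int = 13
    max_len: int = 27
    upstream: int = 10_000
    downstream: int = 10_000
    bin_width: int = 100
    alpha: float = 0.05
    p_cut: float = 0.05
    strand_mode: str = "sense"
    max_truncated_fraction: float = 0.5

    @property
    def missing_inputs(self) -> list[str]:
        return [k for k in _PATH_KEYS if getattr(self, k) is None]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bases"] = list(self.bases)
        return d


def validate_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, reporting every violation at once.

    An empty file yields a config with all defaults (input paths flagged
    via ``missing_inputs``); unknown keys are rejected for typo safety.
    Relative paths are resolved against the config file's directory.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError([f"config file not found: {path}"]) from exc
    except yaml.YAMLError as exc:
        raise ConfigError([f"invalid YAML in {path}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: config must be a YAML mapping"])

    problems = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in sorted(set(raw) - known):
        problems.append(f"unknown config key {key!r}")
    raw = {k: v for k, v in raw.items() if k in known}
    if "bases" in raw:
        raw["bases"] = tuple(raw["bases"])
    cfg = RunConfig(**raw)

    for key in _PATH_KEYS:
        val = getattr(cfg, key)
        if val is not None:
            setattr(cfg, key, str((path.parent / val).resolve()))

    if cfg.bin_width <= 0:
        problems.append("bin_width must be positive")
    else:
        if cfg.upstream <= 0 or cfg.upstream % cfg.bin_width:
            problems.append(
                f"upstream {cfg.upstream} must be a positive multiple of bin_width {cfg.bin_width}"
            )
        if cfg.downstream <= 0 or cfg.downstream % cfg.bin_width:
            problems.append(
                f"downstream {cfg.downstream} must be a positive multiple of bin_width {cfg.bin_width}"
            )
    if not 1 <= cfg.min_len <= cfg.max_len:
        problems.append(f"need 1 <= min_len <= max_len, got ({cfg.min_len}, {cfg.max_len})")
    if not 0 < cfg.alpha <= 1:
        problems.append(f"alpha must be in (0, 1], got {cfg.alpha}")
    if not 0 < cfg.p_cut <= cfg.alpha:
        problems.append(f"p_cut must be in (0, alpha={cfg.alpha}], got {cfg.p_cut}")
    if cfg.strand_mode not in ("sense", "reference"):
        problems.append(f"strand_mode must be 'sense' or 'reference', got {cfg.strand_mode!r}")
    if invalid := [b for b in cfg.bases if b not in ("A", "C", "G", "T")]:
        problems.append(f"invalid bases {invalid}")
    if cfg.annotation_dialect not in ("tsv", "bed"):
        problems.append(f"annotation_dialect must be 'tsv' or 'bed'")
    if not 0 <= cfg.max_truncated_fraction < 1:
        problems.append("max_truncated_fraction must be in [0, 1)")
    if problems:
        raise ConfigError(problems)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except RepeatDensityError as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _read_groups(path: str) -> dict[str, dict[str, str]]:
    with open(path) as fh:
        groups = yaml.safe_load(fh)
    if not isinstance(groups, dict):
        raise ConfigError([f"{path}: groups file must be a YAML mapping"])
    if "expr1" in groups and "expr2" in groups:
        return {"expr1": groups["expr1"], "expr2": groups["expr2"]}
    # one flat map shared by both matrices
    return {"expr1": groups, "expr2": groups}


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report (also written to disk)."""
    if config.missing_inputs:
        raise ConfigError(
            [f"input path {k!r} not set" for k in config.missing_inputs]
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load ------------------------------------------------------------
    @_stage("load")
    def load():
        genome = read_fasta(config.genome)
        genes = read_annotation(config.annotation, config.annotation_dialect, genome)
        groups = _read_groups(config.groups)
        em1 = read_expression(config.expr1, groups["expr1"])
        em2 = read_expression(config.expr2, groups["expr2"])
        return genome, genes, em1, em2

    genome, genes, em1, em2 = load()

    # --- scan ------------------------------------------------------------
    @_stage("scan")
    def scan():
        index = scan_genome(genome, config.bases, config.min_len, config.max_len)
        write_repeats_bed(index.all_runs(), out / "repeats.bed")
        return index

    index = scan()
    n_runs = {b: sum(len(by.get(b, [])) for by in index.runs.values()) for b in config.bases}

    # --- classify ---------------------------------------------------------
    @_stage("classify")
    def classify():
        cls1 = classify_genes(em1, config.alpha, config.experiment1_id)
        cls2 = classify_genes(em2, config.alpha, config.experiment2_id)
        cls1.table.to_csv(out / "classification_experiment1.tsv", sep="\t")
        cls2.table.to_csv(out / "classification_experiment2.tsv", sep="\t")
        return cls1, cls2

    cls1, cls2 = classify()

    # --- intersect ----------------------------------------------------------
    @_stage("intersect")
    def do_intersect():
        results = {}
        for direction in ("Dn", "Up"):
            res = intersect(cls1, cls2, direction)
            filtered = filter_by_pvalue(res, cls1, cls2, config.p_cut)
            pd.DataFrame(
                {
                    "gene_id": sorted(res.genes),
                    "p_experiment1": [cls1.p_value(g) for g in sorted(res.genes)],
                    "p_experiment2": [cls2.p_value(g) for g in sorted(res.genes)],
                    "passes_p_cut": [g in set(filtered) for g in sorted(res.genes)],
                }
            ).to_csv(out / f"intersection_{direction.lower()}.tsv", sep="\t", index=False)
            results[direction] = (res, filtered)
        return results

    intersections = do_intersect()

    # --- profile ------------------------------------------------------------
    @_stage("profile")
    def do_profile():
        profiles = {b: {} for b in config.bases}
        dropped = []
        for gene in genes:
            chrom_len = genome.chrom_length(gene.chrom)
            window = make_window(
                gene, chrom_len, config.upstream, config.downstream, config.bin_width
            )
            if window.truncated_fraction > config.max_truncated_fraction:
                dropped.append(gene.gene_id)
                logger.warning(
                    "gene %s dropped: window %.0f%% truncated",
                    gene.gene_id, 100 * window.truncated_fraction,
                )
                continue
            for b in config.bases:
                profiles[b][gene.gene_id] = gene_bin_profile(
                    gene, index, b, chrom_len,
                    config.upstream, config.downstream, config.bin_width,
                    config.strand_mode,
                )
        rows = []
        for b in config.bases:
            for gid, prof in profiles[b].items():
                rows.append(
                    [gid, b, gene_window_density(prof)] + prof.bin_bp.tolist()
                )
        n_bins = (config.upstream + config.downstream) // config.bin_width
        pd.DataFrame(
            rows,
            columns=["gene_id", "base", "window_density_bp_per_mbp"]
            + [f"bin_{i + 1}" for i in range(n_bins)],
        ).to_csv(out / "gene_profiles.tsv", sep="\t", index=False)
        return profiles, dropped

    profiles, dropped_genes = do_profile()

    # --- compare -------------------------------------------------------------
    @_stage("compare")
    def do_compare():
        comparisons = []
        curves = []
        for exp_id, cls in ((config.experiment1_id, cls1), (config.experiment2_id, cls2)):
            for b in config.bases:
                by_class = densities_by_class(profiles[b], cls)
                for class_label in ("Dn", "Up"):
                    if len(by_class[class_label]) < 2 or len(by_class["Nu"]) < 2:
                        logger.warning(
                            "%s %s %s-vs-Nu skipped: <2 genes in a class",
                            exp_id, b, class_label,
                        )
                        continue
                    cmp_res = compare_classes(
                        by_class[class_label], by_class["Nu"],
                        base=b, contrast=f"{class_label}-vs-Nu",
                    )
                    d = cmp_res.to_dict()
                    d["experiment"] = exp_id
                    comparisons.append(d)
                for class_label in ("Dn", "Nu", "Up"):
                    members = cls.genes_called(class_label)
                    profs = [profiles[b][g] for g in sorted(members) if g in profiles[b]]
                    if not profs:
                        continue
                    dp = group_density_profile(profs, class_label)
                    for i, dens in enumerate(dp.density):
                        curves.append((exp_id, b, class_label, i + 1, dens))
        pd.DataFrame(
            curves, columns=["experiment", "base", "class", "bin", "density_bp_per_mbp"]
        ).to_csv(out / "group_density_profiles.tsv", sep="\t", index=False)
        with open(out / "density_comparisons.json", "w") as fh:
            json.dump(comparisons, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return comparisons

    comparisons = do_compare()

    # --- report -----------------------------------------------------------
    report = {
        "tool": {"name": "repeatdensity", "version": __version__},
        "config": config.to_dict(),
        "counts": {
            "chromosomes": len(genome),
            "genes": len(genes),
            "genes_dropped_truncated": len(dropped_genes),
            "runs_by_base": n_runs,
            "classification": {
                config.experiment1_id: cls1.counts(),
                config.experiment2_id: cls2.counts(),
            },
            "intersection": {
                d: {
                    "overlap": res.overlap,
                    "n_experiment1": res.n_experiment1,
                    "n_experiment2": res.n_experiment2,
                    "universe": res.universe_size,
                    "overlap_p_value": res.p_value,
                    "filtered_at_p_cut": len(filtered),
                }
                for d, (res, filtered) in intersections.items()
            },
        },
        "density_comparisons": comparisons,
    }
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name not in ("report.json", "report.txt") and f.is_file():
            manifest[f.name] = _sha256(f)
    report["manifest"] = manifest
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = [
        f"repeatdensity {report['tool']['version']} — run report",
        f"generated {report['timestamp']}",
        "",
        "counts:",
    ]
    c = report["counts"]
    lines.append(f"  chromosomes: {c['chromosomes']}  genes: {c['genes']}"
                 f"  (dropped truncated: {c['genes_dropped_truncated']})")
    lines.append(f"  repeat runs by base: {c['runs_by_base']}")
    for exp, counts in c["classification"].items():
        lines.append(f"  {exp}: Up={counts['Up']}  Dn={counts['Dn']}  Nu={counts['Nu']}")
    for d, info in c["intersection"].items():
        lines.append(
            f"  intersection {d}: overlap={info['overlap']} "
            f"(exp1={info['n_experiment1']}, exp2={info['n_experiment2']}, "
            f"universe={info['universe']}); filtered at p_cut: {info['filtered_at_p_cut']}"
        )
    lines.append("")
    lines.append("density comparisons (per-gene window density, bp/Mbp):")
    for cmp_d in report["density_comparisons"]:
        lines.append(
            f"  {cmp_d['experiment']} {cmp_d['base']} {cmp_d['contrast']}: "
            f"mean={cmp_d['mean_class_bp_per_mbp']:.1f} vs Nu {cmp_d['mean_nu_bp_per_mbp']:.1f}, "
            f"t={cmp_d['t']:.3f}, p={cmp_d['p']:.3g} ({cmp_d['direction']})"
        )
    return "\n".join(lines) + "\n"
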