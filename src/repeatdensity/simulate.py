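"""Synthetic genomes, annotations, and expression matrices with known truth.

The generator emulates the study's inputs at desk scale: a genome in which
every homopolymer A/T run of scorable length is planted at a known place,
a one-TSS-per-gene annotation whose windows never overlap, and two
two-replicate-per-group log-intensity expression experiments with planted
up/down effects partially shared between them. Every random draw flows
from a single mandatory seed, and identical configs produce byte-identical
outputs.

Background homopolymers at or above the scanner's minimum length are
suppressed by breaking them during generation, so the planted truth table
is exhaustive; the generator re-scans its own output and refuses to return
a genome whose scan disagrees with the truth table.

Defaults reflect the emulated study design where it states one (two
replicates per group, 13–27 bp runs, 200 x 100 bp bins) and otherwise a
realistic desk-scale choice: ~5 scorable runs per 20 kb TSS window,
log2-scale intensities near 8 with replicate noise SD 0.25, and a planted
effect of 1 log2 unit (a two-fold change, 4x the noise SD).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RepeatDensityError
from .io import (
    ExpressionMatrix,
    GeneRecord,
    GenomeSequence,
    write_annotation_tsv,
    write_expression,
    write_fasta,
)
from .profile import assign_run_to_bins, make_window
from .scanner import RepeatRun, scan_genome

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the generator. ``seed`` is mandatory — no silent nondeterminism."""

    seed: int
    n_chroms: int = 2
    n_genes: int = 500
    class_sizes: tuple[int, int, int] = (50, 400, 50)  # (n_dn, n_nu, n_up)
    upstream: int = 10_000
    downstream: int = 10_000
    bin_width: int = 100
    min_len: int = 13
    max_len: int = 27
    gene_spacing: int | None = None  # default: window extent + 1000 bp
    strand_fraction_plus: float = 0.5
    background_runs_per_window: float = 5.0
    enrichment_factor: float = 1.0  # multiplies the Dn class's planted-run rate
    placement: str = "random"  # random | bin_aligned | straddle
    suppress_background: bool = True
    # expression
    n_replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    effect_size: float = 1.0  # log2 units; 4 x noise_sd by default
    shared_fraction: float = 0.8  # planted genes common to both experiments

    def __post_init__(self):
        problems = []
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.n_chroms < 1 or self.n_genes < 1:
            problems.append("n_chroms and n_genes must be positive")
        if len(self.class_sizes) != 3 or any(c < 0 for c in self.class_sizes):
            problems.append("class_sizes must be three non-negative counts (dn, nu, up)")
        elif sum(self.class_sizes) != self.n_genes:
            problems.append(
                f"class_sizes {tuple(self.class_sizes)} must sum to n_genes {self.n_genes}"
            )
        if self.enrichment_factor < 0:
            problems.append("enrichment_factor must be >= 0")
        if self.bin_width <= 0:
            problems.append("bin_width must be positive")
        elif self.upstream % self.bin_width or self.downstream % self.bin_width:
            problems.append("extents must be multiples of bin_width")
        if not 1 <= self.min_len <= self.max_len:
            problems.append("need 1 <= min_len <= max_len")
        if not 0 <= self.shared_fraction <= 1:
            problems.append("shared_fraction must be in [0, 1]")
        if not 0 <= self.strand_fraction_plus <= 1:
            problems.append("strand_fraction_plus must be in [0, 1]")
        if self.placement not in ("random", "bin_aligned", "straddle"):
            problems.append(f"unknown placement {self.placement!r}")
        if self.n_replicates < 2:
            problems.append("n_replicates must be >= 2 (t-test undefined below that)")
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            problems.append("noise_sd must be positive, baseline_sd non-negative")
        spacing = self.spacing
        if spacing < self.window_extent + 2:
            problems.append(
                f"gene_spacing {spacing} too small for window extent {self.window_extent}"
            )
        if problems:
            raise ConfigError(problems)

    @property
    def window_extent(self) -> int:
        return self.upstream + self.downstream

    @property
    def spacing(self) -> int:
        return self.gene_spacing if self.gene_spacing else self.window_extent + 1000

    @property
    def margin(self) -> int:
        return max(self.upstream, self.downstream) + 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_sizes"] = list(self.class_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError([f"unknown simulation key {k!r}" for k in sorted(unknown)])
        d = dict(d)
        if "class_sizes" in d:
            d["class_sizes"] = tuple(d["class_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedRun:
    chrom: str
    base: str
    start: int
    length: int
    gene_id: str
    bin_bp: tuple[tuple[int, int], ...]  # ((bin index, bp), ...) in transcription order


@dataclass
class SyntheticTruth:
    """Exhaustive record of everything the generator planted."""

    runs: list[PlantedRun] = field(default_factory=list)
    gene_classes: dict[str, str] = field(default_factory=dict)  # gene -> Dn/Nu/Up
    expression_effects: dict[str, dict[str, str]] = field(default_factory=dict)

    def runs_as_set(self) -> set[tuple]:
        return {(r.chrom, r.base, r.start, r.length) for r in self.runs}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "runs": [
                {
                    "chrom": r.chrom,
                    "base": r.base,
                    "start": r.start,
                    "length": r.length,
                    "gene_id": r.gene_id,
                    "bin_bp": [list(x) for x in r.bin_bp],
                }
                for r in self.runs
            ],
            "gene_classes": self.gene_classes,
            "expression_effects": self.expression_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        runs = [
            PlantedRun(
                chrom=r["chrom"],
                base=r["base"],
                start=r["start"],
                length=r["length"],
                gene_id=r["gene_id"],
                bin_bp=tuple(tuple(x) for x in r["bin_bp"]),
            )
            for r in payload["runs"]
        ]
        return cls(
            runs=runs,
            gene_classes=payload["gene_classes"],
            expression_effects=payload["expression_effects"],
        )


# ---------------------------------------------------------------------------
# Genome + annotation


def _break_long_runs(codes: np.ndarray, min_len: int, rng) -> None:
    """Destroy every A/T homopolymer of length >= min_len in place.

    Such runs occur at rate ~(1/4)^min_len per bp in i.i.d. sequence, so a
    byte-level seed search is far cheaper than materialising run arrays.
    """
    raw = codes.tobytes()
    n = len(raw)
    for code in (_BASE_CODES["A"], _BASE_CODES["T"]):
        byte = bytes([code])
        seed = byte * min_len
        i = raw.find(seed)
        while i != -1:
            s = i
            while s > 0 and raw[s - 1] == code:
                s -= 1
            e = i + min_len
            while e < n and raw[e] == code:
                e += 1
            breaks = np.arange(s + min_len - 1, e, min_len - 1)
            codes[breaks] = rng.choice([_BASE_CODES["C"], _BASE_CODES["G"]], size=len(breaks))
            i = raw.find(seed, e + 1)


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneRecord], SyntheticTruth]:
    """Emit a genome with planted maximal runs, a TSS annotation, and the truth.

    Genes sit on a regular grid with small jitter, windows disjoint; each
    gene's window receives Poisson(rate) planted runs, where the rate is
    ``background_runs_per_window`` times ``enrichment_factor`` for Dn-class
    genes. Planted runs get C/G flanking bases, so they are maximal by
    construction; a post-hoc rescan certifies the truth table.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_dn, n_nu, n_up = config.class_sizes
    labels = np.array(["Dn"] * n_dn + ["Nu"] * n_nu + ["Up"] * n_up, dtype=object)
    rng.shuffle(labels)

    per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    truth = SyntheticTruth()
    genes: list[GeneRecord] = []
    records: dict[str, str] = {}
    gene_no = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        length = 2 * config.margin + max(k, 1) * config.spacing
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        if config.suppress_background:
            _break_long_runs(codes, config.min_len, rng)
        for gi in range(k):
            gene_id = f"g{gene_no + 1:05d}"
            cls = str(labels[gene_no])
            gene_no += 1
            jitter = int(rng.integers(0, 200))
            tss = config.margin + gi * config.spacing + jitter
            strand = "+" if rng.random() < config.strand_fraction_plus else "-"
            if strand == "+":
                gene_end = tss + config.downstream
            else:
                gene_end = tss - config.downstream
            gene = GeneRecord(gene_id, chrom, strand, tss, gene_end)
            genes.append(gene)
            truth.gene_classes[gene_id] = cls
            _plant_runs_for_gene(codes, gene, cls, config, length, rng, truth)
        records[chrom] = _CODE_BASES[codes].tobytes().decode("ascii")

    genome = GenomeSequence(records)
    if config.suppress_background:
        _verify_truth(genome, config, truth)
    return genome, genes, truth


def _plant_runs_for_gene(codes, gene, cls, config, chrom_length, rng, truth) -> None:
    rate = config.background_runs_per_window
    if cls == "Dn":
        rate *= config.enrichment_factor
    n_runs = int(rng.poisson(rate))
    if gene.strand == "+":
        ws, we = gene.tss - config.upstream, gene.tss + config.downstream
    else:
        ws, we = gene.tss - config.downstream + 1, gene.tss + config.upstream + 1
    window = make_window(
        gene, chrom_length, config.upstream, config.downstream, config.bin_width
    )
    occupied: list[tuple[int, int]] = []
    n_bins = window.n_bins
    for _ in range(n_runs):
        run_len = int(rng.integers(config.min_len, config.max_len + 1))
        base = "A" if rng.random() < 0.5 else "T"
        pos = None
        for _attempt in range(50):
            if config.placement == "bin_aligned":
                b = int(rng.integers(0, n_bins))
                cand = ws + b * config.bin_width
            elif config.placement == "straddle":
                b = int(rng.integers(1, n_bins))
                cand = ws + b * config.bin_width - run_len // 2
            else:
                cand = int(rng.integers(ws, we - run_len + 1))
            if cand < 1 or cand + run_len > chrom_length - 1:
                continue
            if cand < ws or cand + run_len > we:
                continue
            lo, hi = cand - 1, cand + run_len + 1
            if any(lo < o_hi and hi > o_lo for o_lo, o_hi in occupied):
                continue
            pos = cand
            break
        if pos is None:
            continue  # window too crowded; truth stays exhaustive
        occupied.append((pos - 1, pos + run_len + 1))
        codes[pos : pos + run_len] = _BASE_CODES[base]
        codes[pos - 1] = rng.choice([_BASE_CODES["C"], _BASE_CODES["G"]])
        codes[pos + run_len] = rng.choice([_BASE_CODES["C"], _BASE_CODES["G"]])
        run = RepeatRun(base=base, start=pos, length=run_len, chrom=gene.chrom)
        bins = assign_run_to_bins(run, window)
        truth.runs.append(
            PlantedRun(
                chrom=gene.chrom,
                base=base,
                start=pos,
                length=run_len,
                gene_id=gene.gene_id,
                bin_bp=tuple(sorted(bins.items())),
            )
        )


def _verify_truth(genome, config, truth) -> None:
    """Self-check: the scan of the emitted genome must equal the truth table."""
    index = scan_genome(genome, ("A", "T"), config.min_len, config.max_len)
    scanned = {(r.chrom, r.base, r.start, r.length) for r in index.all_runs()}
    planted = truth.runs_as_set()
    if scanned != planted:
        extra = list(scanned - planted)[:3]
        missing = list(planted - scanned)[:3]
        raise RepeatDensityError(
            f"generator self-check failed: {len(scanned - planted)} unplanted "
            f"run(s) (e.g. {extra}) and {len(planted - scanned)} lost planted "
            f"run(s) (e.g. {missing})"
        )


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two log-scale expression experiments with planted effects.

    Experiment 1's planted directions follow the gene classes in ``truth``
    (Dn -> down, Up -> up). Experiment 2 keeps ``shared_fraction`` of each
    planted set and replaces the remainder with previously-null genes, so
    the cross-experiment intersection has a known expected membership.
    Null genes have test and control drawn from the same normal; planted
    genes have the test mean shifted by ±effect_size. Updates
    ``truth.expression_effects`` in place.
    """
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = list(truth.gene_classes)
    eff1 = {
        g: ("down" if c == "Dn" else "up")
        for g, c in truth.gene_classes.items()
        if c in ("Dn", "Up")
    }
    null_pool = [g for g in gene_ids if g not in eff1]
    rng.shuffle(null_pool)
    eff2: dict[str, str] = {}
    taken = 0
    for direction in ("down", "up"):
        members = [g for g in gene_ids if eff1.get(g) == direction]
        n_keep = int(round(config.shared_fraction * len(members)))
        kept = list(rng.choice(members, size=n_keep, replace=False)) if n_keep else []
        fresh = null_pool[taken : taken + len(members) - n_keep]
        taken += len(members) - n_keep
        for g in kept + fresh:
            eff2[g] = direction
    truth.expression_effects = {"experiment1": eff1, "experiment2": eff2}

    matrices = []
    for effects in (eff1, eff2):
        mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(gene_ids))
        shift = np.array(
            [
                config.effect_size * (1 if effects.get(g) == "up" else -1 if effects.get(g) == "down" else 0)
                for g in gene_ids
            ]
        )
        n = config.n_replicates
        test = (
            mu[:, None]
            + shift[:, None]
            + rng.normal(0, config.noise_sd, size=(len(gene_ids), n))
        )
        control = mu[:, None] + rng.normal(0, config.noise_sd, size=(len(gene_ids), n))
        cols = [f"test_rep{i + 1}" for i in range(n)] + [
            f"control_rep{i + 1}" for i in range(n)
        ]
        values = pd.DataFrame(
            np.hstack([test, control]),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=cols,
        )
        groups = {c: ("test" if c.startswith("test") else "control") for c in cols}
        matrices.append(ExpressionMatrix(values=values, group_of=groups))
    return matrices[0], matrices[1]


# ---------------------------------------------------------------------------
# Fixture bundles


def emit_fixture_bundle(
    config: SimulationConfig, out_dir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a self-contained directory the pipeline can consume end-to-end.

    Contents: genome.fa, genes.tsv, expr1.tsv, expr2.tsv, groups.yaml,
    truth.json, sim_config.yaml and a ready-made run_config.yaml with the
    simulation's window and scan parameters.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigError(
            [f"output directory {out} exists and is not empty (use force)"]
        )
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome_and_annotation(config)
    em1, em2 = generate_expression(config, truth)

    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fa"), ("annotation", "genes.tsv"),
        ("expr1", "expr1.tsv"), ("expr2", "expr2.tsv"),
        ("groups", "groups.yaml"), ("truth", "truth.json"),
        ("sim_config", "sim_config.yaml"), ("run_config", "run_config.yaml"),
    ]}
    write_fasta(genome, paths["genome"])
    write_annotation_tsv(genes, paths["annotation"])
    write_expression(em1, paths["expr1"])
    write_expression(em2, paths["expr2"])
    groups = {
        "expr1": em1.group_of,
        "expr2": em2.group_of,
    }
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump(groups, fh, sort_keys=True)
    truth.to_json(paths["truth"])
    with open(paths["sim_config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    run_cfg = {
        "genome": "genome.fa",
        "annotation": "genes.tsv",
        "expr1": "expr1.tsv",
        "expr2": "expr2.tsv",
        "groups": "groups.yaml",
        "min_len": config.min_len,
        "max_len": config.max_len,
        "upstream": config.upstream,
        "downstream": config.downstream,
        "bin_width": config.bin_width,
        "alpha": 0.05,
        "p_cut": 0.05,
    }
    with open(paths["run_config"], "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return paths
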