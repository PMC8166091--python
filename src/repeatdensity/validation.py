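"""Simulation studies that certify the pipeline's statistical behaviour.

Three replicated studies, each run entirely through the public pipeline
surface (generate -> scan -> profile -> compare / classify):

* null calibration — random class labels on a homogeneous genome must make
  the class-vs-neutral t-test fire at ~alpha;
* planted-enrichment recovery — doubling the planted repeat rate of the
  down-regulated class must be detected as an increase at small p;
* expression-classifier calibration — pure-null matrices must yield ~alpha
  Up+Dn calls, and planted four-noise-SD effects must be recovered at a
  stable sensitivity despite only two replicates per group (df = 2).

Study problem sizes default to desk scale: the null calibration uses 40 x
100 bp windows (2 kb either side of the TSS) since calibration is geometry-
free, while enrichment recovery keeps the full 200-bin window.
"""

from __future__ import annotations

import numpy as np

from .compare import compare_classes
from .expression import classify_genes
from .profile import gene_bin_profile, gene_window_density
from .scanner import scan_genome
from .simulate import SimulationConfig, SyntheticTruth, generate_expression, generate_genome_and_annotation


def _subseed(seed: int, k: int) -> int:
    return (seed * 100_003 + k) % (2**31 - 1)


def _class_densities(cfg: SimulationConfig, base: str = "T"):
    """One generate->scan->profile pass; per-gene window densities by class."""
    genome, genes, truth = generate_genome_and_annotation(cfg)
    index = scan_genome(genome, ("A", "T"), cfg.min_len, cfg.max_len)
    out: dict[str, list[float]] = {"Dn": [], "Nu": [], "Up": []}
    for gene in genes:
        prof = gene_bin_profile(
            gene, index, base, genome.chrom_length(gene.chrom),
            cfg.upstream, cfg.downstream, cfg.bin_width,
        )
        out[truth.gene_classes[gene.gene_id]].append(gene_window_density(prof))
    return out


def null_calibration_study(
    seed: int,
    n_replicates: int = 200,
    n_genes: int = 300,
    n_class: int = 60,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicates whose class-vs-Nu p-value is <= alpha under the null.

    Every replicate draws a fresh homogeneous genome (enrichment factor 1,
    so the shuffled Dn/Nu labels are pure random labels) and compares the
    'Dn' genes' T-repeat densities against the 'Nu' genes'.
    """
    hits = 0
    pvalues = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=_subseed(seed, i), n_chroms=1,
            n_genes=n_genes, class_sizes=(n_class, n_genes - n_class, 0),
            upstream=2000, downstream=2000, bin_width=100, gene_spacing=4200,
            background_runs_per_window=5.0, enrichment_factor=1.0,
        )
        by_class = _class_densities(cfg)
        res = compare_classes(by_class["Dn"], by_class["Nu"], "T", "Dn-vs-Nu")
        pvalues.append(res.p_value)
        hits += res.p_value <= alpha
    return {
        "fraction_significant": hits / n_replicates,
        "n_replicates": n_replicates,
        "pvalues": pvalues,
    }


def enrichment_recovery_study(
    seed: int,
    n_replicates: int = 50,
    n_dn: int = 300,
    n_nu: int = 1500,
    enrichment_factor: float = 2.0,
    p_threshold: float = 1e-3,
) -> dict:
    """How often a doubled Dn-class repeat rate is detected as 'increased'.

    Full 200 x 100 bp window geometry; per replicate one t-test of the Dn
    genes' T-repeat window densities against the Nu genes'.
    """
    recovered = 0
    ratios = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            seed=_subseed(seed, 10_000 + i), n_chroms=1,
            n_genes=n_dn + n_nu, class_sizes=(n_dn, n_nu, 0),
            enrichment_factor=enrichment_factor,
        )
        by_class = _class_densities(cfg)
        res = compare_classes(by_class["Dn"], by_class["Nu"], "T", "Dn-vs-Nu")
        if res.direction == "increased" and res.p_value <= p_threshold:
            recovered += 1
        if res.mean_nu > 0:
            ratios.append(res.mean_class / res.mean_nu)
    return {
        "recovery_rate": recovered / n_replicates,
        "mean_density_ratio": float(np.mean(ratios)),
        "n_replicates": n_replicates,
    }


def _truth_for(cfg: SimulationConfig) -> SyntheticTruth:
    n_dn, n_nu, n_up = cfg.class_sizes
    classes = ["Dn"] * n_dn + ["Nu"] * n_nu + ["Up"] * n_up
    return SyntheticTruth(
        gene_classes={f"g{i:05d}": c for i, c in enumerate(classes)}
    )


def expression_calibration_study(
    seed: int,
    n_null_replicates: int = 100,
    n_planted_replicates: int = 30,
    n_genes: int = 400,
    alpha: float = 0.05,
) -> dict:
    """Null call rate and planted-effect sensitivity of the gene classifier.

    Null part: matrices with no planted effects; the Up+Dn fraction should
    sit at ~alpha. Planted part: 50 down + 50 up genes with the default
    4-noise-SD effect; sensitivity is the fraction of planted genes called
    with the correct direction at alpha.
    """
    null_calls = 0
    for i in range(n_null_replicates):
        cfg = SimulationConfig(
            seed=_subseed(seed, 20_000 + i),
            n_genes=n_genes, class_sizes=(0, n_genes, 0),
        )
        em, _ = generate_expression(cfg, _truth_for(cfg))
        counts = classify_genes(em, alpha).counts()
        null_calls += counts["Up"] + counts["Dn"]
    null_rate = null_calls / (n_null_replicates * n_genes)

    hit = total = 0
    for i in range(n_planted_replicates):
        cfg = SimulationConfig(
            seed=_subseed(seed, 30_000 + i),
            n_genes=n_genes, class_sizes=(50, n_genes - 100, 50),
        )
        truth = _truth_for(cfg)
        em, _ = generate_expression(cfg, truth)
        cls = classify_genes(em, alpha)
        for g, d in truth.expression_effects["experiment1"].items():
            total += 1
            hit += cls.calls[g] == ("Dn" if d == "down" else "Up")
    return {
        "null_call_rate": null_rate,
        "sensitivity": hit / total,
        "n_null_replicates": n_null_replicates,
        "n_planted_replicates": n_planted_replicates,
    }
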