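"""TSS-anchored bin windows, proportional repeat assignment, and densities.

Each gene gets a window of ``n_bins`` contiguous bins of ``bin_width`` bp
anchored at its TSS, indexed 1..n_bins in transcription direction: with
the defaults (10 kb upstream, 10 kb downstream, 100 bp bins) that is 200
bins, of which bins 1–100 cover exactly the 10,000 bp upstream of the TSS
and bins 101–200 a 10,000 bp intragenic stretch. Repeat base pairs are
assigned to bins positionwise, so a run straddling a bin boundary
contributes to each bin exactly the number of its bases falling in that
bin (proportional assignment); base pairs outside the window are dropped.

Densities are reported in bp/Mbp: 1e6 x (repeat bp) / (surveyed bp), with
the denominator reduced where a window is truncated by a chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RepeatDensityError, ValidationError
from .io import GeneRecord
from .scanner import COMPLEMENT, RepeatIndex, RepeatRun

DEFAULT_UPSTREAM = 10_000
DEFAULT_DOWNSTREAM = 10_000
DEFAULT_BIN_WIDTH = 100


@dataclass
class TssWindow:
    """Bin geometry around one TSS, in reference coordinates.

    ``bin_starts``/``bin_ends`` are 0-based half-open intervals, clipped at
    chromosome boundaries, listed in transcription order (bin 1 farthest
    upstream). ``covered_bp`` is the clipped width of each bin.
    """

    gene_id: str
    chrom: str
    strand: str
    bin_width: int
    upstream_extent: int
    downstream_extent: int
    bin_starts: np.ndarray
    bin_ends: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    @property
    def covered_bp(self) -> np.ndarray:
        return self.bin_ends - self.bin_starts

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval [start, end) covered by the clipped window."""
        cov = self.covered_bp
        if not cov.any():
            return (0, 0)
        nz = np.flatnonzero(cov)
        return int(self.bin_starts[nz].min()), int(self.bin_ends[nz].max())

    @property
    def truncated_fraction(self) -> float:
        total = self.n_bins * self.bin_width
        return 1.0 - float(self.covered_bp.sum()) / total


@dataclass
class BinProfile:
    """Per-gene repeat bp per bin (transcription order) plus surveyed bp."""

    gene_id: str
    base: str
    bin_bp: np.ndarray
    covered_bp: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_bp)


@dataclass
class DensityProfile:
    """Pooled per-bin density for a group of genes, bp/Mbp."""

    group_label: str
    base: str
    n_genes: int
    density: np.ndarray
    mean_window_density: float


def make_window(
    gene: GeneRecord,
    chrom_length: int,
    upstream_extent: int = DEFAULT_UPSTREAM,
    downstream_extent: int = DEFAULT_DOWNSTREAM,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> TssWindow:
    """Build the TSS window for one gene.

    Plus strand: reference span [tss - upstream, tss + downstream), bins
    numbered left to right. Minus strand: span [tss - downstream + 1,
    tss + upstream + 1), bins numbered right to left so bin 1 is again
    farthest upstream in transcription direction. Bins are clipped at
    chromosome boundaries.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    for name, extent in (("upstream", upstream_extent), ("downstream", downstream_extent)):
        if extent <= 0 or extent % bin_width:
            raise ValidationError(
                f"{name} extent {extent} must be a positive multiple of "
                f"bin_width {bin_width}"
            )
    n_bins = (upstream_extent + downstream_extent) // bin_width
    idx = np.arange(n_bins, dtype=np.int64)
    if gene.strand == "+":
        w_start = gene.tss - upstream_extent
        starts = w_start + idx * bin_width
        ends = starts + bin_width
    else:
        w_end = gene.tss + upstream_extent + 1
        ends = w_end - idx * bin_width
        starts = ends - bin_width
    starts = np.clip(starts, 0, chrom_length)
    ends = np.clip(ends, 0, chrom_length)
    return TssWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        bin_width=bin_width,
        upstream_extent=upstream_extent,
        downstream_extent=downstream_extent,
        bin_starts=starts,
        bin_ends=ends,
    )


def assign_run_to_bins(run: RepeatRun, window: TssWindow) -> dict[int, int]:
    """Positionwise split of a run's base pairs over the window's bins.

    Returns a sparse map {1-based bin index: bp}. The values sum to the
    overlap between the run and the (clipped) window; a zero-overlap run
    yields an empty map.
    """
    if run.chrom is not None and run.chrom != window.chrom:
        raise ValidationError(
            f"run on {run.chrom!r} assigned to window on {window.chrom!r}"
        )
    ov = np.minimum(window.bin_ends, run.end) - np.maximum(window.bin_starts, run.start)
    hit = np.flatnonzero(ov > 0)
    return {int(i) + 1: int(ov[i]) for i in hit}


def gene_bin_profile(
    gene: GeneRecord,
    index: RepeatIndex,
    base: str,
    chrom_length: int,
    upstream_extent: int = DEFAULT_UPSTREAM,
    downstream_extent: int = DEFAULT_DOWNSTREAM,
    bin_width: int = DEFAULT_BIN_WIDTH,
    strand_mode: str = "sense",
) -> BinProfile:
    """Per-bin repeat bp for one gene, using the length filter baked into ``index``.

    ``strand_mode='sense'`` (default) reports the base as read on the
    gene's own strand: for a minus-strand gene the A profile is computed
    from reference-strand T runs, and vice versa. ``'reference'`` counts
    the literal reference-strand base for every gene.
    """
    if strand_mode not in ("sense", "reference"):
        raise ValidationError(f"strand_mode must be 'sense' or 'reference', got {strand_mode!r}")
    if gene.chrom not in index.runs:
        raise RepeatDensityError(
            f"gene {gene.gene_id!r}: chromosome {gene.chrom!r} absent from repeat index"
        )
    window = make_window(
        gene, chrom_length, upstream_extent, downstream_extent, bin_width
    )
    ref_base = base
    if strand_mode == "sense" and gene.strand == "-":
        ref_base = COMPLEMENT[base]
    bin_bp = np.zeros(window.n_bins, dtype=float)
    span = window.span
    if span[1] > span[0]:
        for run in index.query(window.chrom, ref_base, span[0], span[1]):
            for bin_idx, bp in assign_run_to_bins(run, window).items():
                bin_bp[bin_idx - 1] += bp
    return BinProfile(
        gene_id=gene.gene_id,
        base=base,
        bin_bp=bin_bp,
        covered_bp=window.covered_bp.astype(float),
    )


def gene_window_density(profile: BinProfile) -> float:
    """Whole-window repeat density for one gene, bp/Mbp."""
    covered = float(profile.covered_bp.sum())
    if covered <= 0:
        raise ValidationError(
            f"gene {profile.gene_id!r}: window has zero covered bp; drop it upstream"
        )
    return 1e6 * float(profile.bin_bp.sum()) / covered


def group_density_profile(profiles: list[BinProfile], label: str) -> DensityProfile:
    """Pool a group of per-gene profiles into one per-bin density curve.

    density[i] = 1e6 * sum_genes bin_bp[i] / sum_genes covered_bp[i];
    ``mean_window_density`` is the mean over genes of each gene's
    whole-window density.
    """
    if not profiles:
        raise ValidationError(f"group {label!r}: no profiles")
    base = profiles[0].base
    n_bins = profiles[0].n_bins
    for p in profiles:
        if p.base != base or p.n_bins != n_bins:
            raise ValidationError(
                f"group {label!r}: mixed profile geometry or base "
                f"({p.gene_id!r} vs {profiles[0].gene_id!r})"
            )
    bp = np.sum([p.bin_bp for p in profiles], axis=0)
    cov = np.sum([p.covered_bp for p in profiles], axis=0)
    if (cov <= 0).any():
        raise ValidationError(f"group {label!r}: a bin has zero pooled coverage")
    density = 1e6 * bp / cov
    mean_density = float(np.mean([gene_window_density(p) for p in profiles]))
    return DensityProfile(
        group_label=label,
        base=base,
        n_genes=len(profiles),
        density=density,
        mean_window_density=mean_density,
    )
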