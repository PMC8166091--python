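import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import minus_gene, plus_gene
from repeatdensity import (
    BinProfile,
    GeneRecord,
    GenomeSequence,
    RepeatDensityError,
    RepeatRun,
    ValidationError,
    assign_run_to_bins,
    gene_bin_profile,
    gene_window_density,
    group_density_profile,
    make_window,
    scan_genome,
)
from repeatdensity.scanner import reverse_complement

CHROM_LEN = 1_000_000


class TestMakeWindow:
    def test_default_geometry_plus_strand(self):
        w = make_window(plus_gene(50_000), CHROM_LEN)
        assert w.n_bins == 200
        assert (w.covered_bp == 100).all()
        # bins 1-100 jointly cover exactly the 10 kb upstream of the TSS
        up = slice(0, 100)
        assert w.bin_starts[up].min() == 40_000
        assert w.bin_ends[up].max() == 50_000
        assert w.covered_bp[up].sum() == 10_000

    def test_minus_strand_mirror(self):
        w = make_window(minus_gene(50_000), CHROM_LEN)
        up = slice(0, 100)
        # upstream of a minus-strand gene lies right of the TSS: (50000, 60000]
        assert w.bin_starts[up].min() == 50_001
        assert w.bin_ends[up].max() == 60_001
        assert w.bin_starts[0] == 59_901  # bin 1 farthest upstream

    def test_boundary_truncation(self):
        w = make_window(plus_gene(500), CHROM_LEN)
        assert w.covered_bp[:100].sum() == 500
        assert w.covered_bp[100:].sum() == 10_000

    def test_indivisible_extent_rejected(self):
        with pytest.raises(ValidationError, match="multiple of bin_width"):
            make_window(plus_gene(50_000), CHROM_LEN, upstream_extent=10_050)

    def test_truncated_fraction(self):
        w = make_window(plus_gene(500), CHROM_LEN)
        assert w.truncated_fraction == pytest.approx(9_500 / 20_000)


class TestAssignRunToBins:
    def test_worked_sum_of_fully_contained_runs(self):
        """Three runs of 12, 13 and 15 bp inside one bin sum to 40 bp."""
        w = make_window(plus_gene(50_000), CHROM_LEN)
        b0 = int(w.bin_starts[41])  # an arbitrary bin, fully inside
        total = {}
        for offset, length in ((0, 12), (20, 13), (40, 15)):
            run = RepeatRun(base="A", start=b0 + offset, length=length, chrom="chr1")
            for i, bp in assign_run_to_bins(run, w).items():
                total[i] = total.get(i, 0) + bp
        assert total == {42: 40}

    def test_boundary_straddling_split(self):
        w = make_window(plus_gene(50_000), CHROM_LEN)
        # 20-bp run with 7 bp in bin 42, 13 bp in bin 43
        start = int(w.bin_ends[41]) - 7
        run = RepeatRun(base="A", start=start, length=20, chrom="chr1")
        assert assign_run_to_bins(run, w) == {42: 7, 43: 13}

    def test_run_outside_window_empty(self):
        w = make_window(plus_gene(50_000), CHROM_LEN)
        run = RepeatRun(base="A", start=500, length=20, chrom="chr1")
        assert assign_run_to_bins(run, w) == {}

    def test_wrong_chromosome_rejected(self):
        w = make_window(plus_gene(50_000), CHROM_LEN)
        with pytest.raises(ValidationError):
            assign_run_to_bins(RepeatRun(base="A", start=0, length=5, chrom="chr9"), w)

    @settings(derandomize=True, max_examples=300)
    @given(
        tss=st.integers(min_value=0, max_value=99_999),
        strand=st.sampled_from("+-"),
        start=st.integers(min_value=0, max_value=99_999),
        length=st.integers(min_value=1, max_value=40),
    )
    def test_conservation(self, tss, strand, start, length):
        """Per-bin assignments sum exactly to the run/window overlap."""
        gene = GeneRecord("g", "chr1", strand, tss, tss)
        w = make_window(gene, 100_000)
        run = RepeatRun(base="A", start=start, length=length, chrom="chr1")
        assigned = sum(assign_run_to_bins(run, w).values())
        lo, hi = w.span
        overlap = max(0, min(hi, run.end) - max(lo, run.start))
        assert assigned == overlap


def _genome_with_run(run_start, run_len, base="A", length=CHROM_LEN):
    seq = ["C"] * length
    seq[run_start : run_start + run_len] = [base] * run_len
    return GenomeSequence({"chr1": "".join(seq)})


class TestGeneBinProfile:
    def test_no_runs_gives_zero_profile(self):
        genome = GenomeSequence({"chr1": "CG" * 50_000})
        index = scan_genome(genome)
        prof = gene_bin_profile(plus_gene(50_000), index, "A", 100_000)
        assert prof.bin_bp.sum() == 0

    def test_planted_run_lands_in_expected_bin(self):
        # 15-bp A run fully inside bin 42 of a + gene with tss=50,000:
        # bin 42 covers [44100, 44200)
        genome = _genome_with_run(44_120, 15, length=100_000)
        index = scan_genome(genome)
        prof = gene_bin_profile(plus_gene(50_000), index, "A", 100_000)
        assert prof.bin_bp[41] == 15
        assert prof.bin_bp.sum() == 15

    def test_strand_mirror_of_same_locus(self):
        genome = _genome_with_run(44_120, 15, length=100_000)
        index = scan_genome(genome)
        plus = gene_bin_profile(plus_gene(50_000), index, "A", 100_000,
                                strand_mode="reference")
        minus = gene_bin_profile(
            GeneRecord("g1", "chr1", "-", 50_000, 40_000), index, "A", 100_000,
            strand_mode="reference",
        )
        # minus-strand window spans [40001, 60001): same run, mirrored bin order
        assert minus.bin_bp[::-1][41] == 15

    def test_sense_mode_swaps_base_for_minus_gene(self):
        genome = _genome_with_run(44_120, 15, base="T", length=100_000)
        index = scan_genome(genome)
        minus = gene_bin_profile(minus_gene(40_000), index, "A", 100_000)
        # the reference T run is an A run on the gene's sense strand
        assert minus.bin_bp.sum() == 15

    def test_missing_chromosome_rejected(self):
        genome = GenomeSequence({"chr1": "CG" * 500})
        index = scan_genome(genome)
        with pytest.raises(RepeatDensityError, match="absent"):
            gene_bin_profile(plus_gene(500, chrom="chrX"), index, "A", 1000)

    def test_strand_invariance_under_reverse_complement(self):
        """Reverse-complementing the genome and flipping strands leaves
        sense-strand profiles identical with A and T labels swapped."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=60_000))
        seq = seq[:20_000] + "A" * 15 + seq[20_015:30_000] + "T" * 14 + seq[30_014:]
        genome = GenomeSequence({"chr1": seq})
        n = len(seq)
        genome_rc = GenomeSequence({"chr1": reverse_complement(seq)})
        gene_fwd = GeneRecord("g", "chr1", "+", 25_000, 35_000)
        gene_rev = GeneRecord("g", "chr1", "-", n - 1 - 25_000, n - 1 - 35_000)
        idx_fwd, idx_rc = scan_genome(genome), scan_genome(genome_rc)
        for base, swapped in (("A", "T"), ("T", "A")):
            p1 = gene_bin_profile(gene_fwd, idx_fwd, base, n,
                                  upstream_extent=2000, downstream_extent=2000)
            p2 = gene_bin_profile(gene_rev, idx_rc, base, n,
                                  upstream_extent=2000, downstream_extent=2000)
            assert np.array_equal(p1.bin_bp, p2.bin_bp)


class TestDensities:
    def test_window_density_arithmetic(self):
        prof = BinProfile("g", "A", np.array([40.0] + [0.0] * 199),
                          np.full(200, 100.0))
        assert gene_window_density(prof) == pytest.approx(2_000.0)  # 40 bp / 20 kb

    def test_zero_profile_zero_density(self):
        prof = BinProfile("g", "A", np.zeros(200), np.full(200, 100.0))
        assert gene_window_density(prof) == 0.0

    def test_zero_coverage_rejected(self):
        prof = BinProfile("g", "A", np.zeros(2), np.zeros(2))
        with pytest.raises(ValidationError):
            gene_window_density(prof)

    def test_single_gene_group_equals_gene_density(self):
        prof = BinProfile("g", "A", np.arange(200.0), np.full(200, 100.0))
        dp = group_density_profile([prof], "Nu")
        assert np.allclose(dp.density, 1e6 * prof.bin_bp / prof.covered_bp)
        assert dp.mean_window_density == pytest.approx(gene_window_density(prof))

    def test_two_gene_pooled_formula(self):
        v = np.zeros(200); v[3] = 12.0
        w = np.zeros(200); w[3] = 8.0
        cov = np.full(200, 100.0)
        dp = group_density_profile(
            [BinProfile("a", "A", v, cov), BinProfile("b", "A", w, cov)], "Dn"
        )
        assert dp.density[3] == pytest.approx(1e6 * 20 / 200)

    def test_mixed_geometry_rejected(self):
        a = BinProfile("a", "A", np.zeros(200), np.full(200, 100.0))
        b = BinProfile("b", "A", np.zeros(100), np.full(100, 100.0))
        with pytest.raises(ValidationError, match="geometry"):
            group_density_profile([a, b], "Nu")

    def test_group_density_matches_brute_force_recount(self):
        """Pooled group density equals an end-to-end recount from raw runs."""
        from repeatdensity import SimulationConfig, generate_genome_and_annotation

        cfg = SimulationConfig(
            seed=17, n_chroms=1, n_genes=30, class_sizes=(6, 18, 6),
            upstream=2000, downstream=2000, bin_width=100, gene_spacing=4200,
            background_runs_per_window=4.0,
        )
        genome, genes, truth = generate_genome_and_annotation(cfg)
        index = scan_genome(genome, ("A", "T"), 13, 27)
        profs = [
            gene_bin_profile(g, index, "A", genome.chrom_length(g.chrom),
                             2000, 2000, 100, strand_mode="reference")
            for g in genes
        ]
        dp = group_density_profile(profs, "all")
        # brute force: count reference A-run bp per bin straight from the truth
        n_bins = 40
        bp = np.zeros(n_bins)
        by_gene = {g.gene_id: g for g in genes}
        for run in truth.runs:
            if run.base != "A":
                continue
            gene = by_gene[run.gene_id]
            for bin_idx, n in run.bin_bp:
                # truth bins are in transcription order already
                bp[bin_idx - 1] += n
        # reference-mode bins of minus genes are transcription-order too
        # (same window partition), so pooled totals agree after mirroring
        got = np.zeros(n_bins)
        for p in profs:
            got += p.bin_bp
        assert got.sum() == bp.sum()
        cov = np.sum([p.covered_bp for p in profs], axis=0)
        assert np.allclose(dp.density, 1e6 * got / cov)

    def test_density_linearity_in_run_content(self):
        v = np.zeros(200); v[7] = 15.0
        cov = np.full(200, 100.0)
        d1 = gene_window_density(BinProfile("a", "A", v, cov))
        d3 = gene_window_density(BinProfile("a", "A", 3 * v, cov))
        assert d3 == pytest.approx(3 * d1)
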