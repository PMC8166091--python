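import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_expression
from repeatdensity import (
    SimulationConfig,
    ValidationError,
    classify_genes,
    filter_by_pvalue,
    gene_ttest,
    generate_expression,
    generate_genome_and_annotation,
    intersect,
)
from repeatdensity.simulate import SyntheticTruth


class TestGeneTtest:
    def test_identical_groups_flat(self):
        m = make_expression({"g1": [5, 5, 5, 5]}, ["t1", "t2"], ["c1", "c2"])
        r = gene_ttest(m, "g1")
        assert (r.t_stat, r.p_value, r.direction) == (0.0, 1.0, "flat")

    def test_matches_scipy_student_ttest(self):
        m = make_expression({"g1": [2.0, 2.2, 1.0, 1.1]}, ["t1", "t2"], ["c1", "c2"])
        r = gene_ttest(m, "g1")
        t_ref, p_ref = sps.ttest_ind([2.0, 2.2], [1.0, 1.1], equal_var=True)
        assert r.t_stat == pytest.approx(t_ref, rel=1e-12)
        assert r.p_value == pytest.approx(p_ref, rel=1e-12)
        assert r.direction == "up" and r.df == 2

    def test_agrees_with_scipy_to_12_digits_on_random_input(self):
        rng = np.random.default_rng(7)
        for n1, n2 in ((2, 2), (3, 2), (4, 5)):
            for _ in range(50):
                x, y = rng.normal(size=n1), rng.normal(size=n2)
                m = make_expression(
                    {"g": np.concatenate([x, y])},
                    [f"t{i}" for i in range(n1)],
                    [f"c{i}" for i in range(n2)],
                )
                r = gene_ttest(m, "g")
                t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
                assert r.t_stat == pytest.approx(t_ref, rel=1e-12)
                assert r.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_label_swap_antisymmetry(self):
        vals = [2.0, 2.3, 1.0, 1.4]
        m = make_expression({"g": vals}, ["t1", "t2"], ["c1", "c2"])
        swapped = make_expression(
            {"g": vals[2:] + vals[:2]}, ["t1", "t2"], ["c1", "c2"]
        )
        r, rs = gene_ttest(m, "g"), gene_ttest(swapped, "g")
        assert rs.t_stat == pytest.approx(-r.t_stat)
        assert rs.p_value == pytest.approx(r.p_value)
        assert {r.direction, rs.direction} == {"up", "down"}

    def test_degenerate_zero_variance_unequal_means(self):
        m = make_expression({"g": [2.0, 2.0, 1.0, 1.0]}, ["t1", "t2"], ["c1", "c2"])
        r = gene_ttest(m, "g")
        assert r.p_value == 0.0 and np.isinf(r.t_stat) and r.direction == "up"

    def test_welch_variant(self):
        m = make_expression({"g": [2.0, 2.9, 1.0, 1.1]}, ["t1", "t2"], ["c1", "c2"])
        r = gene_ttest(m, "g", equal_var=False)
        t_ref, p_ref = sps.ttest_ind([2.0, 2.9], [1.0, 1.1], equal_var=False)
        assert r.t_stat == pytest.approx(t_ref, rel=1e-12)
        assert r.p_value == pytest.approx(p_ref, rel=1e-12)


class TestClassifyGenes:
    def test_partition_invariant(self, four_sample_matrix):
        cls = classify_genes(four_sample_matrix, 0.05)
        counts = cls.counts()
        assert sum(counts.values()) == len(four_sample_matrix.gene_ids)

    def test_threshold_inclusive_and_exclusive(self, four_sample_matrix):
        cls = classify_genes(four_sample_matrix, 0.05)
        for gid in four_sample_matrix.gene_ids:
            row = cls.table.loc[gid]
            if row["call"] == "Nu":
                assert row["p"] > 0.05 or row["direction"] == "flat"
            else:
                assert row["p"] <= 0.05
                assert (row["call"] == "Up") == (row["direction"] == "up")
        # calling at alpha exactly equal to some gene's p keeps that gene
        p_star = cls.table["p"].min()
        cls_at = classify_genes(four_sample_matrix, alpha=float(p_star))
        gid = cls.table["p"].idxmin()
        assert cls_at.table.loc[gid, "call"] in ("Up", "Dn")

    def test_alpha_monotonicity(self, four_sample_matrix):
        wide = classify_genes(four_sample_matrix, 0.2)
        narrow = classify_genes(four_sample_matrix, 0.01)
        for call in ("Up", "Dn"):
            assert narrow.genes_called(call) <= wide.genes_called(call)

    def test_null_matrix_calibration(self):
        """Under pure null, the Up+Dn fraction is ~alpha."""
        rng = np.random.default_rng(11)
        n_genes, reps = 400, 40
        frac = []
        for _ in range(reps):
            vals = {f"g{i}": rng.normal(8, 0.3, 4) for i in range(n_genes)}
            m = make_expression(vals, ["t1", "t2"], ["c1", "c2"])
            cls = classify_genes(m, 0.05)
            c = cls.counts()
            frac.append((c["Up"] + c["Dn"]) / n_genes)
        mean = np.mean(frac)
        se = np.sqrt(0.05 * 0.95 / (n_genes * reps))
        assert abs(mean - 0.05) < 5 * se

    def test_planted_effects_recovered(self):
        cfg = SimulationConfig(seed=23, n_genes=300, class_sizes=(40, 220, 40))
        truth = SyntheticTruth(
            gene_classes={f"g{i:05d}": c
                          for i, c in enumerate(["Dn"] * 40 + ["Nu"] * 220 + ["Up"] * 40)}
        )
        em1, _ = generate_expression(cfg, truth)
        cls = classify_genes(em1, 0.05, "e1")
        eff = truth.expression_effects["experiment1"]
        planted_dn = {g for g, d in eff.items() if d == "down"}
        recovered = cls.genes_called("Dn") & planted_dn
        # 4-sigma effects at 2 replicates: recovery well above the 5% null rate
        assert len(recovered) / len(planted_dn) > 0.25
        null_genes = [g for g in truth.gene_classes if g not in eff]
        null_called = sum(
            1 for g in null_genes if cls.calls[g] != "Nu"
        )
        assert null_called / len(null_genes) < 0.15


class TestIntersect:
    def _cls(self, experiment_id, calls, pvals=None):
        import pandas as pd

        genes = list(calls)
        table = pd.DataFrame(
            {
                "t": 0.0,
                "p": [pvals[g] if pvals else 0.01 for g in genes],
                "direction": ["down" if c == "Dn" else "up" if c == "Up" else "flat"
                              for c in calls.values()],
                "call": list(calls.values()),
                "df": 2.0,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        from repeatdensity import GeneClassification

        return GeneClassification(experiment_id, 0.05, table)

    def test_set_semantics(self):
        cls1 = self._cls("e1", {"a": "Dn", "b": "Dn", "c": "Dn", "d": "Nu"})
        cls2 = self._cls("e2", {"a": "Nu", "b": "Dn", "c": "Dn", "d": "Dn"})
        res = intersect(cls1, cls2, "Dn")
        assert res.genes == {"b", "c"} and res.overlap == 2
        assert (res.n_experiment1, res.n_experiment2) == (3, 3)

    def test_disjoint_sets_empty(self):
        cls1 = self._cls("e1", {"a": "Dn", "b": "Nu"})
        cls2 = self._cls("e2", {"a": "Nu", "b": "Dn"})
        res = intersect(cls1, cls2, "Dn")
        assert res.genes == set() and res.overlap == 0

    def test_empty_shared_universe_rejected(self):
        cls1 = self._cls("e1", {"a": "Dn"})
        cls2 = self._cls("e2", {"b": "Dn"})
        with pytest.raises(ValidationError, match="share no genes"):
            intersect(cls1, cls2, "Dn")

    def test_hypergeometric_overlap_matches_scipy(self):
        cls1 = self._cls("e1", {c: ("Dn" if c in "abc" else "Nu") for c in "abcdefgh"})
        cls2 = self._cls("e2", {c: ("Dn" if c in "bcd" else "Nu") for c in "abcdefgh"})
        res = intersect(cls1, cls2, "Dn")
        assert res.p_value == pytest.approx(sps.hypergeom.sf(res.overlap - 1, 8, 3, 3))

    def test_planted_shared_genes_recovered_in_intersection(self):
        cfg = SimulationConfig(seed=31, n_genes=300, class_sizes=(40, 220, 40),
                               shared_fraction=1.0, effect_size=2.0)
        genome_classes = {f"g{i:05d}": c
                         for i, c in enumerate(["Dn"] * 40 + ["Nu"] * 220 + ["Up"] * 40)}
        truth = SyntheticTruth(gene_classes=genome_classes)
        em1, em2 = generate_expression(cfg, truth)
        cls1 = classify_genes(em1, 0.05, "e1")
        cls2 = classify_genes(em2, 0.05, "e2")
        res = intersect(cls1, cls2, "Dn")
        planted = {g for g, d in truth.expression_effects["experiment1"].items()
                   if d == "down"}
        # every intersection member recovered from planted truth is genuine;
        # brute-force recount of the overlap agrees
        brute = cls1.genes_called("Dn") & cls2.genes_called("Dn")
        assert res.genes == brute
        assert len(res.genes & planted) >= 0.5 * len(planted)

    def test_filter_by_pvalue_both_experiment_rule(self):
        cls1 = self._cls("e1", {"a": "Dn", "b": "Dn"}, pvals={"a": 0.03, "b": 0.009})
        cls2 = self._cls("e2", {"a": "Dn", "b": "Dn"}, pvals={"a": 0.008, "b": 0.008})
        res = intersect(cls1, cls2, "Dn")
        assert filter_by_pvalue(res, cls1, cls2, 0.01) == ["b"]  # a fails exp1
        assert filter_by_pvalue(res, cls1, cls2, 0.05) == ["a", "b"]

    def test_filter_at_alpha_is_identity(self):
        cls1 = self._cls("e1", {"a": "Dn", "b": "Dn"}, pvals={"a": 0.03, "b": 0.049})
        cls2 = self._cls("e2", {"a": "Dn", "b": "Dn"}, pvals={"a": 0.02, "b": 0.04})
        res = intersect(cls1, cls2, "Dn")
        assert set(filter_by_pvalue(res, cls1, cls2, 0.05)) == res.genes

    def test_p_cut_above_alpha_rejected(self):
        cls1 = self._cls("e1", {"a": "Dn"})
        cls2 = self._cls("e2", {"a": "Dn"})
        res = intersect(cls1, cls2, "Dn")
        with pytest.raises(ValidationError):
            filter_by_pvalue(res, cls1, cls2, 0.2)

    def test_p_cut_monotonicity(self):
        rng = np.random.default_rng(13)
        pv = {f"g{i}": float(rng.uniform(0, 0.05)) for i in range(30)}
        calls = {g: "Dn" for g in pv}
        cls1 = self._cls("e1", calls, pvals=pv)
        pv2 = {g: float(rng.uniform(0, 0.05)) for g in pv}
        cls2 = self._cls("e2", calls, pvals=pv2)
        res = intersect(cls1, cls2, "Dn")
        sizes = [len(filter_by_pvalue(res, cls1, cls2, c)) for c in (0.05, 0.02, 0.01, 0.001)]
        assert sizes == sorted(sizes, reverse=True)
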