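"""Per-gene differential-expression calls and cross-experiment intersection.

Each gene is tested with a two-sided pooled-variance (Student's) t-test of
its test-group replicates against its control-group replicates, then
called Up (p <= alpha, test mean higher), Dn (p <= alpha, test mean
lower), or Nu (everything else). The three calls partition the gene
universe. Threshold comparisons are inclusive. With the study's two
replicates per group the test has 2 degrees of freedom; df is surfaced in
the output and no variance moderation or multiple-testing correction is
applied — Benjamini-Hochberg adjusted p-values can be emitted for
information only.

Two experiments' call sets are combined by plain set intersection per
direction; an optional hypergeometric overlap p-value quantifies whether
the overlap exceeds chance within the shared gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix
from .stats import hypergeom_overlap_pvalue, matrix_ttest

logger = logging.getLogger(__name__)

CALL_LABELS = ("Up", "Dn", "Nu")


@dataclass(frozen=True)
class GeneTestResult:
    gene_id: str
    t_stat: float
    p_value: float
    direction: str  # up / down / flat — sign of mean(test) - mean(control)
    df: float


@dataclass
class GeneClassification:
    """Up/Dn/Nu calls for one experiment, with the per-gene test table.

    ``table`` is indexed by gene_id with columns t, p, direction, call, df
    (and p_adj when requested).
    """

    experiment_id: str
    alpha: float
    table: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def calls(self) -> dict[str, str]:
        return self.table["call"].to_dict()

    def genes_called(self, call: str) -> set[str]:
        if call not in CALL_LABELS:
            raise ValidationError(f"call must be one of {CALL_LABELS}, got {call!r}")
        return set(self.table.index[self.table["call"] == call])

    def p_value(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "p"])

    def counts(self) -> dict[str, int]:
        return {c: int((self.table["call"] == c).sum()) for c in CALL_LABELS}


@dataclass
class IntersectionResult:
    """Genes called the same direction in both experiments."""

    direction: str  # 'Dn' or 'Up'
    genes: set[str]
    n_experiment1: int
    n_experiment2: int
    overlap: int
    universe_size: int
    p_value: float | None = None


def gene_ttest(matrix: ExpressionMatrix, gene_id: str, equal_var: bool = True) -> GeneTestResult:
    """Student's t-test of test vs control replicates for one gene."""
    if gene_id not in matrix.values.index:
        raise ValidationError(f"gene {gene_id!r} absent from expression matrix")
    row = matrix.values.loc[gene_id]
    x = row[matrix.test_samples].to_numpy(dtype=float)
    y = row[matrix.control_samples].to_numpy(dtype=float)
    t, p, df = matrix_ttest(x[None, :], y[None, :], equal_var=equal_var)
    return _result(gene_id, float(t[0]), float(p[0]), float(df[0]),
                   float(x.mean() - y.mean()))


def _result(gene_id, t, p, df, mean_diff) -> GeneTestResult:
    if mean_diff > 0:
        direction = "up"
    elif mean_diff < 0:
        direction = "down"
    else:
        direction = "flat"
    if np.isinf(t):
        logger.warning(
            "gene %s: zero pooled variance with unequal means (degenerate t-test)",
            gene_id,
        )
    return GeneTestResult(gene_id, t, p, direction, df)


def classify_genes(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    experiment_id: str = "experiment",
    equal_var: bool = True,
    adjust: bool = False,
) -> GeneClassification:
    """Call every gene Up/Dn/Nu at the inclusive threshold p <= alpha.

    ``adjust=True`` adds a Benjamini-Hochberg adjusted p column for
    information; calls always use the raw p-values.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    X = matrix.values[matrix.test_samples].to_numpy(dtype=float)
    Y = matrix.values[matrix.control_samples].to_numpy(dtype=float)
    t, p, df = matrix_ttest(X, Y, equal_var=equal_var)
    diff = X.mean(axis=1) - Y.mean(axis=1)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "flat"))
    call = np.full(len(t), "Nu", dtype=object)
    call[(p <= alpha) & (direction == "up")] = "Up"
    call[(p <= alpha) & (direction == "down")] = "Dn"
    table = pd.DataFrame(
        {"t": t, "p": p, "direction": direction, "call": call, "df": df},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    if adjust:
        table["p_adj"] = _benjamini_hochberg(p)
    n_degenerate = int(np.isinf(t).sum())
    if n_degenerate:
        logger.warning(
            "%s: %d gene(s) with zero pooled variance and unequal means",
            experiment_id,
            n_degenerate,
        )
    return GeneClassification(experiment_id=experiment_id, alpha=alpha, table=table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def intersect(
    cls1: GeneClassification,
    cls2: GeneClassification,
    direction: str,
    overlap_pvalue: bool = True,
) -> IntersectionResult:
    """Genes called ``direction`` ('Dn' or 'Up') in BOTH experiments.

    The shared universe is the intersection of the two gene sets; genes
    known to only one experiment are dropped with a warning.
    """
    if direction not in ("Dn", "Up"):
        raise ValidationError(f"direction must be 'Dn' or 'Up', got {direction!r}")
    u1, u2 = set(cls1.gene_ids), set(cls2.gene_ids)
    universe = u1 & u2
    if not universe:
        raise ValidationError("experiments share no genes; cannot intersect")
    dropped = (u1 | u2) - universe
    if dropped:
        logger.warning(
            "intersect: %d gene(s) present in only one experiment dropped",
            len(dropped),
        )
    set1 = cls1.genes_called(direction) & universe
    set2 = cls2.genes_called(direction) & universe
    genes = set1 & set2
    p = None
    if overlap_pvalue:
        p = hypergeom_overlap_pvalue(len(genes), len(set1), len(set2), len(universe))
    return IntersectionResult(
        direction=direction,
        genes=genes,
        n_experiment1=len(set1),
        n_experiment2=len(set2),
        overlap=len(genes),
        universe_size=len(universe),
        p_value=p,
    )


def filter_by_pvalue(
    result: IntersectionResult,
    cls1: GeneClassification,
    cls2: GeneClassification,
    p_cut: float,
) -> list[str]:
    """Intersection genes with p <= p_cut in BOTH experiments, sorted.

    ``p_cut`` must not exceed either classification's alpha — a looser cut
    could not have produced the intersection being filtered.
    """
    if p_cut > min(cls1.alpha, cls2.alpha):
        raise ValidationError(
            f"p_cut {p_cut} exceeds classification alpha "
            f"({cls1.alpha}, {cls2.alpha})"
        )
    return sorted(
        g for g in result.genes
        if cls1.p_value(g) <= p_cut and cls2.p_value(g) <= p_cut
    )
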