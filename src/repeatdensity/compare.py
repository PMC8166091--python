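"""Group-level repeat-density comparisons between expression classes.

The unit of observation is the gene: each gene contributes its
whole-window repeat density (bp/Mbp), and the Dn and Up classes are each
compared against the neutral (Nu) class with a two-sided Student's
pooled-variance t-test. An exploratory per-bin variant applies the same
test bin-wise with no multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import CALL_LABELS, GeneClassification
from .profile import BinProfile, gene_window_density
from .stats import matrix_ttest, pooled_ttest

logger = logging.getLogger(__name__)


@dataclass
class DensityComparison:
    """One class-vs-neutral test on per-gene window densities."""

    base: str
    contrast: str  # 'Dn-vs-Nu' or 'Up-vs-Nu'
    n_class: int
    n_nu: int
    mean_class: float  # bp/Mbp
    mean_nu: float  # bp/Mbp
    t_stat: float
    p_value: float
    df: float
    direction: str  # 'increased' / 'reduced' relative to Nu

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "contrast": self.contrast,
            "n_class": self.n_class,
            "n_nu": self.n_nu,
            "mean_class_bp_per_mbp": self.mean_class,
            "mean_nu_bp_per_mbp": self.mean_nu,
            "t": self.t_stat,
            "p": self.p_value,
            "df": self.df,
            "direction": self.direction,
        }


def densities_by_class(
    profiles: Mapping[str, BinProfile],
    classification: GeneClassification,
) -> dict[str, np.ndarray]:
    """Per-gene window densities split by Up/Dn/Nu call.

    Classified genes lacking a profile are dropped with a warning (e.g.
    windows discarded for chromosome-end truncation).
    """
    values: dict[str, list[float]] = {c: [] for c in CALL_LABELS}
    missing = 0
    for gene_id, call in classification.calls.items():
        prof = profiles.get(gene_id)
        if prof is None:
            missing += 1
            continue
        values[call].append(gene_window_density(prof))
    if missing:
        logger.warning(
            "%s: %d classified gene(s) without a profile dropped",
            classification.experiment_id,
            missing,
        )
    return {c: np.asarray(v, dtype=float) for c, v in values.items()}


def compare_classes(
    values_class,
    values_nu,
    base: str = "",
    contrast: str = "class-vs-Nu",
    equal_var: bool = True,
) -> DensityComparison:
    """Student's t-test of one class's densities against the neutral class's."""
    x = np.asarray(values_class, dtype=float)
    y = np.asarray(values_nu, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"{contrast}: need >=2 genes per side, got {len(x)} and {len(y)}"
        )
    t, p, df = pooled_ttest(x, y, equal_var=equal_var)
    return DensityComparison(
        base=base,
        contrast=contrast,
        n_class=len(x),
        n_nu=len(y),
        mean_class=float(x.mean()),
        mean_nu=float(y.mean()),
        t_stat=t,
        p_value=p,
        df=df,
        direction="increased" if x.mean() >= y.mean() else "reduced",
    )


def per_bin_comparison(
    profiles: Mapping[str, BinProfile],
    classification: GeneClassification,
    base: str,
    class_label: str = "Dn",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Exploratory bin-wise class-vs-Nu tests (no multiplicity correction).

    Per-gene per-bin densities are 1e6 * bin_bp / covered_bp; bins a gene
    does not cover (chromosome-end truncation) are excluded gene-wise.
    Returns one row per bin: bin, mean_class, mean_nu, t, p.
    """
    if class_label not in ("Dn", "Up"):
        raise ValidationError(f"class_label must be 'Dn' or 'Up', got {class_label!r}")

    def _stack(genes):
        mats = []
        for g in genes:
            prof = profiles.get(g)
            if prof is None:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(prof.covered_bp > 0, 1e6 * prof.bin_bp / prof.covered_bp, np.nan)
            mats.append(d)
        return np.asarray(mats, dtype=float)

    X = _stack(sorted(classification.genes_called(class_label)))
    Y = _stack(sorted(classification.genes_called("Nu")))
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValidationError(
            f"per-bin comparison needs >=2 genes per side "
            f"(got {X.shape[0]} {class_label}, {Y.shape[0]} Nu)"
        )
    n_bins = X.shape[1]
    rows = []
    for i in range(n_bins):
        x = X[:, i][~np.isnan(X[:, i])]
        y = Y[:, i][~np.isnan(Y[:, i])]
        if len(x) < 2 or len(y) < 2:
            rows.append((i + 1, np.nan, np.nan, np.nan, np.nan))
            continue
        t, p, _ = pooled_ttest(x, y, equal_var=equal_var)
        rows.append((i + 1, float(x.mean()), float(y.mean()), t, p))
    return pd.DataFrame(rows, columns=["bin", "mean_class", "mean_nu", "t", "p"])


def plot_density_profiles(density_profiles, path, title: str | None = None):
    """QC plot of per-bin group density curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for dp in density_profiles:
        n = len(dp.density)
        ax.plot(np.arange(1, n + 1), dp.density,
                label=f"{dp.group_label} ({dp.base}, n={dp.n_genes})")
        ax.axvline(n / 2 + 0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("bin (transcription direction; TSS at centre)")
    ax.set_ylabel("repeat density (bp/Mbp)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
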