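"""Comparative-Ct (2^-ddCt) quantification of miRNA expression.

Implements the Livak comparative-Ct arithmetic used for tissue contrasts:
technical replicates are averaged on the Ct scale, each gene is normalized
to a reference small RNA (U6 by default) within each tissue
(dCt = Ct_gene - Ct_ref), the test tissue is referenced to the calibrator
tissue (ddCt = dCt_test - dCt_cal), and expression is reported as
fold change = 2^-ddCt.  Amplification efficiency is fixed at 2; no
efficiency correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError

CT_COLUMNS = ["tissue", "gene", "replicate", "ct"]


@dataclass(frozen=True)
class CtMeasurement:
    """One well: a tissue x gene x replicate Ct value."""

    tissue: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise DomainError("Ct must be positive")
        if self.replicate < 1:
            raise DomainError("replicate index starts at 1")


@dataclass(frozen=True)
class FoldChangeResult:
    """ddCt arithmetic for one gene in a test-vs-calibrator contrast."""

    gene: str
    delta_ct_test: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    fold_change: float
    sd_test: float | None = None
    sd_calibrator: float | None = None


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns tissue, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"Ct table lacks column(s) {sorted(missing)}")
    return df[CT_COLUMNS]


def mean_ct(values) -> tuple[float, float | None]:
    """Replicate mean and sample SD of Ct values (SD missing for n=1)."""
    values = list(values)
    if not values:
        raise DomainError("at least one replicate is required")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def fold_change(
    ct_gene_test: float,
    ct_ref_test: float,
    ct_gene_cal: float,
    ct_ref_cal: float,
    gene: str = "",
) -> FoldChangeResult:
    """2^-ddCt from four (replicate-averaged) Ct values."""
    for v in (ct_gene_test, ct_ref_test, ct_gene_cal, ct_ref_cal):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise DomainError("all four Ct inputs must be present")
    d_test = ct_gene_test - ct_ref_test
    d_cal = ct_gene_cal - ct_ref_cal
    ddct = d_test - d_cal
    return FoldChangeResult(
        gene=gene,
        delta_ct_test=d_test,
        delta_ct_calibrator=d_cal,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
    )


def tissue_contrast(
    table: pd.DataFrame,
    test: str,
    calibrator: str,
    reference_gene: str = "U6",
) -> list[FoldChangeResult]:
    """Per-gene fold changes of ``test`` over ``calibrator`` tissue.

    Replicates are averaged on the Ct scale before any subtraction.  Genes
    missing in either tissue are skipped with a warning; a missing
    reference gene raises :class:`DomainError`.
    """
    means: dict[tuple[str, str], tuple[float, float | None]] = {}
    for (tissue, gene), grp in table.groupby(["tissue", "gene"]):
        means[(tissue, gene)] = mean_ct(grp["ct"].tolist())
    for tissue in (test, calibrator):
        if (tissue, reference_gene) not in means:
            raise DomainError(
                f"reference gene {reference_gene!r} not measured in "
                f"tissue {tissue!r}"
            )
    ref_test = means[(test, reference_gene)][0]
    ref_cal = means[(calibrator, reference_gene)][0]
    genes = sorted(
        {g for (_, g) in means if g != reference_gene}
    )
    results: list[FoldChangeResult] = []
    for gene in genes:
        if (test, gene) not in means or (calibrator, gene) not in means:
            warnings.warn(
                f"gene {gene!r} not measured in both tissues; skipped"
            )
            continue
        (m_test, sd_test) = means[(test, gene)]
        (m_cal, sd_cal) = means[(calibrator, gene)]
        res = fold_change(m_test, ref_test, m_cal, ref_cal, gene=gene)
        results.append(
            FoldChangeResult(
                gene=gene,
                delta_ct_test=res.delta_ct_test,
                delta_ct_calibrator=res.delta_ct_calibrator,
                delta_delta_ct=res.delta_delta_ct,
                fold_change=res.fold_change,
                sd_test=sd_test,
                sd_calibrator=sd_cal,
            )
        )
    return results


def contrast_to_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    """Tabulate :func:`tissue_contrast` output."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "delta_delta_ct": r.delta_delta_ct,
                "fold_change": r.fold_change,
                "sd_test": r.sd_test,
                "sd_calibrator": r.sd_calibrator,
            }
            for r in results
        ],
        columns=[
            "gene",
            "delta_delta_ct",
            "fold_change",
            "sd_test",
            "sd_calibrator",
        ],
    )


def plot_fold_changes(results: list[FoldChangeResult], path=None):
    """Bar chart of per-gene fold changes (matplotlib Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = [r.gene for r in results]
    folds = [r.fold_change for r in results]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(genes, folds, color="#4878a8")
    ax.set_ylabel("fold change (2^-ddCt)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
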