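"""Downstream impact of suboptimal protocols on differential-expression calls.

A balanced two-channel dye-swap design reduces exactly to one orientation-
corrected log ratio per gene and slide; a one-sample t test of that ratio
against zero is then equivalent to the balanced two-channel ANOVA with slide
as block. Raw p-values are converted to Benjamini-Hochberg false discovery
rates and genes are counted significant at a strict q < cutoff. Comparing an
optimal against a degraded protocol yields the set of *lost* genes, whose
fold-change distribution and category enrichment (e.g. transcription
factors, via Fisher's exact test) quantify the biological cost of suboptimal
hybridization conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel_io import AnnotationTable, ExpressionSet, ValidationError

__all__ = [
    "DEResult",
    "Contingency2x2",
    "dye_swap_log_ratios",
    "de_test",
    "bh_fdr",
    "count_significant",
    "compare_protocol_de",
    "fisher_enrichment",
    "tf_enrichment_table",
    "write_de_results",
]


def dye_swap_log_ratios(es: ExpressionSet) -> pd.DataFrame:
    """Orientation-corrected per-slide log ratios, genes x slides.

    For each slide, the ratio is (observation with sample label 1) minus
    (observation with label 0) on the log scale, so a positive value always
    means higher expression in sample 1 regardless of which dye carried it.
    """
    slides = es.slides
    slide_arr = es.obs["slide"].to_numpy()
    y = es.y
    cols = {}
    for s in slides:
        i1 = np.flatnonzero((slide_arr == s) & (y == 1))
        i0 = np.flatnonzero((slide_arr == s) & (y == 0))
        if len(i1) != 1 or len(i0) != 1:
            raise ValidationError(f"slide {s!r} is missing a channel")
        cols[s] = es.values[:, i1[0]] - es.values[:, i0[0]]
    return pd.DataFrame(cols, index=pd.Index(es.gene_ids, name="gene_id"))


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one protocol.

    ``table`` columns: logfc (mean corrected log2 ratio), t, p (two-sided),
    q (BH-FDR). ``n_sig(cutoff)`` counts genes with q strictly below the
    cutoff.
    """

    table: pd.DataFrame
    protocol: str = "NA"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, cutoff: float = 0.01) -> pd.Index:
        return self.table.index[self.table["q"] < cutoff]

    def n_sig(self, cutoff: float = 0.01) -> int:
        return int((self.table["q"] < cutoff).sum())


def de_test(ratios: pd.DataFrame, protocol: str = "NA") -> DEResult:
    """One-sample t test of the mean corrected log ratio against zero.

    Two-sided p from the t distribution with (slides - 1) degrees of freedom.
    Degenerate zero-variance genes get p = 0 when the mean ratio is non-zero
    (infinite t) and p = 1 when all ratios are exactly zero (t = 0).
    """
    n = ratios.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 slides for a t test")
    m = ratios.mean(axis=1).to_numpy()
    sd = ratios.std(axis=1, ddof=1).to_numpy()
    zero_var = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        t = np.where(zero_var, np.sign(m) * np.where(m != 0.0, np.inf, 0.0), t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(zero_var, np.where(m != 0.0, 0.0, 1.0), p)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"logfc": m, "t": t, "p": p, "q": q},
        index=ratios.index.copy(),
    )
    return DEResult(table=table, protocol=protocol)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values, capped at
    1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_significant(de: DEResult, cutoff: float = 0.01) -> int:
    """Number of genes with q strictly below ``cutoff``."""
    return de.n_sig(cutoff)


def _five_number(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return dict(zip(("min", "q1", "median", "q3", "max"), (float(v) for v in q)))


def compare_protocol_de(
    de_opt: DEResult, de_sub: DEResult, cutoff: float = 0.01
) -> dict:
    """Profile the genes lost when moving from an optimal to a degraded protocol.

    ``lost`` = significant under the optimal protocol but not under the
    suboptimal one; ``retained`` = significant under both. The report splits
    the lost set by fold-change sign and gives five-number summaries of
    |log2 FC| (from the optimal protocol's estimates) for the retained and
    lost sets — the degraded protocol typically loses the genes with the more
    subtle fold changes.
    """
    if list(de_opt.table.index) != list(de_sub.table.index):
        raise ValidationError("gene universes differ between the two results")
    sig_opt = set(de_opt.significant(cutoff))
    sig_sub = set(de_sub.significant(cutoff))
    lost = sorted(sig_opt - sig_sub)
    retained = sorted(sig_opt & sig_sub)
    logfc = de_opt.table["logfc"]
    lost_up = [g for g in lost if logfc[g] > 0]
    lost_down = [g for g in lost if logfc[g] < 0]
    return {
        "cutoff": cutoff,
        "n_sig_opt": len(sig_opt),
        "n_sig_sub": len(sig_sub),
        "lost": lost,
        "retained": retained,
        "lost_up": lost_up,
        "lost_down": lost_down,
        "abs_logfc_retained": _five_number(np.abs(logfc[retained].to_numpy())),
        "abs_logfc_lost": _five_number(np.abs(logfc[lost].to_numpy())),
    }


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 contingency table: category membership x detection status."""

    a: int  # in category, detected only under the optimal protocol (lost set)
    b: int  # in category, detected under both / the comparison set
    c: int  # not in category, first column
    d: int  # not in category, second column

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in vals):
            raise ValidationError("counts must be non-negative integers")
        if sum(vals) == 0:
            raise ValidationError("contingency table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_enrichment(tab: Contingency2x2 | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the two-sided p-value (sum of hypergeometric probabilities of all
    tables with the fixed margins that are no more likely than the observed
    one) and the sample odds ratio ``(a*d)/(b*c)`` (infinite when ``b*c`` is
    zero but ``a*d`` is not, NaN when both products vanish).
    """
    if not isinstance(tab, Contingency2x2):
        (a, b), (c, d) = tab
        tab = Contingency2x2(int(a), int(b), int(c), int(d))
    arr = tab.as_array()
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    ad = tab.a * tab.d
    bc = tab.b * tab.c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return p, odds


def tf_enrichment_table(
    report: dict, annotation: AnnotationTable
) -> Contingency2x2:
    """Build the category x detection table from a protocol-comparison report.

    Column 1 counts the lost genes (detected only under the optimal
    protocol), column 2 the retained genes; rows split by the annotation
    flag (e.g. transcription factor or not).
    """
    lost_flags = annotation.flag_for(report["lost"])
    ret_flags = annotation.flag_for(report["retained"])
    return Contingency2x2(
        a=int(lost_flags.sum()),
        b=int(ret_flags.sum()),
        c=int(len(lost_flags) - lost_flags.sum()),
        d=int(len(ret_flags) - ret_flags.sum()),
    )


def write_de_results(de: DEResult, path, cutoff: float = 0.01) -> None:
    out = de.table.copy()
    out["significant"] = out["q"] < cutoff
    out.to_csv(path, sep="\t", lineterminator="\n")
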