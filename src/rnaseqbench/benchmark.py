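"""Rank-based precision and accuracy scoring of quantification pipelines.

Precision: for each housekeeping gene, a non-parametric coefficient of
variation CoV = MAD / median is computed over a cell line's control
replicates, separately inside every pipeline. Pipelines are then ranked per
gene (rank 1 = lowest CoV, average ranks on ties) and each pipeline's
precision index is the median of its gene ranks — lower is more precise.

Accuracy: for each qRT-PCR candidate gene, the Pearson correlation between a
pipeline's expression values and the duplicate-averaged Ct values over the
same control samples. Because Ct falls as expression rises, a strong
inverse association (most negative r) is best: pipelines are ranked per gene
ascending in r, and the accuracy index is again the median gene rank.

The overall index sums precision and accuracy indices over cell lines, so
both components carry equal weight; with two cell lines this equals twice
the sum of the cross-cell-line median precision and median accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionPanel
from .qpcr import average_duplicates

logger = logging.getLogger(__name__)


def gene_cov(values: Sequence[float] | np.ndarray) -> float:
    """Non-parametric coefficient of variation, MAD / median.

    MAD is the raw median absolute deviation from the median (no consistency
    factor). Returns NaN when the median is zero (undefined ratio).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CoV needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("CoV input must be finite")
    med = float(np.median(x))
    if med == 0.0:
        return float("nan")
    mad = float(np.median(np.abs(x - med)))
    return mad / med


def _cov_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise MAD/median; NaN rows where the median is 0."""
    med = np.median(x, axis=1)
    mad = np.median(np.abs(x - med[:, None]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(med == 0.0, np.nan, mad / med)
    return out


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; NaN rows where either vector is constant."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_correlation(expression: Sequence[float],
                         ct: Sequence[float]) -> float:
    """Pearson r between expression and Ct over aligned samples.

    NaN when either vector is constant (correlation undefined).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and ct vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    return _pearson(x, y)


@dataclass
class PrecisionResult:
    """Per-pipeline precision index for one cell line, with audit trail."""

    cell_line: str
    index: pd.Series            # pipeline → median CoV rank
    cov: pd.DataFrame           # gene × pipeline CoV values
    ranks: pd.DataFrame         # gene × pipeline cross-pipeline ranks
    dropped_genes: list[str]    # genes with undefined CoV in any pipeline


@dataclass
class AccuracyResult:
    """Per-pipeline accuracy index for one cell line, with audit trail."""

    cell_line: str
    index: pd.Series
    r: pd.DataFrame             # gene × pipeline Pearson r
    ranks: pd.DataFrame
    dropped_genes: list[str]    # genes with undefined r in every pipeline


@dataclass
class PipelineScoreTable:
    """Combined ranking: one row per pipeline.

    Columns: median_precision and median_accuracy (medians across cell
    lines), overall (sum of precision + accuracy indices over cell lines)
    and rank (ascending in overall; ties broken by median accuracy, then
    pipeline id).
    """

    frame: pd.DataFrame

    @property
    def pipeline_ids(self) -> list[str]:
        return list(self.frame.index)


def _check_panels(panels: Sequence[ExpressionPanel],
                  genes: Sequence[str],
                  samples: Sequence[str]) -> None:
    if not panels:
        raise ValueError("empty panel collection")
    if not genes:
        raise ValueError("empty gene set")
    for panel in panels:
        missing_g = set(genes) - set(panel.gene_ids)
        if missing_g:
            raise ValueError(
                f"panel {panel.pipeline_id}: missing gene(s) "
                f"{sorted(missing_g)[:5]}")
        missing_s = set(samples) - set(panel.sample_ids)
        if missing_s:
            raise ValueError(
                f"panel {panel.pipeline_id}: missing sample(s) "
                f"{sorted(missing_s)}")


def precision_index(panels: Sequence[ExpressionPanel],
                    hkg_genes: Sequence[str],
                    cell_line: str,
                    control_samples: Sequence[str]) -> PrecisionResult:
    """Median cross-pipeline CoV rank per pipeline, one cell line.

    Genes whose CoV is undefined (zero median) in any pipeline are dropped
    from the ranking universe and logged, rather than imputed.
    """
    panels = list(panels)
    control_samples = list(control_samples)
    if len(control_samples) < 2:
        raise ValueError("need at least 2 replicate control samples")
    _check_panels(panels, hkg_genes, control_samples)

    cov = pd.DataFrame(
        {p.pipeline_id: _cov_rows(
            p.values.loc[list(hkg_genes), control_samples].to_numpy())
         for p in panels},
        index=list(hkg_genes))

    defined = cov.notna().all(axis=1)
    dropped = list(cov.index[~defined])
    if dropped:
        logger.info("precision/%s: dropped %d gene(s) with undefined CoV: %s",
                    cell_line, len(dropped), dropped[:10])
    cov_kept = cov.loc[defined]
    if cov_kept.empty:
        raise ValueError("no gene with defined CoV in every pipeline")
    ranks = cov_kept.rank(axis=1, method="average", ascending=True)
    index = ranks.median(axis=0)
    index.name = f"precision_{cell_line}"
    return PrecisionResult(cell_line=cell_line, index=index, cov=cov,
                           ranks=ranks, dropped_genes=dropped)


def accuracy_index(panels: Sequence[ExpressionPanel],
                   ct: pd.DataFrame,
                   candidate_genes: Sequence[str],
                   cell_line: str,
                   control_samples: Sequence[str]) -> AccuracyResult:
    """Median cross-pipeline correlation rank per pipeline, one cell line.

    Rank 1 goes to the most negative Pearson r (strongest inverse Ct
    association); undefined correlations rank last within their gene. Genes
    with undefined r in every pipeline (e.g. constant Ct) are dropped.
    """
    panels = list(panels)
    control_samples = list(control_samples)
    if len(control_samples) < 3:
        raise ValueError("need at least 3 control samples for correlation")
    _check_panels(panels, candidate_genes, control_samples)

    averaged = average_duplicates(ct)
    ct_wide = averaged.pivot(index="gene", columns="sample", values="ct")
    missing = set(candidate_genes) - set(ct_wide.index)
    if missing:
        raise ValueError(f"candidate gene(s) absent from Ct table: "
                         f"{sorted(missing)[:5]}")
    missing_s = set(control_samples) - set(ct_wide.columns)
    if missing_s:
        raise ValueError(f"control sample(s) absent from Ct table: "
                         f"{sorted(missing_s)}")

    ct_block = ct_wide.loc[list(candidate_genes), control_samples].to_numpy()
    r = pd.DataFrame(
        {p.pipeline_id: _pearson_rows(
            p.values.loc[list(candidate_genes), control_samples].to_numpy(),
            ct_block)
         for p in panels},
        index=list(candidate_genes))

    all_nan = r.isna().all(axis=1)
    dropped = list(r.index[all_nan])
    if dropped:
        logger.info("accuracy/%s: dropped %d gene(s) with undefined r: %s",
                    cell_line, len(dropped), dropped[:10])
    r_kept = r.loc[~all_nan]
    if r_kept.empty:
        raise ValueError("no gene with a defined correlation in any pipeline")
    # ascending rank on r; NaN (undefined) correlations pushed to the bottom
    ranks = r_kept.rank(axis=1, method="average", ascending=True,
                        na_option="bottom")
    index = ranks.median(axis=0)
    index.name = f"accuracy_{cell_line}"
    return AccuracyResult(cell_line=cell_line, index=index, r=r,
                          ranks=ranks, dropped_genes=dropped)


def overall_ranking(precision: Mapping[str, PrecisionResult],
                    accuracy: Mapping[str, AccuracyResult],
                    manifest: pd.DataFrame | None = None) -> PipelineScoreTable:
    """Combine per-cell-line precision and accuracy into the final table.

    overall = Σ over cell lines of (precision index + accuracy index);
    median_precision / median_accuracy are medians across cell lines. Final
    rank ascends in overall, ties broken by median accuracy then pipeline
    id. With an optional manifest the step labels are merged in.
    """
    if set(precision) != set(accuracy):
        raise ValueError("precision and accuracy cover different cell lines")
    if not precision:
        raise ValueError("no cell lines supplied")
    cell_lines = sorted(precision)
    pipelines = list(precision[cell_lines[0]].index.index)
    for cl in cell_lines:
        for res in (precision[cl], accuracy[cl]):
            if set(res.index.index) != set(pipelines):
                raise ValueError("pipeline sets differ between results")

    prec = pd.DataFrame({cl: precision[cl].index for cl in cell_lines})
    acc = pd.DataFrame({cl: accuracy[cl].index for cl in cell_lines})
    prec = prec.loc[pipelines]
    acc = acc.loc[pipelines]

    frame = pd.DataFrame(index=pd.Index(pipelines, name="pipeline_id"))
    frame["median_precision"] = prec.median(axis=1)
    frame["median_accuracy"] = acc.median(axis=1)
    frame["overall"] = (prec + acc).sum(axis=1)
    frame = (frame.reset_index()
             .sort_values(["overall", "median_accuracy", "pipeline_id"],
                          kind="mergesort")
             .set_index("pipeline_id"))
    frame["rank"] = np.arange(1, len(frame) + 1)
    if manifest is not None:
        labels = manifest.set_index("pipeline_id")
        frame = frame.join(labels, how="left")
    return PipelineScoreTable(frame=frame)


def top_n(table: PipelineScoreTable, n: int) -> list[str]:
    """The first ``n`` pipeline ids by final rank."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(table.frame):
        raise ValueError("n exceeds the number of pipelines")
    ordered = table.frame.sort_values("rank")
    return list(ordered.index[:n])
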