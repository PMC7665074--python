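"""Diagnostic evaluation of differential-expression methods against qRT-PCR.

qRT-PCR truth labels come from Welch two-sample t-tests on normalized ΔCt
values between the two groups of a contrast, BH-adjusted across genes;
a gene is truly differentially expressed when its adjusted p-value clears
the FDR cut-off. Each RNA-seq DE method's adjusted p-values are then
cross-tabulated against the truth and summarized with seven diagnostic
parameters — TPR, TNR, PPV, NPV, ACC, AUC and MCC — at each cut-off.
Methods are also compared to each other by the Euclidean distance between
their binary call vectors under average-linkage (UPGMA) clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score

from .containers import SampleSheet, condition_contrast_pairs
from .group_stats import bh_adjust
from .qpcr import DeltaCtTable

logger = logging.getLogger(__name__)

DEFAULT_FDR_CUTOFFS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: group A vs group B sample ids."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name}: overlapping groups")


def default_contrasts(design: SampleSheet) -> list[Contrast]:
    """The registry of the study's five contrasts, built from the design."""
    contrasts = []
    for name, (cl_a, t_a), (cl_b, t_b) in condition_contrast_pairs(design):
        contrasts.append(Contrast(
            name=name,
            group_a=tuple(design.samples_for(cl_a, t_a)),
            group_b=tuple(design.samples_for(cl_b, t_b))))
    return contrasts


@dataclass(frozen=True)
class DEMethod:
    """One evaluated DE method: algorithm plus internal normalization."""

    label: str
    algorithm: str
    normalization: str | None = None


def de_method_registry() -> list[DEMethod]:
    """The 17 evaluated DE methods.

    Eleven algorithms; edgeR exact, edgeR GLM and NOISeq each contribute
    three internal normalization variants (TMM, UQ, FPKM), the other eight
    a single entry: 8 + 3 × 3 = 17.
    """
    single = ["baySeq", "Cuffdiff", "DESeq2", "EBSeq", "Ballgown",
              "limma trend", "limma voom", "SAMseq"]
    multi = ["edgeR exact", "edgeR GLM", "NOISeq"]
    variants = ["TMM", "UQ", "FPKM"]
    methods = [DEMethod(label=a, algorithm=a) for a in single]
    methods += [DEMethod(label=f"{a} {v}", algorithm=a, normalization=v)
                for a in multi for v in variants]
    return methods


@dataclass
class TruthLabels:
    """qRT-PCR DE truth for one contrast at one FDR cut-off."""

    contrast: str
    fdr: float
    labels: pd.Series            # gene → bool (adjusted p < fdr)
    adj_p: pd.Series
    raw_p: pd.Series


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def qpcr_de_truth(delta_ct: DeltaCtTable,
                  contrast: Contrast,
                  fdr: float = 0.05) -> TruthLabels:
    """Welch t-test per gene on ΔCt between the contrast's groups, BH FDR.

    Groups need at least two samples each; a gene constant in both groups
    gets p = 1 when the means agree and p = 0 otherwise.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    wide = delta_ct.wide()
    for label, group in (("A", contrast.group_a), ("B", contrast.group_b)):
        missing = set(group) - set(wide.columns)
        if missing:
            raise ValueError(f"contrast {contrast.name}: group {label} "
                             f"sample(s) missing: {sorted(missing)}")
        if len(group) < 2:
            raise ValueError(f"contrast {contrast.name}: group {label} "
                             f"has fewer than 2 samples")
    a = wide[list(contrast.group_a)].to_numpy()
    b = wide[list(contrast.group_b)].to_numpy()
    raw = pd.Series([_welch_p(a[i], b[i]) for i in range(len(wide.index))],
                    index=wide.index, name="raw_p")
    adj = pd.Series(bh_adjust(raw.to_numpy()), index=wide.index, name="adj_p")
    labels = adj < fdr
    labels.name = "de"
    return TruthLabels(contrast=contrast.name, fdr=fdr, labels=labels,
                       adj_p=adj, raw_p=raw)


def confusion(method_adj_p: pd.Series,
              truth: TruthLabels,
              cutoff: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of method calls (adj p < cutoff) against truth."""
    if set(method_adj_p.index) != set(truth.labels.index):
        raise ValueError("method and truth gene sets differ")
    pred = (method_adj_p.reindex(truth.labels.index) < cutoff)
    actual = truth.labels
    tp = int((pred & actual).sum())
    fp = int((pred & ~actual).sum())
    tn = int((~pred & ~actual).sum())
    fn = int((~pred & actual).sum())
    return tp, fp, tn, fn


@dataclass
class DiagnosticMetrics:
    """Confusion counts and the seven diagnostic parameters."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    tnr: float
    ppv: float
    npv: float
    acc: float
    mcc: float
    auc: float                   # NaN when truth has a single class

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "tpr", "tnr", "ppv", "npv",
                 "acc", "mcc", "auc")}


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def diagnostics(counts: tuple[int, int, int, int],
                method_adj_p: pd.Series | None = None,
                truth: TruthLabels | None = None) -> DiagnosticMetrics:
    """Seven diagnostic parameters from a confusion table.

    AUC requires the method's adjusted p-values and the truth labels: it is
    the midrank Mann–Whitney statistic of the DE-evidence score
    (1 − adjusted p) between truth-positive and truth-negative genes, NaN
    when truth holds a single class.
    """
    tp, fp, tn, fn = (int(c) for c in counts)
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative confusion count")
    auc = float("nan")
    if method_adj_p is not None and truth is not None:
        y = truth.labels.to_numpy()
        if 0 < y.sum() < y.size:
            score = 1.0 - method_adj_p.reindex(truth.labels.index).to_numpy()
            auc = float(roc_auc_score(y, score))
        else:
            logger.warning("AUC undefined: truth holds a single class")
    return DiagnosticMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=_ratio(tp, tp + fn), tnr=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        acc=_ratio(tp + tn, tp + fp + tn + fn),
        mcc=mcc_from_counts(tp, fp, tn, fn), auc=auc)


def evaluate_method(method_adj_p: pd.Series,
                    truth: TruthLabels,
                    cutoff: float) -> DiagnosticMetrics:
    """Confusion + diagnostics of one method at one cut-off."""
    counts = confusion(method_adj_p, truth, cutoff)
    return diagnostics(counts, method_adj_p, truth)


def deg_counts(results: Mapping[str, pd.Series],
               cutoffs: Sequence[float] = DEFAULT_FDR_CUTOFFS) -> pd.DataFrame:
    """DEG counts per method × cut-off (adjusted p < cutoff)."""
    rows = {}
    for method, adj_p in results.items():
        rows[method] = {c: int((adj_p < c).sum()) for c in cutoffs}
    frame = pd.DataFrame(rows).T
    frame.index.name = "method"
    frame.columns.name = "cutoff"
    return frame


def method_similarity(results: Mapping[str, pd.Series],
                      cutoff: float,
                      feature: str = "calls") -> tuple[pd.DataFrame,
                                                       np.ndarray]:
    """Euclidean distances between methods and their UPGMA linkage.

    Feature vectors are binary calls at the cut-off (``feature='calls'``)
    or the adjusted p-values themselves (``feature='adj_p'``). Returns the
    square distance matrix (method × method) and the scipy linkage matrix
    computed with unweighted group-average linkage.
    """
    if feature not in {"calls", "adj_p"}:
        raise ValueError(f"unknown feature: {feature!r}")
    methods = list(results)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    genes = list(results[methods[0]].index)
    for m in methods[1:]:
        if set(results[m].index) != set(genes):
            raise ValueError("methods cover different gene sets")
    mat = np.vstack([
        ((results[m].reindex(genes) < cutoff).to_numpy(dtype=float)
         if feature == "calls"
         else results[m].reindex(genes).to_numpy(dtype=float))
        for m in methods])
    condensed = pdist(mat, metric="euclidean")
    dist = pd.DataFrame(squareform(condensed), index=methods, columns=methods)
    linkage = hierarchy.linkage(condensed, method="average")
    return dist, linkage


def linkage_to_newick(linkage: np.ndarray,
                      labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def performance_rank(metrics: pd.DataFrame,
                     metric_columns: Sequence[str] = (
                         "tpr", "tnr", "ppv", "npv", "acc", "auc", "mcc"),
                     ) -> dict[str, pd.DataFrame]:
    """Aggregate method performance three ways.

    ``metrics`` is long-format with columns method, contrast, cutoff plus
    the seven parameters (higher = better for all). Ranking rules:

    * by scenario: per contrast, metrics are averaged over cut-offs, each
      parameter ranks the methods (rank 1 = best, ties averaged), and a
      method's scenario score is its mean rank across the parameters;
    * by cutoff: symmetric, averaging over contrasts within each cut-off;
    * overall: the mean of a method's per-scenario and per-cutoff scores,
      re-ranked ascending.

    Missing (NaN) cells are excluded pairwise with a warning. Returns
    {'by_scenario', 'by_cutoff', 'overall'} tables.
    """
    required = {"method", "contrast", "cutoff", *metric_columns}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing column(s): {sorted(missing)}")
    if metrics[list(metric_columns)].isna().any().any():
        logger.warning("NaN metric cells excluded pairwise from ranking")

    def mean_rank(frame: pd.DataFrame) -> pd.Series:
        ranks = frame.rank(ascending=False, method="average")
        return ranks.mean(axis=1, skipna=True)

    by_scenario = {}
    for contrast, sub in metrics.groupby("contrast"):
        avg = sub.groupby("method")[list(metric_columns)].mean()
        by_scenario[contrast] = mean_rank(avg)
    scenario = pd.DataFrame(by_scenario)
    scenario.columns.name = "contrast"

    by_cutoff = {}
    for cutoff, sub in metrics.groupby("cutoff"):
        avg = sub.groupby("method")[list(metric_columns)].mean()
        by_cutoff[cutoff] = mean_rank(avg)
    cutoff_table = pd.DataFrame(by_cutoff)
    cutoff_table.columns.name = "cutoff"

    combined = pd.concat([scenario, cutoff_table], axis=1)
    overall_score = combined.mean(axis=1)
    overall = pd.DataFrame({
        "mean_rank": overall_score,
        "rank": overall_score.rank(method="average")})
    overall = overall.sort_values(["rank", "mean_rank"])
    return {"by_scenario": scenario, "by_cutoff": cutoff_table,
            "overall": overall}
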