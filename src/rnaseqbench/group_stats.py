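"""Non-parametric group comparisons: Kruskal–Wallis, Dunn post hoc, BH FDR.

Pipelines grouped by the algorithm used at one step (trimmer, aligner,
counter, normalization) are compared on their scaled overall scores with
the Kruskal–Wallis rank test; pairwise follow-up uses Dunn's z-test with
the tie-corrected pooled variance, and the C(k, 2) p-values are adjusted by
the Benjamini–Hochberg step-up procedure. Dunn p-values here are two-sided
(halve them for the one-sided convention some R packages report).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .benchmark import PipelineScoreTable


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _group_arrays(values: Sequence[float],
                  groups: Sequence[str]) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups differ in length")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    out = {str(label): v[g == label] for label in pd.unique(g)}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for label, arr in out.items():
        if arr.size == 0:
            raise ValueError(f"empty group: {label}")
    return out


def kruskal_wallis(values: Sequence[float],
                   groups: Sequence[str]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    When every observation is identical the tie correction degenerates;
    H is then defined as 0 with p = 1.
    """
    arrays = _group_arrays(values, groups)
    flat = np.concatenate(list(arrays.values()))
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays.values())
    return float(h), float(p)


@dataclass
class GroupTestResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise table."""

    h: float
    p: float
    pairwise: pd.DataFrame       # group_i, group_j, z, p_raw, p_adj
    summaries: pd.DataFrame      # group → n, mean_rank


def dunn_posthoc(values: Sequence[float],
                 groups: Sequence[str],
                 adjust: str = "bh") -> GroupTestResult:
    """Dunn's pairwise z-tests on mean ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)),
    T = t³ − t summed over tie groups; two-sided normal p-values, adjusted
    across the C(k, 2) comparisons ('bh' or 'none').
    """
    if adjust not in {"bh", "none"}:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    arrays = _group_arrays(values, groups)
    labels = list(arrays)
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    n = v.size
    ranks = stats.rankdata(v)

    _, counts = np.unique(v, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    mean_ranks = {lab: float(ranks[g == lab].mean()) for lab in labels}
    sizes = {lab: int((g == lab).sum()) for lab in labels}

    rows = []
    degenerate = var_base <= 0  # every value identical
    for a, b in combinations(labels, 2):
        if degenerate:
            z = 0.0
        else:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_i": a, "group_j": b, "z": float(z),
                     "p_raw": p_raw})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = (bh_adjust(pairwise["p_raw"].to_numpy())
                         if adjust == "bh" else pairwise["p_raw"])
    h, p = kruskal_wallis(values, groups)
    summaries = pd.DataFrame(
        {"n": pd.Series(sizes), "mean_rank": pd.Series(mean_ranks)})
    summaries.index.name = "group"
    return GroupTestResult(h=h, p=p, pairwise=pairwise, summaries=summaries)


def scale_overall(overall: pd.Series,
                  low: float = 1.0, high: float = 100.0) -> pd.Series:
    """Min–max scale overall indices into [low, high].

    A constant vector maps to the midpoint of the range.
    """
    x = overall.astype(float)
    span = x.max() - x.min()
    if span == 0:
        return pd.Series((low + high) / 2.0, index=x.index)
    return low + (high - low) * (x - x.min()) / span


def compare_step(scores: PipelineScoreTable,
                 manifest: pd.DataFrame,
                 step: str,
                 exclude_normalizations: Iterable[str] = ()) -> tuple[
                     GroupTestResult, GroupTestResult | None]:
    """Compare pipelines grouped by the algorithm used at one step.

    The per-pipeline overall index is min–max scaled to 1–100 across the
    included pipelines, then tested by Kruskal–Wallis + Dunn. When an
    exclusion set of normalization labels is given (e.g. the raw-count-like
    normalizations that bimodalize the score distribution), the analysis is
    re-run on the reduced pipeline set and both results returned.
    """
    if step not in {"trimmer", "aligner", "counter", "normalization"}:
        raise ValueError(f"unknown step: {step!r}")
    labels = manifest.set_index("pipeline_id")[step]
    missing = set(scores.pipeline_ids) - set(labels.index)
    if missing:
        raise ValueError(f"pipeline(s) absent from manifest: "
                         f"{sorted(missing)[:5]}")
    overall = scores.frame["overall"]

    def run(ids: list[str]) -> GroupTestResult:
        lab = labels.loc[ids]
        if lab.nunique() < 2:
            raise ValueError(
                f"step {step!r} has a single label level on this subset")
        scaled = scale_overall(overall.loc[ids])
        return dunn_posthoc(scaled.to_numpy(), lab.to_numpy())

    full = run(list(scores.pipeline_ids))
    excl = set(exclude_normalizations)
    if not excl:
        return full, None
    norm = manifest.set_index("pipeline_id")["normalization"]
    kept = [p for p in scores.pipeline_ids if norm[p] not in excl]
    if not kept:
        raise ValueError("exclusion set removes every pipeline")
    return full, run(kept)
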