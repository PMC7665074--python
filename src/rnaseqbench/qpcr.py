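"""ΔCt normalization and reference-gene stability estimation.

Expression measured by qRT-PCR arrives as cycle-threshold (Ct) values:
the PCR cycle at which fluorescence crosses a threshold, inversely related
to log template abundance. Normalized expression is expressed as

    ΔCt = Ct(reference) − Ct(target)

so larger ΔCt means more expressed. Three reference choices are supported:
(a) endogenous control — the mean Ct of designated control genes per sample;
(b) global median — the per-sample median Ct over genes below a Ct ceiling;
(c) most stable gene — a single gene chosen by consensus of four stability
estimators (geNorm, NormFinder, BestKeeper, comparative ΔCt).

All stability estimators run on technical-duplicate-averaged Ct values,
which already live on a log2-expression-like scale; methods built on
standard deviations of pairwise Ct differences are unchanged by this choice,
and for BestKeeper the SD-of-Ct statistic is the ranking key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STABILITY_METHODS = ("genorm", "normfinder", "bestkeeper", "comparative_dct")


def average_duplicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical duplicates to one Ct per (gene, sample).

    Accepts a long table with or without a ``duplicate`` column; averaging
    is the arithmetic mean on the Ct scale. Idempotent.
    """
    required = {"gene", "sample", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    out = (ct.groupby(["gene", "sample"], sort=False, as_index=False)["ct"]
           .mean())
    return out


def _ct_wide(ct: pd.DataFrame) -> pd.DataFrame:
    """Duplicate-averaged gene × sample Ct matrix; must be complete."""
    averaged = average_duplicates(ct)
    wide = averaged.pivot(index="gene", columns="sample", values="ct")
    if wide.isna().any().any():
        holes = wide.stack(dropna=False)
        holes = holes[holes.isna()]
        raise ValueError(
            f"missing Ct measurement(s), e.g. {list(holes.index[:3])}")
    return wide


@dataclass
class DeltaCtTable:
    """Normalized qRT-PCR expression, one ΔCt per (gene, sample)."""

    frame: pd.DataFrame          # columns: gene, sample, delta_ct
    scheme: str                  # endogenous | global_median | most_stable
    params: dict = field(default_factory=dict)

    def wide(self) -> pd.DataFrame:
        return self.frame.pivot(index="gene", columns="sample",
                                values="delta_ct")


def _to_delta_long(delta_wide: pd.DataFrame, scheme: str,
                   params: dict) -> DeltaCtTable:
    frame = (delta_wide.stack().rename("delta_ct").reset_index())
    frame.columns = ["gene", "sample", "delta_ct"]
    return DeltaCtTable(frame=frame, scheme=scheme, params=params)


def delta_ct_endogenous(ct: pd.DataFrame,
                        control_genes: Sequence[str]) -> DeltaCtTable:
    """ΔCt against the per-sample mean Ct of designated control genes."""
    control_genes = list(control_genes)
    if not control_genes:
        raise ValueError("control gene list is empty")
    wide = _ct_wide(ct)
    missing = set(control_genes) - set(wide.index)
    if missing:
        raise ValueError(f"control gene(s) missing from Ct table: "
                         f"{sorted(missing)}")
    reference = wide.loc[control_genes].mean(axis=0)
    delta = reference - wide
    return _to_delta_long(delta, "endogenous",
                          {"control_genes": control_genes})


def delta_ct_global_median(ct: pd.DataFrame,
                           ct_ceiling: float = 35.0) -> DeltaCtTable:
    """ΔCt against the per-sample median Ct of genes with Ct < ceiling.

    The ceiling excludes near-background amplification (strict comparison);
    a sample with no gene below the ceiling is a hard error.
    """
    wide = _ct_wide(ct)
    below = wide.where(wide < ct_ceiling)
    empty = below.columns[below.isna().all(axis=0)]
    if len(empty):
        raise ValueError(
            f"sample(s) with no gene below the Ct ceiling {ct_ceiling}: "
            f"{list(empty)}")
    reference = below.median(axis=0)
    delta = reference - wide
    return _to_delta_long(delta, "global_median", {"ct_ceiling": ct_ceiling})


def delta_ct_most_stable(ct: pd.DataFrame,
                         stable_gene: "str | ConsensusRanking") -> DeltaCtTable:
    """ΔCt against a single most-stable reference gene."""
    gene = (stable_gene.most_stable
            if isinstance(stable_gene, ConsensusRanking) else stable_gene)
    wide = _ct_wide(ct)
    if gene not in wide.index:
        raise ValueError(f"stable gene {gene!r} missing from Ct table")
    delta = wide.loc[gene] - wide
    return _to_delta_long(delta, "most_stable", {"stable_gene": gene})


@dataclass
class StabilityResult:
    """Per-gene stability values (lower = more stable) from one estimator."""

    method: str
    values: pd.Series            # gene → stability value
    ranks: pd.Series             # gene → rank, average ranks on ties
    extras: dict = field(default_factory=dict)


def _rank_stability(method: str, values: pd.Series,
                    extras: dict | None = None) -> StabilityResult:
    ranks = values.rank(method="average", ascending=True)
    return StabilityResult(method=method, values=values, ranks=ranks,
                           extras=extras or {})


def _pairwise_sd(wide: pd.DataFrame) -> pd.DataFrame:
    """V[j, k] = SD over samples of (Ct_j − Ct_k), sample SD (ddof=1)."""
    genes = list(wide.index)
    x = wide.to_numpy()
    n = len(genes)
    v = np.zeros((n, n))
    for j in range(n):
        diff = x[j][None, :] - x  # all genes vs gene j
        v[j] = diff.std(axis=1, ddof=1)
    return pd.DataFrame(v, index=genes, columns=genes)


def stability_genorm(ct: pd.DataFrame) -> StabilityResult:
    """geNorm expression-stability measure M with iterative pruning.

    M_j is the mean over the other genes of the SD of pairwise Ct
    differences. The least stable gene (highest M) is excluded and M is
    recomputed on the survivors until two genes remain; each gene's
    stability value is its M from the round of its exclusion, and the final
    pair shares the last round's M. Ties at the maximum are excluded in
    lexicographic gene-id order for determinism.
    """
    wide = _ct_wide(ct)
    if len(wide.index) < 3:
        raise ValueError("geNorm needs at least 3 genes")
    if len(wide.columns) < 2:
        raise ValueError("geNorm needs at least 2 samples")
    remaining = sorted(wide.index)
    values: dict[str, float] = {}
    while len(remaining) > 2:
        v = _pairwise_sd(wide.loc[remaining])
        m = (v.sum(axis=1)) / (len(remaining) - 1)
        worst = m[m == m.max()].index.min()  # lexicographic on ties
        values[worst] = float(m[worst])
        remaining.remove(worst)
    v = _pairwise_sd(wide.loc[remaining])
    m = v.sum(axis=1) / (len(remaining) - 1)
    for g in remaining:
        values[g] = float(m[g])
    series = pd.Series(values).reindex(wide.index)
    series.name = "genorm_M"
    return _rank_stability("genorm", series)


def stability_comparative_dct(ct: pd.DataFrame) -> StabilityResult:
    """Comparative ΔCt stability: mean pairwise SD, no pruning."""
    wide = _ct_wide(ct)
    if len(wide.index) < 2:
        raise ValueError("comparative ΔCt needs at least 2 genes")
    if len(wide.columns) < 2:
        raise ValueError("comparative ΔCt needs at least 2 samples")
    v = _pairwise_sd(wide)
    values = v.sum(axis=1) / (len(wide.index) - 1)
    values.name = "comparative_dct_meanSD"
    return _rank_stability("comparative_dct", values)


def stability_bestkeeper(ct: pd.DataFrame) -> StabilityResult:
    """BestKeeper: per-gene Ct standard deviation, plus index correlation.

    The ranking key is the sample SD of each gene's Ct (lower = more
    stable). The Pearson correlation of each gene with the BestKeeper index
    — the per-sample arithmetic mean Ct across genes — is reported in
    ``extras['index_correlation']`` (NaN when the index or the gene is
    constant) but not ranked on.
    """
    wide = _ct_wide(ct)
    if len(wide.index) < 2:
        raise ValueError("BestKeeper needs at least 2 genes")
    values = wide.std(axis=1, ddof=1)
    values.name = "bestkeeper_SD"
    index = wide.mean(axis=0)
    corr = {}
    idx = index.to_numpy()
    for g in wide.index:
        x = wide.loc[g].to_numpy()
        if np.std(idx) == 0.0 or np.std(x) == 0.0:
            corr[g] = float("nan")
        else:
            corr[g] = float(np.corrcoef(x, idx)[0, 1])
    return _rank_stability("bestkeeper", values,
                           {"index_correlation": pd.Series(corr)})


def stability_normfinder(ct: pd.DataFrame,
                         groups: Mapping[str, str]) -> StabilityResult:
    """Model-based stability decomposing intra- and inter-group variation.

    Estimator (documented here and pinned by an independent oracle test):
    Ct values are first centred per sample by the mean over genes, removing
    the sample loading. For gene g and group i, let a_ig be the mean and
    s²_ig the sample variance (ddof=1) of the centred values, n_i the group
    size, and d_ig = a_ig − mean over groups of a_ig the inter-group bias.
    The stability value is

        ρ_g = mean_i |d_ig|  +  mean_i sqrt(s²_ig / n_i),

    the absolute group-bias estimate plus the averaged intra-group standard
    error; lower is more stable. A gene with no group bias and no
    within-group variation attains exactly 0.
    """
    wide = _ct_wide(ct)
    if len(wide.index) < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    missing = set(wide.columns) - set(groups)
    if missing:
        raise ValueError(f"sample(s) without group label: {sorted(missing)}")
    labels = pd.Series({s: groups[s] for s in wide.columns})
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("NormFinder needs at least 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 samples: "
                         f"{sorted(small.index)}")

    centred = wide - wide.mean(axis=0)
    group_names = sorted(sizes.index)
    a = pd.DataFrame(index=wide.index, columns=group_names, dtype=float)
    se = pd.DataFrame(index=wide.index, columns=group_names, dtype=float)
    for gname in group_names:
        cols = labels.index[labels == gname]
        sub = centred[cols]
        a[gname] = sub.mean(axis=1)
        se[gname] = np.sqrt(sub.var(axis=1, ddof=1) / len(cols))
    d = a.sub(a.mean(axis=1), axis=0)
    values = d.abs().mean(axis=1) + se.mean(axis=1)
    values.name = "normfinder_stability"
    return _rank_stability("normfinder", values,
                           {"group_bias": d, "group_se": se})


@dataclass
class ConsensusRanking:
    """Geometric-mean aggregation of the four stability rankings."""

    geo_mean: pd.Series          # gene → geometric mean of method ranks
    order: list[str]             # genes, most stable first
    most_stable: str
    method_ranks: pd.DataFrame   # gene × method


def consensus_rank(results: Iterable[StabilityResult]) -> ConsensusRanking:
    """Aggregate stability rankings by geometric mean of per-method ranks.

    All results must cover the same gene set. The final order ascends in the
    geometric mean with lexicographic gene-id tie-breaks; the first gene is
    the most stable.
    """
    results = list(results)
    if not results:
        raise ValueError("no stability results supplied")
    gene_set = set(results[0].ranks.index)
    for res in results[1:]:
        if set(res.ranks.index) != gene_set:
            raise ValueError("stability results cover different gene sets")
    ranks = pd.DataFrame({res.method: res.ranks for res in results})
    geo = np.exp(np.log(ranks).mean(axis=1))
    geo.name = "consensus_geomean_rank"
    order = sorted(geo.index, key=lambda g: (geo[g], g))
    return ConsensusRanking(geo_mean=geo, order=order,
                            most_stable=order[0], method_ranks=ranks)


def stability_report(ct: pd.DataFrame,
                     groups: Mapping[str, str]) -> tuple[
                         list[StabilityResult], ConsensusRanking]:
    """Run all four estimators and their consensus on one Ct table."""
    results = [
        stability_genorm(ct),
        stability_normfinder(ct, groups),
        stability_bestkeeper(ct),
        stability_comparative_dct(ct),
    ]
    return results, consensus_rank(results)
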