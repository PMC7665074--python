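"""Housekeeping reference set and qRT-PCR candidate gene selection.

The reference (HKg) set holds genes expressed above a minimum number of
expression units in every control sample of every pipeline examined — genes
whose quantification can be compared across pipelines without dropout.
From that universe, qRT-PCR candidates are drawn by dispersion: the genes
with the highest and lowest median non-parametric CoV across pipelines,
a seeded random draw from the middle stratum, and designated control genes
appended regardless of their CoV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionPanel


@dataclass
class HkgSet:
    """Genes passing the expression filter in every panel examined."""

    gene_ids: list[str]
    min_units: float
    samples: list[str]
    n_panels: int

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class CandidateSet:
    """qRT-PCR candidate genes: high/low/mid dispersion plus controls."""

    high_cov: list[str]
    low_cov: list[str]
    mid_random: list[str]
    controls: list[str]
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return self.high_cov + self.low_cov + self.mid_random + self.controls

    def __len__(self) -> int:
        return len(self.gene_ids)


def filter_expressed(panels: Sequence[ExpressionPanel],
                     samples: Sequence[str],
                     min_units: float = 4.0) -> HkgSet:
    """Keep genes with ≥ ``min_units`` in every listed sample of every panel.

    The threshold is inclusive (a value of exactly ``min_units`` survives);
    gene order follows the first panel. Units are whatever each pipeline's
    normalization emits — the filter is applied per panel, so a gene must
    clear the bar under every pipeline's own scale.
    """
    panels = list(panels)
    samples = list(samples)
    if not panels:
        raise ValueError("empty panel collection")
    if not samples:
        raise ValueError("empty sample list")
    keep: pd.Series | None = None
    for panel in panels:
        missing = set(samples) - set(panel.sample_ids)
        if missing:
            raise ValueError(f"panel {panel.pipeline_id}: missing sample(s) "
                             f"{sorted(missing)}")
        ok = (panel.values[samples] >= min_units).all(axis=1)
        keep = ok if keep is None else (keep & ok.reindex(keep.index,
                                                          fill_value=False))
    assert keep is not None
    genes = [g for g in panels[0].gene_ids if keep.get(g, False)]
    return HkgSet(gene_ids=genes, min_units=min_units,
                  samples=samples, n_panels=len(panels))


def median_cov(panels: Sequence[ExpressionPanel],
               genes: Sequence[str],
               samples: Sequence[str]) -> pd.Series:
    """Per-gene median across pipelines of CoV over the given samples."""
    from .benchmark import _cov_rows

    cov = pd.DataFrame(
        {p.pipeline_id: _cov_rows(
            p.values.loc[list(genes), list(samples)].to_numpy())
         for p in panels},
        index=list(genes))
    out = cov.median(axis=1)
    out.name = "median_cov"
    return out


def select_candidates(hkg: HkgSet,
                      cov: Mapping[str, float] | pd.Series,
                      controls: Sequence[str],
                      n_high: int = 10,
                      n_low: int = 10,
                      n_mid: int = 10,
                      seed: int = 0) -> CandidateSet:
    """Pick high/low/mid-dispersion candidates plus control genes.

    ``cov`` maps every HKg gene to its median CoV. The ``n_high`` largest
    and ``n_low`` smallest CoV genes are taken with lexicographic gene-id
    tie-breaks; ``n_mid`` genes are drawn uniformly (seeded) from the
    remaining middle stratum. Control genes are excluded from all three
    draws and appended regardless of their CoV, so the result has
    ``n_high + n_low + n_mid + len(controls)`` genes.
    """
    controls = list(controls)
    missing_ctrl = set(controls) - set(hkg.gene_ids)
    if missing_ctrl:
        raise ValueError(f"control gene(s) outside the expressed universe: "
                         f"{sorted(missing_ctrl)}")
    eligible = [g for g in hkg.gene_ids if g not in set(controls)]
    needed = n_high + n_low + n_mid
    if len(eligible) < needed:
        raise ValueError(f"only {len(eligible)} eligible genes for "
                         f"{needed} requested")
    cov = pd.Series(cov)
    missing_cov = set(eligible) - set(cov.index)
    if missing_cov:
        raise ValueError(f"median CoV undefined for gene(s): "
                         f"{sorted(missing_cov)[:5]}")

    by_high = sorted(eligible, key=lambda g: (-cov[g], g))
    high = by_high[:n_high]
    rest = [g for g in eligible if g not in set(high)]
    by_low = sorted(rest, key=lambda g: (cov[g], g))
    low = by_low[:n_low]
    middle = [g for g in rest if g not in set(low)]
    rng = np.random.default_rng([seed, 51])
    mid = sorted(rng.choice(middle, size=n_mid, replace=False).tolist())
    return CandidateSet(high_cov=high, low_cov=low, mid_random=mid,
                        controls=controls, seed=seed)
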