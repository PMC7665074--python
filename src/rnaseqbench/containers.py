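"""Shared data containers.

The package exchanges three kinds of tables:

* expression panels — one genes × samples matrix per quantification pipeline,
  tagged with the pipeline's trimming/alignment/counting/normalization labels;
* a sample sheet — the experimental design (cell line × treatment × replicate);
* qRT-PCR cycle-threshold (Ct) tables in long format, one row per
  (gene, sample, technical duplicate).

Panels and Ct tables are thin wrappers around :class:`pandas.DataFrame` with
validated schemas, so every downstream module can rely on the same invariants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CELL_LINES = ("CLA", "CLB")
TREATMENTS = ("T0", "T1", "T2")

#: Long-format Ct table column names, in canonical order.
CT_COLUMNS = ("gene", "sample", "duplicate", "ct")


@dataclass(frozen=True)
class SampleSheet:
    """Experimental design: one row per sample.

    The default design mirrors a 2 cell-line × 3 treatment × 3 replicate
    layout (18 samples); any design with unique (cell_line, treatment,
    replicate) triples is accepted.
    """

    frame: pd.DataFrame  # columns: sample_id, cell_line, treatment, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "cell_line", "treatment", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame.empty:
            raise ValueError("sample sheet is empty")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        triples = self.frame[["cell_line", "treatment", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("duplicate (cell_line, treatment, replicate) triple")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def condition(self, sample_id: str) -> tuple[str, str]:
        """(cell_line, treatment) of one sample."""
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return str(row["cell_line"].iloc[0]), str(row["treatment"].iloc[0])

    def samples_for(self, cell_line: str | None = None,
                    treatment: str | None = None) -> list[str]:
        """Sample ids matching the given cell line and/or treatment."""
        mask = pd.Series(True, index=self.frame.index)
        if cell_line is not None:
            mask &= self.frame["cell_line"] == cell_line
        if treatment is not None:
            mask &= self.frame["treatment"] == treatment
        return list(self.frame.loc[mask, "sample_id"])

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.frame["cell_line"]))

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """Unique (cell_line, treatment) pairs in design order."""
        seen = dict.fromkeys(
            zip(self.frame["cell_line"], self.frame["treatment"]))
        return [tuple(map(str, k)) for k in seen]


def default_design(cell_lines: Sequence[str] = CELL_LINES,
                   treatments: Sequence[str] = TREATMENTS,
                   n_replicates: int = 3) -> SampleSheet:
    """The study design: 2 cell lines × 3 treatments × 3 replicates.

    T0 is the vehicle (DMSO) control; T1 and T2 are the two drug treatments.
    Sample ids follow ``{cell_line}_{treatment}_R{replicate}``.
    """
    rows = [
        {"sample_id": f"{cl}_{t}_R{r}", "cell_line": cl,
         "treatment": t, "replicate": r}
        for cl in cell_lines for t in treatments
        for r in range(1, n_replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


@dataclass
class ExpressionPanel:
    """One pipeline's gene × sample expression matrix plus its configuration.

    ``values`` holds strictly numeric expression (rows: gene ids, columns:
    sample ids). The four labels record the algorithm used at each step of the
    pipeline that produced the matrix; they drive the by-step group
    comparisons and the ranking table output.
    """

    pipeline_id: str
    values: pd.DataFrame
    trimmer: str = "NA"
    aligner: str = "NA"
    counter: str = "NA"
    normalization: str = "NA"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene id(s): {list(dupes)}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression panel contains non-numeric values")
        if self.values.isna().any().any():
            raise ValueError("expression panel contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def labels(self) -> dict[str, str]:
        return {"trimmer": self.trimmer, "aligner": self.aligner,
                "counter": self.counter, "normalization": self.normalization}


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format Ct table and return it with canonical columns.

    Required columns: gene, sample, duplicate, ct. (gene, sample, duplicate)
    keys must be unique and Ct values finite and positive.
    """
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    ct = ct.loc[:, list(CT_COLUMNS)].copy()
    if ct.duplicated(subset=["gene", "sample", "duplicate"]).any():
        raise ValueError("duplicate (gene, sample, duplicate) key in Ct table")
    values = pd.to_numeric(ct["ct"], errors="coerce")
    if values.isna().any() or not np.isfinite(values).all():
        raise ValueError("non-numeric or non-finite Ct value")
    if (values <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    ct["ct"] = values.astype(float)
    return ct


def manifest_frame(panels: Iterable[ExpressionPanel]) -> pd.DataFrame:
    """Pipeline manifest (one row of step labels per panel)."""
    rows = [{"pipeline_id": p.pipeline_id, **p.labels} for p in panels]
    return pd.DataFrame(rows)


def condition_key(cell_line: str, treatment: str) -> str:
    return f"{cell_line}:{treatment}"


def condition_contrast_pairs(
    design: SampleSheet,
) -> list[tuple[str, tuple[str, str], tuple[str, str]]]:
    """Condition-level contrast registry for a design.

    The registry holds the treated-vs-control contrast for every (cell line,
    non-control treatment) pair plus the between-cell-line contrast at the
    control treatment; the control treatment is the first one in design
    order. On the default design this yields the five contrasts
    CLA-T0 vs CLB-T0, CLA-T1 vs CLA-T0, CLA-T2 vs CLA-T0, CLB-T1 vs CLB-T0
    and CLB-T2 vs CLB-T0.
    """
    cell_lines = design.cell_lines
    treatments = list(dict.fromkeys(design.frame["treatment"]))
    control = treatments[0]
    pairs: list[tuple[str, tuple[str, str], tuple[str, str]]] = []
    first = cell_lines[0]
    for other in cell_lines[1:]:
        name = f"{first}-{control}_vs_{other}-{control}"
        pairs.append((name, (first, control), (other, control)))
    for cl in cell_lines:
        for t in treatments[1:]:
            name = f"{cl}-{t}_vs_{cl}-{control}"
            pairs.append((name, (cl, t), (cl, control)))
    return pairs
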