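"""Ground-truthed synthetic data emulating a multi-pipeline RNA-seq study.

The generators plant a known truth — per-condition mean log2 expression,
differential-expression labels with fixed effect sizes, and a designated
most-stable qRT-PCR gene — and then emit (a) one distorted expression panel
per quantification pipeline and (b) a paired qRT-PCR Ct table, so that every
downstream scoring stage can be checked against what was planted.

Noise model: expression noise is Gaussian on the log2 scale (log-normal
expression) and Ct noise is Gaussian on the Ct scale. Pipeline distortion is
``value = s_p · bias_p(g) · 2^(mu + ε)`` with a global scale factor ``s_p``,
a per-gene multiplicative bias drawn once per pipeline, and i.i.d. noise of
standard deviation ``σ_p``. Ct values follow the inverse linear relation
``Ct = α − β · (mu + ε)``: higher expression, lower cycle threshold.

All generators are pure functions of their arguments plus an integer seed;
the global seed is split into fixed per-operation substreams so adding a
call to one generator never shifts the stream of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionPanel,
    SampleSheet,
    condition_contrast_pairs,
    condition_key,
)

# Substream tags: generate_truth / generate_panels / generate_ct_table.
_TRUTH_STREAM = 11
_PANEL_STREAM = 21
_CT_STREAM = 31
_DE_STREAM = 61

#: Relative Ct-noise multiplier of the planted most-stable gene. All other
#: genes carry multiplier 1, i.e. the stable gene is 3× quieter.
STABLE_GENE_NOISE_SCALE = 1.0 / 3.0


@dataclass(eq=False)
class TruthSet:
    """Planted ground truth for one synthetic study.

    ``mu`` is the true mean log2 expression per gene (rows) and condition
    (columns keyed ``cell_line:treatment``). ``de_labels`` and ``log2fc``
    are per gene × contrast: a gene labelled differentially expressed in a
    contrast has |log2fc| equal to the planted effect size there, and every
    unlabelled gene has log2fc exactly 0. ``ct_noise_scale`` holds the
    per-gene relative qRT-PCR noise multiplier; ``stable_gene`` carries the
    smallest one.
    """

    gene_ids: list[str]
    mu: pd.DataFrame
    de_labels: pd.DataFrame
    log2fc: pd.DataFrame
    ct_noise_scale: pd.Series
    stable_gene: str
    seed: int

    @property
    def contrast_names(self) -> list[str]:
        return list(self.de_labels.columns)


@dataclass(frozen=True)
class PipelineSpec:
    """Configuration labels and distortion parameters for one pipeline.

    The four step labels are carried through to the benchmark output; the
    distortion parameters control how far the panel departs from truth:
    ``scale`` (global factor, > 0), ``bias_sd`` (sd of the per-gene log2
    multiplicative bias, drawn once per pipeline) and ``noise_sd`` (sd of
    the per-value log2 noise, ≥ 0).
    """

    pipeline_id: str
    trimmer: str = "trimA"
    aligner: str = "alnA"
    counter: str = "cntA"
    normalization: str = "normA"
    scale: float = 1.0
    bias_sd: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"{self.pipeline_id}: scale factor must be > 0")
        if self.bias_sd < 0 or self.noise_sd < 0:
            raise ValueError(f"{self.pipeline_id}: sd parameters must be ≥ 0")


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_truth(n_genes: int,
                   design: SampleSheet,
                   de_fraction: float = 0.1,
                   effect_size: float = 2.0,
                   seed: int = 0,
                   base_mean: float = 8.0,
                   base_sd: float = 1.5) -> TruthSet:
    """Plant per-condition mean log2 expression and DE labels.

    Each gene starts from a common baseline across all conditions, so
    non-DE genes have identical means across treatments within a cell line.
    For each contrast, a seeded fraction ``de_fraction`` of genes receives a
    shift of ±``effect_size`` log2 units: treated-vs-control contrasts shift
    the treated condition only; the between-cell-line contrast shifts every
    condition of the second cell line, leaving its own within-line contrasts
    untouched.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be ≥ 2")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if effect_size < 0:
        raise ValueError("effect_size must be ≥ 0")

    rng = np.random.default_rng([seed, _TRUTH_STREAM])
    genes = _gene_ids(n_genes)
    conditions = [condition_key(cl, t) for cl, t in design.conditions]
    base = rng.normal(base_mean, base_sd, n_genes)
    mu = pd.DataFrame(
        np.tile(base[:, None], (1, len(conditions))),
        index=genes, columns=conditions)

    contrasts = condition_contrast_pairs(design)
    names = [c[0] for c in contrasts]
    de = pd.DataFrame(False, index=genes, columns=names)
    lfc = pd.DataFrame(0.0, index=genes, columns=names)

    for name, (cl_a, t_a), (cl_b, t_b) in contrasts:
        mask = rng.random(n_genes) < de_fraction
        signs = rng.choice([-1.0, 1.0], n_genes)
        shift = np.where(mask, signs * effect_size, 0.0)
        if cl_a == cl_b:
            # within-line contrast: move the treated condition only
            mu[condition_key(cl_a, t_a)] += shift
        else:
            # between-line contrast: move every condition of cell line B so
            # B's own treated-vs-control contrasts are unaffected
            for col in mu.columns:
                if col.startswith(f"{cl_b}:"):
                    mu[col] -= shift
        de[name] = mask
        lfc[name] = shift

    noise_scale = pd.Series(1.0, index=genes, name="ct_noise_scale")
    stable = str(rng.choice(genes))
    noise_scale[stable] = STABLE_GENE_NOISE_SCALE
    return TruthSet(gene_ids=genes, mu=mu, de_labels=de, log2fc=lfc,
                    ct_noise_scale=noise_scale, stable_gene=stable, seed=seed)


def generate_panels(truth: TruthSet,
                    manifest: Sequence[PipelineSpec],
                    design: SampleSheet,
                    seed: int = 0) -> list[ExpressionPanel]:
    """Emit one distorted expression panel per pipeline spec.

    For pipeline p, gene g, sample s:
    ``value = scale_p · 2^(bias_p(g) + mu[g, condition(s)] + ε)`` with
    ``ε ~ N(0, noise_sd_p²)`` and ``bias_p(g) ~ N(0, bias_sd_p²)`` drawn once
    per pipeline. All emitted values are strictly positive.
    """
    manifest = list(manifest)
    if not manifest:
        raise ValueError("pipeline manifest is empty")
    ids = [p.pipeline_id for p in manifest]
    if len(set(ids)) != len(ids):
        raise ValueError("pipeline_id values must be unique within a manifest")

    samples = design.sample_ids
    cond_keys = []
    for s in samples:
        key = condition_key(*design.condition(s))
        if key not in truth.mu.columns:
            raise ValueError(f"sample {s!r} has unknown condition {key!r}")
        cond_keys.append(key)
    mu = truth.mu[cond_keys].to_numpy()  # genes × samples
    n_genes = len(truth.gene_ids)

    panels = []
    for i, spec in enumerate(manifest):
        rng = np.random.default_rng([seed, _PANEL_STREAM, i])
        bias = (rng.normal(0.0, spec.bias_sd, n_genes)
                if spec.bias_sd > 0 else np.zeros(n_genes))
        eps = (rng.normal(0.0, spec.noise_sd, mu.shape)
               if spec.noise_sd > 0 else np.zeros(mu.shape))
        values = spec.scale * np.exp2(bias[:, None] + mu + eps)
        frame = pd.DataFrame(values, index=truth.gene_ids, columns=samples)
        panels.append(ExpressionPanel(
            pipeline_id=spec.pipeline_id, values=frame,
            trimmer=spec.trimmer, aligner=spec.aligner,
            counter=spec.counter, normalization=spec.normalization))
    return panels


def generate_ct_table(truth: TruthSet,
                      genes: Iterable[str] | None = None,
                      design: SampleSheet | None = None,
                      alpha: float = 40.0,
                      beta: float = 1.0,
                      noise_sd: float = 0.25,
                      n_duplicates: int = 2,
                      seed: int = 0) -> pd.DataFrame:
    """Emit a long-format qRT-PCR Ct table for a subset of genes.

    ``Ct[g, s, d] = α − β · (mu[g, condition(s)] + ε)`` with technical
    duplicate noise ``ε ~ N(0, (noise_sd · ct_noise_scale[g])²)``; the
    planted stable gene carries the smallest per-gene noise multiplier.
    α is the no-template intercept in cycles; β > 0 converts log2 expression
    units to cycles (one cycle per doubling at β = 1).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    if n_duplicates < 1:
        raise ValueError("n_duplicates must be ≥ 1")
    if design is None:
        raise ValueError("a SampleSheet design is required")
    gene_list = list(genes) if genes is not None else list(truth.gene_ids)
    unknown = set(gene_list) - set(truth.gene_ids)
    if unknown:
        raise ValueError(f"genes not in truth set: {sorted(unknown)}")

    rng = np.random.default_rng([seed, _CT_STREAM])
    samples = design.sample_ids
    cond_keys = [condition_key(*design.condition(s)) for s in samples]
    mu = truth.mu.loc[gene_list, cond_keys].to_numpy()  # genes × samples
    scale = truth.ct_noise_scale[gene_list].to_numpy()

    records = []
    for d in range(1, n_duplicates + 1):
        sd = noise_sd * scale[:, None]
        eps = rng.normal(0.0, 1.0, mu.shape) * sd if noise_sd > 0 else 0.0
        ct = alpha - beta * (mu + eps)
        for gi, g in enumerate(gene_list):
            for si, s in enumerate(samples):
                records.append((g, s, d, float(np.asarray(ct)[gi, si])))
    frame = pd.DataFrame(records, columns=["gene", "sample", "duplicate", "ct"])
    return frame.sort_values(["gene", "sample", "duplicate"],
                             ignore_index=True)


def generate_de_results(truth: TruthSet,
                        method_quality: "dict[str, float]",
                        seed: int = 0) -> dict[str, dict[str, pd.Series]]:
    """Synthetic stand-ins for DE-method result tables.

    Real DE packages are inputs to the evaluator, not part of it; this
    generator emits per-method adjusted p-values whose fidelity to the
    planted truth is controlled by a signal-to-noise ``quality`` q ≥ 0.
    Per gene, a pseudo test statistic ``t = q · log2fc / 2 + ε`` with
    standard normal ε gives a two-sided normal p-value — exactly uniform
    for non-DE genes, concentrated near 0 for planted genes when q is
    large — which is then BH-adjusted within each contrast. q = 0 yields a
    pure-noise method.

    Returns {contrast: {method: adjusted-p series}}.
    """
    from scipy import stats as _stats

    from .group_stats import bh_adjust

    out: dict[str, dict[str, pd.Series]] = {}
    for ci, contrast in enumerate(truth.contrast_names):
        lfc = truth.log2fc[contrast].to_numpy()
        per_method: dict[str, pd.Series] = {}
        for mi, (method, quality) in enumerate(sorted(method_quality.items())):
            if quality < 0:
                raise ValueError(f"{method}: quality must be ≥ 0")
            rng = np.random.default_rng([seed, _DE_STREAM, ci, mi])
            t = quality * lfc / 2.0 + rng.normal(0.0, 1.0, lfc.size)
            raw = 2.0 * _stats.norm.sf(np.abs(t))
            adj = bh_adjust(raw)
            per_method[method] = pd.Series(adj, index=truth.gene_ids,
                                           name="adj_p")
        out[contrast] = per_method
    return out


def default_manifest(n_pipelines: int = 8,
                     noise_range: tuple[float, float] = (0.05, 0.6),
                     seed: int = 0) -> list[PipelineSpec]:
    """A small manifest of pipelines with graded distortion.

    Labels cycle through 3 trimmers × 3 aligners × 2 counters × 2
    normalizations; noise sds are evenly spaced across ``noise_range`` and
    scale factors drawn log-uniformly in [0.5, 2], emulating pipelines that
    disagree in units but share the underlying signal.
    """
    if n_pipelines < 1:
        raise ValueError("n_pipelines must be ≥ 1")
    rng = np.random.default_rng([seed, 41])
    trimmers = ["Trimmomatic", "Cutadapt", "BBDuk"]
    aligners = ["STAR", "TopHat2", "HiSat2"]
    counters = ["HTSeq UNION", "HTSeq INTER"]
    norms = ["TMM", "FPKM"]
    lo, hi = noise_range
    noise = np.linspace(lo, hi, n_pipelines)
    specs = []
    for i in range(n_pipelines):
        specs.append(PipelineSpec(
            pipeline_id=f"P{i + 1:03d}",
            trimmer=trimmers[i % 3],
            aligner=aligners[(i // 3) % 3],
            counter=counters[i % 2],
            normalization=norms[(i // 2) % 2],
            scale=float(np.exp2(rng.uniform(-1, 1))),
            bias_sd=0.0,
            noise_sd=float(noise[i])))
    return specs
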