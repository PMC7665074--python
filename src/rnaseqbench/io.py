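"""Readers, writers, run configuration and the end-to-end orchestration.

All exchanged tables are UTF-8 TSV with '.' as the decimal separator
(gene descriptions may contain commas, so TSV over CSV). Expression panels
are genes × samples with the gene id in the first column; Ct tables are
long format (gene, sample, duplicate, ct). Parse errors name the offending
line. The truth set and summary are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import benchmark, de_eval, group_stats, hkg, qpcr, synthetic
from .containers import (
    CT_COLUMNS,
    ExpressionPanel,
    SampleSheet,
    manifest_frame,
    validate_ct_table,
)

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


# ---------------------------------------------------------------- panels

def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    frame = panel.values.copy()
    frame.insert(0, "gene_id", frame.index)
    frame.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path,
               pipeline_id: str | None = None,
               labels: Mapping[str, str] | None = None) -> ExpressionPanel:
    """Read a genes × samples TSV; errors name the offending line.

    The header row holds sample ids after the gene-id column. Duplicate
    gene ids, ragged rows and non-numeric cells (including comma decimals)
    are rejected with the 1-based line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise ValueError(f"{path.name}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path.name} line 1: expected gene-id column "
                         "plus at least one sample column")
    samples = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path.name} line {lineno}: ragged row "
                             f"({len(cells)} fields, expected {len(header)})")
        gene = cells[0]
        if gene in seen:
            raise ValueError(f"{path.name} line {lineno}: duplicate gene id "
                             f"{gene!r}")
        seen.add(gene)
        try:
            values = [float(c) for c in cells[1:]]
        except ValueError:
            bad = next(c for c in cells[1:] if not _is_float(c))
            raise ValueError(f"{path.name} line {lineno}: non-numeric cell "
                             f"{bad!r}") from None
        genes.append(gene)
        rows.append(values)
    frame = pd.DataFrame(rows, index=genes, columns=samples)
    labels = dict(labels or {})
    return ExpressionPanel(
        pipeline_id=pipeline_id or path.stem,
        values=frame,
        trimmer=labels.get("trimmer", "NA"),
        aligner=labels.get("aligner", "NA"),
        counter=labels.get("counter", "NA"),
        normalization=labels.get("normalization", "NA"))


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_manifest(panels: Sequence[ExpressionPanel],
                   path: str | Path) -> None:
    manifest_frame(panels).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pipeline_id", "trimmer", "aligner", "counter",
                "normalization"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    if frame["pipeline_id"].duplicated().any():
        raise ValueError("manifest holds duplicate pipeline_id values")
    return frame


def read_panels_dir(panels_dir: str | Path,
                    manifest: pd.DataFrame) -> list[ExpressionPanel]:
    panels_dir = Path(panels_dir)
    panels = []
    for _, row in manifest.iterrows():
        pid = row["pipeline_id"]
        path = panels_dir / f"{pid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"panel file missing for pipeline {pid}: "
                                    f"{path}")
        panels.append(read_panel(path, pipeline_id=pid, labels=row.to_dict()))
    if not panels:
        raise ValueError(f"no panels listed in manifest for {panels_dir}")
    return panels


# ---------------------------------------------------------------- Ct tables

def write_ct(ct: pd.DataFrame, path: str | Path) -> None:
    ct.loc[:, list(CT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_ct(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct TSV and validate it.

    Rejects missing columns, duplicate (gene, sample, duplicate) keys,
    non-positive Ct values and comma-decimal numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {sorted(missing)}")
    bad = [v for v in frame["ct"] if not _is_float(v)]
    if bad:
        raise ValueError(f"{path.name}: non-numeric Ct value {bad[0]!r} "
                         "(decimal separator must be '.')")
    frame["ct"] = frame["ct"].astype(float)
    frame["duplicate"] = frame["duplicate"].astype(int)
    return validate_ct_table(frame)


# ---------------------------------------------------------------- sheets/JSON

def write_sample_sheet(design: SampleSheet, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t",
                        dtype={"sample_id": str, "cell_line": str,
                               "treatment": str, "replicate": int})
    return SampleSheet(frame)


def write_truth(truth: synthetic.TruthSet, path: str | Path) -> None:
    payload = {
        "gene_ids": truth.gene_ids,
        "mu": truth.mu.to_dict(orient="index"),
        "de_labels": truth.de_labels.astype(bool).to_dict(orient="index"),
        "log2fc": truth.log2fc.to_dict(orient="index"),
        "ct_noise_scale": truth.ct_noise_scale.to_dict(),
        "stable_gene": truth.stable_gene,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> synthetic.TruthSet:
    payload = json.loads(Path(path).read_text())
    genes = payload["gene_ids"]
    return synthetic.TruthSet(
        gene_ids=genes,
        mu=pd.DataFrame.from_dict(payload["mu"], orient="index").loc[genes],
        de_labels=pd.DataFrame.from_dict(
            payload["de_labels"], orient="index").loc[genes].astype(bool),
        log2fc=pd.DataFrame.from_dict(
            payload["log2fc"], orient="index").loc[genes],
        ct_noise_scale=pd.Series(payload["ct_noise_scale"]).loc[genes],
        stable_gene=payload["stable_gene"],
        seed=int(payload["seed"]))


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Paths, thresholds and flags for a full benchmark run.

    Defaults mirror the framework's canonical values: expression filter at
    4 units, Ct ceiling 35 cycles, FDR cut-offs 0.05/0.01/0.001 (strictly
    decreasing), 10 + 10 + 10 candidate genes plus controls.
    """

    panels_dir: str
    manifest: str
    ct_table: str
    sample_sheet: str
    out_dir: str
    de_results_dir: str | None = None
    min_units: float = 4.0
    ct_ceiling: float = 35.0
    fdr_cutoffs: list[float] = field(
        default_factory=lambda: [0.05, 0.01, 0.001])
    n_high: int = 10
    n_low: int = 10
    n_mid: int = 10
    control_genes: list[str] = field(default_factory=list)
    seed: int = 0
    truth_cutoff_mode: str = "matched"   # matched | fixed
    fixed_truth_fdr: float = 0.05
    similarity_feature: str = "calls"    # calls | adj_p
    exclude_normalizations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cutoffs = list(self.fdr_cutoffs)
        if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("fdr_cutoffs must be strictly decreasing")
        if self.truth_cutoff_mode not in {"matched", "fixed"}:
            raise ValueError("truth_cutoff_mode must be 'matched' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


# ---------------------------------------------------------------- run_all

def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(config: RunConfig) -> dict:
    """Run the whole benchmark from files and write the report bundle.

    Stages: expression filtering → candidate selection → reference-gene
    stability and the three ΔCt schemes → per-cell-line precision and
    accuracy → overall ranking → by-step group statistics → (when DE
    result tables are supplied) DE diagnostics. Writes TSV/JSON artefacts
    under ``config.out_dir`` and returns the JSON summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_all flags: truth_cutoff_mode=%s similarity_feature=%s "
                "min_units=%s ct_ceiling=%s seed=%s",
                config.truth_cutoff_mode, config.similarity_feature,
                config.min_units, config.ct_ceiling, config.seed)

    design = _stage("read-sample-sheet")(read_sample_sheet)(
        config.sample_sheet)
    manifest = _stage("read-manifest")(read_manifest)(config.manifest)
    panels = _stage("read-panels")(read_panels_dir)(
        config.panels_dir, manifest)
    ct = _stage("read-ct")(read_ct)(config.ct_table)

    control_treatment = list(dict.fromkeys(design.frame["treatment"]))[0]
    control_samples = design.samples_for(treatment=control_treatment)

    @_stage("select-hkg")
    def _hkg():
        return hkg.filter_expressed(panels, control_samples,
                                    config.min_units)
    hkg_set = _hkg()
    write_json({"gene_ids": hkg_set.gene_ids,
                "min_units": hkg_set.min_units,
                "samples": hkg_set.samples,
                "n_panels": hkg_set.n_panels}, out / "hkg.json")

    @_stage("select-candidates")
    def _cand():
        cov = hkg.median_cov(panels, hkg_set.gene_ids, control_samples)
        return hkg.select_candidates(
            hkg_set, cov, config.control_genes,
            config.n_high, config.n_low, config.n_mid, config.seed)
    candidates = _cand()
    write_json({"high_cov": candidates.high_cov,
                "low_cov": candidates.low_cov,
                "mid_random": candidates.mid_random,
                "controls": candidates.controls,
                "seed": candidates.seed}, out / "candidates.json")

    @_stage("stability")
    def _stability():
        groups = {s: design.condition(s)[0] for s in design.sample_ids}
        ct_sub = ct[ct["gene"].isin(candidates.gene_ids)]
        return qpcr.stability_report(ct_sub, groups)
    stability_results, consensus = _stability()
    stab_rows = []
    for res in stability_results:
        for gene in res.values.index:
            stab_rows.append({"gene": gene, "method": res.method,
                              "value": res.values[gene],
                              "rank": res.ranks[gene]})
    pd.DataFrame(stab_rows).to_csv(out / "stability.tsv", sep="\t",
                                   index=False)
    write_json({"most_stable": consensus.most_stable,
                "order": consensus.order,
                "geo_mean": consensus.geo_mean.to_dict()},
               out / "consensus.json")

    @_stage("qpcr-normalize")
    def _delta():
        tables = {
            "global_median": qpcr.delta_ct_global_median(
                ct, config.ct_ceiling),
            "most_stable": qpcr.delta_ct_most_stable(ct, consensus),
        }
        if config.control_genes:
            tables["endogenous"] = qpcr.delta_ct_endogenous(
                ct, config.control_genes)
        return tables
    delta_tables = _delta()
    for scheme, table in delta_tables.items():
        table.frame.to_csv(out / f"delta_ct_{scheme}.tsv", sep="\t",
                           index=False)

    @_stage("benchmark")
    def _scores():
        precision, accuracy = {}, {}
        for cl in design.cell_lines:
            cl_controls = design.samples_for(cl, control_treatment)
            precision[cl] = benchmark.precision_index(
                panels, hkg_set.gene_ids, cl, cl_controls)
            accuracy[cl] = benchmark.accuracy_index(
                panels, ct, candidates.gene_ids, cl, cl_controls)
        return benchmark.overall_ranking(precision, accuracy, manifest)
    scores = _scores()
    table = scores.frame.reset_index()
    table.to_csv(out / "pipeline_scores.tsv", sep="\t", index=False)

    @_stage("compare-step")
    def _steps():
        results = {}
        for step in ("trimmer", "aligner", "counter", "normalization"):
            if manifest[step].nunique() < 2:
                logger.info("skipping step %s: single label level", step)
                continue
            full, reduced = group_stats.compare_step(
                scores, manifest, step, config.exclude_normalizations)
            results[step] = {"full": full, "reduced": reduced}
        return results
    step_results = _steps()
    step_rows = []
    for step, res in step_results.items():
        for tag in ("full", "reduced"):
            r = res[tag]
            if r is None:
                continue
            for _, row in r.pairwise.iterrows():
                step_rows.append({"step": step, "subset": tag,
                                  "kw_h": r.h, "kw_p": r.p, **row.to_dict()})
    pd.DataFrame(step_rows).to_csv(out / "step_comparisons.tsv", sep="\t",
                                   index=False)

    de_summary = None
    if config.de_results_dir is not None:
        @_stage("evaluate-de")
        def _de():
            return evaluate_de_dir(
                config.de_results_dir, delta_tables["global_median"],
                design, config.fdr_cutoffs, config.truth_cutoff_mode,
                config.fixed_truth_fdr, config.similarity_feature, out)
        de_summary = _de()

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_pipelines": len(panels),
        "n_hkg_genes": len(hkg_set),
        "n_candidate_genes": len(candidates),
        "most_stable_gene": consensus.most_stable,
        "top_pipelines": benchmark.top_n(scores, min(10, len(panels))),
        "best_pipeline": benchmark.top_n(scores, 1)[0],
        "step_kw_p": {step: res["full"].p
                      for step, res in step_results.items()},
        "flags": {"truth_cutoff_mode": config.truth_cutoff_mode,
                  "similarity_feature": config.similarity_feature,
                  "min_units": config.min_units,
                  "ct_ceiling": config.ct_ceiling},
    }
    if de_summary is not None:
        summary["de"] = de_summary
    write_json(summary, out / "summary.json")
    return summary


def read_de_results(de_dir: str | Path) -> dict[str, dict[str, pd.Series]]:
    """Read DE result tables: one TSV per method × contrast.

    File naming: ``<method>__<contrast>.tsv`` with columns gene and adj_p
    (optional raw_p, effect). Returns {contrast: {method: adj_p series}}.
    """
    de_dir = Path(de_dir)
    results: dict[str, dict[str, pd.Series]] = {}
    files = sorted(de_dir.glob("*.tsv"))
    if not files:
        raise ValueError(f"no DE result tables found in {de_dir}")
    for path in files:
        stem = path.stem
        if "__" not in stem:
            raise ValueError(f"{path.name}: expected <method>__<contrast>.tsv")
        method, contrast = stem.split("__", 1)
        frame = pd.read_csv(path, sep="\t")
        if "gene" not in frame.columns or "adj_p" not in frame.columns:
            raise ValueError(f"{path.name}: needs columns gene, adj_p")
        series = frame.set_index("gene")["adj_p"].astype(float)
        if ((series < 0) | (series > 1)).any():
            raise ValueError(f"{path.name}: adjusted p outside [0, 1]")
        results.setdefault(contrast, {})[method] = series
    return results


def evaluate_de_dir(de_dir: str | Path,
                    delta_ct: qpcr.DeltaCtTable,
                    design: SampleSheet,
                    cutoffs: Sequence[float],
                    truth_cutoff_mode: str,
                    fixed_truth_fdr: float,
                    similarity_feature: str,
                    out: Path) -> dict:
    """Score every DE result table against qRT-PCR truth; write reports."""
    results = read_de_results(de_dir)
    contrasts = {c.name: c for c in de_eval.default_contrasts(design)}
    metric_rows = []
    for contrast_name, methods in results.items():
        if contrast_name not in contrasts:
            raise ValueError(f"unknown contrast in DE results: "
                             f"{contrast_name!r}")
        contrast = contrasts[contrast_name]
        for cutoff in cutoffs:
            truth_fdr = (cutoff if truth_cutoff_mode == "matched"
                         else fixed_truth_fdr)
            truth = de_eval.qpcr_de_truth(delta_ct, contrast, truth_fdr)
            truth_genes = list(truth.labels.index)
            for method, adj_p in methods.items():
                # DE methods report genome-wide; truth covers the qRT-PCR
                # measured genes only, so score on that intersection
                missing = set(truth_genes) - set(adj_p.index)
                if missing:
                    raise ValueError(
                        f"method {method}: missing qRT-PCR gene(s) "
                        f"{sorted(missing)[:5]}")
                metrics = de_eval.evaluate_method(
                    adj_p.loc[truth_genes], truth, cutoff)
                metric_rows.append({"method": method,
                                    "contrast": contrast_name,
                                    "cutoff": cutoff,
                                    **metrics.as_dict()})
    metrics_table = pd.DataFrame(metric_rows)
    metrics_table.to_csv(out / "de_diagnostics.tsv", sep="\t", index=False)

    counts_frames = []
    for contrast_name, methods in results.items():
        counts = de_eval.deg_counts(methods, cutoffs)
        counts["contrast"] = contrast_name
        counts_frames.append(counts.reset_index())
    pd.concat(counts_frames, ignore_index=True).to_csv(
        out / "deg_counts.tsv", sep="\t", index=False)

    newicks = {}
    for contrast_name, methods in results.items():
        if len(methods) >= 2:
            _, linkage = de_eval.method_similarity(
                methods, cutoffs[0], similarity_feature)
            newicks[contrast_name] = de_eval.linkage_to_newick(
                linkage, list(methods))
    (out / "method_trees.nwk").write_text(
        "".join(f"{name}\t{nwk}\n" for name, nwk in newicks.items()))

    ranking = de_eval.performance_rank(metrics_table)
    ranking["overall"].reset_index(names="method").to_csv(
        out / "de_method_ranking.tsv", sep="\t", index=False)
    best = ranking["overall"].index[0]
    return {"n_methods": int(metrics_table["method"].nunique()),
            "n_contrasts": int(metrics_table["contrast"].nunique()),
            "best_method": str(best)}
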