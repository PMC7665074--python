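"""Score pipelines for precision and accuracy and print the final ranking.

Precision: median cross-pipeline rank of the non-parametric CoV
(MAD/median) over housekeeping genes in each cell line's control
replicates. Accuracy: median cross-pipeline rank of the Pearson r between
expression and qRT-PCR Ct (rank 1 = strongest inverse association). The
overall index sums both over cell lines — lower is better, and with two
cell lines it equals 2 x (median precision + median accuracy).
"""

from rnaseqbench import (
    accuracy_index,
    default_design,
    default_manifest,
    filter_expressed,
    generate_ct_table,
    generate_panels,
    generate_truth,
    median_cov,
    overall_ranking,
    precision_index,
    select_candidates,
    top_n,
)
from rnaseqbench.containers import manifest_frame

design = default_design()
truth = generate_truth(400, design, de_fraction=0.1, effect_size=2.0, seed=1)
manifest = default_manifest(6, seed=1)  # graded noise: P001 is the quietest
panels = generate_panels(truth, manifest, design, seed=1)

controls = design.samples_for(treatment="T0")
hkg = filter_expressed(panels, controls, min_units=4.0)
cov = median_cov(panels, hkg.gene_ids, controls)
candidates = select_candidates(hkg, cov, controls=hkg.gene_ids[:2], seed=1)
ct = generate_ct_table(truth, candidates.gene_ids, design=design, seed=1)

precision, accuracy = {}, {}
for cl in design.cell_lines:
    cl_controls = design.samples_for(cl, "T0")
    precision[cl] = precision_index(panels, hkg.gene_ids, cl, cl_controls)
    accuracy[cl] = accuracy_index(panels, ct, candidates.gene_ids, cl,
                                  cl_controls)

table = overall_ranking(precision, accuracy, manifest_frame(panels))
cols = ["rank", "trimmer", "aligner", "counter", "normalization",
        "median_precision", "median_accuracy", "overall"]
print(f"housekeeping reference set: {len(hkg)} genes; "
      f"qPCR candidates: {len(candidates)} genes")
print(table.frame[cols].to_string())
print(f"best pipeline: {top_n(table, 1)[0]} "
      "(the one generated with the smallest noise sd)")
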