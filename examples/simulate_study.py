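"""Generate a ground-truthed synthetic study and inspect what was planted.

The generator emulates an 18-sample design (2 cell lines × 3 treatments ×
3 replicates), a panel of quantification pipelines with graded distortion,
and a paired qRT-PCR Ct table whose planted most-stable gene carries the
smallest technical noise.
"""

from rnaseqbench import (
    default_design,
    default_manifest,
    generate_ct_table,
    generate_panels,
    generate_truth,
)

design = default_design()
truth = generate_truth(n_genes=200, design=design, de_fraction=0.1,
                       effect_size=2.0, seed=42)
manifest = default_manifest(n_pipelines=6, seed=42)
panels = generate_panels(truth, manifest, design, seed=42)
ct = generate_ct_table(truth, truth.gene_ids[:20], design=design, seed=42)

print(f"design: {len(design.sample_ids)} samples, "
      f"{design.cell_lines} x {sorted(set(design.frame['treatment']))}")
print(f"planted DE genes per contrast:")
for contrast in truth.contrast_names:
    print(f"  {contrast}: {int(truth.de_labels[contrast].sum())}")
print(f"planted most-stable qPCR gene: {truth.stable_gene}")
print(f"pipelines: {[p.pipeline_id for p in panels]} "
      f"(noise sd {[round(s.noise_sd, 2) for s in manifest]})")
print(f"Ct table: {len(ct)} measurements "
      f"({ct['gene'].nunique()} genes x {ct['sample'].nunique()} samples "
      f"x {ct['duplicate'].nunique()} duplicates)")
# Every downstream stage can now be scored against this planted truth.
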