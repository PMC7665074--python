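"""Normalize a small qRT-PCR Ct table under the three ΔCt schemes.

ΔCt = Ct(reference) − Ct(target): larger means more expressed. The three
reference choices are the mean Ct of designated control genes, the
per-sample median Ct of genes below the 35-cycle ceiling, and a single
most-stable gene.
"""

import pandas as pd

from rnaseqbench import (
    delta_ct_endogenous,
    delta_ct_global_median,
    delta_ct_most_stable,
)

ct = pd.DataFrame(
    [("ctrl1", s, d, v) for s, d, v in
     [("s1", 1, 20.0), ("s1", 2, 20.4), ("s2", 1, 21.0), ("s2", 2, 21.2)]]
    + [("ctrl2", s, 1, v) for s, v in [("s1", 22.0), ("s2", 23.0)]]
    + [("ctrl2", s, 2, v) for s, v in [("s1", 22.2), ("s2", 22.8)]]
    + [("target", s, 1, v) for s, v in [("s1", 25.0), ("s2", 27.0)]]
    + [("target", s, 2, v) for s, v in [("s1", 25.4), ("s2", 26.6)]],
    columns=["gene", "sample", "duplicate", "ct"])

for label, delta in [
    ("endogenous (mean of ctrl1, ctrl2)",
     delta_ct_endogenous(ct, ["ctrl1", "ctrl2"])),
    ("global median (Ct < 35)", delta_ct_global_median(ct)),
    ("most stable gene (ctrl1)", delta_ct_most_stable(ct, "ctrl1")),
]:
    print(f"\n{label}:")
    print(delta.wide().round(2).to_string())
# Technical duplicates are averaged first; a negative ΔCt means the gene is
# less abundant than the reference in that sample.
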