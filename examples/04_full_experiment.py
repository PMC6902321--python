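"""The full factorial: 3 models x 3 scenarios over replicates.

Reproduces the layout of the published comparison at a small scale: each
cell is the replicate mean (SD) of a variance component with paired-t stars
against the simulated truth.  Two replicates keep this example quick; the
bundled acceptance suite runs five.
"""

import gsvcbias as g
from gsvcbias.experiment import run_experiment

result = run_experiment(g.mini_scale(), master_seed=3, n_replicates=2,
                        models=("P-AM", "ssGBLUP"),
                        scenarios=("pheno1", "pheno2"))
print(result.to_text())
print()
print("Rows 'truth' give the simulated P-base and G-base variances; the")
print("pheno2 cells are compared against the G-base truth.")
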