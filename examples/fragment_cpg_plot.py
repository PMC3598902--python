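"""The Fragment CpG-plot: kit specificity and sensitivity from sequences alone.

Simulates two virtual capture kits on one genome — one specific and
sensitive (low nonspecific floor, high per-methyl-CpG affinity), one neither
— and prints the normalized CpG-count histogram F_i / sum(F_i) of their
captured fragments.  A low fraction at i = 0 marks specificity; a peak at
low non-zero i marks sensitivity.
"""

from pathlib import Path

import numpy as np

from mbdqc.cpgplot import fragment_cpg_histogram, write_cpg_plot
from mbdqc.simulate import (
    GenomeModel,
    KitArchetype,
    MethylationModel,
    assign_methylation,
    simulate_capture,
    simulate_genome,
)

genome, islands = simulate_genome(GenomeModel(length=200_000), seed=1)
rng = np.random.default_rng(2)
truth = assign_methylation(genome, islands, MethylationModel(), rng)

kits = [KitArchetype(0.01, 0.4, "specific+sensitive"),
        KitArchetype(0.3, 0.05, "nonspecific")]
hists = []
for kit in kits:
    pool = simulate_capture(genome, truth, kit, n_molecules=30_000, seed=rng)
    hists.append(fragment_cpg_histogram(pool, genome, sample_label=kit.label))

outdir = Path("scratch/examples/cpgplot")
outdir.mkdir(parents=True, exist_ok=True)
write_cpg_plot(hists, outdir / "cpg_plot.tsv", figure_path=outdir / "cpg_plot.svg")

for h in hists:
    low_cpg = h.fractions[1:6].sum()
    print(f"{h.sample_label:22s} fraction at 0 CpGs: {h.fractions[0]:.4f}   "
          f"fraction at 1-5 CpGs: {low_cpg:.3f}")
print()
print("The specific kit captures almost no CpG-free fragments (low mass at")
print("i = 0 marks specificity), while the nonspecific kit's histogram tracks")
print("the genomic background. Plot written to", outdir / "cpg_plot.svg")
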