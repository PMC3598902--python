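# mbdqc

Quality evaluation for MBD-based methylation enrichment sequencing
(MBD-seq / MethylCap-seq) from the sequence data itself.

Affinity capture with methyl-CpG binding domains followed by paired-end
sequencing is a cost-efficient route to genome-wide DNA-methylation
profiles, but kits and protocols differ enormously in yield, sensitivity
and specificity — and validating each run externally (bisulfite sequencing,
arrays) is expensive. `mbdqc` implements the sequence-only diagnostics that
make this evaluation cheap:

* **Fragment reconstruction and duplicate collapse.** A *mapped fragment*
  is the reference interval spanning both sequenced mates and the gap
  between them; pairs are kept when both mates map uniquely (MAPQ ≥ 20),
  on one chromosome, inward-oriented, within a 400 bp span. Fragments with
  identical coordinates are presumed PCR copies and collapsed with a
  multiplicity.
* **Yield accounting.** Sequenced → uniquely mapped → non-duplicate
  fragment counts with the standard one-decimal percentages. Low yield with
  a low non-duplicate fraction indicts the capture, not the sequencer.
* **The Fragment CpG-plot.** For `F_i` fragments containing `i` CpGs the
  plot shows `F_i / Σ_i F_i` against `i`. Because fractions sum to one it
  is yield-independent: low mass at `i = 0` indicates capture specificity,
  enrichment at low non-zero `i` indicates sensitivity to sparsely
  methylated loci.
* **Enrichment profiles against independent calls.** Fragment incidences
  over RRBS (2 % bins, coverage ≥ 20) or array beta (5 % bins) methylation
  degrees, normalized to one, divided by the background distribution of all
  assessed CpGs; the bin from which the ratio stays ≥ 1 (the *enrichment
  onset*) proxies sensitivity.
* **A capture simulator.** Synthetic genomes with CpG islands, bimodal
  island methylation, ~200 bp fragmentation, capture probability
  `p(m) = ε + (1 − ε)(1 − (1 − q)^m)` for `m` methylated CpGs, PCR
  duplicates and RRBS-like noisy observation — so the whole chain is
  testable at desk scale.

## Worked example

`python examples/fragment_cpg_plot.py` simulates two virtual kits on one
200 kb genome and prints:

```
specific+sensitive     fraction at 0 CpGs: 0.0064   fraction at 1-5 CpGs: 0.844
nonspecific            fraction at 0 CpGs: 0.1677   fraction at 1-5 CpGs: 0.708
```

The specific kit (ε = 0.01, q = 0.4) captures almost no CpG-free fragments
— 0.6 % versus 17 % for the nonspecific one (ε = 0.3, q = 0.05) — which is
exactly the signature the Fragment CpG-plot reads off real libraries.
`examples/enrichment_profile.py` does the same against a simulated RRBS
table:

```
fraction of incidences in bins 0-4  (degree < 0.10): kit 0.076 vs background 0.136
fraction of incidences in bins 45-49 (degree >= 0.90): kit 0.465 vs background 0.433
enrichment onset: bin 14 (methylation degree >= 0.28)
```

i.e. the virtual kit is depleted for unmethylated loci, enriched for
methylated ones, and its profile rises above background from ~28 %
methylation upward.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation end-to-end from the given seed: it simulates
a capture experiment, reconstructs and deduplicates fragments from the
emitted mate pairs, prints the yield accounting, the Fragment CpG-plot
fraction at zero CpGs and the enrichment-onset bin, and writes the JSON
result table to `--out`.

## Layout

```
src/mbdqc/
  fragio.py          alignments, FASTA, methylation tables; fragments; yield
  cpgplot.py         CpG counting and the Fragment CpG-plot
  enrichprofile.py   binned methylation profiles, background ratio, onset
  simulate.py        genome/methylation/capture/sequencing/bisulfite models
  pipeline.py        stage runners with config + run manifests
examples/            one narrative script per capability
docs/methods.md      models, parameters, numerical choices, limitations
```
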