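"""The Fragment CpG-plot: CpG counts per mapped fragment, normalized.

For a sample with F_i fragments containing i CpGs, the plot depicts
F_i / sum_i(F_i) against i.  Low mass at i = 0 indicates capture specificity
(few fragments without any CpG); enrichment at low non-zero i indicates
sensitivity to sparsely methylated loci.  Because the fractions sum to one
the diagnostic is independent of sequencing yield.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mbdqc.fragio import MappedFragment, ReferenceGenome


@dataclass
class FragmentCpGHistogram:
    """Counts F_i of fragments with i CpGs, i = 0..i_max, plus fractions."""

    counts: np.ndarray
    sample_label: str = "sample"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1-d array of non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("histogram has no fragments")
        return self.counts / self.total

    @property
    def i_max(self) -> int:
        return len(self.counts) - 1


def count_cpgs(fragment: MappedFragment, genome: ReferenceGenome) -> int:
    """Number of CpG dinucleotides wholly inside the fragment interval.

    Counted on the forward strand only (CpG is its own reverse complement,
    so counting both strands would double).  Matching is case-insensitive by
    default so soft-masked repeats keep their CpGs; N never matches.  A "CG"
    whose G lies outside [start, end) is not counted.
    """
    seq = genome.fetch(fragment.chrom, fragment.start, fragment.end)
    return seq.upper().count("CG")


def fragment_cpg_histogram(
    fragments: Sequence[MappedFragment],
    genome: ReferenceGenome,
    dedup: bool = True,
    sample_label: str = "sample",
) -> FragmentCpGHistogram:
    """Tally F_i over fragments and return the normalized histogram.

    With ``dedup=True`` (default, matching the use of non-duplicate
    fragments) each distinct fragment counts once regardless of its
    multiplicity; with ``dedup=False`` multiplicities weight the tally.
    """
    if len(fragments) == 0:
        raise ValueError("cannot build a Fragment CpG-plot from zero fragments")
    cpg_counts = np.array([count_cpgs(f, genome) for f in fragments])
    weights = (
        np.ones(len(fragments), dtype=np.int64)
        if dedup
        else np.array([f.multiplicity for f in fragments], dtype=np.int64)
    )
    counts = np.bincount(cpg_counts, weights=weights).astype(np.int64)
    return FragmentCpGHistogram(counts, sample_label=sample_label)


def write_cpg_plot(
    histograms: FragmentCpGHistogram | Sequence[FragmentCpGHistogram],
    table_path: str | Path,
    figure_path: str | Path | None = None,
    i_max_display: int | None = None,
) -> None:
    """Write the Fragment CpG-plot table (and optionally an overlay figure).

    The TSV carries one row per (sample, i): columns sample, i, F_i,
    fraction.  ``i_max_display`` truncates the *figure* x-axis only; the
    table always carries the full histogram.
    """
    if isinstance(histograms, FragmentCpGHistogram):
        histograms = [histograms]
    if len(histograms) == 0:
        raise ValueError("need at least one histogram")
    rows = []
    for h in histograms:
        fracs = h.fractions
        for i, (c, f) in enumerate(zip(h.counts, fracs)):
            rows.append({"sample": h.sample_label, "i": i, "F_i": int(c), "fraction": f})
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False, float_format="%.17g")

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for h in histograms:
            xs = np.arange(len(h.counts))
            ax.plot(xs, h.fractions, marker="o", markersize=3, label=h.sample_label)
        ax.set_xlabel("CpGs per mapped fragment (i)")
        ax.set_ylabel("fraction of fragments  $F_i/\\Sigma_i F_i$")
        ax.set_title("Fragment CpG-plot")
        if i_max_display is not None:
            ax.set_xlim(-0.5, i_max_display + 0.5)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(figure_path)
        plt.close(fig)


def read_cpg_table(table_path: str | Path) -> dict[str, FragmentCpGHistogram]:
    """Re-read a Fragment CpG-plot TSV into histograms keyed by sample label."""
    df = pd.read_csv(table_path, sep="\t", dtype={"sample": str})
    out: dict[str, FragmentCpGHistogram] = {}
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values("i")
        counts = np.zeros(int(grp["i"].max()) + 1, dtype=np.int64)
        counts[grp["i"].to_numpy()] = grp["F_i"].to_numpy()
        out[sample] = FragmentCpGHistogram(counts, sample_label=sample)
    return out
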