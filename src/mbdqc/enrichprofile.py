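"""Yield-independent enrichment profiles over binned methylation degrees.

Fragments are related to independently assessed per-CpG methylation degrees
(RRBS-like counts or array-like betas).  Degrees are binned (2% bins for
RRBS, 5% for arrays) and each fragment contributes one incidence to every
bin represented among its assessed CpGs; the per-bin incidence fractions sum
to one, so the profile is independent of sequencing yield.  Dividing a kit's
profile by the background profile (the distribution of all assessed degrees)
gives per-bin enrichment ratios; the lowest bin from which the ratio stays
>= 1 upward is the enrichment onset, a proxy for capture sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mbdqc.fragio import DEFAULT_MIN_COVERAGE, MappedFragment, MethylationTable

logger = logging.getLogger("mbdqc")

RRBS_BIN_WIDTH = 0.02
ARRAY_BIN_WIDTH = 0.05

#: nudge so a degree within float error of a bin edge lands in the upper bin
_EDGE_EPS = 1e-9


def n_bins(bin_width: float) -> int:
    return math.ceil(1.0 / bin_width - _EDGE_EPS)


def assign_bin(degree: float, bin_width: float) -> int:
    """Bin index for a methylation degree: floor(degree / w), last bin closed.

    Edges are half-open ([k·w, (k+1)·w)); a degree exactly at an edge (or
    within float error of it) goes to the upper bin — the deterministic
    tie-break — and degree 1.0 falls in the last bin.
    """
    if not 0.0 <= degree <= 1.0:
        raise ValueError(f"methylation degree {degree} outside [0, 1]")
    nb = n_bins(bin_width)
    return min(int(degree / bin_width + _EDGE_EPS), nb - 1)


def _assign_bins(degrees: np.ndarray, bin_width: float) -> np.ndarray:
    if len(degrees) and (np.min(degrees) < 0 or np.max(degrees) > 1):
        raise ValueError("methylation degrees outside [0, 1]")
    nb = n_bins(bin_width)
    return np.minimum((degrees / bin_width + _EDGE_EPS).astype(np.int64), nb - 1)


@dataclass
class MethylationBinProfile:
    """Per-bin incidence counts and fractions over binned methylation degrees."""

    bin_width: float
    raw_counts: np.ndarray
    kind: str = "kit"  # "kit" or "background"

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
        if len(self.raw_counts) != n_bins(self.bin_width):
            raise ValueError(
                f"expected {n_bins(self.bin_width)} bins for width {self.bin_width}, "
                f"got {len(self.raw_counts)}"
            )
        if (self.raw_counts < 0).any():
            raise ValueError("incidence counts must be non-negative")

    @property
    def bin_edges(self) -> np.ndarray:
        nb = n_bins(self.bin_width)
        edges = np.arange(nb + 1) * self.bin_width
        edges[-1] = 1.0
        return edges

    @property
    def total(self) -> int:
        return int(self.raw_counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("profile has no incidences")
        return self.raw_counts / self.total


def filter_by_coverage(
    table: MethylationTable, min_cov: int = DEFAULT_MIN_COVERAGE
) -> MethylationTable:
    """Drop CpG records observed at coverage below ``min_cov``.

    Only read-count (rrbs) sources carry real coverage; array-like and
    ground-truth tables pass unchanged.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if table.source_kind != "rrbs" or min_cov == 0:
        return MethylationTable(table.df.copy(), table.source_kind)
    kept = table.df[table.df["coverage"] >= min_cov].reset_index(drop=True)
    return MethylationTable(kept, table.source_kind)


def _per_chrom_index(table: MethylationTable, bin_width: float):
    """Sorted CpG positions and their bin indices, per chromosome."""
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in table.df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        deg = grp["degree"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        index[chrom] = (pos[order], _assign_bins(deg[order], bin_width))
    return index


def fragment_bin_fractions(
    fragments: Sequence[MappedFragment],
    table: MethylationTable,
    bin_width: float = RRBS_BIN_WIDTH,
    semantics: str = "set",
) -> MethylationBinProfile:
    """Per-bin fractions of fragment incidences over assessed methylation bins.

    A CpG is "in" a fragment when its forward-strand C position lies in
    [start, end).  With ``semantics="set"`` (default) a fragment contributes
    one incidence to each *distinct* bin among its assessed CpGs — a fragment
    with several CpGs may belong to several fractions, but multiple same-bin
    CpGs count once.  ``semantics="cpg"`` counts every assessed CpG.
    Fragments containing no assessed CpG contribute nothing.  The table
    should already be coverage-filtered and the fragments deduplicated.
    """
    if semantics not in ("set", "cpg"):
        raise ValueError(f"unknown incidence semantics {semantics!r}")
    nb = n_bins(bin_width)
    index = _per_chrom_index(table, bin_width)
    counts = np.zeros(nb, dtype=np.int64)
    n_empty = 0
    for f in fragments:
        if f.chrom not in index:
            n_empty += 1
            continue
        pos, bins = index[f.chrom]
        lo = np.searchsorted(pos, f.start, side="left")
        hi = np.searchsorted(pos, f.end, side="left")
        if hi == lo:
            n_empty += 1
            continue
        hit = bins[lo:hi]
        if semantics == "set":
            hit = np.unique(hit)
        np.add.at(counts, hit, 1)
    if counts.sum() == 0:
        raise ValueError(
            f"no overlap between the {len(fragments)} fragments and the "
            f"{len(table)} assessed CpGs — check chromosome naming and coverage filter"
        )
    logger.info(
        "fragment_bin_fractions: %d incidences from %d fragments "
        "(%d fragments without assessed CpGs)",
        int(counts.sum()),
        len(fragments),
        n_empty,
    )
    return MethylationBinProfile(bin_width, counts, kind="kit")


def background_profile(
    table: MethylationTable, bin_width: float = RRBS_BIN_WIDTH
) -> MethylationBinProfile:
    """Distribution of all assessed methylation degrees (one incidence per CpG)."""
    if len(table) == 0:
        raise ValueError("cannot build a background profile from an empty table")
    bins = _assign_bins(table.df["degree"].to_numpy(dtype=float), bin_width)
    counts = np.bincount(bins, minlength=n_bins(bin_width)).astype(np.int64)
    return MethylationBinProfile(bin_width, counts, kind="background")


@dataclass
class EnrichmentProfile:
    """Per-bin kit/background fraction ratios with the enrichment-onset bin.

    ``ratio`` is NaN where the background fraction is zero (missing, not
    infinite).  ``onset_bin`` is the lowest bin index from which the ratio is
    >= 1 in every higher *occupied* bin — the methylation degree above which
    the kit consistently enriches over background — or None when even the
    topmost occupied bin is below background.
    """

    bin_width: float
    ratio: np.ndarray
    onset_bin: int | None = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        defined = ~np.isnan(self.ratio)
        if (self.ratio[defined] < 0).any():
            raise ValueError("enrichment ratios must be >= 0 where defined")
        object.__setattr__(self, "onset_bin", self._compute_onset())

    def _compute_onset(self) -> int | None:
        ok = np.isnan(self.ratio) | (self.ratio >= 1.0)
        defined = ~np.isnan(self.ratio)
        if not defined.any():
            return None
        last_defined = int(np.max(np.nonzero(defined)[0]))
        if not ok[: last_defined + 1][::-1][0]:
            return None
        onset = last_defined
        for i in range(last_defined, -1, -1):
            if not ok[i]:
                break
            if defined[i]:
                onset = i
        return onset


def enrichment_ratio(
    kit: MethylationBinProfile, background: MethylationBinProfile
) -> EnrichmentProfile:
    """Divide a kit profile by the background profile, bin by bin."""
    if kit.bin_width != background.bin_width or len(kit.raw_counts) != len(
        background.raw_counts
    ):
        raise ValueError("kit and background profiles must share binning")
    kf = kit.fractions
    bf = background.fractions
    ratio = np.full(len(kf), np.nan)
    occupied = bf > 0
    ratio[occupied] = kf[occupied] / bf[occupied]
    return EnrichmentProfile(kit.bin_width, ratio)


def write_profile_table(
    kit: MethylationBinProfile,
    background: MethylationBinProfile,
    profile: EnrichmentProfile,
    path,
) -> None:
    """TSV with (bin_low, bin_high, kit_fraction, background_fraction, ratio)."""
    import pandas as pd

    edges = kit.bin_edges
    pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "kit_fraction": kit.fractions,
            "background_fraction": background.fractions,
            "ratio": profile.ratio,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def plot_profiles(
    kits: dict[str, MethylationBinProfile],
    background: MethylationBinProfile,
    figure_path,
) -> None:
    """Two-panel overlay: per-bin fractions (with background) and ratios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = background.bin_edges
    mids = (edges[:-1] + edges[1:]) / 2
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    ax1.plot(mids, background.fractions, color="black", label="background")
    for label, prof in kits.items():
        ax1.plot(mids, prof.fractions, label=label)
        r = enrichment_ratio(prof, background)
        ax2.plot(mids, r.ratio, label=label)
    ax2.axhline(1.0, color="black", linewidth=0.8, linestyle="--")
    ax1.set_xlabel("methylation degree")
    ax1.set_ylabel("fraction of fragment incidences")
    ax2.set_xlabel("methylation degree")
    ax2.set_ylabel("ratio to background")
    ax1.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)
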