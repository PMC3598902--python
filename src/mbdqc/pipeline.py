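"""Stage runners tying the QC chain together with config and manifests.

Each ``run_*`` function consumes a :class:`RunConfig`, writes plain-text TSV
outputs (figures optionally) into ``config.outdir`` and drops a JSON run
manifest (parameters, package version, seed, input checksums, outputs) so
every run is reproducible from its manifest.  Per-filter rejection tallies
are logged for audit against the conservation invariants.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from mbdqc import __version__
from mbdqc import cpgplot, enrichprofile, fragio, simulate

logger = logging.getLogger("mbdqc")

STAGES = ("fragments", "yield", "cpgplot", "enrich-profile", "simulate")


@dataclass
class RunConfig:
    """Everything one stage run needs; defaults mirror the QC conventions.

    ``max_span`` 400 bp, mapping quality >= 20 for "unique", duplicate
    collapse on, coverage filter >= 20 for RRBS-like tables, bin width 0.02
    (RRBS) / 0.05 (array).
    """

    stage: str
    outdir: str | Path = "."
    alignments: str | Path | None = None
    dialect: str = "sam"
    fragments_bed: str | Path | None = None
    reference: str | Path | None = None
    methylation: str | Path | None = None
    methylation_kind: str = "rrbs"
    max_span: int = fragio.DEFAULT_MAX_SPAN
    mapq_threshold: int = fragio.DEFAULT_MAPQ_THRESHOLD
    dedup: bool = True
    bin_width: float | None = None
    min_coverage: int = fragio.DEFAULT_MIN_COVERAGE
    semantics: str = "set"
    figures: bool = False
    seed: int = 0
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.max_span <= 0 or self.min_coverage < 0 or self.mapq_threshold < 0:
            raise ValueError("numeric parameters outside documented ranges")

    def effective_bin_width(self) -> float:
        if self.bin_width is not None:
            return self.bin_width
        return (
            enrichprofile.ARRAY_BIN_WIDTH
            if self.methylation_kind == "array"
            else enrichprofile.RRBS_BIN_WIDTH
        )


class MissingInputError(FileNotFoundError):
    pass


def _require(path: str | Path | None, what: str) -> Path:
    if path is None:
        raise MissingInputError(f"stage requires {what}, but none was configured")
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"{what} not found: {p}")
    return p


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    config: RunConfig, outdir: Path, inputs: list[Path], outputs: list[Path]
) -> Path:
    manifest = {
        "stage": config.stage,
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()
        },
        "inputs": {str(p): _md5(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / f"{config.stage.replace('-', '_')}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_fragments(config: RunConfig, inputs: list[Path]) -> list[fragio.MappedFragment]:
    """Fragments from a BED, or reconstructed (and optionally deduped) from alignments."""
    if config.fragments_bed is not None:
        bed = _require(config.fragments_bed, "fragments BED")
        inputs.append(bed)
        return fragio.read_fragments_bed(bed)
    aln = _require(config.alignments, "alignments (SAM/BEDPE)")
    inputs.append(aln)
    pairs = fragio.read_alignment_pairs(aln, config.dialect, config.mapq_threshold)
    fragments = fragio.reconstruct_fragments(pairs, max_span=config.max_span)
    if config.dedup:
        fragments = fragio.deduplicate_fragments(fragments)
    return fragments


def run_fragments(config: RunConfig) -> Path:
    """Reconstruct (and dedup) fragments; write them as BED."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    fragments = _load_fragments(config, inputs)
    bed = outdir / "fragments.bed"
    fragio.write_fragments_bed(fragments, bed)
    _write_manifest(config, outdir, inputs, [bed])
    return bed


def run_yield(config: RunConfig) -> Path:
    """Yield accounting: sequenced / uniquely mapped / non-duplicate counts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = _require(config.alignments, "alignments (SAM/BEDPE)")
    pairs = fragio.read_alignment_pairs(aln, config.dialect, config.mapq_threshold)
    tally = fragio.FilterTally()
    unique = fragio.reconstruct_fragments(pairs, max_span=config.max_span, tally=tally)
    dedup = fragio.deduplicate_fragments(unique)
    summary = fragio.yield_summary(len(pairs), unique, dedup)
    out = outdir / "yield_summary.tsv"
    fragio.write_yield_summary(summary, out)
    logger.info(
        "yield: %d pairs -> %d unique -> %d non-duplicate", len(pairs), len(unique), len(dedup)
    )
    _write_manifest(config, outdir, [aln], [out])
    return out


def run_cpgplot(config: RunConfig) -> Path:
    """Fragment CpG-plot table (and figure when ``figures`` is set)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    fragments = _load_fragments(config, inputs)
    ref = _require(config.reference, "reference FASTA")
    inputs.append(ref)
    genome = fragio.read_reference(ref)
    hist = cpgplot.fragment_cpg_histogram(fragments, genome, dedup=config.dedup)
    table = outdir / "cpg_plot.tsv"
    fig = outdir / "cpg_plot.svg" if config.figures else None
    cpgplot.write_cpg_plot(hist, table, figure_path=fig)
    outputs = [table] + ([fig] if fig else [])
    _write_manifest(config, outdir, inputs, outputs)
    return table


def run_enrich_profile(config: RunConfig) -> Path:
    """Binned fraction profiles vs independent methylation calls, plus ratios."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    fragments = _load_fragments(config, inputs)
    meth_path = _require(config.methylation, "methylation TSV")
    inputs.append(meth_path)
    table = fragio.read_methylation_table(meth_path, config.methylation_kind)
    table = enrichprofile.filter_by_coverage(table, config.min_coverage)
    w = config.effective_bin_width()
    kit = enrichprofile.fragment_bin_fractions(fragments, table, w, config.semantics)
    background = enrichprofile.background_profile(table, w)
    ratio = enrichprofile.enrichment_ratio(kit, background)
    out = outdir / "enrichment_profile.tsv"
    enrichprofile.write_profile_table(kit, background, ratio, out)
    outputs = [out]
    if config.figures:
        fig = outdir / "enrichment_profile.svg"
        enrichprofile.plot_profiles({"kit": kit}, background, fig)
        outputs.append(fig)
    logger.info("enrich-profile: onset bin %s", ratio.onset_bin)
    _write_manifest(config, outdir, inputs, outputs)
    return out


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a full synthetic experiment: FASTA, BEDPE, BED, TSVs, metadata."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(config.sim)
    genome_model = simulate.GenomeModel(**sim.pop("genome_model", {}))
    meth_model = simulate.MethylationModel(**sim.pop("methylation_model", {}))
    kit = simulate.KitArchetype(**sim.pop("kit", {"epsilon": 0.02, "q": 0.25}))
    exp = simulate.simulate_experiment(
        seed=config.seed,
        genome_model=genome_model,
        methylation_model=meth_model,
        kit=kit,
        **sim,
    )
    paths = {
        "fasta": outdir / "genome.fa",
        "bedpe": outdir / "sequenced.bedpe",
        "bed": outdir / "sequenced.bed",
        "rrbs": outdir / "observed_rrbs.tsv",
        "true": outdir / "true_methylation.tsv",
        "metadata": outdir / "simulation_metadata.json",
    }
    fragio.write_fasta(exp.genome, paths["fasta"])
    fragio.write_pairs_bedpe(exp.sequenced, paths["bedpe"])
    fragio.write_fragments_bed(exp.sequenced, paths["bed"])
    fragio.write_methylation_table(exp.observed_rrbs, paths["rrbs"])
    fragio.write_methylation_table(
        fragio.MethylationTable(exp.true_methylation.df, "array"), paths["true"]
    )
    paths["metadata"].write_text(
        json.dumps(
            {
                "seed": exp.seed,
                "params": exp.params,
                "n_islands": len(exp.islands),
                "n_cpgs": len(exp.true_methylation),
                "pool_size": len(exp.captured_pool),
                "n_sequenced": len(exp.sequenced),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    _write_manifest(config, outdir, [], list(paths.values()))
    return paths


_RUNNERS = {
    "fragments": run_fragments,
    "yield": run_yield,
    "cpgplot": run_cpgplot,
    "enrich-profile": run_enrich_profile,
    "simulate": run_simulate,
}


def run(config: RunConfig):
    """Dispatch a configured stage; returns the primary output path(s)."""
    return _RUNNERS[config.stage](config)
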