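"""Pipeline orchestration: simulate -> mappability -> nuclear calling ->
mitochondrial calling -> rate estimation.

A single seed in the config drives every stage; per-stage child seeds are
derived by indexed spawning from that seed, so any stage can be re-run
independently with identical results.  All outputs are plain text (FASTA,
TSV pileups, BED, VCF, JSON) and a MANIFEST records a content hash of each
artifact for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .consensus import mean_coverage
from .io_formats import GenomeSequence, read_fasta, read_pileup
from .mappability import MappabilityMask, SelfMapParams, self_map_coverage, unique_fraction
from .mito_heteroplasmy import MitoParams, call_heteroplasmies, mito_rate
from .nuclear_calling import (
    FilterParams,
    classify_genome,
    extract_mutations,
    iter_classifications,
    tally,
)
from .rate_estimation import error_rate, focal_filter_mask, rate_ci
from .synthetic_data import (
    BASE_ARR,
    SimulationConfig,
    counts_to_sites,
    simulate_experiment,
)

log = logging.getLogger("malines")


def stage_seed(seed: int, stage_index: int) -> int:
    """Child seed for one pipeline stage, kept below 2**31."""
    state = np.random.SeedSequence([seed, stage_index]).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


def ref_index(genome: GenomeSequence) -> np.ndarray:
    """Base -> column index array; -1 where the reference is N."""
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    idx = np.searchsorted(BASE_ARR, np.clip(arr, None, ord("T")))
    idx = np.where(
        (idx < 4) & (BASE_ARR[np.clip(idx, 0, 3)] == arr), idx, -1
    )
    return idx


def counts_from_pileup(
    path: str | Path, dialect: str, genome: GenomeSequence
) -> np.ndarray:
    """Load one line's pileup file into an (n_sites, 4) count matrix,
    extended to the full contig length (absent positions get depth 0)."""
    counts = np.zeros((len(genome), 4), dtype=np.int64)
    for site in read_pileup(path, dialect):
        if site.contig != genome.name:
            continue
        if site.position > len(genome):
            raise io_formats.FormatError(
                f"{path}: position {site.position} beyond contig "
                f"{genome.name!r} length {len(genome)}"
            )
        for b, c in site.counts.items():
            counts[site.position - 1, io_formats.BASE_INDEX[b]] = c
    return counts


def read_mask_bed(path: str | Path, genome: GenomeSequence) -> MappabilityMask:
    """Rebuild a unique-site mask from its BED output.

    Self-coverage is not recoverable from BED; it is filled with 2L inside
    unique blocks and 0 outside, which preserves the unique flags.
    """
    unique = np.zeros(len(genome), dtype=bool)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end = line.split()[:3]
            if contig == genome.name:
                unique[int(start) : int(end)] = True
    L = 31
    return MappabilityMask(
        contig=genome.name,
        read_length=L,
        self_coverage=np.where(unique, 2 * L, 0),
        unique=unique,
    )


@dataclass
class PipelineConfig:
    """Everything `run-all` needs.  The defaults are a demonstration-scale
    version of the study design: three lines, 1000 generations, ~10x
    nuclear coverage, deep mitochondrial coverage with planted
    heteroplasmies."""

    seed: int = 0
    outdir: str = "malines_out"
    generations: int = 1000
    level: float = 0.95
    filters: FilterParams = field(default_factory=FilterParams)
    mito: MitoParams = field(default_factory=MitoParams)
    selfmap: SelfMapParams = field(default_factory=SelfMapParams)
    nuclear_sim: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            genome_length=40_000,
            at_fraction=0.78,
            repeat_spec=[(120, 2)],
            true_nuclear_rate=5e-8,
            shared_diff_count=5,
            mean_coverage=(9.0, 10.0, 11.0),
            per_read_error=0.002,
            contig_name="chr1",
        )
    )
    mito_sim: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            genome_length=4_000,
            at_fraction=0.7257,
            mean_coverage=(4000.0,),
            per_read_error=0.002,
            heteroplasmy_spec=[(0.44, 1), (0.08, 3), (0.05, 2)],
            circular=True,
            contig_name="mito",
        )
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "outdir", "generations", "level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filters" in raw:
            kwargs["filters"] = FilterParams(**raw["filters"])
        if "mito" in raw:
            kwargs["mito"] = MitoParams(**raw["mito"])
        if "selfmap" in raw:
            kwargs["selfmap"] = SelfMapParams(**raw["selfmap"])
        for key in ("nuclear_sim", "mito_sim"):
            if key in raw:
                spec = dict(raw[key])
                if "repeat_spec" in spec:
                    spec["repeat_spec"] = [tuple(x) for x in spec["repeat_spec"]]
                if "heteroplasmy_spec" in spec:
                    spec["heteroplasmy_spec"] = [
                        tuple(x) for x in spec["heteroplasmy_spec"]
                    ]
                kwargs[key] = SimulationConfig(**spec)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the full artifact set.

    Returns the rates report.  A MANIFEST.json listing each artifact with
    its SHA-256 is written last; on a stage failure the partial outputs
    remain and the MANIFEST marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"complete": False, "files": {}}
    manifest_path = outdir / "MANIFEST.json"

    def record(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    try:
        # Stage 1: simulate nuclear and mitochondrial data sets.
        nuc_cfg = dataclasses.replace(
            config.nuclear_sim, seed=stage_seed(config.seed, 0)
        )
        mito_cfg = dataclasses.replace(
            config.mito_sim, seed=stage_seed(config.seed, 1)
        )
        log.info("simulating nuclear data (%d bp)", nuc_cfg.genome_length)
        nuc = simulate_experiment(nuc_cfg)
        log.info("simulating mitochondrial data (%d bp)", mito_cfg.genome_length)
        mito = simulate_experiment(mito_cfg)

        with open(outdir / "reference.fa", "w") as fh:
            for g in (nuc.genome, mito.genome):
                fh.write(f">{g.name}\n{g.sequence}\n")
        record(outdir / "reference.fa")
        for exp in (nuc, mito):
            for lid, counts in exp.counts.items():
                p = outdir / f"{exp.genome.name}.{lid}.pileup.tsv"
                io_formats.write_simple_pileup(
                    counts_to_sites(counts, exp.genome), p
                )
                record(p)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "nuclear_mutations": nuc.truth.mutations,
                    "shared_diffs": nuc.truth.shared_diffs,
                    "heteroplasmies": mito.truth.heteroplasmies,
                },
                fh,
                indent=2,
            )
        record(outdir / "truth.json")

        # Stage 2: mappability masks.
        log.info("self-mapping nuclear contig")
        nuc_mask = self_map_coverage(nuc.genome, config.selfmap)
        log.info("self-mapping mitochondrial contig (circular)")
        mito_mask = self_map_coverage(mito.genome, config.selfmap)
        for mask in (nuc_mask, mito_mask):
            p = outdir / f"{mask.contig}.unique.bed"
            io_formats.write_mask_bed(mask, p)
            record(p)

        # Stage 3: nuclear calling.
        log.info("classifying nuclear sites")
        line_ids = list(nuc.counts)
        counts3 = np.stack([nuc.counts[l] for l in line_ids])
        means = [
            mean_coverage(counts3[i].sum(axis=1), nuc_mask, line_ids[i]).mean_coverage
            for i in range(len(line_ids))
        ]
        outcomes = classify_genome(
            counts3, nuc.ref_idx, nuc_mask.unique, means, config.filters
        )
        t = tally(outcomes, line_ids)
        muts = extract_mutations(
            outcomes, counts3, nuc.ref_idx, nuc.genome.name, line_ids
        )
        io_formats.write_vcf(muts, outdir / "mutations.vcf", "reference.fa")
        record(outdir / "mutations.vcf")
        io_formats.write_classifications_tsv(
            iter_classifications(outcomes, nuc.genome.name, line_ids),
            outdir / "classifications.tsv",
        )
        record(outdir / "classifications.tsv")

        # Stage 4: mitochondrial heteroplasmy calling.
        log.info("calling mitochondrial heteroplasmies")
        het_calls, n_sites = call_heteroplasmies(
            mito.counts,
            mito.ref_idx,
            mito_mask.unique,
            config.mito,
            contig=mito.genome.name,
        )
        with open(outdir / "heteroplasmies.tsv", "w") as fh:
            fh.write("contig\tposition\tline\tref\talt\tfrequency\tcoverage\n")
            for c in het_calls:
                fh.write(
                    f"{c.contig}\t{c.position}\t{c.line_id}\t{c.ref_base}\t"
                    f"{c.alt_base}\t{c.frequency:.6f}\t{c.coverage}\n"
                )
        record(outdir / "heteroplasmies.tsv")
        mito_est = mito_rate(
            het_calls, n_sites, config.generations, config.level
        )

        # Stage 5: rates report.
        log.info("estimating rates")
        nuclear_est = rate_ci(
            t.mutations, t.unchanged + t.mutations, config.generations,
            config.level,
        )
        err_raw = error_rate({l: nuc.counts[l] for l in line_ids})
        err_filt = error_rate(
            {l: nuc.counts[l] for l in line_ids},
            {
                l: focal_filter_mask(
                    nuc.counts[l], nuc_mask.unique, means[i], config.filters
                )
                for i, l in enumerate(line_ids)
            },
        )
        report = {
            "parameters": {
                "seed": config.seed,
                "generations": config.generations,
                "level": config.level,
                "filters": dataclasses.asdict(config.filters),
                "mito": dataclasses.asdict(config.mito),
                "selfmap": dataclasses.asdict(config.selfmap),
            },
            "mappability": {
                nuc.genome.name: dict(
                    zip(("fraction", "bases"), unique_fraction(nuc_mask))
                ),
                mito.genome.name: dict(
                    zip(("fraction", "bases"), unique_fraction(mito_mask))
                ),
            },
            "nuclear": {
                "tally": t.to_dict(),
                "rate": nuclear_est.to_dict(),
            },
            "mitochondrial": mito_est.to_dict(),
            "error_rate": {
                "unfiltered": err_raw.per_line | {"overall": err_raw.overall},
                "filtered": err_filt.per_line | {"overall": err_filt.overall},
            },
        }
        io_formats.write_rates_json(report, outdir / "rates.json")
        record(outdir / "rates.json")
        manifest["complete"] = True
        return report
    finally:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
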