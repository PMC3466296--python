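"""Synthetic genomes, planted mutations, and error-bearing pileups.

The study's raw reads are not needed to exercise any pipeline stage: every
rule downstream of alignment consumes only per-site base counts, so the
simulator emulates the data at that level.  It reproduces the features of
the real experiment that the rules react to:

* an AT-rich haploid genome (78% AT nuclear, 72.57% mitochondrial) with
  optional exact repeat blocks that defeat the mappability mask;
* per-line point mutations planted at a known true rate over g generations
  (counts Poisson-distributed, positions uniform, alternate base uniform
  over the three non-reference bases);
* shared ancestor-vs-reference differences present identically in every
  line — the phenomenon behind the published 1916-of-1917 shared-candidate
  exclusions;
* heteroplasmic mitochondrial sites where each read's template base is the
  alternate with probability equal to the site's true allele frequency;
* Poisson-distributed coverage (defaults 9-11x nuclear, thousands-x
  mitochondrial) and a uniform per-read error rate e (default 0.002), with
  errors uniform over the three other bases.

Reads are never materialised: nothing in the calling rules looks at a read
beyond its base at one site, so pileup counts are drawn directly
(multinomially given the depth).  Everything is bit-reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import BASES, GenomeSequence, PileupSite

BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-condition defaults: 3 MA lines, g = 1000 generations, ~10x
    nuclear coverage, per-read error 0.002, 78% AT."""

    seed: int = 0
    genome_length: int = 50_000
    at_fraction: float = 0.78
    repeat_spec: list[tuple[int, int]] = field(default_factory=list)
    n_lines: int = 3
    generations: int = 1000
    true_nuclear_rate: float = 0.0
    shared_diff_count: int = 0
    mean_coverage: Sequence[float] = (9.0, 10.0, 11.0)
    per_read_error: float = 0.002
    heteroplasmy_spec: list[tuple[float, int]] = field(default_factory=list)
    circular: bool = False
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.at_fraction <= 1:
            raise ValueError("at_fraction must be in [0, 1]")
        if not 0 <= self.per_read_error < 1:
            raise ValueError("per_read_error must be in [0, 1)")
        if self.genome_length < 1 or self.n_lines < 1 or self.generations < 1:
            raise ValueError("lengths and counts must be positive")
        if len(self.mean_coverage) not in (1, self.n_lines):
            raise ValueError(
                "mean_coverage must have one entry or one per line"
            )
        expected = self.true_nuclear_rate * self.genome_length * self.generations
        if expected >= self.genome_length / 10:
            raise ValueError(
                "true_nuclear_rate * length * generations too large "
                "(planted mutations would saturate the genome)"
            )

    @property
    def line_ids(self) -> list[str]:
        return [f"line{i+1}" for i in range(self.n_lines)]

    def coverage_for(self, line_index: int) -> float:
        if len(self.mean_coverage) == 1:
            return float(self.mean_coverage[0])
        return float(self.mean_coverage[line_index])


@dataclass
class TruthSet:
    """Ground truth of one simulation, for recovery tests."""

    mutations: dict[str, list[tuple[int, str, str]]]  # line -> (pos1, ref, alt)
    shared_diffs: list[tuple[int, str, str]]
    heteroplasmies: dict[str, list[tuple[int, str, str, float]]]
    depths: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[tuple[int, int]]]:
    """Draw an i.i.d. genome with P(A)=P(T)=at_fraction/2, then stamp exact
    repeat blocks.

    Each ``(block_length, copies)`` entry copies one randomly placed source
    block to copies-1 further non-overlapping locations, creating exact
    duplications the mappability stage must mask.  Returns the genome and
    the 0-based half-open coordinates of all repeat block placements.
    """
    if rng is None:
        rng = _rng(config.seed)
    n = config.genome_length
    at = config.at_fraction
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    seq = rng.choice(BASE_ARR, size=n, p=p)

    placements: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []

    def free(start: int, length: int) -> bool:
        return all(
            start + length <= s or start >= e for s, e in occupied
        )

    for block_len, copies in config.repeat_spec:
        if block_len * copies > n:
            raise ValueError(
                f"repeat block {block_len}x{copies} exceeds genome length"
            )
        spots = []
        for _ in range(10_000):
            s = int(rng.integers(0, n - block_len + 1))
            if free(s, block_len):
                spots.append(s)
                occupied.append((s, s + block_len))
                if len(spots) == copies:
                    break
        else:
            raise ValueError("could not place repeat blocks without overlap")
        src = seq[spots[0] : spots[0] + block_len].copy()
        for s in spots:
            seq[s : s + block_len] = src
            placements.append((s, s + block_len))

    genome = GenomeSequence(
        name=config.contig_name,
        sequence=seq.tobytes().decode(),
        circular=config.circular,
    )
    return genome, sorted(placements)


def _mutate_base(rng: np.random.Generator, base_idx: int) -> int:
    """Uniform choice among the three non-reference bases."""
    return int((base_idx + 1 + rng.integers(0, 3)) % 4)


def plant_mutations(
    genome: GenomeSequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], TruthSet]:
    """Per line, plant Poisson(rate * length * g) point mutations, plus
    shared ancestor-vs-reference differences applied identically to every
    line.  Returns per-line true genomes (as base-index arrays) and the
    truth set.  Planted positions are distinct within and across lines so
    each mutation is unambiguously unique to its line."""
    if rng is None:
        rng = _rng(config.seed)
    n = len(genome)
    ref = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    ref_idx = np.searchsorted(BASE_ARR, ref)  # BASE_ARR is sorted (ACGT)

    lam = config.true_nuclear_rate * n * config.generations
    per_line_counts = rng.poisson(lam, size=config.n_lines)
    total_needed = int(per_line_counts.sum()) + config.shared_diff_count
    if total_needed > n:
        raise ValueError("more planted changes than genome positions")
    all_pos = rng.choice(n, size=total_needed, replace=False)

    truth = TruthSet(mutations={}, shared_diffs=[], heteroplasmies={})
    genomes: dict[str, np.ndarray] = {}
    cursor = 0

    shared_pos = all_pos[:config.shared_diff_count]
    cursor = config.shared_diff_count
    shared: list[tuple[int, str, str]] = []
    shared_alt = {}
    for pos in shared_pos:
        alt = _mutate_base(rng, int(ref_idx[pos]))
        shared_alt[int(pos)] = alt
        shared.append((int(pos) + 1, BASES[ref_idx[pos]], BASES[alt]))
    truth.shared_diffs = sorted(shared)

    for i, lid in enumerate(config.line_ids):
        g = ref_idx.copy()
        for pos, alt in shared_alt.items():
            g[pos] = alt
        muts = []
        k = int(per_line_counts[i])
        for pos in all_pos[cursor : cursor + k]:
            alt = _mutate_base(rng, int(ref_idx[pos]))
            g[pos] = alt
            muts.append((int(pos) + 1, BASES[ref_idx[pos]], BASES[alt]))
        cursor += k
        truth.mutations[lid] = sorted(muts)
        genomes[lid] = g
    return genomes, truth


def plant_heteroplasmies(
    genome: GenomeSequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[int, str, str, float]]]:
    """Assign heteroplasmic sites per line from ``heteroplasmy_spec``
    (list of (frequency, count) groups).  Positions are drawn without
    replacement across ALL lines, so no planted heteroplasmy recurs in two
    lines (recurrence would trigger the multi-line exclusion)."""
    if rng is None:
        rng = _rng(config.seed)
    n = len(genome)
    ref = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    ref_idx = np.searchsorted(BASE_ARR, ref)
    total = sum(c for _, c in config.heteroplasmy_spec) * config.n_lines
    if total > n:
        raise ValueError("more heteroplasmies than genome positions")
    pos_pool = iter(rng.choice(n, size=total, replace=False))
    out: dict[str, list[tuple[int, str, str, float]]] = {}
    for lid in config.line_ids:
        entries = []
        for freq, count in config.heteroplasmy_spec:
            for _ in range(count):
                pos = int(next(pos_pool))
                alt = _mutate_base(rng, int(ref_idx[pos]))
                entries.append(
                    (pos + 1, BASES[ref_idx[pos]], BASES[alt], float(freq))
                )
        out[lid] = sorted(entries)
    return out


def simulate_pileups(
    line_genome: np.ndarray,
    mean_coverage: float,
    per_read_error: float,
    rng: np.random.Generator,
    heteroplasmies: Sequence[tuple[int, str, str, float]] = (),
) -> np.ndarray:
    """Draw a (n_sites, 4) count matrix for one line.

    Depth ~ Poisson(mean_coverage) per site.  Each read reports the
    template base with probability 1 - e and one of the other three bases
    with probability e/3 each.  At heteroplasmic sites the template of
    each read is the alternate base with probability equal to the site's
    true frequency, the line's base otherwise.
    """
    n = len(line_genome)
    e = per_read_error
    depth = rng.poisson(mean_coverage, size=n)

    # Per-site category probabilities: start from the pure-template error
    # kernel, then mix in heteroplasmic templates.
    probs = np.full((n, 4), e / 3.0)
    probs[np.arange(n), line_genome] = 1.0 - e
    for pos1, _ref, alt, freq in heteroplasmies:
        i = pos1 - 1
        tmpl = np.full(4, e / 3.0)
        tmpl[line_genome[i]] = 1.0 - e
        alt_tmpl = np.full(4, e / 3.0)
        alt_tmpl[BASES.index(alt)] = 1.0 - e
        probs[i] = (1.0 - freq) * tmpl + freq * alt_tmpl

    return rng.multinomial(depth, probs)


@dataclass
class SimulatedExperiment:
    """A full simulated data set: reference, per-line counts, truth."""

    genome: GenomeSequence
    repeat_blocks: list[tuple[int, int]]
    ref_idx: np.ndarray
    counts: dict[str, np.ndarray]  # line id -> (n_sites, 4)
    truth: TruthSet
    config: SimulationConfig


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Genome -> planted mutations (and heteroplasmies) -> pileup counts,
    all from the single config seed via spawned child streams so stages
    are independently reproducible."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(3 + config.n_lines)]
    genome, blocks = simulate_genome(config, rngs[0])
    genomes, truth = plant_mutations(genome, config, rngs[1])
    het = (
        plant_heteroplasmies(genome, config, rngs[2])
        if config.heteroplasmy_spec
        else {lid: [] for lid in config.line_ids}
    )
    truth.heteroplasmies = het
    ref = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    ref_idx = np.searchsorted(BASE_ARR, ref)
    counts = {}
    for i, lid in enumerate(config.line_ids):
        counts[lid] = simulate_pileups(
            genomes[lid],
            config.coverage_for(i),
            config.per_read_error,
            rngs[3 + i],
            heteroplasmies=het[lid],
        )
        truth.depths[lid] = counts[lid].sum(axis=1)
    return SimulatedExperiment(
        genome=genome,
        repeat_blocks=blocks,
        ref_idx=ref_idx,
        counts=counts,
        truth=truth,
        config=config,
    )


def counts_to_sites(
    counts: np.ndarray, genome: GenomeSequence
) -> list[PileupSite]:
    """Materialise a count matrix as PileupSite records (simple_tsv form)."""
    sites = []
    for i in range(len(genome)):
        c = {b: int(counts[i, j]) for j, b in enumerate(BASES) if counts[i, j]}
        sites.append(
            PileupSite(
                contig=genome.name,
                position=i + 1,
                ref_base=genome.sequence[i],
                counts=c,
            )
        )
    return sites
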