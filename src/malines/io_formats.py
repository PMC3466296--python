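"""Reading and writing the formats the pipeline touches.

The atom of the analysis is the per-site, per-line base count: every
downstream rule (majority consensus, the mutation/unchanged classification,
heteroplasmy frequencies) consumes counts over {A, C, G, T} at a 1-based
reference position.  Two pileup dialects are supported:

* ``classic10col`` — the classic samtools 0.1.x ``pileup -c`` layout:
  chromosome, position, reference base, consensus base, consensus quality,
  SNP quality, RMS mapping quality, read depth, read-base string, base
  qualities.  The read-base string is decoded into counts; base qualities
  are parsed but ignored (the calling rules use only base identity,
  coverage and agreement).
* ``simple_tsv`` — contig, position, ref, countA, countC, countG, countT;
  the dialect the simulator writes.

Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.  Dialects are never auto-detected: silently misreading
column 4 (consensus) as column 9 (read bases) would corrupt counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_VALID_CHARS = set("ACGTN")


class FormatError(ValueError):
    """A malformed input file (names the offending line where possible)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A reference contig.

    Nuclear contigs are linear; the mitochondrial contig may be circular,
    in which case windows and positions wrap across the origin.
    """

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"contig {self.name!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PileupSite:
    """Base counts for one line at one reference position (1-based).

    ``depth`` equals the sum of counts: N, indel symbols and deletion
    placeholders are excluded before counting.
    """

    contig: str
    position: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for b in list(self.counts):
            if b not in BASE_INDEX:
                raise ValueError(f"count for non-ACGT base {b!r}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of contigs, case-folded to upper case.

    Record order is preserved.  Characters outside {A,C,G,T,N} raise
    :class:`FormatError`.
    """
    records = []
    path = Path(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters "
                f"{sorted(bad)!r}"
            )
        records.append(GenomeSequence(name=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def decode_pileup_bases(read_string: str, ref_base: str) -> dict[str, int]:
    """Decode a classic pileup read-base string into counts over {A,C,G,T}.

    ``.``/``,`` count as the reference base; ``^X`` (read start, X is the
    mapping-quality character) and ``$`` (read end) are stripped; indel
    fields ``+n<seq>``/``-n<seq>``, deletion placeholders ``*`` and
    ambiguous ``N`` are skipped; mismatch bases are case-folded.
    """
    ref = ref_base.upper()
    counts: dict[str, int] = {}
    i, n = 0, len(read_string)
    while i < n:
        c = read_string[i]
        if c == "^":
            i += 2  # skip the mapping-quality character too
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and read_string[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(
                    f"truncated indel length field at offset {i} in "
                    f"{read_string!r}"
                )
            length = int(read_string[i + 1 : j])
            if j + length > n:
                raise FormatError(
                    f"indel sequence runs past end of string at offset {i}"
                )
            i = j + length
            continue
        if c in ".,":
            if ref in BASE_INDEX:
                counts[ref] = counts.get(ref, 0) + 1
            i += 1
            continue
        b = c.upper()
        if b in BASE_INDEX:
            counts[b] = counts.get(b, 0) + 1
        # '*', 'N', and anything unrecognised contribute nothing
        i += 1
    return counts


def _parse_classic_row(fields: list[str], row_no: int) -> PileupSite:
    if len(fields) != 10:
        raise FormatError(
            f"row {row_no}: expected 10 columns (classic pileup), "
            f"got {len(fields)}"
        )
    contig, pos, ref = fields[0], int(fields[1]), fields[2].upper()
    counts = decode_pileup_bases(fields[8], ref)
    return PileupSite(contig=contig, position=pos, ref_base=ref, counts=counts)


def _parse_simple_row(fields: list[str], row_no: int) -> PileupSite:
    if len(fields) != 7:
        raise FormatError(
            f"row {row_no}: expected 7 columns (simple_tsv), got {len(fields)}"
        )
    contig, pos, ref = fields[0], int(fields[1]), fields[2].upper()
    counts = {
        b: int(fields[3 + i]) for i, b in enumerate(BASES) if int(fields[3 + i])
    }
    return PileupSite(contig=contig, position=pos, ref_base=ref, counts=counts)


def read_pileup(
    path: str | Path,
    dialect: str,
    extend_to: Mapping[str, str] | None = None,
) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` rows from a pileup file.

    Parameters
    ----------
    path
        Plain-text pileup file.
    dialect
        ``"classic10col"`` or ``"simple_tsv"``; never auto-detected.
    extend_to
        Optional mapping contig name -> reference sequence.  When given,
        positions absent from the file are emitted as depth-0 sites so the
        stream spans the full genome (the "extended pileup").  Contigs are
        emitted in mapping order; rows in the file must be sorted by
        position within each contig.
    """
    if dialect == "classic10col":
        parse = _parse_classic_row
    elif dialect == "simple_tsv":
        parse = _parse_simple_row
    else:
        raise ValueError(f"unknown pileup dialect {dialect!r}")

    def rows() -> Iterator[PileupSite]:
        with open(path) as fh:
            for row_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                yield parse(line.split("\t"), row_no)

    if extend_to is None:
        yield from rows()
        return

    # Full-genome extension: fill gaps with depth-0 sites.
    pending = rows()
    current = next(pending, None)
    for contig, refseq in extend_to.items():
        for pos in range(1, len(refseq) + 1):
            if (
                current is not None
                and current.contig == contig
                and current.position == pos
            ):
                yield current
                current = next(pending, None)
            else:
                yield PileupSite(
                    contig=contig,
                    position=pos,
                    ref_base=refseq[pos - 1],
                    counts={},
                )


def write_simple_pileup(sites: Iterable[PileupSite], path: str | Path) -> None:
    """Write sites in the 7-column simple_tsv dialect."""
    with open(path, "w") as fh:
        for s in sites:
            cols = [s.contig, str(s.position), s.ref_base] + [
                str(s.counts.get(b, 0)) for b in BASES
            ]
            fh.write("\t".join(cols) + "\n")


def write_vcf(calls, path: str | Path, reference: str | None = None) -> None:
    """Write mutation calls as a minimal VCF v4.2 file.

    INFO carries the MA line id, read depth and agreement fraction.
    An empty call set yields a header-only (still valid) file.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference:
            fh.write(f"##reference={reference}\n")
        fh.write('##INFO=<ID=LINE,Number=1,Type=String,Description="MA line">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##INFO=<ID=AGREE,Number=1,Type=Float,'
            'Description="Majority agreement fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"LINE={c.line_id};DP={c.coverage};AGREE={c.agreement:.4f}"
            fh.write(
                f"{c.contig}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}"
                f"\t.\tPASS\t{info}\n"
            )


def write_mask_bed(mask, path: str | Path) -> None:
    """Write the uniquely-mappable regions of a mask as BED.

    Internal coordinates are 1-based inclusive; BED is 0-based half-open,
    so a unique block over 1-based positions [31, 100] becomes "30 100".
    """
    with open(path, "w") as fh:
        for start0, end0 in mask.unique_blocks():
            fh.write(f"{mask.contig}\t{start0}\t{end0}\n")


def write_classifications_tsv(classifications, path: str | Path) -> None:
    """Per-line, per-site classification table (mirrors the decision-rule
    diagram columns: position, line, outcome, exclusion reason)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tline\toutcome\treason\n")
        for c in classifications:
            fh.write(
                f"{c.contig}\t{c.position}\t{c.line_id}\t{c.outcome}"
                f"\t{c.reason or '.'}\n"
            )


def write_rates_json(report: dict, path: str | Path) -> None:
    """Structured rate report; full precision is retained here even though
    human-facing summaries round to 2 significant figures."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
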