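"""Splice-junction extraction from gapped RNA-seq alignments.

A spliced alignment carries one or more ``N`` (reference-skip) CIGAR
operations; each skip spans the excised intron of one splice junction.
Junction coordinates are 1-based and intron-anchored: ``donor`` is the
first intronic base after the upstream exon, ``acceptor`` the last
intronic base before the downstream exon.  This matches the convention
of the common aligner splice-junction tables and converts directly to
exon borders (upstream exon ends at donor-1, downstream exon starts at
acceptor+1).

Only alignments that pass a configurable filter policy contribute
support: by default primary, properly paired, non-duplicated spliced
alignments whose read strand (``XS`` attribute) matches the strand of
the target locus.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

__all__ = [
    "Locus",
    "AlignmentFilterPolicy",
    "SpliceJunction",
    "ExtractionStats",
    "DEFAULT_AR_LOCUS",
    "extract_spliced_alignments",
    "junctions_from_alignment",
    "count_junctions",
    "extract_cohort",
    "write_junction_table",
    "read_junction_table",
]

_CIGAR_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_CIGAR_SKIP = 3


@dataclass(frozen=True)
class SpliceJunction:
    """An intron call: (chrom, donor, acceptor, strand) is the identity key.

    ``donor`` and ``acceptor`` are the first and last intronic base
    (1-based, inclusive); strand is '+', '-' or '.' when unresolved.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(
                f"junction donor must precede acceptor, got {self.donor} >= {self.acceptor}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.donor}-{self.acceptor}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "SpliceJunction":
        m = re.fullmatch(r"(.+):(\d+)-(\d+):([+\-.])", key)
        if m is None:
            raise ValueError(f"malformed junction key {key!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass(frozen=True)
class Locus:
    """A 1-based inclusive genomic interval with strand and build label."""

    chrom: str
    start: int
    end: int
    strand: str
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus strand must be + or -, got {self.strand!r}")

    @classmethod
    def parse(cls, text: str, genome_build: str = "GRCh37") -> "Locus":
        """Parse ``chrX:66763863-66951462:+`` (';' also accepted as separator)."""
        m = re.fullmatch(r"([^:;]+)[:;](\d+)-(\d+)[:;]([+\-])", text.strip())
        if m is None:
            raise ValueError(f"cannot parse locus string {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4), genome_build)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


#: The androgen-receptor locus used by default on real data (GRCh37).
DEFAULT_AR_LOCUS = Locus("chrX", 66763863, 66951462, "+", "GRCh37")


@dataclass(frozen=True)
class AlignmentFilterPolicy:
    """Which alignment classes qualify as junction support.

    Defaults implement the usual stringent choice: primary, properly
    paired, non-duplicated spliced alignments on the locus strand.
    Supplementary (chimeric) alignments are excluded together with
    secondary ones under ``require_primary``.
    """

    require_primary: bool = True
    require_properly_paired: bool = True
    exclude_duplicates: bool = True
    require_strand_match: bool = True


@dataclass
class ExtractionStats:
    """Tallies of why records were kept or rejected during extraction."""

    total: int = 0
    kept: int = 0
    unmapped: int = 0
    off_locus: int = 0
    not_spliced: int = 0
    not_primary: int = 0
    not_proper_pair: int = 0
    duplicate: int = 0
    strand_unresolved: int = 0
    strand_mismatch: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _is_spliced(record: pysam.AlignedSegment) -> bool:
    cig = record.cigartuples
    return cig is not None and any(op == _CIGAR_SKIP for op, _ in cig)


def _overlaps_locus(record: pysam.AlignedSegment, locus: Locus) -> bool:
    # Block-level test: any gapless aligned block must intersect the interval,
    # so a read whose intron merely spans the locus does not count as overlap.
    if record.reference_name != locus.chrom:
        return False
    lo, hi = locus.start - 1, locus.end  # 0-based half-open
    if record.reference_start >= hi or (record.reference_end or 0) <= lo:
        return False
    return any(bs < hi and be > lo for bs, be in record.get_blocks())


def read_strand(record: pysam.AlignedSegment) -> str | None:
    """Transcript strand of a spliced read from its ``XS`` attribute."""
    try:
        xs = record.get_tag("XS")
    except KeyError:
        return None
    return xs if xs in {"+", "-"} else None


def extract_spliced_alignments(
    alignment_file: str | Path,
    locus: Locus,
    policy: AlignmentFilterPolicy = AlignmentFilterPolicy(),
    stats: ExtractionStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Yield qualifying spliced alignments overlapping ``locus``.

    A record qualifies when it (a) overlaps the locus with at least one
    aligned block, (b) contains >=1 reference skip, and (c) satisfies every
    enabled policy flag.  Records lacking a strand attribute while
    ``require_strand_match`` is on are skipped and tallied as
    ``strand_unresolved`` in ``stats`` rather than raising.
    """
    path = Path(alignment_file)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        afile = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise ValueError(f"unreadable alignment file {path}: {exc}") from exc
    with afile:
        for record in afile:
            if stats:
                stats.total += 1
            if record.is_unmapped or record.cigartuples is None:
                if stats:
                    stats.unmapped += 1
                continue
            if not _overlaps_locus(record, locus):
                if stats:
                    stats.off_locus += 1
                continue
            if not _is_spliced(record):
                if stats:
                    stats.not_spliced += 1
                continue
            if policy.require_primary and (record.is_secondary or record.is_supplementary):
                if stats:
                    stats.not_primary += 1
                continue
            if policy.require_properly_paired and not record.is_proper_pair:
                if stats:
                    stats.not_proper_pair += 1
                continue
            if policy.exclude_duplicates and record.is_duplicate:
                if stats:
                    stats.duplicate += 1
                continue
            if policy.require_strand_match:
                strand = read_strand(record)
                if strand is None:
                    if stats:
                        stats.strand_unresolved += 1
                    continue
                if strand != locus.strand:
                    if stats:
                        stats.strand_mismatch += 1
                    continue
            if stats:
                stats.kept += 1
            yield record


def junctions_from_alignment(record: pysam.AlignedSegment) -> list[SpliceJunction]:
    """Decode one SpliceJunction per reference-skip gap, in read order.

    donor = reference position immediately after the preceding aligned
    block; acceptor = position immediately before the following block
    (both 1-based).  Strand comes from the read's XS attribute, '.' when
    absent.
    """
    cig = record.cigartuples
    if cig is None:
        raise ValueError(f"record {record.query_name!r} has no alignment gap structure")
    strand = read_strand(record) or "."
    chrom = record.reference_name
    pos = record.reference_start  # 0-based
    out: list[SpliceJunction] = []
    for op, length in cig:
        if op == _CIGAR_SKIP:
            out.append(SpliceJunction(chrom, pos + 1, pos + length, strand))
            pos += length
        elif op in _CIGAR_REF_CONSUMING:
            pos += length
    return out


def count_junctions(
    records_per_sample: Mapping[str, Iterable[pysam.AlignedSegment]],
) -> pd.DataFrame:
    """Tally junction read support per sample.

    Returns a samples x junctions integer DataFrame indexed by sample id
    with junction-key columns.  A read spanning k junctions contributes 1
    to each of the k.  All-zero junctions are dropped, so every retained
    junction has support in at least one sample.
    """
    samples = list(records_per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("sample identifiers must be unique")
    tallies: dict[str, Counter] = {}
    for sample, records in records_per_sample.items():
        counter: Counter = Counter()
        for record in records:
            try:
                juncs = junctions_from_alignment(record)
            except ValueError:
                continue  # malformed gap structure: skip the record
            for j in juncs:
                counter[j.key] += 1
        tallies[sample] = counter
    all_keys = sorted(
        {k for c in tallies.values() for k in c},
        key=lambda k: (lambda j: (j.chrom, j.donor, j.acceptor, j.strand))(
            SpliceJunction.from_key(k)
        ),
    )
    counts = pd.DataFrame(
        [[tallies[s].get(k, 0) for k in all_keys] for s in samples],
        index=pd.Index(samples, name="sample"),
        columns=all_keys,
        dtype=int,
    )
    return counts


def extract_cohort(
    alignment_files: Mapping[str, str | Path],
    locus: Locus,
    policy: AlignmentFilterPolicy = AlignmentFilterPolicy(),
) -> tuple[pd.DataFrame, dict[str, ExtractionStats]]:
    """Run extraction + counting over a cohort of sample -> SAM/BAM path."""
    stats: dict[str, ExtractionStats] = {}

    def _records():
        for sample, path in alignment_files.items():
            stats[sample] = ExtractionStats()
            yield sample, list(
                extract_spliced_alignments(path, locus, policy, stats[sample])
            )

    counts = count_junctions(dict(_records()))
    return counts, stats


def write_junction_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Serialize a junction count matrix as TSV.

    Columns: chrom, donor, acceptor, strand, then one count column per
    sample (junctions as rows, which keeps wide cohorts readable).
    """
    rows = []
    for key in counts.columns:
        j = SpliceJunction.from_key(key)
        rows.append((j.chrom, j.donor, j.acceptor, j.strand))
    meta = pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "strand"])
    table = pd.concat([meta, counts.T.reset_index(drop=True)], axis=1)
    table.to_csv(path, sep="\t", index=False)


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_junction_table` (samples x junction keys)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    keys = [
        SpliceJunction(r.chrom, int(r.donor), int(r.acceptor), r.strand).key
        for r in table.itertuples()
    ]
    counts = table.drop(columns=["chrom", "donor", "acceptor", "strand"]).T
    counts.columns = keys
    counts.index.name = "sample"
    return counts.astype(int)
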