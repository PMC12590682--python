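"""SAM/BAM parsing, identity filtering, and the three gene-count modes.

Reads aligned against the gene catalogue are grouped per read, filtered on
alignment identity (default >= 95%, >= 98% in fast mode), and converted to
per-gene counts under one of three modes:

``unique``
    a gene is credited only with reads whose group maps to that single gene;
``total``
    every gene of a group is credited 1 per read;
``shared`` (default)
    unique reads count 1; a multi-mapped read on genes *G* is apportioned
    in proportion to each gene's unique count, or evenly (1/|G|) when no
    gene of the group has unique support.

Input SAM/BAM must be name-grouped (e.g. ``samtools sort -n``); the NM tag
is required for identity computation.  Each mate of a pair is an
independent read unit by default; ``fragments=True`` collapses mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

DEFAULT_MIN_IDENTITY = 0.95
FAST_MIN_IDENTITY = 0.98


class CountingError(Exception):
    pass


@dataclass
class AlignmentRecord:
    read_id: str
    gene_id: str
    aligned_length: int
    edit_distance: int
    is_secondary: bool = False
    mate_index: int = 1

    def __post_init__(self) -> None:
        if self.aligned_length <= 0:
            raise CountingError(f"{self.read_id}: non-positive aligned length")
        if self.edit_distance < 0:
            raise CountingError(f"{self.read_id}: negative edit distance")


@dataclass
class AlignmentGroup:
    """All retained alignments of one read unit, deduplicated per gene."""

    read_id: str
    records: list[AlignmentRecord]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


@dataclass
class GeneCounts:
    sample_id: str
    counts: dict[str, float]
    mode: str
    n_reads_retained: int

    def detected_genes(self, min_count: float = 1.0) -> set[str]:
        """Genes with at least ``min_count`` (default: >= 1 mapped read)."""
        return {g for g, c in self.counts.items() if c >= min_count}


@dataclass
class FilterStats:
    """Bookkeeping for the identity filter, per sample."""

    n_read_units: int = 0
    n_retained: int = 0
    n_dropped_identity: int = 0
    n_missing_nm: int = 0

    def mapping_rate(self, n_total_reads: int | None = None) -> float:
        denom = n_total_reads if n_total_reads else self.n_read_units
        return self.n_retained / denom if denom else 0.0


def alignment_identity(rec: AlignmentRecord) -> float:
    """Fraction of aligned bases that match: (len - NM) / len."""
    return (rec.aligned_length - rec.edit_distance) / rec.aligned_length


def iter_sam_alignments(
    path: str | Path, stats: FilterStats | None = None
) -> Iterator[tuple[AlignmentRecord, pysam.AlignedSegment]]:
    """Stream mapped alignment records (with their pysam segments).

    Unmapped and duplicate-flagged segments are skipped; secondary and
    supplementary alignments are kept (multi-mapping is the point of
    shared counting).  Segments without an NM tag are dropped and counted
    in ``stats.n_missing_nm``.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_duplicate:
                continue
            try:
                nm = int(seg.get_tag("NM"))
            except KeyError:
                if stats is not None:
                    stats.n_missing_nm += 1
                continue
            alen = seg.query_alignment_length
            if alen is None or alen <= 0:
                continue
            rec = AlignmentRecord(
                read_id=seg.query_name,
                gene_id=seg.reference_name,
                aligned_length=alen,
                edit_distance=nm,
                is_secondary=seg.is_secondary,
                mate_index=2 if (seg.is_paired and seg.is_read2) else 1,
            )
            yield rec, seg


def _group_pairs(
    pairs: Iterable[tuple[AlignmentRecord, object]],
    min_identity: float,
    stats: FilterStats,
    fragments: bool = False,
) -> Iterator[tuple[str, list[tuple[AlignmentRecord, object]]]]:
    """Group (record, payload) pairs by read unit and apply the filter.

    Requires name-grouped input: once a read name is left behind it must
    not reappear, otherwise a name-sort is demanded.
    """
    seen: set[str] = set()
    current: str | None = None
    block: list[tuple[AlignmentRecord, object]] = []

    def flush() -> Iterator[tuple[str, list[tuple[AlignmentRecord, object]]]]:
        units: dict[str, list[tuple[AlignmentRecord, object]]] = {}
        paired = len({r.mate_index for r, _ in block}) > 1
        for rec, payload in block:
            if fragments or not paired:
                key = rec.read_id
            else:
                key = f"{rec.read_id}/{rec.mate_index}"
            units.setdefault(key, []).append((rec, payload))
        for key in units:
            stats.n_read_units += 1
            kept: dict[str, tuple[AlignmentRecord, object]] = {}
            for rec, payload in units[key]:
                if alignment_identity(rec) < min_identity:
                    continue
                prev = kept.get(rec.gene_id)
                # best alignment per gene within a group
                if prev is None or alignment_identity(rec) > alignment_identity(prev[0]):
                    kept[rec.gene_id] = (rec, payload)
            if kept:
                stats.n_retained += 1
                yield key, [kept[g] for g in sorted(kept)]
            else:
                stats.n_dropped_identity += 1

    for rec, payload in pairs:
        if rec.read_id != current:
            if current is not None:
                yield from flush()
                seen.add(current)
            if rec.read_id in seen:
                raise CountingError(
                    f"read {rec.read_id!r} reappears: input is not name-grouped; "
                    "name-sort the SAM/BAM (samtools sort -n) first"
                )
            current = rec.read_id
            block = []
        block.append((rec, payload))
    if current is not None:
        yield from flush()


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    stats: FilterStats | None = None,
    fragments: bool = False,
) -> Iterator[AlignmentGroup]:
    """Filter an alignment stream on identity and group it per read."""
    stats = stats if stats is not None else FilterStats()
    pairs = ((r, None) for r in records)
    for key, kept in _group_pairs(pairs, min_identity, stats, fragments):
        yield AlignmentGroup(read_id=key, records=[r for r, _ in kept])


def load_groups(
    path: str | Path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    fragments: bool = False,
) -> tuple[list[AlignmentGroup], FilterStats]:
    """Read a SAM/BAM and return filtered alignment groups plus stats."""
    stats = FilterStats()
    records = (rec for rec, _ in iter_sam_alignments(path, stats))
    groups = list(filter_alignments(records, min_identity, stats, fragments))
    return groups, stats


def count_unique(groups: Iterable[AlignmentGroup], sample_id: str = "") -> GeneCounts:
    """Count only reads whose group maps to a single gene."""
    counts: dict[str, float] = {}
    n = 0
    for g in groups:
        n += 1
        if len(g.records) == 1:
            gid = g.records[0].gene_id
            counts[gid] = counts.get(gid, 0) + 1
    return GeneCounts(sample_id, counts, "unique", n)


def count_total(groups: Iterable[AlignmentGroup], sample_id: str = "") -> GeneCounts:
    """Credit every gene of a group with 1 per read."""
    counts: dict[str, float] = {}
    n = 0
    for g in groups:
        n += 1
        for rec in g.records:
            counts[rec.gene_id] = counts.get(rec.gene_id, 0) + 1
    return GeneCounts(sample_id, counts, "total", n)


def count_shared(groups: Iterable[AlignmentGroup], sample_id: str = "") -> GeneCounts:
    """Apportion multi-mapped reads by unique-count proportions.

    Single-pass: weights come from the final unique counts over the same
    groups (no iterative refinement).  Total mass equals the number of
    retained reads.
    """
    groups = list(groups)
    unique = count_unique(groups).counts
    counts: dict[str, float] = {}
    for g in groups:
        genes = sorted({r.gene_id for r in g.records})
        if len(genes) == 1:
            counts[genes[0]] = counts.get(genes[0], 0.0) + 1.0
            continue
        denom = sum(unique.get(x, 0) for x in genes)
        for x in genes:
            w = unique.get(x, 0) / denom if denom > 0 else 1.0 / len(genes)
            counts[x] = counts.get(x, 0.0) + w
    return GeneCounts(sample_id, counts, "shared", len(groups))


_COUNTERS = {"unique": count_unique, "total": count_total, "shared": count_shared}


def count_sam(
    path: str | Path,
    mode: str = "shared",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    sample_id: str | None = None,
    fragments: bool = False,
) -> tuple[GeneCounts, FilterStats]:
    """Convenience wrapper: SAM/BAM -> GeneCounts in one call."""
    if mode not in _COUNTERS:
        raise CountingError(f"unknown counting mode {mode!r}")
    groups, stats = load_groups(path, min_identity, fragments)
    sid = sample_id if sample_id is not None else Path(path).stem
    return _COUNTERS[mode](groups, sid), stats


def write_counts(counts: GeneCounts, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("gene_id\tcount\n")
        for g in sorted(counts.counts):
            fh.write(f"{g}\t{counts.counts[g]:.6g}\n")
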