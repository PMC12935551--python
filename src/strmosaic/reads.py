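"""Read-record plumbing: a light container over SAM/BAM alignments.

Sequences are stored in the orientation SAM reports them (reference
orientation for mapped reads); downstream code is strand-agnostic — purity
scoring covers both strands of a motif class, and flank anchoring is tried
in both read orientations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

log = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    read_id: str
    fragment_id: str
    mate_index: int  # 1 or 2
    seq: str
    quals: list[int]  # Phred scores, one per base
    chrom: str | None
    pos: int | None  # 0-based leftmost aligned position
    mapped: bool
    mate_chrom: str | None
    mate_pos: int | None
    mate_mapped: bool
    sample_id: str
    is_reverse: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.read_id}: SEQ/QUAL length mismatch")
        if self.mapped and (self.pos is None or self.pos < 0):
            raise ValueError(f"{self.read_id}: mapped read needs pos >= 0")


def _sample_of(aln: pysam.AlignedSegment, default: str | None) -> str:
    try:
        rg = aln.get_tag("RG")
    except KeyError:
        rg = None
    if rg is not None:
        return str(rg)
    if default is None:
        raise ValueError(
            f"read {aln.query_name} has no RG tag and no --sample id was supplied"
        )
    return default


def read_alignments(path, sample_id: str | None = None):
    """Yield ReadRecords from a SAM/BAM file.

    Sample identity comes from each read's RG tag, falling back to
    ``sample_id``.  Malformed records (missing SEQ/QUAL) are skipped with a
    logged warning; the generator keeps a running ``.skipped`` count on the
    returned iterator via StopIteration value — callers wanting the count
    should use :func:`load_alignments`.
    """
    records, _ = load_alignments(path, sample_id)
    yield from records


def load_alignments(path, sample_id: str | None = None) -> tuple[list[ReadRecord], int]:
    """Read a SAM/BAM file into ReadRecords; returns (records, n_skipped)."""
    records: list[ReadRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if not seq or quals is None or len(seq) != len(quals):
                skipped += 1
                log.warning("skipping malformed read %s", aln.query_name)
                continue
            mate_index = 2 if aln.is_read2 else 1
            records.append(
                ReadRecord(
                    read_id=f"{aln.query_name}/{mate_index}",
                    fragment_id=aln.query_name,
                    mate_index=mate_index,
                    seq=seq,
                    quals=list(quals),
                    chrom=aln.reference_name if not aln.is_unmapped else None,
                    pos=aln.reference_start if not aln.is_unmapped else None,
                    mapped=not aln.is_unmapped,
                    mate_chrom=(
                        aln.next_reference_name if not aln.mate_is_unmapped else None
                    ),
                    mate_pos=(
                        aln.next_reference_start if not aln.mate_is_unmapped else None
                    ),
                    mate_mapped=not aln.mate_is_unmapped,
                    sample_id=_sample_of(aln, sample_id),
                    is_reverse=aln.is_reverse,
                )
            )
    return records, skipped
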