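"""Polymorphic-repeat catalog: the loci at which instability is measured.

The catalog is a BED-like TSV (0-based half-open coordinates) listing each
repeat tract, its canonical motif, the reference unit count, and >=30 bp of
flanking reference sequence on each side.  Flanks serve two purposes:
spanning-read calling anchors on them, and the stutter filter reconstructs
the expected post-repeat sequence from the right flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motif import canonicalize

CATALOG_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "motif",
    "ref_units",
    "left_flank",
    "right_flank",
]


@dataclass(frozen=True)
class RepeatCatalogEntry:
    """One repeat locus: tract coordinates, motif class and flanking sequence."""

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str  # canonical
    ref_units: int
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if not self.left_flank or not self.right_flank:
            raise ValueError(f"{self.locus_id}: flanks must be non-empty")
        object.__setattr__(self, "motif", canonicalize(self.motif))

    @property
    def motif_len(self) -> int:
        return len(self.motif)


def read_catalog(path) -> list[RepeatCatalogEntry]:
    """Load a repeat catalog TSV (columns ``CATALOG_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "locus_id": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return [
        RepeatCatalogEntry(
            locus_id=row.locus_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            motif=row.motif,
            ref_units=int(row.ref_units),
            left_flank=row.left_flank,
            right_flank=row.right_flank,
        )
        for row in df.itertuples()
    ]


def write_catalog(entries: list[RepeatCatalogEntry], path) -> None:
    pd.DataFrame(
        [
            {col: getattr(e, col) for col in CATALOG_COLUMNS}
            for e in sorted(entries, key=lambda e: (e.chrom, e.start, e.locus_id))
        ]
    ).to_csv(path, sep="\t", index=False)


def index_by_chrom(entries: list[RepeatCatalogEntry]) -> dict[str, list[RepeatCatalogEntry]]:
    index: dict[str, list[RepeatCatalogEntry]] = {}
    for e in sorted(entries, key=lambda e: (e.chrom, e.start)):
        index.setdefault(e.chrom, []).append(e)
    return index
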