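"""Harvesting repeat evidence from read alignments.

Three kinds of evidence are extracted per sample and repeat locus:

* **Spanning calls** — reads containing the whole repeat tract plus exact
  flank anchors on both sides give an exact unit-count measurement of the
  allele on the sequenced molecule (alleles up to ~ read length).
* **IRR calls** — in-repeat reads, (almost) entirely repeat sequence,
  witness alleles longer than the read; the locus of origin is recovered
  from where the read's *mate* aligned, since the IRR itself maps
  unreliably inside repeats.
* **IRR pairs** — fragments whose two mates are both IRRs imply the whole
  fragment fits inside the repeat: evidence of very long (~100+ unit)
  alleles.

Germline genotypes (one or two allele lengths per sample and locus) are
derived from spanning-read support; remaining read lengths become candidate
somatic observations for the stutter filter and somatic phenotyping.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .catalog import RepeatCatalogEntry, index_by_chrom
from .motif import (
    DEFAULT_TAU,
    canonicalize,
    class_variants,
    encode_reads,
    purity_batch,
    reverse_complement,
)
from .reads import ReadRecord

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


@dataclass
class IrrCall:
    """One read recognised as an in-repeat read for a motif class."""

    read_id: str
    fragment_id: str
    mate_index: int
    sample_id: str
    motif: str  # canonical
    purity_value: float
    assigned_locus: str | None = None
    assignment_distance: int | None = None
    unassigned_reason: str | None = None


@dataclass
class IrrPair:
    """A fragment whose two mates are both IRRs of the same motif class."""

    fragment_id: str
    sample_id: str
    motif: str
    assigned_locus: str  # locus_id or AMBIGUOUS


@dataclass
class SpanningCall:
    """An exact repeat-length measurement from one read spanning the tract.

    Offsets (``tract_start_offset``, ``repeat_end_offset``) are in the
    orientation in which the flanks anchored; ``seq``/``quals`` are stored in
    that same orientation so the stutter filter can reason about the
    post-repeat junction directly.
    """

    locus_id: str
    sample_id: str
    read_id: str
    unit_count: int
    bp_length: int
    interruptions: list[tuple[int, str]]  # (1-based unit index, observed bases)
    left_anchor_len: int
    right_anchor_len: int
    repeat_end_offset: int  # first base after the tract, oriented read coords
    tract_start_offset: int
    motif_variant: str  # tiling variant of the tract in oriented read coords
    orientation: str  # "+" read as stored, "-" reverse-complemented
    seq: str = field(repr=False, default="")
    quals: list[int] = field(repr=False, default_factory=list)


@dataclass
class GermlineGenotype:
    """One or two inherited allele lengths (units) with read support."""

    sample_id: str
    locus_id: str
    alleles: tuple[int, ...]  # sorted ascending; length 2 (hom = (a, a))
    support: dict[int, int]

    def nearest_allele(self, units: int) -> int:
        """Germline allele closest to ``units`` (ties to the shorter allele)."""
        return min(set(self.alleles), key=lambda a: (abs(units - a), a))


# ---------------------------------------------------------------------------
# IRR detection


def detect_irrs(
    reads: list[ReadRecord],
    motifs: set[str],
    tau: float = DEFAULT_TAU,
) -> list[IrrCall]:
    """Scan reads for IRRs against a set of canonical motif classes.

    A read qualifying for several motif classes (possible only for
    degenerate motifs) emits a single call for the highest-purity class,
    ties broken by canonical-motif lexicographic order.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    canon = sorted({canonicalize(m) for m in motifs})
    calls: list[IrrCall] = []
    by_len: dict[int, list[ReadRecord]] = defaultdict(list)
    skipped = 0
    for r in reads:
        if not r.seq:
            skipped += 1
            log.warning("detect_irrs: skipping empty read %s", r.read_id)
            continue
        by_len[len(r.seq)].append(r)
    for _, group in sorted(by_len.items()):
        mat = encode_reads([r.seq for r in group])
        best_val = None
        best_motif = [None] * len(group)
        for m in canon:
            vals = purity_batch(mat, m)
            if best_val is None:
                best_val = vals.copy()
                best_motif = [m] * len(group)
            else:
                better = vals > best_val
                for i in better.nonzero()[0]:
                    best_motif[i] = m
                best_val[better] = vals[better]
        for i, r in enumerate(group):
            if best_val[i] >= tau:
                calls.append(
                    IrrCall(
                        read_id=r.read_id,
                        fragment_id=r.fragment_id,
                        mate_index=r.mate_index,
                        sample_id=r.sample_id,
                        motif=best_motif[i],
                        purity_value=float(best_val[i]),
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.read_id, c.motif))
    return calls


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(a_start - b_end, b_start - a_end, 0)


def assign_locus(
    irr: IrrCall,
    mate: ReadRecord | None,
    catalog_index: dict[str, list[RepeatCatalogEntry]],
    window_bp: int = 500,
) -> IrrCall:
    """Assign an IRR to the catalog locus its mate aligned near.

    Assignment succeeds only when the mate maps within ``window_bp`` of the
    tract of exactly one catalog locus of the IRR's motif class; otherwise
    the call is left unassigned with the reason recorded.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if mate is None or not mate.mapped or mate.chrom is None:
        irr.assigned_locus = None
        irr.unassigned_reason = "mate-unmapped"
        return irr
    m_start = mate.pos
    m_end = mate.pos + len(mate.seq)
    candidates = [
        (e, _interval_gap(e.start, e.end, m_start, m_end))
        for e in catalog_index.get(mate.chrom, [])
        if e.motif == irr.motif
    ]
    candidates = [(e, d) for e, d in candidates if d <= window_bp]
    if len(candidates) == 1:
        entry, dist = candidates[0]
        irr.assigned_locus = entry.locus_id
        irr.assignment_distance = dist
        irr.unassigned_reason = None
    elif not candidates:
        irr.unassigned_reason = "no-locus-in-window"
    else:
        irr.unassigned_reason = "ambiguous-locus"
    return irr


def find_irr_pairs(irr_calls: list[IrrCall]) -> list[IrrPair]:
    """Detect fragments whose both mates are IRRs of the same motif class.

    A pair inherits the locus at which the sample has anchored (assigned)
    single IRRs of that motif, provided that locus is unique; with anchored
    IRRs at several same-motif loci the pair is reported as ambiguous.
    """
    anchored: dict[tuple[str, str], set[str]] = defaultdict(set)
    for c in irr_calls:
        if c.assigned_locus:
            anchored[(c.sample_id, c.motif)].add(c.assigned_locus)
    by_frag: dict[tuple[str, str, str], set[int]] = defaultdict(set)
    for c in irr_calls:
        by_frag[(c.sample_id, c.fragment_id, c.motif)].add(c.mate_index)
    pairs = []
    for (sample, frag, motif), mates in sorted(by_frag.items()):
        if mates >= {1, 2}:
            loci = anchored.get((sample, motif), set())
            locus = next(iter(loci)) if len(loci) == 1 else AMBIGUOUS
            pairs.append(
                IrrPair(
                    fragment_id=frag,
                    sample_id=sample,
                    motif=motif,
                    assigned_locus=locus,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Spanning-read calling


def _extend_left(seq: str, flank: str, anchor_start: int, base_len: int) -> int:
    ext = 0
    while (
        anchor_start - ext - 1 >= 0
        and base_len + ext + 1 <= len(flank)
        and seq[anchor_start - ext - 1] == flank[-(base_len + ext + 1)]
    ):
        ext += 1
    return base_len + ext


def _extend_right(seq: str, flank: str, anchor_start: int, base_len: int) -> int:
    ext = 0
    while (
        anchor_start + base_len + ext < len(seq)
        and base_len + ext < len(flank)
        and seq[anchor_start + base_len + ext] == flank[base_len + ext]
    ):
        ext += 1
    return base_len + ext


def _try_orientation(
    seq: str,
    entry: RepeatCatalogEntry,
    min_anchor_bp: int,
    max_interruptions: int,
):
    left_anchor = entry.left_flank[-min_anchor_bp:]
    right_anchor = entry.right_flank[:min_anchor_bp]
    i = seq.find(left_anchor)
    if i < 0:
        return None
    t0 = i + min_anchor_bp
    j = seq.find(right_anchor, t0)
    if j < 0:
        return None
    tract = seq[t0:j]
    k = entry.motif_len
    unit_count = len(tract) // k
    # choose the tiling variant (rotation/strand) minimising mismatches
    best_variant, best_mm = None, None
    for v in class_variants(entry.motif):
        mm = sum(1 for p, b in enumerate(tract) if b != v[p % k])
        if best_mm is None or mm < best_mm:
            best_variant, best_mm = v, mm
    interruptions: list[tuple[int, str]] = []
    if best_variant is None:
        best_variant = entry.motif
    for u in range(unit_count):
        obs = tract[u * k : (u + 1) * k]
        if obs != best_variant:
            interruptions.append((u + 1, obs))
    if len(interruptions) > max_interruptions:
        return None
    return {
        "tract_start": t0,
        "repeat_end": j,
        "unit_count": unit_count,
        "bp_length": len(tract),
        "interruptions": interruptions,
        "motif_variant": best_variant,
        "left_anchor_len": _extend_left(seq, entry.left_flank, i, min_anchor_bp),
        "right_anchor_len": _extend_right(seq, entry.right_flank, j, min_anchor_bp),
    }


def call_spanning(
    read: ReadRecord,
    entry: RepeatCatalogEntry,
    min_anchor_bp: int = 10,
    max_interruptions: int = 3,
) -> SpanningCall | None:
    """Measure the repeat length carried by a read spanning the tract.

    Requires an exact substring match of at least ``min_anchor_bp`` to the
    left flank immediately before the repeat and to the right flank
    immediately after it, tried in both read orientations.  The unit count
    is the number of complete motif copies between the anchors; units with
    substitutions are recorded as interruptions (at most
    ``max_interruptions``, beyond which the call is rejected — a read whose
    best explanation needs indels inside the tract is a distinct length
    observation, not an interrupted one, and anchoring handles that
    naturally since length is measured between anchors).

    Returns None when either anchor is absent in both orientations.
    """
    if min(len(entry.left_flank), len(entry.right_flank)) < min_anchor_bp:
        raise ValueError(
            f"{entry.locus_id}: catalog flanks shorter than min_anchor_bp={min_anchor_bp}"
        )
    for orientation, seq, quals in (
        ("+", read.seq, read.quals),
        ("-", reverse_complement(read.seq), read.quals[::-1]),
    ):
        hit = _try_orientation(seq, entry, min_anchor_bp, max_interruptions)
        if hit is not None:
            return SpanningCall(
                locus_id=entry.locus_id,
                sample_id=read.sample_id,
                read_id=read.read_id,
                unit_count=hit["unit_count"],
                bp_length=hit["bp_length"],
                interruptions=hit["interruptions"],
                left_anchor_len=hit["left_anchor_len"],
                right_anchor_len=hit["right_anchor_len"],
                repeat_end_offset=hit["repeat_end"],
                tract_start_offset=hit["tract_start"],
                motif_variant=hit["motif_variant"],
                orientation=orientation,
                seq=seq,
                quals=list(quals),
            )
    return None


# ---------------------------------------------------------------------------
# Genotyping


def genotype_sample(
    calls: list[SpanningCall],
    min_support: int = 2,
    minor_frac: float = 0.2,
) -> GermlineGenotype | None:
    """Call one or two germline allele lengths from spanning-read support.

    The top-supported length is always an allele; the second-most-supported
    length is kept as a heterozygous allele only when its support is at
    least ``max(min_support, minor_frac * top support)``, otherwise the
    sample is called homozygous and minor lengths remain candidate somatic
    observations.  Invariant to read order.
    """
    if not calls:
        return None
    counts = Counter(c.unit_count for c in calls)
    if sum(counts.values()) < min_support:
        log.info(
            "no-genotype for %s at %s: %d < min_support reads",
            calls[0].sample_id,
            calls[0].locus_id,
            sum(counts.values()),
        )
        return None
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_allele, top_n = ranked[0]
    alleles = [top_allele]
    support = {top_allele: top_n}
    if len(ranked) > 1:
        second_allele, second_n = ranked[1]
        if second_n >= max(min_support, minor_frac * top_n):
            alleles.append(second_allele)
            support[second_allele] = second_n
    if len(alleles) == 1:
        alleles.append(alleles[0])
    return GermlineGenotype(
        sample_id=calls[0].sample_id,
        locus_id=calls[0].locus_id,
        alleles=tuple(sorted(alleles)),
        support=support,
    )


# ---------------------------------------------------------------------------
# Driver


@dataclass
class HarvestResult:
    spanning_calls: list[SpanningCall]
    irr_calls: list[IrrCall]
    irr_pairs: list[IrrPair]
    genotypes: dict[tuple[str, str], GermlineGenotype]
    counters: dict[str, int]


def harvest(
    records: list[ReadRecord],
    catalog: list[RepeatCatalogEntry],
    tau: float = DEFAULT_TAU,
    window_bp: int = 500,
    min_anchor_bp: int = 10,
    max_interruptions: int = 3,
    min_support: int = 2,
    minor_frac: float = 0.2,
) -> HarvestResult:
    """Run spanning calling, IRR detection and genotyping over alignments.

    A spanning call and an IRR call are mutually exclusive per read, with
    spanning taking precedence.  Outputs are deterministically ordered
    (sample, locus, read id) and independent of input read order.
    """
    index = index_by_chrom(catalog)
    motifs = {e.motif for e in catalog}
    counters: Counter[str] = Counter()
    by_key = {(r.fragment_id, r.mate_index): r for r in records}

    spanning: list[SpanningCall] = []
    non_spanning: list[ReadRecord] = []
    for r in sorted(records, key=lambda r: (r.sample_id, r.read_id)):
        call = None
        if r.mapped and r.chrom in index:
            for entry in index[r.chrom]:
                if entry.start - len(r.seq) <= r.pos <= entry.end:
                    call = call_spanning(r, entry, min_anchor_bp, max_interruptions)
                    if call is not None:
                        break
        if call is not None:
            spanning.append(call)
            counters["spanning"] += 1
        else:
            non_spanning.append(r)

    irr_calls = detect_irrs(non_spanning, motifs, tau)
    counters["irr"] = len(irr_calls)
    for c in irr_calls:
        mate = by_key.get((c.fragment_id, 2 if c.mate_index == 1 else 1))
        assign_locus(c, mate, index, window_bp)
        if c.assigned_locus is None:
            counters[f"irr-{c.unassigned_reason}"] += 1

    irr_pairs = find_irr_pairs(irr_calls)
    counters["irr_pairs"] = len(irr_pairs)

    by_sample_locus: dict[tuple[str, str], list[SpanningCall]] = defaultdict(list)
    for call in spanning:
        by_sample_locus[(call.sample_id, call.locus_id)].append(call)
    genotypes = {}
    for key in sorted(by_sample_locus):
        gt = genotype_sample(by_sample_locus[key], min_support, minor_frac)
        if gt is not None:
            genotypes[key] = gt
        else:
            counters["no-genotype"] += 1

    spanning.sort(key=lambda c: (c.sample_id, c.locus_id, c.read_id))
    irr_calls.sort(key=lambda c: (c.sample_id, c.assigned_locus or "", c.read_id))
    irr_pairs.sort(key=lambda p: (p.sample_id, p.assigned_locus, p.fragment_id))
    return HarvestResult(spanning, irr_calls, irr_pairs, genotypes, dict(counters))
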