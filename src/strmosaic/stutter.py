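"""PCR-stutter artifact filtering from within-read base-quality signatures.

During bridge amplification a polymerase slippage event produces a
polyclonal flow-cell cluster containing molecules with and without one
extra (or one missing) repeat unit.  The read reports the majority species,
but base qualities collapse at exactly the positions where the two species
disagree — downstream of the point where the shorter species' repeat tract
ends.  A genuine somatic length change, by contrast, comes from a clonal
cluster and keeps clean qualities.

The filter reconstructs the two expected post-junction sequences (right
flank directly, vs one more motif unit then the right flank), finds the
read offsets where they differ (the *signature positions*), and calls a
length-discordant read an artifact when its mean quality over the signature
is absolutely low or depressed relative to the rest of the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean

from .catalog import RepeatCatalogEntry
from .harvest import GermlineGenotype, SpanningCall

log = logging.getLogger(__name__)

ARTIFACT = "artifact"
RETAINED = "retained"
NOT_APPLICABLE = "not-applicable"

#: Absolute mean signature quality at or below which a read is an artifact.
DEFAULT_Q_LOW = 25.0
#: Required drop of signature quality below the rest of the read.
DEFAULT_Q_DROP = 10.0
#: Only single-unit length discordances are classified by default.
DEFAULT_MAX_DELTA = 1


@dataclass
class StutterAssessment:
    read_id: str
    locus_id: str
    delta_units: int
    signature_positions: list[int] = field(default_factory=list)
    mean_q_signature: float | None = None
    mean_q_control: float | None = None
    verdict: str = NOT_APPLICABLE
    reason: str | None = None


def signature_positions(
    call: SpanningCall,
    entry: RepeatCatalogEntry,
    delta_units: int,
    min_tail_bp: int = 10,
) -> list[int]:
    """Read offsets where reads with/without one slippage unit would differ.

    The junction is the read offset where the *shorter* of the two cluster
    species ends its repeat tract (for an apparent +1 read that is one unit
    before the called repeat end; for a -1 read it is the called repeat end
    itself).  From the junction to the read end, two hypothesis sequences
    are compared position by position: (i) the right flank directly and
    (ii) one more motif unit — continuing the tract's phase — followed by
    the right flank.  When the flank itself begins with repeat-like
    sequence the first differing offset falls later than the junction, and
    within a perfect homopolymer/repeat continuation the hypotheses may not
    differ at all.

    Returns an empty list when the junction is absent from the read or too
    close to the read end (< ``min_tail_bp`` bases of usable tail).
    """
    if delta_units == 0 or abs(delta_units) != 1:
        return []
    k = len(call.motif_variant)
    junction = call.repeat_end_offset - (k if delta_units > 0 else 0)
    read_len = len(call.seq)
    tail = read_len - junction
    if junction < call.tract_start_offset or tail < min_tail_bp:
        return []
    # phase-correct continuation of the tract at the junction
    phase = (junction - call.tract_start_offset) % k
    extra = "".join(
        call.motif_variant[(phase + t) % k] for t in range(k)
    )
    short_hyp = entry.right_flank[:tail]
    long_hyp = (extra + entry.right_flank)[:tail]
    n = min(len(short_hyp), len(long_hyp), tail)
    return [junction + t for t in range(n) if short_hyp[t] != long_hyp[t]]


def assess(
    call: SpanningCall,
    genotype: GermlineGenotype,
    entry: RepeatCatalogEntry,
    q_low: float = DEFAULT_Q_LOW,
    q_drop: float = DEFAULT_Q_DROP,
    max_delta: int = DEFAULT_MAX_DELTA,
    min_tail_bp: int = 10,
) -> StutterAssessment:
    """Classify one length-discordant spanning read as artifact or genuine.

    delta is the called unit count minus the nearest germline allele.  The
    verdict is *artifact* iff the mean base quality over the signature
    positions is <= ``q_low`` or <= (mean quality elsewhere in the read)
    minus ``q_drop``; otherwise *retained*.  Reads with delta 0, |delta|
    beyond scope, or no informative signature are *not-applicable*.
    Deterministic given (seq, quals, flanks, genotype).
    """
    delta = call.unit_count - genotype.nearest_allele(call.unit_count)
    out = StutterAssessment(
        read_id=call.read_id, locus_id=call.locus_id, delta_units=delta
    )
    if delta == 0:
        out.reason = "delta-zero"
        return out
    if abs(delta) > max_delta:
        out.reason = "delta-out-of-scope"
        return out
    sig = signature_positions(call, entry, delta, min_tail_bp)
    if not sig:
        out.reason = "no-signature"
        return out
    sig_set = set(sig)
    control = [q for p, q in enumerate(call.quals) if p not in sig_set]
    out.signature_positions = sig
    out.mean_q_signature = fmean(call.quals[p] for p in sig)
    out.mean_q_control = fmean(control) if control else None
    depressed = (
        out.mean_q_control is not None
        and out.mean_q_signature <= out.mean_q_control - q_drop
    )
    out.verdict = ARTIFACT if (out.mean_q_signature <= q_low or depressed) else RETAINED
    return out


def filter_reads(
    calls: list[SpanningCall],
    genotypes: dict[tuple[str, str], GermlineGenotype],
    entries: dict[str, RepeatCatalogEntry],
    q_low: float = DEFAULT_Q_LOW,
    q_drop: float = DEFAULT_Q_DROP,
    max_delta: int = DEFAULT_MAX_DELTA,
    min_tail_bp: int = 10,
) -> tuple[list[SpanningCall], list[StutterAssessment]]:
    """Split spanning calls into somatic-eligible reads and stutter artifacts.

    Length-concordant (delta 0) reads always pass through.  Discordant
    reads pass only with a *retained* verdict; artifact and not-applicable
    reads are excluded from somatic estimation but fully logged in the
    returned assessments.
    """
    retained: list[SpanningCall] = []
    assessments: list[StutterAssessment] = []
    for call in calls:
        gt = genotypes.get((call.sample_id, call.locus_id))
        if gt is None:
            assessments.append(
                StutterAssessment(
                    read_id=call.read_id,
                    locus_id=call.locus_id,
                    delta_units=0,
                    reason="no-genotype",
                )
            )
            continue
        a = assess(
            call, gt, entries[call.locus_id], q_low, q_drop, max_delta, min_tail_bp
        )
        if a.delta_units == 0 or a.verdict == RETAINED:
            retained.append(call)
        if a.delta_units != 0:
            assessments.append(a)
    return retained, assessments
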