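"""Allele-specific germline mutation rates from IBD-shared haplotypes.

Haplotypes inheriting a genomic segment identical-by-descent from a recent
common ancestor should carry identical repeat alleles; length discordances
within an IBD cluster are germline mutations that occurred on the meioses
separating the sharers.  The genetic length of the shared tract informs how
many meioses separate them (exponential tract-length model: a tract shared
through m meioses has mean length 100/m cM), the ancestral allele is
polarized by consensus among sharers (or supplied externally, standing in
for imputation from more-distantly shared haplotypes), and per-generation
rates are event counts over allele-meioses of exposure with exact Poisson
intervals.

Interrupted alleles are distinct allele states — keyed by (length,
interruption signature) — so interrupted and pure alleles of the same
length accrue separate rates, enabling interrupted-vs-pure rate-ratio
comparisons.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

AlleleKey = tuple[int, str]  # (unit length, interruption signature; "" = pure)

CLUSTER_COLUMNS = [
    "cluster_id",
    "sample_id",
    "hap",
    "allele_units",
    "interruption_sig",
    "tract_cm",
]


@dataclass
class IbdMember:
    sample_id: str
    hap: int
    allele_units: int
    interruption_sig: str = ""
    meioses: float | None = None  # per-branch meioses, if known

    @property
    def allele(self) -> AlleleKey:
        return (self.allele_units, self.interruption_sig)


@dataclass
class IbdCluster:
    cluster_id: str
    members: list[IbdMember]
    tract_cm: float | None = None
    ancestral: AlleleKey | None = None  # externally imputed, if available

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster {self.cluster_id} needs >= 2 members")


@dataclass
class MutationEvent:
    cluster_id: str
    sample_id: str
    ancestral_allele: AlleleKey
    step: int  # signed unit change, never 0

    def __post_init__(self) -> None:
        if self.step == 0:
            raise ValueError("mutation event must change length")


@dataclass
class GermlineRateEstimate:
    locus_id: str
    allele: AlleleKey
    direction: int  # +1 expansion, -1 contraction
    events: int
    exposure: float  # allele-meioses
    rate: float
    ci_low: float
    ci_high: float


def meioses_from_tract(tract_cm: float) -> float:
    """Total separating meioses implied by an IBD tract's genetic length.

    Under the exponential tract-length model a segment surviving m meioses
    has mean length 100/m cM, so m_hat = 100 / length, clamped below at 2
    (the closest possible relationship through a common ancestor).
    """
    if tract_cm is None or tract_cm <= 0:
        raise ValueError("tract length must be positive")
    return max(2.0, 100.0 / tract_cm)


def impute_ancestral(cluster: IbdCluster) -> AlleleKey | None:
    """Consensus ancestral allele: the strict modal allele among members.

    Ties — including any discordant pair with no third member — are
    unpolarized (None).
    """
    counts = defaultdict(int)
    for m in cluster.members:
        counts[m.allele] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def extract_events(
    cluster: IbdCluster, ancestral: AlleleKey | None = None
) -> tuple[list[MutationEvent], dict[AlleleKey, float]]:
    """Mutation events and allele-meioses exposure from one IBD cluster.

    ``ancestral`` defaults to the cluster's externally imputed allele if
    present, else the consensus; an unpolarizable cluster contributes
    nothing.  Each member whose allele length differs from the ancestral
    yields one event at the observed signed step (multi-step changes are
    recorded as-is, no intermediate path inference).  Every member
    contributes its branch meioses of exposure — supplied per member when
    known, otherwise half the tract-implied total (the per-branch distance
    to the common ancestor) — attributed to the ancestral allele.
    """
    if ancestral is None:
        ancestral = cluster.ancestral
    if ancestral is None:
        ancestral = impute_ancestral(cluster)
    if ancestral is None:
        return [], {}
    events: list[MutationEvent] = []
    exposure = 0.0
    for m in cluster.members:
        if m.meioses is not None:
            branch = m.meioses
        else:
            branch = meioses_from_tract(cluster.tract_cm) / 2.0
        exposure += branch
        step = m.allele_units - ancestral[0]
        if step != 0:
            events.append(
                MutationEvent(
                    cluster_id=cluster.cluster_id,
                    sample_id=m.sample_id,
                    ancestral_allele=ancestral,
                    step=step,
                )
            )
    return events, {ancestral: exposure}


def poisson_ci(events: int, exposure: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for a rate of events/exposure."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    lo = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2 / exposure
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (events + 1)) / 2 / exposure
    return float(lo), float(hi)


def estimate_rates(
    events: list[MutationEvent],
    exposures: dict[AlleleKey, float],
    locus_id: str = "",
    directions: tuple[int, ...] = (1, -1),
) -> list[GermlineRateEstimate]:
    """Per-allele, per-direction germline rates with exact Poisson 95% CIs.

    Events with |step| > 1 are outside the +/-1 rate bins but are reported
    via a logged count; alleles with zero exposure are omitted.
    """
    by_cell: dict[tuple[AlleleKey, int], int] = defaultdict(int)
    n_multi = 0
    for e in events:
        if e.step in directions:
            by_cell[(e.ancestral_allele, e.step)] += 1
        else:
            n_multi += 1
    if n_multi:
        log.info("estimate_rates: %d multi-step events outside +/-1 bins", n_multi)
    out = []
    for allele in sorted(exposures):
        exposure = exposures[allele]
        if exposure <= 0:
            continue
        for direction in directions:
            k = by_cell.get((allele, direction), 0)
            lo, hi = poisson_ci(k, exposure)
            out.append(
                GermlineRateEstimate(
                    locus_id=locus_id,
                    allele=allele,
                    direction=direction,
                    events=k,
                    exposure=exposure,
                    rate=k / exposure,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
    return out


def locus_mean_rate(
    estimates: list[GermlineRateEstimate], allele_freqs: dict[AlleleKey, float]
) -> float:
    """Allele-frequency-weighted mean mutation rate across alleles."""
    num = den = 0.0
    for est in estimates:
        w = allele_freqs.get(est.allele, 0.0)
        num += w * est.rate
        den += w
    if den == 0:
        raise ValueError("no overlapping alleles between estimates and frequencies")
    return num / den


@dataclass
class RateRatio:
    ratio: float
    ci_low: float
    ci_high: float


def rate_ratio(a: GermlineRateEstimate, b: GermlineRateEstimate) -> RateRatio:
    """Fold difference between two rates with a conditional-binomial CI.

    Conditional on the total event count N = k_a + k_b, k_a is binomial
    with success probability p = E_a r_a / (E_a r_a + E_b r_b); a
    Clopper-Pearson interval on p maps to the rate ratio through
    (p / (1 - p)) * (E_b / E_a).
    """
    if a.exposure <= 0 or b.exposure <= 0:
        raise ValueError("rate_ratio needs positive exposures")
    ka, kb = a.events, b.events
    if ka == 0 and kb == 0:
        raise ValueError("rate ratio undefined with zero events in both cells")
    scale = b.exposure / a.exposure
    n = ka + kb
    p_lo = 0.0 if ka == 0 else stats.beta.ppf(0.025, ka, kb + 1)
    p_hi = 1.0 if ka == n else stats.beta.ppf(0.975, ka + 1, kb)
    ratio = float("inf") if b.rate == 0 else a.rate / b.rate
    lo = p_lo / (1 - p_lo) * scale if p_lo < 1 else float("inf")
    hi = p_hi / (1 - p_hi) * scale if p_hi < 1 else float("inf")
    return RateRatio(ratio=ratio, ci_low=float(lo), ci_high=float(hi))


def pool_rare_alleles(
    haplotype_counts: dict[AlleleKey, int], min_haplotypes: int = 25
) -> dict[AlleleKey, AlleleKey]:
    """Reporting map pooling alleles seen on few haplotypes into neighbours.

    Each allele observed on fewer than ``min_haplotypes`` haplotypes is
    mapped to the nearest-by-length allele of the same interruption
    signature that meets the threshold (ties to the shorter allele); common
    alleles map to themselves.  Alleles with no eligible neighbour are left
    unpooled.
    """
    common = [a for a, n in haplotype_counts.items() if n >= min_haplotypes]
    mapping = {}
    for allele in sorted(haplotype_counts):
        if allele in common:
            mapping[allele] = allele
            continue
        neighbours = [c for c in common if c[1] == allele[1]]
        if neighbours:
            mapping[allele] = min(
                neighbours, key=lambda c: (abs(c[0] - allele[0]), c[0])
            )
        else:
            mapping[allele] = allele
    return mapping


# ---------------------------------------------------------------------------
# TSV I/O


def read_clusters(path) -> list[IbdCluster]:
    """Load IBD clusters from TSV.

    Required columns: cluster_id, sample_id, hap, allele_units,
    interruption_sig, tract_cm.  Optional: meioses (per-branch), and
    ancestral_units/ancestral_sig carrying an externally imputed ancestral
    allele (e.g. from more-distantly shared haplotypes).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"cluster_id": str, "sample_id": str}, keep_default_na=False
    )
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    clusters = []
    for cid, sub in df.groupby("cluster_id", sort=True):
        members = [
            IbdMember(
                sample_id=row.sample_id,
                hap=int(row.hap),
                allele_units=int(row.allele_units),
                interruption_sig=str(row.interruption_sig or ""),
                meioses=float(row.meioses) if "meioses" in df.columns and row.meioses != "" else None,
            )
            for row in sub.itertuples()
        ]
        tract = sub["tract_cm"].iloc[0]
        ancestral = None
        if "ancestral_units" in df.columns and str(sub["ancestral_units"].iloc[0]) != "":
            sig = str(sub["ancestral_sig"].iloc[0]) if "ancestral_sig" in df.columns else ""
            ancestral = (int(sub["ancestral_units"].iloc[0]), sig)
        clusters.append(
            IbdCluster(
                cluster_id=str(cid),
                members=members,
                tract_cm=float(tract) if str(tract) != "" else None,
                ancestral=ancestral,
            )
        )
    return clusters


def rates_frame(estimates: list[GermlineRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": e.locus_id,
                "allele_units": e.allele[0],
                "interruption_sig": e.allele[1],
                "direction": e.direction,
                "events": e.events,
                "exposure": e.exposure,
                "rate": e.rate,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in sorted(estimates, key=lambda e: (e.locus_id, e.allele, -e.direction))
        ]
    )
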