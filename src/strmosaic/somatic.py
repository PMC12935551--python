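"""Somatic-instability quantities built from filtered read evidence.

The central quantity for alleles short enough to span is the *somatic
expansion fraction*: the average fraction of blood cells in which a given
repeat allele has gained one repeat unit, estimated per sample as
``n_shifted / (n_base + n_shifted)`` over reads attributable to the allele,
with a Wilson 95% interval.  Fractions grow with age for unstable repeats,
so weighted regression on age and covariate screens (age, DNA-repair gene
dosages) sit alongside.

Alleles longer than the read cannot be spanned; their length is estimated
by counting in-repeat reads — E[IRR count] = c * (L - R + 1) for a tract of
L bp at haploid read-start density c — and fragments fully inside the
repeat (IRR pairs) give a better-powered long-expansion metric.  Because
the informative signal is somatic *deviation*, per-individual metrics are
calibrated against other individuals sharing the same inherited allele
(z-score plus within-group inverse-normal transform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .harvest import GermlineGenotype, SpanningCall

log = logging.getLogger(__name__)


@dataclass
class AlleleExpansionEstimate:
    locus_id: str
    allele: int
    direction: int  # +1 expansion, -1 contraction
    n_base_reads: int
    n_shifted_reads: int
    fraction: float
    ci_low: float
    ci_high: float
    age_bin: str | None = None
    sample_id: str | None = None


@dataclass
class LongAlleleMetrics:
    sample_id: str
    locus_id: str
    irr_count: int
    irr_pair_count: int
    haploid_start_density: float
    censored: bool
    est_length_bp: float | None
    est_length_units: float | None


@dataclass
class AgeTrend:
    slope: float
    stderr: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int


# ---------------------------------------------------------------------------
# Expansion fractions from spanning reads


def attributable_counts(
    calls: list[SpanningCall],
    genotype: GermlineGenotype,
    allele: int,
    direction: int = 1,
    attribution_gap: int = 3,
) -> tuple[int, int] | None:
    """Count reads attributable to ``allele`` and to ``allele + direction``.

    Eligibility: the sample carries the allele, carries no germline allele
    equal to allele+direction, and the *other* germline allele is either
    identical (a/a homozygote, per-allele-copy interpretation) or at least
    ``attribution_gap`` units away from the allele so adjacent-length reads
    cannot contaminate the counts.  Returns None when ineligible.
    """
    alleles = genotype.alleles
    if allele not in alleles:
        return None
    shifted = allele + direction
    if shifted in alleles:
        return None
    others = [a for a in alleles if a != allele]
    if others and any(abs(a - allele) < attribution_gap for a in others):
        return None
    n_base = sum(1 for c in calls if c.unit_count == allele)
    n_shift = sum(1 for c in calls if c.unit_count == shifted)
    return n_base, n_shift


def expansion_fraction(
    n_base: int,
    n_shifted: int,
    locus_id: str = "",
    allele: int = 0,
    direction: int = 1,
    sample_id: str | None = None,
    age_bin: str | None = None,
) -> AlleleExpansionEstimate:
    """Somatic fraction n_shifted / (n_base + n_shifted) with Wilson 95% CI."""
    total = n_base + n_shifted
    if total <= 0:
        raise ValueError("expansion_fraction needs at least one attributable read")
    frac = n_shifted / total
    lo, hi = proportion_confint(n_shifted, total, alpha=0.05, method="wilson")
    return AlleleExpansionEstimate(
        locus_id=locus_id,
        allele=allele,
        direction=direction,
        n_base_reads=n_base,
        n_shifted_reads=n_shifted,
        fraction=frac,
        ci_low=float(lo),
        ci_high=float(hi),
        age_bin=age_bin,
        sample_id=sample_id,
    )


def pool_by_allele_age(
    estimates: list[AlleleExpansionEstimate],
) -> list[AlleleExpansionEstimate]:
    """Pool per-individual estimates into (locus, allele, direction, age bin).

    Counts are summed before taking the ratio (unbiased under varying
    coverage, unlike averaging per-individual ratios); the Wilson interval
    is recomputed on the pooled counts.  Empty cells simply do not appear.
    """
    pooled: dict[tuple, list[int]] = {}
    for e in estimates:
        key = (e.locus_id, e.allele, e.direction, e.age_bin)
        acc = pooled.setdefault(key, [0, 0])
        acc[0] += e.n_base_reads
        acc[1] += e.n_shifted_reads
    return [
        expansion_fraction(nb, ns, locus_id=loc, allele=a, direction=d, age_bin=ab)
        for (loc, a, d, ab), (nb, ns) in sorted(
            pooled.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], str(kv[0][3]))
        )
    ]


def age_trend(values, ages, weights=None) -> AgeTrend:
    """Weighted least-squares slope of a somatic metric on age (per year)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("age_trend requires >= 3 distinct ages")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    lo, hi = res.conf_int()[1]
    return AgeTrend(
        slope=float(res.params[1]),
        stderr=float(res.bse[1]),
        ci_low=float(lo),
        ci_high=float(hi),
        pvalue=float(res.pvalues[1]),
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# Long alleles: IRR counting and fragment metrics


def long_allele_length(
    irr_count: int,
    haploid_start_density: float,
    read_length: int = 151,
    motif_len: int = 3,
    sample_id: str = "",
    locus_id: str = "",
    irr_pair_count: int = 0,
) -> LongAlleleMetrics:
    """Rough long-allele length from the IRR count.

    A read is an IRR only if it starts within the tract's L - R + 1
    eligible positions, so E[irr_count] = c * max(0, L - R + 1); inverting
    gives L_hat = (R - 1) + irr_count / c in bp.  Zero IRRs leaves the
    estimate censored at L < R.  In a mosaic sample the estimate is the
    cell-averaged expanded-allele length.
    """
    if haploid_start_density <= 0:
        raise ValueError("haploid start density c must be positive")
    if irr_count == 0:
        return LongAlleleMetrics(
            sample_id, locus_id, 0, irr_pair_count, haploid_start_density, True, None, None
        )
    est_bp = (read_length - 1) + irr_count / haploid_start_density
    return LongAlleleMetrics(
        sample_id=sample_id,
        locus_id=locus_id,
        irr_count=irr_count,
        irr_pair_count=irr_pair_count,
        haploid_start_density=haploid_start_density,
        censored=False,
        est_length_bp=est_bp,
        est_length_units=est_bp / motif_len,
    )


def estimate_start_density(
    total_mapped_bases: float, genome_size: float, read_length: int = 151
) -> float:
    """Haploid read-start density from genome-wide coverage accounting."""
    return (total_mapped_bases / (2.0 * genome_size)) / read_length


def expected_irr_pairs(
    tract_bp: float,
    fragment_mean: float,
    fragment_sd: float,
    fragment_start_density: float,
    read_length: int = 151,
) -> float:
    """Expected count of fragments wholly inside a tract of given length.

    A fragment of length F fits inside an L bp tract from max(0, L - F + 1)
    start positions; the expectation integrates that over the fragment
    length distribution (normal, truncated below at the read length) and
    multiplies by the per-bp haploid fragment-start density.  Monotone
    increasing in L.
    """
    if fragment_sd <= 0:
        yield_bp = max(0.0, tract_bp - fragment_mean + 1)
        return fragment_start_density * yield_bp
    lengths = np.arange(read_length, int(fragment_mean + 6 * fragment_sd) + 1)
    pdf = stats.norm.pdf(lengths, loc=fragment_mean, scale=fragment_sd)
    pdf /= pdf.sum()
    yield_bp = np.maximum(0.0, tract_bp - lengths + 1)
    return float(fragment_start_density * (pdf * yield_bp).sum())


def fragment_score(irr_pair_count: int, fragment_start_density: float) -> float:
    """Highly-expanded-fragment score: IRR pairs per expected pair yield/bp.

    Normalising the pair count by the per-bp fragment-start density turns
    it into an estimate of the expected eligible-start span
    E[max(0, L - F + 1)], which is monotone in the true allele length L.
    """
    if fragment_start_density <= 0:
        raise ValueError("fragment start density must be positive")
    return irr_pair_count / fragment_start_density


# ---------------------------------------------------------------------------
# Calibration against individuals sharing the inherited allele


def calibrate_by_group(
    metrics: pd.DataFrame,
    value_col: str = "raw_metric",
    group_col: str = "group_id",
    min_group: int = 10,
) -> pd.DataFrame:
    """Calibrate per-sample metrics within inherited-allele groups.

    Within each group of samples sharing the same inherited allele the
    metric is z-scored ((x - mean) / sd, sample sd) and rank inverse-normal
    transformed (offset (r - 0.5) / n, ties by average rank).  Groups
    smaller than ``min_group`` and zero-variance groups are dropped with
    their reason logged.  Returns a DataFrame with sample_id, group_id,
    raw_metric, group_mean, group_sd, z_value, int_value.
    """
    out = []
    for group, sub in metrics.groupby(group_col, sort=True):
        n = len(sub)
        if n < min_group:
            log.info("calibrate_by_group: dropping group %s (n=%d < %d)", group, n, min_group)
            continue
        x = sub[value_col].to_numpy(dtype=float)
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            log.info("calibrate_by_group: dropping zero-variance group %s", group)
            continue
        ranks = stats.rankdata(x, method="average")
        res = sub[["sample_id"]].copy()
        res["group_id"] = group
        res["raw_metric"] = x
        res["group_mean"] = mean
        res["group_sd"] = sd
        res["z_value"] = (x - mean) / sd
        res["int_value"] = stats.norm.ppf((ranks - 0.5) / n)
        out.append(res)
    if not out:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "group_id",
                "raw_metric",
                "group_mean",
                "group_sd",
                "z_value",
                "int_value",
            ]
        )
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["group_id", "sample_id"])
        .reset_index(drop=True)
    )


def midlength_score(
    calls: list[SpanningCall],
    genotype: GermlineGenotype,
    allele: int,
    attribution_gap: int = 3,
    max_delta: int = 1,
) -> float | None:
    """Mean increase in repeat length across retained spanning reads.

    Averages (called units - allele) over reads attributable to the allele
    with called length in [allele, allele + max_delta]; under a mosaic
    fraction f of +1 cells its expectation is f.  Returns None when no
    reads are attributable (eligibility mirrors attributable_counts).
    """
    alleles = genotype.alleles
    if allele not in alleles:
        return None
    others = [a for a in alleles if a != allele]
    if others and any(abs(a - allele) < attribution_gap for a in others):
        return None
    shifts = [
        c.unit_count - allele
        for c in calls
        if allele <= c.unit_count <= allele + max_delta
    ]
    if not shifts:
        return None
    return float(np.mean(shifts))


def screen_instability(phenotype, covariate) -> tuple[float, float]:
    """Association test of a somatic phenotype with age or a genotype dosage.

    Ordinary least squares of phenotype on the covariate; returns the slope
    z statistic and two-sided p-value.  Raises on a constant covariate.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant; association undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.tvalues[1]), float(res.pvalues[1])
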