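"""Ground-truth simulator for repeat-instability analyses.

Simulates a single synthetic repeat locus (configurable motif, reference
unit count, flanking sequence), a population of individuals with inherited
allele lengths and ages, age-dependent somatic mosaicism (a fraction
f = r_s(a) * age of cells carry a+1 units — the single-step model matching
+1-unit somatic quantification), IBD-sharing clusters whose branches mutate
stepwise per meiosis, and 151 bp paired-end reads over the locus with
substitution errors and PCR-stutter events carrying their depressed
base-quality signature.  Every stochastic draw flows from one
numpy Generator; identical config + seed gives byte-identical SAM and truth
tables.

Default parameter values describe the world the source data come from:
151 bp reads at ~30x depth with ~400 +/- 60 bp fragments; germline
expansion ~5e-4 per meiosis with a 3:1 expansion:contraction asymmetry
(the high end of common CAG-repeat loci); somatic expansion ~2e-4 per year
so that a 25-unit carrier reaches ~1% expanded cells by age 50; stutter in
~2% of repeat-overlapping reads with qualities collapsing to ~Q15 at
signature positions against a Q37 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import pysam

from .catalog import RepeatCatalogEntry
from .ibd import IbdCluster, IbdMember
from .motif import reverse_complement
from .reads import ReadRecord

SPANNING = "spanning"
IRR = "irr"
PARTIAL = "partial"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_flank(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@dataclass
class SimConfig:
    """Stated world for the simulator; see module docstring for rationale."""

    motif: str = "CAG"
    ref_units: int = 18
    locus_id: str = "locus1"
    chrom: str = "chrSYN"
    flank_len: int = 600
    left_flank: str | None = None
    right_flank: str | None = None
    # inherited allele length distribution (units -> probability)
    allele_dist: dict[int, float] = field(
        default_factory=lambda: {12: 0.3, 18: 0.5, 25: 0.2}
    )
    # germline per-meiosis step rates; callables (vectorised over unit arrays)
    # override the constants when supplied
    germline_expand_rate: float = 5e-4
    germline_contract_rate: float = 5e-4 / 3
    germline_rate_fn: Callable | None = None  # (units_array, direction) -> rates
    # somatic: fraction of cells gaining +1 unit per year of age
    somatic_rate_per_year: float = 2e-4
    somatic_rate_fn: Callable | None = None  # units -> per-year rate
    read_length: int = 151
    haploid_depth: float = 30.0
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    error_rate: float = 0.001
    stutter_prob: float = 0.02
    stutter_q_mean: float = 15.0
    stutter_q_sd: float = 5.0
    base_q: int = 37
    min_anchor_bp: int = 10
    age_range: tuple[int, int] = (40, 70)

    def __post_init__(self) -> None:
        for rate in (
            self.germline_expand_rate,
            self.germline_contract_rate,
            self.stutter_prob,
            self.error_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates and probabilities must be in [0, 1]")
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment mean must exceed the read length")
        if self.left_flank is None:
            self.left_flank = _random_flank(self.flank_len, seed=2_025_01)
        if self.right_flank is None:
            self.right_flank = _random_flank(self.flank_len, seed=2_025_02)

    # -- derived geometry ---------------------------------------------------

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def tract_start(self) -> int:
        return len(self.left_flank)

    @property
    def reference(self) -> str:
        return self.left_flank + self.motif * self.ref_units + self.right_flank

    @property
    def fragment_start_density(self) -> float:
        """Haploid fragment starts per bp (two reads each): depth / (2R)."""
        return self.haploid_depth / (2.0 * self.read_length)

    @property
    def read_start_density(self) -> float:
        """Haploid read starts per bp: c in E[IRR count] = c (L - R + 1)."""
        return self.haploid_depth / self.read_length

    def catalog_entry(self) -> RepeatCatalogEntry:
        return RepeatCatalogEntry(
            locus_id=self.locus_id,
            chrom=self.chrom,
            start=self.tract_start,
            end=self.tract_start + self.motif_len * self.ref_units,
            motif=self.motif,
            ref_units=self.ref_units,
            left_flank=self.left_flank,
            right_flank=self.right_flank,
        )

    def molecule(self, units: int) -> str:
        return self.left_flank + self.motif * units + self.right_flank

    def germline_rate(self, units, direction: int):
        if self.germline_rate_fn is not None:
            return self.germline_rate_fn(units, direction)
        const = (
            self.germline_expand_rate if direction > 0 else self.germline_contract_rate
        )
        return np.full_like(np.asarray(units, dtype=float), const)

    def somatic_rate(self, units: int) -> float:
        if self.somatic_rate_fn is not None:
            return float(self.somatic_rate_fn(units))
        return self.somatic_rate_per_year


# ---------------------------------------------------------------------------
# Population and mosaicism


def simulate_population(config: SimConfig, n_individuals: int, rng) -> pd.DataFrame:
    """Draw genotypes, ages and inherited-allele group labels.

    Alleles are i.i.d. from the configured length distribution; the group
    label is the longer inherited allele length, standing in for imputed
    haplotype groups; ages are uniform over the configured range.
    """
    units = np.array(sorted(config.allele_dist))
    probs = np.array([config.allele_dist[u] for u in units], dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("allele distribution must have non-negative mass")
    probs = probs / probs.sum()
    a1 = rng.choice(units, size=n_individuals, p=probs)
    a2 = rng.choice(units, size=n_individuals, p=probs)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n_individuals)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n_individuals)],
            "allele1": np.minimum(a1, a2).astype(int),
            "allele2": np.maximum(a1, a2).astype(int),
            "age": ages.astype(int),
            "group_id": [f"a{u}" for u in np.maximum(a1, a2).astype(int)],
        }
    )


def simulate_mosaic(
    genotype: tuple[int, int], age: float, config: SimConfig
) -> list[list[tuple[int, float]]]:
    """Cell-population mixture per haplotype under the single-step model.

    For each inherited allele a, a fraction f = r_s(a) * age of cells carry
    a+1 units and the remainder carry a; f is clipped at 1 with a warning
    implied by the clip.  Fractions sum to 1 per haplotype.
    """
    mixtures = []
    for a in genotype:
        f = min(1.0, config.somatic_rate(a) * age)
        parts = [(int(a), 1.0 - f)]
        if f > 0:
            parts.append((int(a) + 1, f))
        mixtures.append(parts)
    return mixtures


# ---------------------------------------------------------------------------
# Reads


@dataclass
class SimRead:
    read_id: str
    fragment_id: str
    mate_index: int
    sample_id: str
    seq: str  # SAM orientation (reverse-strand mates stored revcomp'ed)
    quals: list[int]
    pos: int  # 0-based reference position
    mate_pos: int
    is_reverse: bool
    # truth labels
    hap: int
    source_units: int
    class_label: str
    repeat_overlap: bool
    stutter: bool
    stutter_delta: int


def _map_to_reference(mol_pos: int, config: SimConfig, units: int) -> int:
    """Project a molecule coordinate onto the reference (indels at the tract)."""
    t0 = config.tract_start
    shift = (units - config.ref_units) * config.motif_len
    if mol_pos <= t0:
        return mol_pos
    if mol_pos >= t0 + units * config.motif_len:
        return max(t0, mol_pos - shift)
    return t0


def _classify(start: int, end: int, config: SimConfig, units: int) -> str:
    t0 = config.tract_start
    t1 = t0 + units * config.motif_len
    if start >= t0 and end <= t1:
        return IRR
    if start <= t0 - config.min_anchor_bp and end >= t1 + config.min_anchor_bp:
        return SPANNING
    return PARTIAL


def _apply_errors(seq_arr: np.ndarray, rate: float, rng) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(seq_arr.size) < rate)
    for p in hits:
        choices = _BASES[_BASES != seq_arr[p]]
        seq_arr[p] = rng.choice(choices)


def simulate_reads(
    sample_id: str,
    mixtures: list[list[tuple[int, float]]],
    config: SimConfig,
    rng,
    keep: str = "all",
) -> list[SimRead]:
    """Generate paired-end reads over the locus for one individual.

    Fragments are placed uniformly per haplotype at the configured depth;
    fragment lengths are normal, truncated below at the read length.  Each
    read is truth-classified against its molecule's tract geometry
    (spanning / IRR / partial).  Substitution errors are i.i.d.; with
    probability ``stutter_prob``, a repeat-overlapping read is re-extracted
    from a molecule one unit longer or shorter and its base qualities at
    the positions where the two species disagree are redrawn from the
    degraded stutter distribution.  ``keep="overlap"`` discards fragments
    not touching the tract (a focusing device for repeat-local analyses;
    truth labels are unaffected).
    """
    out: list[SimRead] = []
    frag_idx = 0
    for hap, mixture in enumerate(mixtures):
        for units, frac in mixture:
            if frac <= 0:
                continue
            mol = config.molecule(units)
            g = len(mol)
            t0 = config.tract_start
            t1 = t0 + units * config.motif_len
            # starts are uniform over the whole region at exactly c_frag per bp;
            # fragments overrunning the region end are dropped (an edge effect
            # confined to the far right flank, away from the tract)
            n_frags = rng.poisson(config.fragment_start_density * frac * g)
            for _ in range(n_frags):
                f_len = int(
                    max(
                        config.read_length,
                        round(rng.normal(config.fragment_mean, config.fragment_sd)),
                    )
                )
                start = int(rng.integers(0, g))
                if start + f_len > g:
                    continue
                frag_id = f"{sample_id}:f{frag_idx}"
                frag_idx += 1
                if keep == "overlap" and not (start < t1 and start + f_len > t0):
                    continue
                windows = (
                    (1, start, start + config.read_length, False),
                    (2, start + f_len - config.read_length, start + f_len, True),
                )
                mate_ref = [
                    _map_to_reference(w[1], config, units) for w in windows
                ]
                for (mate, w0, w1, rev), pos, mpos in zip(
                    windows, mate_ref, mate_ref[::-1]
                ):
                    arr = np.frombuffer(
                        mol[w0:w1].encode("ascii"), dtype=np.uint8
                    ).copy()
                    quals = np.full(arr.size, config.base_q, dtype=int)
                    stutter = False
                    delta = 0
                    overlap = w0 < t1 and w1 > t0
                    if (
                        config.stutter_prob > 0
                        and overlap
                        and rng.random() < config.stutter_prob
                    ):
                        stutter = True
                        delta = 1 if (units <= 1 or rng.random() < 0.5) else -1
                        alt = config.molecule(units + delta)
                        alt_arr = np.frombuffer(
                            alt[w0 : w0 + arr.size].encode("ascii"), dtype=np.uint8
                        ).copy()
                        if alt_arr.size == arr.size:
                            diff = np.flatnonzero(alt_arr != arr)
                            arr = alt_arr
                            if diff.size:
                                degraded = np.clip(
                                    rng.normal(
                                        config.stutter_q_mean,
                                        config.stutter_q_sd,
                                        diff.size,
                                    ),
                                    2,
                                    config.base_q,
                                ).round()
                                quals[diff] = degraded.astype(int)
                        else:
                            stutter, delta = False, 0
                    _apply_errors(arr, config.error_rate, rng)
                    seq = arr.tobytes().decode("ascii")
                    qlist = quals.tolist()
                    if rev:
                        seq = reverse_complement(seq)
                        qlist = qlist[::-1]
                    out.append(
                        SimRead(
                            read_id=f"{frag_id}/{mate}",
                            fragment_id=frag_id,
                            mate_index=mate,
                            sample_id=sample_id,
                            seq=seq,
                            quals=qlist,
                            pos=pos,
                            mate_pos=mpos,
                            is_reverse=rev,
                            hap=hap,
                            source_units=units,
                            class_label=_classify(w0, w1, config, units),
                            repeat_overlap=overlap,
                            stutter=stutter,
                            stutter_delta=delta,
                        )
                    )
    return out


def to_read_records(sim_reads: list[SimRead], config: SimConfig) -> list[ReadRecord]:
    """View simulated reads as alignment records (no SAM round-trip)."""
    return [
        ReadRecord(
            read_id=r.read_id,
            fragment_id=r.fragment_id,
            mate_index=r.mate_index,
            seq=r.seq,
            quals=list(r.quals),
            chrom=config.chrom,
            pos=r.pos,
            mapped=True,
            mate_chrom=config.chrom,
            mate_pos=r.mate_pos,
            mate_mapped=True,
            sample_id=r.sample_id,
            is_reverse=r.is_reverse,
        )
        for r in sim_reads
    ]


def truth_frame(sim_reads: list[SimRead]) -> pd.DataFrame:
    """Per-read truth table: one row per emitted read."""
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "sample_id": r.sample_id,
                "hap": r.hap,
                "source_units": r.source_units,
                "class": r.class_label,
                "repeat_overlap": r.repeat_overlap,
                "stutter": r.stutter,
                "stutter_delta": r.stutter_delta,
            }
            for r in sorted(sim_reads, key=lambda r: (r.sample_id, r.read_id))
        ]
    )


def write_sam(sim_reads: list[SimRead], config: SimConfig, path) -> None:
    """Emit simulated reads as a text SAM file with @SQ and @RG headers."""
    samples = sorted({r.sample_id for r in sim_reads})
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": config.chrom, "LN": len(config.reference) + 2000}],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sorted(sim_reads, key=lambda r: (r.sample_id, r.fragment_id, r.mate_index)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.fragment_id
            a.flag = (
                0x1  # paired
                | 0x2  # proper pair
                | (0x10 if r.is_reverse else 0x20)
                | (0x40 if r.mate_index == 1 else 0x80)
            )
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.query_sequence = r.seq
            a.query_qualities = r.quals
            a.next_reference_id = 0
            a.next_reference_start = r.mate_pos
            a.set_tag("RG", r.sample_id)
            out.write(a)


# ---------------------------------------------------------------------------
# IBD clusters


def _mutate_branches(units: np.ndarray, meioses: int, config: SimConfig, rng) -> np.ndarray:
    units = units.astype(int).copy()
    for _ in range(meioses):
        up = np.asarray(config.germline_rate(units, +1), dtype=float)
        dn = np.asarray(config.germline_rate(units, -1), dtype=float)
        u = rng.random(units.size)
        units = units + (u < up).astype(int) - ((u >= up) & (u < up + dn)).astype(int)
        units = np.maximum(units, 1)
    return units


def simulate_ibd(
    config: SimConfig,
    n_clusters: int,
    cluster_size: int = 2,
    total_meioses: float = 10.0,
    rng=None,
    emit_ancestral: bool = True,
) -> tuple[list[IbdCluster], pd.DataFrame]:
    """Simulate IBD-sharing clusters with per-meiosis stepwise mutation.

    The ancestral allele of each cluster is drawn from the configured
    distribution; each member's branch runs ``total_meioses / 2`` meioses,
    mutating +1/-1 stepwise at the configured germline rates; the shared
    tract length is exponential with mean ``100 / total_meioses`` cM.  With
    ``emit_ancestral`` the truth ancestral allele is attached to each
    cluster, standing in for imputation from more-distantly shared
    haplotypes (needed to polarize discordant pairs); without it,
    polarization falls back to the in-cluster consensus.
    """
    if rng is None:
        raise ValueError("simulate_ibd requires an explicit rng")
    units = np.array(sorted(config.allele_dist))
    probs = np.array([config.allele_dist[u] for u in units], dtype=float)
    probs /= probs.sum()
    ancestral = rng.choice(units, size=n_clusters, p=probs).astype(int)
    branch_meioses = int(round(total_meioses / 2.0))
    member_units = np.empty((n_clusters, cluster_size), dtype=int)
    for j in range(cluster_size):
        member_units[:, j] = _mutate_branches(ancestral, branch_meioses, config, rng)
    tract_cm = np.maximum(rng.exponential(100.0 / total_meioses, n_clusters), 1e-3)

    clusters: list[IbdCluster] = []
    truth_rows = []
    for i in range(n_clusters):
        cid = f"c{i:06d}"
        members = [
            IbdMember(
                sample_id=f"{cid}m{j}",
                hap=0,
                allele_units=int(member_units[i, j]),
                interruption_sig="",
                meioses=float(branch_meioses),
            )
            for j in range(cluster_size)
        ]
        clusters.append(
            IbdCluster(
                cluster_id=cid,
                members=members,
                tract_cm=float(tract_cm[i]),
                ancestral=(int(ancestral[i]), "") if emit_ancestral else None,
            )
        )
        for j in range(cluster_size):
            step = int(member_units[i, j] - ancestral[i])
            if step != 0:
                truth_rows.append(
                    {
                        "cluster_id": cid,
                        "member": f"{cid}m{j}",
                        "ancestral_units": int(ancestral[i]),
                        "step": step,
                    }
                )
    truth = pd.DataFrame(truth_rows, columns=["cluster_id", "member", "ancestral_units", "step"])
    return clusters, truth


def clusters_frame(clusters: list[IbdCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "sample_id": m.sample_id,
                    "hap": m.hap,
                    "allele_units": m.allele_units,
                    "interruption_sig": m.interruption_sig,
                    "tract_cm": c.tract_cm,
                    "meioses": "" if m.meioses is None else m.meioses,
                    "ancestral_units": "" if c.ancestral is None else c.ancestral[0],
                    "ancestral_sig": "" if c.ancestral is None else c.ancestral[1],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SimDataset:
    config: SimConfig
    population: pd.DataFrame
    reads: list[SimRead]
    truth_reads: pd.DataFrame


def simulate_dataset(
    config: SimConfig, n_individuals: int, seed: int, keep: str = "all"
) -> SimDataset:
    """Population + mosaicism + reads for ``n_individuals``, one seed."""
    rng = np.random.default_rng(seed)
    pop = simulate_population(config, n_individuals, rng)
    reads: list[SimRead] = []
    for row in pop.itertuples():
        mixtures = simulate_mosaic((row.allele1, row.allele2), row.age, config)
        reads.extend(simulate_reads(row.sample_id, mixtures, config, rng, keep=keep))
    return SimDataset(
        config=config,
        population=pop,
        reads=reads,
        truth_reads=truth_frame(reads),
    )


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Copy of a config with fields replaced (flanks regenerated if reset)."""
    return replace(config, **kwargs)


def load_config(path, **overrides) -> SimConfig:
    """Load a SimConfig from a flat key-value file.

    One ``key value`` (or ``key=value``) pair per line; ``#`` starts a
    comment.  Keys are SimConfig field names; ``allele_dist`` is written as
    ``units:prob`` pairs separated by commas (e.g. ``12:0.3,18:0.5,25:0.2``)
    and ``age_range`` as ``low,high``.  Keyword overrides win over file
    values.
    """
    import dataclasses

    fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    values: dict = {}
    for raw in Path(str(path)).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = (
            line.partition("=") if "=" in line else line.partition(" ")
        )
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ValueError(f"unknown simulator config key: {key!r}")
        if key == "allele_dist":
            values[key] = {
                int(u): float(p)
                for u, p in (pair.split(":") for pair in val.split(","))
            }
        elif key == "age_range":
            low, high = val.split(",")
            values[key] = (int(low), int(high))
        elif key in ("germline_rate_fn", "somatic_rate_fn"):
            raise ValueError(f"{key} cannot be set from a config file")
        else:
            typ = fields[key].type
            if typ == "int":
                values[key] = int(val)
            elif typ == "float":
                values[key] = float(val)
            else:
                values[key] = val
    values.update(overrides)
    return SimConfig(**values)
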