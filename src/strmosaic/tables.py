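"""Deterministic TSV views of the in-memory call objects.

All frames are sorted (sample, locus, read id) so outputs are byte-stable
and independent of read input order.
"""

from __future__ import annotations

import pandas as pd

from .harvest import GermlineGenotype, IrrCall, IrrPair, SpanningCall
from .stutter import StutterAssessment


def spanning_frame(calls: list[SpanningCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "locus_id": c.locus_id,
                "read_id": c.read_id,
                "unit_count": c.unit_count,
                "bp_length": c.bp_length,
                "interruptions": ";".join(f"{u}:{b}" for u, b in c.interruptions),
                "left_anchor_len": c.left_anchor_len,
                "right_anchor_len": c.right_anchor_len,
                "orientation": c.orientation,
            }
            for c in sorted(calls, key=lambda c: (c.sample_id, c.locus_id, c.read_id))
        ],
        columns=[
            "sample_id",
            "locus_id",
            "read_id",
            "unit_count",
            "bp_length",
            "interruptions",
            "left_anchor_len",
            "right_anchor_len",
            "orientation",
        ],
    )


def irr_frame(calls: list[IrrCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "read_id": c.read_id,
                "motif": c.motif,
                "purity": round(c.purity_value, 6),
                "assigned_locus": c.assigned_locus or "",
                "assignment_distance": (
                    "" if c.assignment_distance is None else c.assignment_distance
                ),
                "unassigned_reason": c.unassigned_reason or "",
            }
            for c in sorted(
                calls, key=lambda c: (c.sample_id, c.assigned_locus or "", c.read_id)
            )
        ],
        columns=[
            "sample_id",
            "read_id",
            "motif",
            "purity",
            "assigned_locus",
            "assignment_distance",
            "unassigned_reason",
        ],
    )


def pairs_frame(pairs: list[IrrPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "fragment_id": p.fragment_id,
                "motif": p.motif,
                "assigned_locus": p.assigned_locus,
            }
            for p in sorted(
                pairs, key=lambda p: (p.sample_id, p.assigned_locus, p.fragment_id)
            )
        ],
        columns=["sample_id", "fragment_id", "motif", "assigned_locus"],
    )


def genotypes_frame(genotypes: dict[tuple[str, str], GermlineGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": g.sample_id,
                "locus_id": g.locus_id,
                "allele1": g.alleles[0],
                "allele2": g.alleles[1],
                "support": ";".join(
                    f"{a}:{n}" for a, n in sorted(g.support.items())
                ),
            }
            for _, g in sorted(genotypes.items())
        ],
        columns=["sample_id", "locus_id", "allele1", "allele2", "support"],
    )


def assessments_frame(assessments: list[StutterAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "locus_id": a.locus_id,
                "delta_units": a.delta_units,
                "n_signature_positions": len(a.signature_positions),
                "mean_q_signature": (
                    "" if a.mean_q_signature is None else round(a.mean_q_signature, 3)
                ),
                "mean_q_control": (
                    "" if a.mean_q_control is None else round(a.mean_q_control, 3)
                ),
                "verdict": a.verdict,
                "reason": a.reason or "",
            }
            for a in sorted(assessments, key=lambda a: (a.locus_id, a.read_id))
        ],
        columns=[
            "read_id",
            "locus_id",
            "delta_units",
            "n_signature_positions",
            "mean_q_signature",
            "mean_q_control",
            "verdict",
            "reason",
        ],
    )
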