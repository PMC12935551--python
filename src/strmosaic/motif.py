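"""Repeat-motif canonicalization and repeat-purity scoring.

A short tandem repeat (STR) motif is a 2-6 bp unit over {A,C,G,T}.  Reads
sequenced from either strand of a repeat tract, starting at any phase of the
unit, all belong to one motif *class*: the set of rotations of the motif
together with the rotations of its reverse complement.  We identify the class
by its lexicographically smallest member (the *canonical* motif), so e.g.
CAG, AGC, GCA, CTG, TGC and GCT all canonicalize to AGC.

Purity quantifies how much of a read is explained by tiling a single motif
class — the primitive behind in-repeat-read (IRR) detection, where reads
"entirely or almost entirely" made of repeat units flag alleles longer than
the read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "InvalidMotifError",
    "Motif",
    "PurityScore",
    "canonicalize",
    "is_irr",
    "purity",
    "purity_batch",
    "reverse_complement",
    "rotations",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default purity threshold for calling a read an IRR ("almost entirely"
#: repeat units); at 151 bp this tolerates ~7 mismatching positions.
DEFAULT_TAU = 0.95


class InvalidMotifError(ValueError):
    """Raised for motifs outside the 2-6 bp ACGT space."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    """All cyclic rotations of ``seq``, starting from offset 0."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def _validate(motif: str) -> str:
    if not isinstance(motif, str):
        raise InvalidMotifError(f"motif must be a string, got {type(motif)!r}")
    m = motif.upper()
    if not 2 <= len(m) <= 6:
        raise InvalidMotifError(f"motif length must be 2-6 bp, got {motif!r}")
    if set(m) - set("ACGT"):
        raise InvalidMotifError(f"motif must be over ACGT, got {motif!r}")
    return m


@lru_cache(maxsize=4096)
def canonicalize(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string among all rotations of
    ``motif`` and all rotations of its reverse complement.  Idempotent, and
    constant across the whole class (e.g. every CAG/CTG rotation -> "AGC").
    """
    m = _validate(motif)
    return min(rotations(m) + rotations(reverse_complement(m)))


@lru_cache(maxsize=4096)
def class_variants(motif: str) -> tuple[str, ...]:
    """The distinct members of a motif class, canonical rotations first.

    Ordering is the deterministic tie-break order for purity: rotations of
    the canonical form from offset 0, then rotations of its reverse
    complement not already listed.
    """
    canon = canonicalize(motif)
    seen: list[str] = []
    for v in rotations(canon) + rotations(reverse_complement(canon)):
        if v not in seen:
            seen.append(v)
    return tuple(seen)


@dataclass(frozen=True)
class Motif:
    """A repeat unit plus its strand/rotation-free canonical form."""

    bases: str
    canonical: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate(self.bases))
        object.__setattr__(self, "canonical", canonicalize(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass
class PurityScore:
    """Fraction of read positions explained by tiling one motif variant.

    value = 1 - len(mismatch_positions) / len(read); 1.0 iff the read is an
    exact tiling of some rotation (either strand) of the motif.
    """

    value: float
    best_rotation: str
    mismatch_positions: list[int]


@lru_cache(maxsize=4096)
def _variant_bytes(motif: str) -> tuple[tuple[str, bytes], ...]:
    return tuple((v, v.encode("ascii")) for v in class_variants(motif))


def _tiled(variant: bytes, length: int) -> np.ndarray:
    reps = -(-length // len(variant))  # ceil
    arr = np.frombuffer(variant * reps, dtype=np.uint8)
    return arr[:length]


def _as_motif_str(motif: "Motif | str") -> str:
    return motif.bases if isinstance(motif, Motif) else _validate(motif)


def purity(read_seq: str, motif: "Motif | str") -> PurityScore:
    """Score how completely ``read_seq`` tiles the motif class of ``motif``.

    The score is the maximum, over all rotation/reverse-complement variants
    of the motif, of the fraction of positions matching a tiling of that
    variant from read offset 0.  Mismatch offsets are reported for the
    arg-max variant; ties go to the variant earliest in canonical rotation
    order.  Any non-ACGT base (e.g. N) counts as a mismatch.
    """
    if not read_seq:
        raise ValueError("empty read sequence")
    seq = np.frombuffer(read_seq.upper().encode("ascii"), dtype=np.uint8)
    n = seq.size
    best_val = -1.0
    best_var = ""
    best_mm: np.ndarray | None = None
    for variant, vb in _variant_bytes(_as_motif_str(motif)):
        matches = seq == _tiled(vb, n)
        val = float(matches.mean())
        if val > best_val:
            best_val = val
            best_var = variant
            best_mm = matches
    assert best_mm is not None
    return PurityScore(
        value=best_val,
        best_rotation=best_var,
        mismatch_positions=[int(i) for i in np.flatnonzero(~best_mm)],
    )


def purity_batch(seqs: np.ndarray, motif: "Motif | str") -> np.ndarray:
    """Vectorised purity values for many equal-length reads.

    ``seqs`` is a (n_reads, read_length) uint8 array of ASCII bases (see
    :func:`encode_reads`).  Returns the per-read purity value only (no
    mismatch bookkeeping); used on the hot IRR-scanning path.
    """
    n, length = seqs.shape
    best = np.zeros(n)
    for _, vb in _variant_bytes(_as_motif_str(motif)):
        np.maximum(best, (seqs == _tiled(vb, length)).mean(axis=1), out=best)
    return best


def encode_reads(read_seqs: list[str]) -> np.ndarray:
    """Pack equal-length read strings into a uint8 matrix for purity_batch."""
    if not read_seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    joined = "".join(s.upper() for s in read_seqs)
    return np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(
        len(read_seqs), -1
    )


def is_irr(read_seq: str, motif: "Motif | str", tau: float = DEFAULT_TAU) -> bool:
    """True iff the read is (almost) entirely repeat units of the motif class."""
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    return purity(read_seq, motif).value >= tau
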