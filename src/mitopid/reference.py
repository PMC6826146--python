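"""Circular mtDNA coordinate arithmetic, region definition, substitution typing.

Human mtDNA is a circle of 16,569 bp in the rCRS coordinate frame; the
interrogated D-loop window runs from position 16,560 through position 279 and
therefore wraps through the origin, giving 289 callable positions.  All
coordinates in this package are 1-based and inclusive, matching mtDNA
community convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

RCRS_LENGTH = 16569
DEFAULT_REGION_START = 16560
DEFAULT_REGION_END = 279

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID_BASES = frozenset("ACGTN")

# integer base codes used throughout the pipeline
A, C, G, T, N_CODE, GAP = 0, 1, 2, 3, 4, 5
NO_CALL = 6          # sub-threshold consensus column (participant base assumed)
NOT_COVERED = 255    # read does not cover this reference position

_BASE_TO_CODE = {"A": A, "C": C, "G": G, "T": T, "N": N_CODE, "-": GAP}
_CODE_TO_BASE = {v: k for k, v in _BASE_TO_CODE.items()}
_CODE_TO_BASE[NO_CALL] = "."
_CODE_TO_BASE[NOT_COVERED] = "?"

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (unknown letters become N)."""
    return _ENCODE_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[int(c)] for c in codes)


class CoordinateError(ValueError):
    """A position falls outside the genome or region bounds."""


@dataclass(frozen=True)
class CircularGenome:
    """A circular reference genome with 1-based, wrapping coordinates."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in reference: {sorted(bad)}")
        if not seq:
            raise ValueError("empty reference sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position; positions wrap (length+1 == 1)."""
        return self.sequence[(position - 1) % self.length]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularGenome":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"reference FASTA must contain exactly one record, found {len(records)}"
            )
        return cls(name=records[0].id, sequence=str(records[0].seq))


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive interval on the circle; start > end wraps the origin."""

    start: int = DEFAULT_REGION_START
    end: int = DEFAULT_REGION_END

    @property
    def crosses_origin(self) -> bool:
        return self.start > self.end

    def length(self, genome_len: int) -> int:
        if self.crosses_origin:
            return genome_len - self.start + 1 + self.end
        return self.end - self.start + 1


def region_positions(region: RegionSpec, genome_len: int) -> list[int]:
    """Ordered 1-based positions of a circular region, wrapping after genome_len.

    For the default D-loop window (16,560 -> 279 on a 16,569-bp genome) this
    yields 289 positions: 16,560..16,569 followed by 1..279.
    """
    for pos in (region.start, region.end):
        if not 1 <= pos <= genome_len:
            raise CoordinateError(
                f"region bound {pos} outside genome of length {genome_len}"
            )
    if region.crosses_origin:
        return list(range(region.start, genome_len + 1)) + list(
            range(1, region.end + 1)
        )
    return list(range(region.start, region.end + 1))


def region_sequence(genome: CircularGenome, region: RegionSpec) -> str:
    return "".join(genome.base(p) for p in region_positions(region, genome.length))


class InvalidSubstitutionError(ValueError):
    """ref == alt, or a base outside {A, C, G, T}."""


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a point substitution as ``"transition"`` or ``"transversion"``.

    Transitions are the within-class changes A<->G and C<->T (the polymerase
    gamma error signature); the eight remaining ordered pairs are
    transversions (the oxidative-damage signature).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise InvalidSubstitutionError(f"ref and alt are identical ({ref})")
    for b in (ref, alt):
        if b not in "ACGT" or len(b) != 1:
            raise InvalidSubstitutionError(f"ambiguous or invalid base {b!r}")
    if (ref in PURINES) == (alt in PURINES):
        return "transition"
    return "transversion"
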