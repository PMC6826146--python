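"""Projection of read payloads onto reference-region coordinates.

Each payload is aligned to the interrogated region of the reference and
projected to a fixed-length vector of per-position base calls (A/C/G/T, N,
gap, or not-covered).  Insertions relative to the reference are dropped from
the coordinate frame — indels are out of scope for calling — so downstream
consensus building works on plain columns.

Alignment is global with affine gap penalties and free end gaps, so a payload
that covers only part of the region aligns where it belongs without terminal
gap cost.  Payloads whose length equals the region length and that match the
reference closely skip dynamic programming entirely (substitution-only reads
are the overwhelmingly common case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align

from mitopid.io_demux import (
    REASON_SHORT_READ,
    REASON_UNALIGNABLE,
    RejectedRead,
    TaggedRead,
)
from mitopid.reference import (
    GAP,
    NOT_COVERED,
    CircularGenome,
    RegionSpec,
    encode_bases,
    region_positions,
    region_sequence,
)

DEFAULT_MIN_IDENTITY = 0.70


@dataclass(frozen=True)
class ProjectedRead:
    """A tagged read with its per-position base calls over the region."""

    read: TaggedRead
    calls: np.ndarray  # uint8, length = region length
    covered_start: int  # first region index covered (0-based)
    covered_end: int  # last region index covered (0-based, inclusive)
    identity: float

    @property
    def pid(self) -> str:
        return self.read.pid

    @property
    def read_id(self) -> str:
        return self.read.read_id


class ReferenceAligner:
    """Affine-gap pairwise aligner projecting payloads to region coordinates."""

    def __init__(
        self,
        genome: CircularGenome,
        region: RegionSpec,
        match: float = 1.0,
        mismatch: float = -1.0,
        gap_open: float = -4.0,
        gap_extend: float = -1.0,
        min_identity: float = DEFAULT_MIN_IDENTITY,
    ):
        self.genome = genome
        self.region = region
        self.positions = region_positions(region, genome.length)
        self.region_seq = region_sequence(genome, region)
        self.region_codes = encode_bases(self.region_seq)
        self.min_identity = min_identity
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        with warnings.catch_warnings():
            # biopython 1.88 renamed the end-gap attributes; accept either name
            warnings.simplefilter("ignore")
            try:
                aligner.end_insertion_score = 0
                aligner.end_deletion_score = 0
            except AttributeError:
                aligner.target_end_gap_score = 0
                aligner.query_end_gap_score = 0
        self._aligner = aligner

    def index_of(self, position: int) -> int:
        """0-based region index of a 1-based reference position."""
        return self.positions.index(position)

    def project(self, payload: str) -> ProjectedRead | None:
        """Project a payload; returns None when identity is below the floor."""
        n = len(self.region_codes)
        codes = encode_bases(payload)
        # fast path: substitution-only payload spanning the whole region
        if len(codes) >= n:
            head = codes[:n]
            ident = float(np.mean(head == self.region_codes))
            if ident >= max(self.min_identity, 0.9):
                return ProjectedRead(
                    read=None,  # type: ignore[arg-type]  # filled by caller
                    calls=head,
                    covered_start=0,
                    covered_end=n - 1,
                    identity=ident,
                )
        return self._project_dp(codes, payload)

    def _project_dp(self, codes: np.ndarray, payload: str) -> ProjectedRead | None:
        alignment = self._aligner.align(self.region_seq, payload)[0]
        target_segs, query_segs = alignment.aligned
        if len(target_segs) == 0:
            return None
        calls = np.full(len(self.region_codes), NOT_COVERED, dtype=np.uint8)
        matches = 0
        aligned_cols = 0
        for (ts, te), (qs, qe) in zip(target_segs, query_segs):
            calls[ts:te] = codes[qs:qe]
            matches += int(np.sum(codes[qs:qe] == self.region_codes[ts:te]))
            aligned_cols += te - ts
        start = int(target_segs[0][0])
        end = int(target_segs[-1][1]) - 1
        # deletions: uncovered region positions inside the aligned span
        span = calls[start : end + 1]
        span[span == NOT_COVERED] = GAP
        identity = matches / aligned_cols if aligned_cols else 0.0
        if identity < self.min_identity:
            return None
        # a credible alignment must engage most of the shorter sequence;
        # otherwise a random payload could pass on a tiny terminal overlap
        if aligned_cols < 0.5 * min(len(codes), len(self.region_codes)):
            return None
        return ProjectedRead(
            read=None,  # type: ignore[arg-type]
            calls=calls,
            covered_start=start,
            covered_end=end,
            identity=identity,
        )


def filter_reach(
    tagged_reads: list[TaggedRead],
    aligner: ReferenceAligner,
    min_position: int = 279,
) -> tuple[list[ProjectedRead], list[RejectedRead]]:
    """Keep reads whose alignment to the region covers ``min_position``.

    Coverage, not raw length or identity, is the criterion, so a read with
    mismatches but full span is kept while a read stopping short of position
    279 is rejected as ``short_read``.  Payloads that cannot be aligned above
    the identity floor are rejected as ``unalignable``.
    """
    target_idx = aligner.index_of(min_position)
    kept: list[ProjectedRead] = []
    rejects: list[RejectedRead] = []
    for tr in tagged_reads:
        proj = aligner.project(tr.payload)
        if proj is None:
            rejects.append(RejectedRead(tr.read_id, REASON_UNALIGNABLE))
            continue
        if proj.covered_end < target_idx:
            rejects.append(RejectedRead(tr.read_id, REASON_SHORT_READ))
            continue
        kept.append(
            ProjectedRead(
                read=tr,
                calls=proj.calls,
                covered_start=proj.covered_start,
                covered_end=proj.covered_end,
                identity=proj.identity,
            )
        )
    return kept, rejects
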