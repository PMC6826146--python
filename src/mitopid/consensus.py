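"""PID-group and participant-level consensus building.

Reads sharing a primer ID descend from one template molecule, so a true
template mutation appears in (nearly) all of them while a PCR or sequencing
error appears in a scattered minority.  A PID-group consensus therefore calls
a base only when it reaches a support threshold (default 75%) within a group
of at least ``min_group_size`` (default 5) reads; sub-threshold columns carry
a no-call marker and can never emit a variant.  The participant consensus —
the sample's own reference against which mutations are defined — is the
per-column plurality over all eligible PID consensuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitopid.align import ProjectedRead
from mitopid.reference import GAP, N_CODE, NO_CALL, NOT_COVERED

MIN_GROUP_SIZE = 5
SUPPORT_THRESHOLD = 0.75
MIN_PARTICIPANT_GROUPS = 100


class GroupIneligibleError(ValueError):
    """A consensus was requested for a group below the minimum size."""


class ParticipantQCError(ValueError):
    """Too few eligible PID groups to build a participant consensus."""


@dataclass
class PidGroup:
    """Reads sharing one primer ID (one original template molecule)."""

    pid: str
    reads: list[ProjectedRead]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class PidConsensus:
    """Column-wise consensus of one PID group over the interrogated region."""

    pid: str
    bases: np.ndarray  # uint8 codes; NO_CALL where support is sub-threshold
    support: np.ndarray  # top-base support fraction per column (nan if uncovered)
    size: int


@dataclass
class ParticipantConsensus:
    """Plurality base per position across a sample's PID consensuses."""

    mid_id: str
    bases: np.ndarray
    n_groups_used: int


def group_by_pid(
    tagged_reads: list[ProjectedRead],
    min_group_size: int = MIN_GROUP_SIZE,
) -> tuple[list[PidGroup], list[PidGroup]]:
    """Partition reads into PID groups; returns ``(eligible, undersized)``.

    Groups with fewer than ``min_group_size`` reads are excluded from calling
    but returned for accounting; ``len(eligible)`` is the denominator of the
    burden frequency.
    """
    by_pid: dict[str, list[ProjectedRead]] = {}
    for read in tagged_reads:
        by_pid.setdefault(read.pid, []).append(read)
    eligible, undersized = [], []
    for pid, members in by_pid.items():
        group = PidGroup(pid=pid, reads=members)
        (eligible if group.size >= min_group_size else undersized).append(group)
    return eligible, undersized


def _column_counts(matrix: np.ndarray, codes: tuple[int, ...]) -> np.ndarray:
    """Stack of per-column counts for each code; shape (len(codes), n_cols)."""
    return np.stack([(matrix == c).sum(axis=0) for c in codes])


def build_pid_consensus(
    group: PidGroup,
    support_threshold: float = SUPPORT_THRESHOLD,
    min_group_size: int = MIN_GROUP_SIZE,
) -> PidConsensus:
    """Column-wise threshold consensus of a PID group.

    Per column, the plurality call among {A, C, G, T, gap} over the reads
    covering that column becomes the consensus iff its support fraction
    (votes / covering reads) reaches ``support_threshold`` — the threshold is
    inclusive, so 6 of 8 reads (75% exactly) calls.  Sub-threshold or
    uncovered columns carry NO_CALL; N calls cover nothing.
    """
    if group.size < min_group_size:
        raise GroupIneligibleError(
            f"PID group {group.pid} has {group.size} reads (< {min_group_size})"
        )
    matrix = np.stack([r.calls for r in group.reads])
    vote_codes = (0, 1, 2, 3, GAP)  # A C G T gap
    counts = _column_counts(matrix, vote_codes)
    covering = counts.sum(axis=0)
    top_idx = counts.argmax(axis=0)
    top_count = counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        support = np.where(covering > 0, top_count / np.maximum(covering, 1), np.nan)
    bases = np.array([vote_codes[i] for i in top_idx], dtype=np.uint8)
    called = (covering > 0) & (top_count / np.maximum(covering, 1) >= support_threshold)
    bases[~called] = NO_CALL
    return PidConsensus(pid=group.pid, bases=bases, support=support, size=group.size)


def build_participant_consensus(
    pid_consensuses: list[PidConsensus],
    reference_codes: np.ndarray,
    mid_id: str = "",
    min_participant_groups: int = MIN_PARTICIPANT_GROUPS,
) -> ParticipantConsensus:
    """Plurality base per column across PID consensuses.

    No-call, gap, and N columns are excluded from the vote.  Ties resolve to
    the reference base when the reference is among the tied leaders (never
    fabricating a variant from a 50/50 split) and to the alphabetically first
    base otherwise; columns with no votes at all fall back to the reference.
    """
    if len(pid_consensuses) < min_participant_groups:
        raise ParticipantQCError(
            f"sample {mid_id or '<unnamed>'}: {len(pid_consensuses)} eligible PID "
            f"groups (< {min_participant_groups}); sample fails QC"
        )
    matrix = np.stack([c.bases for c in pid_consensuses])
    counts = _column_counts(matrix, (0, 1, 2, 3))  # A C G T only
    top_count = counts.max(axis=0)
    bases = counts.argmax(axis=0).astype(np.uint8)  # argmax = first (lowest code) on tie
    ref_is_tied = (
        (reference_codes < 4)
        & (np.take_along_axis(counts, reference_codes[None, :].astype(int) % 4, axis=0)[0] == top_count)
    )
    bases = np.where(ref_is_tied, reference_codes, bases).astype(np.uint8)
    no_votes = top_count == 0
    bases = np.where(no_votes, reference_codes, bases).astype(np.uint8)
    return ParticipantConsensus(
        mid_id=mid_id, bases=bases, n_groups_used=len(pid_consensuses)
    )
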