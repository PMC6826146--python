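"""FASTA/FNA read parsing, MID demultiplexing, and PID extraction.

Reads are 454-style single-end amplicons laid out as
``MID (sample barcode) + 19-bp PID (template barcode) + D-loop payload``.
A read is assigned to a sample when exactly one MID from the table occurs
within the first ``search_window`` bases; reads matching no MID, more than
one MID, too short to yield a 19-bp PID, or with an ambiguous (N-containing)
PID are rejected with a recorded reason.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

PID_LENGTH = 19
DEFAULT_SEARCH_WINDOW = 100

REASON_NO_MID = "no_mid"
REASON_AMBIGUOUS_MID = "ambiguous_mid"
REASON_TRUNCATED = "truncated"
REASON_PID_AMBIGUOUS = "pid_ambiguous"
REASON_SHORT_READ = "short_read"
REASON_UNALIGNABLE = "unalignable"


@dataclass(frozen=True)
class RawRead:
    read_id: str
    bases: str


@dataclass(frozen=True)
class TaggedRead:
    """A read with recognised MID, extracted 19-bp PID, and remaining payload."""

    read_id: str
    mid_id: str
    pid: str
    payload: str


@dataclass(frozen=True)
class RejectedRead:
    read_id: str
    reason: str


class MidTable:
    """Mapping of sample id to MID barcode sequence.

    MIDs must be pairwise distinct and prefix-free so that barcode hits are
    unambiguous.
    """

    def __init__(self, entries: dict[str, str]):
        if not entries:
            raise ValueError("MID table is empty")
        seqs = [s.upper() for s in entries.values()]
        for s in seqs:
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"MID sequence {s!r} is not a plain A/C/G/T string")
        if len(set(seqs)) != len(seqs):
            raise ValueError("MID sequences are not pairwise distinct")
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                if a.startswith(b) or b.startswith(a):
                    raise ValueError(f"MID {a} is a prefix of MID {b}")
        self.entries = {k: s.upper() for k, s in entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mid_id: str) -> str:
        return self.entries[mid_id]

    def items(self):
        return self.entries.items()

    @property
    def max_length(self) -> int:
        return max(len(s) for s in self.entries.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MidTable":
        entries: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() in ("mid_id", "id", "name"):
                    continue  # header row
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'mid_id<TAB>sequence'")
                entries[parts[0]] = parts[1]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("mid_id\tsequence\n")
            for mid_id, seq in self.entries.items():
                fh.write(f"{mid_id}\t{seq}\n")


def read_fasta(path: str | Path) -> list[RawRead]:
    """Parse a FASTA/FNA file (plain or gzip) into RawReads, order preserved.

    Sequences are uppercased; multi-line records are concatenated.  An empty
    file yields an empty list with a logged warning.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    reads: list[RawRead] = []
    with opener(path, "rt") as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, "fasta")):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise ValueError(f"record {idx} in {path} has an empty header")
            if not seq:
                raise ValueError(f"record {idx} ({rec.id}) in {path} is empty")
            reads.append(RawRead(read_id=rec.id, bases=seq))
    if not reads:
        log.warning("no records parsed from %s", path)
    return reads


def _find_mid(
    bases: str, mid_seq: str, search_window: int, max_mismatch: int = 0
) -> int | None:
    """Leftmost start offset of mid_seq with offset < search_window, else None."""
    if max_mismatch == 0:
        pos = bases.find(mid_seq, 0, search_window + len(mid_seq) - 1)
        return pos if (pos != -1 and pos < search_window) else None
    k = len(mid_seq)
    for off in range(min(search_window, max(len(bases) - k + 1, 0))):
        window = bases[off : off + k]
        if sum(a != b for a, b in zip(window, mid_seq)) <= max_mismatch:
            return off
    return None


def demultiplex(
    reads: list[RawRead],
    mid_table: MidTable,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[tuple[RawRead, int]]], list[RejectedRead]]:
    """Assign reads to MID bins; returns ``(bins, rejects)``.

    ``bins[mid_id]`` holds ``(read, mid_end_offset)`` pairs where
    ``mid_end_offset`` indexes the first base after the barcode.  A read
    matching no MID within the window is rejected as ``no_mid``; a read
    matching two distinct MIDs is rejected as ``ambiguous_mid``.  Every input
    read lands in exactly one bin or in the reject list.
    """
    if search_window < mid_table.max_length:
        raise ValueError("search_window shorter than the longest MID")
    bins: dict[str, list[tuple[RawRead, int]]] = {m: [] for m in mid_table.entries}
    rejects: list[RejectedRead] = []
    for read in reads:
        hits = []
        for mid_id, mid_seq in mid_table.items():
            off = _find_mid(read.bases, mid_seq, search_window, max_mismatch)
            if off is not None:
                hits.append((off, mid_id, mid_seq))
        if not hits:
            rejects.append(RejectedRead(read.read_id, REASON_NO_MID))
        elif len(hits) > 1:
            rejects.append(RejectedRead(read.read_id, REASON_AMBIGUOUS_MID))
        else:
            off, mid_id, mid_seq = hits[0]
            bins[mid_id].append((read, off + len(mid_seq)))
    return bins, rejects


def extract_pid(
    read: RawRead,
    mid_id: str,
    mid_end_offset: int,
    pid_length: int = PID_LENGTH,
) -> TaggedRead | RejectedRead:
    """Extract the PID (the ``pid_length`` bases after the MID) and payload.

    Reads with fewer than ``pid_length`` + 1 bases after the MID are rejected
    as truncated; a PID containing N is rejected as ``pid_ambiguous``, since a
    miscalled PID would merge or split template groups.
    """
    tail = read.bases[mid_end_offset:]
    if len(tail) <= pid_length:
        return RejectedRead(read.read_id, REASON_TRUNCATED)
    pid, payload = tail[:pid_length], tail[pid_length:]
    if "N" in pid:
        return RejectedRead(read.read_id, REASON_PID_AMBIGUOUS)
    return TaggedRead(read_id=read.read_id, mid_id=mid_id, pid=pid, payload=payload)


def demux_and_tag(
    reads: list[RawRead],
    mid_table: MidTable,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    pid_length: int = PID_LENGTH,
    max_mismatch: int = 0,
) -> tuple[dict[str, list[TaggedRead]], list[RejectedRead]]:
    """Full read-level flow: MID binning then PID extraction, per sample."""
    bins, rejects = demultiplex(reads, mid_table, search_window, max_mismatch)
    tagged: dict[str, list[TaggedRead]] = {m: [] for m in bins}
    for mid_id, members in bins.items():
        for read, mid_end in members:
            result = extract_pid(read, mid_id, mid_end, pid_length)
            if isinstance(result, RejectedRead):
                rejects.append(result)
            else:
                tagged[mid_id].append(result)
    return tagged, rejects


def reject_counts(rejects: list[RejectedRead]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in rejects:
        counts[r.reason] = counts.get(r.reason, 0) + 1
    return counts


def write_rejects_tsv(rejects: list[RejectedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for r in rejects:
            fh.write(f"{r.read_id}\t{r.reason}\n")
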