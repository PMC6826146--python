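"""Variant calling against the participant consensus and burden statistics.

A mutation is any difference between a PID-group consensus base (which must
have cleared the 75% support threshold) and the participant consensus base at
an interrogated position.  Aggregated over a sample's eligible PID groups, a
variant seen in <=2% of groups is somatic (a de novo, non-expanded mutation on
the sequenced strand) and in >2% of groups is heteroplasmic (a clonally
expanded species).  The somatic burden is expressed per 10,000 bp:

    freq = n_somatic * 10,000 / (n_groups * region_len)

with ``region_len`` = 289 for the default D-loop window, and optionally
rescaled to mutations per 16,569-bp mtDNA genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mitopid.consensus import ParticipantConsensus, PidConsensus
from mitopid.reference import (
    RCRS_LENGTH,
    classify_substitution,
    decode_bases,
)

HETEROPLASMY_CUTOFF = 0.02
REGION_LEN = 289

_CODE_TO_BASE = "ACGT"


class UndefinedFrequencyError(ZeroDivisionError):
    """Burden frequency requested for a sample with zero eligible groups."""


@dataclass(frozen=True)
class VariantCall:
    """A substitution aggregated over a sample's PID groups."""

    position: int  # 1-based rCRS coordinate
    participant_base: str
    alt_base: str
    n_support_groups: int
    fraction_of_groups: float
    var_class: str  # "somatic" | "heteroplasmic"
    subst_class: str  # "transition" | "transversion"


@dataclass
class BurdenResult:
    """Per-sample somatic substitution burden and heteroplasmy summary."""

    sample_id: str
    n_somatic: int
    n_groups: int
    region_len: int
    freq_per_10kb: float
    freq_transformed: float
    per_genome: float
    ti_count: int
    tv_count: int
    heteroplasmy_present: bool
    heteroplasmic_sites: list[VariantCall] = field(default_factory=list)
    variants: list[VariantCall] = field(default_factory=list)


@dataclass
class ControlSummary:
    """Assay background (plasmid controls) and run-to-run repeatability."""

    background_median: float
    background_iqr: tuple[float, float]
    cv_percent: float | None
    n_controls: int
    n_replicates: int


def call_group_variants(
    pid_consensus: PidConsensus,
    participant: ParticipantConsensus,
    positions: list[int],
) -> list[tuple[int, str]]:
    """Differences between one PID-group consensus and the participant consensus.

    Emits ``(rCRS position, alt base)`` where both consensuses carry a real
    base (A/C/G/T), the bases differ, and the position lies in the region.
    No-call, gap, and N columns emit nothing; a reference N also disables the
    position (handled upstream by the participant consensus carrying N there).
    """
    group = pid_consensus.bases
    part = participant.bases
    diff = (group < 4) & (part < 4) & (group != part)
    return [
        (positions[i], _CODE_TO_BASE[group[i]]) for i in np.flatnonzero(diff)
    ]


def classify_calls(
    group_calls: list[list[tuple[int, str]]],
    participant: ParticipantConsensus,
    positions: list[int],
    n_groups: int,
    heteroplasmy_cutoff: float = HETEROPLASMY_CUTOFF,
    by_position_only: bool = False,
) -> list[VariantCall]:
    """Aggregate per-group calls into classified VariantCalls.

    Calls are keyed by (position, alt) by default — two different alleles at
    one site are distinct molecular events; ``by_position_only=True`` restores
    aggregation by position alone.  The fraction of supporting groups decides
    the class: somatic iff fraction <= cutoff (inclusive), else heteroplasmic.
    """
    if n_groups < 1:
        raise UndefinedFrequencyError("n_groups must be >= 1")
    pos_index = {p: i for i, p in enumerate(positions)}
    tally: dict[tuple, int] = {}
    alt_seen: dict[tuple, str] = {}
    for calls in group_calls:
        for pos, alt in calls:
            key = (pos,) if by_position_only else (pos, alt)
            tally[key] = tally.get(key, 0) + 1
            alt_seen.setdefault(key, alt)
    variants: list[VariantCall] = []
    for key, count in sorted(tally.items()):
        pos = key[0]
        alt = alt_seen[key]
        part_code = int(participant.bases[pos_index[pos]])
        part_base = _CODE_TO_BASE[part_code] if part_code < 4 else "N"
        fraction = count / n_groups
        var_class = "somatic" if fraction <= heteroplasmy_cutoff else "heteroplasmic"
        variants.append(
            VariantCall(
                position=pos,
                participant_base=part_base,
                alt_base=alt,
                n_support_groups=count,
                fraction_of_groups=fraction,
                var_class=var_class,
                subst_class=classify_substitution(part_base, alt)
                if part_base in "ACGT"
                else "transversion",
            )
        )
    return variants


def somatic_frequency(
    n_somatic: int, n_groups: int, region_len: int = REGION_LEN
) -> float:
    """Somatic substitutions per 10,000 bp: n_somatic*10,000/(n_groups*region_len)."""
    if n_groups < 1:
        raise UndefinedFrequencyError(
            "somatic frequency undefined with zero eligible PID groups"
        )
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    return n_somatic * 10_000 / (n_groups * region_len)


def per_genome_burden(
    freq_transformed: float, genome_length: int = RCRS_LENGTH
) -> float:
    """Convert an ln(x+1)-transformed per-10-kb burden to mutations per genome.

    Inverts the transform then rescales: (exp(t) - 1) * genome_length / 10,000.
    A transformed median of 0.42 per 10,000 bp corresponds to 0.86 mutations
    per 16,569-bp mtDNA genome.
    """
    if freq_transformed < 0:
        raise ValueError("transformed frequency must be >= 0")
    return (math.exp(freq_transformed) - 1.0) * genome_length / 10_000


def compute_burden(
    sample_id: str,
    variants: list[VariantCall],
    n_groups: int,
    region_len: int = REGION_LEN,
    genome_length: int = RCRS_LENGTH,
) -> BurdenResult:
    """Assemble the per-sample burden summary from classified variants.

    ``n_somatic`` counts group-level events: a somatic allele supported by 2
    of 300 groups contributes 2 (the numerator is per template molecule).
    Heteroplasmic sites never contribute to the somatic count.
    """
    somatic = [v for v in variants if v.var_class == "somatic"]
    hetero = [v for v in variants if v.var_class == "heteroplasmic"]
    n_somatic = sum(v.n_support_groups for v in somatic)
    freq = somatic_frequency(n_somatic, n_groups, region_len)
    freq_t = math.log1p(freq)
    ti = sum(v.n_support_groups for v in somatic if v.subst_class == "transition")
    tv = n_somatic - ti
    return BurdenResult(
        sample_id=sample_id,
        n_somatic=n_somatic,
        n_groups=n_groups,
        region_len=region_len,
        freq_per_10kb=freq,
        freq_transformed=freq_t,
        per_genome=per_genome_burden(freq_t, genome_length),
        ti_count=ti,
        tv_count=tv,
        heteroplasmy_present=bool(hetero),
        heteroplasmic_sites=hetero,
        variants=variants,
    )


def summarize_controls(
    controls: list[BurdenResult],
    replicates: list[BurdenResult] | None = None,
) -> ControlSummary:
    """Background (median and IQR over plasmid controls) and assay CV.

    The CV is the sample (n-1) standard deviation over replicate runs of the
    same clinical sample, divided by their mean, in percent.  Background is
    reported, never subtracted from sample burdens.
    """
    if not controls:
        raise ValueError("at least one control run is required")
    freqs = np.array([c.freq_per_10kb for c in controls], dtype=float)
    q1, med, q3 = np.percentile(freqs, [25, 50, 75])
    cv = None
    n_rep = 0
    if replicates:
        if len(replicates) < 2:
            raise ValueError("CV requires at least two replicate runs")
        rep = np.array([r.freq_per_10kb for r in replicates], dtype=float)
        mean = rep.mean()
        if mean == 0:
            raise ValueError("CV undefined: replicate mean is zero")
        cv = float(rep.std(ddof=1) / mean * 100)
        n_rep = len(replicates)
    return ControlSummary(
        background_median=float(med),
        background_iqr=(float(q1), float(q3)),
        cv_percent=cv,
        n_controls=len(controls),
        n_replicates=n_rep,
    )
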