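"""End-to-end pipeline: demux -> consensus -> calling -> burden, with config.

Every threshold defaults to the assay's a-priori value (MID search window
100 bp, 19-bp PID, group size >= 5, 75% support, >= 100 groups per
participant, 2% heteroplasmy cutoff, region 16,560-279 on a 16,569-bp
genome).  Samples are processed independently; re-running with identical
inputs and config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mitopid import __version__
from mitopid.align import ProjectedRead, ReferenceAligner, filter_reach
from mitopid.calling import (
    BurdenResult,
    call_group_variants,
    classify_calls,
    compute_burden,
)
from mitopid.consensus import (
    ParticipantQCError,
    build_participant_consensus,
    build_pid_consensus,
    group_by_pid,
)
from mitopid.io_demux import (
    MidTable,
    RejectedRead,
    demux_and_tag,
    read_fasta,
    reject_counts,
)
from mitopid.reference import CircularGenome, RegionSpec, decode_bases

log = logging.getLogger(__name__)

DEFAULTS: dict[str, object] = {
    "demux.search_window": 100,
    "pid.length": 19,
    "mid.max_mismatch": 0,
    "consensus.min_group_size": 5,
    "consensus.support_threshold": 0.75,
    "consensus.min_participant_groups": 100,
    "heteroplasmy.cutoff": 0.02,
    "heteroplasmy.by_position_only": False,
    "region.start": 16560,
    "region.end": 279,
    "region.min_position": 279,
    "genome.length": 16569,
    "align.min_identity": 0.70,
    "seed": 0,
}

_PATH_KEYS = ("reads", "reference", "mids", "cohort", "out")


class ConfigError(ValueError):
    """One or more configuration problems; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample: str, message: str):
        self.stage, self.sample = stage, sample
        super().__init__(f"stage {stage} (sample {sample or '-'}): {message}")


def validate_config(config: dict | None) -> dict:
    """Normalize a config dict: inject defaults, reject unknown keys and
    out-of-range thresholds (all problems reported together)."""
    config = dict(config or {})
    errors: list[str] = []
    normalized = dict(DEFAULTS)
    for key, value in config.items():
        if key in _PATH_KEYS:
            normalized[key] = value
            continue
        if key not in DEFAULTS:
            errors.append(f"unknown config key {key!r}")
            continue
        normalized[key] = value
    g = normalized["genome.length"]
    checks = [
        (normalized["demux.search_window"] >= 1, "demux.search_window must be >= 1"),
        (normalized["pid.length"] >= 1, "pid.length must be >= 1"),
        (
            0 < normalized["consensus.support_threshold"] <= 1,
            "consensus.support_threshold must be in (0, 1]",
        ),
        (
            normalized["consensus.min_group_size"] >= 1,
            "consensus.min_group_size must be >= 1",
        ),
        (
            normalized["consensus.min_participant_groups"] >= 1,
            "consensus.min_participant_groups must be >= 1",
        ),
        (
            0 <= normalized["heteroplasmy.cutoff"] <= 1,
            "heteroplasmy.cutoff must be a probability in [0, 1]",
        ),
        (g >= 1, "genome.length must be >= 1"),
        (
            1 <= normalized["region.start"] <= g,
            f"region.start outside [1, {g}]",
        ),
        (1 <= normalized["region.end"] <= g, f"region.end outside [1, {g}]"),
        (
            0 < normalized["align.min_identity"] <= 1,
            "align.min_identity must be in (0, 1]",
        ),
    ]
    for ok, msg in checks:
        if not ok:
            errors.append(msg)
    if errors:
        raise ConfigError(errors)
    return normalized


def config_hash(config: dict) -> str:
    payload = json.dumps(
        {k: v for k, v in sorted(config.items())}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# capacity arithmetic for run planning
# ---------------------------------------------------------------------------


def samples_per_run(amplicons_per_library: int = 12, n_libraries: int = 8) -> int:
    """Sequencing-run capacity: MID-tagged amplicons per library x libraries."""
    return amplicons_per_library * n_libraries


def reads_per_extract(
    reads_per_lane: int = 120_000, amplicons_per_lane: int = 12
) -> float:
    """Expected reads per DNA extract when amplicons are pooled evenly."""
    return reads_per_lane / amplicons_per_lane


# ---------------------------------------------------------------------------
# per-sample analysis
# ---------------------------------------------------------------------------


@dataclass
class SampleResult:
    sample_id: str
    n_tagged: int
    n_reach: int
    n_rejected_reach: int
    n_groups_eligible: int
    n_groups_undersized: int
    qc_pass: bool
    qc_reason: str | None
    burden: BurdenResult | None
    participant_bases: np.ndarray | None
    group_sizes: list[int] = field(default_factory=list)


def analyze_sample(
    sample_id: str,
    projected: list[ProjectedRead],
    aligner: ReferenceAligner,
    config: dict,
    n_tagged: int | None = None,
    n_rejected_reach: int = 0,
) -> SampleResult:
    """Consensus building, calling, and burden for one sample's kept reads."""
    eligible, undersized = group_by_pid(
        projected, min_group_size=config["consensus.min_group_size"]
    )
    result = SampleResult(
        sample_id=sample_id,
        n_tagged=n_tagged if n_tagged is not None else len(projected),
        n_reach=len(projected),
        n_rejected_reach=n_rejected_reach,
        n_groups_eligible=len(eligible),
        n_groups_undersized=len(undersized),
        qc_pass=False,
        qc_reason=None,
        burden=None,
        participant_bases=None,
        group_sizes=sorted(g.size for g in eligible),
    )
    if not eligible:
        result.qc_reason = "no eligible PID groups"
        return result
    consensuses = [
        build_pid_consensus(
            g,
            support_threshold=config["consensus.support_threshold"],
            min_group_size=config["consensus.min_group_size"],
        )
        for g in eligible
    ]
    try:
        participant = build_participant_consensus(
            consensuses,
            aligner.region_codes,
            mid_id=sample_id,
            min_participant_groups=config["consensus.min_participant_groups"],
        )
    except ParticipantQCError as exc:
        result.qc_reason = str(exc)
        return result
    group_calls = [
        call_group_variants(c, participant, aligner.positions) for c in consensuses
    ]
    variants = classify_calls(
        group_calls,
        participant,
        aligner.positions,
        n_groups=len(eligible),
        heteroplasmy_cutoff=config["heteroplasmy.cutoff"],
        by_position_only=config["heteroplasmy.by_position_only"],
    )
    result.burden = compute_burden(
        sample_id,
        variants,
        n_groups=len(eligible),
        region_len=len(aligner.positions),
        genome_length=config["genome.length"],
    )
    result.qc_pass = True
    result.participant_bases = participant.bases
    return result


def run_reads(
    reads: list,
    genome: CircularGenome,
    mid_table: MidTable,
    config: dict | None = None,
) -> tuple[dict[str, SampleResult], list[RejectedRead], dict]:
    """In-memory pipeline over parsed reads; returns per-sample results,
    global rejects, and the normalized config."""
    config = validate_config(config)
    region = RegionSpec(start=config["region.start"], end=config["region.end"])
    aligner = ReferenceAligner(
        genome, region, min_identity=config["align.min_identity"]
    )
    tagged, rejects = demux_and_tag(
        reads,
        mid_table,
        search_window=config["demux.search_window"],
        pid_length=config["pid.length"],
        max_mismatch=config["mid.max_mismatch"],
    )
    results: dict[str, SampleResult] = {}
    for mid_id, sample_reads in tagged.items():
        if not sample_reads:
            continue
        kept, reach_rejects = filter_reach(
            sample_reads, aligner, min_position=config["region.min_position"]
        )
        rejects.extend(reach_rejects)
        results[mid_id] = analyze_sample(
            mid_id,
            kept,
            aligner,
            config,
            n_tagged=len(sample_reads),
            n_rejected_reach=len(reach_rejects),
        )
    return results, rejects, config


@dataclass
class RunReport:
    version: str
    config: dict
    config_digest: str
    n_input_reads: int
    reject_reasons: dict[str, int]
    samples: dict[str, SampleResult]

    def counts_telescope(self) -> bool:
        """Input reads == tagged reads + read-level rejects, at every stage."""
        n_tagged = sum(s.n_tagged for s in self.samples.values())
        n_rejected = sum(self.reject_reasons.values())
        reach_ok = all(
            s.n_tagged == s.n_reach + s.n_rejected_reach
            for s in self.samples.values()
        )
        return (self.n_input_reads == n_tagged + n_rejected - sum(
            s.n_rejected_reach for s in self.samples.values()
        )) and reach_ok

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_digest": self.config_digest,
            "n_input_reads": self.n_input_reads,
            "reject_reasons": self.reject_reasons,
            "samples": {
                sid: {
                    "n_tagged": s.n_tagged,
                    "n_reach": s.n_reach,
                    "n_groups_eligible": s.n_groups_eligible,
                    "n_groups_undersized": s.n_groups_undersized,
                    "qc_pass": s.qc_pass,
                    "qc_reason": s.qc_reason,
                    "n_somatic": s.burden.n_somatic if s.burden else None,
                    "freq_per_10kb": s.burden.freq_per_10kb if s.burden else None,
                    "heteroplasmy_present": (
                        s.burden.heteroplasmy_present if s.burden else None
                    ),
                }
                for sid, s in self.samples.items()
            },
        }


def run_pipeline(config: dict) -> RunReport:
    """File-level pipeline: reads FASTA + reference + MID table -> outputs.

    Required config keys: ``reads``, ``reference``, ``mids``, ``out``.
    Writes rejects.tsv, groups.tsv, variants.tsv, burden.tsv, consensus.fasta,
    report.json, and the normalized config, under ``out``.
    """
    normalized = validate_config(config)
    for key in ("reads", "reference", "mids", "out"):
        if key not in normalized:
            raise ConfigError([f"missing required config key {key!r}"])
    out = Path(normalized["out"])
    out.mkdir(parents=True, exist_ok=True)

    genome = CircularGenome.from_fasta(normalized["reference"])
    if genome.length != normalized["genome.length"]:
        raise ConfigError(
            [
                f"reference length {genome.length} != genome.length "
                f"{normalized['genome.length']}"
            ]
        )
    mid_table = MidTable.from_tsv(normalized["mids"])
    reads = read_fasta(normalized["reads"])
    if not reads:
        raise PipelineError("demux", "-", f"no reads in {normalized['reads']}")

    results, rejects, normalized = run_reads(reads, genome, mid_table, normalized)

    # persist stage outputs as plain TSV/FASTA so every stage is auditable
    with open(out / "rejects.tsv", "w") as fh:
        fh.write("read_id\treason\n")
        for r in rejects:
            fh.write(f"{r.read_id}\t{r.reason}\n")
    with open(out / "groups.tsv", "w") as fh:
        fh.write("sample\tn_groups_eligible\tn_groups_undersized\n")
        for sid, s in sorted(results.items()):
            fh.write(f"{sid}\t{s.n_groups_eligible}\t{s.n_groups_undersized}\n")
    rows = []
    for sid, s in sorted(results.items()):
        if s.burden:
            for v in s.burden.variants:
                rows.append(
                    {
                        "sample": sid,
                        "position": v.position,
                        "participant_base": v.participant_base,
                        "alt": v.alt_base,
                        "n_support_groups": v.n_support_groups,
                        "fraction": v.fraction_of_groups,
                        "class": v.var_class,
                        "ti_tv": v.subst_class,
                    }
                )
    pd.DataFrame(
        rows,
        columns=[
            "sample", "position", "participant_base", "alt",
            "n_support_groups", "fraction", "class", "ti_tv",
        ],
    ).to_csv(out / "variants.tsv", sep="\t", index=False)
    burden_rows = []
    for sid, s in sorted(results.items()):
        if s.burden:
            b = s.burden
            burden_rows.append(
                {
                    "sample": sid,
                    "n_somatic": b.n_somatic,
                    "n_groups": b.n_groups,
                    "region_len": b.region_len,
                    "freq_per_10kb": b.freq_per_10kb,
                    "freq_transformed": b.freq_transformed,
                    "per_genome": b.per_genome,
                    "ti_count": b.ti_count,
                    "tv_count": b.tv_count,
                    "heteroplasmy_present": b.heteroplasmy_present,
                }
            )
    pd.DataFrame(burden_rows).to_csv(out / "burden.tsv", sep="\t", index=False)
    with open(out / "consensus.fasta", "w") as fh:
        for sid, s in sorted(results.items()):
            if s.participant_bases is not None:
                fh.write(f">{sid} participant_consensus 1-based region\n")
                fh.write(decode_bases(s.participant_bases) + "\n")

    report = RunReport(
        version=__version__,
        config=normalized,
        config_digest=config_hash(normalized),
        n_input_reads=len(reads),
        reject_reasons=reject_counts(rejects),
        samples=results,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    with open(out / "config.json", "w") as fh:
        json.dump({k: v for k, v in sorted(normalized.items())}, fh, indent=2, default=str)
    return report
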