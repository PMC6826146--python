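"""Synthetic templates, PID-tagged reads, plasmid controls, and cohorts.

The generator emulates the assay's data-generating process: a bottleneck of
~2,000 original template molecules per sample, each labelled with a random
19-base PID during a single primer-extension cycle; planted heteroplasmic
variants carried by a fraction f of templates; Poisson-distributed somatic
substitutions per template; a reads-per-template distribution (default
Poisson, mean 6); and independent per-read-base scattered substitution
errors standing in for post-extension PCR and sequencing errors.  Every draw
is recorded in a truth object so pipeline output can be checked exactly.

The bundled reference genome is synthetic (random sequence of rCRS length):
the pipeline's region logic depends only on coordinates, not on the actual
rCRS bases, and no download is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from mitopid.reference import (
    RCRS_LENGTH,
    CircularGenome,
    RegionSpec,
    decode_bases,
    region_positions,
    region_sequence,
    encode_bases,
)

log = logging.getLogger(__name__)

# 12 synthetic sample barcodes, length 10, pairwise Hamming distance >= 5
DEFAULT_MIDS: dict[str, str] = {
    "MID01": "AAGCCCAATA",
    "MID02": "AACCACTCTG",
    "MID03": "ACTGGCCGAA",
    "MID04": "TAGGGATATA",
    "MID05": "GGCAACGACA",
    "MID06": "TGTGCGGCGA",
    "MID07": "CCCTTGCGAC",
    "MID08": "AGTGACGCTT",
    "MID09": "TCGCCGTTGC",
    "MID10": "CTAAACCTAT",
    "MID11": "TTGAAGGAGT",
    "MID12": "CTAGCAGCCG",
}

_TI_ALT = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T
_TV_ALTS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)

_BASES = "ACGT"


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    ``somatic_rate`` is the expected number of planted substitutions per
    template over the whole region (Poisson); ``heteroplasmies`` is a list of
    ``(position, alt_base, template_fraction)``; ``ti_weight`` is the
    probability that a planted or error substitution is a transition;
    ``reads_per_template`` is ``("poisson", mean)`` or ``("fixed", k)``;
    ``error_rate`` is the per-read-base scattered substitution probability.
    """

    seed: int = 0
    n_templates: int = 2000
    somatic_rate: float = 0.015
    heteroplasmies: tuple[tuple[int, str, float], ...] = ()
    ti_weight: float = 0.8
    reads_per_template: tuple[str, float] = ("poisson", 6.0)
    error_rate: float = 0.003
    mid_id: str = "MID01"
    pid_length: int = 19
    het_planting: str = "bernoulli"  # or "exact": round(f * n_templates) carriers

    def __post_init__(self):
        if self.somatic_rate < 0:
            raise SimConfigError("somatic_rate must be >= 0")
        if not 0 <= self.error_rate <= 0.25:
            raise SimConfigError("error_rate must be in [0, 0.25]")
        for pos, alt, f in self.heteroplasmies:
            if not 0 <= f <= 1:
                raise SimConfigError(f"heteroplasmy fraction {f} outside [0, 1]")
            if alt not in _BASES:
                raise SimConfigError(f"heteroplasmy alt {alt!r} not a base")
        if self.reads_per_template[0] not in ("poisson", "fixed"):
            raise SimConfigError("reads_per_template must be ('poisson', m) or ('fixed', k)")
        if self.het_planting not in ("bernoulli", "exact"):
            raise SimConfigError("het_planting must be 'bernoulli' or 'exact'")


@dataclass
class SimTruth:
    """Exhaustive record of every planted variant and error draw."""

    planted_somatic: list[tuple[int, int, str]] = field(default_factory=list)
    # (template_id, rCRS position, alt base)
    het_carriers: dict[tuple[int, str], list[int]] = field(default_factory=dict)
    pids: list[str] = field(default_factory=list)
    reads_per_template: np.ndarray | None = None
    n_error_bases: int = 0

    def expected_somatic_events(self, min_reads: int = 5) -> int:
        """Planted somatic events on templates that received >= min_reads reads."""
        assert self.reads_per_template is not None
        ok = {
            tid
            for tid in range(len(self.pids))
            if self.reads_per_template[tid] >= min_reads
        }
        return sum(1 for tid, _, _ in self.planted_somatic if tid in ok)

    def n_eligible_templates(self, min_reads: int = 5) -> int:
        assert self.reads_per_template is not None
        return int(np.sum(self.reads_per_template >= min_reads))


def synthetic_reference(
    length: int = RCRS_LENGTH, seed: int = 16569, name: str = "synthetic_rCRS_frame"
) -> CircularGenome:
    """A synthetic circular genome of rCRS length (stand-in for rCRS).

    The sequence is random (seeded, reproducible); only its length and the
    coordinate frame matter to the pipeline.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    return CircularGenome(name=name, sequence=seq)


def _draw_alt(ref_code: int, rng: np.random.Generator, ti_weight: float) -> int:
    if rng.random() < ti_weight:
        return int(_TI_ALT[ref_code])
    return int(_TV_ALTS[ref_code][rng.integers(0, 2)])


def simulate_templates(
    genome: CircularGenome,
    region: RegionSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SimTruth]:
    """Generate template molecules (codes, one row per template) plus truth.

    Each template starts as a copy of the reference region; heteroplasmic
    variants are applied to a Bernoulli(f) (or exact round(f*n)) subset of
    templates, then Poisson(somatic_rate) substitutions are planted per
    template at uniform positions.  Each template receives a PID drawn
    uniformly from the 4^19 space; collisions are logged.
    """
    positions = region_positions(region, genome.length)
    pos_index = {p: i for i, p in enumerate(positions)}
    ref_codes = encode_bases(region_sequence(genome, region))
    n, R = config.n_templates, len(ref_codes)
    templates = np.tile(ref_codes, (n, 1))
    truth = SimTruth()

    for pos, alt, f in config.heteroplasmies:
        if pos not in pos_index:
            raise SimConfigError(f"heteroplasmy position {pos} outside the region")
        if config.het_planting == "exact":
            k = int(round(f * n))
            carriers = rng.choice(n, size=k, replace=False)
        else:
            carriers = np.flatnonzero(rng.random(n) < f)
        templates[carriers, pos_index[pos]] = _BASES.index(alt)
        truth.het_carriers[(pos, alt)] = sorted(int(c) for c in carriers)

    n_subs = rng.poisson(config.somatic_rate, size=n)
    for tid in np.flatnonzero(n_subs):
        # distinct positions within a template so every planted event is
        # recoverable by diffing the template against the reference
        idxs = rng.choice(R, size=min(int(n_subs[tid]), R), replace=False)
        for idx in idxs:
            ref_code = int(templates[tid, idx])
            alt_code = _draw_alt(ref_code, rng, config.ti_weight)
            templates[tid, idx] = alt_code
            truth.planted_somatic.append((int(tid), positions[idx], _BASES[alt_code]))

    pid_codes = rng.integers(0, 4, size=(n, config.pid_length))
    truth.pids = ["".join(_BASES[c] for c in row) for row in pid_codes]
    n_collisions = n - len(set(truth.pids))
    if n_collisions:
        log.warning("PID collision: %d templates share a PID", n_collisions)
    return templates, truth


def simulate_reads(
    templates: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    mid_table: dict[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Emit shuffled (read_id, sequence) pairs: MID + PID + payload.

    Per template the read count follows ``reads_per_template``; each read is
    the template sequence with i.i.d. per-base substitution errors at
    ``error_rate`` (alt drawn by ``ti_weight``).  Read counts and the total
    number of error bases are recorded in the truth object.
    """
    mid_seq = (mid_table or DEFAULT_MIDS)[config.mid_id]
    n, R = templates.shape
    kind, param = config.reads_per_template
    if kind == "poisson":
        counts = rng.poisson(param, size=n)
    else:
        counts = np.full(n, int(param))
    truth.reads_per_template = counts
    reads: list[tuple[str, str]] = []
    serial = 0
    for tid in range(n):
        k = int(counts[tid])
        if k == 0:
            continue
        payloads = np.tile(templates[tid], (k, 1))
        if config.error_rate > 0:
            err_mask = rng.random((k, R)) < config.error_rate
            for r, c in zip(*np.nonzero(err_mask)):
                payloads[r, c] = _draw_alt(int(payloads[r, c]), rng, config.ti_weight)
            truth.n_error_bases += int(err_mask.sum())
        pid = truth.pids[tid]
        for r in range(k):
            reads.append(
                (f"read{serial:07d}", mid_seq + pid + decode_bases(payloads[r]))
            )
            serial += 1
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_sample(
    genome: CircularGenome,
    region: RegionSpec,
    config: SimConfig,
    mid_table: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Convenience wrapper: templates + reads from one seeded RNG."""
    rng = np.random.default_rng(config.seed)
    templates, truth = simulate_templates(genome, region, config, rng)
    reads = simulate_reads(templates, truth, config, rng, mid_table)
    return reads, truth


def simulate_control_run(
    genome: CircularGenome,
    region: RegionSpec,
    config: SimConfig,
    mid_table: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """A clonal plasmid control: zero planted variation, only scattered errors."""
    clean = replace(config, somatic_rate=0.0, heteroplasmies=())
    return simulate_sample(genome, region, clean, mid_table)


def write_fasta(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortEffects:
    """Generative coefficients for the synthetic cohort.

    Burden is linear on the ln(x+1) scale with Gaussian noise; heteroplasmy
    is logistic with an age x smoking interaction.  Defaults emulate the
    study population: ages spanning 2-72 years, 35% current smokers, 56%
    HIV-positive (43% of whom with peak pVL >= 100,000 copies/ml), a
    transformed burden around 0.4 at mid-life, and heteroplasmy rising with
    age among never smokers but falling with age among smokers.
    """

    burden_intercept: float = 0.2
    beta_age: float = 0.006
    beta_smoking: float = 0.0
    beta_hiv_low: float = 0.0
    beta_hiv_high: float = 0.0
    noise_sd: float = 0.25
    het_intercept: float = -3.0
    het_beta_age: float = 0.05
    het_beta_smoking: float = 2.0
    het_beta_interaction: float = -0.08
    age_range: tuple[float, float] = (2.0, 72.0)
    p_smoker: float = 0.35
    p_hiv: float = 0.56
    p_high_peak_given_hiv: float = 0.43


def simulate_cohort(
    n: int = 164,
    effects: CohortEffects = CohortEffects(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic cohort table plus the generative truth.

    Returns a DataFrame with columns id, age, smoking, hiv3, freq_per_10kb,
    burden_t, heteroplasmy, and a truth dict of every coefficient used.
    """
    for p in (effects.p_smoker, effects.p_hiv, effects.p_high_peak_given_hiv):
        if not 0 <= p <= 1:
            raise SimConfigError(f"probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    age = rng.uniform(*effects.age_range, size=n)
    smoker = (rng.random(n) < effects.p_smoker).astype(int)
    hiv_pos = rng.random(n) < effects.p_hiv
    high_peak = hiv_pos & (rng.random(n) < effects.p_high_peak_given_hiv)
    hiv3 = np.where(
        ~hiv_pos, "negative", np.where(high_peak, "positive_high_peak", "positive_low_peak")
    )
    burden_t = (
        effects.burden_intercept
        + effects.beta_age * age
        + effects.beta_smoking * smoker
        + effects.beta_hiv_low * (hiv3 == "positive_low_peak")
        + effects.beta_hiv_high * (hiv3 == "positive_high_peak")
        + rng.normal(0, effects.noise_sd, size=n)
    )
    # burden_t is Gaussian by construction (the regression layer's generative
    # model); the implied raw frequency can dip slightly below zero at young
    # ages, an accepted artifact of emulating only the transformed scale
    logit = (
        effects.het_intercept
        + effects.het_beta_age * age
        + effects.het_beta_smoking * smoker
        + effects.het_beta_interaction * age * smoker
    )
    p_het = 1 / (1 + np.exp(-logit))
    hetero = (rng.random(n) < p_het).astype(int)
    df = pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "smoking": np.where(smoker == 1, "current", "never"),
            "smoker": smoker,
            "hiv3": hiv3,
            "burden_t": burden_t,
            "freq_per_10kb": np.expm1(burden_t),
            "heteroplasmy": hetero,
        }
    )
    truth = {
        "n": n,
        "seed": seed,
        **{k: getattr(effects, k) for k in CohortEffects.__dataclass_fields__},
    }
    return df, truth
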