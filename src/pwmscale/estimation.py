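"""Estimate the energy-scaling parameter lambda from a PWM and landscape.

The mismatch energy of a site is the score drop from the consensus,
scaled: E_mismatch = (S_max - S) / lambda. Anchoring the top-0.1% score
of the background landscape to the maximum tolerable mismatch energy
gives

    lambda = (S_max - S_top0.1%) / E_maxMismatch,

with E_maxMismatch assumed proportional to motif information content:
E_maxMismatch = <E> * If / <If>. The calibration constants default to
<E> = 6 bits (microfluidic binding-energy measurements: binding decays by
~2-3 mismatches at ~2 bits each) and <If> = 13.2 bits (the mean
information content those measurements correspond to). Both are
configurable: a different top-score threshold requires a matching change
of the average mismatch energy.

Lambda values compared across motifs of different lengths are z-scored
within motif-length groups (7-8, 9-10, 11-12, 13-15, >=16 bp) to control
for the length dependence of information content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateMotifError,
    ParameterError,
    ShortMotifError,
    UndefinedZScoreError,
)
from .landscape import ScoreDistribution, top_quantile_score, _record_window_scores
from .motif import PWM, encode_sequence
from .landscape import iter_fasta

__all__ = [
    "EstimationConfig",
    "LambdaEstimate",
    "SiteRecord",
    "max_mismatch_energy",
    "estimate_lambda",
    "mismatch_energy",
    "binding_strength_track",
    "zscore_normalize",
    "LENGTH_GROUPS",
    "write_lambda_table",
    "write_bed",
    "write_bedgraph",
]


@dataclass(frozen=True)
class EstimationConfig:
    """Calibration constants for the lambda equation."""

    top_quantile: float = 0.001
    avg_mismatch_bits: float = 6.0
    avg_information: float = 13.2
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.top_quantile < 1:
            raise ParameterError("top_quantile must lie in (0, 1)")
        if self.avg_mismatch_bits <= 0:
            raise ParameterError("avg_mismatch_bits must be > 0")
        if self.avg_information <= 0:
            raise ParameterError("avg_information must be > 0")
        if self.pseudocount <= 0:
            raise ParameterError("pseudocount must be > 0")


@dataclass
class LambdaEstimate:
    """A lambda value with the quantities it was assembled from."""

    lam: float
    s_max: float
    s_top: float
    e_max_mismatch: float
    information_content: float
    config: EstimationConfig
    motif_id: str = ""


def max_mismatch_energy(
    information_content: float, config: EstimationConfig = EstimationConfig()
) -> float:
    """Maximum tolerable mismatch energy, linear in information content.

    E = <E_maxMismatch> * (If / <If>); at If = <If> this is exactly the
    configured average (6 bits by default).
    """
    if information_content <= 0:
        raise DegenerateMotifError(
            "zero information content: mismatch energy (and lambda) undefined"
        )
    return config.avg_mismatch_bits * (
        information_content / config.avg_information
    )


def estimate_lambda(
    pwm: PWM,
    dist: ScoreDistribution,
    config: EstimationConfig = EstimationConfig(),
) -> LambdaEstimate:
    """Estimate lambda for ``pwm`` from its background score landscape."""
    s_max = pwm.s_max
    s_top = top_quantile_score(dist, config.top_quantile)
    if s_top >= s_max - 1e-12:
        raise ShortMotifError(
            f"top-{config.top_quantile:g} score equals the consensus score "
            f"({s_max:.4f} bits): score range collapsed; the motif is too "
            "short (or the landscape too small) for this threshold"
        )
    e_max = max_mismatch_energy(pwm.information_content, config)
    return LambdaEstimate(
        lam=(s_max - s_top) / e_max,
        s_max=s_max,
        s_top=s_top,
        e_max_mismatch=e_max,
        information_content=pwm.information_content,
        config=config,
        motif_id=pwm.source_pfm_id,
    )


def mismatch_energy(estimate: LambdaEstimate, score: float) -> float:
    """Scaled energetic penalty of a site vs the consensus: (S_max - S)/lambda.

    Zero at the consensus; exactly ``e_max_mismatch`` at the top-quantile
    boundary score.
    """
    if score > estimate.s_max + 1e-9:
        raise ParameterError("site score exceeds the consensus score")
    return (estimate.s_max - score) / estimate.lam


@dataclass
class SiteRecord:
    """One above-threshold site on a scanned sequence.

    ``strength = e_max_mismatch - mismatch_energy`` is non-negative for all
    emitted sites and comparable across TFs after lambda scaling (a site at
    the consensus scores the motif's full mismatch-energy budget).
    Intervals are 0-based half-open on the forward strand.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    motif_id: str
    score: float
    mismatch_energy: float
    strength: float


def binding_strength_track(
    estimate: LambdaEstimate,
    pwm: PWM,
    sequences,
    dist: ScoreDistribution | None = None,
    strand_mode: str = "both",
) -> list[SiteRecord]:
    """Annotate every window scoring at or above the top-quantile boundary.

    Emits one record per qualifying window and strand with the raw score,
    its lambda-scaled mismatch energy and the binding strength.
    """
    threshold = estimate.s_top
    records: list[SiteRecord] = []
    L = pwm.length
    for seq_id, seq in iter_fasta(sequences):
        per = _record_window_scores(pwm, encode_sequence(seq), strand_mode)
        strands = ["+"] + (["-"] if strand_mode == "both" else [])
        for strand in strands:
            scores = per[strand]
            keep = scores >= threshold - 1e-12
            for off, s in zip(per["offsets"][keep], scores[keep]):
                e = mismatch_energy(estimate, float(s))
                records.append(
                    SiteRecord(
                        sequence_id=seq_id,
                        start=int(off),
                        end=int(off) + L,
                        strand=strand,
                        motif_id=estimate.motif_id or pwm.source_pfm_id,
                        score=float(s),
                        mismatch_energy=e,
                        strength=max(estimate.e_max_mismatch - e, 0.0),
                    )
                )
    return records


#: motif-length groups for z-normalization; length-6 motifs pass the
#: length filter but fall below the first stated group and are assigned
#: to the 7-8 bp group.
LENGTH_GROUPS = (
    (0, 8, "7-8"),
    (9, 10, "9-10"),
    (11, 12, "11-12"),
    (13, 15, "13-15"),
    (16, 10**9, ">=16"),
)


def length_group(length: int) -> str:
    for lo, hi, label in LENGTH_GROUPS:
        if lo <= length <= hi:
            return label
    raise ParameterError(f"no length group for motif length {length}")


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score lambda within motif-length groups.

    ``table`` needs columns ``length`` and ``lam``; returns a copy with
    ``length_group`` and ``z_score`` columns added. The population
    (n-denominator) standard deviation is used, so a two-member group maps
    to exactly {-1, +1}. Groups with a single member or zero spread have
    no defined z-score and raise.
    """
    out = table.copy()
    out["length_group"] = [length_group(int(x)) for x in out["length"]]
    z = pd.Series(np.nan, index=out.index, dtype=float)
    for label, sub in out.groupby("length_group"):
        lams = sub["lam"].to_numpy(dtype=float)
        if lams.size < 2:
            raise UndefinedZScoreError(
                f"length group '{label}' has a single member; z undefined"
            )
        sd = lams.std(ddof=0)
        if sd == 0:
            raise UndefinedZScoreError(
                f"length group '{label}' has zero lambda spread; z undefined"
            )
        z.loc[sub.index] = (lams - lams.mean()) / sd
    out["z_score"] = z
    return out


# ---------------------------------------------------------------------------
# serialization


def write_lambda_table(table: pd.DataFrame, handle, header_meta: dict | None = None):
    """Write a lambda table as TSV with ``#`` metadata header lines."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}\t{val}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    finally:
        if own:
            fh.close()


def _scaled_bed_score(strength: float, e_max: float) -> int:
    return int(round(1000 * min(max(strength / e_max, 0.0), 1.0)))


def write_bed(records, handle, e_max_by_motif: dict[str, float]):
    """BED6+3: name=motif id, score=strength scaled 0-1000, then raw
    score, mismatch energy and strength columns."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write(
            "# BED6+3: chrom start end name score(strength scaled 0-1000) "
            "strand raw_score_bits mismatch_energy_bits strength_bits\n"
        )
        for r in records:
            scaled = _scaled_bed_score(r.strength, e_max_by_motif[r.motif_id])
            fh.write(
                f"{r.sequence_id}\t{r.start}\t{r.end}\t{r.motif_id}\t"
                f"{scaled}\t{r.strand}\t{r.score:.4f}\t"
                f"{r.mismatch_energy:.4f}\t{r.strength:.4f}\n"
            )
    finally:
        if own:
            fh.close()


def write_bedgraph(records, handle):
    """bedGraph of binding strength (bits); overlapping sites emitted as-is."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write("# bedGraph of lambda-scaled binding strength (bits)\n")
        for r in records:
            fh.write(f"{r.sequence_id}\t{r.start}\t{r.end}\t{r.strength:.4f}\n")
    finally:
        if own:
            fh.close()
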