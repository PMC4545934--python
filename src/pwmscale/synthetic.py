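"""Synthetic backgrounds and motifs with controlled statistical structure.

Random i.i.d. sequence of matched GC content is a validated surrogate for
genomic background when estimating score-landscape quantiles: at genome
scale, local sequence patterns have little influence on the overall
distribution of binding-site strengths. This module generates such
sequences, random count PFMs of tunable sharpness, and perturbed PWM
pairs that emulate two motif-database versions of the same TF.

All randomness flows from the single integer seed in :class:`FixtureSpec`;
independent substreams are derived per generator, so fixtures are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .motif import (
    BASES,
    PFM,
    PWM,
    BackgroundModel,
    BACKGROUND_PRESETS,
    build_pwm,
)

__all__ = [
    "FixtureSpec",
    "random_sequence",
    "random_pfm",
    "perturbed_pwm_pair",
    "write_fasta",
    "write_jaspar",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic generators.

    concentration is the Dirichlet parameter of the per-column nucleotide
    distribution behind :func:`random_pfm`: small values give sharp,
    information-rich columns; large values approach uniform columns with
    information content near zero.
    """

    seed: int = 0
    sequence_length: int = 100_000
    gc_content: float = 0.5
    motif_length: int = 10
    n_sequences: int = 50
    concentration: float = 0.5
    noise: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ParameterError("gc_content must lie in (0, 1)")
        if min(self.sequence_length, self.motif_length, self.n_sequences) < 1:
            raise ParameterError("lengths and depths must be positive")
        if self.concentration <= 0:
            raise ParameterError("concentration must be > 0")
        if not 0 <= self.noise <= 1:
            raise ParameterError("noise must lie in [0, 1]")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent, reproducible substream per generator kind
    return np.random.default_rng([spec.seed, stream])


def random_sequence(spec: FixtureSpec, name: str = "random") -> tuple[str, str]:
    """An i.i.d. DNA sequence with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2.

    Returns an (id, sequence) FASTA-style record.
    """
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    rng = _rng(spec, 1)
    codes = rng.choice(4, size=spec.sequence_length, p=probs)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    return (f"{name}_gc{gc:g}_seed{spec.seed}", seq)


def random_pfm(spec: FixtureSpec, motif_id: str = "") -> PFM:
    """A random count PFM: per column, a Dirichlet(concentration) draw of
    nucleotide propensities, then ``n_sequences`` multinomial counts."""
    rng = _rng(spec, 2)
    alpha = np.full(4, spec.concentration)
    counts = np.empty((4, spec.motif_length))
    for k in range(spec.motif_length):
        p = rng.dirichlet(alpha)
        counts[:, k] = rng.multinomial(spec.n_sequences, p)
    return PFM(
        counts=counts,
        n_sequences=spec.n_sequences,
        motif_id=motif_id or f"synth_seed{spec.seed}",
        tf_name="synthetic",
    )


def perturbed_pwm_pair(
    spec: FixtureSpec,
    background: BackgroundModel = BACKGROUND_PRESETS["uniform"],
    pseudocount: float = 1.0,
) -> tuple[PWM, PWM]:
    """Two PWMs of the "same TF": the second rebuilt after blending the
    first PFM's columns with random Dirichlet noise.

    counts2 = (1-noise)*counts + noise*n_sequences*Dirichlet(1,1,1,1) per
    column, so noise=0 returns an identical pair and noise=1 an unrelated
    motif of the same length.
    """
    pfm1 = random_pfm(spec)
    rng = _rng(spec, 3)
    pert = rng.dirichlet(np.ones(4), size=spec.motif_length).T
    counts2 = (1 - spec.noise) * pfm1.counts + (
        spec.noise * spec.n_sequences * pert
    )
    pfm2 = PFM(
        counts=counts2,
        n_sequences=pfm1.n_sequences,
        motif_id=pfm1.motif_id + "_alt",
        tf_name=pfm1.tf_name,
    )
    return (
        build_pwm(pfm1, background, pseudocount),
        build_pwm(pfm2, background, pseudocount),
    )


def write_fasta(records, handle) -> None:
    """Write (id, sequence) records as FASTA, 70 columns."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    finally:
        if own:
            fh.close()


def write_jaspar(pfms, handle) -> None:
    """Write PFMs in the bracketed JASPAR plain-text dialect."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for pfm in pfms:
            fh.write(
                f">{pfm.motif_id} {pfm.tf_name} ; "
                f"n_sequences={pfm.n_sequences}\n"
            )
            for i, base in enumerate(BASES):
                row = " ".join(f"{c:g}" for c in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")
    finally:
        if own:
            fh.close()
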