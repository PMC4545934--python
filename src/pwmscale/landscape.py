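"""Score landscapes: the distribution of PWM scores over a background.

Two kinds are supported. An *empirical* landscape holds the multiset of
window scores from scanning actual sequence (one observation per scorable
window and strand). An *exact* landscape is the distribution of the score
of an i.i.d. background k-mer, computed by column-wise convolution on a
score grid of width ``epsilon`` bits; each grid bin carries the
probability-weighted mean of the true (unrounded) scores that fell into
it, so the support values are exact whenever a bin holds a single
distinct score.

The top-q score S_top(q) and the -log10 tail quantile of a score are the
quantities downstream lambda estimation needs: the standard threshold is
the top 0.1% of scanned positions, i.e. a -log10 cumulative of 3.0.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import (
    EmptyLandscapeError,
    InsufficientSampleError,
    ParameterError,
)
from .motif import PWM, BackgroundModel, encode_sequence, reverse_complement

__all__ = [
    "ScoreDistribution",
    "scan_scores",
    "exact_distribution",
    "top_quantile_score",
    "log_quantile",
    "iter_fasta",
    "write_histogram_tsv",
]


@dataclass
class ScoreDistribution:
    """A landscape of PWM scores supporting tail-quantile queries.

    For ``kind='empirical'``, ``scores`` is the sorted (ascending) multiset
    of window scores and ``probs`` is None; ``n_positions`` counts the
    observations. For ``kind='exact'``, ``scores`` is the ascending support
    and ``probs`` the matching probabilities (summing to 1); the landscape
    represents all 4^L k-mers, weighted by the background.
    """

    kind: str
    scores: np.ndarray
    probs: np.ndarray | None = None
    n_positions: int = 0
    strand_mode: str = "forward"
    source_label: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.kind not in ("empirical", "exact"):
            raise ParameterError(f"unknown landscape kind {self.kind!r}")
        if self.scores.size == 0:
            raise EmptyLandscapeError("score landscape is empty")
        if self.kind == "exact":
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != self.scores.shape:
                raise ParameterError("support and probabilities differ in shape")
            if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
                raise ParameterError("exact probabilities must be >=0, sum 1")
            self.n_positions = self.n_positions or 1
        else:
            self.n_positions = int(self.scores.size)

    # -- tail machinery -------------------------------------------------

    def tail_probability(self, score: float) -> float:
        """P(score' >= score) under the landscape."""
        idx = np.searchsorted(self.scores, score, side="left")
        if self.kind == "empirical":
            return float(self.scores.size - idx) / self.scores.size
        return float(self.probs[idx:].sum())

    @property
    def min_score(self) -> float:
        return float(self.scores[0])

    @property
    def max_score(self) -> float:
        return float(self.scores[-1])


def _record_window_scores(
    pwm: PWM, codes: np.ndarray, strand_mode: str
) -> dict[str, np.ndarray]:
    """Window scores per strand for one encoded sequence.

    Windows overlapping any non-ACGT symbol are dropped (not scored).
    Returns arrays keyed by '+'/'-' with one entry per *valid* offset, and
    '+offsets' giving the surviving forward-strand offsets.
    """
    L = pwm.length
    n = codes.size - L + 1
    if n <= 0:
        return {"+": np.empty(0), "-": np.empty(0), "offsets": np.empty(0, int)}
    bad = np.concatenate(([0], np.cumsum(codes < 0)))
    valid = (bad[L:] - bad[:-L]) == 0
    offsets = np.nonzero(valid)[0]
    safe = np.where(codes < 0, 0, codes)
    fwd = np.zeros(n)
    for k in range(L):
        fwd += pwm.weights[safe[k : k + n], k]
    out = {"+": fwd[offsets], "offsets": offsets}
    if strand_mode == "both":
        rc = reverse_complement(pwm)
        rev = np.zeros(n)
        for k in range(L):
            rev += rc.weights[safe[k : k + n], k]
        out["-"] = rev[offsets]
    return out


def iter_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from flexible sequence input.

    Accepts a FASTA path (optionally .gz), an iterable of Biopython
    SeqRecords, of (id, seq) tuples, or of bare sequence strings.
    """
    import os

    if isinstance(source, (str, os.PathLike)):
        from Bio import SeqIO

        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq)
        return
    for item in source:
        if isinstance(item, str):
            yield "seq", item
        elif isinstance(item, tuple):
            yield item[0], str(item[1])
        else:  # SeqRecord-like
            yield item.id, str(item.seq)


def scan_scores(
    pwm: PWM, sequences, strand_mode: str = "both", source_label: str = ""
) -> ScoreDistribution:
    """Empirical landscape: score every valid window of every sequence.

    With ``strand_mode='both'`` the forward and reverse-complement score at
    each offset are separate observations, so a sequence of length n
    contributes up to 2*(n-L+1) scores.
    """
    if strand_mode not in ("forward", "both"):
        raise ParameterError(f"unknown strand_mode {strand_mode!r}")
    chunks = []
    for _, seq in iter_fasta(sequences):
        per = _record_window_scores(pwm, encode_sequence(seq), strand_mode)
        chunks.append(per["+"])
        if strand_mode == "both":
            chunks.append(per["-"])
    scores = np.concatenate(chunks) if chunks else np.empty(0)
    if scores.size == 0:
        raise EmptyLandscapeError(
            "no scorable window in the supplied sequences"
        )
    scores.sort()
    return ScoreDistribution(
        kind="empirical",
        scores=scores,
        strand_mode=strand_mode,
        source_label=source_label,
    )


def exact_distribution(
    pwm: PWM, background: BackgroundModel | None = None, epsilon: float = 0.001
) -> ScoreDistribution:
    """Exact i.i.d. score distribution by dynamic programming.

    The score of a random k-mer X_1..X_L with X_k ~ background is the sum
    of column weights; its distribution is built by convolving columns on
    a grid of width ``epsilon`` bits. Alongside each bin's probability we
    accumulate the probability-weighted sum of true scores, and report the
    bin's weighted-mean true score as its support value: cumulative
    probabilities are correct to within the binning (<= epsilon*L in score
    placement), and support values are exact when bins do not merge
    distinct scores.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    bg = background if background is not None else pwm.background
    f = bg.freqs
    W = pwm.weights
    offsets = np.rint(W / epsilon).astype(np.int64)
    col_min = offsets.min(axis=0)
    rel = offsets - col_min[None, :]

    prob = np.array([1.0])
    mass = np.array([0.0])  # probability-weighted sum of true scores
    for k in range(W.shape[1]):
        span = int(rel[:, k].max())
        new_prob = np.zeros(prob.size + span)
        new_mass = np.zeros(prob.size + span)
        for i in range(4):
            sh = int(rel[i, k])
            new_prob[sh : sh + prob.size] += prob * f[i]
            new_mass[sh : sh + prob.size] += (mass + prob * W[i, k]) * f[i]
        prob, mass = new_prob, new_mass

    nz = prob > 0
    support = mass[nz] / prob[nz]
    probs = prob[nz]
    order = np.argsort(support, kind="stable")
    return ScoreDistribution(
        kind="exact",
        scores=support[order],
        probs=probs[order] / probs.sum(),
        strand_mode="forward",
        source_label=f"exact:{bg.label}:eps={epsilon:g}",
    )


def top_quantile_score(dist: ScoreDistribution, q: float = 0.001) -> float:
    """Score at the top-q tail boundary, S_top(q).

    Nearest-rank convention: the largest score s in the support with
    P(score >= s) >= q. Empirically that is the rank-ceil(q*n) score from
    the top of the sorted multiset. Monotone: smaller q gives a larger or
    equal score.
    """
    if not 0 < q <= 1:
        raise ParameterError("quantile q must lie in (0, 1]")
    if dist.kind == "empirical":
        n = dist.n_positions
        if q * n < 1:
            raise InsufficientSampleError(
                f"cannot resolve top-{q:g} quantile from {n} observations"
            )
        rank = math.ceil(q * n)
        return float(dist.scores[n - rank])
    tail = np.cumsum(dist.probs[::-1])
    # first index from the top where the tail reaches q (tolerating float
    # dust from the convolution sums)
    idx = int(np.searchsorted(tail, q - 1e-12, side="left"))
    idx = min(idx, dist.scores.size - 1)
    return float(dist.scores[::-1][idx])


def log_quantile(dist: ScoreDistribution, score: float) -> float:
    """-log10 of the upper-tail probability of ``score``.

    3.0 corresponds exactly to the top-0.1% boundary; 0.0 to the support
    minimum; +inf if the score exceeds the maximum support.
    """
    if score > dist.max_score:
        return float("inf")
    tail = dist.tail_probability(score)
    if tail <= 0:
        return float("inf")
    return float(-math.log10(tail))


def write_histogram_tsv(
    dist: ScoreDistribution, handle, bin_width: float | None = None
) -> None:
    """Write the landscape as 2-column TSV (score bin, count|probability)."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write(f"# kind\t{dist.kind}\n")
        fh.write(f"# n_positions\t{dist.n_positions}\n")
        fh.write(f"# strand_mode\t{dist.strand_mode}\n")
        if dist.kind == "exact":
            fh.write("score\tprobability\n")
            for s, p in zip(dist.scores, dist.probs):
                fh.write(f"{s:.6f}\t{p:.10g}\n")
        else:
            width = bin_width or 0.01
            lo = math.floor(dist.min_score / width)
            hi = math.floor(dist.max_score / width)
            edges = np.arange(lo, hi + 2) * width
            counts, _ = np.histogram(dist.scores, bins=edges)
            fh.write("score_bin\tcount\n")
            for e, c in zip(edges[:-1], counts):
                if c:
                    fh.write(f"{e:.6f}\t{c}\n")
    finally:
        if own:
            fh.close()
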