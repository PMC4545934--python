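"""Convert lambda between alternative PWMs of one TF via residence times.

Under the facilitated-diffusion picture a TF's expected residence time at
a site is exponential in its scaled score, tau_j = tau0(lambda) *
exp(S_j / lambda): stronger sites are bound longer. tau0 normalizes the
landscape-average residence time to exactly 1 time unit, so only
relative residence times are meaningful and no external simulator is
needed.

Top-scoring sites (beyond the -log10 cumulative quantile 3.0, i.e. the
top 0.1%) are stratified into log-quantile bins of width 0.1 and the
per-bin average residence time forms a profile. Given a reference PWM
with a known lambda, the candidate PWM's lambda is chosen on a grid
(0.1 to 3.0 by default) to minimize either the mean squared error
between the two bin profiles or the summed absolute difference of their
log residence times. Grid points whose bin averages fall outside the
range spanned by the reference profile are infeasible ("blank regions"),
which typically happens at very small lambda where the top bins explode.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import (
    EmptyProfileError,
    IncomparableProfilesError,
    ParameterError,
)
from .landscape import ScoreDistribution
from .motif import PWM

logger = logging.getLogger(__name__)

__all__ = [
    "ResidenceProfile",
    "ConversionResult",
    "tau0",
    "residence_times",
    "residence_profile",
    "objective_mse",
    "objective_abslog",
    "feasibility",
    "convert_lambda",
    "default_grid",
    "heatmap_matrix",
    "write_heatmap_tsv",
    "write_conversion_json",
]

MIN_LOGQ = 3.0
BIN_WIDTH = 0.1


def _log_mean_exp(dist: ScoreDistribution, lam: float) -> float:
    """log of the landscape average of exp(S/lambda)."""
    if dist.kind == "exact":
        return float(logsumexp(dist.scores / lam, b=dist.probs))
    return float(logsumexp(dist.scores / lam) - math.log(dist.n_positions))


def tau0(dist: ScoreDistribution, lam: float) -> float:
    """Base residence time normalizing the landscape mean to 1 time unit.

    tau0(lambda) = 1 / mean_j exp(S_j / lambda), evaluated in log space.
    """
    if lam <= 0:
        raise ParameterError("lambda must be > 0")
    return float(np.exp(-_log_mean_exp(dist, lam)))


def residence_times(dist: ScoreDistribution, lam: float) -> np.ndarray:
    """Residence time tau_j = tau0 * exp(S_j/lambda) per landscape entry.

    Strictly increasing in the score; the landscape (probability-weighted,
    for exact distributions) mean is 1 by construction.
    """
    if lam <= 0:
        raise ParameterError("lambda must be > 0")
    log_tau0 = -_log_mean_exp(dist, lam)
    return np.exp(dist.scores / lam + log_tau0)


@dataclass
class ResidenceProfile:
    """Bin-averaged residence times of top sites, by strength log-quantile.

    ``bin_edges`` start at the -log10 quantile 3.0 with width 0.1 and run
    to just past the best site; bin i covers [edges[i], edges[i+1]).
    Bins with no site hold NaN in ``bin_mean_tau`` and 0 weight in
    ``bin_counts`` (empirical: site counts; exact: probability mass).
    """

    lam: float
    tau0: float
    bin_edges: np.ndarray
    bin_mean_tau: np.ndarray
    bin_counts: np.ndarray
    pwm_id: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean_tau)

    @property
    def occupied(self) -> np.ndarray:
        return self.bin_counts > 0


class _ProfileEngine:
    """Precomputes bin membership of one landscape's top sites so that
    residence profiles at many lambda values are cheap: bins depend only
    on score ranks, never on lambda."""

    def __init__(
        self,
        dist: ScoreDistribution,
        min_logq: float = MIN_LOGQ,
        bin_width: float = BIN_WIDTH,
    ):
        self.dist = dist
        self.min_logq = min_logq
        self.bin_width = bin_width
        if dist.kind == "empirical":
            values, counts = np.unique(dist.scores, return_counts=True)
            weights = counts.astype(float)
            total = float(dist.n_positions)
        else:
            values, weights = dist.scores, dist.probs
            total = 1.0
        # upper-tail mass of each unique score (P(score' >= v))
        tail = np.cumsum(weights[::-1])[::-1] / total
        with np.errstate(divide="ignore"):
            logq = -np.log10(tail)
        keep = logq >= min_logq
        if not np.any(keep):
            raise EmptyProfileError(
                f"no site beyond the -log10 quantile {min_logq:g} boundary"
            )
        self.values = values[keep]
        self.weights = weights[keep]
        bins = np.floor((logq[keep] - min_logq) / bin_width).astype(int)
        self.bins = bins
        self.n_bins = int(bins.max()) + 1
        self.bin_edges = min_logq + bin_width * np.arange(self.n_bins + 1)
        self.bin_weight = np.bincount(
            bins, weights=self.weights, minlength=self.n_bins
        )

    def profile(self, lam: float, pwm_id: str = "") -> ResidenceProfile:
        if lam <= 0:
            raise ParameterError("lambda must be > 0")
        log_tau0 = -_log_mean_exp(self.dist, lam)
        # max-shifted linear accumulation: normalized residence times are
        # bounded by the landscape size, so exp(shift + log_tau0) is safe
        x = self.values / lam
        shift = float(x.max())
        ex = self.weights * np.exp(x - shift)
        sums = np.bincount(self.bins, weights=ex, minlength=self.n_bins)
        occupied = self.bin_weight > 0
        mean_tau = np.full(self.n_bins, np.nan)
        mean_tau[occupied] = (
            sums[occupied] / self.bin_weight[occupied]
        ) * math.exp(shift + log_tau0)
        return ResidenceProfile(
            lam=lam,
            tau0=math.exp(log_tau0),
            bin_edges=self.bin_edges,
            bin_mean_tau=mean_tau,
            bin_counts=self.bin_weight.copy(),
            pwm_id=pwm_id,
        )


def residence_profile(
    pwm_id: str,
    dist: ScoreDistribution,
    lam: float,
    min_logq: float = MIN_LOGQ,
    bin_width: float = BIN_WIDTH,
) -> ResidenceProfile:
    """Average residence time of top sites per 0.1-wide log-quantile bin.

    Sites with -log10 tail quantile >= ``min_logq`` are binned by
    [3.0, 3.1), [3.1, 3.2), ... up to the best site; each bin reports the
    arithmetic mean residence time of its members.
    """
    return _ProfileEngine(dist, min_logq, bin_width).profile(lam, pwm_id)


def _common_occupied(ref: ResidenceProfile, cand: ResidenceProfile) -> np.ndarray:
    n = min(ref.n_bins, cand.n_bins)
    return np.nonzero(ref.occupied[:n] & cand.occupied[:n])[0]


def _require_comparable(ref, cand):
    common = _common_occupied(ref, cand)
    if common.size < 2:
        raise IncomparableProfilesError(
            f"only {common.size} log-quantile bin(s) occupied in both "
            "profiles; need at least 2"
        )
    return common


def objective_mse(ref: ResidenceProfile, cand: ResidenceProfile) -> float:
    """Mean squared difference of bin-average residence times over the
    bins occupied in both profiles; zero iff the bin means coincide."""
    common = _require_comparable(ref, cand)
    d = cand.bin_mean_tau[common] - ref.bin_mean_tau[common]
    with np.errstate(over="ignore"):
        return float(np.mean(np.square(d)))


def objective_abslog(ref: ResidenceProfile, cand: ResidenceProfile) -> float:
    """Sum over shared bins of |ln tau_cand - ln tau_ref| (outlier-robust
    alternative to the MSE)."""
    common = _require_comparable(ref, cand)
    return float(
        np.abs(
            np.log(cand.bin_mean_tau[common]) - np.log(ref.bin_mean_tau[common])
        ).sum()
    )


def feasibility(ref: ResidenceProfile, cand: ResidenceProfile) -> bool:
    """True iff the candidate's shared-bin averages stay inside the range
    spanned by the reference profile's occupied bins.

    Candidate lambdas that push residence times off the reference scale
    (the heatmap's blank regions, typically at very small lambda) are
    unsuitable.
    """
    common = _require_comparable(ref, cand)
    ref_tau = ref.bin_mean_tau[ref.occupied]
    lo, hi = float(ref_tau.min()), float(ref_tau.max())
    c = cand.bin_mean_tau[common]
    return bool(np.all(c >= lo * (1 - 1e-12)) and np.all(c <= hi * (1 + 1e-12)))


def default_grid(start: float = 0.1, stop: float = 3.0, step: float = 0.01):
    """The lambda search grid: 0.1 to 3.0 inclusive, step 0.01."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


@dataclass
class ConversionResult:
    """Grid diagnostics and the selected lambda of a conversion run."""

    lambda_grid: np.ndarray
    objective_values: np.ndarray
    feasible: np.ndarray
    selected_lambda: float
    objective_kind: str
    reference_profile: ResidenceProfile
    candidate_profiles: list
    forced: bool = False
    ref_lambda: float = float("nan")


def convert_lambda(
    ref_pwm: PWM,
    ref_lam: float,
    cand_pwm: PWM,
    ref_dist: ScoreDistribution,
    cand_dist: ScoreDistribution,
    grid: np.ndarray | None = None,
    objective_kind: str = "mse",
    min_logq: float = MIN_LOGQ,
    bin_width: float = BIN_WIDTH,
) -> ConversionResult:
    """Pick the candidate PWM's lambda by matching residence profiles.

    The reference profile is computed once at ``ref_lam``; the candidate
    profile is recomputed at every grid lambda and compared with the
    chosen objective. Among feasible grid points the minimizer is
    selected (ties break to the smallest lambda); if no point is feasible
    the global minimizer is returned with ``forced=True`` and a warning.
    """
    if ref_lam <= 0:
        raise ParameterError("reference lambda must be > 0")
    objective = {"mse": objective_mse, "abslog": objective_abslog}.get(
        objective_kind
    )
    if objective is None:
        raise ParameterError(f"unknown objective kind {objective_kind!r}")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ParameterError("grid must be strictly increasing and positive")

    ref_profile = residence_profile(
        ref_pwm.source_pfm_id, ref_dist, ref_lam, min_logq, bin_width
    )
    engine = _ProfileEngine(cand_dist, min_logq, bin_width)
    profiles, objectives, feasible = [], [], []
    for lam in grid:
        prof = engine.profile(float(lam), cand_pwm.source_pfm_id)
        profiles.append(prof)
        objectives.append(objective(ref_profile, prof))
        feasible.append(feasibility(ref_profile, prof))
    objectives = np.asarray(objectives)
    feasible = np.asarray(feasible, dtype=bool)

    if np.any(feasible):
        masked = np.where(feasible, objectives, np.inf)
        idx = int(np.argmin(masked))  # first minimum = smallest lambda
        forced = False
    else:
        idx = int(np.argmin(objectives))
        forced = True
        logger.warning(
            "no feasible lambda on the grid; returning the global "
            "objective minimum %.3f (forced)", grid[idx],
        )
    return ConversionResult(
        lambda_grid=grid,
        objective_values=objectives,
        feasible=feasible,
        selected_lambda=float(grid[idx]),
        objective_kind=objective_kind,
        reference_profile=ref_profile,
        candidate_profiles=profiles,
        forced=forced,
        ref_lambda=ref_lam,
    )


def heatmap_matrix(result: ConversionResult) -> np.ndarray:
    """Bin-by-grid matrix of candidate residence times for heatmap export.

    Rows are strength bins (-log10 quantile, weakest first), columns the
    lambda grid; cells of infeasible grid points, and empty bins, are NaN
    (masked)."""
    n_bins = max(p.n_bins for p in result.candidate_profiles)
    mat = np.full((n_bins, len(result.lambda_grid)), np.nan)
    for j, (prof, ok) in enumerate(
        zip(result.candidate_profiles, result.feasible)
    ):
        if not ok:
            continue
        mat[: prof.n_bins, j] = prof.bin_mean_tau
    return mat


def write_heatmap_tsv(result: ConversionResult, handle) -> None:
    mat = heatmap_matrix(result)
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write("# rows: -log10 quantile bin lower edge; columns: lambda\n")
        fh.write(
            "bin\t" + "\t".join(f"{l:g}" for l in result.lambda_grid) + "\n"
        )
        e0 = result.candidate_profiles[0].bin_edges
        edges = e0[0] + (e0[1] - e0[0]) * np.arange(mat.shape[0])
        for i in range(mat.shape[0]):
            row = "\t".join(
                "NA" if np.isnan(v) else f"{v:.6g}" for v in mat[i]
            )
            fh.write(f"{edges[i]:.1f}\t{row}\n")
    finally:
        if own:
            fh.close()


def write_conversion_json(
    result: ConversionResult, handle, meta: dict | None = None
) -> None:
    payload = {
        **(meta or {}),
        "selected_lambda": result.selected_lambda,
        "objective_kind": result.objective_kind,
        "forced": bool(result.forced),
        "ref_lambda": result.ref_lambda,
        "reference_pwm": result.reference_profile.pwm_id,
        "lambda_grid": result.lambda_grid.tolist(),
        "objective_values": [
            None if not np.isfinite(v) else float(v)
            for v in result.objective_values
        ],
        "feasible": result.feasible.astype(bool).tolist(),
    }
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    finally:
        if own:
            fh.close()
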