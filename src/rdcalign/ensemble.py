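"""Conformer-ensemble analysis of RDCs.

A flexible molecule samples several conformers; the measured coupling of each
atom pair is the population-weighted average of the per-conformer couplings.
Given per-conformer predictions (e.g. from alignment simulation — valid even
when the conformers have different alignment tensors), populations are found
by exhaustive search over the simplex lattice {p : p_k in {0, step, ..., 1},
sum p = 1}, maximizing the composite quality score RQ = (R + 1)^2 / QS of the
weighted average against experiment. Candidate structures (diastereomers,
single conformers) are ranked by the same score via RQ ratios.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .core_io import RDCSet
from .tensor_fit import QS_FLOOR, monte_carlo_errors, propagate_rq_error, quality_stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConformerSet",
    "EnsembleResult",
    "CandidateScore",
    "simplex_lattice",
    "average_rdcs",
    "fit_populations",
    "compare_ensemble_sizes",
    "rank_candidates",
]


@dataclass(frozen=True)
class ConformerSet:
    """Per-conformer predicted RDCs over a common atom-pair list."""

    labels: tuple[str, ...]
    d_pred: tuple[RDCSet, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.d_pred) or not self.d_pred:
            raise ValueError("need one label per conformer and at least one conformer")
        pairs0 = self.d_pred[0].pairs
        for s in self.d_pred[1:]:
            if s.pairs != pairs0:
                raise ValueError("all conformer RDC sets must share the same atom-pair list")

    @property
    def n_conformers(self) -> int:
        return len(self.d_pred)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return self.d_pred[0].pairs

    @property
    def prediction_matrix(self) -> np.ndarray:
        """(n_conformers, n_pairs) coupling matrix, Hz."""
        return np.array([s.values for s in self.d_pred])


@dataclass(frozen=True)
class EnsembleResult:
    """Populations with the fit statistics of the weighted-average couplings."""

    labels: tuple[str, ...]
    populations: np.ndarray  # fractions, sum to 1
    d_avg: np.ndarray  # Hz
    r: float
    q: float
    qs: float
    rq: float
    slope: float
    r_err: float = 0.0
    qs_err: float = 0.0
    rq_err: float = 0.0
    population_err: np.ndarray | None = None


@dataclass(frozen=True)
class CandidateScore:
    label: str
    r: float
    qs: float
    rq: float
    rq_ratio: float
    r_err: float = 0.0
    qs_err: float = 0.0
    rq_err: float = 0.0
    reliable: bool = True  # False when r < 0.8: too weak to identify the correct structure


def average_rdcs(conformer_set: ConformerSet, populations) -> RDCSet:
    """Population-weighted per-pair average of the conformer couplings."""
    p = np.asarray(populations, float)
    if p.shape != (conformer_set.n_conformers,):
        raise ValueError(
            f"got {p.size} populations for {conformer_set.n_conformers} conformers"
        )
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("populations must be non-negative and sum to 1")
    d_avg = p @ conformer_set.prediction_matrix
    base = conformer_set.d_pred[0]
    return base.with_values(d_avg, medium=base.medium)


def simplex_lattice(n: int, step: float) -> np.ndarray:
    """All population vectors with entries on the multiple-of-``step`` grid
    summing to 1, shape (n_points, n)."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 evenly")
    points = []
    def rec(prefix: list[int], remaining: int, slots: int):
        if slots == 1:
            points.append(prefix + [remaining])
            return
        for k in range(remaining + 1):
            rec(prefix + [k], remaining - k, slots - 1)
    rec([], m, n)
    return np.array(points, float) / m


def _stats_over_lattice(
    lattice: np.ndarray, pred: np.ndarray, d_exp: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (r, qs, rq, slope) of d_exp against every lattice average."""
    d_avg = lattice @ pred  # (n_points, n_pairs)
    rms_exp = np.sqrt(np.mean(d_exp**2))
    denom2 = np.sum(d_avg**2, axis=1)
    ok = denom2 > 0
    slope = np.zeros(len(d_avg))
    slope[ok] = (d_avg[ok] @ d_exp) / denom2[ok]
    resid = d_exp[None, :] - slope[:, None] * d_avg
    qs = np.sqrt(np.mean(resid**2, axis=1)) / rms_exp
    ex = d_exp - d_exp.mean()
    av = d_avg - d_avg.mean(axis=1, keepdims=True)
    av_norm = np.sqrt(np.sum(av**2, axis=1))
    varying = av_norm > 0
    r = np.zeros(len(d_avg))
    r[varying] = (av[varying] @ ex) / (av_norm[varying] * np.sqrt(np.sum(ex**2)))
    rq = np.where(ok, (r + 1.0) ** 2 / np.maximum(qs, QS_FLOOR), -np.inf)
    return r, qs, rq, slope


def _argmax_tiebreak(lattice: np.ndarray, rq: np.ndarray) -> int:
    """Index of the maximal RQ; exact ties resolve in favour of the vector
    assigning weight to earlier-listed conformers (lexicographically greatest)."""
    best = rq.max()
    tied = np.flatnonzero(rq == best)
    if len(tied) > 1:
        logger.info("RQ landscape flat over %d lattice points; tie-break applied", len(tied))
        order = np.lexsort(lattice[tied].T[::-1])  # lexicographic by p_0, p_1, ...
        return int(tied[order[-1]])
    return int(tied[0])


def fit_populations(
    conformer_set: ConformerSet,
    d_exp: RDCSet | np.ndarray,
    step: float = 0.01,
    n_monte_carlo: int = 0,
    seed: int | None = None,
) -> EnsembleResult:
    """RQ-maximizing conformer populations by exhaustive simplex grid search.

    With ``n_monte_carlo > 0`` the whole search is repeated on noise
    replicates of the experimental couplings, giving standard deviations of
    R, QS, RQ and of each population fraction.
    """
    if conformer_set.n_conformers < 2:
        raise ValueError("population fitting needs at least 2 conformers")
    exp_set = d_exp if isinstance(d_exp, RDCSet) else None
    d = d_exp.values if isinstance(d_exp, RDCSet) else np.asarray(d_exp, float)
    pred = conformer_set.prediction_matrix
    if d.size == 0:
        raise ValueError("empty experimental RDC list")
    if d.shape != (pred.shape[1],):
        raise ValueError("experimental couplings do not match the conformer pair list")
    lattice = simplex_lattice(conformer_set.n_conformers, step)
    r, qs, rq, slope = _stats_over_lattice(lattice, pred, d)
    i = _argmax_tiebreak(lattice, rq)
    p = lattice[i]
    d_avg = p @ pred
    q = float(np.sqrt(np.mean((d - d_avg) ** 2)) / np.sqrt(np.mean(d**2)))
    r_err = qs_err = rq_err = 0.0
    pop_err = None
    if n_monte_carlo > 0:
        if exp_set is None:
            raise ValueError("Monte Carlo errors need an RDCSet with per-record sigmas")
        rng = np.random.default_rng(seed)
        reps = np.empty((n_monte_carlo, 3))
        pops = np.empty((n_monte_carlo, conformer_set.n_conformers))
        sig = exp_set.sigmas
        for k in range(n_monte_carlo):
            noisy = d + rng.normal(0.0, 1.0, size=d.shape) * sig
            rr, qq, rrqq, _ = _stats_over_lattice(lattice, pred, noisy)
            j = _argmax_tiebreak(lattice, rrqq)
            reps[k] = rr[j], qq[j], rrqq[j]
            pops[k] = lattice[j]
        r_err = float(reps[:, 0].std(ddof=0))
        qs_err = float(reps[:, 1].std(ddof=0))
        rq_err = propagate_rq_error(float(r[i]), float(qs[i]), float(rq[i]), r_err, qs_err)
        pop_err = pops.std(axis=0, ddof=0)
    return EnsembleResult(
        labels=conformer_set.labels,
        populations=p,
        d_avg=d_avg,
        r=float(r[i]),
        q=q,
        qs=float(qs[i]),
        rq=float(rq[i]),
        slope=float(slope[i]),
        r_err=r_err,
        qs_err=qs_err,
        rq_err=rq_err,
        population_err=pop_err,
    )


def _single_conformer_result(conformer_set: ConformerSet, idx: int, d: np.ndarray) -> EnsembleResult:
    pred = conformer_set.prediction_matrix[idx]
    r, q, slope, qs, rq = quality_stats(d, pred)
    p = np.zeros(conformer_set.n_conformers)
    p[idx] = 1.0
    return EnsembleResult(
        labels=conformer_set.labels, populations=p, d_avg=pred,
        r=r, q=q, qs=qs, rq=rq, slope=slope,
    )


def compare_ensemble_sizes(
    conformer_set: ConformerSet,
    d_exp: RDCSet | np.ndarray,
    sizes: tuple[int, ...] = (1, 2, 3),
    step: float = 0.01,
) -> dict[int, dict]:
    """Best RQ-maximized ensemble for each requested size.

    Every subset of each size is searched; the report maps size to the
    winning subset's labels, populations (over the full conformer list) and
    statistics, plus the RQ ratio relative to the best ensemble overall.
    The optimal RQ is non-decreasing in ensemble size (nested search spaces).
    """
    n = conformer_set.n_conformers
    d = d_exp.values if isinstance(d_exp, RDCSet) else np.asarray(d_exp, float)
    if any(s < 1 or s > n for s in sizes):
        raise ValueError(f"sizes must lie in 1..{n}")
    report: dict[int, dict] = {}
    for size in sorted(sizes):
        best: EnsembleResult | None = None
        for subset in itertools.combinations(range(n), size):
            if size == 1:
                res = _single_conformer_result(conformer_set, subset[0], d)
            else:
                sub = ConformerSet(
                    labels=tuple(conformer_set.labels[j] for j in subset),
                    d_pred=tuple(conformer_set.d_pred[j] for j in subset),
                )
                sub_res = fit_populations(sub, d, step=step)
                p_full = np.zeros(n)
                p_full[list(subset)] = sub_res.populations
                res = EnsembleResult(
                    labels=conformer_set.labels, populations=p_full,
                    d_avg=sub_res.d_avg, r=sub_res.r, q=sub_res.q, qs=sub_res.qs,
                    rq=sub_res.rq, slope=sub_res.slope,
                )
            if best is None or res.rq > best.rq:
                best = res
        report[size] = {"result": best, "rq": best.rq}
    best_rq = max(entry["rq"] for entry in report.values())
    for entry in report.values():
        entry["rq_ratio"] = entry["rq"] / best_rq if best_rq > 0 else 0.0
    return report


def rank_candidates(
    candidates: list[tuple[str, RDCSet | np.ndarray]],
    d_exp: RDCSet,
    n_monte_carlo: int = 0,
    seed: int | None = None,
    r_threshold: float = 0.8,
) -> list[CandidateScore]:
    """Rank candidate structures by RQ against one experimental RDC set.

    Each candidate supplies predicted couplings over the experimental pair
    list. Scores carry the RQ ratio to the best candidate and, with
    ``n_monte_carlo > 0``, Monte Carlo errors. Candidates with R below
    ``r_threshold`` are flagged unreliable: such weak correlations are not
    sufficient to identify the correct stereoisomer. Ties in RQ keep a
    stable order by label.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    d = d_exp.values
    scores = []
    for label, pred in candidates:
        dp = pred.values if isinstance(pred, RDCSet) else np.asarray(pred, float)
        if dp.shape != d.shape:
            raise ValueError(f"candidate {label!r}: pair list does not match experiment")
        r, q, slope, qs, rq = quality_stats(d, dp)
        r_err = qs_err = rq_err = 0.0
        if n_monte_carlo > 0:
            def score_fn(noisy: RDCSet, dp=dp) -> tuple[float, float, float]:
                rr, _, _, qq, rrqq = quality_stats(noisy.values, dp)
                return rr, qq, rrqq
            r_err, qs_err, rq_err = monte_carlo_errors(
                score_fn, d_exp, n_rep=n_monte_carlo, seed=seed, base=(r, qs, rq)
            )
        scores.append(CandidateScore(
            label=label, r=r, qs=qs, rq=rq, rq_ratio=0.0,
            r_err=r_err, qs_err=qs_err, rq_err=rq_err,
            reliable=r >= r_threshold,
        ))
    best = max(s.rq for s in scores)
    scores = [
        CandidateScore(
            label=s.label, r=s.r, qs=s.qs, rq=s.rq,
            rq_ratio=s.rq / best if best > 0 else 0.0,
            r_err=s.r_err, qs_err=s.qs_err, rq_err=s.rq_err, reliable=s.reliable,
        )
        for s in scores
    ]
    return sorted(scores, key=lambda s: (-s.rq, s.label))
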