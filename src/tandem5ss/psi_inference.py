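"""Bayesian inference of the inclusion fraction psi at tandem donors.

psi is the fraction of transcripts using the intron-proximal donor (the
"percent spliced in" of the alternative exon-terminal segment); distal usage
is 1 - psi. Given n_proximal and n_distal isoform-diagnostic reads, the
sampling probability that a diagnostic read supports the proximal isoform is

    p(psi) = psi * l_inc / (psi * l_inc + (1 - psi) * l_exc)

where l_inc and l_exc are the effective lengths (number of distinct diagnostic
read placements) of the inclusion and exclusion isoforms. With equal effective
lengths — pure junction-read counting, the default — p(psi) = psi and the
posterior under a uniform prior is Beta(n_proximal + 1, n_distal + 1).

The posterior is computed on a midpoint grid over (0, 1) rather than by MCMC:
the problem is one-dimensional, so deterministic quadrature is exact enough to
check against closed forms. Two-condition comparisons report delta-psi and a
Bayes factor for H1 "psi differs" (independent uniform priors) against H0
"psi equal" (one shared uniform prior), followed by the standard four-part
filter: minimum inclusion reads, minimum exclusion reads, |delta psi| >= 0.2,
and Bayes factor >= 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_formats import CountRecord

DEFAULT_GRID_STEP = 0.001


@dataclass(frozen=True)
class FilterThresholds:
    """Significance filter for two-condition comparisons."""

    num_inc: int = 1
    num_exc: int = 1
    delta_psi: float = 0.2
    bayes_factor: float = 10.0

    def __post_init__(self) -> None:
        if min(self.num_inc, self.num_exc) < 0 or self.delta_psi <= 0 or self.bayes_factor <= 0:
            raise ValueError("filter thresholds must be positive")


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class PsiPosterior:
    """Grid posterior over the inclusion fraction for one event and sample."""

    event_id: str
    sample_id: str
    grid: np.ndarray
    density: np.ndarray
    posterior_mean: float
    ci_low: float
    ci_high: float
    n_distal: int
    n_proximal: int
    l_inc: float
    l_exc: float
    no_data: bool = False


@dataclass
class DeltaPsiResult:
    """Two-condition comparison of one event (sample 2 = perturbation)."""

    event_id: str
    psi1: float
    psi2: float
    delta_psi: float
    bayes_factor: float
    n_distal1: int
    n_proximal1: int
    n_distal2: int
    n_proximal2: int
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    pass_num_inc: bool = False
    pass_num_exc: bool = False
    pass_delta: bool = False
    pass_bf: bool = False

    @property
    def significant(self) -> bool:
        return self.pass_num_inc and self.pass_num_exc and self.pass_delta and self.pass_bf


def psi_grid(h: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Midpoint grid over (0, 1) with step h: psi_i = (i + 1/2) h."""
    if h <= 0 or h >= 1:
        raise ValueError(f"grid step must lie in (0, 1), got {h}")
    n = int(round(1.0 / h))
    return (np.arange(n) + 0.5) * h


def read_probability(psi: np.ndarray, l_inc: float, l_exc: float) -> np.ndarray:
    """Probability a diagnostic read supports the proximal (inclusion) isoform."""
    return psi * l_inc / (psi * l_inc + (1.0 - psi) * l_exc)


def _log_likelihood(
    grid: np.ndarray, n_distal: int, n_proximal: int, l_inc: float, l_exc: float
) -> np.ndarray:
    p = read_probability(grid, l_inc, l_exc)
    ll = np.zeros_like(grid)
    if n_proximal:
        ll += n_proximal * np.log(p)
    if n_distal:
        ll += n_distal * np.log1p(-p)
    return ll


def _check_counts(n_distal: int, n_proximal: int) -> None:
    if n_distal < 0 or n_proximal < 0:
        raise ValueError(f"counts must be non-negative, got ({n_distal}, {n_proximal})")


def _mean_and_ci(grid: np.ndarray, density: np.ndarray, h: float) -> tuple[float, float, float]:
    mean = float(h * np.sum(grid * density))
    # midpoint-rule CDF evaluated at the grid points
    cdf = h * np.cumsum(density) - 0.5 * h * density
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return mean, lo, hi


def psi_posterior(
    n_distal: int,
    n_proximal: int,
    l_inc: float = 1.0,
    l_exc: float = 1.0,
    h: float = DEFAULT_GRID_STEP,
    event_id: str = "",
    sample_id: str = "",
) -> PsiPosterior:
    """Posterior over psi under a uniform prior, on the midpoint grid.

    With l_inc == l_exc this is Beta(n_proximal + 1, n_distal + 1) restricted
    to the grid. Zero total counts return the flat prior with ``no_data`` set.
    """
    _check_counts(n_distal, n_proximal)
    if l_inc <= 0 or l_exc <= 0:
        raise ValueError("effective lengths must be positive")
    grid = psi_grid(h)
    ll = _log_likelihood(grid, n_distal, n_proximal, l_inc, l_exc)
    log_density = ll - logsumexp(ll) - np.log(h)
    density = np.exp(log_density)
    mean, lo, hi = _mean_and_ci(grid, density, h)
    return PsiPosterior(
        event_id=event_id,
        sample_id=sample_id,
        grid=grid,
        density=density,
        posterior_mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_distal=n_distal,
        n_proximal=n_proximal,
        l_inc=l_inc,
        l_exc=l_exc,
        no_data=(n_distal + n_proximal == 0),
    )


def bayes_factor(
    counts1: tuple[int, int],
    counts2: tuple[int, int],
    l_inc: float = 1.0,
    l_exc: float = 1.0,
    h: float = DEFAULT_GRID_STEP,
    event_id: str = "",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> DeltaPsiResult:
    """Compare two samples: delta-psi, Bayes factor, and filter flags.

    ``counts1``/``counts2`` are (n_distal, n_proximal) for the control and
    perturbation samples. Marginal likelihoods use the same midpoint rule as
    the posterior: m(H1) = m1 * m2 with independent uniform priors, and
    m(H0) integrates the product likelihood under one shared uniform prior.
    """
    nd1, np1 = counts1
    nd2, np2 = counts2
    _check_counts(nd1, np1)
    _check_counts(nd2, np2)
    grid = psi_grid(h)
    log_h = np.log(h)
    ll1 = _log_likelihood(grid, nd1, np1, l_inc, l_exc)
    ll2 = _log_likelihood(grid, nd2, np2, l_inc, l_exc)
    log_m1 = log_h + logsumexp(ll1)
    log_m2 = log_h + logsumexp(ll2)
    log_m0 = log_h + logsumexp(ll1 + ll2)
    bf = float(np.exp(log_m1 + log_m2 - log_m0))

    post1 = psi_posterior(nd1, np1, l_inc, l_exc, h)
    post2 = psi_posterior(nd2, np2, l_inc, l_exc, h)
    result = DeltaPsiResult(
        event_id=event_id,
        psi1=post1.posterior_mean,
        psi2=post2.posterior_mean,
        delta_psi=post2.posterior_mean - post1.posterior_mean,
        bayes_factor=bf,
        n_distal1=nd1,
        n_proximal1=np1,
        n_distal2=nd2,
        n_proximal2=np2,
    )
    return apply_filters(result, thresholds)


def apply_filters(
    result: DeltaPsiResult, thresholds: FilterThresholds = DEFAULT_THRESHOLDS
) -> DeltaPsiResult:
    """Set the four pass flags on a comparison result.

    Inclusion/exclusion read minima apply to counts summed across the two
    samples (recorded in the result so the scope choice is auditable).
    """
    return replace(
        result,
        thresholds=thresholds,
        pass_num_inc=result.n_proximal1 + result.n_proximal2 >= thresholds.num_inc,
        pass_num_exc=result.n_distal1 + result.n_distal2 >= thresholds.num_exc,
        pass_delta=abs(result.delta_psi) >= thresholds.delta_psi,
        pass_bf=result.bayes_factor >= thresholds.bayes_factor,
    )


# ---------------------------------------------------------------------------
# cohort-level interface


def compare_conditions(
    records: Sequence[CountRecord],
    control: str,
    treatment: str,
    l_inc: float = 1.0,
    l_exc: float = 1.0,
    h: float = DEFAULT_GRID_STEP,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> list[DeltaPsiResult]:
    """Run the two-condition comparison for every event in a count table.

    Counts are pooled per (event, sample); an event missing either sample
    contributes zero counts for it (and then fails the read-minimum filters).
    """
    pooled: dict[str, dict[str, list[int]]] = {}
    for rec in records:
        ev = pooled.setdefault(rec.event_id, {})
        pair = ev.setdefault(rec.sample_id, [0, 0])
        pair[0] += rec.n_distal
        pair[1] += rec.n_proximal
    results = []
    for event_id in sorted(pooled):
        samples = pooled[event_id]
        c1 = tuple(samples.get(control, (0, 0)))
        c2 = tuple(samples.get(treatment, (0, 0)))
        results.append(
            bayes_factor(c1, c2, l_inc, l_exc, h, event_id=event_id, thresholds=thresholds)
        )
    return results


def results_to_frame(results: Sequence[DeltaPsiResult]) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "psi_ctrl": r.psi1,
            "psi_kd": r.psi2,
            "delta_psi": r.delta_psi,
            "bayes_factor": r.bayes_factor,
            "n_distal_ctrl": r.n_distal1,
            "n_proximal_ctrl": r.n_proximal1,
            "n_distal_kd": r.n_distal2,
            "n_proximal_kd": r.n_proximal2,
            "pass_num_inc": r.pass_num_inc,
            "pass_num_exc": r.pass_num_exc,
            "pass_delta": r.pass_delta,
            "pass_bf": r.pass_bf,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def write_results(results: Sequence[DeltaPsiResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> list[DeltaPsiResult]:
    """Read a results TSV back into DeltaPsiResult records (flags recomputed)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        r = DeltaPsiResult(
            event_id=str(row.event_id),
            psi1=float(row.psi_ctrl),
            psi2=float(row.psi_kd),
            delta_psi=float(row.delta_psi),
            bayes_factor=float(row.bayes_factor),
            n_distal1=int(row.n_distal_ctrl),
            n_proximal1=int(row.n_proximal_ctrl),
            n_distal2=int(row.n_distal_kd),
            n_proximal2=int(row.n_proximal_kd),
        )
        out.append(apply_filters(r))
    return out
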