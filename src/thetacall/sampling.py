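"""Sampling-with-replacement experiments behind the allele-count thresholds.

Rare alleles define small haplotype classes, and θ estimated from a small
sample is biased: θ₂ shrinks with sample size while θ₁ is inflated for
small samples.  These experiments quantify that bias: a population is
evolved to stationarity (beta initialization + 8N generations of random
mating over a 2000 bp sequence), haplotypes are drawn *with replacement* at
a range of sample sizes, and both θ estimates over the full sequence are
summarized across repetitions (mean and empirical 2.5/97.5% quantiles)
against the full-population reference estimate.  The resulting curves
justify requiring more than 10 haplotypes per class for θ₁ and more than
20 for θ₂.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedEstimateError
from .simulate import SimulationConfig, init_population, step_generation
from .theta import estimate_theta1, estimate_theta2, summary_from_counts

__all__ = ["SamplingConfig", "SamplingResult", "run_sampling", "results_frame"]

#: Default sample sizes swept in the experiments (haplotypes).
DEFAULT_SAMPLE_SIZES = (5, 10, 20, 30, 50, 100, 200)


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling experiment conditions: 2000 bp stationary populations,
    1000 repetitions, population sizes 100 and 500 in the source setting."""

    N: int = 100
    L: int = 2000
    mu: float = 1e-4
    rho: float = 1e-4
    sample_sizes: tuple = DEFAULT_SAMPLE_SIZES
    repetitions: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            N=self.N, L=self.L, mu=self.mu, rho=self.rho, seed=self.seed
        )


@dataclass(frozen=True)
class SamplingResult:
    """Mean and CI of one estimator at one sample size, with the
    full-population reference ("the original estimate")."""

    sample_size: int
    method: str
    mean: float
    ci_low: float
    ci_high: float
    reference: float
    n_defined: int


def _theta_pair(counts: np.ndarray, n: int) -> tuple[float, float]:
    summ = summary_from_counts(counts, n)
    t1 = estimate_theta1(summ).value
    try:
        t2 = estimate_theta2(summ).value
    except UndefinedEstimateError:
        t2 = np.nan
    return t1, t2


def run_sampling(config: SamplingConfig) -> list[SamplingResult]:
    """Run the repeated-sampling experiment.

    One independent stationary population is evolved per repetition; for
    each sample size, haplotypes are drawn with replacement and both θ
    estimates computed over the full sequence.  Sample sizes below 2 are
    rejected.
    """
    if any(s < 2 for s in config.sample_sizes):
        raise ValueError("sample sizes must be >= 2")
    sim = config.sim_config()
    reps = config.repetitions
    sizes = list(config.sample_sizes)
    vals = {m: np.full((reps, len(sizes)), np.nan) for m in ("theta1", "theta2")}
    refs = {m: np.full(reps, np.nan) for m in ("theta1", "theta2")}
    for r, ss in enumerate(np.random.SeedSequence(config.seed).spawn(reps)):
        rng = np.random.default_rng(ss)
        state = init_population(sim, rng)
        for _ in range(sim.burn_in_generations):
            step_generation(state, sim, ledger=None)
        H = state.haplotypes
        two_n = H.shape[0]
        counts = np.add.reduce(H, axis=0, dtype=np.int32)
        refs["theta1"][r], refs["theta2"][r] = _theta_pair(counts, two_n)
        for c, size in enumerate(sizes):
            rows = rng.integers(0, two_n, size=size)
            sc = np.add.reduce(H[rows], axis=0, dtype=np.int32)
            t1, t2 = _theta_pair(sc, size)
            vals["theta1"][r, c] = t1
            vals["theta2"][r, c] = t2
    alpha = (1.0 - config.ci_level) / 2.0
    out = []
    for m in ("theta1", "theta2"):
        ref = float(np.nanmean(refs[m]))
        for c, size in enumerate(sizes):
            col = vals[m][:, c]
            ok = col[np.isfinite(col)]
            out.append(SamplingResult(
                sample_size=size,
                method=m,
                mean=float(ok.mean()) if ok.size else np.nan,
                ci_low=float(np.quantile(ok, alpha)) if ok.size else np.nan,
                ci_high=float(np.quantile(ok, 1.0 - alpha)) if ok.size else np.nan,
                reference=ref,
                n_defined=int(ok.size),
            ))
    return out


def results_frame(results: list[SamplingResult]) -> pd.DataFrame:
    """Tidy DataFrame of SamplingResult rows."""
    return pd.DataFrame([r.__dict__ for r in results])
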