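"""Forward Wright–Fisher finite-sites simulator with recombination.

The simulator validates the diversity-based ancestral caller against known
truth.  A constant-size diploid population (N individuals, 2N haplotypes)
evolves over a binary sequence of L sites: each generation, offspring are
formed by random union of gametes (each gamete recombines its parent's two
haplotypes with an independent per-bp-gap crossover probability ρ), and
every (haplotype, site) then flips its allele with probability μ.  Alleles
are binary finite-sites states — mutation can recur and revert — so the
population reaches a stationary diversity governed by θ = 4Nμ.

The population is initialized at approximate equilibrium (each site's
frequency drawn from Beta(4Nμ, 4Nμ), Wright's stationary law) and burned in
for 8N further generations.  Ground truth is kept in a
:class:`MutationLedger`: a mutation that hits a monomorphic site founds a
new variant whose derived allele and birth generation are recorded; drift
to fixation or loss retires the entry.  Only variants born after burn-in
carry truth and are scored.

:func:`run_experiment` runs the full evaluation harness: at each evaluation
generation every ledgered segregating variant passing the allele-count
filter is called with both θ estimators over a ±radius window and scored
against the ledger, pooling observations across replicates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "MutationLedger",
    "init_population",
    "step_generation",
    "run_replicate",
    "run_experiment",
    "summarize_accuracy",
    "theta_trajectory",
    "population_theta",
    "OUTCOME_LABELS",
]

# Outcome codes for one (variant, generation, method) observation.
CORRECT, WRONG, TIE, FILTERED, UNDEFINED = 0, 1, 2, 3, 4
OUTCOME_LABELS = {
    CORRECT: "correct",
    WRONG: "wrong",
    TIE: "tie",
    FILTERED: "filtered",
    UNDEFINED: "undefined",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulation experiments.

    Defaults are the main validation setting: N=100 diploids, 30 kb
    sequence, μ = ρ = 1e-4 per bp per generation, 8N burn-in, 1000 tracked
    generations, ±2000 bp evaluation window.  Evaluation runs every tracked
    generation up to ``eval_dense_until`` and every ``eval_stride``-th
    thereafter.  Allele-count filters follow the caller defaults (more than
    10 haplotypes per class for θ₁, more than 20 for θ₂).
    """

    N: int = 100
    L: int = 30000
    mu: float = 1e-4
    rho: float = 1e-4
    burn_in: int | None = None  # defaults to 8N
    tracked_generations: int = 1000
    radius: int = 2000
    n_replicates: int = 20
    seed: int = 0
    eval_dense_until: int = 500
    eval_stride: int = 10
    min_count_theta1: int = 11
    min_count_theta2: int = 21
    max_missing_bp: int = 3000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.rho <= 1.0):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def burn_in_generations(self) -> int:
        return 8 * self.N if self.burn_in is None else self.burn_in


@dataclass
class SimulationState:
    """Population state: 2N binary haplotypes over L sites."""

    haplotypes: np.ndarray  # (2N, L) uint8 in {0, 1}
    generation: int
    rng: np.random.Generator
    _scratch: np.ndarray | None = None
    last_n_mutations: int = 0  # mutation events drawn in the latest step

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


class MutationLedger:
    """Ground-truth bookkeeping of derived alleles, one slot per site.

    A slot is live (``birth_gen >= 0``) while its variant segregates; a
    recurrent mutation at a segregating site does not re-define the derived
    allele; fixation or loss retires the slot until a fresh mutation at the
    (then monomorphic) site re-founds it.
    """

    def __init__(self, L: int):
        self.birth_gen = np.full(L, -1, dtype=np.int32)
        self.derived = np.full(L, -1, dtype=np.int8)

    def live_sites(self) -> np.ndarray:
        return np.flatnonzero(self.birth_gen >= 0)

    def open(self, sites: np.ndarray, derived: np.ndarray, gen: int) -> None:
        self.birth_gen[sites] = gen
        self.derived[sites] = derived

    def retire(self, sites: np.ndarray) -> None:
        self.birth_gen[sites] = -1
        self.derived[sites] = -1


def init_population(config: SimulationConfig, rng: np.random.Generator) -> SimulationState:
    """Population at approximate stationarity.

    Each site's initial frequency is drawn from Beta(4Nμ, 4Nμ) and alleles
    are assigned independently per haplotype at that frequency.  With μ = 0
    the Beta(0, 0) limit is the two-point {0, 1} law: every site starts
    monomorphic for a fair coin's choice of allele.
    """
    two_n = 2 * config.N
    a = 4.0 * config.N * config.mu
    if a == 0.0:
        freq = rng.integers(0, 2, size=config.L).astype(float)
    else:
        freq = rng.beta(a, a, size=config.L)
    haplotypes = (rng.random((two_n, config.L)) < freq).astype(np.uint8)
    return SimulationState(haplotypes=haplotypes, generation=0, rng=rng)


def _make_gametes(H: np.ndarray, out: np.ndarray, L: int, rho: float,
                  rng: np.random.Generator) -> None:
    """Fill ``out`` with 2N recombinant gametes drawn from diploids in ``H``."""
    two_n = H.shape[0]
    n_dip = two_n // 2
    parents = rng.integers(0, n_dip, size=two_n)
    starts = rng.integers(0, 2, size=two_n)
    if rho > 0.0 and L > 1:
        ncx = rng.binomial(L - 1, rho, size=two_n)
    else:
        ncx = np.zeros(two_n, dtype=np.int64)
    total_cx = int(ncx.sum())
    # crossover gap positions; two hits in the same gap cancel (double
    # crossover between adjacent sites restores phase)
    all_cuts = rng.integers(1, L, size=total_cx) if total_cx else None
    ofs = 0
    for g in range(two_n):
        a = 2 * parents[g] + starts[g]
        b = 2 * parents[g] + 1 - starts[g]
        k = ncx[g]
        if k == 0:
            out[g] = H[a]
            continue
        cuts = np.sort(all_cuts[ofs:ofs + k])
        ofs += k
        row = out[g]
        src = (H[a], H[b])
        t = 0
        prev = 0
        for c in cuts:
            row[prev:c] = src[t][prev:c]
            t ^= 1
            prev = c
        row[prev:] = src[t][prev:]


def step_generation(
    state: SimulationState,
    config: SimulationConfig,
    ledger: MutationLedger | None = None,
):
    """Advance one generation in place; returns post-mutation allele-1 counts.

    Order of events: reproduction (random union of recombinant gametes),
    then mutation (binomial number of flips at uniform cells; two hits on
    the same cell cancel).  Ledger updates: drift fixation/loss retires a
    slot; a mutation at a site monomorphic *at the time of mutation* founds
    a new variant; mutation-induced fixation/loss is retired last.
    """
    H = state.haplotypes
    two_n, L = H.shape
    rng = state.rng
    if state._scratch is None:
        state._scratch = np.empty_like(H)
    new = state._scratch

    _make_gametes(H, new, L, config.rho, rng)
    state.haplotypes, state._scratch = new, H
    H = state.haplotypes
    state.generation += 1
    gen = state.generation

    need_counts = ledger is not None
    S = (
        np.add.reduce(H, axis=0, dtype=np.int16).astype(np.int32)
        if need_counts
        else None
    )

    if ledger is not None:
        # drift fixation/loss among live slots, before this generation's mutations
        live = ledger.live_sites()
        if live.size:
            gone = live[(S[live] == 0) | (S[live] == two_n)]
            if gone.size:
                ledger.retire(gone)

    n_mut = rng.binomial(two_n * L, config.mu) if config.mu > 0.0 else 0
    state.last_n_mutations = n_mut
    if n_mut:
        idx = np.unique(rng.integers(0, two_n * L, size=n_mut))
        if ledger is not None:
            sites = (idx % L).astype(np.int64)
            usites = np.unique(sites)
            pre = S[usites]
            mono = (pre == 0) | (pre == two_n)
            found = usites[mono]
            if found.size:
                derived = (pre[mono] == 0).astype(np.int8)  # flips create allele 1 at empty sites
                ledger.open(found, derived, gen)
        H.flat[idx] ^= 1
        if ledger is not None:
            flipped_to = H.flat[idx].astype(np.int32)
            np.add.at(S, idx % L, 2 * flipped_to - 1)
            # mutation-induced fixation/loss (incl. newly founded then lost)
            live = ledger.live_sites()
            if live.size:
                gone = live[(S[live] == 0) | (S[live] == two_n)]
                if gone.size:
                    ledger.retire(gone)
    return S


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------

def _evaluate_generation(H, S, ledger, gen, config, chunks):
    """Score every ledgered segregating variant passing the θ₁ count filter.

    Appends one column-array chunk of observations to ``chunks``.
    """
    from ._kernels import eval_candidates, pack_columns

    two_n, L = H.shape
    live = ledger.live_sites()
    if live.size == 0:
        return
    minor = np.minimum(S[live], two_n - S[live])
    cand = live[minor >= config.min_count_theta1]
    if cand.size == 0:
        return
    radius = config.radius
    span = 2 * radius + 1
    width = np.minimum(cand + radius + 1, L) - np.maximum(cand - radius, 0)
    cand = cand[(span - width) <= config.max_missing_bp]
    if cand.size == 0:
        return
    P64 = pack_columns(H)
    derived = ledger.derived[cand]
    t1a, t1d, t2a, t2d, o1, o2, ndc = eval_candidates(
        H, P64, S, cand, derived, radius, config.min_count_theta2
    )
    chunks.append({
        "generation": np.full(cand.size, gen, dtype=np.int32),
        "site": cand.astype(np.int32),
        "age": (gen - ledger.birth_gen[cand]).astype(np.int32),
        "derived_count": ndc,
        "theta1_anc": t1a,
        "theta1_der": t1d,
        "theta2_anc": t2a,
        "theta2_der": t2d,
        "outcome1": o1,
        "outcome2": o2,
    })


def _eval_generations(config: SimulationConfig) -> np.ndarray:
    t = config.tracked_generations
    dense = np.arange(1, min(config.eval_dense_until, t) + 1)
    if t > config.eval_dense_until:
        sparse = np.arange(
            config.eval_dense_until + config.eval_stride, t + 1, config.eval_stride
        )
        return np.concatenate([dense, sparse])
    return dense


def run_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    keep_state: bool = False,
):
    """Burn-in, then tracked generations with evaluation; one replicate.

    With ``keep_state=True`` returns ``(records, state, ledger)`` so the
    final population can be exported (e.g. as a phased VCF fixture).
    """
    state = init_population(config, rng)
    for _ in range(config.burn_in_generations):
        step_generation(state, config, ledger=None)
    ledger = MutationLedger(config.L)
    state.generation = 0  # tracked-phase clock; ledger births are on this clock
    eval_set = set(int(g) for g in _eval_generations(config))
    chunks: list[dict] = []
    for _ in range(config.tracked_generations):
        S = step_generation(state, config, ledger=ledger)
        if state.generation in eval_set:
            _evaluate_generation(state.haplotypes, S, ledger, state.generation,
                                 config, chunks)
    cols = ("generation", "site", "age", "derived_count",
            "theta1_anc", "theta1_der", "theta2_anc", "theta2_der",
            "outcome1", "outcome2")
    if chunks:
        df = pd.DataFrame(
            {k: np.concatenate([c[k] for c in chunks]) for k in cols}
        )
    else:
        df = pd.DataFrame({k: np.array([]) for k in cols})
    df["n_haplotypes"] = 2 * config.N
    if keep_state:
        return df, state, ledger
    return df


def run_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Run the configured replicates (independent seeded streams) and pool.

    Returns a tidy DataFrame of per-(variant, generation) observations:
    variant age, derived-allele count, θ estimates of the ancestral- and
    derived-allele classes for both methods, and an outcome code per method
    (see :data:`OUTCOME_LABELS`).
    """
    frames = []
    for i, ss in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_replicates)):
        rng = np.random.default_rng(ss)
        df = run_replicate(config, rng)
        df["replicate"] = i
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _called(records: pd.DataFrame, method: str) -> pd.DataFrame:
    o = records["outcome1" if method == "theta1" else "outcome2"]
    return records[(o == CORRECT) | (o == WRONG)]


def _dedup_final(records: pd.DataFrame) -> pd.DataFrame:
    """Keep each variant's last observation (per-variant-final scoring)."""
    r = records.assign(_birth=records["generation"] - records["age"])
    keys = ["replicate", "site", "_birth"] if "replicate" in r else ["site", "_birth"]
    r = r.sort_values("generation").drop_duplicates(keys, keep="last")
    return r.drop(columns="_birth")


def summarize_accuracy(records: pd.DataFrame, per_variant_final: bool = False) -> dict:
    """Cumulative accuracy curves by age and derived frequency, per method.

    Cumulative accuracy at age g is the fraction correct among called
    observations with age <= g (analogously over derived-frequency
    thresholds).  Also reports overall accuracy, the age distribution of
    scored observations and the derived-frequency histogram.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    if per_variant_final:
        records = _dedup_final(records)
    out: dict = {"overall": {}, "by_age": {}, "by_freq": {}}
    for method in ("theta1", "theta2"):
        sub = _called(records, method)
        if sub.empty:
            continue
        ocol = "outcome1" if method == "theta1" else "outcome2"
        correct = (sub[ocol] == CORRECT).to_numpy()
        out["overall"][method] = float(correct.mean())

        ages = sub["age"].to_numpy()
        order = np.argsort(ages, kind="stable")
        cum = np.cumsum(correct[order]) / np.arange(1, order.size + 1)
        uniq, last = np.unique(ages[order], return_index=True)
        idx = np.r_[last[1:] - 1, order.size - 1]
        out["by_age"][method] = pd.DataFrame(
            {"age": uniq, "cum_accuracy": cum[idx]}
        )

        freq = (sub["derived_count"] / sub["n_haplotypes"]).to_numpy()
        order = np.argsort(freq, kind="stable")
        cum = np.cumsum(correct[order]) / np.arange(1, order.size + 1)
        uniq, last = np.unique(freq[order], return_index=True)
        idx = np.r_[last[1:] - 1, order.size - 1]
        out["by_freq"][method] = pd.DataFrame(
            {"derived_freq": uniq, "cum_accuracy": cum[idx]}
        )
    out["ages"] = records["age"].to_numpy()
    out["derived_freqs"] = (records["derived_count"] / records["n_haplotypes"]).to_numpy()
    return out


def theta_trajectory(records: pd.DataFrame, method: str = "theta2") -> pd.DataFrame:
    """Mean θ of ancestral- and derived-allele classes as a function of age."""
    a, d = f"{method}_anc", f"{method}_der"
    sub = records.dropna(subset=[a, d])
    sub = sub[np.isfinite(sub[a]) & np.isfinite(sub[d])]
    grp = sub.groupby("age")[[a, d]].mean()
    return grp.rename(columns={a: "theta_ancestral", d: "theta_derived"}).reset_index()


def population_theta(haplotypes: np.ndarray) -> dict:
    """θ₁ and θ₂ of the full haplotype set over the whole sequence."""
    from .theta import summary_from_counts, estimate_theta1, estimate_theta2

    S = np.count_nonzero(haplotypes, axis=0)
    summ = summary_from_counts(S, haplotypes.shape[0])
    t2 = estimate_theta2(summ).value if summ.v > 0 else math.nan
    return {"theta1": estimate_theta1(summ).value, "theta2": t2}
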