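"""Stochastic mtDNA deletion dynamics in a developing and aging nematode.

Each of the worm's 959 somatic cells carries its own population of ~313 mtDNA
molecules (300,000 per worm).  Molecules turn over continuously ("relaxed
replication"): each is degraded at rate ln2/t_half and the cell immediately
replicates surviving molecules, chosen uniformly at random with replacement,
back to its copy-number target.  A replication from a wild-type template
produces a deletion-bearing molecule with probability ``mu``; mutant templates
breed true.  Deletions are neutral, so within-cell mutant fraction performs
unbiased random genetic drift whose clock is set by the turnover rate — the
engine of clonal expansion.

The default engine is a discrete-time binomial stepper (dt << t_half),
validated against an exact event-driven (Gillespie/Moran) implementation of
the same birth-death-mutation process on small populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import constants

__all__ = [
    "SimParams",
    "WormState",
    "run_development",
    "step_turnover",
    "step_counts",
    "simulate_lifespan",
    "first_passage_time",
    "FirstPassageResult",
    "gillespie_cell",
    "validate_against_ssa",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the worm-level mtDNA deletion simulation.

    mu                      de novo deletion probability per replication
    half_life_days          mtDNA half-life t1/2 (turnover clock)
    copies_per_worm_target  total mtDNA copy-number target for the adult
    n_cells                 somatic cell count of the adult
    threshold               intracellular mutant fraction of biochemical
                            compromise (~0.60)
    dt_days                 stepper time step; must satisfy dt <= t1/2 / 6
    dev_duration_days       egg-to-adult development span
    egg_copies              zygote mtDNA copy number
    replenish_on_extinction refill an mtDNA-extinct cell with wild type
    """

    mu: float = 2e-4
    half_life_days: float = 12.0
    copies_per_worm_target: int = constants.COPIES_PER_WORM
    n_cells: int = constants.N_CELLS
    threshold: float = 0.60
    dt_days: float = 0.25
    dev_duration_days: float = 3.0
    egg_copies: int = 25_000
    replenish_on_extinction: bool = True

    def __post_init__(self):
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if self.half_life_days <= 0:
            raise ValueError("half_life_days must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.dt_days > self.half_life_days / 6:
            raise ValueError("dt_days must be <= half_life_days / 6")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.egg_copies < self.n_cells:
            raise ValueError("egg_copies must be >= n_cells")

    @property
    def cell_target(self) -> int:
        """Per-cell copy-number target."""
        return max(1, round(self.copies_per_worm_target / self.n_cells))

    @property
    def death_prob_per_step(self) -> float:
        return 1.0 - math.exp(-math.log(2.0) / self.half_life_days * self.dt_days)


@dataclass
class WormState:
    """Per-cell wild-type/mutant mtDNA counts at one age."""

    wt: np.ndarray
    mut: np.ndarray
    age_days: float

    @property
    def n_cells(self) -> int:
        return self.wt.size

    @property
    def total_mut(self) -> int:
        return int(self.mut.sum())

    @property
    def total_copies(self) -> int:
        return int(self.wt.sum() + self.mut.sum())

    @property
    def fractions(self) -> np.ndarray:
        tot = self.wt + self.mut
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.mut / np.maximum(tot, 1), 0.0)
        return f

    @property
    def max_fraction(self) -> float:
        return float(self.fractions.max()) if self.n_cells else 0.0


def _replicate(wt, mut, n_new, mu, rng):
    """Add ``n_new`` molecules per cell by uniform template choice.

    Wild-type-templated copies mutate with probability mu; mutant templates
    breed true.  Arrays are modified out-of-place and returned.
    """
    tot = wt + mut
    n_new = np.asarray(n_new)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_mut = np.where(tot > 0, mut / np.maximum(tot, 1), 0.0)
    from_mut = rng.binomial(n_new, p_mut)
    from_wt = n_new - from_mut
    de_novo = rng.binomial(from_wt, mu) if mu > 0 else np.zeros_like(from_wt)
    return wt + from_wt - de_novo, mut + from_mut + de_novo


def run_development(
    p: SimParams, seed: int = 0, founder_mut: int = 0
) -> WormState:
    """Grow a worm from a single zygote to ``n_cells`` adult cells.

    Synchronous binary division rounds (ceil(log2(n_cells))) are spread over
    ``dev_duration_days``; molecules are partitioned binomially between
    daughters at each division, and between rounds the worm-wide copy number
    is replicated up along a linear ramp from ``egg_copies`` to the adult
    target, each replication mutating with probability mu.  After the last
    round, cells are pruned uniformly at random to exactly ``n_cells`` and
    topped up to the adult copy-number target.  (The true *C. elegans*
    lineage is invariant and asynchronous; synchronous-division-plus-pruning
    is a deliberate approximation.)
    """
    rng = np.random.default_rng(seed)
    if founder_mut > p.egg_copies:
        raise ValueError("founder_mut exceeds egg_copies")
    rounds = max(1, math.ceil(math.log2(p.n_cells)))
    wt = np.array([p.egg_copies - founder_mut], dtype=np.int64)
    mut = np.array([founder_mut], dtype=np.int64)
    for k in range(1, rounds + 1):
        # replicate up to the ramp target for this round
        ramp_target = round(
            p.egg_copies + (p.copies_per_worm_target - p.egg_copies) * k / rounds
        )
        tot = wt + mut
        add = ramp_target - int(tot.sum())
        if add > 0:
            per_cell = rng.multinomial(add, tot / tot.sum())
            wt, mut = _replicate(wt, mut, per_cell, p.mu, rng)
        # synchronous binary division, binomial molecule partitioning
        wt_d = rng.binomial(wt, 0.5)
        mut_d = rng.binomial(mut, 0.5)
        wt = np.concatenate([wt_d, wt - wt_d])
        mut = np.concatenate([mut_d, mut - mut_d])
    if wt.size > p.n_cells:
        keep = rng.choice(wt.size, size=p.n_cells, replace=False)
        wt, mut = wt[keep], mut[keep]
    # top up to the adult total after pruning
    tot = wt + mut
    add = p.copies_per_worm_target - int(tot.sum())
    if add > 0:
        per_cell = rng.multinomial(add, tot / tot.sum())
        wt, mut = _replicate(wt, mut, per_cell, p.mu, rng)
    return WormState(wt=wt, mut=mut, age_days=float(p.dev_duration_days))


def step_counts(wt, mut, target, p_death, mu, rng, replenish=True):
    """One turnover step on parallel arrays of cells.

    Degrade each molecule independently with probability ``p_death``, then
    replicate back to ``target`` by uniform-with-replacement template choice
    among survivors (immediate-restore copy-number control).  Cells left with
    zero molecules are replenished as all wild type when ``replenish`` else
    left extinct.
    """
    dw = rng.binomial(wt, p_death)
    dm = rng.binomial(mut, p_death)
    surv_w = wt - dw
    surv_m = mut - dm
    surv = surv_w + surv_m
    extinct = surv == 0
    deficit = np.maximum(np.asarray(target) - surv, 0)
    deficit = np.where(extinct, 0, deficit)
    new_w, new_m = _replicate(surv_w, surv_m, deficit, mu, rng)
    if replenish:
        new_w = np.where(extinct, np.asarray(target), new_w)
        new_m = np.where(extinct, 0, new_m)
    return new_w, new_m


def step_turnover(w: WormState, p: SimParams, seed: Optional[int] = None, rng=None) -> WormState:
    """Advance a worm by one time step ``p.dt_days`` of mtDNA turnover."""
    if rng is None:
        rng = np.random.default_rng(seed)
    wt, mut = step_counts(
        w.wt,
        w.mut,
        p.cell_target,
        p.death_prob_per_step,
        p.mu,
        rng,
        replenish=p.replenish_on_extinction,
    )
    return WormState(wt=wt, mut=mut, age_days=w.age_days + p.dt_days)


def simulate_lifespan(
    p: SimParams,
    t_end_days: float,
    record_every: float = 1.0,
    seed: int = 0,
    founder_mut: int = 0,
):
    """Develop a worm and run turnover to ``t_end_days``, recording summaries.

    Returns a pandas DataFrame with columns age_days, total_mut,
    max_fraction, p50_fraction, p95_fraction, total_copies.
    """
    import pandas as pd

    if t_end_days <= 0:
        raise ValueError("t_end_days must be positive")
    rng = np.random.default_rng(seed)
    w = run_development(p, seed=int(rng.integers(2**31 - 1)), founder_mut=founder_mut)
    records = []

    def record(state):
        f = state.fractions
        records.append(
            {
                "age_days": state.age_days,
                "total_mut": state.total_mut,
                "max_fraction": state.max_fraction,
                "p50_fraction": float(np.median(f)),
                "p95_fraction": float(np.quantile(f, 0.95)),
                "total_copies": state.total_copies,
            }
        )

    record(w)
    next_record = w.age_days + record_every
    while w.age_days < t_end_days - 1e-9:
        w = step_turnover(w, p, rng=rng)
        if w.age_days + 1e-9 >= next_record or w.age_days >= t_end_days - 1e-9:
            record(w)
            next_record += record_every
    return pd.DataFrame.from_records(records)


@dataclass
class FirstPassageResult:
    """First-passage ages (days) of the threshold crossing, one per worm."""

    times_days: np.ndarray
    capped: np.ndarray
    t_cap_days: float
    params: SimParams

    @property
    def mean_days(self) -> float:
        return float(self.times_days.mean())

    @property
    def mean_years(self) -> float:
        return self.mean_days / 365.0

    @property
    def capped_fraction(self) -> float:
        return float(self.capped.mean())

    def quantiles(self, qs=(0.1, 0.5, 0.9)) -> dict:
        return {q: float(np.quantile(self.times_days, q)) for q in qs}

    def to_dict(self) -> dict:
        return {
            "n_worms": int(self.times_days.size),
            "mean_days": self.mean_days,
            "mean_years": self.mean_years,
            "quantiles_days": self.quantiles(),
            "capped_fraction": self.capped_fraction,
            "t_cap_days": self.t_cap_days,
            "half_life_days": self.params.half_life_days,
            "mu": self.params.mu,
            "threshold": self.params.threshold,
        }


def first_passage_time(
    p: SimParams,
    n_worms: int = 25,
    t_cap_days: float = 30 * 365.0,
    seed: int = 0,
) -> FirstPassageResult:
    """Age at which the first of a worm's cells reaches the mutant-fraction
    threshold, simulated independently for ``n_worms`` worms.

    Worms that never cross by ``t_cap_days`` enter the mean at the cap and
    are reported through ``capped_fraction`` rather than dropped.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    master = np.random.default_rng(seed)
    times = np.empty(n_worms)
    capped = np.zeros(n_worms, dtype=bool)
    thr = p.threshold
    target = p.cell_target
    p_death = p.death_prob_per_step
    for i in range(n_worms):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        w = run_development(p, seed=int(rng.integers(2**31 - 1)))
        age = w.age_days
        wt, mut = w.wt, w.mut
        # development may already have produced a crossing (relevant only for
        # seeded founders or extreme mu)
        if (mut / np.maximum(wt + mut, 1)).max() >= thr:
            times[i] = age
            continue
        while age < t_cap_days:
            wt, mut = step_counts(
                wt, mut, target, p_death, p.mu, rng, p.replenish_on_extinction
            )
            age += p.dt_days
            # cheap prefilter (valid while totals are >= target, which holds
            # under immediate-restore): only inspect fractions when some cell
            # could plausibly be over threshold
            if not p.replenish_on_extinction or mut.max() >= thr * target:
                if (mut / np.maximum(wt + mut, 1)).max() >= thr:
                    break
        if age >= t_cap_days:
            times[i] = t_cap_days
            capped[i] = True
        else:
            times[i] = age
    return FirstPassageResult(times_days=times, capped=capped, t_cap_days=t_cap_days, params=p)


# ---------------------------------------------------------------------------
# exact event-driven reference engine (single cell)
# ---------------------------------------------------------------------------


def gillespie_cell(
    n: int,
    half_life_days: float,
    mu: float,
    m0: int,
    t_end_days: float,
    seed: int = 0,
    record_times: Optional[np.ndarray] = None,
):
    """Exact Moran-type SSA for one cell at fixed copy number ``n``.

    Events occur at rate ``n * ln2/t_half``: a uniformly chosen molecule dies
    and is replaced by a copy of a uniformly chosen survivor; wild-type
    templates mutate with probability mu.  Returns (final mutant count,
    absorption flag, recorded mutant counts at ``record_times``).
    """
    rng = np.random.default_rng(seed)
    rate = n * math.log(2.0) / half_life_days
    t = 0.0
    m = int(m0)
    recorded = []
    rec = list(record_times) if record_times is not None else []
    ri = 0
    while True:
        dt = rng.exponential(1.0 / rate)
        t_next = t + dt
        while ri < len(rec) and rec[ri] <= t_next:
            recorded.append(m)
            ri += 1
        if t_next >= t_end_days:
            break
        t = t_next
        die_mut = rng.random() < m / n
        m_surv = m - int(die_mut)
        template_mut = rng.random() < m_surv / (n - 1)
        if template_mut:
            new_mut = True
        else:
            new_mut = mu > 0 and rng.random() < mu
        m = m_surv + int(new_mut)
        if mu == 0 and (m == 0 or m == n):
            break
    while ri < len(rec):
        recorded.append(m)
        ri += 1
    return m, (m == 0 or m == n), np.array(recorded)


def validate_against_ssa(
    n: int = 20,
    half_life_days: float = 3.0,
    mu: float = 0.0,
    m0: int = 10,
    t_end_days: float = 60.0,
    n_runs: int = 500,
    dt_days: float = 0.25,
    checkpoints=(5.0, 10.0, 20.0, 40.0, 60.0),
    seed: int = 0,
) -> dict:
    """Compare the discrete-time stepper with the exact SSA on one small cell.

    Runs ``n_runs`` independent trajectories in both engines and reports the
    mean mutant fraction at the checkpoints plus the mutant-fixation
    probability (mu = 0).  Used by the test-suite as the model-correctness
    harness for the discrete-time approximation.
    """
    rng = np.random.default_rng(seed)
    cps = np.asarray(checkpoints, dtype=float)
    # exact engine
    ssa_frac = np.zeros((n_runs, cps.size))
    ssa_fixed = 0
    for i in range(n_runs):
        m_end, _, rec = gillespie_cell(
            n, half_life_days, mu, m0, t_end_days, seed=int(rng.integers(2**31 - 1)), record_times=cps
        )
        ssa_frac[i] = rec / n
        ssa_fixed += int(m_end == n)
    # discrete engine: one "worm" whose cells are independent replicate cells
    p_death = 1.0 - math.exp(-math.log(2.0) / half_life_days * dt_days)
    wt = np.full(n_runs, n - m0, dtype=np.int64)
    mut = np.full(n_runs, m0, dtype=np.int64)
    t = 0.0
    disc_frac = np.zeros((n_runs, cps.size))
    ci = 0
    while t < t_end_days - 1e-9:
        wt, mut = step_counts(wt, mut, n, p_death, mu, rng, replenish=True)
        t += dt_days
        while ci < cps.size and cps[ci] <= t + 1e-9:
            disc_frac[:, ci] = mut / (wt + mut)
            ci += 1
    disc_fixed = int((mut == n).sum())
    return {
        "checkpoints": cps,
        "ssa_mean_fraction": ssa_frac.mean(axis=0),
        "ssa_se_fraction": ssa_frac.std(axis=0, ddof=1) / math.sqrt(n_runs),
        "discrete_mean_fraction": disc_frac.mean(axis=0),
        "discrete_se_fraction": disc_frac.std(axis=0, ddof=1) / math.sqrt(n_runs),
        "ssa_fixation_prob": ssa_fixed / n_runs,
        "discrete_fixation_prob": disc_fixed / n_runs,
        "n_runs": n_runs,
    }
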