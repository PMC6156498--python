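"""Digital-PCR random mutation capture: simulation, calibration, inversion.

The wet assay pools thousands of worms, extracts mtDNA, dilutes to a working
stock of ~10,000 molecules/ul and aliquots 1 ul into each of 236 wells, one
primer pair per well.  Wild type cannot amplify, so an amplified well implies
>= 1 deletion-bearing molecule compatible with that well's pair.  Because the
mutant copy number is tiny, the whole chain is a cascade of finite-population
sampling events; every step here is a draw without replacement
(hypergeometric), making the simulated well-count distribution exact for the
stated design.

Quantification inverts this chain: a Monte Carlo calibration maps each virtual
homogenate mutant fraction to a distribution of amplified-well counts, and
observed counts are converted to a maximum-likelihood fraction with a 95%
interval read off the same distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import constants
from .genome import Deletion
from .panel import PrimerPanel, is_amplifiable

__all__ = [
    "DeletionSpectrum",
    "UniformDeletionSpectrum",
    "FixedDeletionSpectrum",
    "Homogenate",
    "CaptureDesign",
    "WellOutcome",
    "CaptureResult",
    "CalibrationCurve",
    "MutantFractionEstimate",
    "BurdenReport",
    "simulate_capture",
    "simulate_replicates",
    "build_calibration",
    "estimate_fraction",
    "burden_per_worm",
    "trend_test",
]


# ---------------------------------------------------------------------------
# deletion spectrum priors
# ---------------------------------------------------------------------------


class DeletionSpectrum:
    """Distribution over deletion breakpoints used for virtual mutants."""

    id: str = "abstract"

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def pair_detectabilities(
        self, panel: PrimerPanel, n_mc: int = 200_000, seed: int = 7
    ) -> np.ndarray:
        """Per-pair probability that one spectrum draw is amplifiable.

        Estimated once by Monte Carlo; used by the vectorized calibration.
        """
        rng = np.random.default_rng(seed)
        b5, b3 = self.sample(rng, n_mc)
        m = panel.amplifiable_matrix(b5, b3)
        return m.mean(axis=0)


@dataclass
class UniformDeletionSpectrum(DeletionSpectrum):
    """Sporadic prior: two i.i.d. uniform breakpoints in the scanned window,
    ordered, conditioned on length >= min_len (default 500 bp)."""

    region_lo: int = constants.REGION_LO
    region_hi: int = constants.REGION_HI
    min_len: int = 500
    id: str = "uniform-breakpoints"

    def sample(self, rng, n):
        out5 = np.empty(n, dtype=np.int64)
        out3 = np.empty(n, dtype=np.int64)
        got = 0
        while got < n:
            m = max(int((n - got) * 1.3) + 16, 32)
            b1 = rng.integers(self.region_lo, self.region_hi + 1, m)
            b2 = rng.integers(self.region_lo, self.region_hi + 1, m)
            b5 = np.minimum(b1, b2)
            b3 = np.maximum(b1, b2)
            keep = (b3 - b5 + 1) >= self.min_len
            k = min(int(keep.sum()), n - got)
            out5[got : got + k] = b5[keep][:k]
            out3[got : got + k] = b3[keep][:k]
            got += k
        return out5, out3


@dataclass
class FixedDeletionSpectrum(DeletionSpectrum):
    """Degenerate/hotspot prior concentrated on explicit deletions."""

    deletions: Sequence[Deletion] = ()
    weights: Optional[Sequence[float]] = None
    id: str = "fixed"

    def sample(self, rng, n):
        k = len(self.deletions)
        if k == 0:
            raise ValueError("empty fixed spectrum")
        w = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            w = w / w.sum()
        idx = rng.choice(k, size=n, p=w)
        b5 = np.array([d.b5 for d in self.deletions])[idx]
        b3 = np.array([d.b3 for d in self.deletions])[idx]
        return b5, b3


# ---------------------------------------------------------------------------
# experiment containers
# ---------------------------------------------------------------------------


@dataclass
class Homogenate:
    """Pooled-worm mtDNA sample.

    ``mutants`` maps deletion species to copy counts.  A species keyed by
    None is the *sporadic pool*: each of its copies is an independent draw
    from the spectrum, materialized lazily at capture time (the natural model
    for de novo deletions, which are essentially all distinct).
    """

    total_copies: int
    mutants: list[tuple[Optional[Deletion], int]] = field(default_factory=list)

    def __post_init__(self):
        if self.total_copies <= 0:
            raise ValueError("total_copies must be positive")
        if any(c < 0 for _, c in self.mutants):
            raise ValueError("negative mutant copy count")
        if self.mutant_copies > self.total_copies:
            raise ValueError("mutant copies exceed total copies")

    @property
    def mutant_copies(self) -> int:
        return sum(c for _, c in self.mutants)

    @property
    def mutant_fraction(self) -> float:
        return self.mutant_copies / self.total_copies

    @classmethod
    def sporadic(cls, total_copies: int, mutant_fraction: float) -> "Homogenate":
        m = int(round(mutant_fraction * total_copies))
        return cls(total_copies=total_copies, mutants=[(None, m)])


@dataclass(frozen=True)
class CaptureDesign:
    """Sampling-chain design of one mutation capture experiment."""

    n_wells: int = 236
    molecules_per_well: int = 10_000
    extraction_efficiency: float = 1.0
    working_stock_copies: int = 2_360_000
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    n_worms: int = 5_000
    copies_per_worm: int = constants.COPIES_PER_WORM

    def __post_init__(self):
        if not 0 < self.extraction_efficiency <= 1:
            raise ValueError("extraction_efficiency must be in (0, 1]")
        if self.n_wells * self.molecules_per_well > self.working_stock_copies:
            raise ValueError(
                "working stock holds fewer molecules than the wells demand"
            )

    @property
    def homogenate_copies(self) -> int:
        return self.n_worms * self.copies_per_worm


@dataclass(frozen=True)
class WellOutcome:
    pair_name: str
    amplified: bool
    detected: Optional[Deletion]  # amplifiable deletion with shortest product
    deletions_present: tuple[Deletion, ...]


@dataclass
class CaptureResult:
    per_well: list[WellOutcome]

    @property
    def amplified_wells(self) -> int:
        return sum(w.amplified for w in self.per_well)

    @property
    def detections(self) -> list[Deletion]:
        return [w.detected for w in self.per_well if w.detected is not None]


# ---------------------------------------------------------------------------
# sampling-chain internals
# ---------------------------------------------------------------------------


_NP_HYPERGEOM_CAP = 1_000_000_000  # numpy restriction on ngood/nbad


def _rhyper(rng, ngood: int, nbad: int, nsample: int, size=None):
    """Hypergeometric draws valid for populations beyond numpy's 1e9 cap.

    For large populations, samples exactly from the pmf restricted to a
    +-12 SD window around the mode (truncated mass < 1e-30).
    """
    if ngood < _NP_HYPERGEOM_CAP and nbad < _NP_HYPERGEOM_CAP:
        return rng.hypergeometric(ngood, nbad, nsample, size=size)
    from scipy.special import gammaln

    n_total = ngood + nbad
    mean = nsample * ngood / n_total
    var = (
        nsample
        * (ngood / n_total)
        * (nbad / n_total)
        * (n_total - nsample)
        / max(n_total - 1, 1)
    )
    sd = np.sqrt(var)
    lo = int(max(0, nsample - nbad, np.floor(mean - 12 * sd - 5)))
    hi = int(min(ngood, nsample, np.ceil(mean + 12 * sd + 5)))
    if lo >= hi:
        out = np.full(size if size is not None else (), lo, dtype=np.int64)
        return out if size is not None else int(out)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(ngood + 1)
        - gammaln(k + 1)
        - gammaln(ngood - k + 1)
        + gammaln(nbad + 1)
        - gammaln(nsample - k + 1)
        - gammaln(nbad - nsample + k + 1)
    )
    logpmf -= logpmf.max()
    p = np.exp(logpmf)
    p /= p.sum()
    idx = rng.choice(k.size, size=size, p=p)
    return k[idx] + 0 if size is not None else int(k[idx])


def _hypergeom_split(rng, counts: np.ndarray, nsample: int) -> np.ndarray:
    """Draw without replacement ``nsample`` items from colored population
    ``counts`` (conditional/marginals method; exact multivariate
    hypergeometric)."""
    counts = np.asarray(counts, dtype=np.int64)
    out = np.zeros_like(counts)
    remaining = int(counts.sum())
    left = int(nsample)
    if left > remaining:
        raise ValueError("sample larger than population")
    for i, c in enumerate(counts[:-1]):
        if left == 0:
            break
        x = int(_rhyper(rng, int(c), remaining - int(c), left))
        out[i] = x
        left -= x
        remaining -= int(c)
    out[-1] = left if counts.size else 0
    return out


def _draw_stock(h, design, rng):
    """Extraction + dilution: mutant species counts in one working stock."""
    species = [d for d, _ in h.mutants]
    counts = np.array([c for _, c in h.mutants] + [h.total_copies - h.mutant_copies])
    recovered_total = int(round(design.extraction_efficiency * h.total_copies))
    if design.working_stock_copies > recovered_total:
        raise ValueError("working stock demands more molecules than recovered")
    recovered = _hypergeom_split(rng, counts, recovered_total)
    stock = _hypergeom_split(rng, recovered, design.working_stock_copies)
    return species, stock


def _plate_and_read(species, stock, panel, design, spectrum, rng):
    """Partition the working stock across wells and score amplification."""
    n_wells = design.n_wells
    mpw = design.molecules_per_well
    counts = stock.copy()
    outcomes: list[WellOutcome] = []
    L = panel.config.L_max
    for j in range(n_wells):
        pair = panel.pairs[j]
        well = _hypergeom_split(rng, counts, mpw)
        counts = counts - well
        # species aligns with well[:-1]; the last color is wild type
        present: list[Deletion] = []
        for idx, d in enumerate(species):
            c = int(well[idx])
            if c == 0:
                continue
            if d is None:
                b5, b3 = spectrum.sample(rng, c)
                present.extend(Deletion(int(a), int(b)) for a, b in zip(b5, b3))
            else:
                present.extend([d] * c)
        amplifiable = [d for d in present if is_amplifiable(pair, d, L)]
        amplified = len(amplifiable) > 0
        if amplified and design.false_negative_rate > 0:
            if rng.random() < design.false_negative_rate:
                amplified = False
        if not amplified and design.false_positive_rate > 0:
            if rng.random() < design.false_positive_rate:
                amplified = True
        detected = None
        if amplified and amplifiable:
            # PCR favors the shortest product; sequencing reveals that deletion
            detected = min(amplifiable, key=lambda d: pair.wt_amplicon - d.length)
        outcomes.append(
            WellOutcome(
                pair_name=pair.name,
                amplified=amplified,
                detected=detected,
                deletions_present=tuple(present),
            )
        )
    return outcomes, counts


def simulate_capture(
    h: Homogenate,
    panel: PrimerPanel,
    design: CaptureDesign,
    seed: int = 0,
    spectrum: Optional[DeletionSpectrum] = None,
) -> CaptureResult:
    """Simulate one full mutation capture experiment.

    Chain: extraction (hypergeometric at ``extraction_efficiency``), dilution
    to the working stock, sequential without-replacement plating of
    ``molecules_per_well`` into each well, then the binary fluorescence
    readout with optional false positive/negative flips.  Deterministic under
    a fixed seed.
    """
    if len(panel) != design.n_wells:
        raise ValueError(
            f"panel has {len(panel)} pairs but design expects {design.n_wells} wells "
            "(one pair per well)"
        )
    rng = np.random.default_rng(seed)
    spectrum = spectrum or UniformDeletionSpectrum()
    species, stock = _draw_stock(h, design, rng)
    outcomes, _ = _plate_and_read(species, stock, panel, design, spectrum, rng)
    return CaptureResult(per_well=outcomes)


def simulate_replicates(
    h: Homogenate,
    panel: PrimerPanel,
    design: CaptureDesign,
    n_replicates: int,
    seed: int = 0,
    spectrum: Optional[DeletionSpectrum] = None,
) -> list[CaptureResult]:
    """Replicate capture experiments drawing successive working stocks,
    without replacement, from a single extracted sample.

    Molecules consumed by one replicate are unavailable to the next, so a
    single-copy species can never be re-detected across replicates — the
    property that makes within-cohort repeat detections informative about
    copy number (mini clonal expansion) rather than chance.
    """
    if len(panel) != design.n_wells:
        raise ValueError("panel size must match design.n_wells")
    if n_replicates * design.working_stock_copies > int(
        round(design.extraction_efficiency * h.total_copies)
    ):
        raise ValueError("extract too small for the requested replicates")
    rng = np.random.default_rng(seed)
    spectrum = spectrum or UniformDeletionSpectrum()
    species = [d for d, _ in h.mutants]
    counts = np.array([c for _, c in h.mutants] + [h.total_copies - h.mutant_copies])
    recovered_total = int(round(design.extraction_efficiency * h.total_copies))
    counts = _hypergeom_split(rng, counts, recovered_total)
    results = []
    for _ in range(n_replicates):
        stock = _hypergeom_split(rng, counts, design.working_stock_copies)
        counts = counts - stock
        outcomes, _ = _plate_and_read(species, stock, panel, design, spectrum, rng)
        results.append(CaptureResult(per_well=outcomes))
    return results


# ---------------------------------------------------------------------------
# calibration curve
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Monte Carlo map from homogenate mutant fraction to the distribution of
    amplified-well counts."""

    fractions: np.ndarray  # strictly increasing grid
    pmf: np.ndarray  # shape (n_fractions, n_wells + 1), rows sum to 1
    reps: int
    design: CaptureDesign
    spectrum_id: str
    seed: int

    @property
    def n_wells(self) -> int:
        return self.pmf.shape[1] - 1

    def mean_counts(self) -> np.ndarray:
        return self.pmf @ np.arange(self.pmf.shape[1])

    def smoothed_pmf(self) -> np.ndarray:
        """Add-half Laplace smoothing so unseen counts keep finite likelihood."""
        k = self.pmf.shape[1]
        return (self.pmf * self.reps + 0.5) / (self.reps + 0.5 * k)

    def to_json(self, path) -> None:
        payload = {
            "fractions": self.fractions.tolist(),
            "pmf": self.pmf.tolist(),
            "reps": self.reps,
            "design": self.design.__dict__,
            "spectrum_id": self.spectrum_id,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            fractions=np.asarray(payload["fractions"], dtype=float),
            pmf=np.asarray(payload["pmf"], dtype=float),
            reps=int(payload["reps"]),
            design=CaptureDesign(**payload["design"]),
            spectrum_id=payload["spectrum_id"],
            seed=int(payload["seed"]),
        )


def _counts_at_fraction(
    fraction: float,
    q: np.ndarray,
    design: CaptureDesign,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplified-well counts for ``reps`` virtual experiments at one fraction.

    Aggregated sampler, exact in distribution for a sporadic spectrum: mutant
    copies are exchangeable, so the chain reduces to scalar hypergeometric
    draws of the aggregate mutant count (extraction, dilution, then one draw
    per well), and each mutant molecule in well ``j`` is independently
    amplifiable with the pair's spectrum detectability ``q[j]``.
    """
    total = design.homogenate_copies
    m0 = int(round(fraction * total))
    # nested without-replacement draws collapse: the working stock is
    # marginally a uniform subset of the homogenate, so extraction + dilution
    # reduce to a single hypergeometric draw per virtual experiment
    if m0 > 0:
        stock = _rhyper(rng, m0, total - m0, design.working_stock_copies, size=reps)
    else:
        stock = np.zeros(reps, dtype=np.int64)
    remaining_mut = np.asarray(stock, dtype=np.int64)
    remaining_tot = np.full(reps, design.working_stock_copies, dtype=np.int64)
    counts = np.zeros(reps, dtype=np.int64)
    mpw = design.molecules_per_well
    fp, fn = design.false_positive_rate, design.false_negative_rate
    for j in range(design.n_wells):
        nbad = remaining_tot - remaining_mut
        c = np.where(
            remaining_mut > 0,
            rng.hypergeometric(np.maximum(remaining_mut, 1), nbad, mpw),
            0,
        )
        amp = rng.binomial(c, q[j]) >= 1
        if fn > 0:
            amp &= rng.random(reps) >= fn
        if fp > 0:
            amp |= rng.random(reps) < fp
        counts += amp
        remaining_mut -= c
        remaining_tot -= mpw
    return counts


def build_calibration(
    panel: PrimerPanel,
    design: CaptureDesign,
    fraction_grid: Sequence[float],
    reps: int = 1000,
    spectrum: Optional[DeletionSpectrum] = None,
    seed: int = 0,
) -> CalibrationCurve:
    """Calibration curve: for each virtual mutant fraction, repeat the whole
    in silico sampling experiment ``reps`` times and record the empirical
    distribution of amplified-well counts."""
    grid = np.asarray(list(fraction_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty fraction grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("fraction grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > 1e-2:
        raise ValueError("fraction grid must lie within [0, 1e-2]")
    if reps < 100:
        import warnings

        warnings.warn("reps < 100: confidence intervals will be poorly resolved")
    if len(panel) != design.n_wells:
        raise ValueError("panel size must match design.n_wells")
    spectrum = spectrum or UniformDeletionSpectrum(
        region_lo=panel.config.region_lo, region_hi=panel.config.region_hi
    )
    rng = np.random.default_rng(seed)
    q = spectrum.pair_detectabilities(panel)
    pmf = np.zeros((grid.size, design.n_wells + 1))
    for i, f in enumerate(grid):
        counts = _counts_at_fraction(float(f), q, design, reps, rng)
        pmf[i] = np.bincount(counts, minlength=design.n_wells + 1) / reps
    return CalibrationCurve(
        fractions=grid,
        pmf=pmf,
        reps=reps,
        design=design,
        spectrum_id=spectrum.id,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# inversion: observed counts -> mutant fraction
# ---------------------------------------------------------------------------


@dataclass
class MutantFractionEstimate:
    point: float
    ci_lo: float
    ci_hi: float
    observed_counts: list[int]
    copies_per_worm: int = constants.COPIES_PER_WORM
    clamped: bool = False

    @property
    def per_worm_burden(self) -> float:
        return self.point * self.copies_per_worm


def estimate_fraction(
    observed: Sequence[float], curve: CalibrationCurve
) -> MutantFractionEstimate:
    """Invert observed amplified-well counts through the calibration curve.

    The point estimate maximizes the product of (smoothed) empirical count
    probabilities over the fraction grid, refined by quadratic interpolation
    of the log-likelihood in log10(fraction).  The 95% interval inverts the
    Monte Carlo count distributions at the observed median count
    (Clopper-Pearson style): the lowest grid fraction whose upper tail at the
    median reaches 2.5% and the highest whose lower tail does.
    """
    obs = [int(round(c)) for c in observed]
    if len(obs) == 0:
        raise ValueError("no observed counts")
    if any(c < 0 or c > curve.n_wells for c in obs):
        raise ValueError("observed count outside [0, n_wells]")
    sm = curve.smoothed_pmf()
    loglik = np.log(sm[:, obs]).sum(axis=1)
    i = int(np.argmax(loglik))
    point = float(curve.fractions[i])
    # log-quadratic refinement around the grid argmax (positive fractions only)
    if 0 < i < curve.fractions.size - 1 and np.all(curve.fractions[i - 1 : i + 2] > 0):
        x = np.log10(curve.fractions[i - 1 : i + 2])
        y = loglik[i - 1 : i + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
        if a < 0:
            xv = -b / (2 * a)
            if x[0] <= xv <= x[2]:
                point = float(10**xv)
    med = int(np.median(obs))
    upper_tail = curve.pmf[:, med:].sum(axis=1)  # P(count >= med | f)
    lower_tail = curve.pmf[:, : med + 1].sum(axis=1)  # P(count <= med | f)
    lo_ok = np.nonzero(upper_tail >= 0.025)[0]
    hi_ok = np.nonzero(lower_tail >= 0.025)[0]
    clamped = lo_ok.size == 0 or hi_ok.size == 0
    ci_lo = float(curve.fractions[lo_ok[0]]) if lo_ok.size else float(curve.fractions[0])
    ci_hi = float(curve.fractions[hi_ok[-1]]) if hi_ok.size else float(curve.fractions[-1])
    ci_lo = min(ci_lo, point)
    ci_hi = max(ci_hi, point)
    return MutantFractionEstimate(
        point=point,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        observed_counts=obs,
        copies_per_worm=curve.design.copies_per_worm,
        clamped=clamped,
    )


@dataclass(frozen=True)
class BurdenReport:
    per_worm: float
    per_worm_ci: tuple[float, float]
    per_cell: float
    copies_per_worm: int
    n_cells: int = constants.N_CELLS


def burden_per_worm(
    est: MutantFractionEstimate,
    copies_per_worm: int = constants.COPIES_PER_WORM,
    n_cells: int = constants.N_CELLS,
) -> BurdenReport:
    """Scale a mutant-fraction estimate to molecules/worm and per-cell mean."""
    if copies_per_worm <= 0:
        raise ValueError("copies_per_worm must be positive")
    per_worm = est.point * copies_per_worm
    return BurdenReport(
        per_worm=per_worm,
        per_worm_ci=(est.ci_lo * copies_per_worm, est.ci_hi * copies_per_worm),
        per_cell=per_worm / n_cells,
        copies_per_worm=copies_per_worm,
        n_cells=n_cells,
    )


def trend_test(estimates: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS of mutant fraction on age; returns (slope, two-sided p for slope=0)."""
    if len(estimates) < 3:
        raise ValueError("need >= 3 (age, fraction) points")
    ages = np.array([a for a, _ in estimates], dtype=float)
    fracs = np.array([f for _, f in estimates], dtype=float)
    if np.all(ages == ages[0]):
        raise ValueError("all ages identical")
    res = stats.linregress(ages, fracs)
    pvalue = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), pvalue
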