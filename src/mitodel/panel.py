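"""Primer-pair geometry and Monte Carlo deletion-detection coverage.

The random mutation capture assay scans a ~9 kb window of the mitochondrial
genome with forward/reverse primer pairs whose wild-type amplicon is too long
to amplify under the PCR conditions; a pair produces signal only when a
deletion shortens the template below the maximum amplifiable product length
``L_max``.  A pair detects deletion ``d`` iff both primer sites survive
(``fwd.end < d.b5`` and ``d.b3 < rev.start``) and the deleted-template
amplicon ``wt_amplicon - len(d)`` is at most ``L_max``.

Coordinates are 1-based closed template intervals on the plus strand; reverse
primers are stored by their template footprint, not their 5'->3' sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Deletion

__all__ = [
    "Primer",
    "PrimerPair",
    "PanelConfig",
    "PrimerPanel",
    "CoverageReport",
    "build_panel",
    "load_panel",
    "is_amplifiable",
    "amplifying_pairs",
    "coverage_monte_carlo",
]

_ORIENTATIONS = {
    "F": "forward",
    "FWD": "forward",
    "FORWARD": "forward",
    "R": "reverse",
    "REV": "reverse",
    "REVERSE": "reverse",
}


@dataclass(frozen=True)
class Primer:
    name: str
    orientation: str  # "forward" | "reverse"
    start: int  # 1-based leftmost template position
    end: int  # 1-based rightmost template position
    sequence: Optional[str] = None

    def __post_init__(self):
        ori = _ORIENTATIONS.get(str(self.orientation).upper())
        if ori is None:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        object.__setattr__(self, "orientation", ori)
        if self.start > self.end:
            raise ValueError(f"primer {self.name}: start > end")
        if self.start < 1:
            raise ValueError(f"primer {self.name}: start < 1")


@dataclass(frozen=True)
class PrimerPair:
    fwd: Primer
    rev: Primer

    def __post_init__(self):
        if self.fwd.orientation != "forward" or self.rev.orientation != "reverse":
            raise ValueError("pair must be (forward, reverse)")
        if not self.fwd.end < self.rev.start:
            raise ValueError(
                f"pair {self.name}: forward primer must lie strictly upstream"
            )

    @property
    def name(self) -> str:
        return f"{self.fwd.name}|{self.rev.name}"

    @property
    def wt_amplicon(self) -> int:
        """Wild-type product length, outer edge to outer edge."""
        return self.rev.end - self.fwd.start + 1


@dataclass(frozen=True)
class PanelConfig:
    """Panel-wide constants.

    L_max is the maximum product length amplifiable under the PCR conditions
    (default 1,000 bp for a 75 s combined annealing/extension step);
    region_lo..region_hi is the scanned window.  pair_span_cap optionally
    limits wild-type amplicon length during pair enumeration.
    """

    L_max: int = 1000
    region_lo: int = 1800
    region_hi: int = 10800
    pair_span_cap: Optional[int] = None

    def __post_init__(self):
        if self.L_max <= 0:
            raise ValueError("L_max must be positive")
        if not self.region_lo < self.region_hi:
            raise ValueError("region_lo must be < region_hi")


@dataclass
class PrimerPanel:
    primers: list[Primer]
    pairs: list[PrimerPair]
    config: PanelConfig
    # cached plus-strand geometry arrays for vectorized predicates
    _geom: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            if p.wt_amplicon <= self.config.L_max:
                raise ValueError(
                    f"pair {p.name}: wild-type amplicon {p.wt_amplicon} bp would "
                    f"amplify (L_max = {self.config.L_max})"
                )
            if p.name in seen:
                raise ValueError(f"duplicate pair {p.name}")
            seen.add(p.name)
        self._geom = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def geometry(self) -> dict:
        """Arrays (fwd_start, fwd_end, rev_start, rev_end, wt_amplicon)."""
        if self._geom is None:
            self._geom = {
                "fwd_start": np.array([p.fwd.start for p in self.pairs]),
                "fwd_end": np.array([p.fwd.end for p in self.pairs]),
                "rev_start": np.array([p.rev.start for p in self.pairs]),
                "rev_end": np.array([p.rev.end for p in self.pairs]),
                "wt_amplicon": np.array([p.wt_amplicon for p in self.pairs]),
            }
        return self._geom

    def amplifiable_matrix(self, b5, b3, L_max: Optional[int] = None) -> np.ndarray:
        """Boolean matrix (n_deletions, n_pairs) of the amplifiability predicate."""
        L = self.config.L_max if L_max is None else L_max
        g = self.geometry
        b5 = np.asarray(b5)[:, None]
        b3 = np.asarray(b3)[:, None]
        length = b3 - b5 + 1
        mut_amp = g["wt_amplicon"][None, :] - length
        return (g["fwd_end"][None, :] < b5) & (b3 < g["rev_start"][None, :]) & (
            mut_amp <= L
        )


def build_panel(
    primers: Sequence[Primer],
    config: PanelConfig,
    explicit_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> PrimerPanel:
    """Assemble a panel from primers, enumerating valid pairs.

    Without an explicit pair list, keeps every forward x reverse combination
    with the forward strictly upstream whose wild-type amplicon exceeds L_max
    (wild type must not amplify) and, if configured, does not exceed
    pair_span_cap.
    """
    primers = list(primers)
    fwd = {p.name: p for p in primers if p.orientation == "forward"}
    rev = {p.name: p for p in primers if p.orientation == "reverse"}
    pairs: list[PrimerPair] = []
    if explicit_pairs is not None:
        for fname, rname in explicit_pairs:
            if fname not in fwd or rname not in rev:
                raise ValueError(f"unknown primer in explicit pair ({fname}, {rname})")
            pairs.append(PrimerPair(fwd[fname], rev[rname]))
    else:
        for f in fwd.values():
            for r in rev.values():
                if f.end >= r.start:
                    continue
                wt = r.end - f.start + 1
                if wt <= config.L_max:
                    continue
                if config.pair_span_cap is not None and wt > config.pair_span_cap:
                    continue
                pairs.append(PrimerPair(f, r))
        pairs.sort(key=lambda p: (p.fwd.start, p.rev.start))
    return PrimerPanel(primers=primers, pairs=pairs, config=config)


def load_panel(
    tsv_path,
    config: PanelConfig = PanelConfig(),
    explicit_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> PrimerPanel:
    """Read a primer TSV (columns: name, orientation, start, end[, sequence])."""
    df = pd.read_csv(tsv_path, sep="\t")
    for col in ("name", "orientation", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"primer TSV missing column {col!r}")
    primers = [
        Primer(
            name=str(r.name),
            orientation=str(r.orientation),
            start=int(r.start),
            end=int(r.end),
            sequence=str(r.sequence) if "sequence" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]
    return build_panel(primers, config, explicit_pairs)


def is_amplifiable(pair: PrimerPair, d: Deletion, L_max: int) -> bool:
    """True iff both primer sites survive the deletion and the shortened
    template is within the amplifiable length."""
    if not (pair.fwd.end < d.b5 and d.b3 < pair.rev.start):
        return False
    return pair.wt_amplicon - d.length <= L_max


def amplifying_pairs(panel: PrimerPanel, d: Deletion) -> list[PrimerPair]:
    """All panel pairs able to amplify deletion ``d``, in panel order."""
    L = panel.config.L_max
    return [p for p in panel.pairs if is_amplifiable(p, d, L)]


@dataclass(frozen=True)
class CoverageReport:
    coverage: float
    se: float
    retained: int
    n_samples: int
    min_len: int
    L_max: int
    seed: int
    mean_amplifying_pairs: float

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "retained": self.retained,
            "min_len": self.min_len,
            "L_max": self.L_max,
            "coverage": self.coverage,
            "se": self.se,
            "seed": self.seed,
            "mean_amplifying_pairs": self.mean_amplifying_pairs,
        }


def sample_random_deletions(
    rng: np.random.Generator,
    n: int,
    region_lo: int,
    region_hi: int,
    min_len: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Random deletion breakpoints: two i.i.d. uniform integer positions in
    [region_lo, region_hi], ordered, retaining deletions of length >= min_len.
    """
    b1 = rng.integers(region_lo, region_hi + 1, size=n)
    b2 = rng.integers(region_lo, region_hi + 1, size=n)
    b5 = np.minimum(b1, b2)
    b3 = np.maximum(b1, b2)
    keep = (b3 - b5 + 1) >= min_len
    return b5[keep], b3[keep]


def coverage_monte_carlo(
    panel: PrimerPanel,
    n_samples: int = 100_000,
    min_len: int = 500,
    seed: int = 0,
    L_max: Optional[int] = None,
) -> CoverageReport:
    """Fraction of random >= ``min_len`` bp deletions detectable by >= 1 pair.

    Breakpoints are sampled uniformly over the scanned window; the report
    carries the binomial standard error and the retained sample count.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = panel.config
    L = cfg.L_max if L_max is None else L_max
    b5, b3 = sample_random_deletions(rng, n_samples, cfg.region_lo, cfg.region_hi, min_len)
    retained = int(b5.size)
    if retained == 0:
        raise ValueError(
            "no sampled deletion satisfied the length filter; increase n_samples"
        )
    if len(panel) == 0:
        cov, mean_mult = 0.0, 0.0
    else:
        hit = np.zeros(retained, dtype=bool)
        mult = np.zeros(retained, dtype=np.int64)
        chunk = 50_000
        for lo in range(0, retained, chunk):
            m = panel.amplifiable_matrix(b5[lo : lo + chunk], b3[lo : lo + chunk], L_max=L)
            hit[lo : lo + chunk] = m.any(axis=1)
            mult[lo : lo + chunk] = m.sum(axis=1)
        cov = float(hit.mean())
        mean_mult = float(mult.mean())
    se = float(np.sqrt(cov * (1.0 - cov) / retained))
    return CoverageReport(
        coverage=cov,
        se=se,
        retained=retained,
        n_samples=n_samples,
        min_len=min_len,
        L_max=L,
        seed=seed,
        mean_amplifying_pairs=mean_mult,
    )
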