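"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the analysis consumes — reference genome, primer panel, cohort
detection tables, lesion time courses — can be generated here with a seed and
a truth manifest, so the whole package is testable without any downloaded
data.  The synthetic reference matches the *C. elegans* mitochondrial genome
length (13,794 bp) so coordinate conventions are exercised realistically, and
the canonical primer layout reproduces the documented panel geometry: 12
forward and 36 reverse primers over positions 1,800-10,800 forming exactly
236 valid pairs whose wild-type amplicons all exceed L_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants
from .genome import Deletion, MtReference, find_flanking_direct_repeat
from .panel import PanelConfig, Primer, PrimerPanel, build_panel
from .capture import (
    CaptureDesign,
    Homogenate,
    UniformDeletionSpectrum,
    simulate_replicates,
)
from .clonality import DetectionRecord, records_to_frame

__all__ = [
    "SynthSpec",
    "gen_reference",
    "gen_panel",
    "canonical_panel",
    "gen_cohort_detections",
    "gen_lesion_timecourse",
    "worked_example_detections",
]

_BASES = np.array(list("ACGT"))

# canonical 12F/36R layout (even spacing; chosen so that the wild-type
# non-amplification rule at the default L_max = 1000 bp yields exactly 236
# pairs while Monte Carlo detection coverage of >=500 bp deletions stays >95%)
_PRIMER_LEN = 20
_FWD_START_LO, _FWD_START_HI = 1800, 9375
_REV_END_LO, _REV_END_HI = 3150, 10_800


@dataclass
class SynthSpec:
    """Ground-truth knobs for the synthetic world."""

    ref_length: int = constants.MT_GENOME_LENGTH
    planted_repeats: Sequence[tuple[int, int]] = field(default_factory=list)  # (length, count)
    n_forward: int = 12
    n_reverse: int = 36
    region_lo: int = constants.REGION_LO
    region_hi: int = constants.REGION_HI
    L_max: int = 1000
    true_fraction: float = 2.7e-4
    clonal_weight: float = 0.0
    n_cohorts: int = 3
    replicates_per_cohort: int = 3
    age_days: int = 10
    decay_half_life_days: float = 5.0
    decay_noise_cv: float = 0.10
    copy_number_decline: float = 0.0  # fractional copy loss in aged homogenates

    def __post_init__(self):
        for name in ("true_fraction", "clonal_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ref_length <= self.region_hi:
            raise ValueError("ref_length must exceed region_hi")


# ---------------------------------------------------------------------------
# reference with planted junctional repeats
# ---------------------------------------------------------------------------


def _plant_repeat(seq: np.ndarray, d: Deletion, r: int, rng) -> None:
    """Force a start-anchored junctional repeat of exactly length r.

    Copies ``seq[b5 .. b5+r-1]`` onto ``seq[b3+1 .. b3+r]`` and breaks the
    r+1 extension so the planted length is maximal on that placement.
    """
    b5, b3 = d.b5 - 1, d.b3 - 1  # 0-based
    seq[b3 + 1 : b3 + 1 + r] = seq[b5 : b5 + r]
    if seq[b3 + 1 + r] == seq[b5 + r]:
        choices = [b for b in "ACGT" if b != seq[b5 + r]]
        seq[b3 + 1 + r] = choices[rng.integers(len(choices))]


def _break_repeat(seq: np.ndarray, d: Deletion, min_dr: int, max_len: int, rng) -> None:
    """Mutate near the junction until no flanking repeat >= min_dr remains."""
    for _ in range(50):
        ref = MtReference(id="tmp", sequence="".join(seq), circular=False)
        hit = find_flanking_direct_repeat(ref, d, min_len=min_dr, max_len=max_len)
        if hit is None:
            return
        # disrupt the downstream copy of the offending repeat
        pos = d.b3 if hit.side == "end-anchored" else d.b3 + hit.length
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq[pos] = choices[rng.integers(len(choices))]
    raise RuntimeError("could not break accidental repeat")


def gen_reference(
    spec: SynthSpec,
    seed: int = 0,
    planted_deletions: Optional[Sequence[tuple[Deletion, int]]] = None,
    max_retries: int = 200,
) -> tuple[MtReference, list[dict]]:
    """I.i.d. uniform A/C/G/T reference with planted junctional repeats.

    Returns the reference and a manifest listing every planted
    (deletion, repeat length) pair; repeats whose windows would collide are
    re-drawn with bounded retries.  ``planted_deletions`` fixes the planted
    junctions explicitly; otherwise ``spec.planted_repeats`` (length, count)
    pairs are planted at random junctions within the scanned window.
    """
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(4, size=spec.ref_length)].copy()
    manifest: list[dict] = []
    if planted_deletions is None:
        planted_deletions = []
        used: list[tuple[int, int]] = []
        for length, count in spec.planted_repeats:
            for _ in range(count):
                for _attempt in range(max_retries):
                    b5 = int(rng.integers(spec.region_lo, spec.region_hi - 600))
                    b3 = int(rng.integers(b5 + 499, min(spec.region_hi, b5 + 4000)))
                    windows = [(b5, b5 + length + 1), (b3 - length, b3 + length + 2)]
                    if all(
                        w_hi < u_lo or w_lo > u_hi
                        for w_lo, w_hi in windows
                        for u_lo, u_hi in used
                    ):
                        used.extend(windows)
                        planted_deletions.append((Deletion(b5, b3), length))
                        break
                else:
                    raise RuntimeError("could not place planted repeat (too crowded)")
    for d, r in planted_deletions:
        _plant_repeat(seq, d, r, rng)
        manifest.append({"b5": d.b5, "b3": d.b3, "repeat_length": r})
    ref = MtReference(id=f"synthetic-mt-{seed}", sequence="".join(seq), circular=True)
    return ref, manifest


# ---------------------------------------------------------------------------
# primer panel
# ---------------------------------------------------------------------------


def gen_panel(
    spec: SynthSpec = SynthSpec(),
    seed: int = 0,
    jitter: int = 0,
) -> PrimerPanel:
    """Evenly spaced primer panel emulating the documented layout.

    With the default spec (12 forward / 36 reverse primers, window
    1,800-10,800, L_max 1,000) and no jitter this produces exactly 236 valid
    pairs.  ``jitter`` shifts each primer uniformly in +-jitter bp (for
    randomized-panel property tests); jittered panels may have other pair
    counts.
    """
    rng = np.random.default_rng(seed)
    if spec.n_forward == 1:
        fwd_starts = np.array([_FWD_START_LO])
    else:
        fwd_starts = np.round(np.linspace(_FWD_START_LO, _FWD_START_HI, spec.n_forward)).astype(int)
    if spec.n_reverse == 1:
        rev_ends = np.array([_REV_END_HI])
    else:
        rev_ends = np.round(np.linspace(_REV_END_LO, _REV_END_HI, spec.n_reverse)).astype(int)
    if jitter:
        fwd_starts = fwd_starts + rng.integers(-jitter, jitter + 1, fwd_starts.size)
        rev_ends = rev_ends + rng.integers(-jitter, jitter + 1, rev_ends.size)
        fwd_starts = np.clip(fwd_starts, spec.region_lo, spec.region_hi - _PRIMER_LEN)
        rev_ends = np.clip(rev_ends, spec.region_lo + _PRIMER_LEN, spec.region_hi)
    primers = [
        Primer(name=f"F{i+1:02d}", orientation="forward", start=int(s), end=int(s) + _PRIMER_LEN - 1)
        for i, s in enumerate(fwd_starts)
    ] + [
        Primer(name=f"R{j+1:02d}", orientation="reverse", start=int(e) - _PRIMER_LEN + 1, end=int(e))
        for j, e in enumerate(rev_ends)
    ]
    cfg = PanelConfig(L_max=spec.L_max, region_lo=spec.region_lo, region_hi=spec.region_hi)
    return build_panel(primers, cfg)


def canonical_panel() -> PrimerPanel:
    """The default 12F/36R, 236-pair panel at L_max = 1,000 bp."""
    return gen_panel(SynthSpec(), jitter=0)


def panel_to_tsv(panel: PrimerPanel, path) -> None:
    pd.DataFrame(
        {
            "name": [p.name for p in panel.primers],
            "orientation": ["F" if p.orientation == "forward" else "R" for p in panel.primers],
            "start": [p.start for p in panel.primers],
            "end": [p.end for p in panel.primers],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort detection tables
# ---------------------------------------------------------------------------


def gen_cohort_detections(
    spec: SynthSpec,
    panel: PrimerPanel,
    design: Optional[CaptureDesign] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulated detection tables for cohorts with known clonality.

    Each cohort's homogenate holds ``true_fraction`` mutant copies, of which
    ``clonal_weight`` belong to a single expanded clone (a fixed deletion per
    cohort) and the rest are sporadic singletons; replicate capture assays
    then sample the homogenate without replacement.  Returns the detection
    table and a truth manifest (per-cohort clone breakpoints and copy
    numbers).
    """
    design = design or CaptureDesign()
    rng = np.random.default_rng(seed)
    spectrum = UniformDeletionSpectrum(region_lo=spec.region_lo, region_hi=spec.region_hi)
    records: list[DetectionRecord] = []
    truth: dict = {"true_fraction": spec.true_fraction, "clonal_weight": spec.clonal_weight, "cohorts": {}}
    for ci in range(spec.n_cohorts):
        cohort = f"cohort{ci+1}"
        total = design.homogenate_copies
        if spec.copy_number_decline > 0:
            total = int(round(total * (1 - spec.copy_number_decline)))
        m_total = int(round(spec.true_fraction * total))
        m_clone = int(round(spec.clonal_weight * m_total))
        mutants: list = []
        clone_info = None
        if m_clone > 0:
            # the expanded clone must be detectable by >= 1 pair, otherwise the
            # planted clonality signal would be invisible by construction
            for _ in range(200):
                b5, b3 = spectrum.sample(rng, 1)
                clone = Deletion(int(b5[0]), int(b3[0]))
                if panel.amplifiable_matrix([clone.b5], [clone.b3]).any():
                    break
            else:
                raise RuntimeError("could not draw an amplifiable clone")
            mutants.append((clone, m_clone))
            clone_info = {"b5": clone.b5, "b3": clone.b3, "copies": m_clone}
        if m_total - m_clone > 0:
            mutants.append((None, m_total - m_clone))
        h = Homogenate(total_copies=total, mutants=mutants)
        results = simulate_replicates(
            h, panel, design, spec.replicates_per_cohort,
            seed=int(rng.integers(2**31 - 1)), spectrum=spectrum,
        )
        for ri, res in enumerate(results):
            records.extend(
                DetectionRecord(cohort, spec.age_days, f"rep{ri+1}", d)
                for d in res.detections
            )
        truth["cohorts"][cohort] = {
            "total_copies": total,
            "mutant_copies": m_total,
            "clone": clone_info,
            "n_detections": sum(len(r.detections) for r in results),
        }
    return records_to_frame(records), truth


# ---------------------------------------------------------------------------
# lesion time courses
# ---------------------------------------------------------------------------


def gen_lesion_timecourse(
    spec: SynthSpec,
    l0: float = 1.0,
    times: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """First-order lesion decay L(t) = L0 2^(-t / t1/2) with multiplicative
    lognormal noise of coefficient of variation ``decay_noise_cv``."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.linspace(0, 10, 6), dtype=float)
    clean = l0 * np.power(2.0, -t / spec.decay_half_life_days) if np.isfinite(
        spec.decay_half_life_days
    ) else np.full(t.size, l0)
    if spec.decay_noise_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.decay_noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=t.size)
    else:
        noise = np.ones(t.size)
    df = pd.DataFrame({"label": "synthetic", "time_days": t, "lesions": clean * noise})
    truth = {"half_life_days": spec.decay_half_life_days, "l0": l0, "noise_cv": spec.decay_noise_cv}
    return df, truth


# ---------------------------------------------------------------------------
# worked-example detection table (deterministic synthetic twin)
# ---------------------------------------------------------------------------

# multiplicities of the nine deletions repeated within the 10-replicate
# day-10 cohort: 148 total detections over 124 unique junctions
_D10_REPEAT_MULTS = (6, 5, 4, 3, 3, 3, 3, 3, 3)


def worked_example_detections(seed: int = 20) -> tuple[pd.DataFrame, MtReference, dict]:
    """Deterministic synthetic twin of the full deletion-detection experiment.

    Constructs 11 cohorts of aged worms (ages 4/7/10 d) with the canonical
    multiplicity structure of the assay design it emulates:

    * 312 detections of 266 unique deletions overall;
    * one day-10 cohort assayed in 10 replicates: 148 detections, 124 unique,
      9 junctions repeated (multiplicities 6,5,4,3,...), 92.74% seen once;
    * nine junctions recurring between cohorts - eight in exactly two cohorts
      and one in three - of which three are also repeated within the day-10
      cohort;
    * direct repeats >= 8 bp planted at 7 of the 9 within-cohort-repeated
      junctions and 6 of the 9 between-cohort junctions (all three doubly
      repeated junctions carry one), with repeat-free junctions verified.

    The table is a synthetic stand-in built to these documented summary
    marginals (per-junction identities are generated, not measured).
    Returns (detections frame, reference with planted repeats, truth dict).
    """
    rng = np.random.default_rng(seed)
    region_lo, region_hi = constants.REGION_LO, constants.REGION_HI

    def draw_unique(n, existing):
        out = []
        while len(out) < n:
            b5 = int(rng.integers(region_lo, region_hi - 600))
            b3 = int(rng.integers(b5 + 499, min(region_hi, b5 + 4500)))
            key = (b5, b3)
            if key in existing:
                continue
            existing.add(key)
            out.append(Deletion(b5, b3))
        return out

    existing: set = set()
    d10_repeated = draw_unique(9, existing)  # within-day-10 repeated junctions
    d10_singles = draw_unique(115, existing)
    b_fresh = draw_unique(6, existing)  # between-cohort-only junctions B4..B9
    # B1..B3: day-10 repeated junctions that also recur between cohorts
    b1, b2, b3_ = d10_repeated[0], d10_repeated[2], d10_repeated[3]

    day4_within_repeats = draw_unique(12, existing)  # repeated twice in a day-4 cohort
    day4_singles = draw_unique(68, existing)
    day7_singles = draw_unique(49, existing)
    d10b_singles = draw_unique(3, existing)
    d10c_singles = draw_unique(4, existing)

    records: list[DetectionRecord] = []

    def add(cohort, age, rep, d):
        records.append(DetectionRecord(cohort, age, rep, d))

    # --- the 10-replicate day-10 cohort -----------------------------------
    rep_names = [f"rep{r+1}" for r in range(10)]
    for d, mult in zip(d10_repeated, _D10_REPEAT_MULTS):
        for r in range(mult):
            add("D10a", 10, rep_names[r % 10], d)
    for i, d in enumerate(d10_singles):
        add("D10a", 10, rep_names[i % 10], d)

    # --- other day-10 cohorts ---------------------------------------------
    add("D10b", 10, "rep1", b3_)  # between-cohort recurrence of B3
    for d in d10b_singles:
        add("D10b", 10, "rep1", d)
    for d in d10c_singles:
        add("D10c", 10, "rep1", d)

    # --- day-4 cohorts (3 cohorts, 11 replicates) -------------------------
    b4, b5_, b6, b7, b8, b9 = b_fresh
    add("D4a", 4, "rep1", b1)  # between-cohort recurrence of B1
    for cohort, d in (("D4a", b4), ("D4b", b4), ("D4a", b5_), ("D4c", b5_),
                      ("D4b", b6), ("D4c", b6), ("D4a", b9), ("D4b", b9)):
        add(cohort, 4, "rep1", d)
    for i, d in enumerate(day4_within_repeats):
        cohort = ("D4a", "D4b", "D4c")[i % 3]
        add(cohort, 4, "rep1", d)
        add(cohort, 4, "rep2", d)
    for i, d in enumerate(day4_singles):
        cohort = ("D4a", "D4b", "D4c")[i % 3]
        reps = 4 if cohort != "D4c" else 3
        add(cohort, 4, f"rep{(i // 3) % reps + 1}", d)

    # --- day-7 cohorts (5 cohorts, 1 replicate each) ----------------------
    add("D7a", 7, "rep1", b2)  # between-cohort recurrence of B2
    for cohort, d in (("D7a", b7), ("D7b", b7), ("D7c", b8), ("D7d", b8), ("D7e", b9)):
        add(cohort, 7, "rep1", d)
    for i, d in enumerate(day7_singles):
        add(("D7a", "D7b", "D7c", "D7d", "D7e")[i % 5], 7, "rep1", d)

    # --- plant direct repeats ---------------------------------------------
    # within-day-10 repeated set: DR >= 8 bp at 7 of 9 (incl. B1, B2, B3)
    d10_with_dr = [d10_repeated[i] for i in (0, 1, 2, 3, 4, 5, 6)]
    d10_without = [d10_repeated[i] for i in (7, 8)]
    # between-cohort set: DR at 6 of 9 (B1, B2, B3 plus three fresh)
    between_with_dr = [b4, b5_, b6]
    between_without = [b7, b8, b9]
    dr_lengths = (12, 8, 10, 9, 8, 11, 8, 10, 8, 9)
    planted = [
        (d, dr_lengths[i]) for i, d in enumerate(d10_with_dr + between_with_dr)
    ]
    spec = SynthSpec()
    ref, manifest = gen_reference(spec, seed=seed + 1, planted_deletions=planted)
    seq = np.array(list(ref.sequence))
    # planted windows may collide (planting one junction can disturb another),
    # so iterate plant/break to a fixpoint
    without = d10_without + between_without
    for _ in range(20):
        settled = True
        ref = MtReference(id=ref.id, sequence="".join(seq), circular=True)
        for d, r in planted:
            hit = find_flanking_direct_repeat(ref, d, min_len=8, max_len=30)
            if hit is None:
                _plant_repeat(seq, d, r, rng)
                settled = False
        for d in without:
            hit_ref = MtReference(id=ref.id, sequence="".join(seq), circular=True)
            if find_flanking_direct_repeat(hit_ref, d, min_len=8, max_len=30) is not None:
                _break_repeat(seq, d, min_dr=8, max_len=30, rng=rng)
                settled = False
        if settled:
            break
    else:
        raise RuntimeError("planted-repeat construction did not converge")
    ref = MtReference(id=ref.id, sequence="".join(seq), circular=True)

    truth = {
        "n_total": 312,
        "n_unique": 266,
        "day10_cohort": {"id": "D10a", "n_total": 148, "n_unique": 124, "n_repeated": 9},
        "between_repeated": 9,
        "between_in_two": 8,
        "between_in_three": 1,
        "d10_repeated_with_dr": 7,
        "between_repeated_with_dr": 6,
        "planted_repeats": manifest,
    }
    return records_to_frame(records), ref, truth
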