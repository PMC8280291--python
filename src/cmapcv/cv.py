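"""Conduction-velocity distributions and demyelination models.

A median-nerve motor axon population (200 axons by default) is described by
a histogram of conduction velocities (CVs).  The label space used throughout
the package is the fixed 28-bin vector of bin centers

    0, 11, 13, 15, ..., 61, 63  m/s

where bin 0 holds axons in conduction block (they conduct distally but fail
across the forearm segment, contributing nothing to the elbow-stimulation
CMAP) and the odd bins hold conducting axons at their forearm-segment CV.

Demyelination is modeled as a per-axon random reassignment of the forearm
CV to a slower value, under one of six slowing patterns, optionally followed
by an independent 40% chance of conduction block per axon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Label bins in m/s: blocked-axon bin 0 plus odd velocities 11..63.
BIN_CENTERS: np.ndarray = np.array([0] + list(range(11, 64, 2)), dtype=int)
N_BINS = len(BIN_CENTERS)  # 28

#: Healthy-nerve axon counts at 63, 61, ..., 37 m/s (total 200).
_NORMAL_COUNTS_DESC = (1, 2, 2, 6, 18, 30, 42, 39, 27, 17, 9, 4, 2, 1)

DEFAULT_N_AXONS = 200
DEFAULT_BLOCK_PROB = 0.4

_BIN_INDEX = {int(v): i for i, v in enumerate(BIN_CENTERS)}


@dataclass(frozen=True)
class CVHistogram:
    """Axon counts over the 28 CV bins."""

    counts: np.ndarray
    bin_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        b = np.asarray(self.bin_centers, dtype=int)
        if c.shape != (N_BINS,) or b.shape != (N_BINS,):
            raise ValueError(f"histogram requires {N_BINS} bins")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(b, BIN_CENTERS):
            raise ValueError("bin centers must be 0, 11, 13, ..., 63 m/s")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "bin_centers", b)

    def count_at(self, cv: int) -> int:
        """Count in the bin centered at ``cv`` m/s."""
        return int(self.counts[_BIN_INDEX[int(cv)]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"bin_center_m_per_s": self.bin_centers, "count": self.counts}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CVHistogram":
        df = pd.read_csv(path)
        counts = np.zeros(N_BINS, dtype=int)
        for cv, n in zip(df.iloc[:, 0], df.iloc[:, 1]):
            counts[_BIN_INDEX[int(cv)]] = int(n)
        return cls(counts)


@dataclass(frozen=True)
class Axon:
    """One motor axon: its healthy CV, its (possibly slowed) forearm-segment
    CV, and whether it is in conduction block."""

    normal_cv: int
    forearm_cv: int
    blocked: bool = False

    def __post_init__(self) -> None:
        if self.normal_cv % 2 == 0 or not (37 <= self.normal_cv <= 63):
            raise ValueError(f"normal CV must be odd in [37, 63], got {self.normal_cv}")
        if self.forearm_cv % 2 == 0 or not (11 <= self.forearm_cv <= 63):
            raise ValueError(f"forearm CV must be odd in [11, 63], got {self.forearm_cv}")


@dataclass(frozen=True)
class AxonPopulation:
    """A fixed-size axon population with provenance tags.

    ``pattern_id`` is 0 for the unmodified normal model and 1-6 for the
    slowing patterns; ``cb_applied`` records whether the conduction-block
    step has been run (even if it happened to block no axon).
    """

    axons: tuple[Axon, ...]
    pattern_id: int = 0
    cb_applied: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "axons", tuple(self.axons))
        if not (0 <= self.pattern_id <= 6):
            raise ValueError("pattern_id must be 0 (normal) or 1-6")

    def __len__(self) -> int:
        return len(self.axons)

    @property
    def n_blocked(self) -> int:
        return sum(a.blocked for a in self.axons)

    def normal_cvs(self) -> np.ndarray:
        return np.array([a.normal_cv for a in self.axons], dtype=int)

    def forearm_cvs(self) -> np.ndarray:
        return np.array([a.forearm_cv for a in self.axons], dtype=int)

    def blocked_mask(self) -> np.ndarray:
        return np.array([a.blocked for a in self.axons], dtype=bool)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "normal_cv": self.normal_cvs(),
                "forearm_cv": self.forearm_cvs(),
                "blocked": self.blocked_mask().astype(int),
            }
        ).to_csv(path, index=False)


def normal_histogram() -> CVHistogram:
    """The healthy median-nerve CV histogram: 200 axons over 37-63 m/s.

    Counts (from fastest 63 m/s down to 37 m/s):
    1, 2, 2, 6, 18, 30, 42, 39, 27, 17, 9, 4, 2, 1.
    """
    counts = np.zeros(N_BINS, dtype=int)
    for cv, n in zip(range(63, 35, -2), _NORMAL_COUNTS_DESC):
        counts[_BIN_INDEX[cv]] = n
    return CVHistogram(counts)


def population_from_histogram(hist: CVHistogram) -> AxonPopulation:
    """Expand a histogram into individual axons (normal = forearm CV,
    unblocked).  The blocked bin must be empty: a source histogram describes
    conducting axons only."""
    if hist.counts[0] != 0:
        raise ValueError("source histogram must have an empty 0 m/s (blocked) bin")
    axons = []
    for cv, n in zip(hist.bin_centers[1:], hist.counts[1:]):
        axons.extend(Axon(int(cv), int(cv)) for _ in range(int(n)))
    return AxonPopulation(tuple(axons), pattern_id=0, cb_applied=False)


def allowed_cvs(pattern_id: int, original_cv: int) -> tuple[int, ...]:
    """The set of forearm CVs a slowing pattern may assign to an axon whose
    healthy CV is ``original_cv``, sorted ascending.

    Patterns: 1 entire range (original down to 11); 2 severe (11-19);
    3 moderate (21-35); 4 mild (up to 8 m/s slower); 5 moderate-2 (up to
    20 m/s slower); 6 two distributions (mild set plus the severe range).
    """
    if original_cv % 2 == 0 or not (37 <= original_cv <= 63):
        raise ValueError(f"original CV must be odd in [37, 63], got {original_cv}")
    if pattern_id == 1:
        vals = range(11, original_cv + 1, 2)
    elif pattern_id == 2:
        vals = range(11, 20, 2)
    elif pattern_id == 3:
        vals = range(21, 36, 2)
    elif pattern_id == 4:
        vals = range(original_cv - 8, original_cv + 1, 2)
    elif pattern_id == 5:
        vals = range(original_cv - 20, original_cv + 1, 2)
    elif pattern_id == 6:
        vals = sorted(set(range(original_cv - 8, original_cv + 1, 2)) | set(range(11, 20, 2)))
    else:
        raise ValueError(f"pattern_id must be 1-6, got {pattern_id}")
    return tuple(int(v) for v in vals)


def apply_demyelination(
    pop: AxonPopulation,
    pattern_id: int,
    seed: int,
    weights: dict[int, float] | None = None,
) -> AxonPopulation:
    """Randomly slow every conducting axon's forearm CV under a pattern.

    Each axon's forearm CV is drawn independently from
    ``allowed_cvs(pattern_id, normal_cv)``, uniformly by default.
    ``weights`` optionally maps CV values to relative draw weights
    (renormalized over each axon's allowed set), for non-uniform slowing
    scenarios.  Slowing precedes conduction block, so the input population
    must not have had block applied.
    """
    if pop.cb_applied:
        raise ValueError("demyelination must be applied before conduction block")
    if not (1 <= pattern_id <= 6):
        raise ValueError(f"pattern_id must be 1-6, got {pattern_id}")
    rng = np.random.default_rng(seed)
    if weights is not None:
        new_axons = []
        for axon in pop.axons:
            choices = allowed_cvs(pattern_id, axon.normal_cv)
            w = np.array([weights.get(v, 0.0) for v in choices], dtype=float)
            if w.sum() <= 0:
                raise ValueError("weights assign zero mass to an axon's allowed set")
            cv = int(rng.choice(choices, p=w / w.sum()))
            new_axons.append(replace(axon, forearm_cv=cv))
        return AxonPopulation(tuple(new_axons), pattern_id=pattern_id, cb_applied=False)

    # uniform draws, vectorized: index i into each axon's sorted allowed set
    orig = pop.normal_cvs()
    if pattern_id == 1:
        sizes = (orig - 11) // 2 + 1
        idx = rng.integers(0, sizes)
        cvs = orig - 2 * idx
    elif pattern_id == 2:
        cvs = 11 + 2 * rng.integers(0, 5, size=len(pop))
    elif pattern_id == 3:
        cvs = 21 + 2 * rng.integers(0, 8, size=len(pop))
    elif pattern_id == 4:
        cvs = orig - 2 * rng.integers(0, 5, size=len(pop))
    elif pattern_id == 5:
        cvs = orig - 2 * rng.integers(0, 11, size=len(pop))
    else:  # pattern 6: mild set (5 values) plus severe range (5 values)
        idx = rng.integers(0, 10, size=len(pop))
        cvs = np.where(idx < 5, orig - 2 * idx, 11 + 2 * (idx - 5))
    new_axons = tuple(
        replace(axon, forearm_cv=int(cv)) for axon, cv in zip(pop.axons, cvs)
    )
    return AxonPopulation(new_axons, pattern_id=pattern_id, cb_applied=False)


def apply_conduction_block(
    pop: AxonPopulation,
    block_prob: float = DEFAULT_BLOCK_PROB,
    seed: int = 0,
) -> AxonPopulation:
    """Independently block each axon with probability ``block_prob``.

    Blocked axons keep their CVs but contribute nothing to the CMAP and are
    counted in the 0 m/s label bin.
    """
    if not (0.0 <= block_prob <= 1.0):
        raise ValueError("block probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hits = rng.random(len(pop)) < block_prob
    new_axons = tuple(
        replace(a, blocked=bool(h)) for a, h in zip(pop.axons, hits)
    )
    return AxonPopulation(new_axons, pattern_id=pop.pattern_id, cb_applied=True)


def histogram_from_population(pop: AxonPopulation) -> CVHistogram:
    """The label histogram: blocked axons in bin 0, conducting axons at
    their forearm CV.  Counts always sum to the population size."""
    counts = np.zeros(N_BINS, dtype=int)
    for axon in pop.axons:
        if axon.blocked:
            counts[0] += 1
        else:
            idx = _BIN_INDEX.get(axon.forearm_cv)
            if idx is None:
                raise ValueError(f"forearm CV {axon.forearm_cv} is not a label bin")
            counts[idx] += 1
    return CVHistogram(counts)
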