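"""CMAP synthesis by latency-shifted superposition, and corpus building.

The simulated montage is a median-nerve motor study: stimulation at the
elbow, recording over the abductor pollicis brevis (APB).  Conduction is
normal over the 70 mm wrist-to-APB segment (each axon at its healthy CV)
and demyelinated over the 200 mm wrist-to-elbow forearm segment (each axon
at its reassigned forearm CV).  Each conducting axon contributes one copy
of the sMUP template, delayed by its conduction time relative to a
reference axon conducting at 63 m/s in both segments; blocked axons
contribute nothing.  The sum over 200 axons is the 251-sample CMAP on a
0.1 ms grid over [0, 25.0] ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .cv import (
    DEFAULT_BLOCK_PROB,
    DEFAULT_N_AXONS,
    N_BINS,
    Axon,
    AxonPopulation,
    CVHistogram,
    apply_conduction_block,
    apply_demyelination,
    histogram_from_population,
    normal_histogram,
    population_from_histogram,
)
from .template import DT_MS, N_SAMPLES as TEMPLATE_SAMPLES, SMUPTemplate

#: CMAP window: closed [0, 25.0] ms at 0.1 ms -> 251 samples.
WAVEFORM_SAMPLES = 251

#: Group ids 1-6 are the slowing patterns without conduction block,
#: 7-12 the same patterns with the 40% per-axon block.
GROUP_IDS = tuple(range(1, 13))


def group_pattern(group_id: int) -> int:
    """Slowing pattern (1-6) of a group id."""
    return (group_id - 1) % 6 + 1


def group_has_block(group_id: int) -> bool:
    """Whether a group id includes the conduction-block step."""
    return group_id > 6


@dataclass(frozen=True)
class SimConfig:
    """Geometry, sampling and corpus-size parameters of the simulation."""

    distal_distance: float = 70.0     # mm, wrist to APB
    forearm_distance: float = 200.0   # mm, wrist to elbow
    dt: float = DT_MS                 # ms
    window_ms: float = 25.0           # closed interval [0, window]
    n_axons: int = DEFAULT_N_AXONS
    block_prob: float = DEFAULT_BLOCK_PROB
    n_per_group: int = 1000
    train_fraction: float = 0.8
    reference_cv: float = 63.0        # m/s, zero-shift axon

    def __post_init__(self) -> None:
        if self.distal_distance <= 0 or self.forearm_distance <= 0:
            raise ValueError("segment distances must be positive")
        n = self.window_ms / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must be an integer number of dt steps")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms / self.dt)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class LabeledSet:
    """One training pair: a CMAP waveform, its CV-count label, and the
    simulation group it came from."""

    waveform: np.ndarray   # (251,) mV
    label: np.ndarray      # (28,) axon counts
    group_id: int

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        y = np.asarray(self.label, dtype=int)
        if w.shape != (WAVEFORM_SAMPLES,):
            raise ValueError(f"waveform must have {WAVEFORM_SAMPLES} samples")
        if y.shape != (N_BINS,):
            raise ValueError(f"label must have {N_BINS} bins")
        object.__setattr__(self, "waveform", w)
        object.__setattr__(self, "label", y)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[LabeledSet, ...]
    test: tuple[LabeledSet, ...]
    seed: int


def axon_latency_shift(axon: Axon, cfg: SimConfig = SimConfig()) -> float:
    """Latency shift of one axon's sMUP, in ms, relative to the reference
    axon conducting at ``cfg.reference_cv`` in both segments.

    shift = d_distal/normal_cv + d_forearm/forearm_cv
            - (d_distal + d_forearm)/reference_cv

    (mm divided by m/s gives ms).  Non-negative whenever the reference is
    the fastest possible axon.
    """
    if axon.blocked:
        raise ValueError("blocked axons have no latency (no response)")
    if axon.normal_cv <= 0 or axon.forearm_cv <= 0:
        raise ValueError("conduction velocities must be positive")
    total = cfg.distal_distance + cfg.forearm_distance
    return (
        cfg.distal_distance / axon.normal_cv
        + cfg.forearm_distance / axon.forearm_cv
        - total / cfg.reference_cv
    )


def synthesize_cmap(
    template: SMUPTemplate,
    pop: AxonPopulation,
    cfg: SimConfig = SimConfig(),
) -> np.ndarray:
    """Superimpose one latency-shifted sMUP per conducting axon.

    Each shift is rounded to the nearest 0.1 ms grid step; template samples
    shifted past the end of the 25 ms window are discarded.  Blocked axons
    contribute exactly zero, so an all-blocked population yields the zero
    waveform.
    """
    if template.sample_times.shape != (TEMPLATE_SAMPLES,) or not np.isclose(
        template.sample_times[1] - template.sample_times[0], cfg.dt
    ):
        raise ValueError("template grid does not match the simulation dt")
    n = cfg.n_samples
    out = np.zeros(n)
    # group identical shifts: many axons share (normal_cv, forearm_cv)
    shift_counts: dict[int, int] = {}
    for axon in pop.axons:
        if axon.blocked:
            continue
        tau = axon_latency_shift(axon, cfg)
        k = int(np.floor(tau / cfg.dt + 0.5))  # nearest step, half up
        shift_counts[k] = shift_counts.get(k, 0) + 1
    for k, count in shift_counts.items():
        if k >= n:
            continue
        span = min(TEMPLATE_SAMPLES, n - k)
        out[k : k + span] += count * template.amplitudes[:span]
    return out


def simulate_group_set(
    template: SMUPTemplate,
    group_id: int,
    seed: int,
    cfg: SimConfig = SimConfig(),
) -> LabeledSet:
    """Draw one population for a group and synthesize its labeled pair."""
    base = population_from_histogram(normal_histogram())
    rng = np.random.SeedSequence(seed)
    s_slow, s_block = (int(s.generate_state(1)[0] >> 1) for s in rng.spawn(2))
    pop = apply_demyelination(base, group_pattern(group_id), seed=s_slow)
    if group_has_block(group_id):
        pop = apply_conduction_block(pop, cfg.block_prob, seed=s_block)
    waveform = synthesize_cmap(template, pop, cfg)
    label = histogram_from_population(pop).counts
    return LabeledSet(waveform, label, group_id)


def build_corpus(
    template: SMUPTemplate,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[LabeledSet]:
    """Generate the full labeled corpus: ``cfg.n_per_group`` sets for each
    of the 12 groups (six slowing patterns, with and without conduction
    block) — 12,000 sets at the defaults.  Deterministic given ``seed``."""
    master = np.random.SeedSequence(seed)
    corpus: list[LabeledSet] = []
    for group_id, group_seq in zip(GROUP_IDS, master.spawn(len(GROUP_IDS))):
        for set_seq in group_seq.spawn(cfg.n_per_group):
            set_seed = int(set_seq.generate_state(1)[0] >> 1)
            corpus.append(simulate_group_set(template, group_id, set_seed, cfg))
    return corpus


def split_corpus(
    corpus: list[LabeledSet],
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> DatasetSplit:
    """Uniform random train/test partition (no stratification): 80/20 at
    the defaults, disjoint and exhaustive, deterministic given ``seed``."""
    if not corpus:
        raise ValueError("corpus is empty")
    if not (0.0 < cfg.train_fraction < 1.0):
        raise ValueError("train fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(cfg.train_fraction * len(corpus)))
    train = tuple(corpus[i] for i in order[:n_train])
    test = tuple(corpus[i] for i in order[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# corpus containers


def corpus_arrays(sets) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a list of LabeledSet into (waveforms, labels, groups)."""
    w = np.stack([s.waveform for s in sets])
    y = np.stack([s.label for s in sets])
    g = np.array([s.group_id for s in sets], dtype=int)
    return w, y, g


def save_corpus(path, sets, cfg: SimConfig, template: SMUPTemplate | None = None) -> None:
    """Write a corpus to HDF5: datasets ``waveforms`` (N x 251 float),
    ``labels`` (N x 28 int), ``groups`` (N,), config as attrs, template as
    an optional dataset."""
    w, y, g = corpus_arrays(sets)
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=w.astype(np.float64))
        f.create_dataset("labels", data=y.astype(np.int32))
        f.create_dataset("groups", data=g.astype(np.int32))
        f.attrs["config"] = json.dumps(asdict(cfg))
        if template is not None:
            f.create_dataset(
                "template", data=np.column_stack([template.sample_times, template.amplitudes])
            )


def load_corpus(path) -> tuple[list[LabeledSet], SimConfig]:
    with h5py.File(path, "r") as f:
        w = f["waveforms"][:]
        y = f["labels"][:]
        g = f["groups"][:]
        cfg = SimConfig(**json.loads(f.attrs["config"]))
    sets = [LabeledSet(wi, yi, int(gi)) for wi, yi, gi in zip(w, y, g)]
    return sets, cfg
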