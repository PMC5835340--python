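"""Synthetic coupled-oscillator EEG trials with a planted edge set.

The generator emulates the geometry of a multichannel EEG experiment
(channels x samples trials with a pre-stimulus baseline) while keeping the
ground truth of pairwise phase synchronization fully controllable.  Each
planted channel pair shares, after stimulus onset, a common oscillatory
phase at every carrier frequency; each member channel perturbs that phase
with independent Gaussian jitter whose standard deviation depends on the
trial's class.  Because the phase difference of a planted pair is then
N(0, 2*sd^2), its population phase-locking value is exp(-sd^2): the
quantity the connectivity stage measures is a direct function of the
generator's knobs.

Phases are redrawn once per ``jitter_refresh`` seconds (default 1 s,
matching the analysis epoch length), so the 1-s segments of a trial form
the independent ensemble the PLV estimator averages over.  The baseline
segment carries only uncoupled, uniform-phase activity on every channel,
giving baseline normalization a meaningful null reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .connectivity import EEGRecording

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_trial", "generate_dataset",
           "save_dataset", "load_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic EEG experiment.

    Defaults mirror the benchmark geometry used throughout the package:
    61 channels, 100 trials of the more-synchronized class (+1) and 180 of
    the less-synchronized class (-1), 20 planted edges, a beta-band carrier,
    and phase-jitter SDs of 0.3 rad (+1) versus 1.2 rad (-1).
    """

    n_channels: int = 61
    n_trials_pos: int = 100
    n_trials_neg: int = 180
    sampling_rate: float = 128.0
    trial_duration: float = 8.0          # post-stimulus, seconds
    baseline_duration: float = 4.0       # pre-stimulus, seconds
    planted_edges: tuple[tuple[int, int], ...] = ()
    carrier_freqs: tuple[float, ...] = (20.0,)
    coupling_pos: float = 0.3            # phase-jitter SD (rad), class +1
    coupling_neg: float = 1.2            # phase-jitter SD (rad), class -1
    noise_sd: float = 0.5                # additive white noise amplitude SD
    jitter_refresh: float = 1.0          # seconds between phase redraws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_trials_pos < 0 or self.n_trials_neg < 0:
            raise ValueError("trial counts must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trial_duration <= 0 or self.baseline_duration < 0:
            raise ValueError("durations must be positive (baseline may be 0)")
        if self.jitter_refresh <= 0:
            raise ValueError("jitter_refresh must be positive")
        for (i, j) in self.planted_edges:
            if not (0 <= i < j < self.n_channels):
                raise ValueError(f"invalid planted edge ({i}, {j}): need 0 <= i < j < n_channels")
        if len(set(self.planted_edges)) != len(self.planted_edges):
            raise ValueError("duplicate planted edges")
        if not self.carrier_freqs:
            raise ValueError("at least one carrier frequency required")
        for f in self.carrier_freqs:
            if not (0 < f < self.sampling_rate / 2):
                raise ValueError(f"carrier frequency {f} outside (0, Nyquist)")
        if self.coupling_pos < 0 or self.coupling_neg < 0:
            raise ValueError("coupling jitter SDs must be non-negative")
        if self.coupling_pos > self.coupling_neg:
            raise ValueError("coupling_pos must be <= coupling_neg "
                             "(class +1 is the more synchronized class)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def channel_labels(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def edge_of_channel(self) -> dict[int, int]:
        """Map channel -> index of the lowest-indexed planted edge containing it.

        A channel belonging to several planted edges takes its coupled phase
        from the first (lowest-indexed) edge that lists it.
        """
        assignment: dict[int, int] = {}
        for e, (i, j) in enumerate(self.planted_edges):
            assignment.setdefault(i, e)
            assignment.setdefault(j, e)
        return assignment


@dataclass
class SyntheticDataset:
    recordings: list[EEGRecording]
    labels: np.ndarray                      # +/-1 per recording
    ground_truth_edges: list[tuple[int, int]]
    config: SyntheticConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.recordings) != len(self.labels):
            raise ValueError("recordings and labels length mismatch")


def _segment_index(n_samples: int, fs: float, refresh: float) -> np.ndarray:
    """Segment id per sample: phases are redrawn at each segment boundary."""
    seg_len = max(1, int(round(refresh * fs)))
    return np.arange(n_samples) // seg_len


def generate_trial(config: SyntheticConfig, label: int,
                   rng: np.random.Generator) -> EEGRecording:
    """Generate one trial of the given class.

    Random draws, in order, per carrier frequency: common edge phases
    (edges x post-segments), per-channel coupled jitter
    (channels x post-segments), per-channel uncoupled uniform phases
    (channels x all segments); finally additive white noise.
    """
    if label not in (-1, 1):
        raise ValueError("label must be +1 or -1")
    fs = config.sampling_rate
    n_base = int(round(config.baseline_duration * fs))
    n_post = int(round(config.trial_duration * fs))
    n = n_base + n_post
    t = np.arange(n) / fs
    jitter_sd = config.coupling_pos if label == 1 else config.coupling_neg

    seg = _segment_index(n, fs, config.jitter_refresh)
    n_seg = int(seg[-1]) + 1
    post = np.arange(n) >= n_base          # stimulus onset at n_base
    seg_post = seg[post]

    assignment = config.edge_of_channel()
    x = np.zeros((config.n_channels, n))
    for f in config.carrier_freqs:
        omega_t = 2 * np.pi * f * t
        edge_phase = rng.uniform(0, 2 * np.pi,
                                 size=(max(len(config.planted_edges), 1), n_seg))
        coupled_jitter = rng.normal(0.0, jitter_sd if jitter_sd > 0 else 0.0,
                                    size=(config.n_channels, n_seg))
        free_phase = rng.uniform(0, 2 * np.pi, size=(config.n_channels, n_seg))
        for ch in range(config.n_channels):
            phase = free_phase[ch, seg].copy()   # baseline + uncoupled default
            if ch in assignment:
                e = assignment[ch]
                coupled = edge_phase[e, seg_post] + coupled_jitter[ch, seg_post]
                phase[post] = coupled
            x[ch] += np.cos(omega_t + phase)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
    return EEGRecording(samples=x, sampling_rate=fs,
                        channel_labels=config.channel_labels,
                        stimulus_onset=n_base)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full two-class dataset, trial order shuffled by the seed.

    One seeded generator is consumed in a documented order: first the trial
    permutation, then each trial's draws in presentation order.
    """
    rng = np.random.default_rng(config.seed)
    labels = np.concatenate([np.ones(config.n_trials_pos, dtype=int),
                             -np.ones(config.n_trials_neg, dtype=int)])
    order = rng.permutation(len(labels))
    labels = labels[order]
    recordings = [generate_trial(config, int(y), rng) for y in labels]
    return SyntheticDataset(recordings=recordings, labels=labels,
                            ground_truth_edges=list(config.planted_edges),
                            config=config)


def default_benchmark_edges(n_channels: int = 61, n_edges: int = 20,
                            seed: int = 12345) -> tuple[tuple[int, int], ...]:
    """A reproducible disjoint planted-edge set for benchmarks.

    Edges are drawn without replacement over channels so that no channel
    belongs to two planted edges (keeps each edge's coupling independent).
    """
    rng = np.random.default_rng(seed)
    channels = rng.permutation(n_channels)[: 2 * n_edges]
    return tuple(tuple(sorted((int(channels[2 * k]), int(channels[2 * k + 1]))))
                 for k in range(n_edges))


# ---------------------------------------------------------------------------
# on-disk format: per-trial CSV (channels x samples) + JSON manifest

def save_dataset(dataset: SyntheticDataset, path: str | Path) -> Path:
    """Write a dataset as trial_####.csv files plus manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials = []
    for k, rec in enumerate(dataset.recordings):
        name = f"trial_{k:04d}.csv"
        np.savetxt(path / name, rec.samples, delimiter=",")
        trials.append({"file": name, "label": int(dataset.labels[k]),
                       "stimulus_onset": int(rec.stimulus_onset)})
    cfg = dataset.config
    manifest = {
        "format": "brainedge-dataset-v1",
        "sampling_rate": dataset.recordings[0].sampling_rate if dataset.recordings else None,
        "channel_labels": dataset.recordings[0].channel_labels if dataset.recordings else [],
        "planted_edges": [list(e) for e in dataset.ground_truth_edges],
        "trials": trials,
        "config": None if cfg is None else {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_dataset(path: str | Path) -> SyntheticDataset:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format") != "brainedge-dataset-v1":
        raise ValueError(f"unrecognized dataset format in {path}")
    recordings, labels = [], []
    for tr in manifest["trials"]:
        samples = np.loadtxt(path / tr["file"], delimiter=",", ndmin=2)
        recordings.append(EEGRecording(
            samples=samples, sampling_rate=manifest["sampling_rate"],
            channel_labels=manifest["channel_labels"],
            stimulus_onset=tr["stimulus_onset"]))
        labels.append(tr["label"])
    edges = [tuple(e) for e in manifest["planted_edges"]]
    return SyntheticDataset(recordings=recordings, labels=np.asarray(labels),
                            ground_truth_edges=edges)
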