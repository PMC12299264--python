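"""Synthetic labeled IMU windows for controlled HAR experiments.

Real wearable HAR recordings are streams of tri-axial accelerometer
(m/s^2) and gyroscope (rad/s) signals cut into fixed-length windows.
This module emulates such data with a simple additive model: each
activity class is a quasi-periodic waveform (a fundamental plus a few
harmonics, class-specific frequency) rendered on six channels with
per-channel amplitudes and phases, plus i.i.d. Gaussian noise.  A
random per-window time shift imitates windows being cut from a long
recording at arbitrary starts.

Two stock configurations are provided:

* :func:`default_class_specs` — three activity-like classes (sit-up-like
  at 0.5 Hz, walk-like at 2 Hz, stairs-like at 1.5 Hz) that differ on
  every channel, for end-to-end pipeline runs.
* :func:`planted_channel_specs` — classes that are *identical* on five
  channels and differ only on one designated channel (default gyr Y),
  giving a ground-truth target for attribution-recovery experiments.

The generator also supports deliberate corruption
(:func:`inject_zero_rows`) so the preprocessing exclusion rule has
something to remove.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "N_CHANNELS",
    "CHANNEL_NAMES",
    "ConfigurationError",
    "ActivityClassSpec",
    "GeneratorConfig",
    "SensorWindow",
    "LabeledDataset",
    "default_class_specs",
    "planted_channel_specs",
    "generate_dataset",
    "inject_zero_rows",
    "dataset_to_frame",
    "dataset_from_frame",
    "save_dataset_csv",
    "load_dataset_csv",
    "save_config_yaml",
    "load_config_yaml",
]

N_CHANNELS = 6
#: Fixed channel order: accelerometer X/Y/Z then gyroscope X/Y/Z.
CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class ActivityClassSpec:
    """Waveform recipe for one activity class.

    Parameters
    ----------
    class_id
        Small integer label (0-based).
    name
        Human-readable label.
    fundamental_hz
        Frequency of the dominant periodic component (must lie in
        (0, fs/2)).
    channel_amplitudes
        Six per-channel amplitudes in sensor units (all >= 0, at least
        one > 0).
    channel_phases
        Six per-channel phase offsets in radians.
    harmonic_weights
        Relative amplitudes of harmonics 1..K of the fundamental.
    channel_fundamentals
        Optional per-channel frequency overrides, ``{channel_index:
        hz}``.  Lets a single channel carry a class-specific frequency
        while the remaining channels stay identical across classes
        (the "planted channel" construction).
    """

    class_id: int
    name: str
    fundamental_hz: float
    channel_amplitudes: tuple[float, ...]
    channel_phases: tuple[float, ...] = (0.0,) * N_CHANNELS
    harmonic_weights: tuple[float, ...] = (1.0,)
    channel_fundamentals: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "channel_amplitudes", tuple(float(a) for a in self.channel_amplitudes)
        )
        object.__setattr__(
            self, "channel_phases", tuple(float(p) for p in self.channel_phases)
        )
        object.__setattr__(
            self, "harmonic_weights", tuple(float(w) for w in self.harmonic_weights)
        )
        object.__setattr__(
            self,
            "channel_fundamentals",
            {int(k): float(v) for k, v in dict(self.channel_fundamentals).items()},
        )

    def validate(self, fs: float) -> None:
        if not 0.0 < self.fundamental_hz < fs / 2:
            raise ConfigurationError(
                f"class {self.name!r}: fundamental_hz={self.fundamental_hz} "
                f"must lie in (0, fs/2)=(0, {fs / 2})"
            )
        for ch, f in self.channel_fundamentals.items():
            if not 0 <= ch < N_CHANNELS:
                raise ConfigurationError(f"class {self.name!r}: bad channel index {ch}")
            if not 0.0 < f < fs / 2:
                raise ConfigurationError(
                    f"class {self.name!r}: channel {ch} fundamental {f} out of (0, fs/2)"
                )
        if len(self.channel_amplitudes) != N_CHANNELS:
            raise ConfigurationError(
                f"class {self.name!r}: need {N_CHANNELS} channel amplitudes"
            )
        if len(self.channel_phases) != N_CHANNELS:
            raise ConfigurationError(
                f"class {self.name!r}: need {N_CHANNELS} channel phases"
            )
        if any(a < 0 for a in self.channel_amplitudes):
            raise ConfigurationError(f"class {self.name!r}: negative amplitude")
        if not any(a > 0 for a in self.channel_amplitudes):
            raise ConfigurationError(f"class {self.name!r}: all amplitudes zero")
        if len(self.harmonic_weights) == 0:
            raise ConfigurationError(f"class {self.name!r}: empty harmonic_weights")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic dataset.

    ``fs * window_s`` must be an integer number of samples (default
    100 Hz x 3 s = 300).  ``random_phase`` draws a uniform per-window
    time shift of the whole waveform, emulating arbitrary window start
    times within a longer recording.
    """

    class_specs: tuple[ActivityClassSpec, ...]
    n_per_class: int = 100
    fs: float = 100.0
    window_s: float = 3.0
    noise_sd: float = 0.3
    zero_row_fraction: float = 0.0
    seed: int = 0
    random_phase: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_specs", tuple(self.class_specs))

    @property
    def n_samples(self) -> int:
        n = self.fs * self.window_s
        return int(round(n))

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.window_s <= 0:
            raise ConfigurationError(f"window_s must be positive, got {self.window_s}")
        n = self.fs * self.window_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"fs*window_s={n} is not an integer sample count"
            )
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not self.class_specs:
            raise ConfigurationError("class_specs is empty")
        if not 0.0 <= self.zero_row_fraction <= 1.0:
            raise ConfigurationError(
                f"zero_row_fraction must be in [0, 1], got {self.zero_row_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        ids = [s.class_id for s in self.class_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate class_ids: {ids}")
        for spec in self.class_specs:
            spec.validate(self.fs)

    def content_hash(self) -> str:
        """Stable hash of the config for provenance records."""
        payload = json.dumps(_config_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SensorWindow:
    """One labeled 3-s, 6-channel sample: ``values`` is (NT, NC)."""

    values: np.ndarray
    label: int
    window_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"window {self.window_id}: values must be (NT, {N_CHANNELS}), "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"window {self.window_id}: non-finite values")


@dataclass
class LabeledDataset:
    """Ordered collection of windows plus class names and provenance."""

    windows: list[SensorWindow]
    class_names: dict[int, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [w.window_id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate window_ids in dataset")
        missing = {w.label for w in self.windows} - set(self.class_names)
        if missing:
            raise ValueError(f"labels without class_names entry: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return self.windows[0].values.shape[0] if self.windows else 0

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {c: 0 for c in self.class_names}
        for w in self.windows:
            counts[w.label] += 1
        return counts

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``X`` of shape (N, NT, NC) and labels ``y``."""
        X = np.stack([w.values for w in self.windows])
        return X, self.labels()


# ---------------------------------------------------------------------------
# Stock class specifications


def default_class_specs() -> tuple[ActivityClassSpec, ...]:
    """Three activity-like classes differing on every channel."""
    return (
        ActivityClassSpec(
            class_id=0,
            name="sit_up",
            fundamental_hz=0.5,
            channel_amplitudes=(0.8, 0.3, 1.0, 0.6, 1.5, 0.5),
            channel_phases=(0.0, 0.7, 1.3, 2.1, 0.4, 1.8),
            harmonic_weights=(1.0, 0.5, 0.25),
        ),
        ActivityClassSpec(
            class_id=1,
            name="walk",
            fundamental_hz=2.0,
            channel_amplitudes=(1.2, 0.4, 1.6, 1.0, 0.8, 0.9),
            channel_phases=(0.5, 1.1, 0.2, 1.9, 2.6, 0.9),
            harmonic_weights=(1.0, 0.4, 0.2),
        ),
        ActivityClassSpec(
            class_id=2,
            name="stairs_up",
            fundamental_hz=1.5,
            channel_amplitudes=(1.0, 0.35, 1.8, 0.9, 1.1, 1.2),
            channel_phases=(1.0, 0.3, 2.4, 0.8, 1.5, 2.2),
            harmonic_weights=(1.0, 0.6, 0.3),
        ),
    )


def planted_channel_specs(
    planted_channel: int = 4,
    planted_hz: Sequence[float] = (0.5, 2.0, 1.5),
    carrier_hz: float = 1.0,
    amplitude: float = 1.0,
) -> tuple[ActivityClassSpec, ...]:
    """Classes identical on all channels except ``planted_channel``.

    Five channels carry one shared ``carrier_hz`` waveform (identical
    amplitudes and phases across classes, hence zero discriminative
    power); the planted channel carries a class-specific fundamental
    from ``planted_hz``.  Default planted channel is gyr Y (index 4).
    """
    if not 0 <= planted_channel < N_CHANNELS:
        raise ConfigurationError(f"planted_channel out of range: {planted_channel}")
    names = ("sit_up", "walk", "stairs_up")
    phases = (0.0, 0.7, 1.3, 2.1, 0.4, 1.8)
    specs = []
    for k, f in enumerate(planted_hz):
        specs.append(
            ActivityClassSpec(
                class_id=k,
                name=names[k] if k < len(names) else f"class_{k}",
                fundamental_hz=carrier_hz,
                channel_amplitudes=(amplitude,) * N_CHANNELS,
                channel_phases=phases,
                harmonic_weights=(1.0, 0.5, 0.25),
                channel_fundamentals={planted_channel: float(f)},
            )
        )
    return tuple(specs)


# ---------------------------------------------------------------------------
# Generation


def _render_window(
    spec: ActivityClassSpec, t: np.ndarray, time_shift: float
) -> np.ndarray:
    """Noiseless waveform of one window, shape (NT, NC)."""
    out = np.zeros((t.size, N_CHANNELS))
    for ch in range(N_CHANNELS):
        amp = spec.channel_amplitudes[ch]
        if amp == 0.0:
            continue
        f0 = spec.channel_fundamentals.get(ch, spec.fundamental_hz)
        phase = spec.channel_phases[ch]
        sig = np.zeros_like(t)
        for m, w in enumerate(spec.harmonic_weights, start=1):
            sig += w * np.sin(2 * np.pi * m * f0 * (t + time_shift) + phase)
        out[:, ch] = amp * sig
    return out


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate a labeled synthetic dataset; pure function of the config.

    Returns ``n_per_class x |class_specs|`` windows; each window is the
    per-channel sum of harmonics of the class fundamental plus Gaussian
    noise.  Identical config (including seed) gives bit-identical
    output.  If ``zero_row_fraction > 0`` the corresponding corruption
    is applied via :func:`inject_zero_rows` using the same seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nt = config.n_samples
    t = np.arange(nt) / config.fs
    windows: list[SensorWindow] = []
    for spec in config.class_specs:
        period = 1.0 / spec.fundamental_hz
        for w in range(config.n_per_class):
            shift = rng.uniform(0.0, period) if config.random_phase else 0.0
            vals = _render_window(spec, t, shift)
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, vals.shape)
            windows.append(
                SensorWindow(vals, spec.class_id, f"c{spec.class_id}-w{w:05d}")
            )
    ds = LabeledDataset(
        windows=windows,
        class_names={s.class_id: s.name for s in config.class_specs},
        provenance={"config_hash": config.content_hash(), "seed": config.seed},
    )
    if config.zero_row_fraction > 0:
        ds = inject_zero_rows(ds, config.zero_row_fraction, seed=config.seed)
    return ds


def inject_zero_rows(
    dataset: LabeledDataset, fraction: float, seed: int
) -> LabeledDataset:
    """Corrupt ``floor(fraction*N)`` windows with all-zero time rows.

    Selected windows (seeded draw without replacement) get one to three
    time rows set to exact zeros across all six channels — the sentinel
    the preprocessing exclusion rule detects.  Selection is recorded in
    provenance under ``"zero_injected"``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in [0, 1], got {fraction}")
    n_corrupt = int(np.floor(fraction * len(dataset)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(dataset), size=n_corrupt, replace=False).tolist())
    new_windows = []
    corrupted_ids = []
    for idx, w in enumerate(dataset.windows):
        vals = w.values.copy()
        if idx in chosen:
            n_rows = int(rng.integers(1, 4))
            rows = rng.choice(vals.shape[0], size=n_rows, replace=False)
            vals[rows, :] = 0.0
            corrupted_ids.append(w.window_id)
        new_windows.append(SensorWindow(vals, w.label, w.window_id))
    prov = dict(dataset.provenance)
    prov["zero_injected"] = sorted(corrupted_ids)
    return LabeledDataset(new_windows, dict(dataset.class_names), prov)


# ---------------------------------------------------------------------------
# On-disk formats: long-format CSV for data, YAML for configs


def dataset_to_frame(dataset: LabeledDataset) -> pd.DataFrame:
    frames = []
    for w in dataset.windows:
        nt = w.values.shape[0]
        df = pd.DataFrame(w.values, columns=list(CHANNEL_NAMES))
        df.insert(0, "t_index", np.arange(nt))
        df.insert(0, "class", w.label)
        df.insert(0, "window_id", w.window_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def dataset_from_frame(
    frame: pd.DataFrame, class_names: Mapping[int, str] | None = None
) -> LabeledDataset:
    windows = []
    for wid, grp in frame.groupby("window_id", sort=False):
        grp = grp.sort_values("t_index")
        vals = grp[list(CHANNEL_NAMES)].to_numpy(dtype=float)
        label = int(grp["class"].iloc[0])
        windows.append(SensorWindow(vals, label, str(wid)))
    if class_names is None:
        class_names = {lab: f"class_{lab}" for lab in sorted({w.label for w in windows})}
    return LabeledDataset(windows, dict(class_names))


def save_dataset_csv(dataset: LabeledDataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def load_dataset_csv(path, class_names: Mapping[int, str] | None = None) -> LabeledDataset:
    return dataset_from_frame(pd.read_csv(path), class_names)


def _config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "fs": config.fs,
        "window_s": config.window_s,
        "n_per_class": config.n_per_class,
        "noise_sd": config.noise_sd,
        "zero_row_fraction": config.zero_row_fraction,
        "seed": config.seed,
        "random_phase": config.random_phase,
        "class_specs": [
            {
                "class_id": s.class_id,
                "name": s.name,
                "fundamental_hz": s.fundamental_hz,
                "channel_amplitudes": list(s.channel_amplitudes),
                "channel_phases": list(s.channel_phases),
                "harmonic_weights": list(s.harmonic_weights),
                "channel_fundamentals": {str(k): v for k, v in s.channel_fundamentals.items()},
            }
            for s in config.class_specs
        ],
    }


def _config_from_dict(d: Mapping) -> GeneratorConfig:
    specs = tuple(
        ActivityClassSpec(
            class_id=int(s["class_id"]),
            name=str(s["name"]),
            fundamental_hz=float(s["fundamental_hz"]),
            channel_amplitudes=tuple(s["channel_amplitudes"]),
            channel_phases=tuple(s.get("channel_phases", (0.0,) * N_CHANNELS)),
            harmonic_weights=tuple(s.get("harmonic_weights", (1.0,))),
            channel_fundamentals={
                int(k): float(v) for k, v in dict(s.get("channel_fundamentals", {})).items()
            },
        )
        for s in d["class_specs"]
    )
    return GeneratorConfig(
        class_specs=specs,
        n_per_class=int(d.get("n_per_class", 100)),
        fs=float(d.get("fs", 100.0)),
        window_s=float(d.get("window_s", 3.0)),
        noise_sd=float(d.get("noise_sd", 0.3)),
        zero_row_fraction=float(d.get("zero_row_fraction", 0.0)),
        seed=int(d.get("seed", 0)),
        random_phase=bool(d.get("random_phase", True)),
    )


def save_config_yaml(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = _config_from_dict(d)
    cfg.validate()
    return cfg
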