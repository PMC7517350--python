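"""Synthetic multichannel EEG cohorts with known alpha topography.

Each subject's recording is built per stage (segment) from region-localised
alpha sources: every channel of a driven region receives the same
narrowband source — a sinusoid at the subject's alpha frequency (10 Hz plus
per-subject jitter) with a slow random amplitude envelope — scaled by the
region's per-segment gain, plus two independent noise terms per channel:
broadband Gaussian noise and an alpha-band (8–13 Hz) background.  The
in-band background stands for the ubiquitous uncoordinated alpha activity
every sensor picks up; without it, band-limited correlation saturates for
arbitrarily weak sources, which real sensor EEG does not do.  All
channels are then passed through a fixed linear leakage matrix W whose
entries decay with inter-electrode distance on a schematic 2-D 10–20
layout, emulating volume conduction; W is constant over time, segments and
subjects, matching the standard assumption that sensor-level signal mixing
does not vary over time.

Two presets mirror the two arms of a prolonged simulated-driving study:

* ``control`` — no countermeasure; frontal alpha gain decays while
  parieto-occipital gain grows across the six stages, the classic
  posterior alpha rise of accumulating fatigue.
* ``radio`` — an auditory countermeasure; frontal gain stays high in every
  stage (overall larger amplitudes than control), the parieto-occipital
  gain stays low, and the auditory channels T3/T4 carry an extra source in
  stage 1 when the stimulus first engages.

Cohort generation is reproducible from (config, seed, subject index) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .io_montage import MONTAGE_19, Recording, canonical_label

__all__ = [
    "ScenarioConfig",
    "ELECTRODE_XY",
    "leakage_matrix",
    "simulate_recording",
    "simulate_cohort",
    "presets",
]

#: Schematic 2-D coordinates of the 19 electrodes (head of unit radius),
#: used only to parameterise the distance decay of the leakage kernel.
ELECTRODE_XY: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.50, 0.50), "Fz": (0.0, 0.50),
    "F4": (0.50, 0.50), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.50, -0.50), "Pz": (0.0, -0.50),
    "P4": (0.50, -0.50), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative settings for one cohort.

    ``region_gains`` maps a region name to (channel tuple, per-segment gain
    tuple); gains are source amplitudes in the same microvolt-like units as
    ``noise_sd``.
    """

    name: str
    region_gains: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]]
    n_subjects: int = 14
    fs: float = 500.0
    segment_seconds: float = 60.0
    n_segments: int = 6
    channels: tuple[str, ...] = MONTAGE_19
    alpha_freq: float = 10.0
    alpha_freq_jitter_sd: float = 0.5
    amp_mod_sd: float = 0.2
    mixing_spread: float = 0.2
    noise_sd: float = 1.0
    alpha_background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_subjects < 1:
            raise ValueError("need at least one segment and one subject")
        if self.fs <= 0 or self.segment_seconds <= 0:
            raise ValueError("fs and segment_seconds must be positive")
        if self.noise_sd < 0 or self.mixing_spread < 0 or self.alpha_background_sd < 0:
            raise ValueError("noise terms and mixing_spread must be >= 0")
        for name, (chans, gains) in self.region_gains.items():
            if len(gains) != self.n_segments:
                raise ValueError(f"region {name!r}: one gain per segment required")
            if any(g < 0 for g in gains):
                raise ValueError(f"region {name!r}: gains must be >= 0")
            for c in chans:
                canonical_label(c)

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def leakage_matrix(channels=MONTAGE_19, spread: float = 0.2) -> np.ndarray:
    """Distance-decay mixing kernel W, identical for all segments/subjects.

    W_ij = exp(-d_ij^2 / (2 spread^2)) with unit diagonal; ``spread=0``
    yields the identity (no leakage).
    """
    n = len(channels)
    if spread == 0.0:
        return np.eye(n)
    xy = np.asarray([ELECTRODE_XY[canonical_label(c)] for c in channels])
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * spread ** 2))


def _slow_envelope(rng: np.random.Generator, n: int, fs: float,
                   sd: float, knot_seconds: float = 2.0) -> np.ndarray:
    """Positive slowly varying amplitude envelope with mean about 1."""
    if sd == 0.0:
        return np.ones(n)
    n_knots = max(int(np.ceil(n / (knot_seconds * fs))) + 1, 2)
    knots = 1.0 + sd * rng.standard_normal(n_knots)
    t = np.linspace(0.0, n_knots - 1.0, n)
    env = np.interp(t, np.arange(n_knots), knots)
    return np.clip(env, 0.1, None)


def simulate_recording(cfg: ScenarioConfig, subject_index: int) -> Recording:
    """One subject's multichannel recording, segments concatenated.

    Deterministic in (cfg.seed, subject_index): the same pair always yields
    a bit-identical recording.
    """
    if not 0 <= subject_index < cfg.n_subjects:
        raise ValueError(f"subject index {subject_index} outside cohort")
    rng = np.random.default_rng([abs(cfg.seed), 7919, subject_index])
    n_ch = len(cfg.channels)
    per_seg = int(round(cfg.segment_seconds * cfg.fs))
    t = np.arange(per_seg) / cfg.fs
    f_alpha = cfg.alpha_freq + cfg.alpha_freq_jitter_sd * rng.standard_normal()
    W = leakage_matrix(cfg.channels, cfg.mixing_spread)
    index = {canonical_label(c): i for i, c in enumerate(cfg.channels)}

    sos = None
    if cfg.alpha_background_sd > 0.0:
        from scipy.signal import butter
        sos = butter(4, (8.0, 13.0), btype="bandpass", fs=cfg.fs, output="sos")

    pieces = []
    for seg in range(cfg.n_segments):
        X = cfg.noise_sd * rng.standard_normal((n_ch, per_seg))
        if sos is not None:
            from scipy.signal import sosfiltfilt
            bg = sosfiltfilt(sos, rng.standard_normal((n_ch, per_seg)), axis=1)
            bg /= bg.std(axis=1, keepdims=True)
            X += cfg.alpha_background_sd * bg
        for name, (chans, gains) in cfg.region_gains.items():
            g = gains[seg]
            phase = rng.uniform(0.0, 2.0 * np.pi)
            env = _slow_envelope(rng, per_seg, cfg.fs, cfg.amp_mod_sd)
            if g == 0.0:
                continue  # draws above keep the stream aligned across segments
            source = g * env * np.sin(2.0 * np.pi * f_alpha * t + phase)
            for c in chans:
                X[index[canonical_label(c)]] += source
        pieces.append(W @ X)
    return Recording(tuple(canonical_label(c) for c in cfg.channels),
                     cfg.fs, np.concatenate(pieces, axis=1))


def simulate_cohort(cfg: ScenarioConfig):
    """Yield (subject_id, Recording) for every subject of the cohort."""
    prefix = cfg.name[:1].upper() or "S"
    for i in range(cfg.n_subjects):
        yield f"{prefix}{i + 1:02d}", simulate_recording(cfg, i)


def ground_truth(cfg: ScenarioConfig) -> dict:
    """JSON-serialisable record of the generative settings of a cohort."""
    return {
        "name": cfg.name,
        "seed": cfg.seed,
        "fs": cfg.fs,
        "segment_seconds": cfg.segment_seconds,
        "n_segments": cfg.n_segments,
        "n_subjects": cfg.n_subjects,
        "noise_sd": cfg.noise_sd,
        "alpha_background_sd": cfg.alpha_background_sd,
        "mixing_spread": cfg.mixing_spread,
        "region_gains": {
            name: {"channels": list(chans), "gains": list(gains)}
            for name, (chans, gains) in cfg.region_gains.items()
        },
    }


def presets(segment_seconds: float = 60.0, n_subjects: int = 14,
            seed: int = 0) -> tuple[ScenarioConfig, ScenarioConfig]:
    """The two study-arm scenario presets (control, radio).

    Control: frontal gains strictly decreasing, parieto-occipital strictly
    increasing over the six stages.  Radio: frontal gains high throughout
    (segment 6 >= segment 2) with a T3/T4 auditory source in segment 1 and
    a flat low parieto-occipital gain.
    """
    from .io_montage import FRONTAL_CHANNELS, PARIETO_OCCIPITAL_CHANNELS

    control = ScenarioConfig(
        name="control",
        region_gains={
            "frontal": (FRONTAL_CHANNELS, (2.5, 2.0, 1.2, 0.6, 0.4, 0.25)),
            "parieto-occipital": (PARIETO_OCCIPITAL_CHANNELS,
                                  (0.3, 0.8, 1.4, 2.0, 2.5, 3.0)),
        },
        n_subjects=n_subjects,
        segment_seconds=segment_seconds,
        seed=seed,
    )
    radio = ScenarioConfig(
        name="radio",
        region_gains={
            "frontal": (FRONTAL_CHANNELS, (4.0, 3.5, 3.5, 3.5, 3.5, 4.0)),
            "parieto-occipital": (PARIETO_OCCIPITAL_CHANNELS,
                                  (0.5, 0.5, 0.5, 0.5, 0.5, 0.5)),
            "auditory": (("T3", "T4"), (3.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
        },
        n_subjects=n_subjects,
        segment_seconds=segment_seconds,
        seed=seed,
    )
    return control, radio
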