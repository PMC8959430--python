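"""Seeded synthetic multi-channel sEMG-like datasets.

Each movement class is defined by a per-channel amplitude profile and a
spectral sub-band, both drawn once from a dedicated profile seed.  A
repetition of a movement is band-limited Gaussian noise shaped in the class
sub-band, scaled per channel, multiplied by a trapezoidal onset/offset
envelope, plus white sensor noise at a configurable SNR.  Two independent
seed streams (class profiles vs noise) let the class structure stay fixed
while the noise is resampled.

The default protocol mirrors common acquisition setups for forearm sEMG:
5 s contractions separated by 3 s rest, six repetitions per movement, a
20–450 Hz signal band.  The simultaneous variant produces four single
movements, their four valid two-movement combinations (superposed channel
profiles) and rest — nine classes at 8 channels / 1200 Hz.

A Laplace-amplitude variant (``amplitude_dist="laplace"``) deliberately
breaks Gaussianity to exercise the density features on heavier tails.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError
from .signal_io import SignalRecord

__all__ = ["SyntheticConfig", "generate_dataset", "generate_simultaneous_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate a sequential-movement protocol."""

    n_subjects: int = 1
    n_classes: int = 10
    n_channels: int = 8
    n_repetitions: int = 6
    fs: float = 2000.0
    contraction_s: float = 5.0
    rest_s: float = 3.0
    band: tuple[float, float] = (20.0, 450.0)
    snr_db: float = 20.0
    profile_seed: int = 0
    noise_seed: int = 1
    include_rest: bool = False
    amplitude_range: tuple[float, float] = (0.5, 3.0)
    min_profile_separation: float = 1.5  # L2 distance between class amplitude vectors
    amplitude_dist: str = "gaussian"  # "gaussian" | "laplace"

    def __post_init__(self) -> None:
        if not (0.0 < self.band[0] < self.band[1] < self.fs / 2.0):
            raise ConfigError(f"band {self.band} outside (0, fs/2)")
        if self.n_repetitions < 2:
            raise ConfigError("need at least 2 repetitions")
        if min(self.n_subjects, self.n_classes, self.n_channels) < 1:
            raise ConfigError("all counts must be >= 1")
        if self.amplitude_dist not in ("gaussian", "laplace"):
            raise ConfigError(f"unknown amplitude_dist {self.amplitude_dist!r}")


def _class_profiles(config: SyntheticConfig, n_classes: int) -> list[dict]:
    """Per-class channel amplitudes and spectral sub-band, drawn once.

    Movement classes correspond to distinct muscle-activation patterns, so the
    amplitude vectors are rejection-sampled to keep every pair at least
    ``min_profile_separation`` apart in L2 (class separability is a controlled
    property of the generator, not an accident of the draw).
    """
    rng = np.random.default_rng(config.profile_seed)
    lo, hi = config.band
    profiles: list[dict] = []
    accepted: list[np.ndarray] = []
    for _ in range(n_classes):
        best, best_dist = None, -np.inf
        for _attempt in range(100):
            cand = rng.uniform(*config.amplitude_range, size=config.n_channels)
            dist = min(
                (float(np.linalg.norm(cand - a)) for a in accepted),
                default=np.inf,
            )
            if dist > best_dist:
                best, best_dist = cand, dist
            if dist >= config.min_profile_separation:
                break
        accepted.append(best)
        center = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
        width = rng.uniform(0.3, 0.9) * (hi - lo) / 2.0
        sub_lo = max(lo, center - width)
        sub_hi = min(hi, center + width)
        profiles.append({"amps": best, "band": (sub_lo, sub_hi)})
    return profiles


def _trapezoid(n: int, ramp_frac: float = 0.1) -> np.ndarray:
    ramp = max(1, int(round(ramp_frac * n)))
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp :] = np.linspace(1.0, 0.0, ramp)
    return env


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    dist: str,
) -> np.ndarray:
    """Unit-power noise band-limited to ``band``."""
    white = rng.standard_normal(n) if dist == "gaussian" else rng.laplace(size=n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    power = np.mean(shaped**2)
    return shaped / np.sqrt(power) if power > 0 else shaped


def _make_record(
    rng: np.random.Generator,
    config: SyntheticConfig,
    amps: np.ndarray,
    bands: list[tuple[float, float]],
    mix: list[float],
    label: int,
    repetition: int,
    subject: str,
    duration_s: float,
) -> SignalRecord:
    n = int(round(duration_s * config.fs))
    env = _trapezoid(n)
    channels = np.zeros((config.n_channels, n))
    if label != 0:
        for band, coeff in zip(bands, mix):
            base = np.stack(
                [
                    _shaped_noise(rng, n, config.fs, band, config.amplitude_dist)
                    for _ in range(config.n_channels)
                ]
            )
            channels = channels + coeff * base
        channels *= amps[:, None] * env[None, :]
    signal_power = np.mean(channels**2) if label != 0 else 1.0
    noise_power = signal_power * 10.0 ** (-config.snr_db / 10.0)
    sensor = rng.standard_normal(channels.shape) * np.sqrt(noise_power)
    return SignalRecord(
        samples=channels + sensor,
        fs=config.fs,
        label=label,
        repetition=repetition,
        subject=subject,
        meta={"synthetic": True},
    )


def generate_dataset(config: SyntheticConfig) -> list[SignalRecord]:
    """Sequential-movement dataset: one record per (subject, class, repetition)."""
    profiles = _class_profiles(config, config.n_classes)
    rng = np.random.default_rng(config.noise_seed)
    records = []
    for s in range(config.n_subjects):
        subject = f"s{s + 1}"
        for c, prof in enumerate(profiles, start=1):
            for rep in range(1, config.n_repetitions + 1):
                records.append(
                    _make_record(
                        rng, config, prof["amps"], [prof["band"]], [1.0],
                        label=c, repetition=rep, subject=subject,
                        duration_s=config.contraction_s,
                    )
                )
                if config.include_rest:
                    records.append(
                        _make_record(
                            rng, config, prof["amps"], [prof["band"]], [1.0],
                            label=0, repetition=rep, subject=subject,
                            duration_s=config.rest_s,
                        )
                    )
    return records


#: single movements 1–4 and the four valid two-movement combinations
_COMBO_PAIRS = [(1, 3), (1, 4), (2, 3), (2, 4)]


def generate_simultaneous_dataset(
    config: SyntheticConfig | None = None,
) -> list[SignalRecord]:
    """Nine-class simultaneous-movement dataset (rest + 4 singles + 4 combos).

    Requires 8 channels at 1200 Hz (the simultaneous acquisition setup);
    combined classes superpose the two component profiles with unit mixing
    coefficients, so channel power approximately adds.
    """
    if config is None:
        config = SyntheticConfig(
            n_classes=4, n_channels=8, n_repetitions=4, fs=1200.0,
            contraction_s=3.0, band=(20.0, 450.0),
        )
    if config.n_channels != 8 or config.fs != 1200.0:
        raise ConfigError("simultaneous protocol uses 8 channels at 1200 Hz")
    singles = _class_profiles(config, 4)
    rng = np.random.default_rng(config.noise_seed)
    records = []
    for s in range(config.n_subjects):
        subject = f"s{s + 1}"
        for rep in range(1, config.n_repetitions + 1):
            # rest
            records.append(
                _make_record(
                    rng, config, np.zeros(config.n_channels), [], [],
                    label=0, repetition=rep, subject=subject,
                    duration_s=config.contraction_s,
                )
            )
            # single movements 1..4
            for c, prof in enumerate(singles, start=1):
                records.append(
                    _make_record(
                        rng, config, prof["amps"], [prof["band"]], [1.0],
                        label=c, repetition=rep, subject=subject,
                        duration_s=config.contraction_s,
                    )
                )
            # combined movements 5..8
            for k, (m1, m2) in enumerate(_COMBO_PAIRS, start=5):
                p1, p2 = singles[m1 - 1], singles[m2 - 1]
                records.append(
                    _make_combined(rng, config, p1, p2, label=k,
                                   repetition=rep, subject=subject)
                )
    return records


def _make_combined(
    rng: np.random.Generator,
    config: SyntheticConfig,
    p1: dict,
    p2: dict,
    label: int,
    repetition: int,
    subject: str,
) -> SignalRecord:
    """Superpose two independently generated single-movement signals."""
    n = int(round(config.contraction_s * config.fs))
    env = _trapezoid(n)
    total = np.zeros((config.n_channels, n))
    for prof in (p1, p2):
        base = np.stack(
            [
                _shaped_noise(rng, n, config.fs, prof["band"], config.amplitude_dist)
                for _ in range(config.n_channels)
            ]
        )
        total += prof["amps"][:, None] * base
    total *= env[None, :]
    signal_power = np.mean(total**2)
    noise_power = signal_power * 10.0 ** (-config.snr_db / 10.0)
    sensor = rng.standard_normal(total.shape) * np.sqrt(noise_power)
    return SignalRecord(
        samples=total + sensor,
        fs=config.fs,
        label=label,
        repetition=repetition,
        subject=subject,
        meta={"synthetic": True, "combined": True},
    )
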