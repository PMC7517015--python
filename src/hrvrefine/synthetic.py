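"""Synthetic RR-interval cohorts with NSR-like and CHF-like dynamics.

The generator emulates the statistical structure the refinement pipeline
assumes in a 24-h Holter-derived RR list: a slow circadian baseline with
AR(1) beat-to-beat variability, episodic fast-heart-rate periods, ectopic
beats labeled non-'N', occasional artifact intervals longer than 2 s, and
quantization of every physiological value to the 128 Hz sampling grid
(multiples of 7.8125 ms — required for the mode gate to be meaningful).

The two archetypes differ the way the cohorts differ: the NSR-like profile
has a high-variability baseline and rare, irregular fast episodes (exercise-
like), while the CHF-like profile has a fast low-variability baseline and
frequent, very regular fast episodes (symptom-like). Fast episodes are
AR(1) with the profile's own autocorrelation and a marginal SD equal to
``fast_episode_sd_ms``, because real RR series are strongly autocorrelated;
white-noise episodes would be morphologically unlike any Holter segment.
Profile numbers carry no claim of physiological fidelity beyond exercising
the selection gates (the 600 ms trigger sits between baseline and episode
means).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from hrvrefine.rr_io import CohortManifest, Group, RRRecording, write_manifest, write_rr_file

__all__ = [
    "RR_QUANTUM_MS",
    "SimProfile",
    "nsr_profile",
    "chf_profile",
    "simulate_recording",
    "simulate_cohort",
]

#: 128 Hz sampling period in ms; all physiological RR values are multiples of it.
RR_QUANTUM_MS = 1000.0 / 128.0

_MIN_RR_MS = 250.0  # physiological floor, = 32 sampling periods
_EPISODE_BEATS = (400, 1200)  # uniform episode length; >= 400 so a 300-beat window fits


@dataclass(frozen=True)
class SimProfile:
    """Parameters of one simulated subject.

    fast_episode_rate is the expected number of fast-HR episodes per 10^4
    beats; ectopic_rate and artifact_rate are per-beat probabilities.
    """

    archetype: str  # "NSR_LIKE" | "CHF_LIKE"
    seed: int
    duration_beats: int = 100_000
    base_rr_ms: float = 800.0
    circadian_amp_ms: float = 120.0
    ar1_phi: float = 0.9
    innovation_sd_ms: float = 25.0
    fast_episode_rate: float = 1.5
    fast_episode_mean_rr_ms: float = 555.0
    fast_episode_sd_ms: float = 35.0
    ectopic_rate: float = 0.005
    artifact_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.archetype not in {"NSR_LIKE", "CHF_LIKE"}:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.duration_beats < 1:
            raise ValueError("duration_beats must be >= 1")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        if not 0 <= self.ectopic_rate < 1 or not 0 <= self.artifact_rate < 1:
            raise ValueError("rates must be in [0, 1)")
        if self.fast_episode_rate < 0:
            raise ValueError("fast_episode_rate must be >= 0")
        if not self.base_rr_ms > self.fast_episode_mean_rr_ms > 0:
            raise ValueError("need base_rr_ms > fast_episode_mean_rr_ms > 0")
        if self.innovation_sd_ms < 0 or self.fast_episode_sd_ms < 0 or self.circadian_amp_ms < 0:
            raise ValueError("amplitudes and SDs must be >= 0")


def nsr_profile(seed: int, duration_beats: int = 100_000) -> SimProfile:
    """NSR-like default: variable baseline, rare variable fast episodes."""
    return SimProfile(
        archetype="NSR_LIKE",
        seed=seed,
        duration_beats=duration_beats,
        base_rr_ms=800.0,
        circadian_amp_ms=120.0,
        ar1_phi=0.9,
        innovation_sd_ms=25.0,
        fast_episode_rate=1.5,
        fast_episode_mean_rr_ms=555.0,
        fast_episode_sd_ms=35.0,
        ectopic_rate=0.005,
        artifact_rate=5e-4,
    )


def chf_profile(seed: int, duration_beats: int = 100_000) -> SimProfile:
    """CHF-like default: fast rigid baseline, frequent regular fast episodes."""
    return SimProfile(
        archetype="CHF_LIKE",
        seed=seed,
        duration_beats=duration_beats,
        base_rr_ms=640.0,
        circadian_amp_ms=40.0,
        ar1_phi=0.9,
        innovation_sd_ms=6.0,
        fast_episode_rate=3.5,
        fast_episode_mean_rr_ms=560.0,
        fast_episode_sd_ms=10.0,
        ectopic_rate=0.02,
        artifact_rate=5e-4,
    )


def _ar1(n: int, sd_marginal: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with the given marginal SD (vectorized recursion)."""
    if n == 0:
        return np.empty(0)
    if sd_marginal == 0.0:
        return np.zeros(n)
    innovation_sd = sd_marginal * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innovation_sd, size=n)
    eps[0] = rng.normal(0.0, sd_marginal)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_recording(profile: SimProfile) -> RRRecording:
    """Generate one subject's RR recording from a profile (deterministic in seed)."""
    rng = np.random.default_rng(profile.seed)
    n = profile.duration_beats

    beats_per_day = 24 * 3600 * 1000.0 / profile.base_rr_ms
    circadian = profile.circadian_amp_ms * np.sin(2 * np.pi * np.arange(n) / beats_per_day)
    rr = profile.base_rr_ms + circadian + _ar1(n, _marginal_sd(profile), profile.ar1_phi, rng)

    in_episode = np.zeros(n, dtype=bool)
    n_episodes = rng.poisson(profile.fast_episode_rate * n / 1e4)
    for _ in range(n_episodes):
        length = int(rng.integers(_EPISODE_BEATS[0], _EPISODE_BEATS[1] + 1))
        if length >= n:
            start, length = 0, n
        else:
            start = int(rng.integers(0, n - length))
        rr[start : start + length] = profile.fast_episode_mean_rr_ms + _ar1(
            length, profile.fast_episode_sd_ms, profile.ar1_phi, rng
        )
        in_episode[start : start + length] = True

    labels = np.full(n, "N", dtype="U1")
    ectopic = rng.random(n) < profile.ectopic_rate
    labels[ectopic] = "V"
    # premature (short) ectopic intervals; removed later by label, not value
    rr[ectopic] *= rng.uniform(0.6, 0.85, size=int(ectopic.sum()))

    rr = np.maximum(np.round(rr / RR_QUANTUM_MS) * RR_QUANTUM_MS, _MIN_RR_MS)

    artifact = rng.random(n) < profile.artifact_rate
    rr[artifact] = rng.uniform(2100.0, 4000.0, size=int(artifact.sum()))
    labels[artifact] = "N"  # missed-beat artifacts look like normal annotations

    return RRRecording(
        subject_id=f"{profile.archetype.lower()}-{profile.seed}",
        group=Group.NSR if profile.archetype == "NSR_LIKE" else Group.CHF,
        rr_ms=rr,
        beat_labels=labels,
        stage_counts={"raw": n},
    )


def _marginal_sd(profile: SimProfile) -> float:
    """Marginal SD of the baseline AR(1) given its innovation SD."""
    return profile.innovation_sd_ms / np.sqrt(1.0 - profile.ar1_phi**2)


def simulate_cohort(
    n_nsr: int,
    n_chf: int,
    seed: int,
    out_dir: str | Path,
    duration_beats: int = 100_000,
) -> CohortManifest:
    """Write a cohort of RR text files plus a ``manifest.csv``.

    Per-subject seeds are drawn deterministically from the master seed, so
    the same (n_nsr, n_chf, seed) always yields identical files.
    """
    if n_nsr < 1 or n_chf < 1:
        raise ValueError("need at least one subject per group")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_nsr + n_chf)

    entries: list[tuple[str, Group, Path]] = []
    for i in range(n_nsr):
        profile = nsr_profile(int(child_seeds[i]), duration_beats)
        rec = simulate_recording(profile)
        sid = f"nsr{i + 1:03d}"
        rec.subject_id = sid
        path = out_dir / f"{sid}.rr"
        write_rr_file(rec, path)
        entries.append((sid, Group.NSR, path))
    for i in range(n_chf):
        profile = chf_profile(int(child_seeds[n_nsr + i]), duration_beats)
        rec = simulate_recording(profile)
        sid = f"chf{i + 1:03d}"
        rec.subject_id = sid
        path = out_dir / f"{sid}.rr"
        write_rr_file(rec, path)
        entries.append((sid, Group.CHF, path))

    manifest = CohortManifest(entries=entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
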