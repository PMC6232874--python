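"""Synthetic three-group EEG-like cohorts with band-specific coupling.

Each subject's channels are built from one shared *rhythmic* source per band
plus independent band-limited Gaussian channel noise:

    channel_c = sum_b [ kappa_gb * s_b + (1 - kappa_gb) * n_cb ] / norm_b
                + sigma_obs * white_c

where ``s_b`` is the subject's shared rhythm in band b (a sinusoid at a
subject-specific frequency inside the band, random phase), ``n_cb``
independent band-filtered noise in the same band (all unit variance),
``norm_b`` restores unit band variance, and ``kappa_gb`` in [0, 1] is the
group's coupling strength in that band.

The shared component is a stable rhythm, not filtered noise, because
cross-entropy metrics respond to shared *pattern recurrence* rather than to
linear correlation: mixing two Gaussian band-limited signals leaves
Cross-SampEn nearly unchanged even at high mixing coefficients, whereas a
regular waveform common to both channels lowers it monotonically once it
dominates.  With the quasi-sinusoidal rhythm used here the metric is
sensitive for kappa of roughly 0.6 and above, so the healthy-control
baseline is placed at kappa = 0.9 and patient effects reduce it within the
sensitive range.

The default effect structure encodes reduced coupling in patients: relative
to the healthy-control baseline of kappa = 0.9 in every band, the MCI group
is 0.15 lower in beta1, and the AD group 0.25 lower in theta and beta1 — so
patients show *higher* Cross-SampEn in the affected bands, the direction the
analysis is designed to detect.  A per-subject kappa jitter (SD 0.1 by
default) models between-subject heterogeneity; it is sized so that groups
overlap realistically — the milder MCI effect stays genuinely harder to
classify than the AD effect rather than both saturating.
``effect_direction="patients_more_coupled"`` mirrors the effects for
sensitivity analyses.

This is a statistical test-bed, not a physiological EEG model: there is no
1/f background, no alpha peak, and no volume conduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocessing import (
    CANONICAL_BANDS,
    DEFAULT_CHANNELS,
    GROUPS,
    BandSpec,
    Recording,
    design_bandpass,
    _filtfilt,
)

__all__ = [
    "SyntheticCohortSpec",
    "band_limited_source",
    "stable_rhythm",
    "generate_subject",
    "generate_cohort",
    "default_kappa",
]

#: Healthy-control coupling baseline applied in every band.  Kept inside the
#: kappa range where Cross-SampEn responds to the shared rhythm (>= ~0.6).
BASE_KAPPA = 0.9
#: Coupling reduction for MCI (beta1) and AD (theta and beta1).
MCI_EFFECT = 0.15
AD_EFFECT = 0.25
AFFECTED = {"MCI": ("beta1",), "AD": ("theta", "beta1")}


def default_kappa(effect_direction: str = "patients_less_coupled") -> dict[str, dict[str, float]]:
    """Per-group, per-band coupling strengths encoding the default effects."""
    if effect_direction not in ("patients_less_coupled", "patients_more_coupled"):
        raise ValueError("unknown effect_direction")
    sign = -1.0 if effect_direction == "patients_less_coupled" else 1.0
    kappa = {g: {b.name: BASE_KAPPA for b in CANONICAL_BANDS} for g in GROUPS}
    kappa["MCI"]["beta1"] = min(max(BASE_KAPPA + sign * MCI_EFFECT, 0.0), 1.0)
    for band in AFFECTED["AD"]:
        kappa["AD"][band] = min(max(BASE_KAPPA + sign * AD_EFFECT, 0.0), 1.0)
    return kappa


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a realistic resting-state study design: 20 subjects per
    group in the
    training set and 17 per group in the test set, 19 channels at 200 Hz,
    5-s epochs, and about 46 artifact-free epochs per 5-min recording.
    """

    seed: int
    n_train: tuple[int, int, int] = (20, 20, 20)  # (HC, MCI, AD)
    n_test: tuple[int, int, int] = (17, 17, 17)
    fs: float = 200.0
    n_channels: int = 19
    epoch_duration_s: float = 5.0
    epochs_per_subject: int = 46
    kappa: dict[str, dict[str, float]] | None = None
    kappa_jitter_sd: float = 0.1
    noise_sd: float = 0.1
    effect_direction: str = "patients_less_coupled"
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if any(n < 2 for n in self.n_train + self.n_test):
            raise ValueError("group sizes must be >= 2")
        if not 1 <= self.n_channels <= len(DEFAULT_CHANNELS):
            raise ValueError("n_channels must be between 1 and 19")
        kappa = self.kappa if self.kappa is not None else default_kappa(self.effect_direction)
        for g, per_band in kappa.items():
            for b, k in per_band.items():
                if not 0.0 <= k <= 1.0:
                    raise ValueError(f"kappa[{g}][{b}] = {k} outside [0, 1]")
        object.__setattr__(self, "kappa", kappa)

    @property
    def channels(self) -> tuple[str, ...]:
        return DEFAULT_CHANNELS[: self.n_channels]

    @property
    def n_samples(self) -> int:
        return int(round(self.epochs_per_subject * self.epoch_duration_s * self.fs))


def _generation_fir_order(band: BandSpec, fs: float) -> int:
    """Sharp generation filter: transition width ~ a quarter of the band.

    The analysis default (3 cycles of the low edge) is too leaky for signal
    *generation*: channel noise must genuinely stay inside its band, or the
    group-dependent noise weight (1 - kappa) bleeds group differences into
    neighboring bands.
    """
    transition_hz = max(0.5, (band.high_hz - band.low_hz) / 4.0)
    order = math.ceil(3.3 * fs / transition_hz)
    return order + (order % 2)


def band_limited_source(
    band: BandSpec, fs: float, n_samples: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Zero-phase band-filtered, z-normalized white noise.

    The passband is inset 10% of the band width from each nominal edge so
    that, together with the sharp generation filter, essentially all noise
    energy stays strictly inside the nominal band.  Adjacent analysis bands
    share boundary frequencies; without the inset, the group-dependent noise
    weight (1 - kappa) of one band would be visible through the neighbor's
    filter and smear group effects across bands.
    """
    if band.high_hz >= fs / 2.0:
        raise ValueError(f"band {band.name} above Nyquist at fs={fs}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    width = band.high_hz - band.low_hz
    inner = BandSpec(band.name, band.low_hz + 0.1 * width, band.high_hz - 0.1 * width)
    taps = design_bandpass(
        inner.low_hz, inner.high_hz, fs, _generation_fir_order(inner, fs)
    )
    x = _filtfilt(taps, rng.standard_normal(n_samples))
    return (x - x.mean()) / x.std()


def stable_rhythm(
    band: BandSpec, fs: float, n_samples: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Unit-variance sinusoid at a random frequency inside the band.

    The frequency is drawn uniformly from the middle 60% of the band (so the
    rhythm survives band-pass filtering intact) and the phase uniformly from
    [0, 2*pi).  A regular shared waveform like this is what cross-entropy
    coupling metrics actually detect; see the module docstring.
    """
    if band.high_hz >= fs / 2.0:
        raise ValueError(f"band {band.name} above Nyquist at fs={fs}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    width = band.high_hz - band.low_hz
    freq = rng.uniform(band.low_hz + 0.2 * width, band.high_hz - 0.2 * width)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_samples) / fs
    x = np.sin(2.0 * np.pi * freq * t + phase)
    return (x - x.mean()) / x.std()


def generate_subject(
    spec: SyntheticCohortSpec,
    group: str,
    subject_seed: np.random.SeedSequence | int,
    subject_id: str = "",
) -> Recording:
    """One subject's multichannel recording under the group's coupling."""
    if group not in GROUPS:
        raise ValueError(f"invalid group {group!r}")
    if isinstance(subject_seed, np.random.SeedSequence):
        rng = np.random.default_rng(subject_seed)
    else:
        rng = np.random.default_rng(int(subject_seed))
    n = spec.n_samples
    n_ch = spec.n_channels
    data = np.zeros((n_ch, n))
    for band in spec.bands:
        kappa_nominal = spec.kappa[group][band.name]
        kappa_subj = float(
            np.clip(kappa_nominal + rng.normal(0.0, spec.kappa_jitter_sd), 0.0, 1.0)
        )
        shared = stable_rhythm(band, spec.fs, n, rng)
        norm = np.hypot(kappa_subj, 1.0 - kappa_subj)
        for c in range(n_ch):
            noise = band_limited_source(band, spec.fs, n, rng)
            data[c] += (kappa_subj * shared + (1.0 - kappa_subj) * noise) / norm
    data += spec.noise_sd * rng.standard_normal((n_ch, n))
    return Recording(
        subject_id=subject_id or f"{group}-{rng.integers(1 << 31)}",
        fs=spec.fs,
        channels=spec.channels,
        data=data,
        group=group,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[list[Recording], list[Recording]]:
    """Disjoint labeled train and test recordings, reproducible from the seed.

    Per-subject seeds are spawned from the master seed, so the cohort is
    bitwise-reproducible and subjects are statistically independent.
    """
    master = np.random.SeedSequence(spec.seed)
    n_subjects = sum(spec.n_train) + sum(spec.n_test)
    children = master.spawn(n_subjects)
    train: list[Recording] = []
    test: list[Recording] = []
    idx = 0
    for split, sizes, out in (("train", spec.n_train, train), ("test", spec.n_test, test)):
        for group, size in zip(GROUPS, sizes):
            for k in range(size):
                rec = generate_subject(
                    spec, group, children[idx], subject_id=f"{split}-{group}-{k:02d}"
                )
                out.append(rec)
                idx += 1
    return train, test
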