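"""Synthetic multi-region LFP cohort generator.

Generates labeled cohorts of per-(mouse, session, region) time series whose
band-power structure is controlled exactly, plus a structured region-level
missingness mask, so that every downstream stage (feature extraction,
completion, sMVCCA ranking, classification) can be exercised and its recovery
properties tested without any recorded data.

Signal model
------------
Each signal is a sum over the three canonical bands of band-limited Gaussian
noise plus a small broadband white-noise floor.  The band component for band
``b`` in region ``r`` has standard deviation ``noise_floor * sqrt(gain)``
where ``gain`` is the configured class effect (diseased mice, informative
regions) times optional per-mouse and per-window log-normal heterogeneity.
Band components are synthesized by brick-wall spectral masking of white noise
(rfft -> zero bins outside [low, high] -> irfft), so their spectral support is
exactly the nominal band and the configured gains map directly onto the
band-amplitude features extracted downstream.

Because power gains enter through ``sqrt(gain)``, a power gain of 4 yields a
2x mean band amplitude in the affected region, which is how the ground-truth
effects are phrased throughout.

Seeding
-------
A single master seed is fanned out by a counter scheme: the RNG of each
(mouse, session, region) stream is seeded by the tuple
``(seed, STREAM_SIGNAL, mouse_index, session, region_index)``, per-mouse
heterogeneity draws by ``(seed, STREAM_JITTER, mouse_index)`` and the mask by
``(seed, STREAM_MASK)``.  Adding mice or sessions therefore never reshuffles
existing signals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandSpec
from .errors import ConfigurationError

#: The nine signal sources of the study cohort: seven brain regions plus the
#: neck EMG and the respiration channel, in the order they are ranked by the
#: real-data analysis.
DEFAULT_REGIONS: tuple[str, ...] = (
    "THL", "PAG", "PL", "AMY", "S1", "ACC", "BR", "NAc", "EMG",
)

# Sub-stream tags for the seed fan-out (arbitrary fixed integers).
_STREAM_SIGNAL = 11
_STREAM_JITTER = 23
_STREAM_MASK = 37
_STREAM_SESSION_JITTER = 41

LABEL_DISEASED = "diseased"
LABEL_WILD = "wild"


def default_effect_sizes() -> dict[str, dict[str, float]]:
    """Graded power gains for the seven informative sources.

    The seven brain regions carry a class effect on the delta and theta bands
    with magnitudes decreasing along the canonical order, emulating a cohort
    in which some regions carry strong disease signatures and others weak
    ones; NAc and EMG carry none.  The gamma band is left untouched so that
    band ratios as well as amplitudes differ between classes.
    """
    gains = (6.0, 5.0, 4.2, 3.5, 3.0, 2.6, 2.2)
    return {
        region: {"delta": g, "theta": g}
        for region, g in zip(DEFAULT_REGIONS[:7], gains)
    }


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study design: 15 diseased-model and 10 wild-type
    mice, nine signal sources of which seven are informative, three sessions
    per mouse and ~11.6% of (mouse, region) cells missing.  The default
    sampling rate (400 Hz) and session length (600 s) are a reduced recording
    scale that preserves every structural property (60-s windows, all three
    bands below Nyquist); the full recording scale (2 kHz, 3600 s) is
    available via :func:`full_recording_scale`.

    ``gain_jitter_sd`` and ``window_jitter_sd`` are standard deviations of
    log-normal power heterogeneity: per (mouse, region, band), shared by both
    classes, and per 60-s window respectively.  They emulate the individual
    differences and slow band-power fluctuations of real recordings; both
    default to 0.35 and 0.25, chosen so that single-region leave-mouse-out
    classification is well above chance but far from perfect, as in real
    cohorts.
    """

    n_diseased: int = 15
    n_wild: int = 10
    regions: tuple[str, ...] = DEFAULT_REGIONS
    informative_regions: tuple[str, ...] = DEFAULT_REGIONS[:7]
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_effect_sizes
    )
    sessions_per_mouse: int = 3
    session_duration: float = 600.0
    fs: float = 400.0
    noise_floor: float = 1.0
    missing_fraction: float = 0.116
    seed: int = 0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    gain_jitter_sd: float | Mapping[str, float] = 0.35
    session_jitter_sd: float | Mapping[str, float] = 0.0
    window_jitter_sd: float = 0.25
    modulation_period: float = 60.0

    @staticmethod
    def _sd_for(spec: float | Mapping[str, float], region: str) -> float:
        if isinstance(spec, Mapping):
            return float(spec.get(region, 0.0))
        return float(spec)

    def jitter_sd_for(self, region: str) -> float:
        """Per-mouse log-power heterogeneity of a region.

        A mapping allows region-specific values: non-neural channels such as
        EMG vary far more between animals (electrode placement, muscle mass)
        than brain LFP amplitudes do.
        """
        return self._sd_for(self.gain_jitter_sd, region)

    def session_jitter_sd_for(self, region: str) -> float:
        """Per-session log-power heterogeneity (day-to-day drift) of a region."""
        return self._sd_for(self.session_jitter_sd, region)

    def validate(self) -> None:
        if self.n_diseased < 1 or self.n_wild < 1:
            raise ConfigurationError(
                "need at least one mouse of each class "
                f"(got n_diseased={self.n_diseased}, n_wild={self.n_wild})"
            )
        if len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("region labels must be unique")
        unknown = set(self.informative_regions) - set(self.regions)
        if unknown:
            raise ConfigurationError(
                f"informative_regions not a subset of regions: {sorted(unknown)}"
            )
        unknown = set(self.effect_sizes) - set(self.regions)
        if unknown:
            raise ConfigurationError(
                f"effect_sizes reference unknown regions: {sorted(unknown)}"
            )
        band_names = {b.name for b in self.bands}
        for region, per_band in self.effect_sizes.items():
            for band, gain in per_band.items():
                if band not in band_names:
                    raise ConfigurationError(
                        f"effect_sizes[{region!r}] references unknown band {band!r}"
                    )
                if not gain > 0:
                    raise ConfigurationError(
                        f"effect_sizes[{region!r}][{band!r}] must be > 0, got {gain}"
                    )
        for band in self.bands:
            band.validate_for_fs(self.fs)
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError(
                f"missing_fraction must lie in [0, 1), got {self.missing_fraction}"
            )
        if self.session_duration <= 0 or self.fs <= 0:
            raise ConfigurationError("session_duration and fs must be positive")
        if self.sessions_per_mouse < 1:
            raise ConfigurationError("sessions_per_mouse must be >= 1")
        if self.noise_floor <= 0:
            raise ConfigurationError("noise_floor must be positive")
        for name, spec in (("gain_jitter_sd", self.gain_jitter_sd),
                           ("session_jitter_sd", self.session_jitter_sd)):
            values = (list(spec.values()) if isinstance(spec, Mapping)
                      else [spec])
            if any(v < 0 for v in values):
                raise ConfigurationError(f"{name} must be >= 0")
            if isinstance(spec, Mapping):
                unknown = set(spec) - set(self.regions)
                if unknown:
                    raise ConfigurationError(
                        f"{name} references unknown regions: {sorted(unknown)}"
                    )
        if self.window_jitter_sd < 0:
            raise ConfigurationError("window_jitter_sd must be >= 0")

    @property
    def mouse_ids(self) -> tuple[str, ...]:
        dis = tuple(f"F759_{i + 1}" for i in range(self.n_diseased))
        wild = tuple(f"wild_{i + 1}" for i in range(self.n_wild))
        return dis + wild

    def label_of(self, mouse_id: str) -> str:
        return LABEL_DISEASED if mouse_id.startswith("F759_") else LABEL_WILD


def ranking_recovery_config(seed: int = 0) -> CohortConfig:
    """Study conditions for the region-ranking recovery experiment.

    Two strongly informative regions (THL, PAG; power gain 6 on delta and
    theta, i.e. 2.45x band amplitude) against seven uninformative sources,
    with the study's ~11.6% region-level missingness, at a reduced cohort
    scale (10 mice, one 300-s session) so that many seeded replicates are
    affordable.  The cross-loading ranking is expected to place THL and PAG
    in the top two ranks.
    """
    effect = {r: {"delta": 6.0, "theta": 6.0} for r in ("THL", "PAG")}
    return CohortConfig(
        n_diseased=6, n_wild=4, sessions_per_mouse=1, session_duration=300.0,
        informative_regions=("THL", "PAG"), effect_sizes=effect,
        gain_jitter_sd=0.1, window_jitter_sd=0.5, missing_fraction=0.116,
        seed=seed,
    )


def r_sweep_config(seed: int = 0) -> CohortConfig:
    """Study conditions for the accuracy-vs-R peak-recovery experiment.

    Full 25-mouse cohort (15 diseased / 10 wild) with exactly seven
    informative brain regions sharing an equal, modest power gain (1.6 on
    delta and theta) and two pure-noise channels (NAc, EMG).  The noise
    channels carry strong session-to-session amplitude drift (log-power sd
    4.0), emulating the day-to-day variability of non-neural recordings:
    they offer no class information, and under leave-mouse-out evaluation
    the drift of a held-out mouse's sessions actively degrades classifiers
    that include them, so the accuracy-vs-R curve is expected to peak at
    R = 7.  Three 900-s sessions per mouse (45 windows each) keep the
    per-fold accuracy estimates tight enough to resolve the peak;
    missingness is disabled to isolate the region-subset effect.
    """
    effect = {r: {"delta": 1.6, "theta": 1.6} for r in DEFAULT_REGIONS[:7]}
    return CohortConfig(
        n_diseased=15, n_wild=10, sessions_per_mouse=3,
        session_duration=900.0,
        informative_regions=DEFAULT_REGIONS[:7], effect_sizes=effect,
        gain_jitter_sd=0.05, window_jitter_sd=0.6,
        session_jitter_sd={"NAc": 4.0, "EMG": 4.0},
        missing_fraction=0.0, seed=seed,
    )


def full_recording_scale(config: CohortConfig | None = None) -> CohortConfig:
    """Return ``config`` (default conditions if None) at full recording scale:
    2 kHz sampling and 3600-s sessions."""
    base = config if config is not None else CohortConfig()
    return replace(base, fs=2000.0, session_duration=3600.0)


@dataclass
class SyntheticCohort:
    """A generated cohort: signals, labels, missingness mask and ground truth.

    ``signals`` maps (mouse_id, session, region) to a 1-D float array; masked
    (mouse, region) cells have no entries.  ``mask`` is a boolean DataFrame
    (mice x regions, True = observed).  ``ground_truth`` retains the effect
    configuration for recovery tests.
    """

    signals: dict[tuple[str, int, str], np.ndarray]
    labels: dict[str, str]
    mask: pd.DataFrame
    fs: float
    config: CohortConfig
    ground_truth: dict

    @property
    def mouse_ids(self) -> list[str]:
        return list(self.mask.index)

    @property
    def regions(self) -> list[str]:
        return list(self.mask.columns)


_BAND_BIN_CACHE: dict[tuple, np.ndarray] = {}


def _band_bins(n: int, fs: float, band: BandSpec) -> np.ndarray:
    key = (n, fs, band.low, band.high)
    if key not in _BAND_BIN_CACHE:
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        _BAND_BIN_CACHE[key] = np.nonzero(
            (freqs >= band.low) & (freqs <= band.high)
        )[0]
    return _BAND_BIN_CACHE[key]


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band: BandSpec) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support exactly [low, high].

    Synthesized directly in the frequency domain: i.i.d. complex Gaussian
    coefficients on the in-band rfft bins, zero elsewhere.
    """
    bins = _band_bins(n, fs, band)
    spec = np.zeros(n // 2 + 1, dtype=complex)
    coeffs = rng.standard_normal((bins.size, 2))
    spec[bins] = coeffs[:, 0] + 1j * coeffs[:, 1]
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _synthesize_signal(rng: np.random.Generator, config: CohortConfig,
                       log_gains: np.ndarray) -> np.ndarray:
    """One session signal: per-band components plus broadband floor.

    ``log_gains`` holds the log power gain per band (class effect + per-mouse
    heterogeneity).  Per-window heterogeneity is applied as a piecewise
    amplitude modulation with period ``modulation_period``.
    """
    n = int(round(config.session_duration * config.fs))
    block = max(1, int(round(config.modulation_period * config.fs)))
    n_blocks = -(-n // block)
    signal = rng.standard_normal(n) * (config.noise_floor / 10.0)
    for b, band in enumerate(config.bands):
        comp = _band_limited_noise(rng, n, config.fs, band)
        amp = config.noise_floor * np.exp(0.5 * log_gains[b])
        if config.window_jitter_sd > 0:
            mod = np.exp(
                0.5 * config.window_jitter_sd * rng.standard_normal(n_blocks)
            )
            comp = comp * np.repeat(mod, block)[:n]
        signal += amp * comp
    return signal


def _draw_masked_cells(n_mice: int, n_regions: int, missing_fraction: float,
                       seed: int) -> list[tuple[int, int]]:
    """Seed-fixed choice of whole (mouse, region) cells to mask.

    Cells are visited in a shuffled order and masked greedily, skipping any
    draw that would leave a mouse with no observed region or a region
    observed by no mouse.
    """
    n_cells = n_mice * n_regions
    n_mask = int(round(missing_fraction * n_cells))
    if n_mask == 0:
        return []
    rng = np.random.default_rng([seed, _STREAM_MASK])
    order = rng.permutation(n_cells)
    observed_per_mouse = np.full(n_mice, n_regions)
    observed_per_region = np.full(n_regions, n_mice)
    masked: list[tuple[int, int]] = []
    for idx in order:
        if len(masked) == n_mask:
            break
        i, j = divmod(int(idx), n_regions)
        if observed_per_mouse[i] <= 1 or observed_per_region[j] <= 1:
            continue
        masked.append((i, j))
        observed_per_mouse[i] -= 1
        observed_per_region[j] -= 1
    if len(masked) < n_mask:
        raise ConfigurationError(
            f"missing_fraction {missing_fraction} incompatible with the "
            "constraint that every mouse keeps >=1 region and every region "
            ">=1 mouse"
        )
    return masked


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort with the configured missingness already applied.

    Deterministic for a fixed ``config.seed``; see the module docstring for
    the seed fan-out scheme.  Signals of masked (mouse, region) cells are
    never generated.
    """
    config.validate()
    mice = config.mouse_ids
    regions = config.regions
    band_names = [b.name for b in config.bands]
    labels = {m: config.label_of(m) for m in mice}
    masked = set(
        _draw_masked_cells(len(mice), len(regions), config.missing_fraction,
                           config.seed)
    )

    signals: dict[tuple[str, int, str], np.ndarray] = {}
    jitters: dict[str, np.ndarray] = {}
    for mi, mouse in enumerate(mice):
        jrng = np.random.default_rng([config.seed, _STREAM_JITTER, mi])
        sds = np.array([config.jitter_sd_for(r) for r in regions])
        jitter = (
            sds[:, None]
            * jrng.standard_normal((len(regions), len(config.bands)))
        )
        jitters[mouse] = jitter
        diseased = labels[mouse] == LABEL_DISEASED
        session_sds = np.array(
            [config.session_jitter_sd_for(r) for r in regions]
        )
        for ri, region in enumerate(regions):
            if (mi, ri) in masked:
                continue
            log_gains = jitter[ri].copy()
            if diseased and region in config.informative_regions:
                per_band = config.effect_sizes.get(region, {})
                for b, name in enumerate(band_names):
                    log_gains[b] += np.log(per_band.get(name, 1.0))
            for session in range(config.sessions_per_mouse):
                session_gains = log_gains
                if session_sds[ri] > 0:
                    srng = np.random.default_rng(
                        [config.seed, _STREAM_SESSION_JITTER, mi, session, ri]
                    )
                    session_gains = log_gains + (
                        session_sds[ri]
                        * srng.standard_normal(len(config.bands))
                    )
                rng = np.random.default_rng(
                    [config.seed, _STREAM_SIGNAL, mi, session, ri]
                )
                signals[(mouse, session, region)] = _synthesize_signal(
                    rng, config, session_gains
                )

    mask = pd.DataFrame(True, index=list(mice), columns=list(regions))
    for i, j in masked:
        mask.iloc[i, j] = False
    return SyntheticCohort(
        signals=signals,
        labels=labels,
        mask=mask,
        fs=config.fs,
        config=config,
        ground_truth={
            "effect_sizes": {r: dict(v) for r, v in config.effect_sizes.items()},
            "informative_regions": tuple(config.informative_regions),
            "gain_jitter": jitters,
        },
    )


def apply_missingness(cohort: SyntheticCohort, missing_fraction: float,
                      seed: int) -> SyntheticCohort:
    """Mask whole (mouse, region) cells uniformly at random.

    The number of masked cells is ``round(missing_fraction * n_mice * M)``.
    Cells are drawn in a seed-fixed shuffled order, skipping any draw that
    would leave a mouse with no observed region or a region observed by no
    mouse.  Masked cells lose their signals.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ConfigurationError(
            f"missing_fraction must lie in [0, 1), got {missing_fraction}"
        )
    mice = cohort.mouse_ids
    regions = cohort.regions
    masked = _draw_masked_cells(len(mice), len(regions), missing_fraction, seed)
    if not masked:
        return cohort

    mask = cohort.mask.copy()
    for i, j in masked:
        mask.iloc[i, j] = False
    signals = {
        key: sig
        for key, sig in cohort.signals.items()
        if mask.loc[key[0], key[2]]
    }
    return SyntheticCohort(
        signals=signals,
        labels=dict(cohort.labels),
        mask=mask,
        fs=cohort.fs,
        config=cohort.config,
        ground_truth=cohort.ground_truth,
    )
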