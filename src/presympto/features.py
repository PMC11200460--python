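"""Band-power feature extraction and feature-matrix assembly.

Each non-overlapping 60-s window of a region signal is Hamming-tapered and
Fourier-transformed; for each of the three canonical bands the features are

* band amplitude: mean one-sided FFT magnitude over the bins inside the band
  (window-length independent), and
* band ratio: summed in-band magnitude divided by the summed magnitude over
  all positive-frequency bins up to Nyquist.

This gives the 6-dimensional per-window feature vector
(delta_amp, theta_amp, gamma_amp, delta_ratio, theta_ratio, gamma_ratio).
Since the bands are disjoint, the three ratios sum to at most one.  Band
statistics are computed from the FFT bins of the raw tapered segment; the
zero-phase Butterworth band-pass is available as an optional pre-filter.

Per-mouse feature tables are stacked into the observed matrix X whose rows
are observation units (individual windows by default, or per-mouse means)
and whose columns are (region, feature) pairs in region-major order, giving
D x M columns, together with a boolean mask marking the missing
(mouse, region) blocks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import DEFAULT_BANDS, BandSpec
from .errors import ConfigurationError, DataError

#: Canonical feature order within a region block.
FEATURE_NAMES: tuple[str, ...] = (
    "delta_amp", "theta_amp", "gamma_amp",
    "delta_ratio", "theta_ratio", "gamma_ratio",
)

#: Feature-vector dimension per region.
D = len(FEATURE_NAMES)

META_COLUMNS = ("mouse", "session", "window", "region")


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping consecutive analysis windows."""

    window_length: float = 60.0
    taper: str = "hamming"

    def n_samples(self, fs: float) -> int:
        n = self.window_length * fs
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"window_length x fs must be a positive integer, got {n}"
            )
        return int(round(n))


from functools import lru_cache


@lru_cache(maxsize=32)
def _taper(name: str, n: int) -> np.ndarray:
    return sps.get_window(name, n)


@lru_cache(maxsize=32)
def _freqs(n: int, fs: float) -> np.ndarray:
    return np.fft.rfftfreq(n, d=1.0 / fs)


def bandpass_filter(signal: np.ndarray, fs: float, band: BandSpec,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    band.validate_for_fs(fs)
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(order, [band.low, band.high], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def extract_window_features(segment: np.ndarray, fs: float,
                            bands: Sequence[BandSpec] = DEFAULT_BANDS,
                            taper: str = "hamming") -> np.ndarray:
    """Feature vector (amplitudes then ratios, band order) of one window.

    An all-zero segment yields the zero vector with a warning, so that the
    mask remains the only missingness channel.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("segment must be a 1-D array with >= 2 samples")
    for band in bands:
        band.validate_for_fs(fs)
    if not np.any(x):
        warnings.warn("all-zero segment: features set to 0", stacklevel=2)
        return np.zeros(2 * len(bands))
    window = _taper(taper, x.size)
    mags = np.abs(np.fft.rfft(x * window))
    freqs = _freqs(x.size, fs)
    total = mags[freqs > 0].sum()
    amps = np.empty(len(bands))
    ratios = np.empty(len(bands))
    for b, band in enumerate(bands):
        in_band = (freqs >= band.low) & (freqs <= band.high)
        if not in_band.any():
            raise ConfigurationError(
                f"band {band.name!r} contains no FFT bin at this window length"
            )
        amps[b] = mags[in_band].mean()
        ratios[b] = mags[in_band].sum() / total
    return np.concatenate([amps, ratios])


def extract_mouse_features(
    mouse_id: str,
    signals: Mapping[tuple[int, str], np.ndarray],
    fs: float,
    window: WindowSpec = WindowSpec(),
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    prefilter: bool = False,
) -> pd.DataFrame:
    """Windowed features of one mouse, rows ordered (session, window, region).

    ``signals`` maps (session, region) to the session trace for that region;
    regions absent from the mapping simply produce no rows (their absence is
    recorded in the mask downstream).  Trailing samples that do not fill a
    complete window are dropped.  With ``prefilter`` set, each band's
    statistics are computed on the band-pass filtered trace instead of the
    raw segment's FFT bins.
    """
    n_win = window.n_samples(fs)
    rows = []
    for (session, region), trace in sorted(
        signals.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        trace = np.asarray(trace, dtype=float)
        n_windows = trace.size // n_win
        filtered = None
        if prefilter:
            filtered = [bandpass_filter(trace, fs, band) for band in bands]
        for w in range(n_windows):
            sl = slice(w * n_win, (w + 1) * n_win)
            if prefilter:
                # Amplitudes from the band-pass filtered trace; ratios stay
                # referenced to the raw segment's full spectrum.
                taper_win = sps.get_window(window.taper, n_win)
                raw_mags = np.abs(np.fft.rfft(trace[sl] * taper_win))
                freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
                total = raw_mags[freqs > 0].sum()
                vec = np.empty(2 * len(bands))
                for b, band in enumerate(bands):
                    mags = np.abs(np.fft.rfft(filtered[b][sl] * taper_win))
                    in_band = (freqs >= band.low) & (freqs <= band.high)
                    vec[b] = mags[in_band].mean()
                    vec[len(bands) + b] = (
                        mags[in_band].sum() / total if total > 0 else 0.0
                    )
            else:
                vec = extract_window_features(
                    trace[sl], fs, bands=bands, taper=window.taper
                )
            rows.append((mouse_id, session, w, region, *vec))
    table = pd.DataFrame(rows, columns=[*META_COLUMNS, *FEATURE_NAMES])
    return table.sort_values(["session", "window", "region"],
                             kind="stable", ignore_index=True)


def cohort_feature_table(cohort, window: WindowSpec = WindowSpec(),
                         prefilter: bool = False) -> pd.DataFrame:
    """Feature table of a whole synthetic cohort (one row per window x region)."""
    tables = []
    for mouse in cohort.mouse_ids:
        signals = {
            (session, region): sig
            for (m, session, region), sig in cohort.signals.items()
            if m == mouse
        }
        tables.append(
            extract_mouse_features(
                mouse, signals, cohort.fs, window=window,
                bands=cohort.config.bands, prefilter=prefilter,
            )
        )
    return pd.concat(tables, ignore_index=True)


@dataclass
class ObservedMatrix:
    """The feature matrix X with its missingness mask.

    ``X`` has one row per observation unit and D x M columns in region-major,
    feature-minor order; entries in masked (mouse, region) blocks are NaN and
    flagged False in ``mask``.  ``row_meta`` carries (mouse, session, window)
    per row (session/window are -1 at mouse-mean level).
    """

    X: np.ndarray
    mask: np.ndarray
    row_meta: pd.DataFrame
    regions: tuple[str, ...]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def d(self) -> int:
        return len(self.feature_names)

    @property
    def column_names(self) -> list[str]:
        return [f"{r}:{f}" for r in self.regions for f in self.feature_names]

    def block(self, m: int) -> slice:
        """Column slice of the m-th region block."""
        return slice(m * self.d, (m + 1) * self.d)


def standardize_columns(observed: ObservedMatrix) -> tuple[ObservedMatrix, np.ndarray, np.ndarray]:
    """Z-score each column over its observed entries.

    Raw band amplitudes scale with the window length (they are mean FFT
    magnitudes) and so sit orders of magnitude above the ratio features;
    optional per-column standardization puts all D x M columns on a common
    scale before completion.  Returns (standardized copy, means, stds);
    constant columns keep std 1.  Masked entries stay NaN.
    """
    X = observed.X.copy()
    means = np.empty(X.shape[1])
    stds = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[observed.mask[:, j], j]
        means[j] = col.mean() if col.size else 0.0
        sd = col.std() if col.size else 1.0
        stds[j] = sd if sd > 0 else 1.0
        X[:, j] = (X[:, j] - means[j]) / stds[j]
    out = ObservedMatrix(X, observed.mask.copy(), observed.row_meta.copy(),
                         observed.regions, observed.feature_names)
    return out, means, stds


def assemble_observed_matrix(
    table: pd.DataFrame,
    mask: pd.DataFrame,
    level: str = "window",
    regions: Sequence[str] | None = None,
) -> ObservedMatrix:
    """Arrange a feature table into the observed matrix X.

    ``mask`` is the (mice x regions) observation mask; its index fixes the
    mouse order and its columns the region order (unless ``regions`` is
    given, which must be a permutation-consistent ordering shared by all
    mice).  ``level`` selects window-level rows (default; one row per
    mouse x session x window) or mouse-mean rows (one row per mouse, features
    averaged over that mouse's windows).
    """
    if level not in ("window", "mouse_mean"):
        raise ConfigurationError(f"unknown level {level!r}")
    region_order = tuple(regions) if regions is not None else tuple(mask.columns)
    if set(region_order) != set(mask.columns):
        raise DataError("region order inconsistent with mask columns")
    extra = set(table["region"].unique()) - set(region_order)
    if extra:
        raise DataError(f"feature table contains unknown regions: {sorted(extra)}")

    mice = list(mask.index)
    d = D
    n_cols = d * len(region_order)

    if level == "mouse_mean":
        X = np.full((len(mice), n_cols), np.nan)
        mask_out = np.zeros((len(mice), n_cols), dtype=bool)
        grouped = table.groupby(["mouse", "region"], sort=False)[
            list(FEATURE_NAMES)
        ].mean()
        for i, mouse in enumerate(mice):
            for m, region in enumerate(region_order):
                if not mask.loc[mouse, region]:
                    continue
                if (mouse, region) not in grouped.index:
                    continue
                X[i, m * d:(m + 1) * d] = grouped.loc[(mouse, region)].to_numpy()
                mask_out[i, m * d:(m + 1) * d] = True
        row_meta = pd.DataFrame(
            {"mouse": mice, "session": -1, "window": -1}
        )
        return ObservedMatrix(X, mask_out, row_meta, region_order)

    # window level: rows ordered by (mouse order, session, window)
    units = (
        table[["mouse", "session", "window"]]
        .drop_duplicates()
        .assign(_mi=lambda f: f["mouse"].map({m: i for i, m in enumerate(mice)}))
        .sort_values(["_mi", "session", "window"], kind="stable")
        .drop(columns="_mi")
        .reset_index(drop=True)
    )
    X = np.full((len(units), n_cols), np.nan)
    mask_out = np.zeros((len(units), n_cols), dtype=bool)
    indexed = table.set_index(["mouse", "session", "window", "region"])[
        list(FEATURE_NAMES)
    ]
    for r, (mouse, session, wdw) in enumerate(
        units.itertuples(index=False, name=None)
    ):
        for m, region in enumerate(region_order):
            if not mask.loc[mouse, region]:
                continue
            key = (mouse, session, wdw, region)
            if key not in indexed.index:
                continue
            X[r, m * d:(m + 1) * d] = indexed.loc[key].to_numpy()
            mask_out[r, m * d:(m + 1) * d] = True
    return ObservedMatrix(X, mask_out, units, region_order)
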