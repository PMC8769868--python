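"""Signal preprocessing and autoregressive feature extraction.

The identification features are the coefficients of an autoregressive (AR)
model fitted per channel to each (band-pass filtered, notch filtered and
optionally wavelet-denoised) recording.  An AR(p) model

    x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t,   e_t ~ WN(0, sigma^2)

summarises the spectral shape of a channel in p numbers; subjects differ in
those numbers, recordings of one subject scatter around them.  Features are
assembled into a channel-blocked table: the p columns of channel c occupy the
contiguous column range [c*p, (c+1)*p), so masking a channel removes exactly
its block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from statsmodels.regression.linear_model import burg, yule_walker

__all__ = [
    "ARModel",
    "FeatureTable",
    "PreprocessingConfig",
    "bandpass_notch",
    "wavelet_denoise",
    "fit_ar",
    "extract_features",
    "load_signals",
]

AR_PRESETS = (5, 10, 20)


@dataclass(frozen=True)
class ARModel:
    """Fitted autoregressive model: x_t = sum_j coefficients[j] * x_{t-1-j} + e_t."""

    order: int
    coefficients: np.ndarray
    noise_variance: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (self.order,):
            raise ValueError(
                f"expected {self.order} coefficients, got shape {coef.shape}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        object.__setattr__(self, "coefficients", coef)

    @property
    def is_stable(self) -> bool:
        """True if all characteristic roots lie strictly inside the unit circle."""
        roots = np.roots(np.concatenate(([1.0], -self.coefficients)))
        return bool(np.all(np.abs(roots) < 1.0)) if roots.size else True


@dataclass
class FeatureTable:
    """Channel-blocked feature matrix with subject labels.

    ``matrix`` has one row per subject-recording (or per subject after
    aggregation) and ``n_channels * coeffs_per_channel`` columns.
    ``channel_blocks[c]`` is the slice of columns belonging to channel ``c``
    (0-based internally; user-facing output is 1-based).
    """

    matrix: np.ndarray
    subjects: np.ndarray
    recordings: np.ndarray
    channel_blocks: dict[int, slice]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.recordings = np.asarray(self.recordings)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.subjects) != self.matrix.shape[0]:
            raise ValueError("one subject label per row required")
        if len(self.recordings) != self.matrix.shape[0]:
            raise ValueError("one recording label per row required")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")
        covered = np.zeros(self.matrix.shape[1], dtype=bool)
        for c, sl in self.channel_blocks.items():
            if covered[sl].any():
                raise ValueError(f"channel block {c} overlaps another block")
            covered[sl] = True
        if not covered.all():
            raise ValueError("channel blocks do not partition the columns")

    @property
    def n_channels(self) -> int:
        return len(self.channel_blocks)

    @property
    def coeffs_per_channel(self) -> int:
        return self.matrix.shape[1] // self.n_channels

    def columns_for(self, channels: np.ndarray) -> np.ndarray:
        """Column indices of the blocks of the given 0-based channel indices."""
        cols: list[np.ndarray] = []
        for c in np.atleast_1d(channels):
            sl = self.channel_blocks[int(c)]
            cols.append(np.arange(sl.start, sl.stop))
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)

    def drop_channel(self, channel: int) -> "FeatureTable":
        keep = [c for c in sorted(self.channel_blocks) if c != channel]
        cols = self.columns_for(np.asarray(keep))
        p = self.coeffs_per_channel
        blocks = {c: slice(i * p, (i + 1) * p) for i, c in enumerate(keep)}
        return FeatureTable(
            self.matrix[:, cols], self.subjects, self.recordings, blocks, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with `subject,recording,ch{c}_a{j}` columns (1-based names)."""
        p = self.coeffs_per_channel
        names = [
            f"ch{c + 1}_a{j + 1}" for c in sorted(self.channel_blocks) for j in range(p)
        ]
        df = pd.DataFrame(self.matrix, columns=names)
        df.insert(0, "recording", self.recordings)
        df.insert(0, "subject", self.subjects)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "FeatureTable":
        feat_cols = [c for c in df.columns if c.startswith("ch")]
        channels = sorted({int(c.split("_")[0][2:]) - 1 for c in feat_cols})
        p = len(feat_cols) // len(channels)
        blocks = {c: slice(i * p, (i + 1) * p) for i, c in enumerate(channels)}
        ordered = [f"ch{c + 1}_a{j + 1}" for c in channels for j in range(p)]
        return cls(
            df[ordered].to_numpy(float),
            df["subject"].to_numpy(),
            df["recording"].to_numpy(),
            blocks,
            meta or {},
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class PreprocessingConfig:
    """Phase-II settings: band-pass + notch filtering, optional wavelet denoise.

    Defaults: 0.5-50 Hz pass band, 60 Hz notch (US mains), 4th-order zero-phase
    Butterworth; 'db4' level-4 soft universal-threshold denoising, off by
    default because it is a preprocessing option rather than part of the method.
    """

    band: tuple[float, float] = (0.5, 50.0)
    notch: float = 60.0
    filter_order: int = 4
    notch_q: float = 30.0
    denoise: bool = False
    wavelet: str = "db4"
    level: int = 4
    threshold_mode: Literal["soft", "hard"] = "soft"

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def bandpass_notch(
    x: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.5, 50.0),
    notch: float = 60.0,
    filter_order: int = 4,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass then notch filter.

    Both filters are applied forward-backward (``sosfiltfilt``/``filtfilt``) so
    the output has no group delay and the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz is at or above Nyquist {nyq} Hz")
    if notch >= nyq:
        raise ValueError(f"notch frequency {notch} Hz is at or above Nyquist {nyq} Hz")
    sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    b, a = sps.iirnotch(notch, notch_q, fs=sampling_rate)
    return sps.filtfilt(b, a, y)


def wavelet_denoise(
    x: np.ndarray,
    wavelet: str = "db4",
    level: int = 4,
    mode: Literal["soft", "hard"] = "soft",
    threshold: float | None = None,
) -> np.ndarray:
    """Wavelet-shrinkage denoising.

    Decomposes to `level` scales, thresholds the detail coefficients and
    reconstructs.  ``threshold=None`` uses the universal threshold
    sigma * sqrt(2 log n) with sigma estimated from the finest details via the
    median absolute deviation.  ``threshold=0`` reproduces the input up to
    reconstruction tolerance.
    """
    x = np.asarray(x, dtype=float)
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(
            f"unknown wavelet {wavelet!r}; supported: {pywt.wavelist(kind='discrete')}"
        )
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(f"level {level} exceeds maximum {max_level} for length {len(x)}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    if threshold is None:
        detail = coeffs[-1]
        sigma = np.median(np.abs(detail)) / 0.6744897501960817
        threshold = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    if threshold <= 0:  # soft-thresholding at 0 is the identity (and 0/0-safe)
        denoised = coeffs
    else:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode=mode) for c in coeffs[1:]
        ]
    return pywt.waverec(denoised, wavelet)[: len(x)]


def fit_ar(
    x: np.ndarray, order: int, method: Literal["burg", "yule_walker"] = "burg"
) -> ARModel:
    """Fit an AR(order) model; Burg by default, Yule-Walker as alternative."""
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(x) <= 2 * order:
        raise ValueError(f"signal length {len(x)} too short for order {order} (need > {2 * order})")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: autocovariance is degenerate")
    if method == "burg":
        coef, sigma2 = burg(x - x.mean(), order=order)
    elif method == "yule_walker":
        coef, sigma = yule_walker(x, order=order, method="mle")
        sigma2 = sigma**2
    else:
        raise ValueError(f"unknown AR method {method!r}")
    return ARModel(order=order, coefficients=np.asarray(coef), noise_variance=float(sigma2))


def preprocess(x: np.ndarray, sampling_rate: float, cfg: PreprocessingConfig) -> np.ndarray:
    y = bandpass_notch(
        x, sampling_rate, band=cfg.band, notch=cfg.notch,
        filter_order=cfg.filter_order, notch_q=cfg.notch_q,
    )
    if cfg.denoise:
        y = wavelet_denoise(y, wavelet=cfg.wavelet, level=cfg.level, mode=cfg.threshold_mode)
    return y


def extract_features(
    dataset,
    order: int = 5,
    preprocessing: PreprocessingConfig | None = None,
    aggregate: Literal["per_recording", "mean_per_subject"] = "per_recording",
    method: Literal["burg", "yule_walker"] = "burg",
) -> FeatureTable:
    """AR features per channel for every recording of every subject.

    ``per_recording`` yields one row per (subject, recording) — the default,
    so that 10-fold cross-validation has multiple rows per subject.
    ``mean_per_subject`` averages each subject's rows into one.
    """
    sig = np.asarray(dataset.signals, dtype=float)
    n_subj, n_rec, n_chan, _ = sig.shape
    rows = np.empty((n_subj * n_rec, n_chan * order))
    subjects, recordings = [], []
    for s in range(n_subj):
        for r in range(n_rec):
            row = np.empty(n_chan * order)
            for c in range(n_chan):
                x = sig[s, r, c]
                if preprocessing is not None:
                    x = preprocess(x, dataset.sampling_rate, preprocessing)
                try:
                    model = fit_ar(x, order, method=method)
                except ValueError as exc:
                    raise ValueError(
                        f"AR fit failed for subject {dataset.subject_ids[s]}, "
                        f"recording {r + 1}, channel {c + 1}: {exc}"
                    ) from exc
                row[c * order : (c + 1) * order] = model.coefficients
            rows[s * n_rec + r] = row
            subjects.append(dataset.subject_ids[s])
            recordings.append(r + 1)
    blocks = {c: slice(c * order, (c + 1) * order) for c in range(n_chan)}
    meta = {
        "ar_order": order,
        "ar_method": method,
        "aggregate": aggregate,
        "preprocessing": preprocessing.asdict() if preprocessing else None,
        "sampling_rate": dataset.sampling_rate,
    }
    subjects_arr = np.asarray(subjects)
    if aggregate == "mean_per_subject":
        uniq = list(dict.fromkeys(dataset.subject_ids))
        mat = np.vstack([rows[subjects_arr == u].mean(axis=0) for u in uniq])
        return FeatureTable(mat, np.asarray(uniq), np.ones(len(uniq), dtype=int), blocks, meta)
    if aggregate != "per_recording":
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return FeatureTable(rows, subjects_arr, np.asarray(recordings), blocks, meta)


def load_signals(manifest_path: str | Path):
    """Read a dataset written by :func:`eegselect.synthetic.write_signals`."""
    from .synthetic import SignalDataset  # deferred: synthetic imports this module

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    subjects = list(dict.fromkeys(manifest["subject"]))
    recs = sorted(manifest["recording"].unique())
    first = pd.read_csv(manifest_path.parent / manifest["path"].iloc[0])
    signals = np.empty((len(subjects), len(recs), first.shape[1], first.shape[0]))
    for _, row in manifest.iterrows():
        df = pd.read_csv(manifest_path.parent / row["path"])
        s = subjects.index(row["subject"])
        r = recs.index(row["recording"])
        signals[s, r] = df.to_numpy(float).T
    return SignalDataset(
        signals=signals,
        subject_ids=list(subjects),
        sampling_rate=float(manifest["sampling_rate"].iloc[0]),
        channel_names=list(first.columns),
    )
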