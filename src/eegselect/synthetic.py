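"""Synthetic EEG-like data with a planted set of discriminative channels.

Real channel-selection benchmarks (64-electrode motor-imagery montages, ~100
subjects, a dozen recordings each) cannot ship with a package, so this module
generates datasets of the same shape with known ground truth: only a chosen
subset S* of channels carries subject identity.  Identity is encoded in the
AR coefficients of the channel processes — not in amplitude — so that the AR
feature-extraction stage is the information bottleneck, exactly as in the
pipeline this package implements.

Generative model, per channel:

* informative channel (in S*): subject s has reflection coefficients
  k_s = tanh(k_template + effect_size * SUBJECT_SCALE * delta_s) with delta_s
  drawn once per (subject, channel); the tanh keeps |k|<1, hence the AR
  polynomial stable.  Each recording perturbs the AR coefficients with
  additive N(0, noise_sd^2 * COEF_PERTURB_SCALE^2) noise and projects back to
  stability by shrinking any root to modulus <1.
* background channel (not in S*): one shared stable AR process for everyone;
  recordings differ only through their innovation sequences.

With effect_size=0 every subject runs the same processes and identification
accuracy collapses to chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import FeatureTable

__all__ = [
    "PlantSpec",
    "SignalDataset",
    "generate_signals",
    "generate_feature_table",
    "write_signals",
]

GEN_AR_ORDER = 5
SUBJECT_SCALE = 0.05  # reflection-coefficient offset per unit effect_size
COEF_PERTURB_SCALE = 0.02  # AR-coefficient sd per unit noise_sd, per recording
BURN_IN = 200
MAX_STABILITY_RETRIES = 50


@dataclass(frozen=True)
class PlantSpec:
    """Ground-truth layout of a planted-channel dataset."""

    n_subjects: int
    n_recordings: int
    n_channels: int
    informative_channels: tuple[int, ...]
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "informative_channels", tuple(sorted(set(self.informative_channels)))
        )
        s = set(self.informative_channels)
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_recordings < 1:
            raise ValueError("need at least 1 recording per subject")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not s:
            raise ValueError("informative channel set must be non-empty")
        if not s <= set(range(self.n_channels)):
            raise ValueError("informative channels must be 0-based indices < n_channels")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def informative_mask(self) -> np.ndarray:
        m = np.zeros(self.n_channels, dtype=int)
        m[list(self.informative_channels)] = 1
        return m


@dataclass
class SignalDataset:
    """Raw multichannel records, shape [subject, recording, channel, sample]."""

    signals: np.ndarray
    subject_ids: list
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4-D [subject, recording, channel, sample]")
        n_subj, _, n_chan, _ = self.signals.shape
        if len(self.subject_ids) != n_subj:
            raise ValueError("one subject id per subject required")
        if n_chan < 2:
            raise ValueError("need at least 2 channels")
        if not self.channel_names:
            self.channel_names = [f"ch{c + 1}" for c in range(n_chan)]
        if len(self.channel_names) != n_chan:
            raise ValueError("one channel name per channel required")


def _reflection_to_ar(k: np.ndarray) -> np.ndarray:
    """Levinson-Durbin step-up: reflection coefficients -> AR coefficients.

    Returns a with x_t = sum_j a[j] x_{t-1-j} + e_t; stable whenever all |k|<1.
    """
    a = np.empty(0)
    for m, km in enumerate(k, start=1):
        prev = a
        a = np.empty(m)
        a[: m - 1] = prev - km * prev[::-1]
        a[m - 1] = km
    return a


def _stabilize(a: np.ndarray, margin: float = 0.98) -> np.ndarray:
    """Shrink characteristic roots inside the unit circle if necessary."""
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    max_mod = np.max(np.abs(roots)) if roots.size else 0.0
    if max_mod < 1.0:
        return a
    roots = roots * (margin / max_mod)
    new_poly = np.poly(roots).real
    return -new_poly[1:] / new_poly[0]


def _simulate_ar(a: np.ndarray, n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    e = rng.standard_normal(n + BURN_IN) * sd
    x = sps.lfilter([1.0], np.concatenate(([1.0], -a)), e)
    return x[BURN_IN:]


def _draw_stable_ar(rng: np.random.Generator, spread: float = 0.3) -> np.ndarray:
    k = rng.uniform(-spread, spread, size=GEN_AR_ORDER)
    return _reflection_to_ar(k)


def generate_signals(
    spec: PlantSpec, sampling_rate: float = 160.0, duration: float = 4.0
) -> SignalDataset:
    """Generate a planted-channel multichannel signal dataset.

    ``sampling_rate`` and ``duration`` default to 160 Hz x 4 s segments, the
    scale of one motor-imagery trial.  Reproducible for a fixed ``spec.seed``.
    """
    n_samples = int(round(duration * sampling_rate))
    if n_samples < 256:
        raise ValueError("duration x sampling_rate must give at least 256 samples")
    if n_samples < 2 * GEN_AR_ORDER + 1:
        raise ValueError("too few samples for the generating AR order")
    ss = np.random.SeedSequence(spec.seed)
    rng_proc, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    informative = set(spec.informative_channels)
    # shared background processes, one per non-informative channel
    shared = {c: _draw_stable_ar(rng_proc) for c in range(spec.n_channels) if c not in informative}
    # subject-specific processes on the planted channels
    template = {c: rng_proc.uniform(-0.3, 0.3, size=GEN_AR_ORDER) for c in informative}
    subject_ar: dict[tuple[int, int], np.ndarray] = {}
    for s in range(spec.n_subjects):
        for c in informative:
            delta = rng_proc.standard_normal(GEN_AR_ORDER)
            k = np.tanh(template[c] + spec.effect_size * SUBJECT_SCALE * delta)
            subject_ar[(s, c)] = _reflection_to_ar(k)

    signals = np.empty((spec.n_subjects, spec.n_recordings, spec.n_channels, n_samples))
    for s in range(spec.n_subjects):
        for r in range(spec.n_recordings):
            for c in range(spec.n_channels):
                if c in informative:
                    base = subject_ar[(s, c)]
                    a = None
                    for _ in range(MAX_STABILITY_RETRIES):
                        cand = base + rng_noise.standard_normal(GEN_AR_ORDER) * (
                            spec.noise_sd * COEF_PERTURB_SCALE
                        )
                        cand = _stabilize(cand)
                        roots = np.roots(np.concatenate(([1.0], -cand)))
                        if np.all(np.abs(roots) < 1.0):
                            a = cand
                            break
                    if a is None:
                        raise RuntimeError(
                            f"could not stabilise perturbed AR process for subject {s}, "
                            f"channel {c} after {MAX_STABILITY_RETRIES} retries"
                        )
                else:
                    a = shared[c]
                signals[s, r, c] = _simulate_ar(a, n_samples, rng_noise)

    return SignalDataset(
        signals=signals,
        subject_ids=[f"S{s + 1:03d}" for s in range(spec.n_subjects)],
        sampling_rate=sampling_rate,
        channel_names=[f"ch{c + 1}" for c in range(spec.n_channels)],
    )


def generate_feature_table(spec: PlantSpec, coeffs_per_channel: int = 5) -> FeatureTable:
    """Planted channel-blocked feature table, bypassing the signal stage.

    Columns of channels in S* get subject-specific means drawn from
    N(0, sigma_mu^2) with sigma_mu = effect_size * noise_sd / sqrt(|S*|); all
    cells carry N(0, noise_sd^2) noise on top, so non-informative columns are
    pure noise.  ``effect_size`` therefore measures the *joint* separation of
    the planted set: identity evidence is distributed across the planted
    channels (as over real electrodes), each one individually only weakly
    informative, so near-ceiling identification requires most of S*.
    """
    if coeffs_per_channel < 1:
        raise ValueError("coeffs_per_channel must be >= 1")
    p = coeffs_per_channel
    d = spec.n_channels
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_rows = spec.n_subjects * spec.n_recordings
    X = rng.standard_normal((n_rows, d * p)) * spec.noise_sd
    subjects = np.repeat([f"S{s + 1:03d}" for s in range(spec.n_subjects)], spec.n_recordings)
    recordings = np.tile(np.arange(1, spec.n_recordings + 1), spec.n_subjects)
    sigma_mu = spec.effect_size * spec.noise_sd / np.sqrt(len(spec.informative_channels))
    means = rng.standard_normal((spec.n_subjects, d * p)) * sigma_mu
    info_cols = np.concatenate(
        [np.arange(c * p, (c + 1) * p) for c in spec.informative_channels]
    )
    for s in range(spec.n_subjects):
        rows = slice(s * spec.n_recordings, (s + 1) * spec.n_recordings)
        X[rows, info_cols] += means[s, info_cols]
    blocks = {c: slice(c * p, (c + 1) * p) for c in range(d)}
    meta = {
        "planted": True,
        "informative_channels": list(spec.informative_channels),
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return FeatureTable(X, subjects, recordings, blocks, meta)


def write_signals(dataset: SignalDataset, out_dir: str | Path) -> Path:
    """Write one CSV per subject-recording (columns = channels) plus a manifest.

    Returns the manifest path; :func:`eegselect.features.load_signals` reads it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    n_subj, n_rec = dataset.signals.shape[:2]
    for s in range(n_subj):
        for r in range(n_rec):
            name = f"{dataset.subject_ids[s]}_rec{r + 1:02d}.csv"
            pd.DataFrame(
                dataset.signals[s, r].T, columns=dataset.channel_names
            ).to_csv(out_dir / name, index=False)
            records.append(
                {
                    "subject": dataset.subject_ids[s],
                    "recording": r + 1,
                    "path": name,
                    "sampling_rate": dataset.sampling_rate,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
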