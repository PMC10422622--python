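"""Synthetic ECG records with class-specific beat morphology.

Each record emulates one entry of a PTB-XL-style collection: a short
multi-lead voltage trace sampled at 100 or 500 Hz and labelled with one of
five diagnostic superclasses (NORM, MI, STTC, CD, HYP) or NULL (no usable
diagnostic statement).  A beat is modelled as a sum of five Gaussian bumps —
the P, Q, R, S and T waves — repeated at the heart rate, plus white Gaussian
noise.  Class identity enters only through fixed, documented shifts of the
wave parameters (see :data:`CLASS_MORPHOLOGY`); NULL records borrow the
morphology of a random diagnostic class so that only the label, not the
waveform, distinguishes them.

Preprocessing mirrors the standard pipeline for such collections: drop
NULL-labelled records, resample everything to a common rate (100 Hz by
default), and z-score each lead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

DIAGNOSTIC_CLASSES = ("NORM", "MI", "STTC", "CD", "HYP")
NULL_LABEL = "NULL"
ALL_LABELS = DIAGNOSTIC_CLASSES + (NULL_LABEL,)

#: Wave table: (center offset from the R peak [s], amplitude [mV], width [s]).
_NORMAL_WAVES = {
    "P": (-0.20, 0.10, 0.025),
    "Q": (-0.05, -0.15, 0.010),
    "R": (0.00, 1.00, 0.012),
    "S": (0.04, -0.25, 0.010),
    "T": (0.25, 0.30, 0.050),
}


@dataclass(frozen=True)
class BeatMorphology:
    """Parameters of the periodic five-wave beat model.

    ``waves`` maps wave name -> (center offset [s], amplitude [mV],
    width [s]); offsets are relative to the R-wave peak.
    """

    waves: dict[str, tuple[float, float, float]]
    heart_rate: float = 70.0  # beats/min
    baseline: float = 0.0  # mV
    noise_sd: float = 0.05  # mV

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name!r} has non-positive width")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


def _normal_morphology(**kw) -> BeatMorphology:
    return BeatMorphology(waves=dict(_NORMAL_WAVES), **kw)


def _shift(waves: dict, name: str, center=None, amp=None, width=None) -> None:
    c, a, w = waves[name]
    waves[name] = (c if center is None else center,
                   a if amp is None else amp,
                   w if width is None else width)


def class_morphology(label: str, noise_sd: float = 0.05) -> BeatMorphology:
    """Beat morphology for a diagnostic class.

    Fixed shift table relative to NORM:

    * ``MI``   — deepened Q wave; T widened and pulled toward the S wave,
      elevating the ST segment.
    * ``STTC`` — inverted, slightly delayed T wave.
    * ``CD``   — QRS widths roughly doubled (widened QRS complex).
    * ``HYP``  — amplified R wave.
    """
    if label not in DIAGNOSTIC_CLASSES:
        raise ValueError(f"unknown diagnostic class {label!r}")
    waves = dict(_NORMAL_WAVES)
    if label == "MI":
        _shift(waves, "Q", amp=-0.45)
        _shift(waves, "T", center=0.18, width=0.090)
    elif label == "STTC":
        _shift(waves, "T", center=0.30, amp=-0.25)
    elif label == "CD":
        for w in ("Q", "R", "S"):
            c, a, width = waves[w]
            _shift(waves, w, width=width * 2.2)
    elif label == "HYP":
        _shift(waves, "R", amp=1.80)
    return BeatMorphology(waves=waves, noise_sd=noise_sd)


CLASS_MORPHOLOGY = {c: class_morphology(c) for c in DIAGNOSTIC_CLASSES}


@dataclass
class ECGRecord:
    """One labelled waveform: ``signal`` has shape (leads, samples)."""

    id: str
    signal: np.ndarray
    fs: float
    label: str

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in ALL_LABELS:
            raise ValueError(f"label {self.label!r} not in {ALL_LABELS}")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Dataset:
    records: list[ECGRecord]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def beat_waveform(t: np.ndarray, morphology: BeatMorphology) -> np.ndarray:
    """Noise-free periodic waveform evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    period = morphology.period
    out = np.full(t.shape, morphology.baseline, dtype=float)
    t_max = float(t.max(initial=0.0))
    # R peaks at period/2, 3*period/2, ... ; pad one beat each side so that
    # wide T/P tails from neighbouring beats are included.
    n_beats = int(np.ceil(t_max / period)) + 2
    centers = (np.arange(-1, n_beats) + 0.5) * period
    for _, (offset, amp, width) in morphology.waves.items():
        d = t[..., None] - (centers + offset)
        out += amp * np.exp(-0.5 * (d / width) ** 2).sum(axis=-1)
    return out


def generate_record(
    label: str,
    duration_s: float = 10.0,
    fs: float = 100.0,
    lead_count: int = 1,
    seed: int | None = 0,
    noise_sd: float = 0.05,
    record_id: str | None = None,
) -> ECGRecord:
    """Generate one labelled record; deterministic for a fixed seed.

    NULL records draw their morphology uniformly from the five diagnostic
    classes (the rng consumes this draw first).  Leads beyond the first are
    attenuated copies (gain 1/(1+0.15*lead)) with independent noise.
    """
    if label not in ALL_LABELS:
        raise ValueError(f"unknown label {label!r}")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if lead_count < 1:
        raise ValueError("lead_count must be >= 1")
    rng = np.random.default_rng(seed)
    if label == NULL_LABEL:
        morph_label = str(rng.choice(DIAGNOSTIC_CLASSES))
    else:
        morph_label = label
    morphology = class_morphology(morph_label, noise_sd=noise_sd)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    clean = beat_waveform(t, morphology)
    gains = 1.0 / (1.0 + 0.15 * np.arange(lead_count))
    sig = gains[:, None] * clean[None, :]
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    rid = record_id if record_id is not None else f"{label}-{seed}"
    return ECGRecord(id=rid, signal=sig, fs=fs, label=label)


def generate_dataset(
    n_records: int = 3000,
    class_proportions: dict[str, float] | None = None,
    n_null: int = 35,
    fs_mix: float = 0.5,
    seed: int = 0,
    duration_s: float = 10.0,
    lead_count: int = 1,
    noise_sd: float = 0.05,
) -> Dataset:
    """Generate a labelled collection with exactly ``n_null`` NULL records.

    The remaining ``n_records - n_null`` labels follow ``class_proportions``
    over the five diagnostic classes using largest-remainder rounding, so
    per-class counts are exact and test-assertable.  ``fs_mix`` is the
    fraction of records generated at 500 Hz (the rest at 100 Hz), mimicking
    a collection distributed at two rates.
    """
    if n_null < 0 or n_null > n_records:
        raise ValueError("need 0 <= n_null <= n_records")
    if class_proportions is None:
        class_proportions = {c: 1.0 / len(DIAGNOSTIC_CLASSES) for c in DIAGNOSTIC_CLASSES}
    if set(class_proportions) != set(DIAGNOSTIC_CLASSES):
        raise ValueError("proportions must cover exactly the 5 diagnostic classes")
    props = np.array([class_proportions[c] for c in DIAGNOSTIC_CLASSES], dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if not 0.0 <= fs_mix <= 1.0:
        raise ValueError("fs_mix must be a fraction in [0, 1]")

    n_labelled = n_records - n_null
    quotas = props * n_labelled
    counts = np.floor(quotas).astype(int)
    remainder = n_labelled - counts.sum()
    order = np.argsort(-(quotas - counts))  # largest remainders first
    counts[order[:remainder]] += 1

    labels = [c for c, k in zip(DIAGNOSTIC_CLASSES, counts) for _ in range(k)]
    labels += [NULL_LABEL] * n_null
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    n_500 = int(round(fs_mix * n_records))
    fs_values = np.full(n_records, 100.0)
    fs_values[rng.choice(n_records, size=n_500, replace=False)] = 500.0

    records = []
    for i, (label, fs) in enumerate(zip(labels, fs_values)):
        child_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            generate_record(
                label, duration_s=duration_s, fs=fs, lead_count=lead_count,
                seed=child_seed, noise_sd=noise_sd, record_id=f"rec{i:05d}",
            )
        )
    params = dict(
        n_records=n_records, n_null=n_null, fs_mix=fs_mix, duration_s=duration_s,
        lead_count=lead_count, noise_sd=noise_sd,
        class_proportions={c: float(p) for c, p in zip(DIAGNOSTIC_CLASSES, props)},
    )
    return Dataset(records=records, seed=seed, params=params)


def remove_null(dataset: Dataset) -> Dataset:
    """Drop NULL-labelled records, preserving order."""
    kept = [r for r in dataset.records if r.label != NULL_LABEL]
    return Dataset(records=kept, seed=dataset.seed, params=dict(dataset.params))


def resample(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Fourier-domain resampling to ``target_fs``.

    Band-limited and alias-free for the band-limited synthetic waveforms;
    the identity when the rate is unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if target_fs == record.fs:
        return ECGRecord(record.id, record.signal.copy(), record.fs, record.label)
    n_out = int(round(record.duration * target_fs))
    out = _sig.resample(record.signal, n_out, axis=1)
    return ECGRecord(record.id, out, target_fs, record.label)


def normalize(record: ECGRecord) -> ECGRecord:
    """Z-score each lead; a constant lead maps to all zeros."""
    if record.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize")
    sig = record.signal
    mean = sig.mean(axis=1, keepdims=True)
    sd = sig.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (sig - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ECGRecord(record.id, out, record.fs, record.label)


# ---------------------------------------------------------------------------
# flat-file container: one row per (record, lead), ragged rows padded blank

def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV plus a JSON sidecar with generation metadata."""
    path = Path(path)
    max_n = max((r.n_samples for r in dataset.records), default=0)
    rows = []
    for r in dataset.records:
        for lead in range(r.n_leads):
            row = {"id": r.id, "label": r.label, "fs": r.fs, "lead": lead,
                   "n_samples": r.n_samples}
            samples = np.full(max_n, np.nan)
            samples[: r.n_samples] = r.signal[lead]
            row.update({f"s{i}": samples[i] for i in range(max_n)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {"seed": dataset.seed, "params": dataset.params, "format_version": 1}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    # keep_default_na: the literal label "NULL" must survive the round trip
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    records = []
    for rid, group in df.groupby("id", sort=False):
        group = group.sort_values("lead")
        n = int(group["n_samples"].iloc[0])
        sig = group[sample_cols].to_numpy(dtype=float)[:, :n]
        records.append(ECGRecord(id=str(rid), signal=sig,
                                 fs=float(group["fs"].iloc[0]),
                                 label=str(group["label"].iloc[0])))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    seed, params = None, {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        seed, params = meta.get("seed"), meta.get("params", {})
    return Dataset(records=records, seed=seed, params=params)
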