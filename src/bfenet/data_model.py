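"""Feature containers, I/O, normalization and LOSO fold generation.

The in-memory unit is one trial's differential-entropy (DE) tensor of shape
``channels x time_windows x bands`` together with its label and provenance
(subject / session / trial identifiers), mirroring the layout in which the
SEED family of EEG emotion datasets distributes precomputed DE features
(62 channels x W windows x 5 bands, with W varying per trial and short
trials zero-padded at the tail).

Two on-disk layouts are supported: a hierarchical HDF5 container with
per-trial datasets named ``<prefix><k>`` plus a label vector per session
(the SEED convention), and a flat directory of ``.npy`` arrays described by
a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


class SchemaError(ValueError):
    """A container did not match the declared trial/label schema."""


class ValidationError(ValueError):
    """A feature array violated a structural invariant (shape, finiteness)."""


@dataclass(frozen=True)
class FeatureSample:
    """One trial's DE tensor with label and provenance.

    ``features`` has shape (n_channels, T, n_bands); windows at positions
    >= ``native_length`` are zero padding appended to equalize trial lengths.
    """

    subject_id: str
    session_id: str
    trial_id: str
    label: int
    features: np.ndarray
    native_length: int

    def __post_init__(self):
        x = np.asarray(self.features, dtype=np.float64)
        if x.ndim != 3:
            raise ValidationError(
                f"trial {self.trial_id}: expected 3 axes (channels, time, bands), "
                f"got shape {x.shape}"
            )
        if x.shape[0] < 2:
            raise ValidationError(f"trial {self.trial_id}: need >= 2 channels")
        if not np.isfinite(x).all():
            raise ValidationError(f"trial {self.trial_id}: non-finite feature values")
        if not (0 < self.native_length <= x.shape[1]):
            raise ValidationError(
                f"trial {self.trial_id}: native_length {self.native_length} "
                f"outside (0, {x.shape[1]}]"
            )
        if self.native_length < x.shape[1] and np.any(x[:, self.native_length :, :]):
            raise ValidationError(
                f"trial {self.trial_id}: padded frames beyond {self.native_length} "
                "must be exactly zero"
            )
        object.__setattr__(self, "features", x)

    @property
    def n_channels(self) -> int:
        return self.features.shape[0]

    @property
    def n_bands(self) -> int:
        return self.features.shape[2]

    def unpadded(self) -> np.ndarray:
        """The (channels, native_length, bands) view without padding."""
        return self.features[:, : self.native_length, :]


@dataclass
class DatasetRegistry:
    """An ordered collection of trials spanning subjects and sessions."""

    samples: list[FeatureSample]
    n_classes: int
    band_names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self):
        if not self.samples:
            raise ValidationError("registry has no samples")
        nb = {s.n_bands for s in self.samples}
        if len(nb) != 1 or nb.pop() != len(self.band_names):
            raise ValidationError("band count inconsistent with band_names")
        bad = [s.trial_id for s in self.samples if not 0 <= s.label < self.n_classes]
        if bad:
            raise ValidationError(f"labels outside [0, {self.n_classes}): {bad[:3]}")

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.samples})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_channels(self) -> int:
        return self.samples[0].n_channels

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def features(self) -> np.ndarray:
        """Stacked (n_samples, channels, T, bands) array; trials must share T."""
        return np.stack([s.features for s in self.samples])


@dataclass(frozen=True)
class LOSOFold:
    test_subject: str
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass(frozen=True)
class ContainerSchema:
    """Names the per-trial datasets and the label vector inside a container."""

    trial_prefix: str = "de_LDS"
    label_key: str = "labels"
    subject_id: str = "s01"
    session_id: str = "1"


# ---------------------------------------------------------------------------
# I/O


def _samples_from_group(
    group, schema: ContainerSchema, subject_id: str, session_id: str
) -> list[FeatureSample]:
    keys = sorted(
        (k for k in group.keys() if k.startswith(schema.trial_prefix) and k != schema.label_key),
        key=lambda k: int(k[len(schema.trial_prefix) :]),
    )
    if not keys:
        raise SchemaError(
            f"no datasets with prefix {schema.trial_prefix!r} in {group.name or '/'}"
        )
    if schema.label_key not in group:
        raise SchemaError(f"missing label vector {schema.label_key!r}")
    labels = np.asarray(group[schema.label_key][()], dtype=int)
    if labels.shape != (len(keys),):
        raise SchemaError(
            f"label vector length {labels.shape} != number of trials {len(keys)}"
        )
    out = []
    for k, lab in zip(keys, labels):
        arr = np.asarray(group[k][()])
        if arr.ndim != 3:
            raise SchemaError(f"trial {k!r}: expected 3 axes, got shape {arr.shape}")
        out.append(
            FeatureSample(
                subject_id=subject_id,
                session_id=session_id,
                trial_id=k,
                label=int(lab),
                features=arr,
                native_length=arr.shape[1],
            )
        )
    return out


def load_feature_file(path, schema: ContainerSchema = ContainerSchema()) -> list[FeatureSample]:
    """Load one session's trials from an HDF5 container.

    Trials live in datasets ``<trial_prefix><k>`` (k = 1, 2, ...) of shape
    (channels, W, bands) with labels in a companion integer vector.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        subject = f.attrs.get("subject_id", schema.subject_id)
        session = f.attrs.get("session_id", schema.session_id)
        return _samples_from_group(f, schema, str(subject), str(session))


def save_registry(registry: DatasetRegistry, path, schema: ContainerSchema = ContainerSchema()) -> None:
    """Write a registry to a hierarchical HDF5 container ``/subject/session/<trials>``."""
    by_group: dict[tuple[str, str], list[FeatureSample]] = {}
    for s in registry.samples:
        by_group.setdefault((s.subject_id, s.session_id), []).append(s)
    with h5py.File(path, "w") as f:
        f.attrs["n_classes"] = registry.n_classes
        f.attrs["band_names"] = ",".join(registry.band_names)
        for (subj, sess), samples in by_group.items():
            g = f.require_group(subj).require_group(sess)
            labels = []
            for i, s in enumerate(samples, start=1):
                ds = g.create_dataset(f"{schema.trial_prefix}{i}", data=s.features)
                ds.attrs["native_length"] = s.native_length
                ds.attrs["trial_id"] = s.trial_id
                labels.append(s.label)
            g.create_dataset(schema.label_key, data=np.array(labels, dtype=int))


def load_registry(path, schema: ContainerSchema = ContainerSchema()) -> DatasetRegistry:
    """Read a registry written by :func:`save_registry`."""
    samples: list[FeatureSample] = []
    with h5py.File(path, "r") as f:
        n_classes = int(f.attrs["n_classes"])
        band_names = tuple(f.attrs["band_names"].split(","))
        for subj in sorted(f.keys()):
            for sess in sorted(f[subj].keys()):
                g = f[subj][sess]
                loaded = _samples_from_group(g, schema, subj, sess)
                for s in loaded:
                    attrs = g[s.trial_id].attrs
                    nl = int(attrs.get("native_length", s.features.shape[1]))
                    tid = str(attrs.get("trial_id", s.trial_id))
                    samples.append(replace(s, native_length=nl, trial_id=tid))
    return DatasetRegistry(samples=samples, n_classes=n_classes, band_names=band_names)


def save_registry_npy(registry: DatasetRegistry, out_dir) -> None:
    """Flat directory-of-arrays layout with a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_classes": registry.n_classes,
        "band_names": list(registry.band_names),
        "trials": [],
    }
    for i, s in enumerate(registry.samples):
        fname = f"trial_{i:05d}.npy"
        np.save(out / fname, s.features)
        manifest["trials"].append(
            {
                "file": fname,
                "subject_id": s.subject_id,
                "session_id": s.session_id,
                "trial_id": s.trial_id,
                "label": s.label,
                "native_length": s.native_length,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_registry_npy(in_dir) -> DatasetRegistry:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = [
        FeatureSample(
            subject_id=t["subject_id"],
            session_id=t["session_id"],
            trial_id=t["trial_id"],
            label=t["label"],
            features=np.load(src / t["file"]),
            native_length=t["native_length"],
        )
        for t in manifest["trials"]
    ]
    return DatasetRegistry(
        samples=samples,
        n_classes=manifest["n_classes"],
        band_names=tuple(manifest["band_names"]),
    )


# ---------------------------------------------------------------------------
# Transformations


def pad_to_length(sample: FeatureSample, target_T: int) -> FeatureSample:
    """Append zero frames along the time axis up to ``target_T``.

    Trailing padding keeps stimulus onset aligned at frame 0. A trial longer
    than the target is an error: truncation would silently discard data.
    """
    T = sample.features.shape[1]
    if sample.native_length > target_T:
        raise ValidationError(
            f"trial {sample.trial_id}: native length {sample.native_length} "
            f"exceeds target {target_T}"
        )
    if T == target_T:
        return sample
    if T > target_T:
        raise ValidationError(
            f"trial {sample.trial_id}: time axis {T} exceeds target {target_T}"
        )
    pad = np.zeros((sample.n_channels, target_T - T, sample.n_bands))
    return replace(sample, features=np.concatenate([sample.features, pad], axis=1))


def normalize_per_subject(registry: DatasetRegistry) -> DatasetRegistry:
    """Z-score each (subject, channel, band) series over unpadded frames.

    Statistics pool all of a subject's trials (population variance); padded
    frames are excluded from the statistics and remain exactly zero. A
    zero-variance slice is set to zero with a logged warning rather than
    dividing by zero.
    """
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(registry.samples):
        by_subject.setdefault(s.subject_id, []).append(i)

    new_samples = list(registry.samples)
    for subj, idxs in by_subject.items():
        pooled = np.concatenate(
            [registry.samples[i].unpadded() for i in idxs], axis=1
        )  # (channels, total_frames, bands)
        mu = pooled.mean(axis=1)
        sd = pooled.std(axis=1)  # population std
        zero_var = sd == 0
        if zero_var.any():
            logger.warning(
                "subject %s: %d zero-variance (channel, band) slices set to zero",
                subj,
                int(zero_var.sum()),
            )
        safe_sd = np.where(zero_var, 1.0, sd)
        for i in idxs:
            s = registry.samples[i]
            x = s.features.copy()
            W = s.native_length
            z = (x[:, :W, :] - mu[:, None, :]) / safe_sd[:, None, :]
            z[np.broadcast_to(zero_var[:, None, :], z.shape)] = 0.0
            x[:, :W, :] = z
            new_samples[i] = replace(s, features=x)
    return DatasetRegistry(
        samples=new_samples, n_classes=registry.n_classes, band_names=registry.band_names
    )


def loso_splits(registry: DatasetRegistry) -> list[LOSOFold]:
    """Leave-one-subject-out folds in lexicographic subject order.

    Each fold tests on every trial of one subject and trains on all trials
    of the remaining subjects; the test sets partition the registry.
    """
    subjects = registry.subjects
    if len(subjects) < 2:
        raise ValidationError("LOSO requires at least 2 subjects")
    subj_of = np.array([s.subject_id for s in registry.samples])
    all_idx = np.arange(len(registry.samples))
    folds = []
    for subj in subjects:
        mask = subj_of == subj
        folds.append(
            LOSOFold(
                test_subject=subj,
                train_indices=all_idx[~mask],
                test_indices=all_idx[mask],
            )
        )
    return folds


def load_montage(path) -> "pd.DataFrame":
    """Electrode montage CSV with columns name, x, y, z."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise SchemaError(f"montage must have columns {sorted(required)}")
    return df
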