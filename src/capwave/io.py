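"""Dataset and checkpoint containers, CSV import/export, run configuration.

Datasets live in an HDF5 container::

    /records/<id>/radial   float64 mmHg
    /records/<id>/aortic   float64 mmHg

with per-record attributes (fs plus the subject's hemodynamic parameters)
and root attributes carrying provenance (schema version, generator seed,
cohort spec JSON).  Checkpoints store the architecture config, the flat
named parameter arrays, the normalization constants (a, b) and the model
seed, so ``reconstruct`` never needs the training configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortSpec, PairedRecord, ShapeParams, SubjectParams
from .errors import SchemaError, ValidationError
from .model.network import ModelConfig, TCNAttention
from .preprocessing import NormalizationScheme
from .training import TrainConfig
from .waveform import PressureWaveform

DATASET_SCHEMA = "capwave-dataset-1"
CHECKPOINT_SCHEMA = "capwave-checkpoint-1"

_SUBJECT_FIELDS = ("heart_rate", "radial_sbp", "radial_dbp", "aortic_sbp",
                   "aortic_dbp", "tube_delay", "reflection_coeff")
_SHAPE_FIELDS = ("peak_time", "decay_tau", "dicrotic_amp", "dicrotic_frac",
                 "dicrotic_width")


def config_hash(obj) -> str:
    """Short stable hash of any dataclass / dict configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_dataset(cohort: Cohort | Sequence[PairedRecord], path,
                  spec: CohortSpec | None = None, seed: int | None = None) -> None:
    """Write records plus provenance; accepts a Cohort or a record list."""
    if isinstance(cohort, Cohort):
        records, spec, seed = cohort.records, cohort.spec, cohort.seed
    else:
        records = list(cohort)
    if not records:
        raise ValidationError("refusing to write an empty dataset")
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = DATASET_SCHEMA
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if spec is not None:
            f.attrs["spec"] = spec.to_json()
            f.attrs["config_hash"] = config_hash(dataclasses.asdict(spec))
        grp = f.create_group("records")
        for rec in records:
            g = grp.create_group(rec.record_id)
            g.create_dataset("radial", data=rec.radial.values)
            g.create_dataset("aortic", data=rec.aortic.values)
            g.attrs["fs"] = rec.radial.fs
            for name in _SUBJECT_FIELDS:
                g.attrs[name] = getattr(rec.subject, name)
            for name in _SHAPE_FIELDS:
                g.attrs[f"shape_{name}"] = getattr(rec.subject.shape_params, name)


def read_dataset(path) -> Cohort:
    """Read a dataset container back; round-trips with :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"dataset file not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {path}: {exc}") from exc
    with f:
        schema = f.attrs.get("schema")
        if schema != DATASET_SCHEMA:
            raise SchemaError(
                f"schema mismatch in {path}: expected {DATASET_SCHEMA!r}, "
                f"found {schema!r}"
            )
        spec = (CohortSpec.from_json(f.attrs["spec"])
                if "spec" in f.attrs else CohortSpec())
        seed = int(f.attrs.get("seed", -1))
        records = []
        for rid in sorted(f["records"]):
            g = f["records"][rid]
            fs = float(g.attrs["fs"])
            subject = SubjectParams(
                **{name: float(g.attrs[name]) for name in _SUBJECT_FIELDS},
                shape_params=ShapeParams(
                    **{name: float(g.attrs[f"shape_{name}"]) for name in _SHAPE_FIELDS}
                ),
            )
            records.append(PairedRecord(
                radial=PressureWaveform(g["radial"][...], fs),
                aortic=PressureWaveform(g["aortic"][...], fs),
                subject=subject,
                record_id=rid,
            ))
    return Cohort(records=records, spec=spec, seed=seed)


def export_csv(records: Cohort | Sequence[PairedRecord], path) -> None:
    """Columnar text export: record_id, t_s, radial_mmHg, aortic_mmHg."""
    records = list(records)
    if not records:
        raise ValidationError("refusing to export an empty record list")
    frames = []
    for rec in records:
        frames.append(pd.DataFrame({
            "record_id": rec.record_id,
            "t_s": rec.radial.times,
            "radial_mmHg": rec.radial.values,
            "aortic_mmHg": rec.aortic.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv_waveform(path, column: str = "radial_mmHg") -> PressureWaveform:
    """Read a single-record CSV (as written by :func:`export_csv`)."""
    df = pd.read_csv(path)
    for col in ("t_s", column):
        if col not in df.columns:
            raise SchemaError(f"CSV {path} lacks required column {col!r}")
    if "record_id" in df.columns and df["record_id"].nunique() > 1:
        raise ValidationError("CSV contains multiple records; expected one")
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValidationError("CSV must contain at least 2 samples")
    fs = 1.0 / float(np.mean(np.diff(t)))
    return PressureWaveform(df[column].to_numpy(dtype=np.float64), fs)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(model: TCNAttention, path,
                    scheme: NormalizationScheme | None = None) -> None:
    scheme = scheme or NormalizationScheme()
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = CHECKPOINT_SCHEMA
        f.attrs["config"] = model.config.to_json()
        f.attrs["seed"] = model.seed
        f.attrs["norm_a"] = scheme.a
        f.attrs["norm_b"] = scheme.b
        f.attrs["norm_method"] = scheme.method
        g = f.create_group("params")
        for name, p in model.named_params().items():
            g.create_dataset(name, data=p.value)


def load_checkpoint(path) -> tuple[TCNAttention, NormalizationScheme]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"checkpoint file not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {path}: {exc}") from exc
    with f:
        schema = f.attrs.get("schema")
        if schema != CHECKPOINT_SCHEMA:
            raise SchemaError(
                f"schema mismatch in {path}: expected {CHECKPOINT_SCHEMA!r}, "
                f"found {schema!r}"
            )
        config = ModelConfig.from_json(f.attrs["config"])
        model = TCNAttention(config, seed=int(f.attrs["seed"]))
        params = model.named_params()
        stored = set(f["params"])
        if stored != set(params):
            raise SchemaError("checkpoint parameter names do not match the "
                              "declared architecture")
        for name, p in params.items():
            value = f["params"][name][...]
            if value.shape != p.value.shape:
                raise SchemaError(f"parameter {name} has shape {value.shape}, "
                                  f"expected {p.value.shape}")
            p.value[...] = value
        scheme = NormalizationScheme(method=str(f.attrs["norm_method"]),
                                     a=float(f.attrs["norm_a"]),
                                     b=float(f.attrs["norm_b"]))
    return model, scheme


# -- run configuration -------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything one end-to-end run needs, serializable to YAML."""

    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    scheme: NormalizationScheme = dataclasses.field(default_factory=NormalizationScheme)
    arch: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    log_level: str = "INFO"

    @property
    def hash(self) -> str:
        return config_hash(self)


def _tuplify(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    return RunConfig(
        cohort=_tuplify(CohortSpec, raw.get("cohort", {})),
        scheme=_tuplify(NormalizationScheme, raw.get("scheme", {})),
        arch=_tuplify(ModelConfig, raw.get("arch", {})),
        train=_tuplify(TrainConfig, raw.get("train", {})),
        log_level=raw.get("log_level", "INFO"),
    )
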