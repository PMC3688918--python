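"""Data model and readers/writers for injection-level LC-MS feature tables.

The external file convention follows MarkerLynx-style aligned exports:
features in rows (columns ``feature_id, rt, mz`` followed by one intensity
column per injection), plus a separate injection-metadata CSV. In memory the
collapsed :class:`FeatureMatrix` is sample-per-row, matching the usual
``X (n_samples x n_features)`` chemometrics orientation; the single transpose
happens at this boundary. Zero intensity encodes "not detected" throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputStructureError, ValidationError

ROLE_SAMPLE = "sample"
ROLE_BLANK = "blank"
CLASS_HYPOXIA = "hypoxia"
CLASS_NORMOXIA = "normoxia"

#: JSON schema version written by :func:`write_results`.
RESULTS_SCHEMA_VERSION = 1

_METADATA_COLUMNS = [
    "injection_id",
    "sample_id",
    "replicate_index",
    "role",
    "class_label",
    "run_order",
]


def canonical_feature_id(rt: float, mz: float) -> str:
    """Render the (retention time, m/z) pair as the canonical ``RT_MZ`` id.

    Two decimals for retention time (minutes), four for m/z, so tabulated
    references like ``"0.69_489.1157"`` are addressable.
    """
    return f"{rt:.2f}_{mz:.4f}"


@dataclass(frozen=True)
class FeatureDescriptor:
    """An aligned marker: identifier plus retention time (min) and m/z."""

    feature_id: str
    rt: float
    mz: float

    def __post_init__(self):
        if not self.feature_id:
            raise ValidationError("feature_id must be a non-empty string")
        if self.rt < 0:
            raise ValidationError(f"negative retention time for {self.feature_id}")
        if not (50.0 <= self.mz <= 950.0):
            raise ValidationError(
                f"m/z {self.mz} for {self.feature_id} outside the profiling "
                "acquisition range [50, 950]"
            )


@dataclass(frozen=True)
class InjectionRecord:
    """One LC-MS injection: a sample replicate or a solvent blank."""

    injection_id: str
    sample_id: Optional[str]
    replicate_index: int
    role: str
    class_label: Optional[str]
    run_order: int

    def __post_init__(self):
        if self.role not in (ROLE_SAMPLE, ROLE_BLANK):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.role == ROLE_BLANK and (
            self.sample_id is not None or self.class_label is not None
        ):
            raise ValidationError(
                f"blank injection {self.injection_id} must not carry a "
                "sample_id or class_label"
            )
        if self.role == ROLE_SAMPLE and self.sample_id is None:
            raise ValidationError(
                f"sample injection {self.injection_id} lacks a sample_id"
            )
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        if self.run_order < 1:
            raise ValidationError("run_order must be >= 1")


@dataclass
class InjectionTable:
    """Injection-level intensities with feature and injection metadata.

    ``intensity`` is ``[n_features x n_injections]`` with 0 meaning "not
    detected". ``is_area``/``is_mz`` optionally carry the per-injection
    internal-standard peak area and measured IS m/z.
    """

    features: list[FeatureDescriptor]
    injections: list[InjectionRecord]
    intensity: np.ndarray
    is_area: Optional[np.ndarray] = None
    is_mz: Optional[np.ndarray] = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.features), len(self.injections)):
            raise InputStructureError(
                f"intensity shape {self.intensity.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.injections)} injections"
            )
        if np.any(self.intensity < 0):
            raise ValidationError("negative intensities are not allowed")
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature ids: {dupes}")
        orders = [r.run_order for r in self.injections]
        if len(set(orders)) != len(orders):
            raise ValidationError("run_order values must be unique")
        for arr_name in ("is_area", "is_mz"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(self.injections),):
                    raise InputStructureError(
                        f"{arr_name} must have one entry per injection"
                    )
                setattr(self, arr_name, arr)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    @property
    def sample_ids(self) -> list[str]:
        """Ordered unique biological sample ids (first appearance order)."""
        seen: dict[str, None] = {}
        for rec in self.injections:
            if rec.role == ROLE_SAMPLE and rec.sample_id not in seen:
                seen[rec.sample_id] = None
        return list(seen)

    def sample_injection_indices(self, sample_id: str) -> list[int]:
        return [
            i
            for i, rec in enumerate(self.injections)
            if rec.role == ROLE_SAMPLE and rec.sample_id == sample_id
        ]

    @property
    def blank_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.injections) if r.role == ROLE_BLANK]

    def class_of(self, sample_id: str) -> Optional[str]:
        for rec in self.injections:
            if rec.sample_id == sample_id:
                return rec.class_label
        raise KeyError(sample_id)


@dataclass
class FeatureMatrix:
    """Collapsed samples x features matrix with class labels.

    ``provenance`` records the preprocessing stage: ``X1`` (replicate
    medians), ``X2`` (after blank-feature removal), ``X3`` (after the
    low-frequency filter) or ``custom``.
    """

    sample_ids: list[str]
    class_labels: list[Optional[str]]
    features: list[FeatureDescriptor]
    values: np.ndarray
    provenance: str = "custom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise InputStructureError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.features)} features"
            )
        if len(self.class_labels) != len(self.sample_ids):
            raise InputStructureError("one class label per sample required")
        if self.provenance not in ("X1", "X2", "X3", "custom"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def y01(self) -> np.ndarray:
        """Class labels coded 0 = hypoxia, 1 = normoxia."""
        codes = {CLASS_HYPOXIA: 0.0, CLASS_NORMOXIA: 1.0}
        try:
            return np.array([codes[c] for c in self.class_labels])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unlabelled or unknown class: {exc}") from exc

    def subset_features(self, keep: Sequence[int], provenance: str) -> "FeatureMatrix":
        keep = list(keep)
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            class_labels=list(self.class_labels),
            features=[self.features[i] for i in keep],
            values=self.values[:, keep].copy(),
            provenance=provenance,
        )


# ---------------------------------------------------------------------------
# CSV readers/writers


def _read_table(path, dialect: Optional[dict] = None) -> pd.DataFrame:
    sep = (dialect or {}).get("sep")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype={"injection_id": str, "sample_id": str})


def read_injection_table(
    path_intensities, path_metadata, dialect: Optional[dict] = None
) -> InjectionTable:
    """Read an aligned feature table plus its injection metadata.

    Raises :class:`InputStructureError` naming the offending injections if
    the intensity columns and the metadata rows do not match exactly.
    """
    inten = _read_table(path_intensities, dialect)
    meta = _read_table(path_metadata, dialect)

    required = ["feature_id", "rt", "mz"]
    missing = [c for c in required if c not in inten.columns]
    if missing:
        raise InputStructureError(f"intensity file lacks columns: {missing}")
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise InputStructureError(f"metadata file lacks columns: {missing}")

    intensity_cols = [c for c in inten.columns if c not in required]
    meta_ids = list(meta["injection_id"].astype(str))
    extra_cols = sorted(set(intensity_cols) - set(meta_ids))
    extra_meta = sorted(set(meta_ids) - set(intensity_cols))
    if extra_cols or extra_meta:
        raise InputStructureError(
            "intensity columns and metadata injections disagree; "
            f"columns without metadata: {extra_cols}; "
            f"metadata without columns: {extra_meta}"
        )

    features = [
        FeatureDescriptor(str(row.feature_id), float(row.rt), float(row.mz))
        for row in inten.itertuples()
    ]

    def _opt(v):
        return None if (pd.isna(v) or v == "") else str(v)

    meta = meta.set_index(meta["injection_id"].astype(str))
    records = []
    for inj_id in intensity_cols:  # preserve file column order
        row = meta.loc[inj_id]
        records.append(
            InjectionRecord(
                injection_id=inj_id,
                sample_id=_opt(row["sample_id"]),
                replicate_index=int(row["replicate_index"]),
                role=str(row["role"]),
                class_label=_opt(row["class_label"]),
                run_order=int(row["run_order"]),
            )
        )

    matrix = inten[intensity_cols].to_numpy(dtype=float)
    if np.any(matrix < 0):
        bad = [features[i].feature_id for i in np.unique(np.where(matrix < 0)[0])]
        raise ValidationError(f"negative intensities in features: {bad}")

    def _channel(col):
        if col not in meta.columns:
            return None
        vals = meta.loc[intensity_cols, col].to_numpy(dtype=float)
        return None if np.all(np.isnan(vals)) else vals

    return InjectionTable(
        features=features,
        injections=records,
        intensity=matrix,
        is_area=_channel("is_area"),
        is_mz=_channel("is_mz"),
    )


def write_injection_table(table: InjectionTable, path_intensities, path_metadata):
    """Write the feature-per-row intensity CSV and the metadata CSV."""
    inj_ids = [r.injection_id for r in table.injections]
    df = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in table.features],
            "rt": [f.rt for f in table.features],
            "mz": [f.mz for f in table.features],
        }
    )
    for j, inj in enumerate(inj_ids):
        df[inj] = table.intensity[:, j]
    df.to_csv(path_intensities, index=False)

    meta = pd.DataFrame(
        {
            "injection_id": inj_ids,
            "sample_id": [r.sample_id or "" for r in table.injections],
            "replicate_index": [r.replicate_index for r in table.injections],
            "role": [r.role for r in table.injections],
            "class_label": [r.class_label or "" for r in table.injections],
            "run_order": [r.run_order for r in table.injections],
        }
    )
    if table.is_area is not None:
        meta["is_area"] = table.is_area
    if table.is_mz is not None:
        meta["is_mz"] = table.is_mz
    meta.to_csv(path_metadata, index=False)


def write_feature_matrix(matrix: FeatureMatrix, path):
    """Write a collapsed matrix in the feature-per-row file orientation."""
    df = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "rt": [f.rt for f in matrix.features],
            "mz": [f.mz for f in matrix.features],
        }
    )
    for i, sid in enumerate(matrix.sample_ids):
        df[sid] = matrix.values[i, :]
    df.to_csv(path, index=False)


def read_feature_matrix(path, class_labels: dict, provenance: str = "custom"):
    """Read a collapsed matrix written by :func:`write_feature_matrix`.

    ``class_labels`` maps sample id -> class label (or None).
    """
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c not in ("feature_id", "rt", "mz")]
    features = [
        FeatureDescriptor(str(r.feature_id), float(r.rt), float(r.mz))
        for r in df.itertuples()
    ]
    return FeatureMatrix(
        sample_ids=sample_cols,
        class_labels=[class_labels.get(s) for s in sample_cols],
        features=features,
        values=df[sample_cols].to_numpy(dtype=float).T,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Versioned JSON results


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj, path):
    """Serialize a pipeline result object to versioned, key-sorted JSON.

    ``obj`` may be a dataclass with ``to_dict`` or any JSON-able mapping.
    """
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    doc = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "result_type": type(obj).__name__,
        "payload": _jsonable(payload),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_results(path) -> dict:
    """Read a results JSON document, returning its payload dict."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != RESULTS_SCHEMA_VERSION:
        raise InputStructureError(
            f"unsupported results schema version {doc.get('schema_version')}"
        )
    return doc["payload"]
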