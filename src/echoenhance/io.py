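"""Readers/writers for images, cohort CSVs, diagnosis tables and run configs."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .diagnosis import DiagnosisTable, PatientRecord, Sex
from .image import EchoImage

__all__ = [
    "read_image",
    "write_image",
    "write_cohort_csv",
    "read_cohort_csv",
    "read_table_csv",
    "write_table_csv",
    "RunConfig",
    "load_config",
    "save_config",
    "stage_seed",
]

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "lad_mm",
    "lvdd_mm",
    "lvef_pct",
    "smi_kg_m2",
    "grip_kg",
    "gait_m_s",
]

_MODE_DEPTH = {"L": 8, "I;16": 16}


def read_image(path: str | Path) -> EchoImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF into ``[0, 1]`` intensities."""
    with Image.open(path) as im:
        mode = im.mode
        if mode == "I":  # some 16-bit TIFFs load as 32-bit signed
            arr = np.asarray(im)
            if arr.max() > 65535 or arr.min() < 0:
                raise ValueError(f"{path}: mode 'I' image exceeds the 16-bit range")
            return EchoImage.from_integer_array(arr, bit_depth=16)
        if mode not in _MODE_DEPTH:
            raise ValueError(
                f"{path}: unsupported image mode {mode!r}; expected 8-bit ('L') or "
                "16-bit ('I;16') grayscale — convert color/palette images first"
            )
        return EchoImage.from_integer_array(np.asarray(im), bit_depth=_MODE_DEPTH[mode])


def write_image(image: EchoImage, path: str | Path) -> None:
    """Quantize to ``2**n - 1`` levels and write as grayscale PNG/TIFF."""
    if image.bit_depth not in (8, 16):
        raise ValueError(f"file output supports bit depth 8 or 16, got {image.bit_depth}")
    arr = image.quantize()
    if image.bit_depth == 8:
        Image.fromarray(arr).save(path)
    else:
        im = Image.new("I;16", (image.width, image.height))
        im.frombytes(arr.astype("<u2").tobytes())
        im.save(path)


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "sex": r.sex.value,
            "lad_mm": r.lad,
            "lvdd_mm": r.lvdd,
            "lvef_pct": r.lvef,
            "smi_kg_m2": r.smi,
            "grip_kg": r.grip,
            "gait_m_s": r.gait_speed,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")

    def opt(value):
        return None if pd.isna(value) else float(value)

    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            sex=Sex(str(row.sex)),
            lad=opt(row.lad_mm),
            lvdd=opt(row.lvdd_mm),
            lvef=opt(row.lvef_pct),
            smi=opt(row.smi_kg_m2),
            grip=opt(row.grip_kg),
            gait_speed=opt(row.gait_m_s),
        )
        for row in df.itertuples(index=False)
    ]


def read_table_csv(path: str | Path) -> DiagnosisTable:
    """Read a diagnosis count table: columns ``group,chf_count,other_count``."""
    df = pd.read_csv(path)
    required = ["group", "chf_count", "other_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: table CSV missing columns {missing}")
    groups = {
        str(row.group): (int(row.chf_count), int(row.other_count))
        for row in df.itertuples(index=False)
    }
    totals = {chf + other for chf, other in groups.values()}
    if len(totals) != 1:
        raise ValueError(f"{path}: group columns sum to different totals {sorted(totals)}")
    return DiagnosisTable(groups=groups, cohort_total=totals.pop())


def write_table_csv(table: DiagnosisTable, path: str | Path) -> None:
    rows = [
        {"group": label, "chf_count": chf, "other_count": other}
        for label, (chf, other) in table.groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from the run seed by stable hashing."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


# Flat, documented configuration key space.  Unknown keys are errors.
_CONFIG_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "runs/demo",
    "phantom.height": 32,
    "phantom.width": 32,
    "degrade.blur_sigma": 1.0,
    "degrade.speckle_sigma": 0.2,
    "degrade.additive_sigma": 0.0,
    "train.n_pairs": 40,
    "train.epochs": 200,
    "train.learning_rate": 0.2,
    "train.batch_size": 2,
    "train.activation": "swish",
    "semisup.enabled": False,
    "semisup.v": 0.5,
    "metrics.ssim_mode": "global",
    "diagnosis.rule": "any",
    "cohort.n_patients": 259,
    "concordance.control_chf": 200,
    "concordance.experimental_chf": 215,
    "concordance.final_chf": 230,
    "concordance.total": 259,
}


@dataclass(frozen=True)
class RunConfig:
    """Flat key/value pipeline configuration; see ``defaults()`` for the keys."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_CONFIG_DEFAULTS)
        unknown = sorted(set(self.values) - set(_CONFIG_DEFAULTS))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        merged.update(self.values)
        object.__setattr__(self, "values", merged)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @staticmethod
    def defaults() -> dict[str, Any]:
        return dict(_CONFIG_DEFAULTS)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    return RunConfig(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.values, sort_keys=True))
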