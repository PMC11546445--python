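"""Reading and writing of PPG signals, dataset manifests, and scalogram images.

File dialects
-------------
* **Signal files** hold one numeric amplitude per line (an optional single
  non-numeric header line is skipped).  A single-row comma/whitespace
  separated file is also accepted, since both layouts are common exports of
  one-channel recordings.
* **Manifests** are CSV with columns
  ``path,subject_id,label,segment_index[,synthetic,source_subject_id]``.
* **Scalogram images** are stored as PNG so round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import EmptyInputError, ParseError, ValidationError

#: Blood-pressure stage labels, in fixed order.  Integer codes are the
#: positions in this tuple: N=0, P=1, S1=2, S2=3.
LABELS: tuple[str, ...] = ("N", "P", "S1", "S2")
LABEL_TO_CODE: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}


def label_code(label: str) -> int:
    """Map a stage label (``N``/``P``/``S1``/``S2``) to its integer code."""
    try:
        return LABEL_TO_CODE[label]
    except KeyError:
        raise ValidationError(
            f"unknown label {label!r}; allowed labels are {list(LABELS)}"
        ) from None


@dataclasses.dataclass
class PPGRecord:
    """One labeled PPG segment with subject provenance.

    ``source_subject_id`` equals ``subject_id`` for real records; synthetic
    records (SMOTE interpolants) carry the id of the subject they were
    interpolated from, so subject-aware splitting can keep them together.
    """

    subject_id: str
    label: str
    segment_index: int
    samples: np.ndarray
    fs: float
    synthetic: bool = False
    source_subject_id: str | None = None

    def __post_init__(self) -> None:
        label_code(self.label)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("samples must be a 1-D sequence of length >= 2")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.segment_index < 0:
            raise ValidationError("segment_index must be >= 0")
        if self.source_subject_id is None:
            self.source_subject_id = self.subject_id

    @property
    def label_code(self) -> int:
        return LABEL_TO_CODE[self.label]


MANIFEST_COLUMNS = [
    "path",
    "subject_id",
    "label",
    "segment_index",
    "synthetic",
    "source_subject_id",
]


@dataclasses.dataclass
class DatasetManifest:
    """Tabular index of a PPG dataset (one row per segment).

    Wraps a :class:`pandas.DataFrame` with the columns of
    :data:`MANIFEST_COLUMNS`.  Validation enforces known labels and
    uniqueness of ``(subject_id, segment_index, synthetic-ordinal)``:
    real rows must be unique per (subject, segment); synthetic rows may
    repeat a (subject, segment) pair and are distinguished by their ordinal.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "synthetic" not in df.columns:
            df["synthetic"] = False
        if "source_subject_id" not in df.columns:
            df["source_subject_id"] = df["subject_id"]
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        df = df[MANIFEST_COLUMNS]
        df["synthetic"] = df["synthetic"].astype(bool)
        df["segment_index"] = df["segment_index"].astype(int)
        df["subject_id"] = df["subject_id"].astype(str)
        df["source_subject_id"] = df["source_subject_id"].astype(str)
        bad = sorted(set(df["label"]) - set(LABELS))
        if bad:
            raise ValidationError(
                f"unknown labels {bad}; allowed labels are {list(LABELS)}"
            )
        real = df[~df["synthetic"]]
        dup = real.duplicated(subset=["subject_id", "segment_index"])
        if dup.any():
            rows = real[dup][["subject_id", "segment_index"]].drop_duplicates()
            raise ValidationError(
                "duplicate (subject_id, segment_index) for real records: "
                + ", ".join(f"({r.subject_id}, {r.segment_index})" for r in rows.itertuples())
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        """Distinct source subject ids, in first-appearance order."""
        return list(dict.fromkeys(self.df["source_subject_id"]))

    def rows(self) -> Iterable[pd.Series]:
        return (row for _, row in self.df.iterrows())

    @classmethod
    def from_records(cls, records: Sequence[PPGRecord], paths: Sequence[str | Path]) -> "DatasetManifest":
        if len(records) != len(paths):
            raise ValidationError("records and paths must have equal length")
        return cls(
            pd.DataFrame(
                {
                    "path": [str(p) for p in paths],
                    "subject_id": [r.subject_id for r in records],
                    "label": [r.label for r in records],
                    "segment_index": [r.segment_index for r in records],
                    "synthetic": [r.synthetic for r in records],
                    "source_subject_id": [r.source_subject_id for r in records],
                }
            )
        )


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_signal(path: str | Path, fs: float = 1000.0) -> np.ndarray:
    """Read a one-column (or one-row) numeric signal file.

    Returns the samples in file order; no resampling or scaling is applied.
    A single leading non-numeric header line is skipped.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty signal file")
    rows = [_tokenize(ln) for ln in lines]

    def parse(tok: str) -> float:
        try:
            return float(tok)
        except ValueError:
            raise ParseError(f"{path}: non-numeric value {tok!r}") from None

    # Header: first line non-numeric, rest parseable.
    try:
        float(rows[0][0])
    except ValueError:
        rows = rows[1:]
        if not rows:
            raise EmptyInputError(f"{path}: header but no data")
    if all(len(r) == 1 for r in rows):
        return np.array([parse(r[0]) for r in rows])
    if len(rows) == 1:  # one-row layout
        return np.array([parse(t) for t in rows[0]])
    raise ParseError(f"{path}: expected one value per line (or a single row)")


def write_signal(samples: np.ndarray, path: str | Path) -> None:
    """Write samples one per line (float repr round-trips exactly)."""
    samples = np.asarray(samples, dtype=float)
    Path(path).write_text("\n".join(repr(float(v)) for v in samples) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, dtype={"subject_id": str, "source_subject_id": str})
    return DatasetManifest(df)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, index=False)


def write_scalogram_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB array to PNG (lossless; round-trip is bit-exact)."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 array, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValidationError("image height and width must be positive")
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise ValidationError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("image values must lie in [0, 255]")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(Path(path), format="PNG")


def read_scalogram_image(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("RGB"))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
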