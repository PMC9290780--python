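"""Dataset manifests: (path, label, split) records with CSV/JSON round-trip.

Labels follow the karyotype convention of the reference set: 0 = Y
chromosome, 1-22 = autosomes, 23 = X chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ManifestRecord", "DatasetManifest", "read_manifest",
           "write_manifest"]

VALID_SPLITS = ("train", "test")


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int
    split: str

    def __post_init__(self):
        if not 0 <= self.label <= 23:
            raise ValueError(f"label {self.label} outside 0-23")
        if self.split not in VALID_SPLITS:
            raise ValueError(f"split {self.split!r} not in {VALID_SPLITS}")


class DatasetManifest:
    def __init__(self, records: list[ManifestRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, DatasetManifest) and \
            self.records == other.records

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def class_counts(self, split: str | None = None) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.path, r.label, r.split) for r in self.records],
            columns=["path", "label", "split"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = [{"path": r.path, "label": r.label, "split": r.split}
                   for r in self.records]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_rows(cls, rows) -> "DatasetManifest":
        records = []
        for lineno, (path, label, split) in enumerate(rows, start=2):
            try:
                records.append(ManifestRecord(str(path), int(label), str(split)))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"manifest line {lineno}: {exc}") from exc
        return cls(records)


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a CSV (columns path,label,split) or its JSON mirror."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = [(d["path"], d["label"], d["split"])
                for d in json.loads(path.read_text())]
        return DatasetManifest.from_rows(rows)
    df = pd.read_csv(path)
    missing = {"path", "label", "split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return DatasetManifest.from_rows(
        df[["path", "label", "split"]].itertuples(index=False, name=None))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        manifest.to_json(path)
    else:
        manifest.to_csv(path)
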