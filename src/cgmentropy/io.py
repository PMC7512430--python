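"""Record file readers/writers, packaged reference tables, flat config files.

Record files are plain CSV, one sample per row::

    # period_s=300
    index,glucose_mmol_per_l
    0,7.8
    1,
    2,8.1

An empty glucose field marks a missing sample.  Class labels live in a
separate manifest (``record_id,class,seed``) so record files stay reusable
across experiments.

The packaged reference tables are the published per-record SampEn scores
of the 23 six-day records (14 A1 / 9 B1) and the 25 leave-one-out rows,
used for replay verification.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GlucoseRecord
from .roc import ScoreSet

#: SHA-256 of the packaged reference tables (drift guard).
FIXTURE_CHECKSUMS = {
    "reference_sampen_scores.csv": "afe2439c7dae76903fa13c9bb0d087fea2a7d67763ce7977432a59f1e62fcd8b",
    "reference_loo_rows.csv": "36c3375918fa26838a0a56fa251412eec376d74580c9b31a13e9cc3f7adf46f9",
}


class RecordParseError(ValueError):
    """Malformed record file; message carries the offending line number."""


def write_record(rec: GlucoseRecord, path) -> None:
    """Write one record in the pinned CSV dialect (missing -> empty field)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# period_s={rec.sampling_period_s}\n")
        fh.write("index,glucose_mmol_per_l\n")
        for i, (v, miss) in enumerate(zip(rec.values, rec.missing_mask)):
            fh.write(f"{i},\n" if miss else f"{i},{v:.4f}\n")


def read_record(path, label: str = "unlabeled", record_id: str | None = None) -> GlucoseRecord:
    """Parse one record file; empty glucose fields become masked samples."""
    path = Path(path)
    period = 300
    values: list[float] = []
    mask: list[bool] = []
    prev_index = -1
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("period_s="):
                    period = int(body.split("=", 1)[1])
                continue
            if line.lower().startswith("index"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise RecordParseError(f"{path.name}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                index = int(parts[0])
            except ValueError as err:
                raise RecordParseError(f"{path.name}:{lineno}: bad index {parts[0]!r}") from err
            if index <= prev_index:
                raise RecordParseError(f"{path.name}:{lineno}: non-monotone index {index}")
            prev_index = index
            if parts[1] == "":
                values.append(0.0)
                mask.append(True)
            else:
                try:
                    values.append(float(parts[1]))
                except ValueError as err:
                    raise RecordParseError(
                        f"{path.name}:{lineno}: bad glucose value {parts[1]!r}"
                    ) from err
                mask.append(False)
    if not values:
        raise RecordParseError(f"{path.name}: no samples found")
    return GlucoseRecord(
        values=np.asarray(values),
        missing_mask=np.asarray(mask),
        sampling_period_s=period,
        label=label,
        record_id=record_id or path.stem,
    )


def read_records(paths, manifest=None) -> list[GlucoseRecord]:
    """Read several record files; labels come from a manifest or filenames.

    ``manifest`` may be a path to a ``record_id,class[,seed]`` CSV or a
    mapping ``record_id -> label``.  Without one, a filename containing
    ``A1`` or ``B1`` sets the label.
    """
    labels: dict[str, str] = {}
    if manifest is not None:
        if isinstance(manifest, (str, Path)):
            df = pd.read_csv(manifest, dtype=str)
            labels = dict(zip(df["record_id"], df["class"]))
        else:
            labels = dict(manifest)
    records = []
    for path in paths:
        stem = Path(path).stem
        label = labels.get(stem)
        if label is None:
            upper = stem.upper()
            label = "A1" if "A1" in upper else "B1" if "B1" in upper else "unlabeled"
        records.append(read_record(path, label=label, record_id=stem))
    return records


def write_cohort(records, directory) -> Path:
    """Write one file per record plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_record(rec, directory / f"{rec.record_id}.csv")
        rows.append({"record_id": rec.record_id, "class": rec.label})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


@dataclass(frozen=True)
class Fixture:
    """Published per-record scores and leave-one-out rows, for replay."""

    scores_table: pd.DataFrame  # record_id, label, sampen
    loo_table: pd.DataFrame  # a1_id, b1_id, auc, threshold, sampen_a1, sampen_b1, accuracy_pct

    def scoreset(self) -> ScoreSet:
        a = self.scores_table[self.scores_table["label"] == "A1"]
        b = self.scores_table[self.scores_table["label"] == "B1"]
        return ScoreSet(
            scores_a1=a["sampen"].to_numpy(),
            scores_b1=b["sampen"].to_numpy(),
            metric_tag="SampEn(m=1, r=0.17), six-day records",
            ids_a1=a["record_id"].tolist(),
            ids_b1=b["record_id"].tolist(),
        )

    def loo_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.loo_table["a1_id"], self.loo_table["b1_id"]))


def _fixture_bytes(name: str) -> bytes:
    return resources.files("cgmentropy.data").joinpath(name).read_bytes()


def verify_fixture_checksums() -> None:
    """Raise if a packaged reference table drifted from its pinned hash."""
    for name, expected in FIXTURE_CHECKSUMS.items():
        digest = hashlib.sha256(_fixture_bytes(name)).hexdigest()
        if digest != expected:
            raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")


def load_fixtures() -> Fixture:
    """Load the packaged reference tables (checksum-verified)."""
    verify_fixture_checksums()
    import io as _io

    scores = pd.read_csv(_io.BytesIO(_fixture_bytes("reference_sampen_scores.csv")))
    loo = pd.read_csv(_io.BytesIO(_fixture_bytes("reference_loo_rows.csv")))
    return Fixture(scores_table=scores, loo_table=loo)


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file with simple type coercion."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            if value.lower() in ("true", "false"):
                out[key] = value.lower() == "true"
            elif "," in value:
                out[key] = [v.strip() for v in value.split(",")]
            else:
                out[key] = value
    return out
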