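"""Readers and writers for morphometric tables and subject metadata.

Two in-memory containers, both plain pandas DataFrames:

* **morphometric table** (long format): columns ``subject_id, hemisphere,
  region, measure, value`` — one row per (subject, hemisphere, region,
  measure) cell.  ``value`` is a finite non-negative float in the natural
  units of the measure (mm for thickness, mm^2 for area, mm^3 for volumes).
* **subject metadata**: columns ``subject_id, group, age, gender, scanner,
  preserved_hemisphere, procedure, ilae_binned``.

``read_region_table`` accepts three dialects: the tidy CSV above, and the
FreeSurfer ``aparc`` / ``aseg`` stats text formats ('#'-prefixed headers,
whitespace-delimited rows).  Regions not in the vocabulary are dropped and
reported in ``df.attrs["unknown_regions"]``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import (
    HEMISPHERES,
    MEASURES,
    RegionVocabulary,
    normalize_region_name,
)

TABLE_COLUMNS = ["subject_id", "hemisphere", "region", "measure", "value"]
META_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "scanner",
    "preserved_hemisphere",
    "procedure",
    "ilae_binned",
]


class MorphoValidationError(ValueError):
    """Raised when a table or metadata frame violates its invariants."""


# ---------------------------------------------------------------------------
# morphometric tables
# ---------------------------------------------------------------------------


def validate_table(table: pd.DataFrame, vocab: RegionVocabulary | None = None) -> pd.DataFrame:
    """Check invariants of a long-format morphometric table.

    Raises :class:`MorphoValidationError` on duplicate keys, non-finite or
    negative values, unknown measures/hemispheres, or a thickness value
    attached to a non-cortical region.  Returns the table unchanged.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise MorphoValidationError(f"table missing columns: {missing}")
    key = ["subject_id", "hemisphere", "region", "measure"]
    dup = table.duplicated(subset=key)
    if dup.any():
        bad = table.loc[dup, key].iloc[0].tolist()
        raise MorphoValidationError(f"duplicate record key: {bad}")
    vals = pd.to_numeric(table["value"], errors="coerce")
    if not np.isfinite(vals.to_numpy(float)).all():
        raise MorphoValidationError("non-finite or non-numeric value present")
    if (vals < 0).any():
        raise MorphoValidationError("negative morphometric value present")
    bad_h = set(table["hemisphere"]) - set(HEMISPHERES)
    if bad_h:
        raise MorphoValidationError(f"unknown hemisphere labels: {sorted(bad_h)}")
    bad_m = set(table["measure"]) - set(MEASURES)
    if bad_m:
        raise MorphoValidationError(f"unknown measures: {sorted(bad_m)}")
    if vocab is not None:
        cortical = set(vocab.cortical)
        thick = table.loc[table["measure"] == "thickness", "region"]
        bad_t = set(thick) - cortical
        if bad_t:
            raise MorphoValidationError(
                f"thickness recorded for non-cortical regions: {sorted(bad_t)}"
            )
    return table


def _finish_table(df: pd.DataFrame, vocab: RegionVocabulary | None) -> pd.DataFrame:
    """Normalize region names, drop unknown regions, validate, sort."""
    df = df.copy()
    df["region"] = df["region"].map(normalize_region_name).where(
        ~df["measure"].eq("gross_volume"), df["region"]
    )
    unknown: list[str] = []
    if vocab is not None:
        known = set(vocab.all_regions)
        mask = df["region"].isin(known)
        unknown = sorted(set(df.loc[~mask, "region"]))
        df = df.loc[mask]
    df = df.sort_values(TABLE_COLUMNS[:4], kind="mergesort").reset_index(drop=True)
    df["value"] = df["value"].astype(float)
    validate_table(df, vocab)
    df.attrs["unknown_regions"] = unknown
    return df


def read_tidy_table(path: str | Path, vocab: RegionVocabulary | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MorphoValidationError(f"{path}: tidy CSV missing columns {missing}")
    return _finish_table(df[TABLE_COLUMNS], vocab)


def write_tidy_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TABLE_COLUMNS].to_csv(path, index=False)


def _parse_stats_lines(path: str | Path) -> tuple[dict[str, str], list[list[str]]]:
    """Split a FreeSurfer stats file into header key/values and data rows."""
    headers: dict[str, str] = {}
    rows: list[list[str]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            parts = body.split(None, 1)
            if len(parts) == 2:
                headers[parts[0]] = parts[1].strip()
            continue
        fields = line.split()
        rows.append([str(lineno)] + fields)
    return headers, rows


def read_freesurfer_aparc(
    path: str | Path,
    subject_id: str | None = None,
    hemisphere: str | None = None,
    vocab: RegionVocabulary | None = None,
) -> pd.DataFrame:
    """Read a FreeSurfer ``?h.aparc.stats`` file into a long-format table.

    Each data row carries (StructName, NumVert, SurfArea, GrayVol, ThickAvg,
    ...); area (mm^2), volume (mm^3) and thickness (mm) are extracted per
    region.  Subject and hemisphere come from the ``# subjectname`` and
    ``# hemi`` header lines unless given explicitly.
    """
    headers, rows = _parse_stats_lines(path)
    subject_id = subject_id or headers.get("subjectname")
    hemi = hemisphere or {"lh": "LH", "rh": "RH"}.get(headers.get("hemi", "").lower())
    if subject_id is None or hemi is None:
        raise MorphoValidationError(
            f"{path}: subject_id/hemisphere not in headers; pass them explicitly"
        )
    records = []
    for row in rows:
        lineno, fields = row[0], row[1:]
        if len(fields) < 5:
            raise MorphoValidationError(f"{path}:{lineno}: malformed aparc row")
        name = fields[0]
        try:
            area, volume, thickness = float(fields[2]), float(fields[3]), float(fields[4])
        except ValueError as exc:
            raise MorphoValidationError(f"{path}:{lineno}: non-numeric field") from exc
        for measure, value in (("thickness", thickness), ("area", area), ("volume", volume)):
            records.append((subject_id, hemi, name, measure, value))
    df = pd.DataFrame(records, columns=TABLE_COLUMNS)
    return _finish_table(df, vocab)


# aseg '# Measure' header names mapped onto (hemisphere, gross measure)
_ASEG_MEASURES = {
    "lhCortexVol": ("LH", "GM"),
    "rhCortexVol": ("RH", "GM"),
    "lhCerebralWhiteMatterVol": ("LH", "WM"),
    "rhCerebralWhiteMatterVol": ("RH", "WM"),
}


def read_freesurfer_aseg(
    path: str | Path,
    subject_id: str | None = None,
    vocab: RegionVocabulary | None = None,
) -> pd.DataFrame:
    """Read a FreeSurfer ``aseg.stats`` file into a long-format table.

    Subcortical rows (``Left-Hippocampus`` ...) become ``subcortical_volume``
    records; lateral-ventricle rows and the ``# Measure lhCortexVol`` /
    ``lhCerebralWhiteMatterVol`` header lines become the gross LV/GM/WM
    volumes.
    """
    headers, rows = _parse_stats_lines(path)
    subject_id = subject_id or headers.get("subjectname")
    if subject_id is None:
        raise MorphoValidationError(f"{path}: subjectname header absent; pass subject_id")
    records = []
    # '# Measure lhCortexVol, lhCortexVol, <desc>, <value>, mm^3'
    for line in Path(path).read_text().splitlines():
        if not line.startswith("# Measure"):
            continue
        parts = [p.strip() for p in line[len("# Measure") :].split(",")]
        if len(parts) >= 4 and parts[0] in _ASEG_MEASURES:
            hemi, gross = _ASEG_MEASURES[parts[0]]
            records.append((subject_id, hemi, gross, "gross_volume", float(parts[3])))
    lv = {"LH": 0.0, "RH": 0.0}
    for row in rows:
        lineno, fields = row[0], row[1:]
        if len(fields) < 5:
            raise MorphoValidationError(f"{path}:{lineno}: malformed aseg row")
        name = fields[4]
        try:
            volume = float(fields[3])
        except ValueError as exc:
            raise MorphoValidationError(f"{path}:{lineno}: non-numeric volume") from exc
        hemi = "LH" if name.startswith("Left-") else "RH" if name.startswith("Right-") else None
        if hemi is None:
            continue
        canonical = normalize_region_name(name)
        if canonical == "LV":  # Lateral-Ventricle and Inf-Lat-Vent pool into LV
            lv[hemi] += volume
            continue
        records.append((subject_id, hemi, name, "subcortical_volume", volume))
    for hemi, vol in lv.items():
        if vol > 0:
            records.append((subject_id, hemi, "LV", "gross_volume", vol))
    df = pd.DataFrame(records, columns=TABLE_COLUMNS)
    return _finish_table(df, vocab)


def read_region_table(
    path: str | Path,
    dialect: str = "tidy_csv",
    vocab: RegionVocabulary | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Read a morphometric table in the named dialect.

    dialect is one of ``tidy_csv``, ``freesurfer_aparc``, ``freesurfer_aseg``.
    Unknown regions are excluded and listed in ``result.attrs["unknown_regions"]``.
    """
    readers = {
        "tidy_csv": read_tidy_table,
        "freesurfer_aparc": read_freesurfer_aparc,
        "freesurfer_aseg": read_freesurfer_aseg,
    }
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(readers)}")
    return readers[dialect](path, vocab=vocab, **kwargs)


# ---------------------------------------------------------------------------
# subject metadata
# ---------------------------------------------------------------------------


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Enforce metadata invariants.

    Controls must have ``preserved_hemisphere='both'`` and ``procedure='none'``;
    patients exactly one preserved hemisphere and a real procedure; ages
    positive; categorical fields restricted to their domains.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MorphoValidationError(f"metadata missing columns: {missing}")
    if meta["subject_id"].duplicated().any():
        raise MorphoValidationError("duplicate subject_id in metadata")
    domains = {
        "group": {"patient", "control"},
        "gender": {"F", "M"},
        "preserved_hemisphere": {"LH", "RH", "both"},
        "procedure": {"resection", "ablation", "none"},
        "ilae_binned": {"high", "low", "none"},
    }
    for col, dom in domains.items():
        bad = set(meta[col].astype(str)) - dom
        if bad:
            raise MorphoValidationError(f"invalid {col} values: {sorted(bad)}")
    ages = pd.to_numeric(meta["age"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any():
        raise MorphoValidationError("age must be a positive number for every subject")
    ctrl = meta["group"] == "control"
    if (meta.loc[ctrl, "preserved_hemisphere"] != "both").any():
        raise MorphoValidationError("controls must have preserved_hemisphere='both'")
    if (meta.loc[ctrl, "procedure"] != "none").any():
        raise MorphoValidationError("controls must have procedure='none'")
    pat = ~ctrl
    if (~meta.loc[pat, "preserved_hemisphere"].isin(["LH", "RH"])).any():
        raise MorphoValidationError("patients must have exactly one preserved hemisphere")
    if (meta.loc[pat, "procedure"] == "none").any():
        raise MorphoValidationError("patients must have a procedure (resection/ablation)")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"subject_id": str})
    meta["age"] = meta["age"].astype(float)
    return validate_metadata(meta[META_COLUMNS]).reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, index=False)
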