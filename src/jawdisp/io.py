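"""File-format glue: landmark/profile/grouping CSVs, NEXUS output, and
run manifests.

CSV is the interchange format between pipeline stages (human-diffable and
regression-friendly); NEXUS appears only at the character-input boundary.
All floating-point artifacts are written with 12 significant digits so
that reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .characters import MISSING, CharacterMatrix, DistanceMatrix
from .errors import InputError
from .measurements import LANDMARK_NAMES, CrossSection, LandmarkSet
from .ordination import Ordination

__all__ = [
    "FLOAT_FORMAT",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_groups_csv",
    "write_groups_csv",
    "write_characters_nexus",
    "write_characters_csv",
    "write_distance_csv",
    "write_ordination",
    "write_frame",
    "write_manifest",
]

FLOAT_FORMAT = "%.12g"

PROFILE_COLUMNS = {
    "ama": "AMA",
    "pma": "PMA",
    "oma": "OMA",
    "smoi": "SMOI",
    "lwr": "LWR",
    "rtw": "RTW",
}


def write_frame(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)
    return path


# ---------------------------------------------------------------------------
# landmarks


def write_landmarks_csv(
    landmarks: list[LandmarkSet], cross_sections: list[CrossSection], path
) -> Path:
    """One row per specimen: specimen_id, <landmark>_{x,y,z}..., cs_a, cs_b, unit."""
    if len(landmarks) != len(cross_sections):
        raise InputError("landmark and cross-section lists differ in length")
    rows = []
    for lm, cs in zip(landmarks, cross_sections):
        row: dict[str, object] = {"specimen_id": lm.specimen_id}
        for name in LANDMARK_NAMES:
            p = getattr(lm, name)
            for axis, value in zip("xyz", p if p is not None else (np.nan,) * 3):
                row[f"{name}_{axis}"] = value
        row["cs_a"] = cs.a
        row["cs_b"] = cs.b
        row["unit"] = lm.length_unit
        rows.append(row)
    return write_frame(pd.DataFrame(rows), path, index=False)


def read_landmarks_csv(path) -> tuple[list[LandmarkSet], list[CrossSection]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise InputError("landmark CSV lacks a specimen_id column")
    landmarks, cross_sections = [], []
    for _, row in df.iterrows():
        points = {}
        for name in LANDMARK_NAMES:
            cols = [f"{name}_{axis}" for axis in "xyz"]
            if not all(c in df.columns for c in cols):
                points[name] = None
                continue
            p = row[cols].to_numpy(dtype=float)
            points[name] = None if np.any(np.isnan(p)) else p
        landmarks.append(
            LandmarkSet(
                specimen_id=str(row["specimen_id"]),
                length_unit=str(row.get("unit", "mm")),
                **points,
            )
        )
        cross_sections.append(CrossSection(a=float(row["cs_a"]), b=float(row["cs_b"])))
    return landmarks, cross_sections


# ---------------------------------------------------------------------------
# profiles


def write_profiles_csv(profiles, path) -> Path:
    rows = [
        {"species_id": p.species_id, **{PROFILE_COLUMNS[k]: v for k, v in p.as_dict().items()}}
        for p in profiles
    ]
    return write_frame(pd.DataFrame(rows), path, index=False)


def read_profiles_csv(path) -> pd.DataFrame:
    """Profiles as species-indexed trait table with AMA..RTW columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"profile file not found: {path}")
    df = pd.read_csv(path).set_index("species_id")
    missing = [c for c in PROFILE_COLUMNS.values() if c not in df.columns]
    if missing:
        raise InputError(f"profile CSV lacks columns: {missing}")
    return df[list(PROFILE_COLUMNS.values())]


# ---------------------------------------------------------------------------
# groups


def write_groups_csv(groups: pd.DataFrame, path) -> Path:
    return write_frame(groups, path, index=True)


def read_groups_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"grouping file not found: {path}")
    return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# characters


def _nexus_cell(value, symbols: str) -> str:
    if value is MISSING:
        return "?"
    if isinstance(value, tuple):
        distinct = sorted(set(value))
        return "{" + "".join(symbols[s] for s in distinct) + "}"
    return symbols[value]


def write_characters_nexus(m: CharacterMatrix, path) -> Path:
    """Write a STANDARD-datatype NEXUS file (quoted labels, '?' missing).

    NEXUS state sets cannot express multisets, so polymorphic multisets
    are flattened to their distinct states; round-tripping through NEXUS
    therefore turns two-state multiset majorities into ties. Use the CSV
    writer when frequency information must survive.
    """
    max_state = max(
        (s for row in m.cells for v in row if v is not MISSING
         for s in (v if isinstance(v, tuple) else (v,))),
        default=0,
    )
    symbols = "0123456789"[: max_state + 1]
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.characters)};",
        f"  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS=\"{symbols}\";",
        "  MATRIX",
    ]
    for taxon, row in zip(m.taxa, m.cells):
        cells = "".join(_nexus_cell(v, symbols) for v in row)
        lines.append(f"    '{taxon}' {cells}")
    lines += ["  ;", "END;", ""]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def _csv_cell(value) -> str:
    if value is MISSING:
        return "?"
    if isinstance(value, tuple):
        return "{" + "".join(str(s) for s in value) + "}"
    return str(value)


def write_characters_csv(m: CharacterMatrix, path) -> Path:
    df = pd.DataFrame(
        [[_csv_cell(v) for v in row] for row in m.cells],
        index=pd.Index(m.taxa, name="taxon"),
        columns=m.characters,
    )
    return write_frame(df, path, index=True)


def write_distance_csv(dm: DistanceMatrix, path) -> Path:
    return write_frame(dm.to_frame(), path, index=True)


# ---------------------------------------------------------------------------
# ordinations and manifests


def write_ordination(ord_: Ordination, out_dir, prefix: str) -> dict[str, str]:
    """Write scores/variance(/loadings) CSVs; returns artifact paths."""
    out_dir = Path(out_dir)
    artifacts = {
        f"{prefix}_scores": str(write_frame(ord_.scores, out_dir / f"{prefix}_scores.csv")),
        f"{prefix}_variance": str(
            write_frame(ord_.variance_table(), out_dir / f"{prefix}_variance.csv")
        ),
    }
    if ord_.loadings is not None:
        artifacts[f"{prefix}_loadings"] = str(
            write_frame(ord_.loadings, out_dir / f"{prefix}_loadings.csv")
        )
    return artifacts


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, stage: str, config: dict, artifacts: dict, counts: dict) -> Path:
    """JSON run manifest: inputs/config (hashed), seed, artifact paths and
    per-artifact row/column counts. Deliberately no timestamps, so reruns
    with identical config are byte-identical.
    """
    from . import __version__

    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "artifacts": artifacts,
        "counts": counts,
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
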