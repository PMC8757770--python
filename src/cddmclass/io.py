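"""Reading and writing of map files and cohort manifests.

Map file format: UTF-8 text, one matrix per file.  Rows are lines; values are
whitespace- or comma-separated decimal floats; lines starting with ``#`` are
comments.  A map is stored as one magnitude file plus one angle file.

Manifest format: a tab-separated table with header columns ``map_id``,
``magnitude_path``, ``angle_path``, ``label``; paths are resolved relative to
the manifest's own directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CDDM, wrap_angle
from .labels import HeartStateLabel, parse_label

MANIFEST_COLUMNS = ("map_id", "magnitude_path", "angle_path", "label")


class MapParseError(ValueError):
    """Raised on malformed map files, with file/line context in the message."""


class ManifestError(ValueError):
    """Raised on malformed or inconsistent manifests."""


def read_matrix(path: str | Path) -> np.ndarray:
    """Parse one plain-text matrix file into a 2-D float array."""
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.replace(",", " ").split()
        try:
            rows.append([float(tok) for tok in tokens])
        except ValueError as exc:
            raise MapParseError(f"{path}:{lineno}: non-numeric token: {exc}") from None
        if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
            raise MapParseError(
                f"{path}:{lineno}: ragged row (expected {len(rows[0])} values, "
                f"got {len(rows[-1])})"
            )
    if not rows:
        raise MapParseError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix as plain text with full float precision."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g")


def read_cddm(
    magnitude_path: str | Path,
    angle_path: str | Path,
    label: HeartStateLabel | None = None,
    map_id: str = "",
    angle_units: str = "radians",
) -> CDDM:
    """Load one map from its magnitude and angle files.

    Angles are converted from degrees when ``angle_units='degrees'`` and are
    always wrapped into (−π, π].
    """
    mag = read_matrix(magnitude_path)
    ang = read_matrix(angle_path)
    if mag.shape != ang.shape:
        raise MapParseError(
            f"shape mismatch: {magnitude_path} is {mag.shape} but "
            f"{angle_path} is {ang.shape}"
        )
    if angle_units == "degrees":
        ang = np.deg2rad(ang)
    elif angle_units != "radians":
        raise ValueError(f"angle_units must be 'radians' or 'degrees', got {angle_units!r}")
    return CDDM(magnitude=mag, angle=wrap_angle(ang), label=label, map_id=str(map_id))


def write_cddm(cddm: CDDM, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a map as ``<map_id>_mag.txt`` and ``<map_id>_ang.txt``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not cddm.map_id:
        raise ValueError("cddm.map_id must be set to write map files")
    mag_path = out_dir / f"{cddm.map_id}_mag.txt"
    ang_path = out_dir / f"{cddm.map_id}_ang.txt"
    write_matrix(cddm.magnitude, mag_path)
    write_matrix(cddm.angle, ang_path)
    return mag_path, ang_path


@dataclass(frozen=True)
class ManifestEntry:
    map_id: str
    magnitude_path: Path
    angle_path: Path
    label: HeartStateLabel


@dataclass
class CohortManifest:
    """A labeled collection of map files.

    ``groups`` maps each label to the list of map_ids carrying it, in
    manifest order (the order also used for deterministic distance-tie
    breaking downstream).
    """

    entries: list[ManifestEntry]
    angle_units: str = "radians"

    def __post_init__(self) -> None:
        ids = [e.map_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate map_ids in manifest: {dupes}")

    @property
    def groups(self) -> dict[HeartStateLabel, list[str]]:
        out: dict[HeartStateLabel, list[str]] = {}
        for e in self.entries:
            out.setdefault(e.label, []).append(e.map_id)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def load_maps(self) -> list[CDDM]:
        """Load every entry's map files, in manifest order."""
        return [
            read_cddm(
                e.magnitude_path,
                e.angle_path,
                label=e.label,
                map_id=e.map_id,
                angle_units=self.angle_units,
            )
            for e in self.entries
        ]


def read_manifest(path: str | Path, angle_units: str = "radians") -> CohortManifest:
    """Load a manifest table and validate labels and referenced files."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ManifestError(f"{path}: cannot parse manifest: {exc}") from None
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    base = path.parent
    entries: list[ManifestEntry] = []
    for row in table.itertuples(index=False):
        mag_path = base / str(row.magnitude_path)
        ang_path = base / str(row.angle_path)
        for p in (mag_path, ang_path):
            if not p.exists():
                raise ManifestError(f"{path}: referenced file does not exist: {p}")
        entries.append(
            ManifestEntry(
                map_id=str(row.map_id),
                magnitude_path=mag_path,
                angle_path=ang_path,
                label=parse_label(str(row.label)),
            )
        )
    return CohortManifest(entries=entries, angle_units=angle_units)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest table with paths relative to the manifest location."""
    path = Path(path)
    base = path.parent
    rows = []
    for e in manifest.entries:
        rows.append(
            {
                "map_id": e.map_id,
                "magnitude_path": _relpath(e.magnitude_path, base),
                "angle_path": _relpath(e.angle_path, base),
                "label": e.label.value,
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


def _relpath(target: Path, base: Path) -> str:
    return os.path.relpath(target, base)
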