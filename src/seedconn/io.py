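"""Readers and writers for the standard formats the pipeline touches.

Tractograms travel as TCK files (streamline vertices in world/scanner
millimetres), parcellations as NIfTI-1 integer label volumes, and region
semantics (name, hemisphere, compartment, seed/target/exclusion role) as
plain TSV tables.  Binary parsing is delegated to :mod:`nibabel`; this
module adds the validation contracts the rest of the pipeline relies on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import nibabel.streamlines as nbs
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TckFormatError",
    "TckTruncationError",
    "LabelVolumeError",
    "RegionTableError",
    "Tractogram",
    "LabelVolume",
    "RegionTable",
    "read_tck",
    "write_tck",
    "read_label_volume",
    "write_label_volume",
    "read_region_table",
    "write_region_table",
    "load_reference_densities",
]

HEMISPHERES = frozenset({"left", "right", "midline"})
COMPARTMENTS = frozenset({"anterior", "posterior", "flocculonodular", "nuclear", "none"})
ROLES = frozenset({"seed", "target", "exclusion"})


class FormatError(ValueError):
    """A file violates its format contract."""


class TckFormatError(FormatError):
    """Malformed TCK header or unsupported dialect."""


class TckTruncationError(FormatError):
    """TCK vertex stream ends before the declared streamline count."""

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset


class LabelVolumeError(FormatError):
    """NIfTI volume is not a valid integer label map."""


class RegionTableError(FormatError):
    """Region table violates its schema or semantic invariants."""


def validate_streamline(points: np.ndarray) -> np.ndarray:
    """Check one streamline: >= 2 vertices, finite, no zero-length segments."""
    pts = np.asarray(points, dtype=np.float32)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FormatError(f"streamline must be (N, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise FormatError(f"streamline needs >= 2 vertices, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise FormatError("streamline contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise FormatError("streamline has repeated consecutive vertices")
    return pts


@dataclass
class Tractogram:
    """A set of streamlines (ordered 3D polylines in world millimetres)."""

    streamlines: list[np.ndarray]
    header: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def validate(self) -> "Tractogram":
        self.streamlines = [validate_streamline(s) for s in self.streamlines]
        return self


@dataclass
class LabelVolume:
    """Integer parcellation grid plus its voxel-index -> world-mm affine.

    Index ``(i, j, k)`` maps to the centre of that voxel under ``affine``
    (NIfTI voxel-centre convention); label 0 is background.
    """

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise LabelVolumeError(f"labels must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LabelVolumeError("labels must be an integer array")
        if self.labels.min() < 0:
            raise LabelVolumeError("labels must be non-negative")
        if self.affine.shape != (4, 4):
            raise LabelVolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0:
            raise LabelVolumeError("affine is singular")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's 3x3 block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


class RegionTable:
    """Label semantics: name, hemisphere, compartment, and role per label ID.

    Enforces exactly one seed, at least one target, unique label IDs, and a
    compartment for every target.  Left/right targets are expected to pair
    by name; an unpaired bilateral target is recorded as a warning, not an
    error (real parcellations occasionally drop one hemisphere's ROI).
    """

    def __init__(self, df: pd.DataFrame):
        required = ["label", "name", "hemisphere", "compartment", "role"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise RegionTableError(f"region table missing columns: {missing}")
        df = df[required].copy()
        df["label"] = df["label"].astype(int)
        for col in ("name", "hemisphere", "compartment", "role"):
            df[col] = df[col].astype(str).str.strip()

        if df["label"].duplicated().any():
            dupes = sorted(df.loc[df["label"].duplicated(), "label"])
            raise RegionTableError(f"duplicate label IDs: {dupes}")
        if (df["label"] <= 0).any():
            raise RegionTableError("label IDs must be positive (0 is background)")
        for col, allowed in (
            ("hemisphere", HEMISPHERES),
            ("compartment", COMPARTMENTS),
            ("role", ROLES),
        ):
            bad = sorted(set(df[col]) - allowed)
            if bad:
                raise RegionTableError(f"unknown {col} token(s): {bad}")

        n_seed = int((df["role"] == "seed").sum())
        if n_seed != 1:
            raise RegionTableError(f"expected exactly one seed row, found {n_seed}")
        targets = df[df["role"] == "target"]
        if len(targets) == 0:
            raise RegionTableError("region table has no target rows")
        untyped = targets[targets["compartment"] == "none"]
        if len(untyped):
            raise RegionTableError(
                f"targets must have a compartment: {sorted(untyped['name'])}"
            )

        self.df = df.set_index("label", drop=False)
        self.warnings: list[str] = []
        left = set(targets.loc[targets["hemisphere"] == "left", "name"])
        right = set(targets.loc[targets["hemisphere"] == "right", "name"])
        for name in sorted(left - right):
            self.warnings.append(f"left target '{name}' has no right counterpart")
        for name in sorted(right - left):
            self.warnings.append(f"right target '{name}' has no left counterpart")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def seed_label(self) -> int:
        return int(self.df.loc[self.df["role"] == "seed", "label"].iloc[0])

    @property
    def target_labels(self) -> np.ndarray:
        return self.df.loc[self.df["role"] == "target", "label"].to_numpy()

    @property
    def exclusion_labels(self) -> np.ndarray:
        return self.df.loc[self.df["role"] == "exclusion", "label"].to_numpy()

    def target_name(self, label: int) -> str:
        row = self.df.loc[label]
        if row["hemisphere"] == "midline":
            return str(row["name"])
        return f"{row['hemisphere'].capitalize()} {row['name']}"

    def bilateral_pairs(self) -> list[tuple[str, int, int]]:
        """(base name, left label, right label) for every paired target."""
        targets = self.df[self.df["role"] == "target"]
        left = targets[targets["hemisphere"] == "left"].set_index("name")["label"]
        right = targets[targets["hemisphere"] == "right"].set_index("name")["label"]
        names = sorted(set(left.index) & set(right.index))
        return [(n, int(left[n]), int(right[n])) for n in names]

    def midline_target_labels(self) -> np.ndarray:
        targets = self.df[self.df["role"] == "target"]
        return targets.loc[targets["hemisphere"] == "midline", "label"].to_numpy()

    def compartment_of(self, label: int) -> str:
        return str(self.df.loc[label, "compartment"])


# ---------------------------------------------------------------------------
# TCK tractograms


def read_tck(path: str | Path) -> Tractogram:
    """Read an MRtrix TCK tractogram.

    Raises
    ------
    TckFormatError
        Missing magic line or malformed/unsupported header.
    TckTruncationError
        Vertex stream ends before the declared streamline count (the byte
        offset of the break, when known, is attached to the exception).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline()
    if not magic.startswith(b"mrtrix tracks"):
        raise TckFormatError(f"{path}: not a TCK file (bad magic line)")
    try:
        tck = nbs.load(str(path), lazy_load=False)
    except nib.filebasedimages.ImageFileError as exc:
        raise TckFormatError(f"{path}: {exc}") from exc
    except Exception as exc:
        name = type(exc).__name__
        if "Header" in name:
            raise TckFormatError(f"{path}: malformed header: {exc}") from exc
        if "Data" in name:
            raise TckTruncationError(
                f"{path}: truncated vertex stream ({exc})",
                byte_offset=path.stat().st_size,
            ) from exc
        raise

    streamlines = [np.asarray(s, dtype=np.float32) for s in tck.streamlines]
    header = {
        str(k): str(v)
        for k, v in tck.header.items()
        if isinstance(v, (str, bytes, int, float))
    }
    declared = header.get("count")
    if declared is not None and int(declared) != len(streamlines):
        raise TckTruncationError(
            f"{path}: header declares {int(declared)} streamlines but the file "
            f"holds {len(streamlines)}",
            byte_offset=path.stat().st_size,
        )
    return Tractogram(streamlines=streamlines, header=header)


def write_tck(tractogram: Tractogram | list[np.ndarray], path: str | Path) -> None:
    """Write a TCK file (Float32LE vertices, standards-conformant header)."""
    if isinstance(tractogram, Tractogram):
        streamlines = tractogram.streamlines
        extra = dict(tractogram.header)
    else:
        streamlines = list(tractogram)
        extra = {}
    streamlines = [validate_streamline(s) for s in streamlines]
    nb_tractogram = nbs.Tractogram(streamlines, affine_to_rasmm=np.eye(4))
    header = {
        k: v
        for k, v in extra.items()
        if k not in {"count", "datatype", "file", "magic_number", "endianness",
                     "nb_streamlines", "voxel_to_rasmm", "_dtype", "_offset_data"}
    }
    tck = nbs.TckFile(nb_tractogram, header=header)
    tck.save(str(path))


# ---------------------------------------------------------------------------
# NIfTI label volumes


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1 integer label volume.

    Values are checked for exact integerness (tolerance 1e-6 after any
    scl_slope/scl_inter application): parcellation labels are categorical
    and a fractional value means the file is not a label map.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise LabelVolumeError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > 1e-6:
            raise LabelVolumeError(f"{path}: voxel values are not integers")
        data = rounded
    labels = data.astype(np.int32)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) <= 0:
        raise LabelVolumeError(f"{path}: affine is singular")
    if labels.min() < 0:
        raise LabelVolumeError(f"{path}: negative label values")
    return LabelVolume(labels=labels, affine=affine)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int32), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Region tables


def read_region_table(path: str | Path) -> RegionTable:
    """Read a TSV region table (columns: label, name, hemisphere, compartment, role)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise RegionTableError(f"{path}: cannot parse TSV: {exc}") from exc
    return RegionTable(df)


def write_region_table(table: RegionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged reference data


def load_reference_densities() -> pd.DataFrame:
    """Load the packaged reference connectivity-density table.

    The table is the group summary of PAG-to-cerebellum normalized
    connectivity density (mean delta_norm in percent, between-subject SD,
    and COV) over the 34 cerebellar lobular, vermal and nuclear pathways of
    a published 100-subject in-vivo tractography cohort, with each pathway's
    hemisphere and Stoodley-Schmahmann compartment.  It serves as a
    realistic end-point for the density, thresholding and compartment
    aggregation stages.
    """
    ref = importlib.resources.files("seedconn.data").joinpath(
        "pag_cerebellum_reference.tsv"
    )
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    df["mean_delta_norm"] = df["mean_delta_norm"].astype(float)
    df["sd"] = df["sd"].astype(float)
    df["cov"] = df["cov"].astype(float)
    return df
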