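"""Shared fixtures and the independent brute-force assignment oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedconn.io import LabelVolume, RegionTable, load_reference_densities
from seedconn.phantom import PhantomConfig, make_phantom_labels


@pytest.fixture(scope="session")
def reference() -> pd.DataFrame:
    return load_reference_densities()


@pytest.fixture(scope="session")
def phantom_geometry():
    cfg = PhantomConfig()
    volume, table = make_phantom_labels(cfg)
    return cfg, volume, table


def region_table_df(
    n_targets: int = 2, seed_label: int = 1, exclusion: bool = True
) -> pd.DataFrame:
    """Minimal region-table frame: 1 seed, n bilateral-ish targets, 1 exclusion."""
    rows = [
        {"label": seed_label, "name": "seed", "hemisphere": "midline",
         "compartment": "none", "role": "seed"}
    ]
    for i in range(n_targets):
        rows.append({"label": seed_label + 1 + i, "name": f"T{i}",
                     "hemisphere": "midline", "compartment": "posterior",
                     "role": "target"})
    if exclusion:
        rows.append({"label": seed_label + 1 + n_targets, "name": "avoid",
                     "hemisphere": "midline", "compartment": "none",
                     "role": "exclusion"})
    return pd.DataFrame(rows)


def simple_scene():
    """20^3 grid: seed(1) at low x, targets 2 and 3 at high x, exclusion 4
    between seed and target 3."""
    volume = LabelVolume(np.zeros((20, 20, 20), dtype=np.int32), np.eye(4))
    volume.labels[1:4, 8:13, 8:13] = 1
    volume.labels[16:19, 3:8, 8:13] = 2
    volume.labels[16:19, 13:18, 8:13] = 3
    volume.labels[9:12, 14:17, 8:13] = 4
    table = RegionTable(region_table_df(n_targets=2))
    return volume, table


def hand_placed_streamlines(rng, n=50):
    """Structured streamlines (index space) with clear ROI penetration or
    clearance for the :func:`simple_scene` geometry.

    Waypoints sit at voxel centres well inside a region or in open
    background, so fine- and coarse-sampled traversal sets coincide and
    oracle comparisons are exact.
    """
    seed_pts = [(2.0, 10.0, 10.0), (2.0, 9.0, 11.0), (3.0, 11.0, 9.0)]
    t2_pts = [(17.0, 5.0, 10.0), (17.0, 6.0, 9.0)]
    t3_pts = [(17.0, 15.0, 10.0), (17.0, 14.0, 11.0)]
    ex_pts = [(10.0, 15.0, 10.0)]
    bg_pts = [(10.0, 2.0, 3.0), (5.0, 18.0, 3.0), (14.0, 10.0, 2.0)]

    def pick(pts):
        return np.asarray(pts[rng.integers(len(pts))], dtype=float)

    kinds = ["s2", "s3", "s23", "sx3", "sbg", "bg"]
    streamlines = []
    for _ in range(n):
        kind = kinds[rng.integers(len(kinds))]
        if kind == "s2":
            way = [pick(seed_pts), pick(t2_pts)]
        elif kind == "s3":
            way = [pick(seed_pts), pick(t3_pts)]
        elif kind == "s23":
            way = [pick(seed_pts), pick(t2_pts), pick(t3_pts)]
        elif kind == "sx3":
            way = [pick(seed_pts), pick(ex_pts), pick(t3_pts)]
        elif kind == "sbg":
            way = [pick(seed_pts), pick(bg_pts)]
        else:
            way = [pick(bg_pts), pick(bg_pts) + rng.normal(0, 0.2, 3)]
        streamlines.append(np.asarray(way))
    return streamlines


ORACLE_AFFINES = {
    "identity": np.eye(4),
    "anisotropic": np.diag([1.5, 1.0, 2.0, 1.0]),
}
_theta = 0.4
_rot = np.eye(4)
_rot[:3, :3] = (
    np.array(
        [[np.cos(_theta), -np.sin(_theta), 0.0],
         [np.sin(_theta), np.cos(_theta), 0.0],
         [0.0, 0.0, 1.0]]
    )
    @ np.diag([1.2, 0.9, 1.1])
)
_rot[:3, 3] = [5.0, -3.0, 2.0]
ORACLE_AFFINES["rotated"] = _rot


# ---------------------------------------------------------------------------
# Brute-force oracle: naive per-streamline fine sampling, independent of the
# vectorized implementation under test.


def oracle_streamline_labels(
    streamline: np.ndarray, volume: LabelVolume, rel_spacing: float = 0.01
) -> set[int]:
    inv = np.linalg.inv(volume.affine)
    edges = np.linalg.norm(volume.affine[:3, :3], axis=0)
    spacing = rel_spacing * float(edges.min())
    shape = np.asarray(volume.labels.shape)
    found: set[int] = set()
    s = np.asarray(streamline, dtype=float)
    for a, b in zip(s[:-1], s[1:]):
        length = np.linalg.norm(b - a)
        k = max(2, int(np.ceil(length / spacing)) + 1)
        pts = a + np.linspace(0.0, 1.0, k)[:, None] * (b - a)
        cont = pts @ inv[:3, :3].T + inv[:3, 3]
        idx = np.trunc(cont + np.copysign(0.5, cont)).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        labs = volume.labels[idx[inb, 0], idx[inb, 1], idx[inb, 2]]
        found.update(int(v) for v in labs[labs != 0])
    return found


def oracle_assign_one(
    streamline: np.ndarray, volume: LabelVolume, table: RegionTable
) -> tuple[str, int]:
    s = np.asarray(streamline)
    if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2 or not np.isfinite(s).all():
        return "invalid", -1
    labs = oracle_streamline_labels(s, volume)
    if labs & set(int(e) for e in table.exclusion_labels):
        return "touches_exclusion", -1
    targets = labs & set(int(t) for t in table.target_labels)
    if len(targets) >= 2:
        return "multiple_targets", -1
    if len(targets) == 0:
        return "no_target", -1
    return "assigned", targets.pop()
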