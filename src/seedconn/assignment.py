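"""Exclusive streamline-to-target assignment.

Each streamline is assigned to at most one target region using the
inclusion/exclusion filtering semantics of ROI-based tract selection:

* a streamline that traverses any exclusion region (region of avoidance)
  is discarded outright (``touches_exclusion``);
* a streamline that traverses two or more target regions belongs to none
  of them — selecting with one target as inclusion mask and all others as
  exclusion masks removes it everywhere (``multiple_targets``);
* a streamline that traverses no target region is discarded
  (``no_target``);
* otherwise it is assigned to the unique target it traverses.

Membership is traversal-based: the polyline is densified so that no voxel
can be skipped between consecutive vertices (sample spacing at most half
the smallest voxel edge), and every sample is mapped to its nearest voxel
through the inverse affine.  Labels are categorical, so lookup is
nearest-voxel, never interpolated.  Seed traversal is ignored by default;
``require_seed=True`` additionally discards streamlines that never touch
the seed region (``no_seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelVolume, RegionTable, Tractogram

__all__ = [
    "OUT_OF_BOUNDS",
    "DISCARD_REASONS",
    "AssignmentResult",
    "world_to_voxel",
    "voxel_indices",
    "streamline_labels",
    "assign",
]

#: Sentinel returned by :func:`world_to_voxel` for points outside the grid.
OUT_OF_BOUNDS = "out_of_bounds"

DISCARD_REASONS = ("touches_exclusion", "multiple_targets", "no_target", "no_seed", "invalid")

_ROLE_NONE, _ROLE_TARGET, _ROLE_EXCLUSION, _ROLE_SEED = 0, 1, 2, 3


def voxel_indices(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points (N, 3) to nearest voxel indices (N, 3).

    Applies the inverse affine (voxel-centre convention) and rounds each
    continuous index half-away-from-zero.  No bounds checking.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    cont = points @ inv[:3, :3].T + inv[:3, 3]
    return np.trunc(cont + np.copysign(0.5, cont)).astype(np.int64)


def world_to_voxel(
    point: np.ndarray, affine: np.ndarray, shape: tuple[int, int, int] | None = None
):
    """Nearest voxel index of one world-mm point.

    Returns a 3-tuple of ints, or :data:`OUT_OF_BOUNDS` when ``shape`` is
    given and the index falls outside the grid.
    """
    idx = voxel_indices(np.asarray(point, dtype=float).reshape(1, 3), affine)[0]
    if shape is not None:
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            return OUT_OF_BOUNDS
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def _concat(streamlines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if not streamlines:
        return np.empty((0, 3)), np.empty(0, dtype=np.int64)
    lengths = np.array([len(s) for s in streamlines], dtype=np.int64)
    pts = np.concatenate([np.asarray(s, dtype=float) for s in streamlines])
    return pts, lengths


def _densified_samples(
    pts: np.ndarray, lengths: np.ndarray, max_spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every polyline so consecutive samples are <= max_spacing apart.

    Operates on the concatenated vertex array; returns ``(samples, owner)``
    where ``owner[i]`` is the streamline index of sample ``i``.  Sample
    order within a streamline is not preserved (only membership matters).
    """
    n_stream = len(lengths)
    owner_vertex = np.repeat(np.arange(n_stream), lengths)
    if len(pts) == 0:
        return pts, owner_vertex
    ends = np.cumsum(lengths)
    seg_mask = np.ones(len(pts), dtype=bool)
    seg_mask[ends - 1] = False
    i0 = np.nonzero(seg_mask)[0]
    if len(i0) == 0:
        return pts, owner_vertex
    vec = pts[i0 + 1] - pts[i0]
    seg_len = np.linalg.norm(vec, axis=1)
    k = np.maximum(1, np.ceil(seg_len / max_spacing).astype(np.int64))
    if np.all(k == 1):
        return pts, owner_vertex

    total = int(k.sum())
    seg_idx = np.repeat(np.arange(len(i0)), k)
    offset = np.concatenate([[0], np.cumsum(k)[:-1]])
    within = np.arange(total) - np.repeat(offset, k)
    t = within / k[seg_idx]
    samples = pts[i0][seg_idx] + t[:, None] * vec[seg_idx]
    finals = pts[ends - 1]
    owner_seg = np.repeat(np.arange(n_stream), lengths - 1)
    samples = np.concatenate([samples, finals])
    owner = np.concatenate([owner_seg[seg_idx], np.arange(n_stream)])
    return samples, owner


def _sample_labels(
    samples: np.ndarray, owner: np.ndarray, volume: LabelVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero voxel labels at in-bounds samples, with their owners."""
    if len(samples) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    idx = voxel_indices(samples, volume.affine)
    shape = np.asarray(volume.labels.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    idx, owner = idx[inb], owner[inb]
    lab = volume.labels[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int64)
    nz = lab != 0
    return lab[nz], owner[nz]


def _max_spacing(volume: LabelVolume) -> float:
    edges = np.linalg.norm(volume.affine[:3, :3], axis=0)
    return 0.5 * float(edges.min())


def streamline_labels(
    streamline: np.ndarray, volume: LabelVolume, densify: bool = True
) -> set[int]:
    """Set of nonzero label IDs a streamline traverses.

    The polyline is densified (sample spacing <= half the smallest voxel
    edge) before lookup unless ``densify=False``; out-of-bounds samples
    contribute nothing.
    """
    pts, lengths = _concat([np.asarray(streamline, dtype=float)])
    if densify:
        samples, owner = _densified_samples(pts, lengths, _max_spacing(volume))
    else:
        samples, owner = pts, np.zeros(len(pts), dtype=np.int64)
    lab, _ = _sample_labels(samples, owner, volume)
    return set(int(v) for v in np.unique(lab))


@dataclass
class AssignmentResult:
    """Per-streamline outcomes plus per-target and per-discard counters.

    ``outcomes`` has one row per input streamline (original order):
    ``outcome`` is ``assigned`` or a discard reason, ``label`` the assigned
    target label (-1 when discarded).  The outcomes always partition the
    tractogram: assigned + discarded == total.
    """

    outcomes: pd.DataFrame
    target_counts: pd.Series
    discard_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_streamlines(self) -> int:
        return len(self.outcomes)

    @property
    def n_assigned(self) -> int:
        return int(self.target_counts.sum())

    @property
    def n_discarded(self) -> int:
        return int(sum(self.discard_counts.values()))

    def to_frame(self) -> pd.DataFrame:
        return self.outcomes.copy()


def assign(
    tractogram: Tractogram | list[np.ndarray],
    volume: LabelVolume,
    table: RegionTable,
    require_seed: bool = False,
) -> AssignmentResult:
    """Assign every streamline to a unique target or a discard reason.

    Decision per streamline, in order of precedence: ``invalid`` (fewer
    than 2 vertices or non-finite coordinates), ``no_seed`` (only with
    ``require_seed=True``), ``touches_exclusion``, ``multiple_targets``,
    ``no_target``, else assigned.  Seed traversal never counts toward the
    target tally.
    """
    streamlines = (
        tractogram.streamlines if isinstance(tractogram, Tractogram) else list(tractogram)
    )
    n = len(streamlines)
    outcome = np.full(n, "no_target", dtype=object)
    assigned_label = np.full(n, -1, dtype=np.int64)

    valid = np.ones(n, dtype=bool)
    for i, s in enumerate(streamlines):
        s = np.asarray(s)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2 or not np.isfinite(s).all():
            valid[i] = False
    outcome[~valid] = "invalid"

    valid_idx = np.nonzero(valid)[0]
    if len(valid_idx):
        pts, lengths = _concat([np.asarray(streamlines[i], dtype=float) for i in valid_idx])
        samples, owner = _densified_samples(pts, lengths, _max_spacing(volume))
        lab, owner = _sample_labels(samples, owner, volume)

        max_label = int(volume.labels.max())
        role = np.zeros(max_label + 1, dtype=np.int8)
        for t in table.target_labels:
            if t <= max_label:
                role[t] = _ROLE_TARGET
        for e in table.exclusion_labels:
            if e <= max_label:
                role[e] = _ROLE_EXCLUSION
        if table.seed_label <= max_label:
            role[table.seed_label] = _ROLE_SEED
        sample_role = role[lab]

        n_valid = len(valid_idx)
        excl = np.bincount(owner[sample_role == _ROLE_EXCLUSION], minlength=n_valid) > 0
        seen_seed = np.bincount(owner[sample_role == _ROLE_SEED], minlength=n_valid) > 0

        tmask = sample_role == _ROLE_TARGET
        key = owner[tmask] * np.int64(max_label + 1) + lab[tmask]
        uniq = np.unique(key)
        t_owner = uniq // (max_label + 1)
        t_label = uniq % (max_label + 1)
        n_targets = np.bincount(t_owner, minlength=n_valid)
        single = n_targets == 1
        unique_label = np.zeros(n_valid, dtype=np.int64)
        keep = single[t_owner]
        unique_label[t_owner[keep]] = t_label[keep]

        local_outcome = np.full(n_valid, "assigned", dtype=object)
        local_label = np.where(single, unique_label, -1)
        local_outcome[n_targets == 0] = "no_target"
        local_label[n_targets == 0] = -1
        local_outcome[n_targets >= 2] = "multiple_targets"
        local_outcome[excl] = "touches_exclusion"
        local_label[excl] = -1
        if require_seed:
            miss = ~seen_seed & ~excl
            local_outcome[miss] = "no_seed"
            local_label[miss] = -1
        local_label[local_outcome != "assigned"] = -1

        outcome[valid_idx] = local_outcome
        assigned_label[valid_idx] = local_label

    outcomes = pd.DataFrame(
        {"streamline": np.arange(n), "outcome": outcome, "label": assigned_label}
    )
    target_counts = pd.Series(0, index=pd.Index(table.target_labels, name="label"))
    assigned = assigned_label[assigned_label >= 0]
    if len(assigned):
        vc = pd.Series(assigned).value_counts()
        target_counts.loc[vc.index] = vc.values
    discard_counts = {
        r: int(np.sum(outcome == r)) for r in DISCARD_REASONS if np.sum(outcome == r)
    }
    return AssignmentResult(
        outcomes=outcomes, target_counts=target_counts, discard_counts=discard_counts
    )
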