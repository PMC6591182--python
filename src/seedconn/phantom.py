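"""Synthetic tractography phantom with known ground-truth connectivity.

The phantom emulates the geometry of a seed-to-cerebellum tracking study
on a small voxel grid: one spherical seed ROI on the midline, bilateral
target ROIs mirror-symmetric about the midline plane plus unpaired
midline targets, and one exclusion ROI (region of avoidance) placed
between the seed and a decoy direction.  Per subject, streamline counts
per target are drawn multinomially around ground-truth density weights;
between-subject variability is log-normal and multiplicative (weights
stay positive and the resulting densities are right-skewed, as real
cohort tables are), and an optional left/right multiplicative shift
injects a known lateralization.  A configurable fraction of streamlines
is made deliberately invalid in each of three ways — crossing the
exclusion ROI, traversing two targets, or ending in background — so the
assignment stage's discard logic is exercised with known truth.

Streamlines are straight seed-to-target polylines resampled to a fixed
vertex spacing with per-vertex Gaussian jitter; candidates whose jittered
path does not realize the intended outcome are rejection-resampled.  No
fibre model or tracking algorithm is claimed — the phantom exists to
exercise the membership and counting logic, not to imitate anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import assign
from .density import delta_norm as _delta_norm
from .io import LabelVolume, RegionTable, Tractogram

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "CohortSubject",
    "Cohort",
    "PhantomGeometryError",
    "PhantomGenerationError",
    "default_true_weights",
    "make_phantom_labels",
    "sample_subject_weights",
    "generate_subject_tractogram",
    "generate_cohort",
    "iter_cohort",
    "expected_delta_norm",
    "simulate_profiles",
]

_COMPARTMENT_CYCLE = ("anterior", "posterior", "flocculonodular", "nuclear")
_NOISE_KINDS = ("noise_exclusion", "noise_multitarget", "noise_offtarget")


class PhantomGeometryError(ValueError):
    """ROIs cannot be placed on the requested grid without overlap."""


class PhantomGenerationError(RuntimeError):
    """Streamline construction failed after the bounded retry budget."""


def default_true_weights(n_bilateral: int, n_midline: int) -> np.ndarray:
    """Symmetric ground-truth weights: within-pair equality (asymmetry comes
    only from ``lateralization_shift``), geometric decay across pathways —
    the decade-wide density spread real profiles show."""
    pairs = 12.0 / 2.0 ** np.arange(n_bilateral)
    midline = 10.0 / 1.5 ** np.arange(n_midline)
    return np.concatenate([np.repeat(pairs, 2), midline])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, cohort and noise parameters of the phantom.

    Distances are in voxels unless suffixed ``_mm``.  Target ordering is
    ``[pair0_left, pair0_right, pair1_left, pair1_right, ..., midline...]``.
    """

    grid_shape: tuple[int, int, int] = (49, 49, 49)
    voxel_size: float = 1.0
    n_targets_bilateral: int = 4
    n_targets_midline: int = 2
    roi_radius: float = 3.0
    target_distance: float = 15.0
    bilateral_x_offset: float = 9.0
    exclusion_offset: float = 7.0
    exclusion_radius: float = 2.0
    n_streamlines: int = 20_000
    true_weights: tuple[float, ...] | None = None
    subject_sigma: float = 0.3
    lateralization_shift: float | tuple[float, ...] = 1.0
    noise_exclusion_frac: float = 0.05
    noise_multitarget_frac: float = 0.05
    noise_offtarget_frac: float = 0.05
    step_mm: float = 0.2
    jitter_sd_factor: float = 0.3
    max_retries: int = 100
    seed: int = 0

    @property
    def n_targets(self) -> int:
        return 2 * self.n_targets_bilateral + self.n_targets_midline

    def weights(self) -> np.ndarray:
        if self.true_weights is None:
            return default_true_weights(self.n_targets_bilateral, self.n_targets_midline)
        return np.asarray(self.true_weights, dtype=float)

    def pair_shifts(self) -> np.ndarray:
        s = self.lateralization_shift
        if np.isscalar(s):
            return np.full(self.n_targets_bilateral, float(s))
        s = np.asarray(s, dtype=float)
        if len(s) != self.n_targets_bilateral:
            raise ValueError("lateralization_shift must be scalar or one value per pair")
        return s

    def validate(self) -> "PhantomConfig":
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        w = self.weights()
        if len(w) != self.n_targets:
            raise ValueError(
                f"true_weights has {len(w)} entries, expected {self.n_targets}"
            )
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("true_weights must be non-negative with positive sum")
        fracs = (
            self.noise_exclusion_frac,
            self.noise_multitarget_frac,
            self.noise_offtarget_frac,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("noise fractions must lie in [0, 1] and sum below 1")
        if self.n_targets_bilateral < 0 or self.n_targets_midline < 0 or self.n_targets == 0:
            raise ValueError("need at least one target")
        self.pair_shifts()
        return self


# ---------------------------------------------------------------------------
# Geometry


def _geometry(config: PhantomConfig) -> dict:
    """ROI centres in voxel-index space. Pure function of the config."""
    shape = np.asarray(config.grid_shape, dtype=float)
    c = (shape - 1) / 2.0
    centers = {"seed": c.copy()}
    r_yz = np.sqrt(config.target_distance**2 - config.bilateral_x_offset**2)
    if not np.isfinite(r_yz) or r_yz <= 0:
        raise PhantomGeometryError("bilateral_x_offset must be below target_distance")
    n_p, n_m = config.n_targets_bilateral, config.n_targets_midline
    targets = []
    phis = np.linspace(np.deg2rad(30), np.deg2rad(150), n_p) if n_p else []
    for phi in phis:
        dy, dz = r_yz * np.cos(phi), r_yz * np.sin(phi)
        targets.append(c + [-config.bilateral_x_offset, dy, dz])  # left
        targets.append(c + [config.bilateral_x_offset, dy, dz])  # right
    psis = np.linspace(np.deg2rad(45), np.deg2rad(135), n_m) if n_m else []
    for psi in psis:
        targets.append(
            c + [0.0, config.target_distance * np.cos(psi), config.target_distance * np.sin(psi)]
        )
    centers["targets"] = np.asarray(targets)
    centers["exclusion"] = c + [0.0, 0.0, -config.exclusion_offset]
    # decoy direction for target-missing noise streamlines: -y, clear of
    # every target (all have z >= 0 elevation) and of the exclusion ROI (-z)
    centers["decoy"] = c + [0.0, -config.target_distance, 0.0]
    return centers


def _affine(config: PhantomConfig) -> np.ndarray:
    """Diagonal affine with the world origin at the grid centre."""
    c = (np.asarray(config.grid_shape, dtype=float) - 1) / 2.0
    aff = np.eye(4)
    aff[:3, :3] *= config.voxel_size
    aff[:3, 3] = -c * config.voxel_size
    return aff


def make_phantom_labels(config: PhantomConfig) -> tuple[LabelVolume, RegionTable]:
    """Paint the seed, target and exclusion ROIs and build the region table.

    Spherical ROIs; bilateral targets are mirror-symmetric about the
    midline plane by construction.  Any overlap or out-of-bounds placement
    raises :class:`PhantomGeometryError`.
    """
    config.validate()
    geo = _geometry(config)
    shape = config.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij"), axis=-1
    )

    rois = [("seed", geo["seed"], config.roi_radius)]
    for j, ctr in enumerate(geo["targets"]):
        rois.append((f"target_{j}", ctr, config.roi_radius))
    rois.append(("exclusion", geo["exclusion"], config.exclusion_radius))

    for lab, (name, ctr, radius) in enumerate(rois, start=1):
        if np.any(ctr - radius < 0) or np.any(ctr + radius > np.asarray(shape) - 1):
            raise PhantomGeometryError(f"ROI '{name}' does not fit on the grid")
        mask = np.sum((grid - ctr) ** 2, axis=-1) <= radius**2
        if not mask.any():
            raise PhantomGeometryError(f"ROI '{name}' contains no voxel")
        if np.any(labels[mask] != 0):
            raise PhantomGeometryError(f"ROI '{name}' overlaps another ROI")
        labels[mask] = lab

    volume = LabelVolume(labels=labels, affine=_affine(config))

    rows = [
        {"label": 1, "name": "seed", "hemisphere": "midline", "compartment": "none",
         "role": "seed"}
    ]
    n_p = config.n_targets_bilateral
    for j in range(n_p):
        comp = _COMPARTMENT_CYCLE[j % len(_COMPARTMENT_CYCLE)]
        base = f"Target {chr(ord('A') + j)}"
        rows.append({"label": 2 + 2 * j, "name": base, "hemisphere": "left",
                     "compartment": comp, "role": "target"})
        rows.append({"label": 3 + 2 * j, "name": base, "hemisphere": "right",
                     "compartment": comp, "role": "target"})
    for k in range(config.n_targets_midline):
        comp = _COMPARTMENT_CYCLE[(n_p + k) % len(_COMPARTMENT_CYCLE)]
        rows.append({"label": 2 + 2 * n_p + k, "name": f"Vermis {chr(ord('A') + k)}",
                     "hemisphere": "midline", "compartment": comp, "role": "target"})
    rows.append({"label": 2 + config.n_targets, "name": "avoidance",
                 "hemisphere": "midline", "compartment": "none", "role": "exclusion"})
    table = RegionTable(pd.DataFrame(rows))
    return volume, table


# ---------------------------------------------------------------------------
# Per-subject sampling


def sample_subject_weights(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """One subject's realized weights: ``true_weight * exp(eps)``,
    ``eps ~ N(0, subject_sigma^2)`` i.i.d. per target, with the left member
    of each pair further multiplied by its lateralization shift."""
    config.validate()
    w = config.weights().copy()
    eps = rng.normal(0.0, config.subject_sigma, size=len(w))
    w = w * np.exp(eps)
    shifts = config.pair_shifts()
    for j in range(config.n_targets_bilateral):
        w[2 * j] *= shifts[j]  # left member
    return w


def _resample_polyline(waypoints: list[np.ndarray], step: float, n_streams: int):
    """Straight polylines through per-streamline waypoint columns.

    ``waypoints`` is a list of (n_streams, 3) arrays (>= 2 entries); each
    consecutive pair forms a segment resampled at spacing <= ``step``.
    Returns (concatenated vertices, per-streamline vertex counts).
    """
    pieces_pts: list[np.ndarray] = []
    pieces_owner: list[np.ndarray] = []
    for s, (P0, P1) in enumerate(zip(waypoints[:-1], waypoints[1:])):
        vec = P1 - P0
        L = np.linalg.norm(vec, axis=1)
        k = np.maximum(1, np.ceil(L / step).astype(np.int64))
        total = int(k.sum())
        idx = np.repeat(np.arange(n_streams), k)
        offset = np.concatenate([[0], np.cumsum(k)[:-1]])
        within = np.arange(total) - np.repeat(offset, k)
        t = within / k[idx]
        pieces_pts.append(P0[idx] + t[:, None] * vec[idx])
        pieces_owner.append(idx)
    pieces_pts.append(waypoints[-1])  # closing vertex of each streamline
    pieces_owner.append(np.arange(n_streams))
    pts = np.concatenate(pieces_pts)
    owner = np.concatenate(pieces_owner)
    order = np.argsort(owner, kind="stable")  # samples are ordered within a segment
    pts, owner = pts[order], owner[order]
    counts = np.bincount(owner, minlength=n_streams)
    return pts, counts


def _voxel_centers_world(volume: LabelVolume, label: int, margin: float = 0.0) -> np.ndarray:
    """World coordinates of voxel centres of ``label``; with ``margin`` > 0,
    only voxels at least that many voxels inside the ROI's bounding sphere."""
    idx = np.argwhere(volume.labels == label).astype(float)
    if margin > 0 and len(idx):
        ctr = idx.mean(axis=0)
        d = np.linalg.norm(idx - ctr, axis=1)
        keep = d <= max(d.max() - margin, 0.0)
        if keep.any():
            idx = idx[keep]
    return idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]


@dataclass
class GroundTruth:
    """Intended outcome of every generated streamline.

    ``intended`` has one row per streamline (final file order): ``kind``
    is ``target`` or a noise tag, ``label`` the intended target label
    (-1 for noise).  ``intended_counts`` maps target labels and noise tags
    to counts and always sums to ``n_streamlines``.
    """

    weights: np.ndarray
    intended: pd.DataFrame
    intended_counts: dict = field(default_factory=dict)

    @property
    def n_streamlines(self) -> int:
        return len(self.intended)


def generate_subject_tractogram(
    volume: LabelVolume,
    table: RegionTable,
    weights: np.ndarray,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[Tractogram, GroundTruth]:
    """Generate one subject's tractogram with known per-streamline intent.

    Valid streamlines run from a uniformly chosen seed voxel centre into
    the interior of exactly one target; noise streamlines are constructed
    to cross the exclusion ROI, traverse two targets, or end in
    background.  Jittered candidates that fail to realize their intended
    outcome (checked by running the assignment stage itself) are
    regenerated, up to ``max_retries`` rounds.
    """
    config.validate()
    weights = np.asarray(weights, dtype=float)
    if len(weights) != config.n_targets:
        raise ValueError("weights length must equal the number of targets")
    n = config.n_streamlines
    n_a = int(round(config.noise_exclusion_frac * n))
    n_b = int(round(config.noise_multitarget_frac * n))
    n_c = int(round(config.noise_offtarget_frac * n))
    if config.n_targets < 2:
        n_b = 0
    n_valid = n - n_a - n_b - n_c
    if n_valid < 0:
        raise ValueError("noise fractions leave no valid streamlines")

    target_labels = table.target_labels
    intended_counts = rng.multinomial(n_valid, weights / weights.sum())

    seed_pts = _voxel_centers_world(volume, table.seed_label)
    target_pts = {
        int(lb): _voxel_centers_world(volume, int(lb), margin=1.0) for lb in target_labels
    }
    geo = _geometry(config)
    A = volume.affine
    excl_world = geo["exclusion"] @ A[:3, :3].T + A[:3, 3]
    decoy_world = geo["decoy"] @ A[:3, :3].T + A[:3, 3]

    # per-streamline intent, generation order: valid (grouped by target), a, b, c
    kind = np.array(
        ["target"] * n_valid
        + ["noise_exclusion"] * n_a
        + ["noise_multitarget"] * n_b
        + ["noise_offtarget"] * n_c,
        dtype=object,
    )
    label = np.concatenate(
        [
            np.repeat(target_labels, intended_counts),
            np.full(n_a + n_b + n_c, -1, dtype=np.int64),
        ]
    )

    jitter_sd = config.jitter_sd_factor * config.voxel_size

    def build(indices: np.ndarray) -> list[np.ndarray]:
        """Build jittered candidate polylines for the given streamline rows."""
        m = len(indices)
        k_rows = kind[indices]
        starts = seed_pts[rng.integers(0, len(seed_pts), size=m)]
        mid = np.empty((m, 3))
        end = np.empty((m, 3))
        use_mid = np.zeros(m, dtype=bool)

        t_rows = np.nonzero(k_rows == "target")[0]
        for lb in np.unique(label[indices[t_rows]]) if len(t_rows) else []:
            rows = t_rows[label[indices[t_rows]] == lb]
            pts = target_pts[int(lb)]
            end[rows] = pts[rng.integers(0, len(pts), size=len(rows))]

        a_rows = np.nonzero(k_rows == "noise_exclusion")[0]
        if len(a_rows):
            mid[a_rows] = excl_world + rng.normal(0, 0.3, size=(len(a_rows), 3))
            end[a_rows] = mid[a_rows] + (mid[a_rows] - starts[a_rows]) * 0.8
            use_mid[a_rows] = True

        b_rows = np.nonzero(k_rows == "noise_multitarget")[0]
        for row in b_rows:
            a, b = rng.choice(len(target_labels), size=2, replace=False)
            pa = target_pts[int(target_labels[a])]
            pb = target_pts[int(target_labels[b])]
            mid[row] = pa[rng.integers(0, len(pa))]
            end[row] = pb[rng.integers(0, len(pb))]
            use_mid[row] = True

        c_rows = np.nonzero(k_rows == "noise_offtarget")[0]
        if len(c_rows):
            end[c_rows] = decoy_world + rng.normal(
                0, config.voxel_size, size=(len(c_rows), 3)
            )
        # straight-through mid-point for single-segment paths keeps the
        # batched two-segment resampler uniform
        mid[~use_mid] = (starts[~use_mid] + end[~use_mid]) / 2.0
        pts, counts = _resample_polyline([starts, mid, end], config.step_mm, m)
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
        return [s.astype(np.float32) for s in np.split(pts, np.cumsum(counts)[:-1])]

    def realized_ok(streamlines: list[np.ndarray], indices: np.ndarray) -> np.ndarray:
        result = assign(streamlines, volume, table)
        got_outcome = result.outcomes["outcome"].to_numpy()
        got_label = result.outcomes["label"].to_numpy()
        k_rows = kind[indices]
        ok = np.zeros(len(indices), dtype=bool)
        t = k_rows == "target"
        ok[t] = (got_outcome[t] == "assigned") & (got_label[t] == label[indices[t]])
        ok[k_rows == "noise_exclusion"] = (
            got_outcome[k_rows == "noise_exclusion"] == "touches_exclusion"
        )
        ok[k_rows == "noise_multitarget"] = (
            got_outcome[k_rows == "noise_multitarget"] == "multiple_targets"
        )
        ok[k_rows == "noise_offtarget"] = (
            got_outcome[k_rows == "noise_offtarget"] == "no_target"
        )
        return ok

    streamlines: list[np.ndarray | None] = [None] * n
    pending = np.arange(n)
    for _ in range(config.max_retries + 1):
        if len(pending) == 0:
            break
        cand = build(pending)
        ok = realized_ok(cand, pending)
        for row in np.nonzero(ok)[0]:
            streamlines[pending[row]] = cand[row]
        pending = pending[~ok]
    if len(pending):
        raise PhantomGenerationError(
            f"{len(pending)} streamlines failed to realize their intent after "
            f"{config.max_retries} retries"
        )

    perm = rng.permutation(n)
    streamlines = [streamlines[i] for i in perm]
    intended = pd.DataFrame({"kind": kind[perm], "label": label[perm]})
    counts: dict = {int(lb): int(c) for lb, c in zip(target_labels, intended_counts)}
    counts.update({"noise_exclusion": n_a, "noise_multitarget": n_b, "noise_offtarget": n_c})
    header = {"phantom": "seedconn", "n_streamlines": str(n)}
    truth = GroundTruth(weights=weights, intended=intended, intended_counts=counts)
    return Tractogram(streamlines=streamlines, header=header), truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSubject:
    subject_id: str
    tractogram: Tractogram
    ground_truth: GroundTruth


@dataclass
class Cohort:
    volume: LabelVolume
    table: RegionTable
    subjects: list[CohortSubject]


def _subject_rng(seed: int, k: int) -> np.random.Generator:
    """Deterministic child generator for subject k (platform-stable)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


def iter_cohort(config: PhantomConfig, n_subjects: int):
    """Yield ``(volume, table, CohortSubject)`` per subject, lazily.

    Deterministic given ``config.seed``: subject ``k`` draws from a child
    seed sequence spawned as ``(seed, k)``, so cohorts are reproducible
    and subjects are independent of cohort size.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config.validate()
    volume, table = make_phantom_labels(config)
    for k in range(n_subjects):
        rng = _subject_rng(config.seed, k)
        weights = sample_subject_weights(config, rng)
        tractogram, truth = generate_subject_tractogram(volume, table, weights, config, rng)
        yield volume, table, CohortSubject(f"sub-{k:03d}", tractogram, truth)


def generate_cohort(config: PhantomConfig, n_subjects: int) -> Cohort:
    """Materialize a full cohort (shared geometry, per-subject tractograms)."""
    subjects = []
    volume = table = None
    for volume, table, subject in iter_cohort(config, n_subjects):
        subjects.append(subject)
    return Cohort(volume=volume, table=table, subjects=subjects)


# ---------------------------------------------------------------------------
# Ground-truth expectations and fast profile simulation


def expected_delta_norm(
    config: PhantomConfig, volume: LabelVolume, table: RegionTable
) -> pd.Series:
    """Volume-corrected normalization of the ground-truth weights: the
    group-level delta_norm the phantom converges to (in percent)."""
    from .density import region_volumes

    w = pd.Series(config.weights(), index=pd.Index(table.target_labels, name="label"))
    vols = region_volumes(volume)
    seed_vol = float(vols.loc[table.seed_label])
    return _delta_norm(w, vols.reindex(w.index), seed_vol)


def simulate_profiles(
    config: PhantomConfig,
    n_subjects: int,
    rng: np.random.Generator,
    target_volumes: pd.Series | None = None,
    seed_volume: float | None = None,
) -> np.ndarray:
    """Simulate per-subject delta_norm profiles from the weight model alone.

    Shortcut for statistical studies of the group-level stages: draws each
    subject's weights and multinomial streamline counts exactly as the full
    phantom does, but skips polyline rasterization.  Returns an
    ``(n_subjects, n_targets)`` array of delta_norm percentages (plain
    delta when no volumes are given — equal-volume geometry).
    """
    config.validate()
    k = config.n_targets
    profiles = np.empty((n_subjects, k))
    index = pd.RangeIndex(k)
    if target_volumes is not None:
        target_volumes = pd.Series(np.asarray(target_volumes, dtype=float), index=index)
    for s in range(n_subjects):
        w = sample_subject_weights(config, rng)
        counts = rng.multinomial(config.n_streamlines, w / w.sum())
        nos = pd.Series(counts, index=index, dtype=float)
        if target_volumes is None:
            profiles[s] = 100.0 * counts / counts.sum()
        else:
            profiles[s] = _delta_norm(nos, target_volumes, seed_volume).to_numpy()
    return profiles
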