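"""Connectivity density profiles, group summaries, and compartment sums.

For one subject the profile over target regions is:

* ``NOS``    — number of streamlines assigned to each target;
* ``delta``  — each target's share of the total assigned NOS, in percent;
* ``delta_norm`` — volume-normalized density: each NOS is first scaled by
  the mean volume of the two ROIs forming the pathway,
  ``w_i = NOS_i / ((V_seed + V_i) / 2)``, and the scaled weights are
  renormalized to percent.  This removes the bias by which larger ROIs
  accumulate more streamlines, and is invariant under a global rescaling
  of all volumes (so the volume unit is immaterial).

Across subjects the group summary carries the mean and sample SD (n - 1)
of ``delta_norm`` per target, the coefficient of variation COV = SD/mean
used as a reliability screen, and a retention flag from the density
threshold (mean ``delta_norm`` > 1 % by default).  Targets can finally be
aggregated into the four Stoodley–Schmahmann cerebellar compartments
(anterior, posterior, flocculonodular, nuclear); aggregation is a plain
sum, so it commutes with averaging over subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import AssignmentResult
from .io import LabelVolume, RegionTable

__all__ = [
    "UndefinedProfileError",
    "SubjectProfile",
    "GroupSummary",
    "count_nos",
    "region_volumes",
    "delta",
    "delta_norm",
    "subject_profile",
    "summarize_group",
    "aggregate_compartments",
    "round_half_away",
]

COMPARTMENT_ORDER = ("anterior", "posterior", "flocculonodular", "nuclear")


class UndefinedProfileError(ValueError):
    """No streamline was assigned to any target: the profile is undefined."""


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero (the convention of the reference tables)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.trunc(x * factor + np.copysign(0.5, x)) / factor
    return float(out) if out.ndim == 0 else out


def count_nos(assignment: AssignmentResult, table: RegionTable) -> pd.Series:
    """Per-target assigned streamline counts (0 for unconnected targets)."""
    counts = assignment.target_counts.reindex(table.target_labels, fill_value=0)
    counts.index.name = "label"
    return counts.astype(int)


def region_volumes(volume: LabelVolume) -> pd.Series:
    """Volume in mm^3 of every nonzero label: voxel count x voxel volume."""
    labels, counts = np.unique(volume.labels, return_counts=True)
    nz = labels != 0
    return pd.Series(
        counts[nz] * volume.voxel_volume,
        index=pd.Index(labels[nz], name="label"),
        name="volume_mm3",
    )


def volume_of(volumes: pd.Series, label: int) -> float:
    """Volume of one label; 0 mm^3 (with a warning) when absent from the grid."""
    if label not in volumes.index:
        warnings.warn(f"label {label} absent from the parcellation; volume 0 mm^3")
        return 0.0
    return float(volumes.loc[label])


def delta(nos: pd.Series) -> pd.Series:
    """Connectivity density: percent contribution of each target to total NOS."""
    total = float(np.asarray(nos).sum())
    if total <= 0:
        raise UndefinedProfileError("total NOS is 0; delta is undefined")
    return 100.0 * nos / total


def delta_norm(nos: pd.Series, volumes: pd.Series, seed_volume: float) -> pd.Series:
    """Volume-normalized connectivity density, in percent.

    Each pathway's NOS is scaled by the mean volume of its two ROIs
    (seed and target) and the scaled weights renormalized to sum to 100.
    """
    nos = pd.Series(nos).astype(float)
    if nos.sum() <= 0:
        raise UndefinedProfileError("total NOS is 0; delta_norm is undefined")
    if seed_volume <= 0:
        raise ValueError("seed volume must be positive")
    vols = pd.Series(volumes).reindex(nos.index).astype(float)
    bad = nos[(nos > 0) & ~(vols > 0)]
    if len(bad):
        raise ValueError(
            f"targets with streamlines but zero/unknown volume: {list(bad.index)}"
        )
    mean_vol = (seed_volume + vols) / 2.0
    w = nos.where(nos == 0, nos / mean_vol).fillna(0.0)
    return 100.0 * w / w.sum()


@dataclass
class SubjectProfile:
    """One subject's per-target connectivity profile.

    ``table`` columns: ``name``, ``nos``, ``delta``, ``delta_norm``,
    ``volume_mm3``, indexed by target label.
    """

    table: pd.DataFrame
    seed_volume: float
    subject_id: str = ""

    @property
    def delta_norm(self) -> pd.Series:
        return self.table["delta_norm"]


def subject_profile(
    assignment: AssignmentResult,
    volume: LabelVolume,
    table: RegionTable,
    subject_id: str = "",
) -> SubjectProfile:
    """Compute NOS, delta and delta_norm for one subject."""
    nos = count_nos(assignment, table)
    vols = region_volumes(volume)
    seed_volume = volume_of(vols, table.seed_label)
    target_vols = pd.Series(
        [volume_of(vols, int(lb)) for lb in table.target_labels],
        index=nos.index,
        dtype=float,
    )
    prof = pd.DataFrame(
        {
            "name": [table.target_name(int(lb)) for lb in nos.index],
            "nos": nos,
            "delta": delta(nos),
            "delta_norm": delta_norm(nos, target_vols, seed_volume),
            "volume_mm3": target_vols,
        }
    )
    return SubjectProfile(table=prof, seed_volume=seed_volume, subject_id=subject_id)


@dataclass
class GroupSummary:
    """Across-subject summary per target: mean delta_norm, SD, COV, retention.

    ``table`` columns: ``name``, ``mean_delta_norm``, ``sd``, ``cov``,
    ``retained``; SD is the sample SD (n - 1), COV = SD / mean (0 when mean
    and SD are both 0), and ``retained`` flags group means above the density
    threshold.  With a single subject SD and COV are NaN markers.
    """

    table: pd.DataFrame
    threshold: float
    n_subjects: int

    @property
    def retained_names(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "name"])


def _stack_delta_norm(profiles: list[SubjectProfile]) -> pd.DataFrame:
    mats = []
    ref_index = profiles[0].table.index
    for p in profiles:
        if not p.table.index.equals(ref_index):
            raise ValueError("profiles have inconsistent target sets")
        mats.append(p.table["delta_norm"].to_numpy())
    return pd.DataFrame(np.vstack(mats), columns=ref_index)


def summarize_group(
    profiles: list[SubjectProfile], threshold: float = 1.0
) -> GroupSummary:
    """Mean/SD/COV of delta_norm across subjects, plus threshold retention."""
    if len(profiles) == 0:
        raise ValueError("no profiles to summarize")
    mat = _stack_delta_norm(profiles)
    mean = mat.mean(axis=0)
    if len(profiles) >= 2:
        sd = mat.std(axis=0, ddof=1)
        cov = pd.Series(
            np.where(mean > 0, sd / mean.replace(0, np.nan), np.where(sd == 0, 0.0, np.nan)),
            index=mean.index,
        )
    else:
        sd = pd.Series(np.nan, index=mean.index)
        cov = pd.Series(np.nan, index=mean.index)
    out = pd.DataFrame(
        {
            "name": profiles[0].table["name"],
            "mean_delta_norm": mean,
            "sd": sd,
            "cov": cov,
            "retained": mean > threshold,
        }
    )
    return GroupSummary(table=out, threshold=threshold, n_subjects=len(profiles))


def aggregate_compartments(values: pd.Series, compartments: pd.Series) -> pd.Series:
    """Sum per-target values into their compartments.

    ``values`` and ``compartments`` are aligned Series (same index: target
    label or structure name).  A target mapped to compartment ``none``
    cannot be aggregated and raises.  Because aggregation is a sum, the
    compartment value of group means equals the group mean of per-subject
    compartment values.
    """
    compartments = compartments.reindex(values.index)
    if compartments.isna().any():
        missing = list(values.index[compartments.isna()])
        raise ValueError(f"no compartment for targets: {missing}")
    if (compartments == "none").any():
        bad = list(values.index[compartments == "none"])
        raise ValueError(f"targets with compartment 'none': {bad}")
    sums = values.groupby(compartments).sum()
    order = [c for c in COMPARTMENT_ORDER if c in sums.index]
    return sums.reindex(order)
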