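"""Seroreactivity statistics: per-sample Z-scores and group-vs-control Z-ratios.

Normalisation is per sample across all distinct peptides on the array
jointly:

    Z_p = (x_p - mean(x)) / SD(x)

where ``x`` are the duplicate-averaged net intensities.  Peptides with
``Z > 2`` (strict) are called reactive.  Group-vs-control comparisons use the
Z-ratio: per-peptide difference of Z-scores divided by the standard deviation
of all such differences,

    Zratio_p = (Z_group,p - Z_control,p) / SD({Z_group,q - Z_control,q}),

with ``Zratio > 1.96`` (the two-sided normal critical value at p < 0.05)
declared significant.  The default significance rule is one-sided (greater),
matching an analysis focused on peptides more reactive in immunized serum
than in control; a two-sided option uses ``|Zratio| > 1.96``.  Sample
standard deviations (n-1 denominator) are used throughout.

Peptides reactive in the control serum are attributed to nonspecific antibody
binding; they are flagged (not deleted) so downstream region calling can
exclude them from candidate protective regions while still reporting them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .signal import IntensityVector

logger = logging.getLogger(__name__)

#: Reactive-peptide threshold on the per-sample Z-score (strict inequality).
DEFAULT_Z_THRESHOLD = 2.0
#: Group-vs-control significance threshold on the Z-ratio (strict inequality);
#: the two-sided standard-normal critical value at p = 0.05.
DEFAULT_ZRATIO_THRESHOLD = 1.96


@dataclass
class ZProfile:
    """Per-peptide Z-scores of one sample plus the fitted constants."""

    sample_id: str
    z: dict[str, float]
    mean_intensity: float
    sd_intensity: float


@dataclass
class ReactivityCall:
    peptide_id: str
    group_label: str
    zscore: float
    is_reactive: bool
    control_reactive: bool = False


@dataclass
class GroupComparison:
    """Z-ratios of one immunized group against the control group."""

    group_label: str
    control_label: str
    zratio: dict[str, float]
    sd_differences: float
    n_tests: int
    significant: set[str] = field(default_factory=set)


def zscore(intensities: IntensityVector, ddof: int = 1) -> ZProfile:
    """Standardise a sample's intensities over all non-missing peptides.

    Raises on fewer than 3 peptides or a degenerate (constant) distribution.
    The resulting profile has mean 0 and SD 1 on the peptides used for
    fitting, and is invariant under affine transforms of the intensities.
    """
    ids = list(intensities.values)
    x = np.asarray([intensities.values[p] for p in ids], dtype=float)
    if x.size < 3:
        raise ValidationError(
            f"{intensities.sample_id}: need >= 3 peptides to normalise, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{intensities.sample_id}: non-finite intensities")
    mean = float(x.mean())
    sd = float(x.std(ddof=ddof))
    if sd == 0.0:
        raise ValidationError(
            f"{intensities.sample_id}: degenerate intensity distribution (SD = 0)"
        )
    z = (x - mean) / sd
    return ZProfile(
        sample_id=intensities.sample_id,
        z=dict(zip(ids, z.tolist())),
        mean_intensity=mean,
        sd_intensity=sd,
    )


def call_reactive(
    profile: ZProfile,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    group_label: str | None = None,
) -> list[ReactivityCall]:
    """Call reactive peptides at ``Z > z_threshold`` (strict inequality)."""
    label = group_label if group_label is not None else profile.sample_id
    return [
        ReactivityCall(
            peptide_id=pid,
            group_label=label,
            zscore=zval,
            is_reactive=zval > z_threshold,
        )
        for pid, zval in profile.z.items()
    ]


def zratio(
    group_profile: ZProfile, control_profile: ZProfile, ddof: int = 1
) -> GroupComparison:
    """Z-ratios of a group profile against a control profile.

    Differences are taken on the peptides shared by both profiles (mismatches
    are logged); the denominator is the sample SD of all those differences.
    Swapping the two profiles negates every Z-ratio.
    """
    shared = [p for p in group_profile.z if p in control_profile.z]
    n_dropped = (len(group_profile.z) - len(shared)) + (
        len(control_profile.z) - len(shared)
    )
    if n_dropped:
        logger.warning(
            "zratio %s vs %s: %d peptides not shared between profiles",
            group_profile.sample_id, control_profile.sample_id, n_dropped,
        )
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared peptides between profiles")
    d = np.asarray(
        [group_profile.z[p] - control_profile.z[p] for p in shared], dtype=float
    )
    sd = float(d.std(ddof=ddof))
    if sd == 0.0:
        raise ValidationError(
            f"identical profiles: SD of Z-score differences is 0 "
            f"({group_profile.sample_id} vs {control_profile.sample_id})"
        )
    return GroupComparison(
        group_label=group_profile.sample_id,
        control_label=control_profile.sample_id,
        zratio=dict(zip(shared, (d / sd).tolist())),
        sd_differences=sd,
        n_tests=len(shared),
    )


def call_significant(
    comparison: GroupComparison,
    zr_threshold: float = DEFAULT_ZRATIO_THRESHOLD,
    sided: str = "greater",
) -> set[str]:
    """Peptides whose Z-ratio exceeds the threshold (strict).

    ``sided="greater"`` (default) uses ``zratio > threshold``;
    ``sided="two"`` uses ``|zratio| > threshold``.
    """
    if sided not in ("greater", "two"):
        raise ValidationError(f"sided must be 'greater' or 'two', got {sided!r}")
    if sided == "greater":
        sig = {p for p, zr in comparison.zratio.items() if zr > zr_threshold}
    else:
        sig = {p for p, zr in comparison.zratio.items() if abs(zr) > zr_threshold}
    comparison.significant = sig
    return sig


def flag_control_reactive(
    group_calls: list[ReactivityCall], control_calls: list[ReactivityCall]
) -> list[ReactivityCall]:
    """Flag peptides reactive in the control serum on the group's calls.

    A peptide is flagged whenever its control Z-score exceeded the reactive
    threshold, regardless of its group Z-score; flagged peptides stay in the
    call list so reports can include or exclude them.
    """
    control_reactive = {c.peptide_id for c in control_calls if c.is_reactive}
    for call in group_calls:
        call.control_reactive = call.peptide_id in control_reactive
    return group_calls
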