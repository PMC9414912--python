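"""Spot-level quantification: GPR parsing, net signal, duplicate averaging.

The raw measurement for each spot is the median foreground fluorescence and
the median local background.  Net signal is foreground minus background
(negative values are retained: downstream Z-scoring is location-scale based
and flooring at zero would distort the empirical distribution).  Duplicate
spots of the same printed peptide are then averaged — background subtraction
first, then the arithmetic mean over surviving duplicates.

The GPR dialect accepted here is minimal: a tab-separated table with columns
``Block``, ``Row``, ``Column``, ``ID``, ``F532 Median``, ``B532 Median`` and
``Flags``; extra columns are ignored, rows with ``Flags < 0`` (bad/absent
spots) are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import PeptideLibrary

logger = logging.getLogger(__name__)

GPR_REQUIRED_COLUMNS = (
    "Block", "Row", "Column", "ID", "F532 Median", "B532 Median", "Flags",
)


@dataclass(frozen=True)
class Spot:
    block: int
    row: int
    col: int
    peptide_id: str
    fg_median: float
    bg_median: float
    flag: int = 0


@dataclass
class SampleScan:
    """One serum pool's spot measurements, cross-referenced to the library."""

    sample_id: str
    group_label: str
    spots: list[Spot]
    n_flagged_dropped: int = 0


@dataclass
class IntensityVector:
    """Duplicate-averaged net intensity per distinct peptide (a.u.)."""

    sample_id: str
    values: dict[str, float]
    missing: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.values)


def read_gpr(
    path,
    library: PeptideLibrary | None = None,
    sample_id: str | None = None,
    group_label: str = "",
) -> SampleScan:
    """Parse a spot quantification table into a :class:`SampleScan`.

    Rows flagged bad/absent (``Flags < 0``) are dropped and counted.  If a
    library is given, spot IDs are validated against its printed spots and
    unknown IDs raise a :class:`ValidationError` listing the offenders.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(GPR_REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(
            f"{path}: GPR table missing required columns {sorted(missing_cols)}"
        )
    flagged = df["Flags"] < 0
    n_dropped = int(flagged.sum())
    if n_dropped:
        logger.warning("%s: dropped %d flagged spots", path, n_dropped)
    df = df[~flagged]
    if library is not None:
        unknown = sorted(set(df["ID"]) - set(library.spot_ids))
        if unknown:
            raise ValidationError(
                f"{path}: spot IDs not present in the array layout: {unknown}"
            )
    spots = [
        Spot(
            block=int(b), row=int(r), col=int(c), peptide_id=str(pid),
            fg_median=float(fg), bg_median=float(bg), flag=int(fl),
        )
        for b, r, c, pid, fg, bg, fl in zip(
            *(df[col] for col in GPR_REQUIRED_COLUMNS)
        )
    ]
    sid = sample_id if sample_id is not None else Path(str(path)).stem
    return SampleScan(
        sample_id=sid, group_label=group_label, spots=spots,
        n_flagged_dropped=n_dropped,
    )


def net_signal(spot: Spot) -> float:
    """Median foreground minus median background; may be negative."""
    return spot.fg_median - spot.bg_median


def average_duplicates(
    scan: SampleScan, library: PeptideLibrary | None = None
) -> IntensityVector:
    """One net intensity per peptide: mean of its surviving duplicate spots.

    Peptides left with a single surviving spot use that value (warned);
    peptides with no surviving spot are recorded as missing and excluded from
    downstream normalization.
    """
    by_id: dict[str, list[float]] = {}
    for spot in scan.spots:
        by_id.setdefault(spot.peptide_id, []).append(net_signal(spot))
    values = {pid: float(np.mean(v)) for pid, v in by_id.items()}
    singles = [pid for pid, v in by_id.items() if len(v) == 1]
    if singles:
        logger.warning(
            "%s: %d peptides have a single surviving spot (e.g. %s)",
            scan.sample_id, len(singles), singles[0],
        )
    missing: tuple[str, ...] = ()
    if library is not None:
        missing = tuple(pid for pid in library.spot_ids if pid not in values)
        if missing:
            logger.warning(
                "%s: %d peptides have no surviving spot and are excluded: %s",
                scan.sample_id, len(missing), list(missing),
            )
    return IntensityVector(sample_id=scan.sample_id, values=values, missing=missing)


def write_intensities(vector: IntensityVector, path) -> None:
    """TSV export of an intensity vector (peptide_id, net_intensity)."""
    df = pd.DataFrame(
        {"peptide_id": list(vector.values), "net_intensity": list(vector.values.values())}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", lineterminator="\n")
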