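"""Synthetic peptide-array experiments with planted epitopes.

Generates everything the analysis consumes — protein FASTA, GAL layout,
per-group GPR spot tables — together with a truth set of planted epitope
intervals, so the whole pipeline is testable end to end without any external
data.

Noise model
-----------
Per distinct printed peptide, background fluorescence is log-normal,
``LogNormal(mu, sigma)`` on the natural scale (right-skewed, as raw array
fluorescence is).  A peptide *responds* to a planted epitope when its
linker-clipped protein span overlaps the epitope interval by at least
``min_overlap`` residues; responding peptides receive an additive effect of
``effect_size`` background standard deviations, so the effect size maps
directly onto the expected Z-score scale.  The two duplicate spots of each
peptide are drawn with multiplicative log-normal noise of coefficient of
variation ``duplicate_cv`` (mean-one factors).  The local background column
is a small constant fraction of the median background level.  The control
group carries signal only on its nonspecific-reactivity intervals, emulating
nonspecific antibody binding in adjuvant-only serum.

All randomness derives from a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import (
    DEFAULT_K,
    DEFAULT_LINKER,
    PeptideLibrary,
    ProteinRecord,
    build_library,
    index_to_protein_span,
    read_fasta,
    write_gal,
)
from .regions import EpitopeRegion, overlap_length
from .signal import GPR_REQUIRED_COLUMNS

logger = logging.getLogger(__name__)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of a synthetic experiment.

    Defaults mirror the array design the analysis targets: three homologous
    antigens of 157 residues each (471 tiles before deduplication, printed in
    duplicate), two immunized serum pools plus one adjuvant-only control,
    three planted epitopes at effect size 8 background-SD, and one
    nonspecific-reactivity interval in the control serum.
    """

    proteins: Sequence[tuple[str, int]] = (
        ("SUBa", 157), ("SUBb", 157), ("SUBc", 157),
    )
    fasta: str | None = None  # overrides random proteins when given
    groups: Sequence[str] = ("cocktail_crossbred", "SUBra_Bindicus", "control")
    control_label: str = "control"
    # group -> [(protein_id, start, end, effect_size in background-SD units)]
    planted_epitopes: Mapping[str, Sequence[tuple[str, int, int, float]]] = field(
        default_factory=lambda: {
            "cocktail_crossbred": [
                ("SUBa", 60, 75, 8.0),
                ("SUBb", 121, 137, 8.0),
            ],
            "SUBra_Bindicus": [
                ("SUBc", 40, 55, 8.0),
            ],
        }
    )
    # nonspecific reactivity of the control serum: (protein_id, start, end)
    control_nonspecific: Sequence[tuple[str, int, int]] = (
        ("SUBa", 100, 110),
    )
    control_effect_size: float = 8.0
    background_mu: float = math.log(500.0)  # log-scale location
    background_sigma: float = 0.4           # log-scale SD
    duplicate_cv: float = 0.1               # CV between duplicate spots
    bg_fraction: float = 0.05               # local background / exp(mu)
    min_overlap: int = 8                    # residues for a peptide to respond
    linker: str = DEFAULT_LINKER
    k: int = DEFAULT_K
    seed: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.min_overlap <= self.k:
            raise ValidationError("min_overlap must be in [1, k]")
        if self.control_label not in self.groups:
            raise ValidationError(
                f"control label {self.control_label!r} not among groups"
            )
        for group, epis in self.planted_epitopes.items():
            if group not in self.groups:
                raise ValidationError(f"planted epitopes for unknown group {group!r}")
            for (_, start, end, eff) in epis:
                if eff < 0:
                    raise ValidationError("effect_size must be >= 0")
                if start > end:
                    raise ValidationError(f"epitope interval ({start}, {end}) inverted")


@dataclass
class TruthSet:
    """Planted intervals and the peptide indices they make respond."""

    planted: dict[str, list[tuple[str, int, int, float]]]
    responding: dict[str, dict[str, tuple[int, ...]]]
    min_overlap: int
    control_label: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "min_overlap": self.min_overlap,
            "control_label": self.control_label,
            "planted": {g: [list(e) for e in v] for g, v in self.planted.items()},
            "responding": {
                g: {p: list(idx) for p, idx in by_prot.items()}
                for g, by_prot in self.responding.items()
            },
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per purpose/group
    return np.random.default_rng([int(config.seed), int(stream)])


def simulate_proteins(config: SimulationConfig) -> list[ProteinRecord]:
    """Random proteins (i.i.d. uniform residues), or the supplied FASTA."""
    if config.fasta is not None:
        return read_fasta(config.fasta)
    rng = _rng(config, 0)
    records = []
    for pid, length in config.proteins:
        if length < config.k:
            raise ValidationError(
                f"protein {pid!r} length {length} < tile length {config.k}"
            )
        seq = "".join(rng.choice(list(_ALPHABET), size=length))
        records.append(ProteinRecord(id=pid, sequence=seq, species_tag=pid))
    return records


def responding_indices(
    protein: ProteinRecord,
    epitope: tuple[int, int],
    min_overlap: int,
    linker_len: int = len(DEFAULT_LINKER),
    k: int = DEFAULT_K,
) -> tuple[int, ...]:
    """Peptide indices whose clipped span overlaps the epitope by >= min_overlap."""
    out = []
    for i in range(1, protein.length + 1):
        span = index_to_protein_span(i, protein.length, linker_len, k)
        if overlap_length(span, epitope) >= min_overlap:
            out.append(i)
    return tuple(out)


def build_truth(config: SimulationConfig, library: PeptideLibrary) -> TruthSet:
    """Derive the responding-peptide truth from the planted intervals."""
    planted: dict[str, list[tuple[str, int, int, float]]] = {}
    responding: dict[str, dict[str, tuple[int, ...]]] = {}
    linker_len = len(config.linker)
    per_group: dict[str, Sequence[tuple[str, int, int, float]]] = {
        g: list(v) for g, v in config.planted_epitopes.items()
    }
    per_group[config.control_label] = [
        (pid, s, e, config.control_effect_size)
        for pid, s, e in config.control_nonspecific
    ]
    for group, epis in per_group.items():
        planted[group] = [tuple(e) for e in epis]
        by_prot: dict[str, set[int]] = {}
        for pid, start, end, _eff in epis:
            if pid not in library.proteins:
                raise ValidationError(f"planted epitope on unknown protein {pid!r}")
            prot = library.proteins[pid]
            if not (1 <= start <= end <= prot.length):
                raise ValidationError(
                    f"epitope ({start}, {end}) outside protein {pid!r}"
                )
            idx = responding_indices(
                prot, (start, end), config.min_overlap, linker_len, config.k
            )
            by_prot.setdefault(pid, set()).update(idx)
        responding[group] = {
            pid: tuple(sorted(v)) for pid, v in sorted(by_prot.items())
        }
    return TruthSet(
        planted=planted, responding=responding,
        min_overlap=config.min_overlap, control_label=config.control_label,
    )


def _lognormal_sd(mu: float, sigma: float) -> float:
    return math.sqrt((math.exp(sigma**2) - 1.0)) * math.exp(mu + sigma**2 / 2.0)


def simulate_scan(
    config: SimulationConfig, library: PeptideLibrary, group: str
) -> pd.DataFrame:
    """Spot table (GPR dialect) for one serum group.

    A deduplicated spot responds if *any* of its origins overlaps a planted
    epitope of this group sufficiently; the shared spot then carries the
    planted signal for every origin, as on the physical array.
    """
    if group not in config.groups:
        raise ValidationError(f"unknown group {group!r}")
    truth = build_truth(config, library)
    responding = truth.responding.get(group, {})
    effects = truth.planted.get(group, [])
    linker_len = len(config.linker)

    # per-spot effect: max effect over responding origins
    spot_effect = np.zeros(library.n_distinct)
    spot_ids = list(library.spot_ids)
    for j, sid in enumerate(spot_ids):
        eff = 0.0
        for pid, index in library.origins_of_spot(sid):
            if index in responding.get(pid, ()):
                prot = library.proteins[pid]
                span = index_to_protein_span(index, prot.length, linker_len, config.k)
                for epid, start, end, e in effects:
                    if epid == pid and overlap_length(span, (start, end)) >= config.min_overlap:
                        eff = max(eff, e)
        spot_effect[j] = eff

    rng = _rng(config, 1 + list(config.groups).index(group))
    n = library.n_distinct
    background = rng.lognormal(config.background_mu, config.background_sigma, size=n)
    sd_bg = _lognormal_sd(config.background_mu, config.background_sigma)
    signal = background + spot_effect * sd_bg
    if config.duplicate_cv > 0:
        s = math.sqrt(math.log(1.0 + config.duplicate_cv**2))
        factors = rng.lognormal(-s**2 / 2.0, s, size=(n, 2))
    else:
        factors = np.ones((n, 2))
    bg_const = config.bg_fraction * math.exp(config.background_mu)

    rows = []
    pos = 0
    n_grid_columns = 24
    for j, sid in enumerate(spot_ids):
        for d in range(2):
            rows.append(
                {
                    "Block": 1,
                    "Row": pos // n_grid_columns + 1,
                    "Column": pos % n_grid_columns + 1,
                    "ID": sid,
                    "F532 Median": signal[j] * factors[j, d] + bg_const,
                    "B532 Median": bg_const,
                    "Flags": 0,
                }
            )
            pos += 1
    return pd.DataFrame(rows, columns=list(GPR_REQUIRED_COLUMNS))


def write_gpr(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", lineterminator="\n")


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    library: PeptideLibrary
    truth: TruthSet
    fasta_path: Path
    gal_path: Path
    gpr_paths: dict[str, Path]
    truth_path: Path


def simulate_experiment(config: SimulationConfig, outdir) -> SimulatedExperiment:
    """Write a complete synthetic experiment bundle to a directory.

    Produces ``proteins.fasta``, ``layout.gal``, one ``<group>.gpr`` per
    serum group and ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = simulate_proteins(config)
    fasta_path = outdir / "proteins.fasta"
    with open(fasta_path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.species_tag}\n")
            for j in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[j : j + 60] + "\n")
    library = build_library(records, linker=config.linker, k=config.k)
    gal_path = outdir / "layout.gal"
    write_gal(library, gal_path)
    truth = build_truth(config, library)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    gpr_paths: dict[str, Path] = {}
    for group in config.groups:
        df = simulate_scan(config, library, group)
        path = outdir / f"{group}.gpr"
        write_gpr(df, path)
        gpr_paths[group] = path
    logger.info(
        "simulated experiment: %d proteins, %d distinct peptides, %d groups -> %s",
        len(records), library.n_distinct, len(config.groups), outdir,
    )
    return SimulatedExperiment(
        config=config, library=library, truth=truth,
        fasta_path=fasta_path, gal_path=gal_path,
        gpr_paths=gpr_paths, truth_path=truth_path,
    )


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    f1: float
    n_epitopes: int
    n_regions: int


def evaluate_recovery(
    truth: TruthSet,
    regions: Sequence[EpitopeRegion],
    min_overlap: int | None = None,
    include_control: bool = False,
) -> RecoveryScore:
    """Score called regions against the planted truth.

    A planted epitope is recovered when some called region of the same
    protein and group overlaps it by at least ``min_overlap`` residues
    (default: the truth set's own threshold); a called region is a true
    positive when it overlaps some planted epitope of its group likewise.
    The control group's nonspecific intervals are excluded unless requested.
    """
    mo = truth.min_overlap if min_overlap is None else min_overlap
    groups = [
        g for g in truth.planted
        if include_control or g != truth.control_label
    ]
    epitopes = [
        (g, pid, (start, end))
        for g in groups
        for pid, start, end, _eff in truth.planted[g]
    ]
    region_list = [r for r in regions if r.group_label in groups]
    recovered = 0
    for g, pid, interval in epitopes:
        if any(
            r.group_label == g and r.protein_id == pid
            and overlap_length(r.span, interval) >= mo
            for r in region_list
        ):
            recovered += 1
    matched_regions = sum(
        1
        for r in region_list
        if any(
            g == r.group_label and pid == r.protein_id
            and overlap_length(r.span, interval) >= mo
            for g, pid, interval in epitopes
        )
    )
    recall = recovered / len(epitopes) if epitopes else 1.0
    if region_list:
        precision = matched_regions / len(region_list)
    else:
        precision = 1.0 if not epitopes else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryScore(
        precision=precision, recall=recall, f1=f1,
        n_epitopes=len(epitopes), n_regions=len(region_list),
    )
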