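"""Tiled peptide library construction and array-index coordinate arithmetic.

A protein of length ``L`` is elongated with a neutral ``GSGSGSG`` linker at
both termini and decomposed into overlapping 15-mer peptides at step 1
(14-residue peptide-peptide overlap), the standard high-resolution design for
linear B-cell epitope mapping on printed peptide arrays.  With a 7-residue
linker this yields exactly ``L`` tiles per protein, and every tile with index
``8 <= i <= L - 7`` is centred on protein residue ``i``: its linker-clipped
protein-coordinate span is ``(i - 7, i + 7)``.  All protein coordinates are
1-based inclusive.

Identical 15-mers arising from different (homologous) proteins are printed
once: the library deduplicates sequences across all proteins and a shared
spot's intensity is later attributed to every origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Neutral linker appended at both termini before tiling.
DEFAULT_LINKER = "GSGSGSG"

#: Tile (peptide) length in residues.
DEFAULT_K = 15


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"{what} contains non-standard residues: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein antigen to be tiled onto the array.

    Positions in ``sequence`` are 1-based.  Only the 20 standard residues are
    accepted: tiles must be synthesizable peptides, so ambiguity codes
    (X, B, Z) are rejected at parse time.
    """

    id: str
    sequence: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence, f"protein {self.id!r}")
        if len(self.sequence) < DEFAULT_K:
            raise ValidationError(
                f"protein {self.id!r} is shorter than one tile "
                f"({len(self.sequence)} < {DEFAULT_K} residues)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TiledPeptide:
    """One 15-mer tile of one protein.

    ``index`` is the per-protein array index (1-based, consecutive);
    ``sequence`` may contain linker residues at its ends for tiles near the
    termini; ``protein_start``/``protein_end`` give the linker-clipped span on
    the protein, 1-based inclusive.
    """

    protein_id: str
    index: int
    sequence: str
    elongated_start: int
    protein_start: int
    protein_end: int
    touches_linker: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.protein_start, self.protein_end)


@dataclass
class PeptideLibrary:
    """All tiles of all proteins plus the cross-protein deduplication map.

    ``unique_sequences`` maps each distinct 15-mer to the list of
    ``(protein_id, index)`` origins, in tiling order.  ``spot_ids`` assigns a
    stable printed-spot identifier (``P0001`` ...) to each distinct sequence
    in first-occurrence order; these IDs name spots in GAL/GPR files.
    """

    proteins: dict[str, ProteinRecord]
    peptides: list[TiledPeptide]
    linker: str = DEFAULT_LINKER
    k: int = DEFAULT_K
    unique_sequences: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    spot_ids: dict[str, str] = field(default_factory=dict)  # spot id -> sequence
    _by_origin: dict[tuple[str, int], TiledPeptide] = field(
        default_factory=dict, repr=False
    )

    @property
    def linker_len(self) -> int:
        return len(self.linker)

    @property
    def n_distinct(self) -> int:
        return len(self.unique_sequences)

    def peptide_at(self, protein_id: str, index: int) -> TiledPeptide:
        return self._by_origin[(protein_id, index)]

    def spot_id_of(self, sequence: str) -> str:
        """Printed-spot ID of a distinct 15-mer sequence."""
        return self._seq_to_spot[sequence]

    @property
    def _seq_to_spot(self) -> dict[str, str]:
        return {seq: sid for sid, seq in self.spot_ids.items()}

    def origins_of_spot(self, spot_id: str) -> list[tuple[str, int]]:
        return self.unique_sequences[self.spot_ids[spot_id]]


def elongate(protein: ProteinRecord | str, linker: str = DEFAULT_LINKER) -> str:
    """Append the neutral linker at both termini.

    Returns ``linker + sequence + linker`` (length ``L + 2 * len(linker)``),
    so that every protein residue, including the termini, appears centred in
    some tile.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not linker:
        raise ValidationError("linker must be non-empty")
    _check_alphabet(linker, "linker")
    _check_alphabet(seq, "sequence")
    return linker + seq + linker


def tile(elongated: str, k: int = DEFAULT_K, step: int = 1) -> list[str]:
    """All length-``k`` windows of ``elongated`` at the given step.

    Consecutive windows share exactly ``k - step`` residues.  With step 1 the
    number of windows is ``len(elongated) - k + 1``.
    """
    n = len(elongated)
    if n < k:
        raise ValidationError(f"sequence of length {n} is shorter than k={k}")
    if step < 1:
        raise ValidationError("step must be >= 1")
    return [elongated[j : j + k] for j in range(0, n - k + 1, step)]


def index_to_protein_span(
    i: int, L: int, linker_len: int = len(DEFAULT_LINKER), k: int = DEFAULT_K
) -> tuple[int, int]:
    """Linker-clipped protein span (1-based inclusive) of tile ``i``.

    Tile ``i`` occupies elongated positions ``i .. i + k - 1``; protein
    residue ``r`` sits at elongated position ``r + linker_len``.  Hence
    ``start = max(1, i - linker_len)`` and
    ``end = min(L, i + k - 1 - linker_len)``.  With the default 7-residue
    linker and 15-mers, interior tiles are centred on residue ``i``:
    ``span = (i - 7, i + 7)``.
    """
    if not 1 <= i <= L + 2 * linker_len - k + 1:
        raise ValidationError(f"tile index {i} out of range for protein length {L}")
    start = max(1, i - linker_len)
    end = min(L, i + k - 1 - linker_len)
    if start > end:
        raise ValidationError(
            f"tile index {i} covers no protein residue (L={L}, linker={linker_len})"
        )
    return start, end


def build_library(
    proteins: Iterable[ProteinRecord],
    linker: str = DEFAULT_LINKER,
    k: int = DEFAULT_K,
) -> PeptideLibrary:
    """Tile every protein and deduplicate 15-mers across proteins.

    Per protein the number of tiles is ``(L + 2*linker_len) - k + 1``; with
    the default 7-residue linker and ``k = 15`` this equals ``L`` exactly,
    with indices consecutive from 1.
    """
    prot_map: dict[str, ProteinRecord] = {}
    peptides: list[TiledPeptide] = []
    unique: dict[str, list[tuple[str, int]]] = {}
    linker_len = len(linker)
    for prot in proteins:
        if prot.id in prot_map:
            raise ValidationError(f"duplicate protein id {prot.id!r}")
        prot_map[prot.id] = prot
        windows = tile(elongate(prot, linker), k=k, step=1)
        L = prot.length
        for j, window in enumerate(windows):
            i = j + 1
            start, end = index_to_protein_span(i, L, linker_len=linker_len, k=k)
            pep = TiledPeptide(
                protein_id=prot.id,
                index=i,
                sequence=window,
                elongated_start=i,
                protein_start=start,
                protein_end=end,
                touches_linker=(i <= linker_len or i > L - (k - 1 - linker_len)),
            )
            peptides.append(pep)
            unique.setdefault(window, []).append((prot.id, i))
    spot_ids = {f"P{n:04d}": seq for n, seq in enumerate(unique, start=1)}
    lib = PeptideLibrary(
        proteins=prot_map,
        peptides=peptides,
        linker=linker,
        k=k,
        unique_sequences=unique,
        spot_ids=spot_ids,
        _by_origin={(p.protein_id, p.index): p for p in peptides},
    )
    logger.info(
        "built library: %d proteins, %d tiles, %d distinct peptides",
        len(prot_map), len(peptides), len(unique),
    )
    return lib


def dedup(library: PeptideLibrary) -> tuple[dict[str, list[tuple[str, int]]], int]:
    """The sequence → origins map and the count of distinct 15-mers."""
    return library.unique_sequences, library.n_distinct


def find_by_sequence(
    seq: str, library: PeptideLibrary
) -> list[tuple[str, int, tuple[int, int]]]:
    """All exact occurrences of a 15-mer on the array.

    Returns ``(protein_id, index, (protein_start, protein_end))`` triples;
    empty if the sequence is not on the array.
    """
    if len(seq) != library.k:
        raise ValidationError(f"query must be a {library.k}-mer, got {len(seq)}")
    return [
        (pid, i, library.peptide_at(pid, i).span)
        for pid, i in library.unique_sequences.get(seq, [])
    ]


# ---------------------------------------------------------------------------
# FASTA / GAL I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The record ID becomes the protein id; the second whitespace token of the
    description, if any, is kept as the species tag (e.g. ``>SUBra R.a``).
    Sequences are validated against the 20 standard residues; offending lines
    are reported with their line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    in_body = False
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith(">"):
            in_body = True
            continue
        if not in_body:
            raise ValidationError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        bad = set(text.upper()) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{path}: line {lineno}: non-standard residues {sorted(bad)!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        tag = tokens[1] if len(tokens) > 1 else rec.id
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), species_tag=tag)
        )
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


GAL_COLUMNS = ("Block", "Row", "Column", "ID", "Name")


def write_gal(library: PeptideLibrary, path, n_grid_columns: int = 24) -> int:
    """Write the printed-array layout as a minimal GAL-style table.

    Each distinct peptide is printed in duplicate: two adjacent spots sharing
    one spot ID, with the peptide sequence in the ``Name`` field.  Returns the
    number of spot rows written.
    """
    rows = []
    pos = 0
    for spot_id, seq in library.spot_ids.items():
        for _ in range(2):  # duplicate spots
            rows.append(
                (1, pos // n_grid_columns + 1, pos % n_grid_columns + 1, spot_id, seq)
            )
            pos += 1
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(GAL_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    logger.info("wrote GAL layout: %d spots (%d distinct peptides)",
                len(rows), library.n_distinct)
    return len(rows)


def read_gal(path) -> dict[str, str]:
    """Read a GAL-style table back to a spot-ID → sequence map."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(GAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: GAL table missing columns {sorted(missing)}")
    ids: dict[str, str] = {}
    for sid, name in zip(df["ID"], df["Name"]):
        if sid in ids and ids[sid] != name:
            raise ValidationError(f"{path}: spot ID {sid!r} has conflicting sequences")
        ids[sid] = name
    return ids
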