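"""Peptide-window containers, table readers and site-vicinity encoding.

A candidate lysine crotonylation (Kcr) site is represented by the
(2ξ+1)-mer peptide window centred on the lysine; with the default flank
ξ = 20 the window is 41 residues long.  Windows that fall off the end of
the parent protein are padded with the symbol ``'X'``.

The numeric form of a window is the *site vicinity vector* (SVV): each of
the 20 canonical residues is mapped to its alphabetical rank 1..20
(A→1, C→2, …, Y→20) and the padding symbol to 0, so padding contributes
nothing to downstream composition and position accumulators.

Coordinates: site positions in user-facing I/O are 1-based (UniProt
convention); all internal indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes in alphabetical order.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Window padding symbol (off-protein positions near the termini).
PADDING = "X"

#: Ambiguity / non-standard codes stripped from the source data; any row
#: containing one of these anywhere is rejected.  'X' is handled apart
#: because it doubles as the padding symbol.
FORBIDDEN_CODES = frozenset("BJOUZ")

#: residue -> SVV code (A→1 … Y→20, X→0)
RESIDUE_CODES = {aa: i + 1 for i, aa in enumerate(CANONICAL_RESIDUES)}
RESIDUE_CODES[PADDING] = 0

#: SVV code -> residue
CODE_RESIDUES = {v: k for k, v in RESIDUE_CODES.items()}

#: Default window flank; 2*20 + 1 = 41-mer windows.
DEFAULT_XI = 20


class WindowError(ValueError):
    """Raised for windows that violate the peptide-window contract."""


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length residue window centred on a candidate lysine.

    Parameters
    ----------
    residues : str
        Window string of odd length 2ξ+1 over the canonical alphabet
        plus terminal ``'X'`` padding.
    label : int
        1 for an annotated crotonylation site, 0 for a non-site.
    source_id : str, optional
        Free-text provenance tag (protein accession, row id, ...).
    allow_non_lysine_center : bool
        Relaxes the central-``K`` requirement; intended only for
        synthetic stress tests.
    """

    residues: str
    label: int
    source_id: str | None = None
    allow_non_lysine_center: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise WindowError(
                f"window length must be odd and >= 3, got {n}"
            )
        bad = set(self.residues) - set(CANONICAL_RESIDUES) - {PADDING}
        if bad:
            raise WindowError(f"invalid residue codes {sorted(bad)!r}")
        if self.label not in (0, 1):
            raise WindowError(f"label must be 0 or 1, got {self.label!r}")
        if self.residues[self.center_index] != "K" and not self.allow_non_lysine_center:
            raise WindowError(
                f"central residue is {self.residues[self.center_index]!r}, "
                "expected 'K' (pass allow_non_lysine_center=True to relax)"
            )
        if _has_internal_padding(self.residues):
            raise WindowError("'X' is permitted only as terminal padding")

    @property
    def center_index(self) -> int:
        """0-based index of the candidate site (always the midpoint)."""
        return len(self.residues) // 2

    @property
    def xi(self) -> int:
        """Flank size ξ; the window spans 2ξ+1 residues."""
        return len(self.residues) // 2

    def __len__(self) -> int:
        return len(self.residues)


def _has_internal_padding(residues: str) -> bool:
    """True if any 'X' occurs outside the terminal padding runs."""
    core = residues.strip(PADDING)
    return PADDING in core


@dataclass
class BenchmarkDataset:
    """An ordered collection of labelled peptide windows.

    ``rejections`` records rows the reader refused, as
    ``(row_index, reason)`` pairs, so ingestion reports can summarise
    the cleaning step.
    """

    windows: list[PeptideWindow]
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(w.label == 1 for w in self.windows)

    @property
    def n_negative(self) -> int:
        return sum(w.label == 0 for w in self.windows)

    @property
    def counts(self) -> tuple[int, int]:
        return (self.n_positive, self.n_negative)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def sequences(self) -> list[str]:
        return [w.residues for w in self.windows]

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": self.sequences, "label": self.labels}
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the ``sequence,label`` dialect consumed by the reader."""
        self.to_frame().to_csv(path, index=False)


def extract_window(
    protein: str,
    site_index: int,
    xi: int = DEFAULT_XI,
    label: int = 0,
    source_id: str | None = None,
    allow_non_lysine_center: bool = False,
) -> PeptideWindow:
    """Cut the (2ξ+1)-mer window centred on a 1-based site position.

    Positions before the first or after the last residue of the protein
    are filled with the padding symbol ``'X'``.

    Parameters
    ----------
    protein : str
        Full protein sequence.
    site_index : int
        1-based position of the candidate lysine within ``protein``.
    xi : int
        Flank size; the window spans ``2*xi + 1`` residues.
    """
    if xi < 1:
        raise ValueError(f"xi must be >= 1, got {xi}")
    if not 1 <= site_index <= len(protein):
        raise IndexError(
            f"site_index {site_index} out of range 1..{len(protein)}"
        )
    center = site_index - 1  # to 0-based
    if protein[center] != "K" and not allow_non_lysine_center:
        raise WindowError(
            f"residue at position {site_index} is {protein[center]!r}, not 'K'"
        )
    lo, hi = center - xi, center + xi + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(protein))
    residues = (
        PADDING * left_pad
        + protein[max(lo, 0) : min(hi, len(protein))]
        + PADDING * right_pad
    )
    return PeptideWindow(
        residues,
        label=label,
        source_id=source_id,
        allow_non_lysine_center=allow_non_lysine_center,
    )


def encode_svv(window: PeptideWindow | str) -> np.ndarray:
    """Encode a window to its site vicinity vector (SVV).

    Each canonical residue maps to its alphabetical rank 1..20 and the
    padding symbol ``'X'`` to the dummy code 0.

    Returns
    -------
    numpy.ndarray of int, shape (2ξ+1,)
    """
    residues = window.residues if isinstance(window, PeptideWindow) else window
    try:
        return np.array([RESIDUE_CODES[aa] for aa in residues], dtype=int)
    except KeyError as exc:  # pragma: no cover - windows are pre-validated
        raise WindowError(f"invalid residue {exc.args[0]!r}") from exc


def decode_svv(values: Sequence[int] | np.ndarray) -> str:
    """Inverse of :func:`encode_svv` (codes 0..20 back to residues)."""
    try:
        return "".join(CODE_RESIDUES[int(v)] for v in values)
    except KeyError as exc:
        raise ValueError(f"invalid SVV code {exc.args[0]!r}") from exc


def _validate_row(sequence: str, expected_length: int | None) -> str | None:
    """Return a rejection reason for a table row, or None if it is valid."""
    if not isinstance(sequence, str) or not sequence:
        return "empty or non-string sequence"
    seq = sequence.strip().upper()
    forbidden = sorted(set(seq) & FORBIDDEN_CODES)
    if forbidden:
        return f"forbidden residue codes {forbidden}"
    other = set(seq) - set(CANONICAL_RESIDUES) - {PADDING}
    if other:
        return f"invalid characters {sorted(other)}"
    if expected_length is not None and len(seq) != expected_length:
        return f"wrong length {len(seq)} (expected {expected_length})"
    if len(seq) % 2 == 0:
        return f"even window length {len(seq)}"
    if _has_internal_padding(seq):
        return "'X' outside terminal padding"
    return None


def read_peptide_table(
    path: str | Path,
    format: str | None = None,
    sequence_column: str = "sequence",
    label_column: str = "label",
    expected_length: int | None = 2 * DEFAULT_XI + 1,
    allow_non_lysine_center: bool = False,
) -> BenchmarkDataset:
    """Read a table of pre-cut labelled peptide windows.

    The canonical dialect is CSV/TSV with ``sequence,label`` columns and
    label ∈ {0, 1}; XLSX exports of the same layout are accepted.  Rows
    violating the window contract (wrong length, forbidden residue codes
    B/J/O/U/Z, internal 'X', non-lysine centre) are rejected
    individually and tallied in ``dataset.rejections``; an input from
    which *no* row survives is a hard error.  Duplicate window strings —
    within a class or, worse, with conflicting labels — are rejected
    with a logged warning.

    Row order of surviving windows is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "csv":
        frame = pd.read_csv(path)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif format == "xlsx":
        frame = pd.read_excel(path)
    else:
        raise ValueError(f"unsupported format {format!r}")

    for col in (sequence_column, label_column):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r} in {path}")

    windows: list[PeptideWindow] = []
    rejections: list[tuple[int, str]] = []
    seen: dict[str, int] = {}  # residues -> label of first occurrence
    for idx, row in enumerate(frame.itertuples(index=False)):
        seq = getattr(row, sequence_column)
        raw_label = getattr(row, label_column)
        try:
            label = int(raw_label)
        except (TypeError, ValueError):
            rejections.append((idx, f"non-integer label {raw_label!r}"))
            continue
        if label not in (0, 1):
            rejections.append((idx, f"label {label} not in {{0, 1}}"))
            continue
        reason = _validate_row(seq, expected_length)
        if reason is not None:
            rejections.append((idx, reason))
            continue
        seq = seq.strip().upper()
        if seq in seen:
            kind = (
                "duplicate window with conflicting label"
                if seen[seq] != label
                else "duplicate window within class"
            )
            logger.warning("row %d: %s", idx, kind)
            rejections.append((idx, kind))
            continue
        try:
            window = PeptideWindow(
                seq,
                label=label,
                source_id=f"{path.name}:{idx}",
                allow_non_lysine_center=allow_non_lysine_center,
            )
        except WindowError as exc:
            rejections.append((idx, str(exc)))
            continue
        seen[seq] = label
        windows.append(window)

    if rejections:
        logger.info(
            "%s: rejected %d of %d rows", path.name, len(rejections), len(frame)
        )
    if not windows:
        raise ValueError(f"no valid peptide windows in {path}")
    return BenchmarkDataset(windows=windows, rejections=rejections)


def read_fasta_sites(
    fasta_path: str | Path,
    sites: Iterable[tuple[str, int, int]],
    xi: int = DEFAULT_XI,
) -> BenchmarkDataset:
    """Cut labelled windows out of whole proteins in a FASTA file.

    ``sites`` yields ``(record_id, position_1based, label)`` triples.
    """
    from Bio import SeqIO

    proteins = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    windows: list[PeptideWindow] = []
    rejections: list[tuple[int, str]] = []
    for idx, (rec_id, pos, label) in enumerate(sites):
        if rec_id not in proteins:
            rejections.append((idx, f"unknown record {rec_id!r}"))
            continue
        try:
            windows.append(
                extract_window(
                    proteins[rec_id], pos, xi=xi, label=label,
                    source_id=f"{rec_id}:{pos}",
                )
            )
        except (WindowError, IndexError) as exc:
            rejections.append((idx, str(exc)))
    if not windows:
        raise ValueError("no valid windows extracted from FASTA input")
    return BenchmarkDataset(windows=windows, rejections=rejections)
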