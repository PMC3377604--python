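"""Reading, validating and filtering protein sequences in FASTA format.

Only the 20 standard one-letter amino-acid codes are accepted after
validation; how nonstandard residues (B, J, O, U, X, Z, ``*``, gaps) are
handled is controlled by an explicit policy, because the downstream CTD
descriptors are defined only over the standard alphabet.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

NonstandardPolicy = Literal["reject", "drop-residue", "skip-record"]


class FastaParseError(ValueError):
    """Raised when the input is not well-formed FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a record violates the sequence invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, free-text description, validated sequence.

    The sequence is upper-case and, once validated, contains only the 20
    standard residues.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise SequenceValidationError("record id must be a non-empty token")
        if not self.sequence:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_standard(self) -> bool:
        return set(self.sequence) <= _STANDARD_SET


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    on_nonstandard: NonstandardPolicy = "skip-record",
) -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path:
        Plain or gzip-compressed FASTA file.
    on_nonstandard:
        What to do with residues outside the 20 standard codes:
        ``"reject"`` raises, ``"drop-residue"`` removes the offending
        characters, ``"skip-record"`` (default) omits the whole record with
        a logged warning.

    Returns
    -------
    Records in file order. An empty file yields an empty list. Duplicate
    ids raise :class:`SequenceValidationError`.
    """
    if on_nonstandard not in ("reject", "drop-residue", "skip-record"):
        raise ValueError(f"unknown nonstandard-residue policy: {on_nonstandard!r}")
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise FastaParseError(
                f"{path}: sequence data before first FASTA header"
            )
        handle.seek(0)
        for seq_rec in SeqIO.parse(handle, "fasta"):
            rid = seq_rec.id
            if rid in seen:
                raise SequenceValidationError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            seq = str(seq_rec.seq).upper().replace("-", "").replace(".", "")
            nonstd = sorted(set(seq) - _STANDARD_SET)
            if nonstd:
                if on_nonstandard == "reject":
                    raise SequenceValidationError(
                        f"{path}: record {rid!r} contains nonstandard residues "
                        f"{''.join(nonstd)}"
                    )
                if on_nonstandard == "skip-record":
                    logger.warning(
                        "skipping record %s: nonstandard residues %s",
                        rid, "".join(nonstd),
                    )
                    continue
                seq = "".join(c for c in seq if c in _STANDARD_SET)
                logger.warning(
                    "record %s: dropped nonstandard residues %s", rid, "".join(nonstd)
                )
            if not seq:
                logger.warning("skipping record %s: no standard residues left", rid)
                continue
            desc = seq_rec.description
            if desc.startswith(rid):
                desc = desc[len(rid):].strip()
            records.append(ProteinRecord(id=rid, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped multi-record FASTA (round-trips with read_fasta)."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def filter_by_length(
    records: list[ProteinRecord], min_exclusive: int = 100
) -> list[ProteinRecord]:
    """Keep records whose length is strictly greater than ``min_exclusive``.

    The default of 100 reflects the dataset-construction convention that
    only proteins of more than 100 residues enter training or screening;
    the boundary (length exactly 100) is excluded.
    """
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    return [r for r in records if len(r) > min_exclusive]
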