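"""The 188-element physicochemical sequence encoding.

Each protein is represented by 20 amino-acid composition values followed by,
for each of 8 physicochemical residue properties, 21 CTD descriptors:
3 composition (C), 3 transition (T) and 15 distribution (D) values —
20 + 8 x 21 = 188 in total.

Every property partitions the 20 standard residues into three disjoint
groups (e.g. for charge: positive {K,R}, neutral, negative {D,E}); the
partition tables are shipped as a versioned data file
(``data/ctd_groupings.tsv``) so that an alternative grouping is a
configuration change rather than a code change.

Descriptor definitions
----------------------
composition
    fraction of residues falling in each group.
transition
    for each unordered group pair (j,k), the fraction of adjacent residue
    pairs in which one residue belongs to group j and the other to group k,
    out of the N-1 adjacent pairs.
distribution
    for each group, the sequence position (as a percentage of the chain
    length) containing the first, 25%, 50%, 75% and 100% of that group's
    residues.  With m occurrences at 1-based positions p_1 < ... < p_m, the
    value at fraction f is 100 * p_q / N with q = max(1, ceil(f*m)); a group
    absent from the sequence contributes five zeros.

Composition and transition values are on a 0-1 scale; distribution values
are on a 0-100 scale.  The layout (index map) is exposed by
:func:`feature_names`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mfescan.sequence_io import STANDARD_AA, ProteinRecord

N_FEATURES = 188
GROUPINGS_VERSION = "1"

#: fixed property order; it determines feature-vector element order
PROPERTY_ORDER = (
    "hydrophobicity",
    "normalized_vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "surface_tension",
    "secondary_structure",
    "solvent_accessibility",
)

_HEADER_SHORT = {
    "hydrophobicity": "HYDRO",
    "normalized_vdw_volume": "VDW",
    "polarity": "POLARITY",
    "polarizability": "POLARIZ",
    "charge": "CHARGE",
    "surface_tension": "SURFTEN",
    "secondary_structure": "SECSTR",
    "solvent_accessibility": "SOLVACC",
}

_DIST_POINTS = ("first", "25", "50", "75", "100")
_DIST_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.00)


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded."""


@dataclass(frozen=True)
class PropertyGrouping:
    """A named partition of the 20 standard residues into three groups.

    Group order is fixed (it determines vector element order); the three
    groups must be pairwise disjoint and cover the standard alphabet
    exactly.
    """

    name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        union: set[str] = set()
        total = 0
        for g in self.groups:
            union |= g
            total += len(g)
        if total != 20 or union != set(STANDARD_AA):
            raise ValueError(
                f"grouping {self.name!r} is not a disjoint partition of the "
                "20 standard residues"
            )

    def group_of(self, residue: str) -> int:
        for j, g in enumerate(self.groups):
            if residue in g:
                return j
        raise KeyError(residue)


def _load_groupings() -> dict[str, PropertyGrouping]:
    text = (
        resources.files("mfescan").joinpath("data/ctd_groupings.tsv").read_text()
    )
    table: dict[str, PropertyGrouping] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, g1, g2, g3 = line.split("\t")
        table[name] = PropertyGrouping(
            name=name, groups=(frozenset(g1), frozenset(g2), frozenset(g3))
        )
    missing = set(PROPERTY_ORDER) - set(table)
    if missing:
        raise RuntimeError(f"grouping table missing properties: {sorted(missing)}")
    return table


GROUPINGS: dict[str, PropertyGrouping] = _load_groupings()


@dataclass(frozen=True)
class FeatureVector:
    """The 188-element encoding of one sequence (layout per feature_names)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have exactly {N_FEATURES} elements, "
                f"got shape {self.values.shape}"
            )


def feature_names() -> list[str]:
    """Column names encoding the fixed 20 + 8x21 layout."""
    names = [f"AAC_{a}" for a in STANDARD_AA]
    for prop in PROPERTY_ORDER:
        s = _HEADER_SHORT[prop]
        names += [f"{s}_C{j}" for j in (1, 2, 3)]
        names += [f"{s}_T{jk}" for jk in ("12", "13", "23")]
        for j in (1, 2, 3):
            names += [f"{s}_D{j}_{p}" for p in _DIST_POINTS]
    assert len(names) == N_FEATURES
    return names


def _check_sequence(sequence: str, min_len: int = 1) -> None:
    if len(sequence) < min_len:
        raise EncodingError(
            f"sequence of length {len(sequence)} too short (need >= {min_len})"
        )
    bad = set(sequence) - set(STANDARD_AA)
    if bad:
        raise EncodingError(f"nonstandard residues in sequence: {sorted(bad)}")


def aa_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 20 residues, alphabetical by one-letter code."""
    _check_sequence(sequence)
    n = len(sequence)
    counts = np.array([sequence.count(a) for a in STANDARD_AA], dtype=float)
    return counts / n


def ctd_composition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Fraction of residues in each of the grouping's three classes."""
    _check_sequence(sequence)
    n = len(sequence)
    counts = np.zeros(3)
    for c in sequence:
        counts[grouping.group_of(c)] += 1
    return counts / n


def ctd_transition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Cross-group adjacency frequencies for pairs (1,2), (1,3), (2,3).

    Each value counts adjacent positions where the two residues fall in the
    two different groups (either order), divided by N-1.
    """
    _check_sequence(sequence, min_len=2)
    n = len(sequence)
    pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
    prev = grouping.group_of(sequence[0])
    for c in sequence[1:]:
        cur = grouping.group_of(c)
        if cur != prev:
            pair_counts[(min(prev, cur), max(prev, cur))] += 1
        prev = cur
    return np.array(
        [pair_counts[(0, 1)], pair_counts[(0, 2)], pair_counts[(1, 2)]],
        dtype=float,
    ) / (n - 1)


def ctd_distribution(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Chain-length percentages locating the first/25/50/75/100% of each group.

    Returns 15 values (5 per group, groups in order). A group with no
    occurrence contributes five zeros.
    """
    _check_sequence(sequence)
    n = len(sequence)
    positions: list[list[int]] = [[], [], []]
    for i, c in enumerate(sequence, start=1):
        positions[grouping.group_of(c)].append(i)
    out = np.zeros(15)
    for j, pos in enumerate(positions):
        m = len(pos)
        if m == 0:
            continue
        for q_idx, f in enumerate(_DIST_FRACTIONS):
            q = max(1, math.ceil(f * m))
            out[5 * j + q_idx] = 100.0 * pos[q - 1] / n
    return out


def encode_sequence(record: ProteinRecord) -> FeatureVector:
    """Encode one validated record as the full 188-element vector.

    Layout: 20 amino-acid composition values, then for each property in
    :data:`PROPERTY_ORDER` the block [C1,C2,C3, T12,T13,T23, D1(5), D2(5),
    D3(5)].
    """
    seq = record.sequence
    _check_sequence(seq, min_len=2)
    parts = [aa_composition(seq)]
    for prop in PROPERTY_ORDER:
        grouping = GROUPINGS[prop]
        parts.append(ctd_composition(seq, grouping))
        parts.append(ctd_transition(seq, grouping))
        parts.append(ctd_distribution(seq, grouping))
    return FeatureVector(values=np.concatenate(parts))


def encode_batch(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Encode records into a (n x 188) frame indexed by record id, file order."""
    rows = []
    ids = []
    for rec in records:
        try:
            rows.append(encode_sequence(rec).values)
        except EncodingError as exc:
            raise EncodingError(f"record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    data = np.vstack(rows) if rows else np.empty((0, N_FEATURES))
    return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=feature_names())


def write_features(features: pd.DataFrame, path) -> None:
    """Persist a feature matrix as TSV (first column = record id)."""
    features.to_csv(path, sep="\t", index=True)


def read_features(path) -> pd.DataFrame:
    """Read a feature-matrix TSV written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    if list(df.columns) != feature_names():
        raise ValueError(f"{path}: feature columns do not match the 188-D layout")
    return df
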