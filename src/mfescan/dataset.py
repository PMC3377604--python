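"""Labeled dataset construction: positives, family-aware negatives.

Positives are the annotated MFEs longer than 100 residues.  Negatives are
drawn one per domain family, after excluding every family that contains at
least one MFE member — so no negative shares a domain family with any
positive (the anti-leakage guarantee of the training-set design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from mfescan.ctd import N_FEATURES, encode_batch
from mfescan.sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1
NEGATIVE_LABEL = -1


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein record with an explicit MFE label and domain families."""

    record: ProteinRecord
    is_mfe: bool
    families: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(not f for f in self.families):
            raise ValueError(
                f"protein {self.record.id!r}: empty family accession"
            )


@dataclass
class LabeledDataset:
    """Feature matrix plus class indices: +1 = MFE, -1 = non-MFE."""

    features: pd.DataFrame
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.labels) == len(self.ids)):
            raise ValueError("features, labels and ids must have equal row counts")
        if self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must have {N_FEATURES} columns")
        if not set(np.unique(self.labels)) <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.ids)

    def save(self, features_path: str | Path, labels_path: str | Path) -> None:
        self.features.to_csv(features_path, sep="\t", index=True)
        pd.DataFrame({"id": self.ids, "label": self.labels}).to_csv(
            labels_path, sep="\t", index=False
        )

    @classmethod
    def load(cls, features_path: str | Path, labels_path: str | Path) -> "LabeledDataset":
        from mfescan.ctd import read_features

        features = read_features(features_path)
        lab = pd.read_csv(labels_path, sep="\t")
        lab = lab.set_index("id").loc[features.index]
        return cls(
            features=features,
            labels=lab["label"].to_numpy(),
            ids=list(features.index),
        )


def select_positives(proteins: Sequence[AnnotatedProtein]) -> list[AnnotatedProtein]:
    """MFE-labeled proteins of length strictly greater than 100."""
    return [p for p in proteins if p.is_mfe and len(p.record) > 100]


def negative_families(proteins: Sequence[AnnotatedProtein]) -> set[str]:
    """Observed families minus every family carrying at least one MFE member."""
    observed: set[str] = set()
    tainted: set[str] = set()
    for p in proteins:
        observed |= p.families
        if p.is_mfe:
            tainted |= p.families
    return observed - tainted


def sample_negatives(
    proteins: Sequence[AnnotatedProtein],
    eligible_families: set[str],
    seed: int,
) -> list[AnnotatedProtein]:
    """One uniformly chosen seed (length > 100) per eligible family.

    Only proteins whose families are all eligible may serve as seeds: a
    protein that also carries an MFE-containing (non-eligible) family shares
    domain architecture with a positive and is excluded from the pool — this
    is the anti-leakage guarantee.  A protein belonging to several eligible
    families is chosen at most once: if a family's draw lands on an already
    chosen protein, the slot is re-drawn from that family's remaining
    members, or dropped when the family is exhausted.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    members: dict[str, list[AnnotatedProtein]] = {f: [] for f in eligible_families}
    for p in proteins:
        if len(p.record) <= 100:
            continue
        if not p.families <= eligible_families:
            continue
        for f in p.families:
            members[f].append(p)
    chosen: dict[str, AnnotatedProtein] = {}
    for fam in sorted(eligible_families):
        pool = sorted(members[fam], key=lambda p: p.record.id)
        if not pool:
            logger.warning("family %s has no member longer than 100; skipped", fam)
            continue
        while pool:
            idx = int(rng.integers(len(pool)))
            cand = pool.pop(idx)
            if cand.record.id not in chosen:
                chosen[cand.record.id] = cand
                break
        else:
            logger.warning("family %s exhausted by deduplication; skipped", fam)
    return list(chosen.values())


def assemble_dataset(
    positives: Sequence[AnnotatedProtein],
    negatives: Sequence[AnnotatedProtein],
    encoder: Callable[[Sequence[ProteinRecord]], pd.DataFrame] = encode_batch,
) -> LabeledDataset:
    """Encode both classes into one labeled dataset (+1 positives first)."""
    pos_ids = {p.record.id for p in positives}
    neg_ids = {p.record.id for p in negatives}
    overlap = pos_ids & neg_ids
    if overlap:
        raise ValueError(f"ids present in both classes: {sorted(overlap)[:5]}")
    records = [p.record for p in positives] + [p.record for p in negatives]
    features = encoder(records)
    labels = np.array(
        [POSITIVE_LABEL] * len(positives) + [NEGATIVE_LABEL] * len(negatives)
    )
    return LabeledDataset(features=features, labels=labels, ids=list(features.index))


def write_annotations(proteins: Iterable[AnnotatedProtein], path: str | Path) -> None:
    """Write the annotation table: id, is_mfe (0/1), semicolon-joined families."""
    rows = [
        {
            "id": p.record.id,
            "is_mfe": int(p.is_mfe),
            "families": ";".join(sorted(p.families)),
        }
        for p in proteins
    ]
    pd.DataFrame(rows, columns=["id", "is_mfe", "families"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[AnnotatedProtein]:
    """Join an annotation table onto parsed records (by id).

    Records without an annotation row are an error: the label must be
    explicit for every protein entering dataset construction.
    """
    table = pd.read_csv(path, sep="\t", dtype={"families": str}, keep_default_na=False)
    if not {"id", "is_mfe", "families"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns id, is_mfe, families")
    by_id = table.set_index("id")
    if by_id.index.has_duplicates:
        raise ValueError(f"{path}: duplicate ids in annotation table")
    out = []
    for rec in records:
        if rec.id not in by_id.index:
            raise ValueError(f"record {rec.id!r} has no annotation row")
        row = by_id.loc[rec.id]
        fams = frozenset(f for f in str(row["families"]).split(";") if f)
        out.append(
            AnnotatedProtein(record=rec, is_mfe=bool(int(row["is_mfe"])), families=fams)
        )
    return out
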