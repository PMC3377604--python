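"""Synthetic labeled protein sequences for end-to-end testing.

Two classes of random sequences over the 20-letter alphabet, both longer
than 100 residues: the negative class draws residues from a background
distribution (uniform by default, optionally natural frequencies), the
positive class from the same background with configurable per-residue
weight multipliers (default: charged residues K, R, D, E up-weighted x3 —
a composition shift the CTD charge descriptors are sensitive to).

Pseudo-family accessions emulate domain-family annotations: every positive
belongs to one of a small pool of MFE families, every negative gets its own
private family, and a configurable fraction of negatives additionally
carries an MFE family so that family-aware negative selection has real
exclusion work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mfescan.dataset import AnnotatedProtein, write_annotations
from mfescan.sequence_io import STANDARD_AA, ProteinRecord, write_fasta

# Approximate residue frequencies of well-annotated proteomes (optional
# background more realistic than uniform).
NATURAL_FREQUENCIES = {
    "A": 0.0826, "C": 0.0136, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0394, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic two-class generator.

    ``class_bias`` maps residue strings to sampling-weight multipliers
    applied to the positive class only; a multiplier of 1.0 everywhere
    makes the two classes distributionally identical (the null).
    ``n_mfe_families`` MFE families are shared among positives;
    ``contaminated_fraction`` of negatives additionally carry an MFE
    family, which family-aware negative selection must exclude.
    """

    n_per_class: int = 100
    length_range: tuple[int, int] = (101, 400)
    class_bias: dict[str, float] = field(default_factory=lambda: {"KRDE": 3.0})
    seed: int = 0
    background: str = "uniform"  # or "natural"
    n_mfe_families: int = 10
    contaminated_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if lo <= 100 or hi < lo:
            raise ValueError("length_range must satisfy 100 < lo <= hi")
        if any(w <= 0 for w in self.class_bias.values()):
            raise ValueError("bias multipliers must be positive")
        if self.background not in ("uniform", "natural"):
            raise ValueError("background must be 'uniform' or 'natural'")
        if not 0.0 <= self.contaminated_fraction <= 1.0:
            raise ValueError("contaminated_fraction must be in [0, 1]")


def _class_weights(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.background == "uniform":
        base = np.ones(20)
    else:
        base = np.array([NATURAL_FREQUENCIES[a] for a in STANDARD_AA])
    pos = base.copy()
    for residues, mult in config.class_bias.items():
        for r in residues:
            pos[STANDARD_AA.index(r)] *= mult
    return base / base.sum(), pos / pos.sum()


def generate(config: SyntheticConfig) -> list[AnnotatedProtein]:
    """Draw the two labeled classes; deterministic per seed.

    Returns positives (``MFE_####``) then negatives (``NEG_####``), each
    with pseudo-family annotations as described in the module docstring.
    """
    rng = np.random.default_rng(config.seed)
    neg_p, pos_p = _class_weights(config)
    alphabet = np.array(list(STANDARD_AA))
    lo, hi = config.length_range
    mfe_fams = [f"FAMP{i:04d}" for i in range(config.n_mfe_families)]

    proteins: list[AnnotatedProtein] = []
    for i in range(config.n_per_class):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=pos_p))
        fam = mfe_fams[int(rng.integers(len(mfe_fams)))]
        proteins.append(
            AnnotatedProtein(
                record=ProteinRecord(id=f"MFE_{i:04d}", sequence=seq),
                is_mfe=True,
                families=frozenset({fam}),
            )
        )
    for i in range(config.n_per_class):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=neg_p))
        fams = {f"FAMN{i:04d}"}
        if rng.random() < config.contaminated_fraction:
            fams.add(mfe_fams[int(rng.integers(len(mfe_fams)))])
        proteins.append(
            AnnotatedProtein(
                record=ProteinRecord(id=f"NEG_{i:04d}", sequence=seq),
                is_mfe=False,
                families=frozenset(fams),
            )
        )
    return proteins


def write_synthetic(
    proteins: list[AnnotatedProtein],
    fasta_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write the FASTA + annotation TSV pair consumed by dataset construction."""
    write_fasta([p.record for p in proteins], fasta_path)
    write_annotations(proteins, annotations_path)
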