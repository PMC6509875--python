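"""Shared domain containers and their plain-text file interfaces.

The package works with gene-level quantities only: a two-condition
expression table, its log-fold-change differentiation profile split into
up/down components, position weight matrices for cis-motifs, promoter
regions, the gene x motif occurrence-count matrix that serves as the
condition-free binding-strength proxy, and named gene sets for enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("basetf")

ALPHABET = "ACGT"

__all__ = [
    "ExpressionPair",
    "DifferentiationProfile",
    "PWM",
    "PromoterRegion",
    "BindingCountMatrix",
    "BaseResult",
    "GeneSetCollection",
    "read_expression_table",
    "read_count_matrix",
    "read_gmt",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")
    return ids


@dataclass
class ExpressionPair:
    """Gene abundances under a control (``e0``) and a treatment (``e1``) sample.

    Abundances are nonnegative, in arbitrary (but shared) expression units.
    Strict positivity is only required at the point where log-fold changes
    are taken (:func:`basetf.engine.diff_expression` drops offenders).
    """

    gene_ids: list[str]
    e0: np.ndarray
    e1: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.e0 = np.asarray(self.e0, dtype=float)
        self.e1 = np.asarray(self.e1, dtype=float)
        n = len(self.gene_ids)
        if n < 1:
            raise ValueError("need at least one gene")
        if self.e0.shape != (n,) or self.e1.shape != (n,):
            raise ValueError("gene_ids, e0 and e1 must have identical length")
        if np.any(self.e0 < 0) or np.any(self.e1 < 0):
            raise ValueError("abundances must be nonnegative")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class DifferentiationProfile:
    """Per-gene log-fold changes ``d`` with the directional split.

    ``d_up = max(d, 0)`` carries the up-regulated mass, ``d_down = max(-d, 0)``
    the down-regulated mass; ``d_up - d_down`` recovers ``d`` exactly and the
    two components are never simultaneously positive.
    """

    gene_ids: list[str]
    d: np.ndarray
    d_up: np.ndarray = field(init=False)
    d_down: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.gene_ids),):
            raise ValueError("gene_ids and d must have identical length")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("log-fold changes must be finite")
        self.d_up = np.maximum(self.d, 0.0)
        self.d_down = np.maximum(-self.d, 0.0)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def direction(self, which: str) -> np.ndarray:
        if which == "up":
            return self.d_up
        if which == "down":
            return self.d_down
        raise ValueError(f"direction must be 'up' or 'down', got {which!r}")


@dataclass
class PWM:
    """Position-specific nucleotide model of one cis-motif.

    ``matrix`` is L x 4 over (A, C, G, T), one row per motif position.
    When ``is_probability`` each row sums to one; raw count matrices keep
    their counts and are normalised by the scanner on demand.
    """

    motif_id: str
    factor_name: str
    matrix: np.ndarray
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(
                f"PWM {self.motif_id}: matrix must be L x 4, got {self.matrix.shape}"
            )
        if self.matrix.shape[0] < 1:
            raise ValueError(f"PWM {self.motif_id}: empty matrix")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.motif_id}: negative entries")
        if self.is_probability:
            sums = self.matrix.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(
                    f"PWM {self.motif_id}: probability rows must sum to 1"
                )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRegion:
    """A promoter window around one gene's TSS.

    Coordinates are 0-based half-open on the reference. On the minus strand
    the stored ``sequence`` is the reverse complement of the reference slice,
    so index 0 of ``sequence`` is the most 5' promoter base with respect to
    transcription.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"{self.gene_id}: non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BindingCountMatrix:
    """Gene x motif matrix of above-threshold motif occurrence counts (tau)."""

    gene_ids: list[str]
    motif_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.motif_ids = _check_unique(self.motif_ids, "motif ids")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.motif_ids)):
            raise ValueError("counts shape inconsistent with labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.motif_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BindingCountMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            motif_ids=[str(m) for m in frame.columns],
            counts=frame.to_numpy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t")

    def column(self, motif_id: str) -> np.ndarray:
        return self.counts[:, self.motif_ids.index(motif_id)]


@dataclass
class BaseResult:
    """Inference result for one motif in one regulation direction."""

    motif_id: str
    factor_name: str
    direction: str
    delta: float
    p_value: float
    q_value: float
    n_permutations: int
    n_genes: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError(f"delta {self.delta} outside [-1, 1]")
        for name, v in (("p_value", self.p_value), ("q_value", self.q_value)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


@dataclass
class GeneSetCollection:
    """Named gene subsets (pathways, GO terms) for enrichment testing."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @classmethod
    def from_members(
        cls, mapping: Mapping[str, Iterable[str]]
    ) -> "GeneSetCollection":
        return cls(
            {
                name: ("", tuple(dict.fromkeys(members)))
                for name, members in mapping.items()
            }
        )


# ---------------------------------------------------------------------------
# plain-text readers


def read_expression_table(path: str | Path):
    """Read a gene-level expression TSV.

    Two layouts are accepted (header required):

    * ``gene_id, expr_control, expr_treatment`` -> :class:`ExpressionPair`
    * ``gene_id, logfc`` -> :class:`DifferentiationProfile` (values taken
      as-is; the statistic is scale-free, so the log base does not matter)
    """
    table = pd.read_csv(path, sep="\t")
    cols = set(table.columns)
    if {"gene_id", "expr_control", "expr_treatment"} <= cols:
        return ExpressionPair(
            gene_ids=[str(g) for g in table["gene_id"]],
            e0=table["expr_control"].to_numpy(float),
            e1=table["expr_treatment"].to_numpy(float),
        )
    if {"gene_id", "logfc"} <= cols:
        return DifferentiationProfile(
            gene_ids=[str(g) for g in table["gene_id"]],
            d=table["logfc"].to_numpy(float),
        )
    raise ValueError(
        f"{path}: expected columns (gene_id, expr_control, expr_treatment) "
        f"or (gene_id, logfc); found {sorted(cols)}"
    )


def read_count_matrix(path: str | Path) -> BindingCountMatrix:
    """Read a gene x motif count TSV (first column gene_id, one column per motif)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: no motif columns")
    return BindingCountMatrix.from_frame(frame)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set-name <TAB> description <TAB> member genes.

    Duplicate members within a set are dropped (first occurrence kept).
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc = parts[0], parts[1]
            members = tuple(dict.fromkeys(m for m in parts[2:] if m))
            if len(members) < len([m for m in parts[2:] if m]):
                logger.info("GMT set %s: duplicate members removed", name)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)
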