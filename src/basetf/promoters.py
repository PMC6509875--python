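"""Strand-aware promoter extraction from a genome FASTA and an annotation.

The default window is 1000 bp upstream to 200 bp downstream of the TSS.
Genes with several transcripts contribute one promoter, anchored at the
5'-most transcript start (minimum start on '+', maximum end on '-'): the
count model assigns a single binding vector per gene, so alternative
promoters are not aggregated. Windows are clipped at chromosome boundaries
(logged); ambiguity characters are kept as N and never matched downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import PromoterRegion, reverse_complement

logger = logging.getLogger("basetf")

__all__ = [
    "TranscriptRecord",
    "choose_tss",
    "extract_promoters",
    "write_promoters_fasta",
    "write_promoters_bed",
]

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 200


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript-level annotation record, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def choose_tss(records: Sequence[TranscriptRecord]) -> tuple[int, str] | None:
    """Resolve one TSS per gene: the 5'-most transcript start.

    On '+' this is the minimum record start; on '-' the maximum record end
    minus one (0-based). Deterministic under record reordering. Returns
    ``None`` (caller skips the gene) when records disagree on strand.
    """
    if not records:
        raise ValueError("choose_tss requires at least one record")
    strands = {r.strand for r in records}
    if len(strands) != 1:
        logger.warning(
            "gene %s: transcripts on conflicting strands, skipped", records[0].gene_id
        )
        return None
    strand = strands.pop()
    if strand == "+":
        return min(r.start for r in records), "+"
    return max(r.end for r in records) - 1, "-"


# ---------------------------------------------------------------------------
# annotation readers (all produce TranscriptRecord lists)


def _attr_lookup(attrs, keys: Iterable[str]) -> str | None:
    for key in keys:
        if key in attrs:
            val = attrs[key]
            if isinstance(val, (list, tuple)):
                val = val[0]
            # GFF3 Parent may be "gene:xyz"
            return str(val).split(":")[-1]
    return None


def _read_gff(path: str | Path) -> list[TranscriptRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    feats = list(db.features_of_type(("transcript", "mRNA")))
    if not feats:
        feats = list(db.features_of_type("gene"))
    records = []
    for f in feats:
        gene_id = _attr_lookup(f.attributes, ("gene_id", "Parent", "gene", "ID", "Name"))
        if gene_id is None:
            logger.warning("annotation record without a gene identifier skipped: %s", f.id)
            continue
        records.append(
            TranscriptRecord(gene_id, f.seqid, f.start - 1, f.end, f.strand)
        )
    return records


def _read_bed6(path: str | Path) -> list[TranscriptRecord]:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        TranscriptRecord(str(r.name_), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def _read_annotation(path: str | Path, fmt: str | None) -> list[TranscriptRecord]:
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff"
    if fmt == "bed":
        return _read_bed6(path)
    if fmt in ("gff", "gff3", "gtf"):
        return _read_gff(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------


class _FastaSource:
    """Uniform access to pyfaidx.Fasta, a path, or an in-memory mapping."""

    def __init__(self, genome):
        if isinstance(genome, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(genome), sequence_always_upper=True)
            self._mapping = None
        elif isinstance(genome, Mapping):
            self._fasta = None
            self._mapping = {k: v.upper() for k, v in genome.items()}
        else:  # assume pyfaidx.Fasta-like
            self._fasta = genome
            self._mapping = None

    def __contains__(self, chrom: str) -> bool:
        if self._mapping is not None:
            return chrom in self._mapping
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._mapping is not None:
            return len(self._mapping[chrom])
        return len(self._fasta[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        if self._mapping is not None:
            return self._mapping[chrom][start:end]
        return str(self._fasta[chrom][start:end])


def extract_promoters(
    genome,
    annotation: str | Path | Sequence[TranscriptRecord],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    annotation_format: str | None = None,
) -> list[PromoterRegion]:
    """One promoter window per gene, honoring strand.

    For a '+' gene with TSS t (0-based) the window is [t - upstream,
    t + downstream); for a '-' gene it is [t - downstream + 1,
    t + upstream + 1) and the stored sequence is reverse-complemented, so
    both strands read 5'-to-3' with respect to transcription. Windows are
    clipped at chromosome ends; unknown chromosomes and strand-conflicting
    genes are skipped with a warning.

    ``genome`` may be a FASTA path, a ``pyfaidx.Fasta``, or a plain
    ``{chrom: sequence}`` mapping. ``annotation`` may be a GFF3/GTF/BED6
    path or an explicit sequence of :class:`TranscriptRecord`.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream < 1:
        raise ValueError("need upstream >= 0, downstream >= 0, upstream + downstream >= 1")
    source = _FastaSource(genome)
    if isinstance(annotation, (str, Path)):
        records = _read_annotation(annotation, annotation_format)
    else:
        records = list(annotation)

    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    promoters: list[PromoterRegion] = []
    for gene_id, recs in by_gene.items():
        chroms = {r.chrom for r in recs}
        if len(chroms) != 1:
            logger.warning("gene %s: transcripts on multiple chromosomes, skipped", gene_id)
            continue
        chrom = chroms.pop()
        if chrom not in source:
            logger.warning("gene %s: chromosome %s not in FASTA, skipped", gene_id, chrom)
            continue
        resolved = choose_tss(recs)
        if resolved is None:
            continue
        tss, strand = resolved
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        chrom_len = source.length(chrom)
        cstart, cend = max(0, start), min(chrom_len, end)
        if (cstart, cend) != (start, end):
            logger.info(
                "gene %s: promoter window [%d, %d) clipped to [%d, %d)",
                gene_id, start, end, cstart, cend,
            )
        if cstart >= cend:
            logger.warning("gene %s: promoter window empty after clipping, skipped", gene_id)
            continue
        seq = source.slice(chrom, cstart, cend)
        if strand == "-":
            seq = reverse_complement(seq)
        promoters.append(
            PromoterRegion(
                gene_id=gene_id, chrom=chrom, start=cstart, end=cend,
                strand=strand, sequence=seq,
            )
        )
    if not promoters:
        raise ValueError("no promoters could be extracted")
    return promoters


def write_promoters_fasta(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    with open(path, "w") as out:
        for p in promoters:
            out.write(f">{p.gene_id}\n{p.sequence}\n")


def write_promoters_bed(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    with open(path, "w") as out:
        for p in promoters:
            out.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n")
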