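"""Synthetic fixtures: expression/count ensembles and toy genomes.

Everything the pipeline consumes can be generated here with a fixed seed:

* ``simulate_null`` — the exchangeability null: log-fold changes drawn
  i.i.d. Normal(0, noise_sd) and motif counts drawn i.i.d. Poisson,
  independent of expression. Used for type-I-error calibration.
* ``simulate_alternative`` — one planted regulator whose promoter counts
  are Poisson with mean inflated in proportion to each gene's
  up-differentiation, emulating a factor whose binding concentrates on
  strongly up-regulated genes. Used for power/recovery checks.
* ``make_toy_genome`` — a single synthetic chromosome with gene models on
  alternating strands and exact-consensus motif copies planted inside known
  promoter windows, emitted as FASTA/GFF3/JASPAR text, with a ground-truth
  plant table for end-to-end count verification.

Default ensemble sizes (500 genes, 50 motifs, Poisson mean 1, unit noise,
effect size 3) are the package's standard study conditions for calibration
and power experiments. A negative-binomial option is provided because real
promoter counts are overdispersed relative to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ALPHABET,
    BindingCountMatrix,
    DifferentiationProfile,
    PWM,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "simulate_null",
    "simulate_alternative",
    "make_toy_genome",
    "ToyGenome",
    "default_toy_pwm",
]


@dataclass
class SimulationConfig:
    """Knobs of the expression/count ensembles.

    ``effect_size`` couples the planted motif's Poisson mean to each gene's
    up-differentiation (0 = null); ``background_count_mean`` is the Poisson
    mean of null counts; ``nb_dispersion``, if set, switches counts to a
    negative binomial with that size parameter (smaller = more overdispersed).
    With ``folded`` the log-fold changes are folded to |Normal(0, noise_sd)|:
    every gene then carries up-direction mass, the profile used for the
    standard power study (a signed profile leaves roughly half the genes
    with zero up-component and correspondingly less signal to detect).
    """

    n_genes: int = 500
    n_motifs: int = 50
    effect_size: float = 3.0
    background_count_mean: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    nb_dispersion: float | None = None
    folded: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.background_count_mean <= 0:
            raise ValueError("background_count_mean must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _motif_ids(m: int) -> list[str]:
    return [f"M{j:03d}" for j in range(m)]


def _draw_counts(rng: np.random.Generator, mean, config: SimulationConfig) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, float), np.shape(mean))
    if config.nb_dispersion is None:
        return rng.poisson(mean)
    size = config.nb_dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_null(
    config: SimulationConfig,
) -> tuple[DifferentiationProfile, BindingCountMatrix]:
    """Expression and counts with no regulator effect (exchangeable pairing)."""
    rng = np.random.default_rng(config.seed)
    d = rng.normal(0.0, config.noise_sd, size=config.n_genes)
    if config.folded:
        d = np.abs(d)
    mean = np.full((config.n_genes, config.n_motifs), config.background_count_mean)
    counts = _draw_counts(rng, mean, config)
    return (
        DifferentiationProfile(gene_ids=_gene_ids(config.n_genes), d=d),
        BindingCountMatrix(
            gene_ids=_gene_ids(config.n_genes),
            motif_ids=_motif_ids(config.n_motifs),
            counts=counts,
        ),
    )


def simulate_alternative(
    config: SimulationConfig, planted_motif_index: int = 0
) -> tuple[DifferentiationProfile, BindingCountMatrix]:
    """Null ensemble plus one planted up-direction regulator.

    The planted motif's count mean for gene i is
    ``background * (1 + effect_size * d_up_i / max d_up)``: binding weight
    concentrates on strongly up-regulated genes, the premise under which
    the BASE statistic should call the factor activated. Coupling through
    d+ (not signed d) keeps the planted signal specifically directional.
    With ``effect_size = 0`` this reduces exactly to :func:`simulate_null`.
    """
    if not 0 <= planted_motif_index < config.n_motifs:
        raise ValueError("planted_motif_index out of range")
    rng = np.random.default_rng(config.seed)
    d = rng.normal(0.0, config.noise_sd, size=config.n_genes)
    if config.folded:
        d = np.abs(d)
    d_up = np.maximum(d, 0.0)
    mean = np.full((config.n_genes, config.n_motifs), config.background_count_mean)
    top = d_up.max()
    if top > 0:
        boost = 1.0 + config.effect_size * d_up / top
        mean[:, planted_motif_index] = config.background_count_mean * boost
    counts = _draw_counts(rng, mean, config)
    return (
        DifferentiationProfile(gene_ids=_gene_ids(config.n_genes), d=d),
        BindingCountMatrix(
            gene_ids=_gene_ids(config.n_genes),
            motif_ids=_motif_ids(config.n_motifs),
            counts=counts,
        ),
    )


# ---------------------------------------------------------------------------
# toy genome


def default_toy_pwm(consensus: str = "ACGGAGGTCA", motif_id: str = "TOY$M1") -> PWM:
    """A sharp, non-palindromic 10-bp motif: 0.97 on the consensus base.

    With uniform 0.01 off-consensus frequencies every mismatch costs exactly
    one tenth of the similarity score, so a 0.95 threshold admits only
    perfect matches — convenient for planted-copy bookkeeping.
    """
    if set(consensus) - set(ALPHABET):
        raise ValueError("consensus must be over ACGT")
    matrix = np.full((len(consensus), 4), 0.01)
    for i, base in enumerate(consensus):
        matrix[i, ALPHABET.index(base)] = 0.97
    return PWM(motif_id=motif_id, factor_name="ToyFactor", matrix=matrix,
               is_probability=True)


@dataclass
class ToyGenome:
    fasta_text: str
    gff3_text: str
    pwm_text: str
    plants: pd.DataFrame  # gene_id, motif_id, copies, offsets (promoter coords)
    upstream: int
    downstream: int
    chrom: str = "chr1"
    pwm: PWM = field(default=None)  # type: ignore[assignment]

    def write_to(self, directory) -> dict[str, str]:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "genome.fa",
            "gff3": directory / "genes.gff3",
            "pwms": directory / "motifs.jaspar",
            "plants": directory / "plants.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff3"].write_text(self.gff3_text)
        paths["pwms"].write_text(self.pwm_text)
        self.plants.to_csv(paths["plants"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def _pwm_to_jaspar(pwm: PWM, scale: int = 100) -> str:
    counts = np.rint(pwm.matrix * scale).astype(int)
    lines = [f">{pwm.motif_id} {pwm.factor_name}"]
    for bi, base in enumerate(ALPHABET):
        row = " ".join(str(counts[pos, bi]) for pos in range(len(pwm)))
        lines.append(f"{base} [ {row} ]")
    return "\n".join(lines) + "\n"


def make_toy_genome(
    n_genes: int = 4,
    promoter_len: int = 1200,
    motif_plants: list[tuple[int, PWM | None, int]] | None = None,
    *,
    tss_offset: int = 1000,
    spacer: int = 100,
    seed: int = 0,
    clip_first: bool = False,
) -> ToyGenome:
    """A synthetic chromosome with known TSSs and planted consensus copies.

    Genes alternate strands. Each gene's promoter window has length
    ``promoter_len`` with the TSS at index ``tss_offset`` (so extraction
    with ``upstream=tss_offset, downstream=promoter_len - tss_offset``
    reproduces the windows exactly). ``motif_plants`` lists
    ``(gene_index, pwm_or_None, copies)``; ``None`` uses the default toy
    motif. Background is i.i.d. uniform ACGT. With ``clip_first`` the first
    gene's window is truncated at the chromosome start to exercise boundary
    clipping; its plants land in the retained part.

    The returned plant table records, per gene, the planted copy number and
    the offsets in extracted-promoter coordinates, so a downstream scan of
    the emitted files can be checked against ground truth.
    """
    motif_plants = list(motif_plants or [])
    rng = np.random.default_rng(seed)
    pwm = default_toy_pwm()
    pwms: dict[str, PWM] = {}
    plants_by_gene: dict[int, list[tuple[PWM, int]]] = {}
    for gene_idx, motif, copies in motif_plants:
        if not 0 <= gene_idx < n_genes:
            raise ValueError(f"gene index {gene_idx} out of range")
        motif = motif or pwm
        pwms[motif.motif_id] = motif
        plants_by_gene.setdefault(gene_idx, []).append((motif, copies))
    if not pwms:
        pwms[pwm.motif_id] = pwm

    downstream = promoter_len - tss_offset
    if downstream < 0 or tss_offset < 0:
        raise ValueError("tss_offset must lie inside the promoter window")
    window = promoter_len
    clip_amount = window // 2 if clip_first else 0

    # lay out windows left to right
    gene_rows = []  # (gene_id, strand, win_ref_start, win_len)
    cursor = spacer
    for g in range(n_genes):
        win_len = window - (clip_amount if g == 0 and clip_first else 0)
        strand = "+" if g % 2 == 0 else "-"
        if g == 0 and clip_first:
            cursor = 0
        gene_rows.append((f"toy{g:03d}", strand, cursor, win_len))
        cursor += win_len + spacer

    chrom_len = cursor + spacer
    chrom = rng.integers(0, 4, size=chrom_len)
    chrom_chars = np.array(list(ALPHABET))[chrom]

    plant_records = []
    gff_lines = ["##gff-version 3"]
    for g, (gene_id, strand, w0, win_len) in enumerate(gene_rows):
        # build the promoter (transcription-oriented) string
        prom = chrom_chars[w0 : w0 + win_len].copy()
        if strand == "-":
            prom = np.array(list(reverse_complement("".join(prom))))
        offsets_all: dict[str, list[int]] = {}
        motifs_here = plants_by_gene.get(g, [])
        placed: list[tuple[int, int]] = []
        for motif, copies in motifs_here:
            L = len(motif)
            offs: list[int] = []
            for _ in range(copies):
                for _attempt in range(1000):
                    o = int(rng.integers(0, win_len - L + 1))
                    if all(o + L <= a or o >= a + b for a, b in placed):
                        placed.append((o, L))
                        offs.append(o)
                        break
                else:
                    raise ValueError("could not place non-overlapping plants")
            for o in offs:
                prom[o : o + L] = list(motif.consensus)
            offsets_all[motif.motif_id] = sorted(offs)
        for motif_id_, offs in offsets_all.items():
            plant_records.append(
                {
                    "gene_id": gene_id,
                    "motif_id": motif_id_,
                    "copies": len(offs),
                    "offsets": ",".join(map(str, offs)),
                }
            )
        if not offsets_all:
            plant_records.append(
                {"gene_id": gene_id, "motif_id": next(iter(pwms)), "copies": 0,
                 "offsets": ""}
            )
        # write the (possibly planted) promoter back into the chromosome
        ref_slice = prom if strand == "+" else np.array(
            list(reverse_complement("".join(prom)))
        )
        chrom_chars[w0 : w0 + win_len] = ref_slice

        # gene model: TSS at promoter index tss_offset (shifted if clipped)
        local_tss = tss_offset - (clip_amount if g == 0 and clip_first else 0)
        local_tss = max(0, local_tss)
        if strand == "+":
            tss_ref = w0 + local_tss
            gstart, gend = tss_ref, min(chrom_len, tss_ref + 300)
        else:
            tss_ref = w0 + win_len - 1 - local_tss
            gstart, gend = max(0, tss_ref - 299), tss_ref + 1
        gff_lines.append(
            "\t".join(
                [
                    "chr1", "toysim", "gene", str(gstart + 1), str(gend), ".",
                    strand, ".", f"ID=gene:{gene_id}",
                ]
            )
        )
        gff_lines.append(
            "\t".join(
                [
                    "chr1", "toysim", "mRNA", str(gstart + 1), str(gend), ".",
                    strand, ".", f"ID=tx:{gene_id}.1;Parent=gene:{gene_id}",
                ]
            )
        )

    seq = "".join(chrom_chars)
    fasta_lines = [">chr1"]
    for i in range(0, len(seq), 70):
        fasta_lines.append(seq[i : i + 70])
    pwm_text = "".join(_pwm_to_jaspar(p) for p in pwms.values())
    plants = pd.DataFrame(plant_records)
    return ToyGenome(
        fasta_text="\n".join(fasta_lines) + "\n",
        gff3_text="\n".join(gff_lines) + "\n",
        pwm_text=pwm_text,
        plants=plants,
        upstream=tss_offset,
        downstream=downstream,
        pwm=pwm,
    )
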