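"""Synthetic degradome generator with ground truth.

Emulates the data structure a 5'P degradome experiment produces: a small
transcriptome (single- and two-exon transcripts on both strands, written as
GFF3 + FASTA), per-library 5'P end-count profiles, and transcription-arrest
decay time courses. Every downstream operation of the pipeline can be tested
against the generating parameters.

Mechanistic model of a library
------------------------------
A transcript's 5'P ends are a mixture of

* a positionally uniform background (weight ``1 - phi``), representing
  ribosome-independent endo/exonucleolytic intermediates, and
* a co-translational component (weight ``phi``, the CTRD fraction) whose
  mass sits on the codon lattice of the CDS — each codon 5' boundary carries
  unit weight, biased onto frame 0 by ``frame_bias`` — except that the two
  terminal-stalling positions 16-17 nt upstream of the stop codon carry
  weight ``stall_weight`` each (the slow-termination footprint of the last
  ribosome). The boundary therefore receives a fraction
  ``2 s / (2 s + n_codons)`` of the CTRD mass, monotone in ``s``.

Genotypes rescale ``phi`` and ``stall_weight`` multiplicatively (an
*xrn4*-like exoribonuclease mutant has both reduced). Library totals are
negative-binomial around each transcript's expression mean; positions are
multinomial. Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import EndCountProfile, ProfileSet, SampleSheet, TranscriptModel
from .decay import DecayTimeCourse
from .tsi import TsiParams

__all__ = [
    "SimulationConfig",
    "SimulatedTranscriptome",
    "simulate_transcriptome",
    "simulate_degradome_library",
    "simulate_experiment",
    "simulate_timecourse",
    "position_probabilities",
    "expected_tsi",
    "ground_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of the synthetic degradome.

    Defaults describe a wild-type-like reference with strong terminational
    stalling plus one exoribonuclease-mutant genotype with CTRD reduced
    (phi x0.5) and stalling reduced (s x0.25), three replicates each —
    the replicate/genotype structure of a two-genotype 5'Pseq batch.
    """

    n_transcripts: int = 500
    cds_length_range: tuple[int, int] = (300, 900)  # excl. stop codon, nt
    utr5_length: int = 50
    utr3_length: int = 60
    expression_mean: float = 300.0  # mean reads per transcript per library
    expression_sigma: float = 0.5  # lognormal spread across transcripts
    ctrd_fraction: float = 0.4  # phi
    stall_weight: float = 8.0  # s, per-position weight at the boundary
    frame_bias: float = 0.8
    boundary_offsets: tuple[int, int] = (-17, -16)
    boundary_split: tuple[float, float] = (0.5, 0.5)
    dispersion: float = 10.0  # negative-binomial size of library totals
    genotypes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"Col0": (1.0, 1.0), "xrn4": (0.5, 0.25)}
    )  # genotype -> (phi multiplier, stall multiplier)
    n_replicates: int = 3
    organ: str = "shoot"
    two_exon_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ctrd_fraction <= 1:
            raise ValueError("ctrd_fraction must be in [0,1]")
        if self.stall_weight < 0:
            raise ValueError("stall_weight must be >= 0")
        if not 0 <= self.frame_bias <= 1:
            raise ValueError("frame_bias must be in [0,1]")
        for g, (pm, sm) in self.genotypes.items():
            if pm < 0 or sm < 0:
                raise ValueError(f"genotype {g}: multipliers must be >= 0")
        flank_reach = max(self.boundary_offsets) + TsiParams().flank_half_width
        if self.utr3_length + 3 <= flank_reach:
            raise ValueError(
                f"utr3_length={self.utr3_length} too short: downstream TSI flank "
                f"reaches {flank_reach} nt past the stop codon start"
            )

    def genotype_params(self, genotype: str) -> tuple[float, float]:
        pm, sm = self.genotypes[genotype]
        return self.ctrd_fraction * pm, self.stall_weight * sm


@dataclass
class SimulatedTranscriptome:
    """Models plus chromosome sequences and per-transcript expression means."""

    models: list[TranscriptModel]
    sequences: dict[str, np.ndarray]  # chrom -> array of bytes (ACGT)
    expression: dict[str, float]
    config: SimulationConfig

    @property
    def models_by_id(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                seq = self.sequences[chrom].tobytes().decode()
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path, stop_codon_features: bool = False) -> None:
        """Write the annotation as GFF3.

        By default the CDS feature includes the stop codon (TAIR-style);
        with ``stop_codon_features`` the CDS excludes it and explicit
        ``stop_codon`` features are emitted (GTF-style dialect).
        """
        lines = ["##gff-version 3"]
        for m in sorted(self.models, key=lambda m: (m.chrom, min(s for s, _ in m.exons))):
            g_lo = min(s for s, _ in m.exons)
            g_hi = max(e for _, e in m.exons)
            lines.append(
                f"{m.chrom}\tctrdseq_sim\tgene\t{g_lo + 1}\t{g_hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}"
            )
            lines.append(
                f"{m.chrom}\tctrdseq_sim\tmRNA\t{g_lo + 1}\t{g_hi}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}"
            )
            for s, e in sorted(m.exons):
                lines.append(
                    f"{m.chrom}\tctrdseq_sim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon;Parent={m.transcript_id}"
                )
            cds_end_t = m.stop_codon_start_t + (0 if stop_codon_features else 3)
            for s, e in _transcript_range_to_genomic(m, m.cds_start_t, cds_end_t):
                lines.append(
                    f"{m.chrom}\tctrdseq_sim\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}"
                )
            if stop_codon_features:
                for s, e in _transcript_range_to_genomic(
                    m, m.stop_codon_start_t, m.stop_codon_start_t + 3
                ):
                    lines.append(
                        f"{m.chrom}\tctrdseq_sim\tstop_codon\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                        f"ID={m.transcript_id}.stop;Parent={m.transcript_id}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")


def _transcript_range_to_genomic(
    m: TranscriptModel, t_lo: int, t_hi: int
) -> list[tuple[int, int]]:
    """Genomic intervals (sorted) covered by transcript positions [t_lo, t_hi)."""
    out = []
    off = 0
    for s, e in m.exons:
        n = e - s
        lo, hi = max(t_lo, off), min(t_hi, off + n)
        if lo < hi:
            if m.strand == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += n
    return sorted(out)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=tuple(key))
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Simulate transcript structures, genome sequence and expression levels.

    Transcripts are placed on five chromosomes with intergenic gaps; about
    half are split into two exons by an intron, strands are drawn 50/50.
    Start (ATG) and stop (TAA) codons are written into the genome sequence in
    transcript orientation. Fully seed-deterministic.
    """
    rng = _rng(config, 0)
    chroms = [f"chr{i}" for i in range(1, 6)]
    cursors = {c: 0 for c in chroms}
    placed: list[tuple[str, str, str, int, int, int, int, int]] = []
    models: list[TranscriptModel] = []
    expression: dict[str, float] = {}

    lo, hi = config.cds_length_range
    for i in range(config.n_transcripts):
        tid = f"SYN{i + 1:05d}.1"
        gid = f"SYN{i + 1:05d}"
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds_len = 3 * n_codons
        L = config.utr5_length + cds_len + 3 + config.utr3_length
        two_exon = rng.random() < config.two_exon_fraction
        intron = int(rng.integers(60, 400)) if two_exon else 0
        split = int(rng.integers(50, L - 50)) if two_exon else L  # transcript coord

        g0 = cursors[chrom]
        span = L + intron
        if strand == "+":
            exons = [(g0, g0 + split)]
            if two_exon:
                exons.append((g0 + split + intron, g0 + span))
        else:
            exons = [(g0 + span - split, g0 + span)]
            if two_exon:
                exons.append((g0, g0 + span - split - intron))
        cursors[chrom] = g0 + span + int(rng.integers(80, 200))

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_start_t=config.utr5_length,
            stop_codon_start_t=config.utr5_length + cds_len,
        )
        models.append(model)
        expression[tid] = float(
            config.expression_mean
            * rng.lognormal(-config.expression_sigma**2 / 2, config.expression_sigma)
        )

    sequences = {
        c: _BASES[_rng(config, 1, j).integers(0, 4, size=max(cursors[c], 1))].copy()
        for j, c in enumerate(chroms)
    }
    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
    for m in models:
        for t, base in [
            (m.cds_start_t, b"A"), (m.cds_start_t + 1, b"T"), (m.cds_start_t + 2, b"G"),
            (m.stop_codon_start_t, b"T"), (m.stop_codon_start_t + 1, b"A"),
            (m.stop_codon_start_t + 2, b"A"),
        ]:
            g = m.to_genomic(t)
            sequences[m.chrom][g] = base if m.strand == "+" else comp[base]
    return SimulatedTranscriptome(models, sequences, expression, config)


def position_probabilities(
    model: TranscriptModel,
    phi: float,
    stall_weight: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-position 5'P end probabilities for one transcript.

    ``(1 - phi)`` uniform background over the whole transcript plus ``phi``
    on the CTRD component (codon lattice biased by ``frame_bias``, terminal
    boundary positions weighted by ``stall_weight``); see the module
    docstring for the mixture.
    """
    L = model.length_t
    p = np.full(L, (1.0 - phi) / L)
    if phi == 0:
        return p
    cds_lo, cds_hi = model.cds_start_t, model.stop_codon_start_t
    cds_len = cds_hi - cds_lo
    n_codons = cds_len // 3

    s = stall_weight
    beta = (2.0 * s) / (2.0 * s + n_codons) if (s > 0 or n_codons > 0) else 0.0
    # lattice component over CDS positions
    lattice = np.full(cds_len, (1.0 - config.frame_bias) / cds_len)
    lattice[0::3] += config.frame_bias / n_codons
    p[cds_lo:cds_hi] += phi * (1.0 - beta) * lattice
    # boundary component
    for off, w in zip(config.boundary_offsets, config.boundary_split):
        p[model.stop_codon_start_t + off] += phi * beta * w
    return p / p.sum()


def simulate_degradome_library(
    transcriptome: SimulatedTranscriptome,
    genotype: str,
    replicate: int,
    library_id: str | None = None,
) -> ProfileSet:
    """Draw one library of 5'P end-count profiles for a genotype replicate.

    Transcript totals are negative-binomial (mean = expression, size =
    dispersion); positions are multinomial with the mixture probabilities.
    The RNG stream is derived from (seed, genotype index, replicate), so the
    same seed reproduces a library exactly and replicates differ.
    """
    config = transcriptome.config
    phi, s = config.genotype_params(genotype)
    g_index = sorted(config.genotypes).index(genotype)
    rng = _rng(config, 2, g_index, int(replicate))
    library_id = library_id or f"{genotype}_{config.organ}_rep{replicate}"

    profiles = ProfileSet(library_id=library_id)
    for m in transcriptome.models:
        mean = transcriptome.expression[m.transcript_id]
        size = config.dispersion
        total = int(rng.negative_binomial(size, size / (size + mean)))
        p = position_probabilities(m, phi, s, config)
        counts = rng.multinomial(total, p)
        profiles[m.transcript_id] = EndCountProfile(m.transcript_id, library_id, counts)
        profiles.n_assigned += total
    return profiles


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[SimulatedTranscriptome, dict[str, ProfileSet], SampleSheet]:
    """Full experiment: transcriptome + all genotype/replicate libraries + sheet."""
    tx = simulate_transcriptome(config)
    profiles_by_library: dict[str, ProfileSet] = {}
    rows = []
    for genotype in config.genotypes:
        for rep in range(1, config.n_replicates + 1):
            lib = f"{genotype}_{config.organ}_rep{rep}"
            profiles_by_library[lib] = simulate_degradome_library(tx, genotype, rep, lib)
            rows.append((lib, genotype, config.organ, rep, ""))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["library_id", "genotype", "organ", "replicate", "path"])
    )
    return tx, profiles_by_library, sheet


def write_bed(profiles: ProfileSet, models_by_id: Mapping[str, TranscriptModel], path) -> None:
    """Export a simulated library as BED6 (one 1-bp record per read's 5' end)."""
    with open(path, "w") as fh:
        for tid in sorted(profiles):
            m = models_by_id[tid]
            counts = profiles[tid].counts
            for t in np.nonzero(counts)[0]:
                g = m.to_genomic(int(t))
                for k in range(int(counts[t])):
                    fh.write(f"{m.chrom}\t{g}\t{g + 1}\t{tid}.{t}.{k}\t0\t{m.strand}\n")


def expected_tsi(
    model: TranscriptModel,
    phi: float,
    stall_weight: float,
    config: SimulationConfig,
    params: TsiParams = TsiParams(),
) -> float:
    """Noise-free TSI implied by the generating mixture (ratio of expectations)."""
    p = position_probabilities(model, phi, stall_weight, config)
    stop = model.stop_codon_start_t
    b = sum(p[stop + o] for o in params.boundary_offsets)
    f = np.mean([p[stop + o] for o in params.flank_offsets()])
    return float(b / f)


def ground_truth(
    transcriptome: SimulatedTranscriptome,
    tsi_min_reference: float = 3.0,
    fold_decrease: float = 2.0,
    reference_genotype: str | None = None,
) -> pd.DataFrame:
    """Expected TSI per transcript per genotype, with true target flags.

    ``true_reference_target`` marks transcripts whose expected reference TSI
    exceeds the threshold; ``true_target_<genotype>`` marks those whose
    expected TSI additionally drops by at least ``fold_decrease`` in that
    genotype.
    """
    config = transcriptome.config
    genotypes = list(config.genotypes)
    reference = reference_genotype or genotypes[0]
    rows = []
    for m in transcriptome.models:
        e = {g: expected_tsi(m, *config.genotype_params(g), config) for g in genotypes}
        row = {"transcript_id": m.transcript_id, "expression": transcriptome.expression[m.transcript_id]}
        for g in genotypes:
            row[f"expected_tsi_{g}"] = e[g]
        is_ref = e[reference] > tsi_min_reference
        row["true_reference_target"] = is_ref
        for g in genotypes:
            if g == reference:
                continue
            row[f"true_target_{g}"] = bool(
                is_ref and e[g] > 0 and e[reference] / e[g] >= fold_decrease
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_timecourse(
    true_halflife: float,
    times: Iterable[float] = (0.0, 30.0, 60.0, 120.0),
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    n0: float = 1.0,
    transcript_id: str = "SYN_TC",
    condition: str = "cordycepin",
) -> DecayTimeCourse:
    """Exponential decay trajectories with multiplicative lognormal noise.

    ``abundance = n0 * 2^(-t / t_half) * exp(N(0, noise_sd))`` per replicate;
    ``noise_sd = 0`` gives the exact exponential.
    """
    if true_halflife <= 0:
        raise ValueError("true_halflife must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(list(times), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(3,)))
    ab = {}
    for r in range(1, n_replicates + 1):
        clean = n0 * np.power(2.0, -t / true_halflife)
        noise = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else 0.0
        ab[r] = clean * np.exp(noise)
    return DecayTimeCourse(transcript_id, condition, t, ab)
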