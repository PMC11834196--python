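"""Annotation parsing, 5'P end counting and tabular I/O.

This module turns a GFF3 annotation into :class:`TranscriptModel` objects
(transcript-strand coordinates, CDS and stop-codon location), assigns aligned
reads' biological 5' ends to transcript positions, and round-trips the
pipeline's tables through TSV.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open. GFF3's 1-based closed
intervals are converted on parse; BED intervals are consumed natively.
Transcript coordinates run 5'->3' on the transcript strand, i.e. position 0
of a minus-strand transcript is the *rightmost* genomic base of its last
(genomically) exon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "EndCountProfile",
    "SampleSheet",
    "ProfileSet",
    "GffParseError",
    "SchemaError",
    "parse_gff",
    "load_5p_ends",
    "build_end_index",
    "read_table",
    "write_table",
    "export_bedgraph",
]


class GffParseError(ValueError):
    """Raised when the GFF3 input cannot be parsed; names the offending line."""


class SchemaError(ValueError):
    """Raised when a table is missing required columns."""


@dataclass
class TranscriptModel:
    """A transcript's exon structure and CDS geometry in transcript coordinates.

    Parameters
    ----------
    exons
        Genomic intervals (0-based, half-open), ordered 5'->3' on the
        *transcript* strand: ascending starts for ``+``, descending for ``-``.
    cds_start_t
        Transcript coordinate of the first coding nucleotide.
    stop_codon_start_t
        Transcript coordinate of the first nucleotide of the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int
    stop_codon_start_t: int
    frame_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        starts = [s for s, _ in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ValueError(f"{self.transcript_id}: exons not 5'->3' on + strand")
        else:
            if starts != sorted(starts, reverse=True):
                raise ValueError(f"{self.transcript_id}: exons not 5'->3' on - strand")
        if not (0 <= self.cds_start_t < self.stop_codon_start_t <= self.length_t - 3):
            raise ValueError(
                f"{self.transcript_id}: CDS geometry out of bounds "
                f"(cds_start_t={self.cds_start_t}, stop={self.stop_codon_start_t}, "
                f"length={self.length_t})"
            )
        if (self.stop_codon_start_t - self.cds_start_t) % 3 != 0:
            # Flag, do not discard: the transcript is excluded from TSI later.
            object.__setattr__(self, "frame_ok", False)
            logger.warning(
                "%s: coding length not a multiple of 3; flagged out-of-frame",
                self.transcript_id,
            )

    @property
    def length_t(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        """Coding length excluding the stop codon."""
        return self.stop_codon_start_t - self.cds_start_t

    def to_transcript(self, g: int) -> int | None:
        """Map a genomic base to its transcript coordinate (None if intronic/outside)."""
        off = 0
        for s, e in self.exons:
            if s <= g < e:
                return off + (g - s if self.strand == "+" else e - 1 - g)
            off += e - s
        return None

    def to_genomic(self, t: int) -> int:
        """Map a transcript coordinate back to its genomic base."""
        if not 0 <= t < self.length_t:
            raise IndexError(f"transcript position {t} outside [0,{self.length_t})")
        off = 0
        for s, e in self.exons:
            n = e - s
            if t < off + n:
                d = t - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise AssertionError("unreachable")


@dataclass
class EndCountProfile:
    """Per-library vector of 5'P read-end counts along one transcript."""

    transcript_id: str
    library_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SampleSheet:
    """Mapping of libraries to genotype/organ/replicate (and optional file path)."""

    frame: pd.DataFrame

    REQUIRED = ("library_id", "genotype", "organ", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        if "path" not in self.frame.columns:
            self.frame = self.frame.assign(path="")
        key = self.frame[["genotype", "organ", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (genotype, organ, replicate): {dup}")
        if self.frame["library_id"].duplicated().any():
            raise ValueError("duplicate library_id in sample sheet")

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(read_table(path, required=cls.REQUIRED))

    def write(self, path: str | Path) -> None:
        write_table(self.frame, path)

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["genotype"]))

    def libraries(self, genotype: str | None = None, organ: str | None = None) -> list[str]:
        df = self.frame
        if genotype is not None:
            df = df[df["genotype"] == genotype]
        if organ is not None:
            df = df[df["organ"] == organ]
        return df["library_id"].tolist()

    def genotype_of(self, library_id: str) -> str:
        row = self.frame[self.frame["library_id"] == library_id]
        if row.empty:
            raise KeyError(f"library {library_id!r} not in sample sheet")
        return str(row["genotype"].iloc[0])


class ProfileSet(dict):
    """``transcript_id -> EndCountProfile`` mapping with read-assignment bookkeeping.

    Behaves as a plain dict; ``n_assigned``/``n_discarded`` record the fate of
    every input read so that ``n_assigned + n_discarded == total reads``
    (reads hitting several overlapping transcripts count once as assigned).
    """

    def __init__(self, *args, library_id: str = "", **kwargs):
        super().__init__(*args, **kwargs)
        self.library_id = library_id
        self.n_assigned = 0
        self.n_discarded = 0


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

_MRNA_TYPES = {"mRNA", "transcript"}


def _validate_gff_lines(path: str | Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GffParseError(f"{path}: malformed GFF3 record at line {i}")


def parse_gff(
    path_gff: str | Path,
    path_fasta: str | Path | None = None,
) -> list[TranscriptModel]:
    """Parse a GFF3 annotation into :class:`TranscriptModel` objects.

    One model is produced per mRNA feature having at least one CDS child.
    The stop codon is located from explicit ``stop_codon`` features when
    present; otherwise the last three nucleotides of the concatenated CDS are
    taken as the stop codon (both common GFF dialects therefore work).

    ``path_fasta`` is accepted for interface completeness (sequence-aware
    extensions); the coordinate model does not require it.
    """
    import gffutils

    _validate_gff_lines(path_gff)
    try:
        db = gffutils.create_db(
            str(path_gff),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise GffParseError(f"{path_gff}: {exc}") from exc

    mrna_ids = {f.id for t in _MRNA_TYPES for f in db.features_of_type(t)}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not any(p in mrna_ids for p in parents):
            warnings.warn(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no mRNA parent; skipped"
            )

    models: list[TranscriptModel] = []
    for mtype in _MRNA_TYPES:
        for mrna in db.features_of_type(mtype, order_by="start"):
            cds_feats = list(db.children(mrna, featuretype="CDS"))
            if not cds_feats:
                warnings.warn(f"mRNA {mrna.id} has no CDS; skipped")
                continue
            exon_feats = list(db.children(mrna, featuretype="exon"))
            if exon_feats:
                exons = sorted((f.start - 1, f.end) for f in exon_feats)
            else:
                exons = [(mrna.start - 1, mrna.end)]
            strand = mrna.strand
            if strand not in ("+", "-"):
                warnings.warn(f"mRNA {mrna.id} without strand; skipped")
                continue
            if strand == "-":
                exons = exons[::-1]
            model_stub = TranscriptModel.__new__(TranscriptModel)
            # build a throwaway mapper for genomic->transcript conversion
            object.__setattr__(model_stub, "strand", strand)
            object.__setattr__(model_stub, "exons", tuple(exons))
            to_t = TranscriptModel.to_transcript.__get__(model_stub)

            cds_iv = sorted((f.start - 1, f.end) for f in cds_feats)
            cds_len = sum(e - s for s, e in cds_iv)
            first_cds_g = cds_iv[0][0] if strand == "+" else cds_iv[-1][1] - 1
            cds_start_t = to_t(first_cds_g)
            stop_feats = list(db.children(mrna, featuretype="stop_codon"))
            if stop_feats:
                stop_iv = sorted((f.start - 1, f.end) for f in stop_feats)
                first_stop_g = stop_iv[0][0] if strand == "+" else stop_iv[-1][1] - 1
                stop_start_t = to_t(first_stop_g)
            else:
                # CDS assumed to include the stop codon
                stop_start_t = cds_start_t + cds_len - 3
            if cds_start_t is None or stop_start_t is None:
                warnings.warn(f"mRNA {mrna.id}: CDS outside exons; skipped")
                continue
            gene_id = (mrna.attributes.get("Parent") or [mrna.id])[0]
            try:
                models.append(
                    TranscriptModel(
                        transcript_id=mrna.id,
                        gene_id=gene_id,
                        chrom=mrna.seqid,
                        strand=strand,
                        exons=tuple(exons),
                        cds_start_t=cds_start_t,
                        stop_codon_start_t=stop_start_t,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"mRNA {mrna.id}: {exc}; skipped")
    return models


# ---------------------------------------------------------------------------
# 5'P end loading
# ---------------------------------------------------------------------------

def build_end_index(models: Iterable[TranscriptModel]):
    """Interval index ``(chrom, strand) -> tree`` for genomic->transcript lookup.

    Each tree interval stores ``(transcript_id, transcript_offset_of_exon)``;
    the transcript position of base ``g`` inside exon ``[s, e)`` is
    ``off + (g - s)`` on ``+`` and ``off + (e - 1 - g)`` on ``-``.
    """
    index: dict[tuple[str, str], IntervalTree] = {}
    for m in models:
        tree = index.setdefault((m.chrom, m.strand), IntervalTree())
        off = 0
        for s, e in m.exons:
            tree.addi(s, e, (m.transcript_id, off))
            off += e - s
    return index


def _assign_end(index, models_by_id, chrom, strand, g, profiles: ProfileSet) -> bool:
    tree = index.get((chrom, strand))
    if tree is None:
        return False
    hits = tree[g]
    if not hits:
        return False
    for iv in hits:
        tid, off = iv.data
        m = models_by_id[tid]
        t = off + (g - iv.begin if strand == "+" else iv.end - 1 - g)
        prof = profiles.get(tid)
        if prof is None:
            prof = EndCountProfile(tid, profiles.library_id, np.zeros(m.length_t, dtype=np.int64))
            profiles[tid] = prof
        prof.counts[t] += 1
    return True


def load_5p_ends(
    path: str | Path,
    models: Iterable[TranscriptModel],
    library_id: str,
) -> ProfileSet:
    """Count biological 5' read ends per transcript position from BED6 or BAM.

    The biological 5' end of a read is its leftmost aligned genomic base for
    ``+`` strand alignments and the rightmost for ``-`` strand alignments.
    Each end increments every transcript whose strand matches and whose exons
    contain that base; reads matching no transcript go to ``n_discarded``.
    """
    models = list(models)
    models_by_id = {m.transcript_id: m for m in models}
    index = build_end_index(models)
    profiles = ProfileSet(library_id=library_id)

    path = Path(path)
    if path.suffix.lower() == ".bam":
        import pysam

        bam = pysam.AlignmentFile(str(path), "rb")
        if not bam.has_index():
            raise ValueError(
                f"{path}: BAM must be coordinate-sorted and indexed (samtools sort && index)"
            )
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = "-" if read.is_reverse else "+"
            g = read.reference_end - 1 if read.is_reverse else read.reference_start
            ok = _assign_end(index, models_by_id, read.reference_name, strand, g, profiles)
            profiles.n_assigned += ok
            profiles.n_discarded += not ok
        bam.close()
    else:
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
        for chrom, start, end, strand in bed.itertuples(index=False):
            g = start if strand == "+" else end - 1
            ok = _assign_end(index, models_by_id, chrom, strand, g, profiles)
            profiles.n_assigned += ok
            profiles.n_discarded += not ok
    return profiles


def export_bedgraph(
    profiles: Mapping[str, EndCountProfile],
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    path: str | Path,
) -> None:
    """Write per-base genomic 5'P end counts as bedGraph (one line per nonzero base)."""
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    rows = []
    for tid, prof in profiles.items():
        m = models[tid]
        for t in np.nonzero(prof.counts)[0]:
            g = m.to_genomic(int(t))
            rows.append((m.chrom, g, g + 1, int(prof.counts[t])))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_profiles(profiles: Mapping[str, EndCountProfile], path: str | Path) -> None:
    """Write a library's profiles as sparse TSV (transcript_id, position, count)."""
    rows = []
    for tid in sorted(profiles):
        counts = profiles[tid].counts
        for t in np.nonzero(counts)[0]:
            rows.append((tid, int(t), int(counts[t])))
    write_table(pd.DataFrame(rows, columns=["transcript_id", "position", "count"]), path)


def read_profiles(
    path: str | Path,
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    library_id: str,
) -> ProfileSet:
    """Read sparse profile TSV back into dense per-transcript count vectors."""
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    df = read_table(path, required=("transcript_id", "position", "count"))
    profiles = ProfileSet(library_id=library_id)
    for tid, g in df.groupby("transcript_id"):
        m = models.get(str(tid))
        if m is None:
            warnings.warn(f"{path}: transcript {tid} not in annotation; skipped")
            continue
        counts = np.zeros(m.length_t, dtype=np.int64)
        counts[g["position"].to_numpy()] = g["count"].to_numpy()
        profiles[str(tid)] = EndCountProfile(str(tid), library_id, counts)
        profiles.n_assigned += int(g["count"].sum())
    return profiles


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline table as TSV (header + tab-separated rows)."""
    table.to_csv(path, sep="\t", index=False)


def read_table(
    path: str | Path,
    required: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a TSV table, enforcing required columns; extra columns are kept."""
    df = pd.read_csv(path, sep="\t")
    required = list(required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if required and extra:
        warnings.warn(f"{path}: extra columns preserved: {extra}")
    return df
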