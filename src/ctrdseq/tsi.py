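"""Terminational Stalling Index (TSI).

The TSI is a per-transcript proxy of co-translational decay activity: the
ratio of the number of 5'P read ends at the ribosome boundary (16-17 nt
upstream of the stop codon, i.e. relative positions {-17, -16}) to the mean
per-position number of 5'P read ends within the flanking 100 nt.

Two conventions matter and are fixed here:

* the boundary statistic is a SUM over the boundary positions while the
  flank statistic is a PER-POSITION mean; a positionally uniform profile
  therefore has an expected TSI of 2.0 (two boundary positions), and the
  target-calling threshold of 3 sits above that background. A mean-based
  boundary statistic is available via ``boundary_stat="mean"``.
* the "flanking 100 nt" are the 50 positions on each side of the boundary
  block, excluding the boundary itself: r in [-67, -18] union [-15, +34]
  under the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import EndCountProfile, SampleSheet, TranscriptModel

__all__ = ["TsiParams", "TsiRecord", "TsiTable", "compute_tsi", "tsi_table"]


@dataclass(frozen=True)
class TsiParams:
    """Window geometry and coverage thresholds for the TSI.

    ``flank_half_width`` positions are taken on each side of the boundary
    block (100 flank positions total under the defaults). Records from
    transcripts that cannot hold the full window are excluded unless
    ``truncate_flank`` is set, in which case at least ``min_flank_positions``
    in-bounds flank positions are required.
    """

    boundary_offsets: tuple[int, ...] = (-17, -16)
    flank_half_width: int = 50
    min_flank_positions: int = 100
    min_total_reads: int = 10
    boundary_stat: str = "sum"
    truncate_flank: bool = False

    def __post_init__(self) -> None:
        if not self.boundary_offsets:
            raise ValueError("boundary_offsets must be non-empty")
        if self.boundary_stat not in ("sum", "mean"):
            raise ValueError("boundary_stat must be 'sum' or 'mean'")
        if set(self.boundary_offsets) & set(self.flank_offsets()):
            raise ValueError("flank positions must exclude the boundary")

    def flank_offsets(self) -> tuple[int, ...]:
        bmin, bmax = min(self.boundary_offsets), max(self.boundary_offsets)
        up = range(bmin - self.flank_half_width, bmin)
        down = range(bmax + 1, bmax + 1 + self.flank_half_width)
        return tuple(up) + tuple(down)


@dataclass
class TsiRecord:
    """One transcript x library TSI measurement.

    ``tsi`` is NaN when undefined; ``status`` records why
    (``zero_flank``, ``low_coverage``, ``window_out_of_bounds``).
    """

    transcript_id: str
    library_id: str
    boundary_count: float
    flank_mean: float
    tsi: float
    status: str = "ok"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.tsi)


def compute_tsi(
    profile: EndCountProfile,
    model: TranscriptModel,
    params: TsiParams = TsiParams(),
) -> TsiRecord:
    """Compute the TSI of one transcript in one library.

    A uniform profile with c reads at every window position yields
    ``boundary_count = 2c``, ``flank_mean = c`` and hence ``tsi = 2.0``
    under the default boundary-sum convention.
    """
    stop = model.stop_codon_start_t
    counts = profile.counts
    L = model.length_t

    b_pos = np.array([stop + o for o in params.boundary_offsets])
    f_pos = np.array([stop + o for o in params.flank_offsets()])
    all_pos = np.concatenate([b_pos, f_pos])
    in_bounds = (all_pos >= 0) & (all_pos < L)

    def undefined(status: str, bc: float = np.nan, fm: float = np.nan) -> TsiRecord:
        return TsiRecord(model.transcript_id, profile.library_id, bc, fm, np.nan, status)

    if not in_bounds.all():
        if not params.truncate_flank or not ((b_pos >= 0) & (b_pos < L)).all():
            return undefined("window_out_of_bounds")
        f_pos = f_pos[(f_pos >= 0) & (f_pos < L)]
        if f_pos.size < params.min_flank_positions:
            return undefined("window_out_of_bounds")

    boundary_count = float(counts[b_pos].sum())
    if params.boundary_stat == "mean":
        boundary_count_stat = boundary_count / len(b_pos)
    else:
        boundary_count_stat = boundary_count
    flank_mean = float(counts[f_pos].mean())

    if counts.sum() < params.min_total_reads:
        return undefined("low_coverage", boundary_count, flank_mean)
    if flank_mean == 0:
        return undefined("zero_flank", boundary_count, flank_mean)
    return TsiRecord(
        model.transcript_id,
        profile.library_id,
        boundary_count,
        flank_mean,
        boundary_count_stat / flank_mean,
    )


@dataclass
class TsiTable:
    """Long table of per-library TSI records plus per-genotype means.

    ``records`` has one row per (transcript, library); ``genotype_means``
    one row per (transcript, genotype) with ``mean_tsi`` averaged over
    replicates with a defined TSI — at least 2 defined replicates are
    required, otherwise the genotype mean is NaN.
    """

    records: pd.DataFrame
    genotype_means: pd.DataFrame

    RECORD_COLUMNS = (
        "transcript_id",
        "library_id",
        "genotype",
        "organ",
        "replicate",
        "boundary_count",
        "flank_mean",
        "tsi",
        "status",
    )
    MEAN_COLUMNS = ("transcript_id", "genotype", "mean_tsi", "n_replicates_defined")

    def mean_tsi(self, genotype: str) -> pd.Series:
        """Per-transcript mean TSI of one genotype, indexed by transcript_id."""
        df = self.genotype_means
        sub = df[df["genotype"] == genotype]
        if sub.empty:
            raise KeyError(f"genotype {genotype!r} not in table")
        return sub.set_index("transcript_id")["mean_tsi"]

    def defined_tsi(self, genotype: str) -> pd.Series:
        """Defined genotype means only (NaN dropped)."""
        return self.mean_tsi(genotype).dropna()


def _genotype_means(records: pd.DataFrame, min_defined: int = 2) -> pd.DataFrame:
    def agg(g: pd.DataFrame) -> pd.Series:
        defined = g["tsi"].dropna()
        mean = defined.mean() if len(defined) >= min_defined else np.nan
        return pd.Series({"mean_tsi": mean, "n_replicates_defined": len(defined)})

    out = (
        records.groupby(["transcript_id", "genotype"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_replicates_defined"] = out["n_replicates_defined"].astype(int)
    return out


def tsi_table(
    profiles_by_library: Mapping[str, Mapping[str, EndCountProfile]],
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    sample_sheet: SampleSheet,
    params: TsiParams = TsiParams(),
) -> TsiTable:
    """Compute TSI for every (transcript, library) and aggregate per genotype.

    Out-of-frame transcripts (coding length not a multiple of 3) are excluded
    with a warning; genotypes with no usable library raise.
    """
    import warnings as _warnings

    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    usable = {tid: m for tid, m in models.items() if m.frame_ok}
    n_bad = len(models) - len(usable)
    if n_bad:
        _warnings.warn(f"{n_bad} out-of-frame transcript(s) excluded from TSI")

    for genotype in sample_sheet.genotypes:
        libs = sample_sheet.libraries(genotype=genotype)
        if not any(lib in profiles_by_library for lib in libs):
            raise ValueError(f"genotype {genotype!r} has no usable library")

    rows = []
    meta = sample_sheet.frame.set_index("library_id")
    for lib, profiles in profiles_by_library.items():
        genotype = meta.loc[lib, "genotype"]
        organ = meta.loc[lib, "organ"]
        replicate = meta.loc[lib, "replicate"]
        for tid, prof in profiles.items():
            m = usable.get(tid)
            if m is None:
                continue
            rec = compute_tsi(prof, m, params)
            rows.append(
                (tid, lib, genotype, organ, replicate,
                 rec.boundary_count, rec.flank_mean, rec.tsi, rec.status)
            )
    records = pd.DataFrame(rows, columns=list(TsiTable.RECORD_COLUMNS))
    return TsiTable(records, _genotype_means(records))
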