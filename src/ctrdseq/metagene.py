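"""Stop-codon-anchored metagene profiles and 3-nt periodicity.

The hallmark of co-translational mRNA decay is an over-accumulation of 5'P
read ends 16-17 nt upstream of stop codons (the footprint of the terminating
ribosome shielding the mRNA from the tracking 5'->3' exoribonuclease) and a
three-nucleotide periodicity of 5'P ends along the CDS. Both signals are
quantified here from per-transcript end-count profiles.

Anchor convention: relative position r = 0 is the FIRST nucleotide of the
stop codon, so the ribosome boundary "16-17 nt upstream" is r in {-17, -16}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import EndCountProfile, TranscriptModel

__all__ = [
    "MetageneMatrix",
    "FramePeriodicity",
    "MetageneError",
    "aggregate_metagene",
    "periodicity_score",
]


class MetageneError(ValueError):
    """No transcript contributed to the requested metagene window."""


def _as_model_map(models) -> Mapping[str, TranscriptModel]:
    if isinstance(models, Mapping):
        return models
    return {m.transcript_id: m for m in models}


@dataclass
class MetageneMatrix:
    """Counts aggregated across transcripts relative to a common anchor."""

    anchor: str
    rel_positions: np.ndarray
    values: np.ndarray
    n_transcripts: int
    normalize: str = "off"

    def peak_offset(self) -> int:
        """Relative position of the global maximum (negative = upstream)."""
        return int(self.rel_positions[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_position": self.rel_positions, "value": self.values}
        )


@dataclass
class FramePeriodicity:
    """Reading-frame distribution and dominant period of CDS 5'P ends."""

    frame_fractions: tuple[float, float, float]
    dominant_period: int | None
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined:
            total = float(sum(self.frame_fractions))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frame fractions sum to {total}, expected 1")


def aggregate_metagene(
    profiles: Mapping[str, EndCountProfile],
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    anchor: str = "stop",
    w_up: int = 100,
    w_down: int = 100,
    normalize: str = "off",
) -> MetageneMatrix:
    """Aggregate 5'P end counts in a window anchored at the stop (or start) codon.

    Parameters
    ----------
    anchor
        ``"stop"`` anchors r=0 at the first nucleotide of the stop codon,
        ``"start"`` at the first nucleotide of the CDS.
    normalize
        ``"off"`` sums raw counts (total is conserved); ``"per_transcript"``
        divides each transcript's window by its own window sum before
        averaging across transcripts (zero-sum windows are skipped), removing
        the abundance bias of the raw sum.

    Transcripts whose window extends past the transcript bounds contribute
    only their in-bounds positions.
    """
    if w_up < 1 or w_down < 1:
        raise ValueError("w_up and w_down must be >= 1")
    if anchor not in ("stop", "start"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if normalize not in ("off", "per_transcript"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    models = _as_model_map(models)

    rel = np.arange(-w_up, w_down + 1)
    total = np.zeros(rel.size, dtype=float)
    coverage = np.zeros(rel.size, dtype=np.int64)
    n_used = 0
    for tid, prof in profiles.items():
        m = models[tid]
        a = m.stop_codon_start_t if anchor == "stop" else m.cds_start_t
        lo, hi = a - w_up, a + w_down  # inclusive transcript positions
        ilo, ihi = max(lo, 0), min(hi, m.length_t - 1)
        if ilo > ihi:
            continue
        window = prof.counts[ilo : ihi + 1].astype(float)
        sl = slice(ilo - lo, ihi - lo + 1)
        if normalize == "per_transcript":
            wsum = window.sum()
            if wsum == 0:
                continue
            window = window / wsum
        total[sl] += window
        coverage[sl] += 1
        n_used += 1
    if n_used == 0:
        raise MetageneError("no transcript overlaps the metagene window")
    if normalize == "per_transcript":
        values = np.divide(total, coverage, out=np.zeros_like(total), where=coverage > 0)
    else:
        values = total
    return MetageneMatrix(anchor, rel, values, n_used, normalize)


def periodicity_score(
    profiles: Mapping[str, EndCountProfile],
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    min_cds_length: int = 30,
    max_lag: int = 10,
) -> FramePeriodicity:
    """Quantify 3-nt periodicity of 5'P ends within the CDS.

    Counts are pooled across transcripts by position relative to the CDS
    start (stop codon excluded). ``frame_fractions[f]`` is the fraction of
    pooled counts at positions with ``(i - cds_start) mod 3 == f``;
    ``dominant_period`` is the lag in ``[2, max_lag]`` maximizing the
    mean-subtracted autocorrelation of the pooled profile.
    """
    models = _as_model_map(models)
    max_len = 0
    for tid in profiles:
        m = models[tid]
        if m.cds_length >= min_cds_length:
            max_len = max(max_len, m.cds_length)
    if max_len == 0:
        warnings.warn("no transcript with CDS length above the minimum; periodicity undefined")
        return FramePeriodicity((np.nan, np.nan, np.nan), None, defined=False)

    pooled = np.zeros(max_len, dtype=float)
    for tid, prof in profiles.items():
        m = models[tid]
        if m.cds_length < min_cds_length:
            continue
        seg = prof.counts[m.cds_start_t : m.stop_codon_start_t]
        pooled[: seg.size] += seg
    if pooled.sum() == 0:
        warnings.warn("all-zero CDS profile; periodicity undefined")
        return FramePeriodicity((np.nan, np.nan, np.nan), None, defined=False)

    frames = np.array([pooled[f::3].sum() for f in range(3)])
    fractions = tuple(frames / frames.sum())

    x = pooled - pooled.mean()
    lags = range(2, min(max_lag, pooled.size - 1) + 1)
    ac = {k: float(np.dot(x[:-k], x[k:])) for k in lags}
    dominant = max(ac, key=ac.get)
    return FramePeriodicity(fractions, int(dominant))
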