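"""mRNA half-life estimation from transcription-arrest time courses.

After transcription arrest (cordycepin chase), the abundance of a transcript
decaying with first-order kinetics follows N(t) = N0 * exp(-lambda * t), so
ln N is linear in time. Each replicate trajectory is fitted by least squares
on the log scale; the half-life is t1/2 = ln 2 / lambda, reported as
mean +/- SD over replicates. Conditions (e.g. cordycepin vs cordycepin+PAP)
are compared with a Welch t-test on the per-replicate half-lives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayTimeCourse",
    "ReplicateFit",
    "DecayFit",
    "HalfLifeComparison",
    "normalize_timecourse",
    "fit_halflife",
    "compare_halflives",
    "read_timecourses",
]

LN2 = float(np.log(2.0))


@dataclass
class DecayTimeCourse:
    """Abundance of one transcript under one condition over a chase.

    ``abundance`` maps replicate index to a vector aligned with ``times``
    (minutes, strictly increasing, starting at 0). Abundances are positive
    concentrations (ddPCR-style units).
    """

    transcript_id: str
    condition: str
    times: np.ndarray
    abundance: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        if self.times[0] != 0:
            raise ValueError("first time point must be 0")
        self.abundance = {int(r): np.asarray(v, dtype=float) for r, v in self.abundance.items()}
        for r, v in self.abundance.items():
            if v.shape != self.times.shape:
                raise ValueError(f"replicate {r}: abundance/times length mismatch")
            if v[0] <= 0:
                raise ValueError(f"replicate {r}: abundance at t=0 must be positive")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.transcript_id, self.condition, r, t, a)
            for r, v in sorted(self.abundance.items())
            for t, a in zip(self.times, v)
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "condition", "replicate", "time_min", "abundance"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DecayTimeCourse":
        tids = df["transcript_id"].unique()
        conds = df["condition"].unique()
        if len(tids) != 1 or len(conds) != 1:
            raise ValueError("frame must hold exactly one (transcript, condition)")
        times = np.sort(df["time_min"].unique())
        ab = {}
        for r, g in df.groupby("replicate"):
            g = g.sort_values("time_min")
            if not np.array_equal(g["time_min"].to_numpy(dtype=float), times):
                raise ValueError(f"replicate {r}: incomplete time grid")
            ab[int(r)] = g["abundance"].to_numpy(dtype=float)
        return cls(str(tids[0]), str(conds[0]), times, ab)


def normalize_timecourse(
    tc: DecayTimeCourse,
    reference: DecayTimeCourse | None = None,
) -> DecayTimeCourse:
    """Scale each replicate to its own t=0 abundance (idempotent).

    When a stable reference transcript's time course is supplied, each
    replicate is first divided by the reference trajectory of the same
    replicate (controls for global extraction/efficiency drift), then
    re-anchored to t=0.
    """
    ab = {}
    for r, v in tc.abundance.items():
        v = v.copy()
        if reference is not None:
            if r not in reference.abundance:
                raise ValueError(f"reference lacks replicate {r}")
            ref = reference.abundance[r]
            if np.any(ref <= 0):
                raise ValueError("reference trajectory must be positive")
            v = v / ref
        if v[0] <= 0:
            raise ValueError(f"replicate {r}: zero abundance at t=0")
        ab[r] = v / v[0]
    return DecayTimeCourse(tc.transcript_id, tc.condition, tc.times.copy(), ab)


@dataclass
class ReplicateFit:
    replicate: int
    decay_rate: float  # lambda, min^-1
    half_life: float  # ln2/lambda; inf when non-decaying
    r_squared: float
    n_points: int
    non_decaying: bool


@dataclass
class DecayFit:
    """Per-replicate exponential fits with the across-replicate summary."""

    transcript_id: str
    condition: str
    replicate_fits: list[ReplicateFit]
    half_life_mean: float
    half_life_sd: float

    @property
    def half_lives(self) -> np.ndarray:
        return np.array(
            [f.half_life for f in self.replicate_fits if not f.non_decaying], dtype=float
        )

    def summary(self) -> str:
        lines = [
            f"Half-life fit: {self.transcript_id} [{self.condition}]",
            f"  t1/2 = {self.half_life_mean:.1f} +/- {self.half_life_sd:.1f} min "
            f"(n = {len(self.half_lives)} replicates)",
        ]
        for f in self.replicate_fits:
            tag = "non-decaying" if f.non_decaying else f"t1/2 = {f.half_life:.1f} min"
            lines.append(
                f"  replicate {f.replicate}: lambda = {f.decay_rate:.4f}/min, "
                f"{tag}, r^2 = {f.r_squared:.3f} ({f.n_points} points)"
            )
        return "\n".join(lines)


def _fit_replicate(times: np.ndarray, values: np.ndarray, replicate: int) -> ReplicateFit | None:
    keep = values > 0
    if not keep.all():
        warnings.warn(
            f"replicate {replicate}: {int((~keep).sum())} non-positive point(s) dropped"
        )
    t, y = times[keep], np.log(values[keep])
    if t.size < 3:
        warnings.warn(f"replicate {replicate}: <3 usable points; fit undefined")
        return None
    slope, intercept = np.polyfit(t, y, 1)
    lam = -float(slope)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    non_decaying = lam <= 1e-12  # tolerance absorbs float noise of a flat fit
    half_life = LN2 / lam if not non_decaying else np.inf
    return ReplicateFit(replicate, lam, half_life, r2, int(t.size), non_decaying)


def fit_halflife(tc: DecayTimeCourse) -> DecayFit:
    """Fit first-order decay per replicate and summarize across replicates.

    The fit is ordinary least squares of ln(abundance) on time; scaling a
    replicate by any constant only shifts the intercept, so normalization
    does not change the rate. Replicates with lambda <= 0 are flagged
    non-decaying and excluded from the half-life mean.
    """
    fits = []
    for r in sorted(tc.abundance):
        f = _fit_replicate(tc.times, tc.abundance[r], r)
        if f is not None:
            fits.append(f)
    hl = np.array([f.half_life for f in fits if not f.non_decaying], dtype=float)
    mean = float(hl.mean()) if hl.size else np.nan
    sd = float(hl.std(ddof=1)) if hl.size > 1 else np.nan
    if any(f.non_decaying for f in fits):
        warnings.warn(f"{tc.transcript_id} [{tc.condition}]: non-decaying replicate(s) flagged")
    return DecayFit(tc.transcript_id, tc.condition, fits, mean, sd)


@dataclass
class HalfLifeComparison:
    p_value: float
    statistic: float
    n_a: int
    n_b: int


def compare_halflives(fit_a: DecayFit, fit_b: DecayFit, equal_var: bool = False) -> HalfLifeComparison:
    """Two-sided t-test (Welch by default) on per-replicate half-lives."""
    a, b = fit_a.half_lives, fit_b.half_lives
    if a.size < 2 or b.size < 2:
        warnings.warn("fewer than 2 usable replicate fits; p-value undefined")
        return HalfLifeComparison(np.nan, np.nan, int(a.size), int(b.size))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return HalfLifeComparison(float(res.pvalue), float(res.statistic), int(a.size), int(b.size))


def read_timecourses(path) -> list[DecayTimeCourse]:
    """Read a tidy time-course TSV (transcript_id, condition, replicate,
    time_min, abundance) into one DecayTimeCourse per (transcript, condition)."""
    from .annotation_io import read_table

    df = read_table(
        path, required=("transcript_id", "condition", "replicate", "time_min", "abundance")
    )
    return [
        DecayTimeCourse.from_frame(g)
        for _, g in df.groupby(["transcript_id", "condition"], sort=True)
    ]
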