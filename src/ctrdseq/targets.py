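"""Target calling, distribution shifts and gene-set overlap statistics.

CTRD targets are defined operationally: a transcript is a reference-genotype
CTRD target when its mean TSI in the reference exceeds a threshold (default
3, strictly), and a target of a given nuclease pathway when its TSI in the
corresponding mutant is at least ``fold_decrease`` times (default 2) lower
than in the reference. Distribution shifts between genotypes are tested with
a Wilcoxon test (paired signed-rank over the common transcript set by
default) and set overlaps with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tsi import TsiTable

__all__ = [
    "TargetCallParams",
    "OverlapResult",
    "VennPartition",
    "WilcoxonShift",
    "call_reference_targets",
    "call_mutant_targets",
    "venn_partition",
    "wilcoxon_shift",
    "hypergeometric_overlap",
    "intersect_external_list",
    "sample_concordance",
    "percentage",
]


@dataclass(frozen=True)
class TargetCallParams:
    reference_genotype: str = "Col0"
    tsi_min_reference: float = 3.0
    fold_decrease: float = 2.0

    def __post_init__(self) -> None:
        if self.tsi_min_reference <= 0:
            raise ValueError("tsi_min_reference must be > 0")
        if self.fold_decrease < 1:
            raise ValueError("fold_decrease must be >= 1")


def percentage(part: float, whole: float) -> float:
    """Percentage of ``part`` in ``whole`` (e.g. targets among analysed transcripts)."""
    if whole == 0:
        raise ZeroDivisionError("empty universe")
    return 100.0 * part / whole


def call_reference_targets(
    table: TsiTable,
    params: TargetCallParams = TargetCallParams(),
) -> set[str]:
    """Transcripts whose reference mean TSI strictly exceeds the threshold.

    Transcripts with an undefined reference mean are excluded; an empty
    result is a warning, not an error.
    """
    means = table.mean_tsi(params.reference_genotype)
    hits = set(means.index[means > params.tsi_min_reference])
    if not hits:
        warnings.warn("no transcript exceeds the reference TSI threshold")
    return hits


def call_mutant_targets(
    table: TsiTable,
    mutant_genotype: str,
    params: TargetCallParams = TargetCallParams(),
) -> pd.DataFrame:
    """Call mutant-pathway targets among the reference CTRD targets.

    Returns one row per reference target: reference and mutant mean TSI,
    ``fold_change = reference/mutant`` and ``is_target``. A mutant mean of 0
    with a positive reference mean is a target with infinite fold change; an
    undefined mutant mean leaves the fold undefined (flagged, not a target).
    """
    if mutant_genotype not in set(table.genotype_means["genotype"]):
        raise KeyError(f"genotype {mutant_genotype!r} not in TSI table")
    ref_targets = call_reference_targets(table, params)
    ref = table.mean_tsi(params.reference_genotype)
    mut = table.mean_tsi(mutant_genotype)

    rows = []
    for tid in sorted(ref_targets):
        r = float(ref.loc[tid])
        m = float(mut.get(tid, np.nan))
        if np.isnan(m):
            fold, is_target, flag = np.nan, False, "mutant_undefined"
        elif m == 0:
            fold, is_target, flag = np.inf, True, "mutant_zero"
        else:
            fold = r / m
            is_target, flag = fold >= params.fold_decrease, ""
        rows.append((tid, r, m, fold, is_target, flag))
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "reference_mean_tsi", "mutant_mean_tsi",
                 "fold_change", "is_target", "flag"],
    )


@dataclass
class VennPartition:
    only_a: set
    only_b: set
    common: set

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.only_b), len(self.common))


def venn_partition(set_a: Iterable, set_b: Iterable) -> VennPartition:
    """Disjoint partition of two sets into A-only, B-only and common members."""
    a, b = set(set_a), set(set_b)
    return VennPartition(a - b, b - a, a & b)


@dataclass
class WilcoxonShift:
    p_value: float
    statistic: float
    direction: int  # sign of the B - A location shift; 0 when undetermined
    n_used: int
    paired: bool


def wilcoxon_shift(
    tsi_ref: Sequence[float],
    tsi_other: Sequence[float],
    paired: bool = True,
    exact_max_n: int = 25,
    min_n: int = 5,
) -> WilcoxonShift:
    """Two-sided Wilcoxon test for a TSI distribution shift between genotypes.

    Paired mode runs the signed-rank test on per-transcript differences
    (pairs with an undefined TSI and zero differences dropped, exact null
    for n <= ``exact_max_n``); unpaired mode
    runs the rank-sum (Mann-Whitney) test. Fewer than ``min_n`` usable
    observations yields an undefined p-value with a warning.
    """
    x = np.asarray(tsi_ref, dtype=float)
    y = np.asarray(tsi_other, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired mode requires equal-length vectors")
        keep = np.isfinite(x) & np.isfinite(y)  # undefined TSIs excluded, not imputed
        d = y[keep] - x[keep]
        d = d[d != 0]
        n = d.size
        if n < min_n:
            warnings.warn(f"only {n} nonzero differences; p-value undefined")
            return WilcoxonShift(np.nan, np.nan, 0, n, True)
        method = "exact" if n <= exact_max_n else "approx"
        try:
            res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
        except ValueError:
            res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
        direction = int(np.sign(np.median(d)))
        return WilcoxonShift(float(res.pvalue), float(res.statistic), direction, n, True)
    n = min(x.size, y.size)
    if n < min_n:
        warnings.warn(f"only {n} observations; p-value undefined")
        return WilcoxonShift(np.nan, np.nan, 0, n, False)
    method = "exact" if max(x.size, y.size) <= exact_max_n else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    direction = int(np.sign(np.median(y) - np.median(x)))
    return WilcoxonShift(float(res.pvalue), float(res.statistic), direction, x.size + y.size, False)


@dataclass
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if not (self.n_overlap <= min(self.n_set_a, self.n_set_b) <= self.n_universe):
            raise ValueError(
                f"inconsistent overlap: |A∩B|={self.n_overlap}, "
                f"|A|={self.n_set_a}, |B|={self.n_set_b}, N={self.n_universe}"
            )


def hypergeometric_overlap(
    n_universe: int,
    set_a: Iterable | int,
    set_b: Iterable | int,
    n_overlap: int | None = None,
) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets.

    ``p = P(X >= n_overlap)`` with ``X ~ Hypergeometric(N, |A|, |B|)``. Sets
    may be passed as collections (overlap computed) or as sizes together with
    an explicit ``n_overlap``.
    """
    if isinstance(set_a, int) or isinstance(set_b, int):
        n_a, n_b = int(set_a), int(set_b)
        if n_overlap is None:
            raise ValueError("n_overlap required when passing set sizes")
        k = int(n_overlap)
    else:
        a, b = set(set_a), set(set_b)
        n_a, n_b = len(a), len(b)
        k = len(a & b) if n_overlap is None else int(n_overlap)
    if max(n_a, n_b) > n_universe:
        raise ValueError("set larger than universe")
    if n_a == 0 or n_b == 0:
        p = 1.0 if k == 0 else np.nan
        return OverlapResult(n_universe, n_a, n_b, k, p)
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_a, n_b))
    return OverlapResult(n_universe, n_a, n_b, k, p)


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(identifier: str, level: str = "gene") -> str:
    """Case-fold an identifier and, at gene level, strip the isoform suffix
    (``AT1G66900.1`` -> ``AT1G66900``)."""
    out = str(identifier).strip().upper()
    if level == "gene":
        out = _VERSION_SUFFIX.sub("", out)
    return out


def intersect_external_list(
    table: TsiTable,
    gene_list: Iterable[str],
    level: str = "gene",
) -> TsiTable:
    """Restrict a TSI table to transcripts present in an external gene list.

    Identifiers on both sides are normalized (case, isoform version suffix at
    gene level) before matching; an empty intersection is a warning.
    """
    wanted = {normalize_gene_id(g, level) for g in gene_list}
    rec = table.records
    keep_rec = rec["transcript_id"].map(lambda t: normalize_gene_id(t, level)).isin(wanted)
    means = table.genotype_means
    keep_means = means["transcript_id"].map(lambda t: normalize_gene_id(t, level)).isin(wanted)
    if not keep_means.any():
        warnings.warn("external list shares no transcript with the TSI table")
    return TsiTable(rec[keep_rec].reset_index(drop=True),
                    means[keep_means].reset_index(drop=True))


@dataclass
class ConcordanceResult:
    coordinates: pd.DataFrame  # sample, PC1, PC2
    variance_explained: tuple[float, float]  # fractions of total variance


def sample_concordance(matrix: pd.DataFrame, log_transform: bool = True) -> ConcordanceResult:
    """Project samples onto the top-2 principal axes of a log-scaled matrix.

    ``matrix`` has samples as rows and features (transcripts) as columns;
    columns containing NaN are dropped. Used as a replicate-concordance QC:
    replicates of a genotype should cluster together.
    """
    if matrix.shape[0] < 3:
        raise ValueError("sample concordance requires >= 3 samples")
    X = matrix.dropna(axis=1).to_numpy(dtype=float)
    if log_transform:
        X = np.log1p(np.clip(X, 0, None))
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        warnings.warn("constant matrix; principal axes are degenerate")
        coords = pd.DataFrame(
            {"sample": matrix.index, "PC1": 0.0, "PC2": 0.0}
        )
        return ConcordanceResult(coords, (0.0, 0.0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    proj = u[:, :2] * s[:2]
    var = s**2 / np.sum(s**2)
    v2 = float(var[1]) if var.size > 1 else 0.0
    coords = pd.DataFrame(
        {"sample": matrix.index, "PC1": proj[:, 0],
         "PC2": proj[:, 1] if proj.shape[1] > 1 else 0.0}
    )
    return ConcordanceResult(coords, (float(var[0]), v2))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values, for users running many overlap tests at once."""
    from statsmodels.stats.multitest import multipletests  # local: optional path

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
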