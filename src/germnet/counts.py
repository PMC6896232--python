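"""Count-matrix handling and normalization for differentiation time courses.

Gene-level read counts (no transcript-length correction — only relative
changes across samples matter) are first grossly normalized to reads per
million aligned reads, then fine-normalized: per-gene log2 ratios against a
reference profile are median-filtered along the expression axis for highly
expressed genes, and each sample is rescaled so those filtered ratios sit on
the identity line.  Differential gene sets per differentiation condition use
a maximal-expression floor (> 3 rpm) combined with a fold-change criterion
(>= 4-fold across the time course including the undifferentiated baseline).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import InputError

logger = logging.getLogger("germnet.counts")

#: default pseudocount (rpm units) for all log transforms and fold ratios
DEFAULT_PSEUDOCOUNT = 1.0
#: reference-profile expression floor for the fine-normalization gene set
DEFAULT_HIGH_EXPR_MIN_RPM = 32.0
#: running-median window (genes) for fine normalization
DEFAULT_MEDIAN_WINDOW = 101

_SAMPLE_NAME_RE = re.compile(r"^(?P<condition>.+)_(?P<day>\d+(?:\.\d+)?)_(?P<replicate>\d+)$")


def parse_sample_name(name: str) -> tuple[str, float, int]:
    """Parse ``condition_day_replicate`` sample names (e.g. ``ectoderm_3_1``)."""
    m = _SAMPLE_NAME_RE.match(name)
    if m is None:
        raise InputError(
            f"sample name {name!r} not in condition_day_replicate form and no "
            "metadata sidecar provided")
    return m["condition"], float(m["day"]), int(m["replicate"])


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with per-sample metadata.

    ``aligned_totals`` are total aligned reads per sample; they may exceed the
    column sums (reads aligning to genes outside the matrix) but must be
    positive.
    """

    counts: pd.DataFrame          # genes x samples, nonnegative integers
    sample_meta: pd.DataFrame     # index = samples; condition, day, replicate
    aligned_totals: pd.Series     # per-sample total aligned reads

    def __post_init__(self) -> None:
        self.counts = self.counts.rename_axis("gene_id")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise InputError(f"duplicate gene ids: {list(dups[:10])}")
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        if list(self.sample_meta.index) != list(self.counts.columns):
            self.sample_meta = self.sample_meta.reindex(self.counts.columns)
        if self.sample_meta.isna().any().any():
            missing = self.sample_meta.index[self.sample_meta.isna().any(axis=1)]
            raise InputError(f"missing metadata for samples: {list(missing)}")
        self.aligned_totals = self.aligned_totals.reindex(self.counts.columns)
        if (self.aligned_totals <= 0).any() or self.aligned_totals.isna().any():
            bad = self.aligned_totals.index[~(self.aligned_totals > 0)]
            raise InputError(f"non-positive aligned totals for: {list(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        """Write counts as TSV plus a ``.meta.tsv`` metadata sidecar."""
        path = Path(path)
        self.counts.to_csv(path, sep="\t", index_label="gene_id")
        meta = self.sample_meta.copy()
        meta["aligned_total"] = self.aligned_totals
        meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t",
                    index_label="sample")


def load_counts(path) -> CountMatrix:
    """Load a count TSV (gene_id rows, sample columns).

    Sample metadata comes from a ``<path>.meta.tsv`` sidecar when present,
    otherwise from ``condition_day_replicate`` column names; aligned totals
    default to column sums (with a log notice) when no sidecar exists.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise InputError(f"duplicate gene ids in {path}: {list(dups[:10])}")
    non_int = df.columns[[not np.issubdtype(dt, np.integer) for dt in df.dtypes]]
    if len(non_int):
        for col in non_int:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or not np.allclose(vals, np.round(vals)):
                bad = df.index[vals.isna() | ~np.isclose(vals, np.round(vals))]
                raise InputError(
                    f"non-integer counts in column {col!r}, e.g. gene "
                    f"{bad[0]!r}")
            df[col] = vals.astype(int)
    sidecar = path.with_suffix(path.suffix + ".meta.tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", index_col="sample")
        missing = [s for s in df.columns if s not in meta.index]
        if missing:
            raise InputError(f"sidecar lacks metadata for samples: {missing}")
        meta = meta.loc[df.columns]
        totals = meta.pop("aligned_total") if "aligned_total" in meta else df.sum(axis=0)
    else:
        parsed = [parse_sample_name(s) for s in df.columns]
        meta = pd.DataFrame(parsed, index=df.columns,
                            columns=["condition", "day", "replicate"])
        totals = df.sum(axis=0).astype(float)
        logger.info("no metadata sidecar; aligned totals set to column sums")
    cm = CountMatrix(df, meta[["condition", "day", "replicate"]],
                     pd.Series(totals, index=df.columns, dtype=float))
    logger.info("loaded %d genes x %d samples from %s",
                len(cm.gene_ids), len(cm.samples), path)
    return cm


@dataclass
class ExpressionMatrix:
    """Depth-normalized expression: rpm and its log2 view."""

    rpm: pd.DataFrame
    sample_meta: pd.DataFrame
    normalization_factors: pd.Series
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if (self.rpm.values < 0).any():
            raise InputError("rpm must be nonnegative")
        if (self.normalization_factors <= 0).any():
            raise InputError("normalization factors must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rpm.columns)

    @property
    def log2_expr(self) -> pd.DataFrame:
        return np.log2(self.rpm + self.pseudocount)

    def to_tsv(self, path) -> None:
        self.rpm.to_csv(path, sep="\t", index_label="gene_id")


def gross_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads per million aligned reads: counts / aligned_total * 1e6."""
    return cm.counts / cm.aligned_totals * 1e6


def fine_normalize(rpm: pd.DataFrame,
                   high_expr_min_rpm: float = DEFAULT_HIGH_EXPR_MIN_RPM,
                   median_window: int = DEFAULT_MEDIAN_WINDOW,
                   reference: pd.Series | None = None,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Residual depth correction after gross normalization.

    For each sample, per-gene log2 ratios to the reference profile (default:
    the per-gene geometric mean across samples) are computed over highly
    expressed genes, ordered by reference expression, smoothed with a running
    median, and the sample is rescaled by 2**(-median of the smoothed ratios)
    so the ratios match the identity line.  Factors are renormalized to
    geometric mean 1, which leaves the reference profile — and hence the
    high-expression gene set — fixed, making the procedure idempotent.

    Returns the rescaled rpm matrix and the per-sample factors.
    """
    if rpm.shape[1] < 2:
        raise InputError("fine normalization needs >= 2 samples")
    with np.errstate(divide="ignore"):
        log_rpm = np.log2(rpm.values)
    if reference is None:
        ref_log2 = np.where(np.isneginf(log_rpm).any(axis=1),
                            -np.inf, log_rpm.mean(axis=1))
    else:
        ref = reference.reindex(rpm.index).values.astype(float)
        with np.errstate(divide="ignore"):
            ref_log2 = np.where(ref > 0, np.log2(np.maximum(ref, 1e-300)), -np.inf)
    high = ref_log2 > np.log2(high_expr_min_rpm)
    n_high = int(high.sum())
    if n_high < median_window:
        raise InputError(
            f"only {n_high} genes exceed {high_expr_min_rpm} rpm on the "
            f"reference profile but the running median needs >= "
            f"{median_window}; lower high_expr_min_rpm or median_window")
    order = np.argsort(ref_log2[high])[::-1]
    ratios = log_rpm[high] - ref_log2[high, None]
    log_factors = np.empty(rpm.shape[1])
    for s in range(rpm.shape[1]):
        smoothed = median_filter(ratios[order, s], size=median_window,
                                 mode="nearest")
        log_factors[s] = -np.median(smoothed)
    log_factors -= log_factors.mean()  # anchor geometric mean of factors at 1
    factors = pd.Series(2.0 ** log_factors, index=rpm.columns)
    logger.info("fine normalization over %d high-expression genes; factors "
                "in [%.3f, %.3f]", n_high, factors.min(), factors.max())
    return rpm * factors, factors


def normalize(cm: CountMatrix,
              high_expr_min_rpm: float = DEFAULT_HIGH_EXPR_MIN_RPM,
              median_window: int = DEFAULT_MEDIAN_WINDOW,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ExpressionMatrix:
    """Gross (depth) then fine (median-matching) normalization."""
    rpm = gross_normalize(cm)
    rpm, factors = fine_normalize(rpm, high_expr_min_rpm=high_expr_min_rpm,
                                  median_window=median_window)
    return ExpressionMatrix(rpm, cm.sample_meta.copy(), factors,
                            pseudocount=pseudocount)


def filter_genes(expr: ExpressionMatrix, min_max_rpm: float = 3.0,
                 min_fold: float = 4.0,
                 samples: list[str] | None = None) -> list[str]:
    """Expressed-and-variable gene filter.

    Keeps genes whose maximal rpm over ``samples`` exceeds ``min_max_rpm``
    and whose pseudocounted max/min ratio is at least ``min_fold``.  Input
    gene order is preserved.
    """
    sub = expr.rpm if samples is None else expr.rpm[samples]
    if sub.shape[1] == 0:
        raise InputError("empty sample subset")
    mx = sub.max(axis=1)
    mn = sub.min(axis=1)
    pc = expr.pseudocount
    keep = (mx > min_max_rpm) & ((mx + pc) / (mn + pc) >= min_fold)
    return list(sub.index[keep])


def differential_sets(expr: ExpressionMatrix,
                      conditions: list[str],
                      min_max_rpm: float = 3.0,
                      min_fold: float = 4.0,
                      baseline_day: float = 0.0,
                      ) -> tuple[dict[str, set[str]], dict[tuple[str, ...], set[str]]]:
    """Per-condition differential gene sets and their Venn regions.

    Each condition's set comes from :func:`filter_genes` over that condition's
    time course together with the shared undifferentiated baseline samples
    (``day == baseline_day``).  Returns the per-condition sets and a dict of
    all non-empty-membership Venn regions keyed by sorted condition tuples
    (7 regions for 3 conditions).
    """
    meta = expr.sample_meta
    known = set(meta["condition"])
    unknown = [c for c in conditions if c not in known]
    if unknown:
        raise InputError(f"unknown condition labels: {unknown}")
    baseline = list(meta.index[meta["day"] == baseline_day])
    sets: dict[str, set[str]] = {}
    for cond in conditions:
        cond_samples = list(meta.index[meta["condition"] == cond])
        subset = list(dict.fromkeys(baseline + cond_samples))
        if len({d for s, d in meta.loc[cond_samples, "day"].items()}) < 2:
            raise InputError(f"condition {cond!r} needs >= 2 timepoints")
        sets[cond] = set(filter_genes(expr, min_max_rpm=min_max_rpm,
                                      min_fold=min_fold, samples=subset))
        logger.info("condition %s: %d differential genes", cond, len(sets[cond]))
    regions = venn_regions(sets)
    return sets, regions


def venn_regions(sets: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Exclusive Venn regions of named sets, keyed by membership tuple."""
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], set[str]] = {}
    for g in universe:
        key = tuple(n for n in names if g in sets[n])
        regions.setdefault(key, set()).add(g)
    # ensure every membership combination is present, even when empty
    from itertools import combinations
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions.setdefault(combo, set())
    return regions
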