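"""Resampling-based gene-set enrichment with BH correction.

The overlap between a gene set (e.g. a KEGG pathway) and a hit list (e.g.
the common differentiation program) is compared against a null distribution
built by repeatedly drawing same-size subsets of the gene pool without
replacement; the empirical p-value uses the +1 correction so it is never
zero and never below 1/(resamples+1).  Across many sets, p-values are
adjusted by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger("germnet.enrichment")


@dataclass
class EnrichmentResult:
    gene_set_id: str
    set_size: int
    observed: int
    resamples: int
    p_value: float
    q_value: float | None = None


def resampling_enrichment(gene_set: set[str], hit_set: set[str],
                          pool: list[str], resamples: int = 10000,
                          rng: np.random.Generator | int | None = None,
                          chunk: int = 512) -> EnrichmentResult:
    """Empirical enrichment p-value from pool resampling.

    p = (1 + #{null overlap >= observed}) / (resamples + 1), where each null
    draw is a random subset of size |gene_set| taken from ``pool`` without
    replacement.
    """
    if resamples < 1000:
        raise InputError("resamples must be >= 1000 for a stable p-value")
    pool = list(pool)
    pool_set = set(pool)
    for name, s in (("gene_set", gene_set), ("hit_set", hit_set)):
        outside = set(s) - pool_set
        if outside:
            raise InputError(f"{name} members outside the pool: "
                             f"{sorted(outside)[:10]}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = len(gene_set)
    observed = len(set(gene_set) & set(hit_set))
    if k == 0:
        return EnrichmentResult("", 0, 0, resamples, 1.0)
    hits = np.fromiter((g in hit_set for g in pool), dtype=bool,
                       count=len(pool))
    exceed = 0
    done = 0
    while done < resamples:
        m = min(chunk, resamples - done)
        # rank-based sampling without replacement, vectorized over draws
        keys = rng.random((m, len(pool)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        overlaps = hits[idx].sum(axis=1)
        exceed += int((overlaps >= observed).sum())
        done += m
    p = (1 + exceed) / (resamples + 1)
    return EnrichmentResult("", k, observed, resamples, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_sets(gene_sets: dict[str, set[str]], hit_set: set[str],
                     pool: list[str], resamples: int = 10000,
                     rng: np.random.Generator | int | None = None
                     ) -> pd.DataFrame:
    """Enrichment of many gene sets against one hit list, BH-adjusted."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    results = []
    for name, gs in gene_sets.items():
        res = resampling_enrichment(set(gs), hit_set, pool,
                                    resamples=resamples, rng=rng)
        res.gene_set_id = name
        results.append(res)
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    df = pd.DataFrame(
        [(r.gene_set_id, r.set_size, r.observed, r.resamples, r.p_value,
          r.q_value) for r in results],
        columns=["gene_set", "set_size", "observed", "resamples", "p_value",
                 "q_value"])
    logger.info("enrichment over %d gene sets; %d at q < 0.05",
                len(df), int((df["q_value"] < 0.05).sum()))
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
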