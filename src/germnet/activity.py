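"""Motif activity response analysis.

Per sample ``s`` the model is ordinary least squares of log2 expression on
promoter site counts,

    log2_expr[g, s] = c[s] + sum_m N[g, m] * A[m, s] + eps[g, s],

so ``A[m, s]`` (the motif activity, log2-expression units per binding site)
summarizes the regulatory influence of motif ``m`` in sample ``s`` and
``c[s]`` absorbs per-sample shifts.  Motif significance follows the
response-analysis tradition: per-sample forward selection in residual space,
admitting at each step the motif with the largest residual-variance
reduction if the F-test of its coefficient, Bonferroni-corrected for the
number of remaining candidates, falls below ``alpha``; after selection the
activities of all selected motifs are refit jointly in every sample so each
node carries a complete activity trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import ExpressionMatrix
from .errors import InputError
from .motifscan import MotifModel, SiteCountMatrix

logger = logging.getLogger("germnet.activity")


@dataclass
class ActivityModel:
    """Fitted motif activities with per-motif significance.

    ``A`` holds activities (motifs x samples), ``c`` the per-sample
    intercepts, ``residual_var`` the per-sample residual variance;
    ``pvalues`` are Bonferroni-corrected selection p-values (best over
    samples) and ``selected`` the motifs admitted in at least one sample.
    """

    A: pd.DataFrame
    c: pd.Series
    residual_var: pd.Series
    pvalues: pd.Series | None = None
    selected: list[str] | None = None
    eligibility: pd.DataFrame | None = None  # per-TF max rpm record

    @property
    def motif_ids(self) -> list[str]:
        return list(self.A.index)

    @property
    def samples(self) -> list[str]:
        return list(self.A.columns)

    def to_tsv(self, path) -> None:
        out = self.A.copy()
        if self.pvalues is not None:
            out.insert(0, "p_value", self.pvalues.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="motif_id")


def resolve_tf_genes(motif: MotifModel,
                     tf_gene_map: dict[str, list[str]] | None) -> list[str]:
    if tf_gene_map is not None and motif.motif_id in tf_gene_map:
        return tf_gene_map[motif.motif_id]
    return motif.tf_genes


def eligible_tfs(expr: ExpressionMatrix, motifs: list[MotifModel],
                 tf_gene_map: dict[str, list[str]] | None = None,
                 min_max_rpm: float = 6.0,
                 samples: list[str] | None = None,
                 ) -> tuple[list[str], pd.DataFrame]:
    """Motifs whose TF gene(s) are expressed above ``min_max_rpm``.

    A dimer motif (e.g. ``Fos::Jun``) is eligible only if EVERY constituent
    gene passes; motifs with no mappable gene are excluded with a warning.
    Returns the eligible motif ids and a per-motif record of the max rpm of
    each constituent gene.
    """
    rpm = expr.rpm if samples is None else expr.rpm[samples]
    eligible, records = [], []
    for motif in motifs:
        genes = resolve_tf_genes(motif, tf_gene_map)
        missing = [g for g in genes if g not in rpm.index]
        if missing:
            warnings.warn(f"motif {motif.motif_id}: no expression for gene(s) "
                          f"{missing}; excluded", stacklevel=2)
            records.append((motif.motif_id, ";".join(genes), np.nan, False))
            continue
        max_rpm = float(rpm.loc[genes].max(axis=1).min())  # weakest constituent
        ok = max_rpm > min_max_rpm
        records.append((motif.motif_id, ";".join(genes), max_rpm, ok))
        if ok:
            eligible.append(motif.motif_id)
    record = pd.DataFrame(records, columns=["motif_id", "tf_genes",
                                            "min_constituent_max_rpm",
                                            "eligible"]).set_index("motif_id")
    logger.info("%d/%d motifs eligible at max rpm > %g",
                len(eligible), len(motifs), min_max_rpm)
    return eligible, record


def _design(log2_expr: pd.DataFrame, N: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if list(N.index) != list(log2_expr.index):
        N = N.reindex(log2_expr.index)
        if N.isna().any().any():
            missing = log2_expr.index[N.isna().any(axis=1)]
            raise InputError(f"site counts missing for genes: "
                             f"{list(missing[:10])}")
    zero = N.columns[(N.values == 0).all(axis=0)]
    if len(zero):
        warnings.warn(f"dropping all-zero site columns: {list(zero)}",
                      stacklevel=3)
        N = N.drop(columns=zero)
    motif_ids = list(N.columns)
    X = np.column_stack([np.ones(len(N)), N.values.astype(float)])
    return X, log2_expr.values, motif_ids


def _check_rank(X: np.ndarray, motif_ids: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[rank:]
        groups = sorted({motif_ids[j - 1] for vec in null
                         for j in np.flatnonzero(np.abs(vec) > 1e-8) if j > 0})
        raise InputError(f"site-count design is rank deficient; collinear "
                         f"motif group: {groups}")


def fit_activities(log2_expr: pd.DataFrame, N: pd.DataFrame | SiteCountMatrix,
                   ) -> ActivityModel:
    """Per-sample OLS of log2 expression on site counts plus intercept.

    Fits are independent across samples (the design is shared, so a single
    factorization serves all).  Requires more genes than candidate motifs
    and a full-rank design.
    """
    if isinstance(N, SiteCountMatrix):
        N = N.N
    X, Y, motif_ids = _design(log2_expr, N)
    n, p = X.shape
    if n <= p:
        raise InputError(f"{n} genes but {p} parameters; need more genes "
                         "than candidate motifs")
    _check_rank(X, motif_ids)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss = (resid ** 2).sum(axis=0)
    res_var = rss / (n - p)
    samples = list(log2_expr.columns)
    return ActivityModel(
        A=pd.DataFrame(coef[1:], index=motif_ids, columns=samples),
        c=pd.Series(coef[0], index=samples),
        residual_var=pd.Series(res_var, index=samples))


def _forward_select_sample(y: np.ndarray, cand: np.ndarray, alpha: float
                           ) -> tuple[list[int], np.ndarray]:
    """Forward selection for one sample.

    Returns admitted candidate indices and the best Bonferroni-corrected
    p-value recorded for every candidate (admitted ones at their admission
    step, the rest at the step where selection stopped).
    """
    n, m = cand.shape
    best_p = np.ones(m)
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis: intercept
    r = y - Q @ (Q.T @ y)
    Xp = cand - Q @ (Q.T @ cand)  # candidates orthogonalized against basis
    remaining = list(range(m))
    admitted: list[int] = []
    while remaining:
        df = n - Q.shape[1] - 1
        if df <= 0:
            break
        norms = (Xp[:, remaining] ** 2).sum(axis=0)
        usable = norms > 1e-10 * n
        if not usable.any():
            break
        proj = Xp[:, remaining].T @ r
        reduction = np.where(usable, proj ** 2 / np.where(usable, norms, 1.0),
                             -np.inf)
        k = int(np.argmax(reduction))
        rss_old = float(r @ r)
        rss_new = rss_old - reduction[k]
        F = reduction[k] / (rss_new / df) if rss_new > 0 else np.inf
        p_raw = stats.f.sf(F, 1, df)
        p_corr = min(p_raw * len(remaining), 1.0)
        idx = remaining[k]
        best_p[idx] = min(best_p[idx], p_corr)
        if p_corr >= alpha:
            # record corrected p-values of the rest at this final state
            for pos, j in enumerate(remaining):
                if usable[pos] and j != idx:
                    rn = rss_old - reduction[pos]
                    pf = stats.f.sf(reduction[pos] / (rn / df), 1, df) if rn > 0 else 0.0
                    best_p[j] = min(best_p[j], min(pf * len(remaining), 1.0))
            break
        admitted.append(idx)
        q = Xp[:, idx] / np.sqrt(norms[k])
        Q = np.column_stack([Q, q])
        r = r - q * (q @ r)
        Xp = Xp - np.outer(q, q @ Xp)
        remaining.pop(k)
    return admitted, best_p


def motif_significance(log2_expr: pd.DataFrame,
                       N: pd.DataFrame | SiteCountMatrix,
                       alpha: float = 0.01) -> ActivityModel:
    """Select significant motifs and refit their activities jointly.

    Per sample, candidates are admitted by forward selection with
    Bonferroni-corrected F-tests at level ``alpha``; a motif's overall
    p-value is its best corrected p over samples, and the selected set is
    the union of per-sample admissions.  Activities of the selected motifs
    are then refit jointly in every sample so trajectories are complete.
    An empty selection is a valid result.
    """
    if isinstance(N, SiteCountMatrix):
        N = N.N
    X, Y, motif_ids = _design(log2_expr, N)
    n, p = X.shape
    if n <= p:
        raise InputError("need more genes than candidate motifs")
    _check_rank(X, motif_ids)
    if alpha >= 1.0:  # degenerate threshold: no significance filter
        model = fit_activities(log2_expr, N[motif_ids])
        model.pvalues = pd.Series(1.0, index=motif_ids)
        model.selected = motif_ids
        return model
    cand = X[:, 1:]
    best_p = np.ones(len(motif_ids))
    admitted_any: set[int] = set()
    for s in range(Y.shape[1]):
        admitted, pvals = _forward_select_sample(Y[:, s], cand, alpha)
        admitted_any.update(admitted)
        best_p = np.minimum(best_p, pvals)
    selected = [motif_ids[i] for i in sorted(admitted_any)]
    pvalues = pd.Series(best_p, index=motif_ids)
    if not selected:
        logger.info("no motif reached significance %g", alpha)
        samples = list(log2_expr.columns)
        return ActivityModel(
            A=pd.DataFrame(index=pd.Index([], dtype=object), columns=samples,
                           dtype=float),
            c=log2_expr.mean(axis=0),
            residual_var=log2_expr.var(axis=0, ddof=1),
            pvalues=pvalues, selected=[])
    model = fit_activities(log2_expr, N[selected])
    model.pvalues = pvalues
    model.selected = selected
    logger.info("selected %d/%d motifs at alpha %g",
                len(selected), len(motif_ids), alpha)
    return model


def activity_expression_correlation(model: ActivityModel,
                                    expr: ExpressionMatrix,
                                    motif_id: str, gene: str,
                                    samples: list[str] | None = None) -> float:
    """Pearson r between a motif's activity and a gene's log2 expression."""
    if motif_id not in model.A.index:
        raise InputError(f"motif {motif_id!r} not in the activity model")
    if gene not in expr.rpm.index:
        raise InputError(f"gene {gene!r} not in the expression matrix")
    samples = samples or [s for s in model.samples if s in expr.samples]
    if len(samples) < 3:
        raise InputError("correlation needs >= 3 shared samples")
    a = model.A.loc[motif_id, samples].values.astype(float)
    e = expr.log2_expr.loc[gene, samples].values.astype(float)
    if np.std(a) == 0 or np.std(e) == 0:
        raise InputError("constant vector in correlation")
    return float(stats.pearsonr(a, e)[0])
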