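"""Gene-set enrichment scoring: ssGSEA, classic GSEA, z-scoring, and
signature-signature correlation.

ssGSEA scores one sample at a time: genes are ranked by expression
(descending, ties broken by stable input order) and the score is the
integrated difference between a rank-weighted in-set ECDF and the
uniform out-of-set ECDF.  In-set steps at rank position i carry weight
i**alpha (alpha = 0.75 by default), normalized by the in-set weight
total; out-of-set steps are 1/(N - |S|).  No cross-set range
normalization is applied because scores are z-scored per signature
across samples immediately afterwards, which makes any affine range
rescaling a no-op.

Classic GSEA uses the Subramanian running sum on a signal-to-noise
ranking, with the significance null taken from gene-set permutation
(random same-size sets): phenotype permutation is undefined at the
replicate counts this pipeline targets.  The permutation p-value is
one-sided within the same-sign null pool, with the +1 guard that keeps
it strictly positive and valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix
from .errors import ValidationError
from .io import GeneSet


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float | None
    p_perm: float | None
    n_perm: int = 0
    n_null_same_sign: int = 0


def _as_series(values) -> pd.Series:
    s = pd.Series(values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValidationError("expression values must be finite")
    return s


def ssgsea_score(expr_sample, gene_set: GeneSet, alpha: float = 0.75) -> float:
    """ssGSEA enrichment of one sample for one gene set.

    ``expr_sample`` maps gene -> expression for a single sample (a
    mapping or pandas Series).  Depends on ranks only: adding a
    constant to all values leaves the score unchanged.
    """
    s = _as_series(expr_sample)
    n = len(s)
    members = set(gene_set.members)
    in_set = s.index.isin(members)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError(
            f"no member of gene set {gene_set.name!r} present in expression vector"
        )
    if n_in == n:
        raise ValidationError(
            f"gene set {gene_set.name!r} equals the whole gene universe"
        )
    # descending rank, ties broken by stable input order
    order = np.argsort(-s.to_numpy(), kind="stable")
    in_sorted = in_set[order]
    ranks = np.arange(1, n + 1, dtype=float)
    w = np.where(in_sorted, ranks**alpha, 0.0)
    cum_in = np.cumsum(w) / w.sum()
    cum_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    expr: pd.DataFrame, gene_set: GeneSet, alpha: float = 0.75
) -> pd.Series:
    """ssGSEA score of every sample (column) of a genes x samples frame."""
    return pd.Series(
        {col: ssgsea_score(expr[col], gene_set, alpha=alpha) for col in expr.columns},
        name=gene_set.name,
    )


def zscore_signature(scores) -> pd.Series:
    """Standardize per-sample scores: (x - mean) / SD with ddof = 1."""
    s = _as_series(scores)
    if len(s) < 2:
        raise ValidationError("z-scoring needs >=2 samples")
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant scores cannot be z-scored (SD = 0)")
    return (s - s.mean()) / sd


def gsea_es(ranked_metric, gene_set: GeneSet, weight: float = 1.0) -> float:
    """Classic GSEA enrichment score on a ranked metric.

    ``ranked_metric`` maps gene -> ranking metric; it is sorted
    descending internally (stable ties).  In-set steps add
    |metric|**weight normalized by the in-set total; out-of-set steps
    subtract 1/(N - |S|).  ES is the running-sum value of maximal
    absolute deviation from zero, signed.
    """
    s = _as_series(ranked_metric)
    order = np.argsort(-s.to_numpy(), kind="stable")
    metric = s.to_numpy()[order]
    in_sorted = s.index.to_numpy()[order]
    mask = np.isin(in_sorted, list(gene_set.members))
    return _es_from_mask(metric, mask, weight)


def _es_from_mask(metric_sorted: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    n = metric_sorted.size
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError("no gene set member present in ranked list")
    if n_in == n:
        raise ValidationError("gene set equals the whole ranked list")
    w = np.abs(metric_sorted) ** weight
    in_total = w[in_set].sum()
    if in_total == 0:
        raise ValidationError(
            "all in-set metric values are zero; weighted steps undefined"
        )
    steps = np.where(in_set, w / in_total, -1.0 / (n - n_in))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def signal_to_noise(
    x: np.ndarray, y: np.ndarray, sd_floor_frac: float = 0.2
) -> np.ndarray:
    """Per-gene signal-to-noise ratio (mu1 - mu2)/(s1 + s2).

    Each group SD is floored at ``sd_floor_frac * |mu|`` of its own
    mean (and at ``sd_floor_frac`` when the mean is 0) to avoid
    degenerate metrics at small replicate counts.
    """
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    s1, s2 = x.std(axis=1, ddof=1), y.std(axis=1, ddof=1)

    def _floor(s, m):
        floor = np.where(m == 0, sd_floor_frac, sd_floor_frac * np.abs(m))
        return np.maximum(s, floor)

    return (m1 - m2) / (_floor(s1, m1) + _floor(s2, m2))


def gsea_permutation(
    expr: ExpressionMatrix,
    groups: tuple[str, str],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Classic GSEA with a gene-set permutation null.

    ``groups`` names (class1, class2) conditions; the ranking metric is
    signal-to-noise of class1 over class2.  The null is built from
    ``n_perm`` random gene sets of the same size; p_perm is one-sided
    within same-sign null scores with a +1 guard, and NES divides ES by
    the mean |null ES| of the same sign.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    s1 = expr.samples_for(groups[0])
    s2 = expr.samples_for(groups[1])
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("each class needs >=2 samples for signal-to-noise")
    metric = pd.Series(
        signal_to_noise(
            expr.values[s1].to_numpy(dtype=float),
            expr.values[s2].to_numpy(dtype=float),
        ),
        index=expr.genes,
    )
    order = np.argsort(-metric.to_numpy(), kind="stable")
    metric_sorted = metric.to_numpy()[order]
    genes_sorted = metric.index.to_numpy()[order]
    present = [g for g in gene_set.members if g in set(expr.genes)]
    if not present:
        raise ValidationError(f"no member of {gene_set.name!r} in the matrix")
    if len(present) >= len(metric):
        raise ValidationError("gene set is not smaller than the gene universe")
    mask = np.isin(genes_sorted, present)
    es = _es_from_mask(metric_sorted, mask, weight)

    rng = np.random.default_rng(seed)
    n = metric_sorted.size
    k = int(mask.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        null_mask = np.zeros(n, dtype=bool)
        null_mask[idx] = True
        null[i] = _es_from_mask(metric_sorted, null_mask, weight)
    same_sign = null >= 0 if es >= 0 else null < 0
    pool = np.abs(null[same_sign])
    n_pool = int(pool.size)
    p = (1 + int((pool >= abs(es)).sum())) / (1 + n_pool)
    nes = float(es / pool.mean()) if n_pool else None
    return EnrichmentResult(
        gene_set=gene_set.name,
        es=float(es),
        nes=nes,
        p_perm=float(p),
        n_perm=n_perm,
        n_null_same_sign=n_pool,
    )


def correlate_signatures(za, zb) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n-2 df) of two score vectors."""
    a = _as_series(za).to_numpy()
    b = _as_series(zb).to_numpy()
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValidationError("correlation needs >=3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero-variance input to correlation")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
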