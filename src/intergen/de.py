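"""Negative-binomial Wald differential expression.

A self-contained two-condition DE engine following the standard bulk
RNA-seq workflow: median-of-ratios size factors, gene-wise
method-of-moments dispersion with shrinkage toward a fitted mean-
dispersion trend, a per-gene NB log-linear model fit by IRLS with the
dispersion held fixed, a Wald test on the condition coefficient, and
Benjamini-Hochberg adjustment.  The NB parameterization throughout is
``Var(Y) = mu + alpha * mu**2``.

Calling rule: a gene is differentially expressed when |fold change|
exceeds the threshold (default 2) and padj is below the cutoff
(default 0.01), both inequalities strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, NormalizationError, ValidationError
from .io import CountMatrix, SampleSheet

_LN2 = math.log(2.0)
_ALPHA_FLOOR = 1e-8


@dataclass
class DEResult:
    """Per-gene statistics for one stress-vs-control contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # index gene; base_mean, log2fc, se_log2fc, wald_stat, p, padj, tested
    species: str = ""

    def __post_init__(self) -> None:
        t = self.table
        both = t["p"].notna() & t["padj"].notna()
        if (t.loc[both, "padj"] + 1e-12 < t.loc[both, "p"]).any():
            raise ValidationError("padj below p: BH property violated")
        untested = ~t["tested"].astype(bool)
        if t.loc[untested, "p"].notna().any() or t.loc[untested, "padj"].notna().any():
            raise ValidationError("untested genes must have missing p and padj")


@dataclass
class DEGCall:
    """Thresholded up/down gene sets for one contrast."""

    contrast: str
    fold_change_threshold: float
    padj_threshold: float
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("up and down sets overlap")

    @property
    def significant(self) -> frozenset[str]:
        return self.up | self.down


def compute_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors with a geometric-mean pseudo-reference.

    Reference genes are those with positive counts in every sample; the
    factor for sample j is the median over reference genes of
    ``count_gj / geomean_g(count_g.)``.
    """
    y = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    y = y.astype(float)
    ref = np.all(y > 0, axis=1)
    if not ref.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; consider adding a "
            "pseudocount or filtering samples"
        )
    logs = np.log(y[ref])
    geomean = np.exp(logs.mean(axis=1, keepdims=True))
    ratios = y[ref] / geomean
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise NormalizationError("non-positive size factor")
    return factors


def estimate_dispersions(
    counts: CountMatrix | np.ndarray,
    size_factors: np.ndarray,
    conditions: np.ndarray | list | None = None,
    shrinkage_weight: float = 0.5,
) -> np.ndarray:
    """Gene-wise MoM dispersions shrunk toward a fitted alpha(mu) trend.

    The gene-wise estimate is ``max(0, (s^2 - m) / m^2)`` on normalized
    counts, with the sample variance pooled within condition groups so
    real condition effects do not inflate it.  A trend
    ``alpha(mu) = a1 / mu + a0`` is fit by least squares over genes with
    positive gene-wise estimates; each gene with a positive estimate is
    shrunk halfway (in log space, with an alpha floor) toward the trend
    value at its mean, and genes whose gene-wise estimate is zero take
    the trend value directly.
    """
    y = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    y = y.astype(float)
    n = y.shape[1]
    if n < 2:
        raise EstimationError("dispersion estimation needs at least 2 samples")
    q = y / np.asarray(size_factors, dtype=float)[None, :]
    if conditions is None:
        groups = [np.arange(n)]
    else:
        conditions = np.asarray(conditions)
        groups = [np.where(conditions == c)[0] for c in pd.unique(conditions)]
    if all(len(g) < 2 for g in groups):
        raise EstimationError("need at least 2 replicates in some condition")
    ss = np.zeros(y.shape[0])
    df = 0
    for g in groups:
        if len(g) < 2:
            continue
        sub = q[:, g]
        ss += sub.var(axis=1, ddof=1) * (len(g) - 1)
        df += len(g) - 1
    s2 = ss / df
    m = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gw = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, 0.0)
    alpha_gw = np.maximum(alpha_gw, 0.0)

    fit_mask = (alpha_gw > 0) & (m > 0)
    if fit_mask.sum() >= 2:
        x = 1.0 / m[fit_mask]
        a1, a0 = np.polyfit(x, alpha_gw[fit_mask], 1)
        a0 = max(a0, _ALPHA_FLOOR)
        a1 = max(a1, 0.0)
    else:  # degenerate input: flat near-zero trend
        a0, a1 = _ALPHA_FLOOR, 0.0
    trend = np.where(m > 0, a1 / np.maximum(m, 1e-300) + a0, a0)
    trend = np.maximum(trend, _ALPHA_FLOOR)

    # a zero gene-wise estimate carries no overdispersion signal at small
    # df; those genes take the trend value (the far-tail calibration of the
    # Wald test collapses if they are shrunk toward the floor instead)
    w = shrinkage_weight
    log_shrunk = np.where(
        alpha_gw > 0,
        (1 - w) * np.log(np.maximum(alpha_gw, _ALPHA_FLOOR)) + w * np.log(trend),
        np.log(trend),
    )
    return np.exp(log_shrunk)


def _fit_nb_glm_two_group(
    y: np.ndarray,
    sf: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for ``mu_ij = sf_j * exp(b0_i + b1_i * x_j)``.

    Returns (b0, b1, se_b1, converged) over genes.  Working weights are
    ``mu / (1 + alpha * mu)`` (log link, NB2 variance).
    """
    y = y.astype(float)
    g, n = y.shape
    offs = np.log(sf)[None, :]
    x = x.astype(float)[None, :]
    eps = 1e-8
    m0 = (y / sf).T[x[0] == 0].T.mean(axis=1)
    m1 = (y / sf).T[x[0] == 1].T.mean(axis=1)
    b0 = np.log(np.maximum(m0, eps))
    b1 = np.log(np.maximum(m1, eps)) - b0
    alpha = np.maximum(alpha, _ALPHA_FLOOR)[:, None]
    converged = np.zeros(g, dtype=bool)
    se_b1 = np.full(g, np.nan)
    swxx_det = np.full(g, np.nan)  # Sw / det, for the SE
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x + offs
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offs) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        ok = det > 1e-300
        nb0 = np.where(ok, (swxx * swz - swx * swxz) / np.where(ok, det, 1.0), b0)
        nb1 = np.where(ok, (sw * swxz - swx * swz) / np.where(ok, det, 1.0), b1)
        nb0 = np.clip(nb0, -50, 50)
        nb1 = np.clip(nb1, -50, 50)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        swxx_det = np.where(ok, sw / np.where(ok, det, 1.0), np.nan)
        newly = (step < tol) & ok
        converged |= newly
        if converged.all():
            break
    with np.errstate(invalid="ignore"):
        se_b1 = np.sqrt(swxx_det)
    return b0, b1, se_b1, converged


def nb_wald_contrast(
    counts: CountMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    generation: str = "F1",
) -> DEResult:
    """Wald test of condition B vs condition A for every gene.

    ``contrast`` is (reference condition, test condition); positive
    log2fc means higher expression under the test condition.  Genes with
    zero counts across all samples of both conditions are not tested.
    """
    cond_a, cond_b = contrast
    samples_a = sheet.samples_for(counts.species_tag, generation, cond_a)
    samples_b = sheet.samples_for(counts.species_tag, generation, cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise EstimationError(
            f"contrast {contrast} needs >=2 replicates per condition "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )
    sub = counts.subset_samples(samples_a + samples_b)
    x = np.array([0] * len(samples_a) + [1] * len(samples_b))
    if size_factors is None:
        size_factors = compute_size_factors(sub)
    else:
        size_factors = np.asarray(size_factors, dtype=float)
        if size_factors.shape[0] == len(counts.sample_ids):
            pos = {s: j for j, s in enumerate(counts.sample_ids)}
            size_factors = size_factors[[pos[s] for s in sub.sample_ids]]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, size_factors, conditions=x)
    else:
        dispersions = np.asarray(dispersions, dtype=float)

    y = sub.counts
    testable = y.sum(axis=1) > 0
    g = y.shape[0]
    b0 = np.full(g, np.nan)
    b1 = np.full(g, np.nan)
    se = np.full(g, np.nan)
    conv = np.zeros(g, dtype=bool)
    if testable.any():
        b0_t, b1_t, se_t, conv_t = _fit_nb_glm_two_group(
            y[testable], size_factors, x, dispersions[testable]
        )
        b0[testable], b1[testable], se[testable], conv[testable] = b0_t, b1_t, se_t, conv_t
    tested = testable & conv & np.isfinite(se) & (se > 0)

    base_mean = (y / size_factors[None, :]).mean(axis=1)
    log2fc = b1 / _LN2
    se_log2fc = se / _LN2
    wald = np.where(tested, b1 / se, np.nan)
    p = np.where(tested, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
    padj = np.full(g, np.nan)
    padj[tested] = bh_adjust(p[tested])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se_log2fc": np.where(tested, se_log2fc, np.nan),
            "wald_stat": wald,
            "p": p,
            "padj": padj,
            "tested": tested,
        },
        index=pd.Index(sub.gene_ids, name="gene"),
    )
    return DEResult(contrast=(cond_a, cond_b), table=table, species=counts.species_tag)


def bh_adjust(pvalues: np.ndarray | list, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries are excluded from the effective test count ``m`` and stay
    NaN in the output.  Output is elementwise >= input and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    k = vals.size
    if k == 0:
        return out
    m_eff = k if m is None else int(m)
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m_eff / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(k)
    result[order] = adj
    out[mask] = result
    return out


def call_degs(
    result: DEResult,
    fold_change_threshold: float = 2.0,
    padj_threshold: float = 0.01,
) -> DEGCall:
    """Apply the >fold-change, padj<cutoff rule (strict inequalities)."""
    t = result.table
    lfc_cut = math.log2(fold_change_threshold)
    ok = t["tested"].astype(bool) & t["padj"].notna() & (t["padj"] < padj_threshold)
    up = frozenset(t.index[ok & (t["log2fc"] > lfc_cut)])
    down = frozenset(t.index[ok & (t["log2fc"] < -lfc_cut)])
    label = f"{result.species}:{result.contrast[1]}_vs_{result.contrast[0]}"
    return DEGCall(label, fold_change_threshold, padj_threshold, up, down)
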