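"""Negative-binomial differential small-RNA analysis (mutant vs control).

A deliberately transparent two-condition pipeline in the DESeq2 mould:
median-of-ratios size factors, per-gene method-of-moments dispersion (no
shrinkage toward a trend), a log-link NB GLM fitted by Fisher scoring with
the size factors as offsets, and a Wald test on the condition coefficient.
Small-sample calibration uses a t reference distribution with the residual
degrees of freedom (n_samples - 2) rather than the normal. Benjamini-
Hochberg controls the FDR; the headline gene set is FDR < 0.05 and
log2FC > 1 on the up-regulated side.

Externally computed results (e.g. an actual DESeq2 table) can be ingested
via :func:`read_results_tsv` and flow through the rest of the pipeline
unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-4
RESULT_COLUMNS = ("gene_id", "base_mean", "log2fc", "p_value", "fdr", "significant_up")

#: column aliases accepted when ingesting external (DESeq2-shaped) results
_ALIASES = {
    "gene_id": ("gene_id", "gene", "id"),
    "base_mean": ("base_mean", "baseMean", "basemean"),
    "log2fc": ("log2fc", "log2FoldChange", "log2_fc", "lfc"),
    "p_value": ("p_value", "pvalue", "pval", "p"),
    "fdr": ("fdr", "padj", "qvalue", "q_value"),
}


def size_factors(matrix: pd.DataFrame | np.ndarray, allow_zeros: bool = False) -> np.ndarray:
    """DESeq-style median-of-ratios size factors, one per sample (column).

    The reference is the per-gene geometric mean across samples; each
    sample's factor is the median count/reference ratio over usable genes.
    By default only genes with positive counts in every sample are usable;
    ``allow_zeros`` relaxes this to genes with a positive geometric mean over
    their positive entries (pseudo-reference fallback for sparse data).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (genes x samples)")
    with np.errstate(divide="ignore"):
        logm = np.log(m)
    pos = m > 0
    if allow_zeros:
        # pseudo-reference over positive entries; per-sample median restricted
        # to that sample's positive counts
        usable = pos.any(axis=1)
        if not usable.any():
            raise ValueError("count matrix is entirely zero")
        logref = np.where(pos, logm, np.nan)[usable].copy()
        logref = np.nanmean(logref, axis=1)
        logratio = logm[usable] - logref[:, None]
        factors = np.empty(m.shape[1])
        for s in range(m.shape[1]):
            vals = logratio[pos[usable][:, s], s]
            if vals.size == 0:
                raise ValueError(f"sample {s} has no positive counts")
            factors[s] = np.exp(np.median(vals))
        return factors
    usable = pos.all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "pass allow_zeros=True for the pseudo-reference fallback"
        )
    logref = logm[usable].mean(axis=1)
    ratios = logm[usable] - logref[:, None]
    return np.exp(np.median(ratios, axis=0))


def estimate_dispersion(
    matrix: pd.DataFrame | np.ndarray,
    factors: np.ndarray,
    conditions: np.ndarray | list,
    floor: float = DISPERSION_FLOOR,
    fixed: float | None = None,
) -> np.ndarray:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within-condition variance (pooled after centering each condition on its
    own mean) is compared with the overall normalized mean:
    ``alpha = (s^2 - mu) / mu^2``, floored at ``floor``. With ``fixed`` set,
    every gene gets that dispersion (required when a condition has a single
    replicate).
    """
    m = np.asarray(matrix, dtype=float)
    conditions = np.asarray(conditions)
    if fixed is not None:
        return np.full(m.shape[0], max(fixed, floor))
    levels, counts = np.unique(conditions, return_counts=True)
    if (counts < 2).any():
        raise ValueError(
            "every condition needs >= 2 replicates for dispersion estimation; "
            "supply fixed= to use a constant dispersion"
        )
    norm = m / np.asarray(factors, dtype=float)[None, :]
    ss = np.zeros(m.shape[0])
    for lev in levels:
        sub = norm[:, conditions == lev]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / (m.shape[1] - len(levels))
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha[~np.isfinite(alpha)] = floor
    return np.maximum(alpha, floor)


def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Fisher scoring for per-gene NB GLM log mu = o + b0 + b1 x.

    Returns (b0, b1, se_b1). ``y`` is genes x samples; ``alpha`` per-gene
    dispersion. Coefficients are clamped to keep separated designs (a group
    with all-zero counts) finite.
    """
    G = y.shape[0]
    mean0 = np.maximum((y * np.exp(-offset)).mean(axis=1), 1e-8)
    b0 = np.log(mean0)
    b1 = np.zeros(G)
    xb = x[None, :]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * xb + offset[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[:, None] * mu)  # Fisher weights for log link
        r = (y - mu) / (1.0 + alpha[:, None] * mu)  # score contributions
        A = w.sum(axis=1)
        B = (w * xb).sum(axis=1)
        C = (w * xb**2).sum(axis=1)
        U0 = r.sum(axis=1)
        U1 = (r * xb).sum(axis=1)
        det = np.maximum(A * C - B**2, 1e-300)
        d0 = (C * U0 - B * U1) / det
        d1 = (A * U1 - B * U0) / det
        step = np.clip(np.stack([d0, d1]), -5, 5)  # damped update
        b0 = np.clip(b0 + step[0], -50, 50)
        b1 = np.clip(b1 + step[1], -30, 30)
        if np.max(np.abs(step)) < tol:
            break
    eta = b0[:, None] + b1[:, None] * xb + offset[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha[:, None] * mu)
    A = w.sum(axis=1)
    B = (w * xb).sum(axis=1)
    C = (w * xb**2).sum(axis=1)
    det = np.maximum(A * C - B**2, 1e-300)
    se_b1 = np.sqrt(A / det)
    return b0, b1, se_b1


def nb_wald_test(
    matrix: pd.DataFrame,
    factors: np.ndarray,
    dispersions: np.ndarray,
    conditions: np.ndarray | list,
    control: str,
) -> pd.DataFrame:
    """Per-gene Wald test of the mutant-vs-control NB GLM coefficient.

    Returns a DataFrame with gene_id, base_mean, log2fc, p_value (no FDR
    yet). All-zero genes get NaN p-values and are excluded from later BH
    adjustment. p-values are two-sided from a t distribution with
    ``n_samples - 2`` degrees of freedom.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("matrix must be a DataFrame with gene_id index")
    conditions = np.asarray(conditions)
    levels = np.unique(conditions)
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {list(levels)}")
    if control not in levels:
        raise ValueError(f"control {control!r} not among conditions {list(levels)}")
    if (conditions == control).all() or (conditions != control).all():
        raise ValueError("degenerate design: one condition is empty")

    y = matrix.to_numpy(dtype=float)
    x = (conditions != control).astype(float)
    offset = np.log(np.asarray(factors, dtype=float))
    alpha = np.asarray(dispersions, dtype=float)

    nonzero = y.sum(axis=1) > 0
    b1 = np.full(y.shape[0], np.nan)
    se = np.full(y.shape[0], np.nan)
    if nonzero.any():
        _, b1_nz, se_nz = _nb_irls(y[nonzero], x, offset, alpha[nonzero])
        b1[nonzero] = b1_nz
        se[nonzero] = se_nz

    df_resid = max(y.shape[1] - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se
    p = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    p = np.where(nonzero, np.minimum(p, 1.0), np.nan)

    base_mean = (y / np.asarray(factors)[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "base_mean": base_mean,
            "log2fc": b1 / np.log(2.0),
            "p_value": p,
        }
    ).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving.

    NaN entries (undefined tests) are excluded from m and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    out[valid] = q
    return out


def call_significant(
    results: pd.DataFrame,
    direction: str = "up",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> set[str]:
    """Gene ids passing FDR < alpha and the fold-change rule.

    ``direction='up'`` requires log2fc > lfc_min (the pipeline's headline
    set); ``'both'`` requires |log2fc| > lfc_min.
    """
    if direction not in ("up", "both"):
        raise ValueError("direction must be 'up' or 'both'")
    fdr_ok = results["fdr"] < alpha
    lfc = results["log2fc"]
    lfc_ok = lfc > lfc_min if direction == "up" else lfc.abs() > lfc_min
    return set(results.loc[fdr_ok & lfc_ok, "gene_id"])


def run_differential(
    matrix: pd.DataFrame,
    conditions: np.ndarray | list,
    control: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    fixed_dispersion: float | None = None,
    allow_zeros: bool = False,
) -> pd.DataFrame:
    """Full differential call: size factors -> dispersion -> Wald -> BH.

    Returns the standard results table (RESULT_COLUMNS) with significant_up
    set from the (alpha, lfc_min) thresholds.
    """
    factors = size_factors(matrix, allow_zeros=allow_zeros)
    disp = estimate_dispersion(matrix, factors, conditions, fixed=fixed_dispersion)
    res = nb_wald_test(matrix, factors, disp, conditions, control)
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["significant_up"] = (res["fdr"] < alpha) & (res["log2fc"] > lfc_min)
    res["significant_up"] = res["significant_up"].fillna(False)
    return res[list(RESULT_COLUMNS)]


def read_results_tsv(path: str, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Ingest an external results table (native or DESeq2 column names)."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, aliases in _ALIASES.items():
        for a in aliases:
            if a in df.columns:
                rename[a] = canonical
                break
        else:
            raise ValueError(f"results table lacks a column for {canonical!r} (any of {aliases})")
    df = df.rename(columns=rename)
    df["significant_up"] = ((df["fdr"] < alpha) & (df["log2fc"] > lfc_min)).fillna(False)
    return df[list(RESULT_COLUMNS)]


def write_results_tsv(results: pd.DataFrame, path: str) -> None:
    results.to_csv(path, sep="\t", index=False)
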