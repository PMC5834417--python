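"""Cross-tracer, cross-region association analysis.

Relates regional uptake of one tracer to regional uptake of another across
subjects — e.g. amyloid signal in thalamus against tau signal in
hippocampus — as a matrix of signed coefficients of determination:
sign(r)·r² per region pair, with cells of small magnitude masked for
display (the raw values are always retained alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["SignedR2Matrix", "signed_r2_matrix", "covariate_r2"]


@dataclass
class SignedR2Matrix:
    """Signed-R² association matrix between two region×subject measures.

    ``values`` has cells with |signed R²| ≤ ``mask_threshold`` set to NaN;
    ``raw`` keeps every value; ``p_values`` holds the per-cell correlation
    test p-values (optionally Benjamini–Hochberg adjusted); ``n`` the number
    of complete subject pairs per cell.
    """

    values: pd.DataFrame        # masked signed R², rows = measure A regions
    raw: pd.DataFrame
    p_values: pd.DataFrame
    n: pd.DataFrame
    mask_threshold: float


def signed_r2_matrix(
    measure_a: pd.DataFrame,
    measure_b: pd.DataFrame,
    mask_threshold: float = 0.3,
    method: str = "pearson",
    fdr: bool = False,
) -> SignedR2Matrix:
    """Signed-R² matrix between two subjects×regions tables.

    Inputs are wide tables indexed by subject with one column per region
    (e.g. BP_ND of tracer A and tracer B). Each cell is sign(r)·r² of the
    across-subject correlation between a region of A and a region of B,
    computed over subjects present in both tables. Cells with fewer than 3
    complete pairs or zero variance are set missing with a warning. Masking
    only affects ``values``; ``raw`` is never destroyed.

    ``method`` is "pearson" (default, matching the linear-regression
    framing) or "spearman"; ``fdr=True`` applies Benjamini–Hochberg to the
    p-values (off by default).
    """
    if not 0 <= mask_threshold <= 1:
        raise ValueError("mask_threshold must be in [0, 1]")
    corr_fn = {"pearson": pearsonr, "spearman": spearmanr}.get(method)
    if corr_fn is None:
        raise ValueError(f"unknown correlation method {method!r}")
    common = measure_a.index.intersection(measure_b.index)
    a = measure_a.loc[common]
    b = measure_b.loc[common]

    raw = pd.DataFrame(np.nan, index=a.columns, columns=b.columns, dtype=float)
    pvals = raw.copy()
    counts = pd.DataFrame(0, index=a.columns, columns=b.columns, dtype=int)
    for ra in a.columns:
        for rb in b.columns:
            pair = pd.concat([a[ra], b[rb]], axis=1).dropna()
            counts.loc[ra, rb] = len(pair)
            if len(pair) < 3:
                logger.warning("cell (%s, %s): %d complete pairs; set missing",
                               ra, rb, len(pair))
                continue
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("cell (%s, %s): zero variance; set missing", ra, rb)
                continue
            r, p = corr_fn(x, y)
            raw.loc[ra, rb] = np.sign(r) * r * r
            pvals.loc[ra, rb] = p
    if fdr:
        flat = pvals.to_numpy().ravel()
        ok = np.isfinite(flat)
        if ok.any():
            flat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
            pvals = pd.DataFrame(flat.reshape(pvals.shape),
                                 index=pvals.index, columns=pvals.columns)
    values = raw.mask(raw.abs() <= mask_threshold)
    return SignedR2Matrix(values=values, raw=raw, p_values=pvals, n=counts,
                          mask_threshold=mask_threshold)


def covariate_r2(values: np.ndarray, covariate: np.ndarray) -> float:
    """Squared Pearson correlation between a regional measure and a
    per-subject covariate (e.g. a cognitive score)."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if v.shape != c.shape or v.ndim != 1:
        raise ValueError("values and covariate must be equal-length vectors")
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(c) == 0 or np.ptp(v) == 0:
        raise ValueError("zero variance in values or covariate")
    r, _ = pearsonr(v, c)
    return float(r * r)
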