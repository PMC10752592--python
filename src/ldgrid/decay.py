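"""Model-based LD-decay regression.

Under genome-wide spread of recombination hotspots a chromosome is a chain
of exchangeable LD segments, so its mean LD satisfies
l_i = (1/beta_i)[E(l_u) - E(l_uv)] + E(l_uv) with beta_i = m_i / m_seg.
Regressing the C chromosomal l_i on x_i = 1/m_i therefore gives

    slope      b1 ~ [E(l_u) - E(l_uv)] * m_seg   (the LD-decay score)
    intercept  b0 ~ E(l_uv)                      (the long-distance LD score)

The fit is ordinary least squares with population-moment (divide-by-C)
covariances, which is the same line; Pearson's R of (x, l) measures how well
a cohort follows the linear norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DecayFit:
    b0: float
    b1: float
    pearson_r: float
    x: np.ndarray
    l: np.ndarray
    residuals: np.ndarray


@dataclass
class LocoTable:
    """Leave-one-chromosome-out refits: label, refit R, delta vs full fit."""

    table: pd.DataFrame


def fit_decay_regression(l, m) -> DecayFit:
    """OLS of chromosomal mean LD on the inverse SNP count.

    ``l`` are the C >= 3 chromosomal mean-LD values, ``m`` the SNP counts.
    """
    l = np.asarray(l, dtype=np.float64)
    m = np.asarray(m)
    if l.shape != m.shape or l.ndim != 1:
        raise ValueError("l and m must be matching 1-D vectors")
    if l.size < 3:
        raise ValueError("decay regression needs at least 3 chromosomes")
    if (m < 2).any():
        raise ValueError("every chromosome needs at least 2 SNPs")
    x = 1.0 / m.astype(np.float64)
    var_x = np.mean(x * x) - np.mean(x) ** 2
    if var_x == 0.0:
        raise ValueError("all SNP counts equal; slope undefined")
    cov_xl = np.mean(x * l) - np.mean(x) * np.mean(l)
    b1 = cov_xl / var_x
    b0 = np.mean(l) - b1 * np.mean(x)
    r = float(np.corrcoef(x, l)[0, 1])
    residuals = l - (b0 + b1 * x)
    return DecayFit(b0=float(b0), b1=float(b1), pearson_r=r,
                    x=x, l=l, residuals=residuals)


def recover_segment_parameters(fit: DecayFit, segment_m: int) -> tuple[float, float]:
    """Invert the decay line into segment-level means:
    E(l_uv) = b0 and E(l_u) = b1 / m_seg + b0."""
    if segment_m < 1:
        raise ValueError("segment size must be positive")
    e_luv = fit.b0
    e_lu = fit.b1 / segment_m + fit.b0
    return e_lu, e_luv


def loco_analysis(l, m, labels=None) -> LocoTable:
    """Refit the decay line dropping each chromosome in turn.

    A chromosome whose removal lifts Pearson's R the most is the one most
    at odds with the linear norm (e.g. a centromere-inflated chromosome).
    """
    l = np.asarray(l, dtype=np.float64)
    m = np.asarray(m)
    if l.size < 4:
        raise ValueError("leave-one-out needs at least 4 chromosomes")
    if labels is None:
        labels = [str(i + 1) for i in range(l.size)]
    full = fit_decay_regression(l, m)
    rows = []
    for i in range(l.size):
        keep = np.arange(l.size) != i
        refit = fit_decay_regression(l[keep], m[keep])
        rows.append({"dropped": labels[i],
                     "pearson_r": refit.pearson_r,
                     "delta_r": refit.pearson_r - full.pearson_r,
                     "b0": refit.b0, "b1": refit.b1})
    return LocoTable(table=pd.DataFrame(rows))
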