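"""Expression-side procedures: expressed-gene flags, differential-direction
classification, the mean-expression slope test, and ddCt qPCR quantification.

Differential significance itself is an external input (gene x contrast
significance calls with a direction); this module only classifies
direction patterns into consistently up / consistently down / complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable

__all__ = [
    "DEClassification",
    "QpcrRecord",
    "expressed_genes",
    "classify_de_direction",
    "slope_test",
    "ddct_relative_expression",
]

DE_CLASSES = ("up", "down", "complex", "ns")


@dataclass(frozen=True)
class DEClassification:
    """Direction-consistency class of one gene across pairwise contrasts."""

    gene_id: str
    de_class: str
    significant_contrasts: tuple[str, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.de_class not in DE_CLASSES:
            raise ValueError(f"unknown DE class {self.de_class!r}")


def expressed_genes(
    expr: ExpressionTable, threshold: float = 1.0
) -> pd.DataFrame:
    """Expressed-gene flags: per timepoint and globally.

    Replicate FPKMs are averaged per timepoint first; a gene is expressed
    at a timepoint when its mean FPKM strictly exceeds *threshold*
    (FPKM > 1 by default), and globally expressed when that holds at any
    timepoint. Returns a gene-indexed DataFrame with one boolean column
    per timepoint plus ``global``.
    """
    fpkm = expr.mean_fpkm()
    flags = fpkm > threshold
    flags["global"] = flags.any(axis=1)
    return flags


def classify_de_direction(sig_calls: pd.DataFrame) -> list[DEClassification]:
    """Classify genes by the consistency of their significant DE directions.

    *sig_calls* has columns gene_id, contrast, direction (up/down) and
    significant (0/1). A gene is ``up`` when it has at least one
    significant contrast and every significant direction is up; ``down``
    symmetrically; ``complex`` when both directions reach significance;
    ``ns`` with no significant contrast. Unknown direction tokens raise.
    """
    bad = set(sig_calls["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown direction tokens {sorted(bad)}")
    out = []
    for gene_id, grp in sig_calls.groupby("gene_id", sort=True):
        sig = grp[grp["significant"].astype(int) == 1]
        dirs = tuple(sig["direction"])
        if not dirs:
            cls = "ns"
        elif all(d == "up" for d in dirs):
            cls = "up"
        elif all(d == "down" for d in dirs):
            cls = "down"
        else:
            cls = "complex"
        out.append(
            DEClassification(gene_id, cls, tuple(sig["contrast"]), dirs)
        )
    return out


def slope_test(
    mean_expression: Sequence[float], times: Sequence[float]
) -> tuple[float, float]:
    """OLS slope of mean expression against time, with the zero-slope t-test.

    Returns ``(slope, p)`` where p is the two-sided tail of the t statistic
    with T-2 degrees of freedom. A perfect fit (zero residual) reports
    p = 0 by convention. Requires at least 3 timepoints.
    """
    y = np.asarray(mean_expression, dtype=float)
    t = np.asarray(times, dtype=float)
    n = y.size
    if n < 3 or t.size != n:
        raise ValueError("need >= 3 timepoints with matching times")
    if np.all(t == t[0]):
        raise ValueError("times must not be constant")
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    resid = y - (ybar + slope * (t - tbar))
    sse = float(np.sum(resid**2))
    if sse <= 0 or math.isclose(sse, 0.0, abs_tol=1e-30):
        return slope, 0.0 if slope != 0 else 1.0
    se = math.sqrt(sse / (n - 2) / sxx)
    tstat = slope / se
    p = 2.0 * float(stats.t.sf(abs(tstat), df=n - 2))
    return slope, p


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement; ``ct=None`` encodes an undetected target."""

    sample: str
    gene: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct <= 40):
            raise ValueError(f"Ct must lie in (0, 40], got {self.ct}")


def ddct_relative_expression(
    records: Iterable[QpcrRecord],
    target_gene: str,
    reference_gene: str,
    calibrator_samples: Sequence[str],
    undetected_ct: float = 40.0,
) -> dict[str, float]:
    """Relative expression per sample by the ddCt method.

    ``dCt = Ct(target) - Ct(reference)`` per sample (technical replicates
    averaged; undetected targets entered at ``undetected_ct`` before
    differencing), ``ddCt = dCt - mean dCt(calibrator samples)``, relative
    expression ``2^(-ddCt)``. The reference gene must be measured in every
    sample; calibrator samples must be present.
    """
    ct: dict[tuple[str, str], list[float]] = {}
    for r in records:
        val = undetected_ct if r.ct is None else r.ct
        ct.setdefault((r.sample, r.gene), []).append(val)
    samples = sorted({s for s, _ in ct})

    def mean_ct(sample: str, gene: str) -> float:
        key = (sample, gene)
        if gene == reference_gene and key not in ct:
            raise ValueError(f"reference gene {gene!r} not measured in sample {sample!r}")
        vals = ct.get(key, [undetected_ct])
        return float(np.mean(vals))

    dct = {s: mean_ct(s, target_gene) - mean_ct(s, reference_gene) for s in samples}
    missing = [s for s in calibrator_samples if s not in dct]
    if missing:
        raise ValueError(f"calibrator samples absent from data: {missing}")
    calib = float(np.mean([dct[s] for s in calibrator_samples]))
    return {s: float(2.0 ** (-(d - calib))) for s, d in dct.items()}
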