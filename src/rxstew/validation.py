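"""Cross-source agreement of metric series (invoice vs dispensing data).

Two nonparametric tools, both implemented here so the statistical core is
oracle-testable and dependency-light:

* Mann-Kendall trend test: S = sum over i<j of sign(x_j - x_i), with the
  tie-corrected variance Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)]/18
  over tie groups of size t, the standard +/-1 continuity correction, and a
  two-sided normal p-value.
* Spearman rank correlation: product-moment correlation of mid-ranks
  (average ranks for ties).

Correlation strength categories follow the surveillance convention used for
reporting: high (rho > 0.7), moderate (0.5 <= rho <= 0.7), low otherwise
(negative rho is low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PairingError


@dataclass
class MannKendallResult:
    s: int
    var_s: float
    z: float
    p: float


def mann_kendall(values: Sequence[float]) -> MannKendallResult:
    """Mann-Kendall trend test on an ordered series (n >= 3)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"Mann-Kendall requires n >= 3, got {n}")
    diff_sign = np.sign(x[np.newaxis, :] - x[:, np.newaxis])
    s = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:  # all values tied
        return MannKendallResult(s=s, var_s=0.0, z=0.0, p=1.0)
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return MannKendallResult(s=s, var_s=var_s, z=z, p=p)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based); ties receive the mean of their rank span."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: Pearson correlation of mid-ranks; nan if degenerate."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise PairingError(f"series lengths differ: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise InsufficientDataError("Spearman requires n >= 2")
    rx, ry = _midranks(xa), _midranks(ya)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def categorize_rho(rho: float) -> str:
    """high iff rho > 0.7; moderate iff 0.5 <= rho <= 0.7; otherwise low."""
    if math.isnan(rho):
        return "low"
    if rho > 0.7:
        return "high"
    if rho >= 0.5:
        return "moderate"
    return "low"


@dataclass
class ComparisonResult:
    facility: str
    n_overlap: int
    spearman_rho: float
    rho_category: str
    mk_a: MannKendallResult
    mk_b: MannKendallResult
    mean_difference: float  # mean(b - a) over overlapping months
    difference_sign: int = field(init=False)

    def __post_init__(self) -> None:
        self.difference_sign = int(np.sign(self.mean_difference))

    def to_dict(self) -> dict:
        return {
            "facility": self.facility,
            "n_overlap": self.n_overlap,
            "spearman_rho": self.spearman_rho,
            "rho_category": self.rho_category,
            "mk_a": vars(self.mk_a),
            "mk_b": vars(self.mk_b),
            "mean_difference": self.mean_difference,
            "difference_sign": self.difference_sign,
        }


def compare_sources(
    a: pd.DataFrame,
    b: pd.DataFrame,
    facility: str = "",
    value_column: str = "dot_per_1000_bdoc",
) -> ComparisonResult:
    """Compare two monthly metric series for one facility.

    Inputs carry ``month`` and *value_column*; comparison is restricted to
    overlapping months (>= 3 required).  ``mean_difference`` is the mean of
    b - a, so a consistently larger second source gives a positive sign.
    """
    sa = a.dropna(subset=[value_column]).set_index("month")[value_column]
    sb = b.dropna(subset=[value_column]).set_index("month")[value_column]
    months = sorted(set(sa.index) & set(sb.index))
    if len(months) < 3:
        raise InsufficientDataError(
            f"only {len(months)} overlapping months; need >= 3"
        )
    xa = sa.loc[months].to_numpy(dtype=float)
    xb = sb.loc[months].to_numpy(dtype=float)
    rho = spearman(xa, xb)
    return ComparisonResult(
        facility=facility,
        n_overlap=len(months),
        spearman_rho=rho,
        rho_category=categorize_rho(rho),
        mk_a=mann_kendall(xa),
        mk_b=mann_kendall(xb),
        mean_difference=float(np.mean(xb - xa)),
    )


def compare_all_facilities(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    value_column: str = "dot_per_1000_bdoc",
) -> pd.DataFrame:
    """Per-facility comparison table over facilities present in both sources."""
    rows = []
    shared = sorted(set(metrics_a["facility"]) & set(metrics_b["facility"]))
    for facility in shared:
        try:
            result = compare_sources(
                metrics_a[metrics_a["facility"] == facility],
                metrics_b[metrics_b["facility"] == facility],
                facility=facility,
                value_column=value_column,
            )
        except InsufficientDataError:
            continue
        rows.append(
            {
                "facility": facility,
                "n_overlap": result.n_overlap,
                "spearman_rho": result.spearman_rho,
                "rho_category": result.rho_category,
                "mk_z_a": result.mk_a.z,
                "mk_p_a": result.mk_a.p,
                "mk_z_b": result.mk_b.z,
                "mk_p_b": result.mk_b.p,
                "mean_difference": result.mean_difference,
                "difference_sign": result.difference_sign,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "facility", "n_overlap", "spearman_rho", "rho_category",
            "mk_z_a", "mk_p_a", "mk_z_b", "mk_p_b",
            "mean_difference", "difference_sign",
        ],
    )
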