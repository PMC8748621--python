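"""Pearson correlation screening of quantitative traits.

Computes the pairwise-complete Pearson correlation matrix over quantitative
traits with two-sided p-values from the exact t transform
t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom, and counts
significantly correlated trait pairs by sign.  No multiple-testing
correction is applied: germplasm surveys conventionally report raw
significant-pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema_io import PhenotypeMatrix


@dataclass
class CorrelationResult:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def pair_list(self) -> pd.DataFrame:
        """Long-format strict-upper-triangle listing (trait_a, trait_b, r, p, sign)."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1 :]:
                r = self.r.loc[a, b]
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": r,
                        "p": self.p.loc[a, b],
                        "n": self.n_used.loc[a, b],
                        "sign": "" if pd.isna(r) else ("+" if r > 0 else ("-" if r < 0 else "0")),
                    }
                )
        return pd.DataFrame(rows)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r on n observations via the t transform."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_matrix(matrix: PhenotypeMatrix | pd.DataFrame) -> CorrelationResult:
    """Pairwise-complete Pearson r and p over the quantitative traits.

    Traits constant over their complete observations cannot be correlated;
    they are excluded with a warning and their rows/columns set to NaN
    (diagonal kept at 1 for non-excluded traits).
    """
    block = (
        matrix.quantitative_block() if isinstance(matrix, PhenotypeMatrix) else matrix.astype(float)
    )
    traits = list(block.columns)
    q = len(traits)
    r = np.full((q, q), np.nan)
    p = np.full((q, q), np.nan)
    n_used = np.zeros((q, q), dtype=int)
    X = block.to_numpy()
    sds = np.nanstd(X, axis=0, ddof=1)
    excluded = [traits[j] for j in range(q) if not sds[j] > 0]
    if excluded:
        warnings.warn(
            f"constant trait(s) excluded from correlation: {excluded}", stacklevel=2
        )
    ok = [j for j in range(q) if traits[j] not in excluded]
    for j in ok:
        r[j, j] = 1.0
        p[j, j] = 0.0
        n_used[j, j] = int(np.isfinite(X[:, j]).sum())
    for ai in range(len(ok)):
        for bi in range(ai + 1, len(ok)):
            i, j = ok[ai], ok[bi]
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n = int(mask.sum())
            n_used[i, j] = n_used[j, i] = n
            if n < 3:
                continue
            xi, xj = X[mask, i], X[mask, j]
            if xi.std(ddof=1) == 0 or xj.std(ddof=1) == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pearson_pvalue(rij, n)
    return CorrelationResult(
        traits=traits,
        r=pd.DataFrame(r, index=traits, columns=traits),
        p=pd.DataFrame(p, index=traits, columns=traits),
        n_used=pd.DataFrame(n_used, index=traits, columns=traits),
        excluded=excluded,
    )


def count_significant_pairs(
    result: CorrelationResult, alpha: float = 0.05
) -> tuple[int, int, int]:
    """(total, positive, negative) significant pairs over the strict upper triangle."""
    positive = negative = 0
    for i, a in enumerate(result.traits):
        for b in result.traits[i + 1 :]:
            rv = result.r.loc[a, b]
            pv = result.p.loc[a, b]
            if pd.isna(rv) or pd.isna(pv) or not (pv < alpha):
                continue
            if rv > 0:
                positive += 1
            elif rv < 0:
                negative += 1
    return positive + negative, positive, negative
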