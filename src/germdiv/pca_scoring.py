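"""Correlation-matrix PCA, contribution rates, composite scoring and selection.

The trait correlation matrix R (q traits) is eigendecomposed; eigenvalues
E_1 >= ... >= E_q sum to q, and component j explains a contribution rate of
E_j/q.  The per-trait coefficients reported for each component are loadings —
eigenvectors scaled by sqrt(E_j) — whose column sums of squares recover E_j.
Components are retained by the Kaiser rule (E_j > 1) by default.

Each individual receives component scores F_j = sum_t loading[t, j] * x_t and
a composite value F = sum_j w_j F_j with unnormalized weights w_j = E_j/q
(they sum to the retained cumulative contribution, not to 1).  Individuals
are ranked by F and flagged as selected, by default those strictly above the
median F — candidate elite germplasm for further observation.

Scores use raw trait values by default (``mode="raw"``); ``"standardized"``
projects z-scores instead, in which case the score variance of component j
equals E_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ZeroVarianceError
from .schema_io import PhenotypeMatrix

_EIG_TOL = 1e-10


@dataclass
class PCAResult:
    traits: list[str]
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # column j = unit eigenvector j, sign-fixed
    loadings: pd.DataFrame  # trait x component, column j = eigenvector_j * sqrt(E_j)
    contribution: np.ndarray  # percent, E_j / q * 100
    cumulative: np.ndarray  # running sum of contribution
    retained: int

    def to_frame(self) -> pd.DataFrame:
        """Per-trait loading columns with eigenvalue/contribution/cumulative rows appended."""
        frame = self.loadings.copy()
        frame.loc["Eigenvalue (E)"] = self.eigenvalues
        frame.loc["Contribution (%)"] = self.contribution
        frame.loc["Cumulative (%)"] = self.cumulative
        return frame


def correlation_eigen(block: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Pearson correlation matrix of ``block``.

    Eigenvalues are sorted descending; each unit eigenvector's sign is fixed
    so its largest-magnitude element is positive, making results
    deterministic.
    """
    X = block.to_numpy(dtype=float)
    n, q = X.shape
    if q < 2:
        raise InsufficientDataError(f"PCA needs >= 2 traits, got {q}")
    if n < 3:
        raise InsufficientDataError(f"PCA needs >= 3 individuals, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values; use complete cases")
    sds = X.std(axis=0, ddof=1)
    if not (sds > 0).all():
        bad = [block.columns[i] for i in np.where(~(sds > 0))[0]]
        raise ZeroVarianceError(f"zero-SD trait(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        pivot = np.argmax(np.abs(V[:, j]))
        if V[pivot, j] < 0:
            V[:, j] = -V[:, j]
    return w, V


def loadings(eigenvalues: np.ndarray, eigenvectors: np.ndarray) -> np.ndarray:
    """Component loadings: eigenvector_j * sqrt(E_j)."""
    w = np.asarray(eigenvalues, dtype=float)
    if (w < -_EIG_TOL).any():
        raise ValueError(f"eigenvalue below tolerance: {w.min()}")
    return np.asarray(eigenvectors) * np.sqrt(np.clip(w, 0.0, None))


def contribution_rates(
    eigenvalues: np.ndarray, q: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component contribution 100*E_j/q (percent) and its running sum.

    ``q`` defaults to the number of eigenvalues supplied; pass it explicitly
    when only the leading eigenvalues of a larger decomposition are at hand.
    """
    w = np.asarray(eigenvalues, dtype=float)
    q = len(w) if q is None else q
    if q == 0:
        raise ValueError("q must be positive")
    contrib = 100.0 * w / q
    return contrib, np.cumsum(contrib)


def retain_components(
    eigenvalues: np.ndarray,
    rule: str = "kaiser",
    k: int | None = None,
    threshold: float = 70.0,
    q: int | None = None,
) -> int:
    """Number of components to keep.

    rule="kaiser": count of eigenvalues > 1 (default);
    rule="fixed": the supplied ``k``;
    rule="cumulative": smallest k whose cumulative contribution reaches
    ``threshold`` percent.
    """
    w = np.asarray(eigenvalues, dtype=float)
    if rule == "kaiser":
        return int((w > 1.0).sum())
    if rule == "fixed":
        if k is None:
            raise ValueError("rule='fixed' requires k")
        return int(k)
    if rule == "cumulative":
        _, cum = contribution_rates(w, q=q)
        reached = np.where(cum >= threshold)[0]
        return int(reached[0]) + 1 if reached.size else len(w)
    raise ValueError(f"unknown retention rule {rule!r}")


def component_scores(
    block: pd.DataFrame,
    loading_matrix: np.ndarray | pd.DataFrame,
    k: int,
    mode: str = "raw",
) -> pd.DataFrame:
    """Per-individual scores F_1..F_k = x . loading_j.

    ``mode="raw"`` projects raw trait values; ``"standardized"`` projects
    z-scores (score variance of component j then equals E_j).
    """
    if isinstance(loading_matrix, pd.DataFrame):
        if list(loading_matrix.index) != list(block.columns):
            raise ValueError("trait order of loadings does not match the data block")
        L = loading_matrix.to_numpy(dtype=float)
    else:
        L = np.asarray(loading_matrix, dtype=float)
        if L.shape[0] != block.shape[1]:
            raise ValueError("trait order/count of loadings does not match the data block")
    if mode not in ("raw", "standardized"):
        raise ValueError(f"unknown score mode {mode!r}")
    X = block.to_numpy(dtype=float)
    if mode == "standardized":
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    scores = X @ L[:, :k]
    return pd.DataFrame(
        scores, index=block.index, columns=[f"F{j + 1}" for j in range(k)]
    )


def composite_score(
    component_score_values: np.ndarray | pd.DataFrame, weights: np.ndarray
) -> np.ndarray | float:
    """Composite F = sum_j w_j F_j, weights w_j = E_j/q (unnormalized)."""
    S = (
        component_score_values.to_numpy(dtype=float)
        if isinstance(component_score_values, pd.DataFrame)
        else np.asarray(component_score_values, dtype=float)
    )
    w = np.asarray(weights, dtype=float)
    if S.shape[-1] != w.shape[0]:
        raise ValueError(f"got {S.shape[-1]} score column(s) but {w.shape[0]} weight(s)")
    F = S @ w
    return float(F) if np.ndim(F) == 0 else F


@dataclass
class ScoreTable:
    table: pd.DataFrame  # columns F1..Fk, F, rank, selected; index = individual id

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def rank_and_select(
    scores: pd.DataFrame,
    composite: np.ndarray,
    rule: str = "median",
    top_k: int | None = None,
    threshold: float | None = None,
) -> ScoreTable:
    """Rank individuals by composite F (descending, ties broken by ID) and
    flag selections.

    rule="median": F strictly above the median F (default);
    rule="top_k": the ``top_k`` best-ranked; rule="threshold": F > ``threshold``.
    """
    if len(scores) == 0:
        raise InsufficientDataError("no individuals to rank")
    table = scores.copy()
    table["F"] = np.asarray(composite, dtype=float)
    order = sorted(range(len(table)), key=lambda i: (-table["F"].iloc[i], str(table.index[i])))
    ranks = np.empty(len(table), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    table["rank"] = ranks
    if rule == "median":
        table["selected"] = table["F"] > float(np.median(table["F"]))
    elif rule == "top_k":
        if top_k is None:
            raise ValueError("rule='top_k' requires top_k")
        table["selected"] = table["rank"] <= top_k
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("rule='threshold' requires threshold")
        table["selected"] = table["F"] > threshold
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return ScoreTable(table=table)


def pca_scores(
    matrix: PhenotypeMatrix,
    retain_rule: str = "kaiser",
    k: int | None = None,
    cumulative_threshold: float = 70.0,
    score_mode: str = "raw",
    select_rule: str = "median",
    top_k: int | None = None,
    select_threshold: float | None = None,
) -> tuple[PCAResult, ScoreTable]:
    """End-to-end PCA scoring of a phenotype matrix (complete cases)."""
    block = matrix.quantitative_block(complete_cases=True)
    w, V = correlation_eigen(block)
    L = loadings(w, V)
    contrib, cum = contribution_rates(w)
    retained = retain_components(
        w, rule=retain_rule, k=k, threshold=cumulative_threshold
    )
    retained = max(1, min(retained, len(w)))
    loading_frame = pd.DataFrame(
        L, index=block.columns, columns=[f"PC{j + 1}" for j in range(len(w))]
    )
    result = PCAResult(
        traits=list(block.columns),
        eigenvalues=w,
        eigenvectors=V,
        loadings=loading_frame,
        contribution=contrib,
        cumulative=cum,
        retained=retained,
    )
    scores = component_scores(block, L, retained, mode=score_mode)
    weights = w[:retained] / len(w)
    F = composite_score(scores, weights)
    score_table = rank_and_select(
        scores, F, rule=select_rule, top_k=top_k, threshold=select_threshold
    )
    return result, score_table
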