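"""Per-trait diversity statistics.

Qualitative traits are summarized by class frequencies ("effective
percentages", computed over non-missing individuals) and the Shannon–Wiener
index H' = -sum(Pi ln Pi) in nats.  Quantitative traits are summarized by
min/max/mean/sample SD and the coefficient of variation CV = 100*s/mean, then
discretized into ten levels of width 0.5 SD around the sample mean (level 1
below mean - 2s, level 10 at or above mean + 2s) so that the same Shannon
index applies.  Under this scheme a normally distributed trait has
H' -> 2.088 in the large-sample limit, which is why observed values near 2
indicate a rich, evenly spread phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGradingError,
    InsufficientDataError,
    ZeroMeanError,
)
from .schema_io import PhenotypeMatrix, TraitSchema

N_LEVELS = 10
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {"fruit": ("FS", "FBS", "FTS", "PC")}


@dataclass
class TraitSummary:
    abbreviation: str
    minimum: float
    maximum: float
    mean: float
    sd: float
    cv: float  # percent
    h_prime: float | None = None


@dataclass
class FrequencyTable:
    abbreviation: str
    classes: list[str]
    counts: list[int]

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n

    @property
    def frequencies(self) -> np.ndarray:
        """Effective percentages Pi*100 over non-missing individuals."""
        return 100.0 * self.probabilities


@dataclass
class QualitativeRow:
    table: FrequencyTable
    h_prime: float


@dataclass
class DiversityTable:
    qualitative: list[QualitativeRow] = field(default_factory=list)
    quantitative: list[TraitSummary] = field(default_factory=list)
    subtotal_h: dict[str, float] = field(default_factory=dict)

    def qualitative_frame(self) -> pd.DataFrame:
        max_k = max((len(r.table.classes) for r in self.qualitative), default=0)
        rows = {}
        for r in self.qualitative:
            freqs = list(r.table.frequencies) + [np.nan] * (max_k - len(r.table.classes))
            rows[r.table.abbreviation] = freqs + [r.h_prime]
        frame = pd.DataFrame.from_dict(
            rows, orient="index", columns=[str(i + 1) for i in range(max_k)] + ["H'"]
        )
        frame.index.name = "trait"
        return frame

    def quantitative_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "trait": s.abbreviation,
                    "minimum": s.minimum,
                    "maximum": s.maximum,
                    "mean": s.mean,
                    "sd": s.sd,
                    "cv": s.cv,
                    "H'": s.h_prime,
                }
                for s in self.quantitative
            ]
        ).set_index("trait")
        return frame


def summarize_quantitative(values: Sequence[float], abbreviation: str = "") -> TraitSummary:
    """Min/max/mean/sample SD (n-1 denominator) and CV of non-missing values."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(
            f"trait {abbreviation or '?'}: need >= 2 non-missing values, got {x.size}"
        )
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return TraitSummary(
        abbreviation=abbreviation,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=mean,
        sd=sd,
        cv=coefficient_of_variation(mean, sd),
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = 100*sd/mean (percent); undefined at mean 0."""
    if mean == 0:
        raise ZeroMeanError("coefficient of variation undefined: mean is zero")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return 100.0 * sd / mean


def grade_quantitative(
    values: Sequence[float], abbreviation: str = ""
) -> tuple[np.ndarray, FrequencyTable]:
    """Assign each value to one of ten SD-width levels around the sample mean.

    Level 1: x < mean - 2s; level 10: x >= mean + 2s; levels 2..9 are
    half-open intervals of width 0.5 s (left-closed, right-open).  Returns the
    per-value level (1..10) and the level frequency table.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("grading requires finite values (filter missing first)")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateGradingError(
            f"trait {abbreviation or '?'}: sd is zero, grading degenerate"
        )
    levels = np.floor((x - mean) / (0.5 * sd)).astype(int) + 6
    levels = np.clip(levels, 1, N_LEVELS)
    counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
    table = FrequencyTable(
        abbreviation=abbreviation,
        classes=[str(i) for i in range(1, N_LEVELS + 1)],
        counts=[int(c) for c in counts],
    )
    return levels, table


def class_frequencies(
    codes: Iterable[str | None], classes: Sequence[str] | None = None, abbreviation: str = ""
) -> FrequencyTable:
    """Count class codes over non-missing individuals.

    ``classes`` fixes the (ordered) class vocabulary; declared classes with
    zero count are retained.  With ``classes=None`` the sorted observed codes
    are used.
    """
    observed = [str(c) for c in codes if c is not None and not (isinstance(c, float) and np.isnan(c))]
    if not observed:
        raise InsufficientDataError(f"trait {abbreviation or '?'}: all values missing")
    if classes is None:
        classes = sorted(set(observed))
    counts = {c: 0 for c in classes}
    for code in observed:
        if code not in counts:
            raise ValueError(
                f"trait {abbreviation or '?'}: code {code!r} not among declared classes"
            )
        counts[code] += 1
    return FrequencyTable(
        abbreviation=abbreviation, classes=list(classes), counts=[counts[c] for c in classes]
    )


def shannon_index(frequencies: Sequence[float]) -> float:
    """Shannon–Wiener H' = -sum(Pi ln Pi) in nats, with 0*ln(0) := 0.

    ``frequencies`` is a probability vector (sums to 1 within 1e-6).
    """
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum():.8f}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def diversity_table(
    matrix: PhenotypeMatrix,
    schema: TraitSchema | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> DiversityTable:
    """Full per-trait diversity table with named-group H' subtotals.

    Qualitative traits: class frequencies -> H'.  Quantitative traits:
    summary stats + ten-level grading -> H'.  The default group "fruit"
    comprises the fruit-form qualitative traits (FS, FBS, FTS, PC).
    """
    schema = schema or matrix.schema
    groups = DEFAULT_GROUPS if groups is None else groups
    result = DiversityTable()
    h_by_trait: dict[str, float] = {}
    for trait in matrix.schema.qualitative:
        table = class_frequencies(
            matrix.data[trait.abbreviation],
            classes=schema[trait.abbreviation].classes,
            abbreviation=trait.abbreviation,
        )
        h = shannon_index(table.probabilities)
        h_by_trait[trait.abbreviation] = h
        result.qualitative.append(QualitativeRow(table=table, h_prime=h))
    for trait in matrix.schema.quantitative:
        values = matrix.data[trait.abbreviation].astype(float).dropna().to_numpy()
        summary = summarize_quantitative(values, abbreviation=trait.abbreviation)
        _, level_table = grade_quantitative(values, abbreviation=trait.abbreviation)
        summary.h_prime = shannon_index(level_table.probabilities)
        h_by_trait[trait.abbreviation] = summary.h_prime
        result.quantitative.append(summary)
    for name, members in groups.items():
        present = [m for m in members if m in h_by_trait]
        result.subtotal_h[name] = float(sum(h_by_trait[m] for m in present))
    return result
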