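"""Seeded synthetic germplasm cohorts.

The study's raw 151-tree phenotype table is unpublished; only per-trait
summaries (means, SDs, class frequencies) are printed.  This module draws
cohorts with exactly that marginal structure — multivariate normal
quantitative traits with configurable correlation, independent categorical
qualitative traits — so every downstream stage (diversity, correlation,
clustering, PCA scoring) can be exercised and property-tested.

Defaults are the published summary statistics: n = 151 individuals, 29
quantitative traits with the printed means/SDs, 8 qualitative traits with the
printed class frequencies.  Draws are untruncated by default: grading and CV
use the sample mean/SD, and truncation would bias parameter-recovery checks;
``clip=True`` clips to the published per-trait minima/maxima instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, NotPositiveSemidefiniteError
from .schema_io import PhenotypeMatrix, TraitSchema, default_schema

_PSD_TOL = 1e-10
_PROB_TOL = 1e-9

# Arbitrary but plausible block correlations used by the "blocks" preset so
# that clustering/PCA demos have structure; not estimates of the real crop.
_BLOCK_PRESET = {
    "tree": (("TH", "CB", "TFD", "YPT"), 0.5),
    "leaf": (("PEL", "LLL", "LLW"), 0.5),
    "fruit": (("FW", "FD", "FL", "PL", "PW", "PIL"), 0.6),
}


@dataclass
class CohortConfig:
    """Everything needed to draw one cohort.

    quantitative_specs: ``{abbr: {"mean": m, "sd": s}}`` (optionally with
    ``minimum``/``maximum`` used only when ``clip`` is on);
    qualitative_specs: ``{abbr: {class_code: probability}}``;
    correlation: square matrix over the quantitative traits in spec order,
    or ``None`` for identity.
    """

    n_individuals: int
    quantitative_specs: dict[str, dict[str, float]]
    qualitative_specs: dict[str, dict[str, float]]
    correlation: np.ndarray | None = None
    seed: int = 0
    clip: bool = False

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("empty cohort: n_individuals must be >= 1")
        for abbr, spec in self.quantitative_specs.items():
            if spec["sd"] < 0:
                raise ConfigError(f"negative sd for trait {abbr!r}")
        for abbr, probs in self.qualitative_specs.items():
            p = np.asarray(list(probs.values()), dtype=float)
            if (p < 0).any():
                raise ConfigError(f"negative class probability for trait {abbr!r}")
            if abs(p.sum() - 1.0) > _PROB_TOL:
                raise ConfigError(
                    f"class probabilities for trait {abbr!r} sum to {p.sum():.12f}, not 1"
                )
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            q = len(self.quantitative_specs)
            if R.shape != (q, q):
                raise ConfigError(f"correlation must be {q}x{q}, got {R.shape}")
            if not np.allclose(R, R.T, atol=1e-12):
                raise ConfigError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ConfigError("correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(R).min() < -_PSD_TOL:
                raise NotPositiveSemidefiniteError(
                    "correlation matrix has eigenvalues below tolerance"
                )


def _load_default_params() -> dict:
    text = resources.files("germdiv.data").joinpath("default_cohort.yaml").read_text()
    return yaml.safe_load(text)


def blocks_correlation(abbreviations: list[str]) -> np.ndarray:
    """The 'blocks' preset: identity plus moderate within-block correlations
    for tree-size, leaf-size and fruit-size trait groups (values arbitrary)."""
    q = len(abbreviations)
    idx = {a: i for i, a in enumerate(abbreviations)}
    R = np.eye(q)
    for members, r in _BLOCK_PRESET.values():
        present = [idx[a] for a in members if a in idx]
        for i in present:
            for j in present:
                if i != j:
                    R[i, j] = r
    return R


def default_config(
    n_individuals: int | None = None,
    seed: int = 0,
    correlation: str | np.ndarray | None = "identity",
) -> CohortConfig:
    """Config preloaded with the published cohort size and trait summaries.

    ``correlation`` may be ``"identity"``, ``"blocks"`` (see
    :func:`blocks_correlation`) or an explicit matrix.
    """
    params = _load_default_params()
    quant = {a: dict(s) for a, s in params["quantitative"].items()}
    qual: dict[str, dict[str, float]] = {}
    for abbr, freqs in params["qualitative"].items():
        total = float(sum(freqs.values()))
        qual[abbr] = {str(c): float(f) / total for c, f in freqs.items()}
    if isinstance(correlation, str):
        if correlation == "identity":
            R = None
        elif correlation == "blocks":
            R = blocks_correlation(list(quant))
        else:
            raise ConfigError(f"unknown correlation preset {correlation!r}")
    else:
        R = correlation
    return CohortConfig(
        n_individuals=n_individuals if n_individuals is not None else int(params["n_individuals"]),
        quantitative_specs=quant,
        qualitative_specs=qual,
        correlation=R,
        seed=seed,
    )


def load_cohort_config(path: str | Path, seed: int | None = None) -> CohortConfig:
    """Read a cohort config from YAML/JSON with the same layout as the bundled
    defaults; omitted sections fall back to the defaults."""
    doc = yaml.safe_load(Path(path).read_text())
    base = _load_default_params()
    quant = {a: dict(s) for a, s in doc.get("quantitative", base["quantitative"]).items()}
    qual_raw = doc.get("qualitative", base["qualitative"])
    qual = {
        str(a): {str(c): float(f) / float(sum(freqs.values())) for c, f in freqs.items()}
        for a, freqs in qual_raw.items()
    }
    R = doc.get("correlation")
    if isinstance(R, list):
        R = np.asarray(R, dtype=float)
    elif isinstance(R, str):
        R = blocks_correlation(list(quant)) if R == "blocks" else None
    return CohortConfig(
        n_individuals=int(doc.get("n_individuals", base["n_individuals"])),
        quantitative_specs=quant,
        qualitative_specs=qual,
        correlation=R,
        seed=int(doc.get("seed", 0)) if seed is None else seed,
        clip=bool(doc.get("clip", False)),
    )


def _correlation_factor(R: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L @ L.T = R, tolerating semidefinite R."""
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        if w.min() < -_PSD_TOL:
            raise NotPositiveSemidefiniteError(
                "correlation matrix has eigenvalues below tolerance"
            ) from None
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_quantitative(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the n x q quantitative block from the configured multivariate normal."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    abbrs = list(config.quantitative_specs)
    means = np.array([config.quantitative_specs[a]["mean"] for a in abbrs])
    sds = np.array([config.quantitative_specs[a]["sd"] for a in abbrs])
    q = len(abbrs)
    R = np.eye(q) if config.correlation is None else np.asarray(config.correlation, dtype=float)
    L = _correlation_factor(R)
    z = rng.standard_normal((config.n_individuals, q))
    X = means + (z @ L.T) * sds
    if config.clip:
        lo = np.array(
            [config.quantitative_specs[a].get("minimum", -np.inf) for a in abbrs], dtype=float
        )
        hi = np.array(
            [config.quantitative_specs[a].get("maximum", np.inf) for a in abbrs], dtype=float
        )
        X = np.clip(X, lo, hi)
    return pd.DataFrame(X, columns=abbrs)


def generate_qualitative(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the qualitative block: independent categorical draws per trait."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    columns = {}
    for abbr, probs in config.qualitative_specs.items():
        classes = list(probs)
        p = np.asarray([probs[c] for c in classes], dtype=float)
        p = p / p.sum()  # remove float round-off within tolerance
        columns[abbr] = rng.choice(classes, size=config.n_individuals, p=p)
    return pd.DataFrame(columns)


def generate_cohort(
    config: CohortConfig, schema: TraitSchema | None = None
) -> PhenotypeMatrix:
    """Assemble a full cohort (ids S0001.. plus both trait blocks) against
    ``schema`` (default: the bundled 37-trait schema)."""
    config.validate()
    schema = schema or default_schema()
    ss = np.random.SeedSequence(config.seed)
    rng_quant, rng_qual = (np.random.default_rng(c) for c in ss.spawn(2))
    quant = generate_quantitative(config, rng_quant)
    qual = generate_qualitative(config, rng_qual)
    ids = [f"S{i + 1:04d}" for i in range(config.n_individuals)]
    data = pd.concat([qual, quant], axis=1)
    data.index = pd.Index(ids, name="id")
    present = [a for a in data.columns]
    sub = schema.subset(present)
    return PhenotypeMatrix(data=data, schema=sub)
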