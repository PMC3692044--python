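"""Linear repression scoring, percentile transformation, aggregation.

Feature values computed per site are aggregated to miRNA–UTR pair level
(summed, with the over-representation p-values recomputed at pair level
and the site count carried along), combined by an ordinary-least-squares
linear model into a predicted log2 fold-change (more negative = stronger
repression), and optionally converted to empirical percentiles where 100
is always the strongest predicted repression regardless of a feature's
natural direction.

No published coefficients exist for this model; the package ships demo
coefficients fitted on its own synthetic dataset (clearly labeled) and a
``fit`` routine for user training tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: the feature registry: every feature the pipeline can produce, with its
#: direction (whether lower or higher raw values mean stronger repression)
LOWER_IS_STRONGER = "lower_is_stronger"
HIGHER_IS_STRONGER = "higher_is_stronger"

FEATURE_DIRECTIONS: dict[str, str] = {
    "dg_duplex": LOWER_IS_STRONGER,
    "dg_binding": LOWER_IS_STRONGER,
    "dg_seed_duplex": LOWER_IS_STRONGER,
    "dg_seed_binding": LOWER_IS_STRONGER,
    "dg_open": LOWER_IS_STRONGER,
    "dg_total": LOWER_IS_STRONGER,
    "prob_binomial": LOWER_IS_STRONGER,
    "prob_exact": LOWER_IS_STRONGER,
    "utr_position": LOWER_IS_STRONGER,
    "score": LOWER_IS_STRONGER,
    "bls": HIGHER_IS_STRONGER,
    "phylop_score": HIGHER_IS_STRONGER,
    "au_content": HIGHER_IS_STRONGER,
    "three_prime_pairing": HIGHER_IS_STRONGER,
    "site_count": HIGHER_IS_STRONGER,
}

#: features summed over sites when aggregating to pair level
_SUMMED = (
    "dg_duplex", "dg_binding", "dg_seed_duplex", "dg_seed_binding",
    "dg_open", "dg_total", "bls", "phylop_score", "au_content",
    "three_prime_pairing",
)
#: features defined at pair level (functions of the whole UTR)
_PAIR_LEVEL = ("prob_binomial", "prob_exact")


@dataclass
class FeatureVector:
    """Named feature → value map at site or pair level."""

    values: dict[str, float]
    level: str = "site"

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_DIRECTIONS)
        if unknown:
            raise DataError(f"unregistered features: {sorted(unknown)}")
        if self.level not in ("site", "pair"):
            raise DataError(f"level must be 'site' or 'pair', got {self.level!r}")


@dataclass
class LinearModel:
    """Intercept + per-feature coefficients for log2 fold-change."""

    intercept: float
    coefficients: dict[str, float]
    training_r2: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(FEATURE_DIRECTIONS)
        if unknown:
            raise DataError(f"coefficients for unregistered features: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)


def aggregate_pair(
    site_features: Sequence[FeatureVector],
    pair_level_values: Mapping[str, float] | None = None,
) -> FeatureVector:
    """Aggregate per-site vectors to one pair-level vector.

    Energy, context and conservation features are summed over sites;
    over-representation p-values must be supplied at pair level (they
    are functions of the total site count on the UTR); the site count is
    recorded as its own feature. Features present in only some sites are
    summed over the sites that have them (NaN marks "unavailable" and is
    skipped); a feature missing from every site is omitted.
    """
    if not site_features:
        raise DataError("aggregate_pair needs at least one site")
    out: dict[str, float] = {}
    for name in _SUMMED + ("utr_position",):
        vals = [
            fv.values[name]
            for fv in site_features
            if name in fv.values and not math.isnan(fv.values[name])
        ]
        if vals:
            out[name] = float(np.sum(vals)) if name != "utr_position" else float(
                np.mean(vals)
            )
    if pair_level_values:
        for name in _PAIR_LEVEL:
            if name in pair_level_values:
                out[name] = float(pair_level_values[name])
    out["site_count"] = float(len(site_features))
    return FeatureVector(values=out, level="pair")


def fit(features: pd.DataFrame, response: Sequence[float]) -> LinearModel:
    """Ordinary-least-squares fit of log2 fold-change on features.

    Requires more rows than columns and a full-rank design; rank
    deficiency raises an error naming the offending (collinear or
    constant) features.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise DataError(f"response length {y.shape} does not match {n} rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("NaN in training data")
    if n < p + 2:
        raise DataError(f"need at least {p + 2} rows to fit {p} features")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # name the culprits: constant columns, then QR-dependent ones
        bad = [c for c, s in zip(features.columns, X.std(axis=0)) if s == 0]
        if not bad:
            _, R = np.linalg.qr(design)
            diag = np.abs(np.diag(R))
            thresh = diag.max() * 1e-10
            bad = [features.columns[i - 1] for i in range(1, p + 1) if diag[i] < thresh]
        raise DataError(f"rank-deficient design; collinear/constant features: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(features.columns, beta[1:])},
        training_r2=r2,
    )


def predict(model: LinearModel, features: FeatureVector | Mapping[str, float]) -> float:
    """intercept + Σ coefficient·value; more negative = stronger repression."""
    values = features.values if isinstance(features, FeatureVector) else features
    missing = [f for f in model.coefficients if f not in values]
    if missing:
        raise DataError(f"features required by the model are missing: {missing}")
    return model.intercept + sum(
        coef * values[name] for name, coef in model.coefficients.items()
    )


def percentile_transform(
    background: Sequence[float],
    value: float,
    feature: str,
    directions: Mapping[str, str] | None = None,
) -> float:
    """Empirical percentile of ``value`` in ``background``, oriented so
    100 = strongest predicted repression. Ties receive averaged ranks.
    """
    directions = directions if directions is not None else FEATURE_DIRECTIONS
    if feature not in directions:
        raise DataError(f"feature {feature!r} absent from direction map")
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise DataError("empty percentile background")
    direction = directions[feature]
    if direction == LOWER_IS_STRONGER:
        bg, value = -bg, -value
    elif direction != HIGHER_IS_STRONGER:
        raise DataError(f"unknown direction {direction!r}")
    if bg.size == 1:
        return 100.0 if value >= bg[0] else 0.0
    less = float(np.sum(bg < value))
    equal = float(np.sum(bg == value))
    rank = less + (equal + 1.0) / 2.0  # averaged tie rank among background
    pct = (rank - 1.0) / (bg.size - 1.0) * 100.0
    return float(min(100.0, max(0.0, pct)))


# ---------------------------------------------------------------------------
# model serialization (flat key=value text)

REGISTRY_VERSION = 1


def save_model(model: LinearModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"registry_version={REGISTRY_VERSION}\n")
        if model.label:
            fh.write(f"label={model.label}\n")
        fh.write(f"intercept={model.intercept!r}\n")
        if model.training_r2 is not None:
            fh.write(f"training_r2={model.training_r2!r}\n")
        for name, coef in model.coefficients.items():
            fh.write(f"coef.{name}={coef!r}\n")


def load_model(path=None, name: str | None = None) -> LinearModel:
    """Load a serialized model; with no path, load a shipped demo model.

    ``name`` selects among shipped demo models: ``"full"`` (default) or
    ``"no_conservation"`` (for inputs without tree/alignment). Both were
    fitted on this package's synthetic dataset.
    """
    if path is None:
        fname = {
            None: "demo_model_synthetic.txt",
            "full": "demo_model_synthetic.txt",
            "no_conservation": "demo_model_synthetic_noconserv.txt",
        }[name]
        text = resources.files("mirtarget.data").joinpath(fname).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    intercept = 0.0
    coefs: dict[str, float] = {}
    r2: float | None = None
    label = ""
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataError(f"model file line {lineno}: expected key=value")
        key, _, val = line.partition("=")
        if key == "intercept":
            intercept = float(val)
        elif key == "training_r2":
            r2 = float(val)
        elif key == "label":
            label = val
        elif key == "registry_version":
            if int(val) != REGISTRY_VERSION:
                raise DataError(f"model registry version {val} unsupported")
        elif key.startswith("coef."):
            coefs[key[5:]] = float(val)
        else:
            raise DataError(f"model file line {lineno}: unknown key {key!r}")
    if not coefs:
        raise DataError("model file defines no coefficients")
    return LinearModel(intercept=intercept, coefficients=coefs, training_r2=r2, label=label)
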