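"""End-to-end orchestration: scan UTRs, compute features, score pairs.

This is the library face of the batch workflow the CLI exposes: for
every miRNA × UTR pair, find seed matches, compute the per-site feature
set (thermodynamic, context, optional conservation), aggregate to pair
level, attach over-representation p-values, predict the repression
score, and format report rows in raw or percentile mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import context_features, thermodynamics
from .conservation import SubstitutionModel, conservation_features
from .errors import DataError
from .io_formats import NucSequence, PhyloTree, SpeciesAlignment
from .occurrence_stats import pover_feature
from .scoring_model import (
    FEATURE_DIRECTIONS,
    FeatureVector,
    LinearModel,
    aggregate_pair,
    load_model,
    percentile_transform,
    predict,
)
from .site_scanner import MiRNA, TargetSite, find_sites, seed_match

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable defaults of the feature pipeline (all overridable)."""

    open_flank: int = thermodynamics.DEFAULT_OPEN_FLANK
    duplex_upstream: int = thermodynamics.DEFAULT_UPSTREAM_EXTENSION
    au_window: int = context_features.AU_WINDOW
    utr_position_cap: int = context_features.UTR_POSITION_CAP
    pover_seed_span: tuple[int, int] = (2, 8)
    neutral_model: str = "JC69"
    normalize_bls: bool = False

    @classmethod
    def from_mapping(cls, items: Mapping[str, str]) -> "PipelineConfig":
        cfg = cls()
        for key, raw in items.items():
            if not hasattr(cfg, key):
                raise DataError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, tuple):
                value = tuple(int(x) for x in raw.split(","))
            else:
                value = raw
            setattr(cfg, key, value)
        return cfg


def read_config(path) -> PipelineConfig:
    """Flat key=value config file → :class:`PipelineConfig`."""
    items: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataError(f"config line {lineno}: expected key=value")
            key, _, val = line.partition("=")
            items[key.strip()] = val.strip()
    return PipelineConfig.from_mapping(items)


def site_feature_vector(
    utr: NucSequence,
    mirna: MiRNA,
    site: TargetSite,
    config: PipelineConfig | None = None,
    tree: PhyloTree | None = None,
    alignment: SpeciesAlignment | None = None,
) -> FeatureVector:
    """All site-level features for one site.

    Conservation features are included only when both tree and alignment
    are supplied and the alignment's ungapped reference row matches this
    UTR's sequence.
    """
    cfg = config or PipelineConfig()
    energies = thermodynamics.site_energies(
        utr, mirna, site, flank=cfg.open_flank, upstream=cfg.duplex_upstream
    )
    values = {
        "dg_duplex": energies.dg_duplex,
        "dg_binding": energies.dg_binding,
        "dg_seed_duplex": energies.dg_seed_duplex,
        "dg_seed_binding": energies.dg_seed_binding,
        "dg_open": energies.dg_open,
        "dg_total": energies.dg_total,
        "au_content": context_features.au_content(utr, site, window=cfg.au_window),
        "utr_position": context_features.utr_position(
            utr, site, cap=cfg.utr_position_cap
        ),
        "three_prime_pairing": context_features.three_prime_pairing(mirna, utr, site),
    }
    if tree is not None and alignment is not None:
        if alignment.ref_ungapped() != utr.residues:
            logger.warning(
                "alignment reference row does not match UTR %s; conservation skipped",
                utr.id,
            )
        else:
            cons = conservation_features(
                tree,
                alignment,
                site,
                seed_match(mirna, (2, 7)),
                neutral=SubstitutionModel(cfg.neutral_model),
                normalize_bls=cfg.normalize_bls,
            )
            values["bls"] = cons.bls
            values["phylop_score"] = cons.phylop_score
    return FeatureVector(values=values, level="site")


def pair_feature_vector(
    utr: NucSequence,
    mirna: MiRNA,
    sites: Sequence[TargetSite],
    config: PipelineConfig | None = None,
    tree: PhyloTree | None = None,
    alignment: SpeciesAlignment | None = None,
) -> FeatureVector:
    """Aggregate site features and attach pair-level p_over features."""
    cfg = config or PipelineConfig()
    site_vectors = [
        site_feature_vector(utr, mirna, s, cfg, tree, alignment) for s in sites
    ]
    pover = {
        "prob_binomial": pover_feature(
            utr, mirna, "binomial", cfg.pover_seed_span
        ).p_over,
        "prob_exact": pover_feature(utr, mirna, "exact", cfg.pover_seed_span).p_over,
    }
    return aggregate_pair(site_vectors, pover)


@dataclass
class PairReport:
    utr_id: str
    mirna_name: str
    sites: list[TargetSite]
    features: FeatureVector
    site_vectors: list[FeatureVector]
    score: float | None = None
    model_variant: str = ""


def scan_all(
    utrs: Sequence[NucSequence], mirnas: Sequence[MiRNA]
) -> list[tuple[NucSequence, MiRNA, list[TargetSite]]]:
    """Seed-match scan of every miRNA × UTR combination, in input order."""
    out = []
    for utr in utrs:
        for mirna in mirnas:
            out.append((utr, mirna, find_sites(utr, mirna)))
    return out


def score_pairs(
    utrs: Sequence[NucSequence],
    mirnas: Sequence[MiRNA],
    model: LinearModel | None = None,
    config: PipelineConfig | None = None,
    tree: PhyloTree | None = None,
    alignment: SpeciesAlignment | None = None,
) -> list[PairReport]:
    """Feature + score computation for every pair with at least one site.

    With no explicit model, a shipped synthetic-data demo model is used:
    the full one when conservation features are available, otherwise the
    conservation-free variant (flagged in ``model_variant``).
    """
    cfg = config or PipelineConfig()
    reports: list[PairReport] = []
    for utr, mirna, sites in scan_all(utrs, mirnas):
        if not sites:
            continue
        site_vectors = [
            site_feature_vector(utr, mirna, s, cfg, tree, alignment) for s in sites
        ]
        pover = {
            "prob_binomial": pover_feature(
                utr, mirna, "binomial", cfg.pover_seed_span
            ).p_over,
            "prob_exact": pover_feature(
                utr, mirna, "exact", cfg.pover_seed_span
            ).p_over,
        }
        features = aggregate_pair(site_vectors, pover)
        if model is None:
            have_conservation = "bls" in features.values
            variant = "full" if have_conservation else "no_conservation"
            used = load_model(name=variant)
            variant_label = f"demo-synthetic:{variant}"
        else:
            used, variant_label = model, "user"
        missing = [f for f in used.coefficients if f not in features.values]
        if missing:
            raise DataError(
                f"pair {utr.id}/{mirna.name}: model needs missing features {missing}"
            )
        score = predict(used, features)
        reports.append(
            PairReport(
                utr_id=utr.id,
                mirna_name=mirna.name,
                sites=sites,
                features=features,
                site_vectors=site_vectors,
                score=score,
                model_variant=variant_label,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# percentile backgrounds and report rows


def collect_background(reports: Sequence[PairReport]) -> dict[str, list[float]]:
    """Per-feature raw-value samples (pair level) for percentile scoring."""
    bg: dict[str, list[float]] = {}
    for rep in reports:
        values = dict(rep.features.values)
        if rep.score is not None:
            values["score"] = rep.score
        for name, val in values.items():
            bg.setdefault(name, []).append(float(val))
    return bg


def save_background(background: Mapping[str, Sequence[float]], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in background.items()}, fh)


def load_background(path) -> dict[str, list[float]]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or not data:
        raise DataError(f"background file {path} is empty or malformed")
    return {str(k): [float(x) for x in v] for k, v in data.items()}


def report_rows(
    reports: Sequence[PairReport],
    mode: str = "raw",
    view: str = "pair",
    background: Mapping[str, Sequence[float]] | None = None,
) -> list[dict[str, object]]:
    """Flatten reports to CSV-ready rows (raw or percentile values).

    Percentile mode requires a background; every feature column and the
    score are transformed so 100 = strongest predicted repression.
    """
    if mode not in ("raw", "percentile"):
        raise DataError(f"unknown mode {mode!r}")
    if view not in ("pair", "site"):
        raise DataError(f"unknown view {view!r}")
    if mode == "percentile" and background is None:
        raise DataError("percentile mode requires a background sample")

    def transform(name: str, value: float) -> float:
        if mode == "raw":
            return value
        if name not in background:
            raise DataError(f"feature {name!r} absent from background")
        return percentile_transform(background[name], value, name)

    rows: list[dict[str, object]] = []
    for rep in reports:
        if view == "pair":
            row: dict[str, object] = {
                "utr_id": rep.utr_id,
                "mirna": rep.mirna_name,
                "site_count": int(rep.features.values.get("site_count", len(rep.sites))),
            }
            for name, val in rep.features.values.items():
                if name == "site_count":
                    continue
                row[name] = transform(name, float(val))
            if rep.score is not None:
                row["score"] = transform("score", rep.score)
                row["model_variant"] = rep.model_variant
            rows.append(row)
        else:
            for site, fv in zip(rep.sites, rep.site_vectors):
                row = {
                    "utr_id": rep.utr_id,
                    "mirna": rep.mirna_name,
                    "start": site.start,
                    "end": site.end,
                    "site_type": str(site.site_type),
                }
                for name, val in fv.values.items():
                    row[name] = transform(name, float(val))
                rows.append(row)
    return rows


def sort_rows(rows: list[dict[str, object]], keys: Sequence[str], mode: str) -> None:
    """Multicolumn in-place sort. Default orientation puts the strongest
    predicted repression first for known features; unknown keys sort
    ascending."""
    for key in reversed(list(keys)):
        direction = FEATURE_DIRECTIONS.get(key)
        if mode == "percentile" and direction is not None:
            reverse = True  # higher percentile = stronger, always
        elif direction == "lower_is_stronger":
            reverse = False
        elif direction == "higher_is_stronger":
            reverse = True
        else:
            reverse = False
        rows.sort(key=lambda r: (r.get(key) is None, r.get(key)), reverse=reverse)


def filter_rows(
    rows: list[dict[str, object]],
    min_bounds: Mapping[str, float],
    max_bounds: Mapping[str, float],
) -> list[dict[str, object]]:
    """Keep rows whose named columns fall inside the given bounds."""
    out = []
    for row in rows:
        keep = True
        for name, bound in min_bounds.items():
            if name not in row:
                raise DataError(f"filter column {name!r} absent from report")
            if float(row[name]) < bound:
                keep = False
        for name, bound in max_bounds.items():
            if name not in row:
                raise DataError(f"filter column {name!r} absent from report")
            if float(row[name]) > bound:
                keep = False
        if keep:
            out.append(row)
    return out
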