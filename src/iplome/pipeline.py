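"""End-to-end driver: features + MS2 -> annotations -> concentrations."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotate import Feature, annotate_features, DEFAULT_MS1_PPM, DEFAULT_MS2_PPM
from .database import LipidDatabase
from .quantify import (
    DilutionSeries,
    blank_filter,
    fit_response_factor,
    matrix_correct,
    quantify_table,
)
from .simulate import SimulatedDataset

__all__ = ["quantify_annotations", "run_pipeline"]


def quantify_annotations(
    features: Sequence[Feature],
    annotations: pd.DataFrame,
    blank_means: pd.Series,
    is_responses: Mapping[str, float],
    is_area_pure: float,
    dilutions: Sequence[DilutionSeries],
    volumes_l: Mapping[str, float],
    blank_ratio: float = 10.0,
) -> pd.DataFrame:
    """Concentration table (lipid x sample, ng/L) from annotated features.

    MS1-only annotations are excluded (no MS2 confirmation, per the
    identification policy); areas of features assigned to the same
    species are summed before the blank filter, matrix correction and
    response-factor division.
    """
    usable = annotations[
        (annotations["name"] != "") & (annotations["confidence"] != "MS1-only")
    ]
    feat_by_id = {f.feature_id: f for f in features}
    samples = sorted({s for f in features for s in f.areas})
    rows: dict[str, pd.Series] = {}
    meta: dict[str, str] = {}
    for _, ann in usable.iterrows():
        f = feat_by_id[ann["feature_id"]]
        areas = pd.Series({s: f.areas.get(s, 0.0) for s in samples})
        name = ann["name"]
        rows[name] = rows.get(name, pd.Series(0.0, index=samples)) + areas
        meta[name] = ann["headgroup"]
    if not rows:
        return pd.DataFrame(columns=samples)
    area_df = pd.DataFrame(rows).T
    bm = blank_means.astype(float).reindex(area_df.index).fillna(0.0)
    area_df = blank_filter(area_df, bm, blank_ratio)
    area_df = matrix_correct(area_df, is_responses, is_area_pure)
    models = {d.standard: fit_response_factor(d) for d in dilutions}
    classes = {name: meta[name] for name in area_df.index}
    return quantify_table(area_df, classes, models, volumes_l)


def run_pipeline(
    dataset: SimulatedDataset,
    db: LipidDatabase,
    rules,
    tol_ppm: float = DEFAULT_MS1_PPM,
    ms2_tol_ppm: float = DEFAULT_MS2_PPM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate and quantify a simulated dataset.

    Returns (annotations, per-feature result table with name and mean
    concentration across samples) for comparison against the truth.
    """
    ann = annotate_features(
        dataset.features, dataset.spectra, db, rules, tol_ppm, ms2_tol_ppm
    )
    quant = quantify_annotations(
        dataset.features,
        ann,
        dataset.blank_means,
        dataset.is_responses,
        dataset.is_area_pure,
        dataset.dilutions,
        dataset.volumes_l,
    )
    mean_conc = quant.mean(axis=1) if len(quant) else pd.Series(dtype=float)
    result = ann[ann["name"] != ""][["feature_id", "name"]].copy()
    result["conc_ng_l"] = result["name"].map(mean_conc)
    return ann, result
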