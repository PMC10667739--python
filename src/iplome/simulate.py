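"""Synthetic LC-MS lipidomics datasets with known ground truth.

Emulates, at desk scale, the evidence a HILIC-Orbitrap acquisition
produces: an aligned feature table (accurate m/z with Gaussian ppm
noise, per-sample peak areas with lognormal noise), positive-mode MS2
spectra carrying headgroup diagnostics, negative-mode MS2 with fatty-
acid carboxylate anions for ester-linked species, solvent-blank areas,
internal-standard responses and response-factor dilution series.

The forward model is the exact inverse of the quantification chain, so
a zero-noise scenario round-trips to the true concentrations exactly;
noisy scenarios let the annotation and quantification accuracy be
measured against the truth table. What is *not* modeled: chromatographic
peak shapes, isotope envelopes, co-elution artifacts, in-source
fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    DiagnosticRule,
    Feature,
    MS2Spectrum,
    _fa_anion_mass,
    default_rules_path,
    read_rules,
)
from .database import LipidDatabase, starter_component_path
from .formula import monoisotopic_mass, parse_formula
from .quantify import DilutionSeries

__all__ = [
    "SyntheticScenario",
    "SimulatedDataset",
    "make_toy_components",
    "random_scenario",
    "simulate_dataset",
    "recovery_report",
    "STANDARD_SLOPES",
    "DILUTION_MASSES",
]

# Injected masses of the dilution series, ng on column.
DILUTION_MASSES = (0.1, 1.0, 2.5, 5.0, 10.0)

# True response factors (peak area per ng) of the simulated authentic
# standards; chosen with the ~order-of-magnitude spread between lipid
# classes seen on electrospray instruments.
STANDARD_SLOPES: Mapping[str, float] = {
    "1G-DAG": 2.0e5,
    "PC-DAG": 8.0e5,
    "PE-DAG": 3.0e5,
    "PG-DAG": 2.5e5,
    "DGTS": 6.0e5,
    "DG-Cer": 1.5e5,
    "DG-DAG": 1.2e5,
}

# Fallback class -> standard used by the forward model (the same rules
# the quantifier applies, so the round trip is exact at zero noise).
_CLASS_TO_STANDARD = {
    "1G": "1G-DAG",
    "PC": "PC-DAG",
    "PE": "PE-DAG",
    "PG": "PG-DAG",
    "DGTS": "DGTS",
    "OL": "DGTS",
    "3Me-OL": "DGTS",
    "DGCC": "DGTS",
    "NAcG-G": "DG-Cer",
    "NAcG-P": "DG-Cer",
    "1G-GA": "DG-Cer",
    "GAc-G": "DG-DAG",
    "2G": "DG-DAG",
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one simulated dataset.

    All noise parameters are >= 0; a fixed seed makes runs
    bit-reproducible. ``truth`` maps (lipid name, adduct) to true
    concentration in ng/L, constant across samples.
    """

    seed: int
    truth: tuple[tuple[str, str, float], ...]
    samples: tuple[str, ...] = ("S1", "S2", "S3")
    volumes_l: Mapping[str, float] = dataclass_field(default_factory=dict)
    mz_noise_ppm: float = 0.0
    area_cv: float = 0.0
    rt_jitter_s: float = 2.0
    blank_frac: float = 0.0          # fraction of lipids contaminating blanks
    blank_level: float = 0.02        # blank area as a fraction of sample area
    is_area_pure: float = 1.0e8
    is_suppression: Mapping[str, float] = dataclass_field(default_factory=dict)
    frac_without_neg_ms2: float = 0.5

    def __post_init__(self) -> None:
        if min(self.mz_noise_ppm, self.area_cv, self.rt_jitter_s, 0.0) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not self.volumes_l:
            object.__setattr__(self, "volumes_l", {s: 20.0 for s in self.samples})
        if not self.is_suppression:
            object.__setattr__(self, "is_suppression", {s: 1.0 for s in self.samples})


@dataclass
class SimulatedDataset:
    """Everything the annotation + quantification pipeline consumes."""

    features: list[Feature]
    spectra: list[MS2Spectrum]
    blank_means: pd.Series                 # lipid name -> mean blank area
    dilutions: list[DilutionSeries]
    is_responses: Mapping[str, float]      # per-sample in-sample IS area
    is_area_pure: float
    volumes_l: Mapping[str, float]
    truth: pd.DataFrame                    # name, adduct, headgroup, conc_ng_l


def make_toy_components(n: int, seed: int = 0, path: str | Path | None = None) -> pd.DataFrame:
    """Draw n rows from the starter component table (deterministic per seed)."""
    full = pd.read_csv(starter_component_path(), sep="\t")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(full):
        raise ValueError(f"starter table has only {len(full)} components")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(full), size=n, replace=False))
    sub = full.iloc[idx].reset_index(drop=True)
    if path is not None:
        sub.to_csv(path, sep="\t", index=False)
    return sub


def random_scenario(
    db: LipidDatabase,
    n_lipids: int = 50,
    seed: int = 42,
    mz_noise_ppm: float = 0.0,
    area_cv: float = 0.0,
    samples: Sequence[str] = ("S1", "S2", "S3"),
    backbones: Sequence[str] = ("DAG", "DEG", "AEG", "Cer", "FA"),
    **kwargs,
) -> SyntheticScenario:
    """Draw ground-truth lipids from a database.

    Picks positive-mode, non-hydroxylated entries with distinct names and
    headgroup variety, and lognormal true concentrations (median ~5 ng/L,
    the dilute range typical of oligotrophic waters). Truth is restricted
    to backbone classes identifiable under the modeled evidence (mass,
    positive-mode headgroup diagnostics, negative-mode ester fragments):
    monoether and alkanediol species are exact mass twins of diethers and
    are excluded from draws, as are the full-structure cores.
    """
    rng = np.random.default_rng(seed)
    pool = db.entries
    pool = pool[
        (pool["polarity"] == "positive")
        & (pool["oh"] == 0)
        & pool["backbone"].isin(backbones)
    ]
    pool = pool.drop_duplicates(subset=["name"], keep="first")
    # spread picks across headgroups for class variety
    picks: list[int] = []
    groups = [g.index.to_numpy() for _, g in pool.groupby("headgroup")]
    rng.shuffle(groups)
    gi = 0
    while len(picks) < min(n_lipids, len(pool)):
        g = groups[gi % len(groups)]
        cand = rng.choice(g)
        if cand not in picks:
            picks.append(cand)
        gi += 1
    chosen = pool.loc[picks]
    conc = np.exp(rng.normal(np.log(5.0), 1.0, size=len(chosen)))
    truth = tuple(
        (str(r["name"]), str(r["adduct"]), float(c))
        for (_, r), c in zip(chosen.iterrows(), conc)
    )
    suppression = {s: float(np.clip(rng.normal(0.8, 0.1), 0.3, 1.0)) for s in samples}
    return SyntheticScenario(
        seed=seed,
        truth=truth,
        samples=tuple(samples),
        mz_noise_ppm=mz_noise_ppm,
        area_cv=area_cv,
        is_suppression=suppression,
        **kwargs,
    )


def _headgroup_rt(headgroup: str) -> float:
    """Deterministic per-headgroup base retention time (s), 60 s apart.

    HILIC separates lipid classes by headgroup polarity; a fixed
    per-class elution slot is enough for the isomer-resolution logic.
    """
    classes = sorted(_CLASS_TO_STANDARD)
    slot = classes.index(headgroup) if headgroup in classes else len(classes)
    return 300.0 + 60.0 * slot


def _headgroup_rule(rules: Sequence[DiagnosticRule], headgroup: str) -> DiagnosticRule | None:
    for r in rules:
        if r.level == "headgroup" and r.target == headgroup and r.polarity == "positive":
            return r
    return None


def simulate_dataset(scenario: SyntheticScenario, db: LipidDatabase) -> SimulatedDataset:
    """Run the forward model: truth -> features, MS2, blanks, dilutions."""
    rng = np.random.default_rng(scenario.seed)
    rules = read_rules(default_rules_path())
    entries = db.entries.set_index(["name", "adduct"])

    features: list[Feature] = []
    spectra: list[MS2Spectrum] = []
    blank_rows: dict[str, float] = {}
    truth_rows = []

    for i, (name, adduct, conc) in enumerate(scenario.truth):
        try:
            row = entries.loc[(name, adduct)]
        except KeyError:
            raise ValueError(f"truth lipid {name} / {adduct} absent from database") from None
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        hg, bb = str(row["headgroup"]), str(row["backbone"])
        std = _CLASS_TO_STANDARD.get(hg)
        if std is None:
            raise ValueError(f"no simulated standard covers class {hg!r}")
        slope = STANDARD_SLOPES[std]
        mz_true = float(row["mz"])
        eps = rng.normal(0.0, scenario.mz_noise_ppm) * 1e-6 if scenario.mz_noise_ppm else 0.0
        # Chain length, unsaturation and hydroxylation shift HILIC retention
        # within a headgroup class by tens of seconds to minutes.
        rt = (
            _headgroup_rt(hg)
            + 0.8 * int(row["c"])
            - 2.0 * int(row["db"])
            + 12.0 * int(row["oh"])
            + (
                rng.uniform(-scenario.rt_jitter_s, scenario.rt_jitter_s)
                if scenario.rt_jitter_s
                else 0.0
            )
        )
        areas: dict[str, float] = {}
        for s in scenario.samples:
            ng = conc * scenario.volumes_l[s]
            noise = (
                float(np.exp(rng.normal(-0.5 * np.log(1 + scenario.area_cv**2) , np.sqrt(np.log(1 + scenario.area_cv**2)))))
                if scenario.area_cv
                else 1.0
            )
            areas[s] = ng * slope * scenario.is_suppression[s] * noise
        fid = f"F{i:04d}"
        features.append(Feature(fid, mz_true * (1 + eps), rt, "positive", areas))
        truth_rows.append((fid, name, adduct, hg, bb, conc))

        if rng.random() < scenario.blank_frac:
            blank_rows[name] = scenario.blank_level * float(np.mean(list(areas.values())))

        # positive MS2: headgroup diagnostic + benign noise peaks
        rule = _headgroup_rule(rules, hg)
        peaks = [(mz_true - 50.0 * rng.random() - 5.0, 1e4)]
        if rule is not None:
            diag = rule.mz if rule.evidence == "fragment" else mz_true - rule.mz
            peaks.append((diag, 5e5))
        if bb == "Cer":
            # sphingoid dehydration, the positive-mode ceramide hallmark
            peaks.append((mz_true - monoisotopic_mass(parse_formula("H2O")), 3e5))
        spectra.append(
            MS2Spectrum(fid, mz_true, rt, "positive", np.array(peaks))
        )

        # negative MS2 (chain confirmation) for ester-chain species
        n_acyl = {"MAG": 1, "DAG": 2, "TAG": 3, "CL": 4, "AEG": 1, "Cer": 1, "AD": 1, "FA": 1}.get(bb)
        if n_acyl and rng.random() >= scenario.frac_without_neg_ms2:
            c_tot, d_tot = int(row["c"]), int(row["db"])
            neg_peaks = []
            if n_acyl == 1 and bb in ("MAG", "FA"):
                neg_peaks.append((_fa_anion_mass(c_tot, d_tot), 2e5))
            elif n_acyl == 1:
                c1 = max(2, c_tot // 2)
                neg_peaks.append((_fa_anion_mass(c1, min(d_tot, 6)), 2e5))
            else:
                c1 = c_tot // 2
                d1 = d_tot // 2
                neg_peaks.append((_fa_anion_mass(c1, d1), 2e5))
                neg_peaks.append((_fa_anion_mass(c_tot - c1, d_tot - d1), 2e5))
            neg_peaks = [(m, h) for m, h in neg_peaks if np.isfinite(m)]
            if neg_peaks:
                spectra.append(
                    MS2Spectrum(fid, mz_true - 2 * (1.00727646), rt, "negative", np.array(neg_peaks))
                )

    dilutions = []
    for std, slope in STANDARD_SLOPES.items():
        pts = tuple((m, m * slope) for m in DILUTION_MASSES)
        dilutions.append(DilutionSeries(std, pts))

    is_responses = {
        s: scenario.is_area_pure * scenario.is_suppression[s] for s in scenario.samples
    }
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "name", "adduct", "headgroup", "backbone", "conc_ng_l"]
    )
    return SimulatedDataset(
        features=features,
        spectra=spectra,
        blank_means=pd.Series(blank_rows, dtype=float),
        dilutions=dilutions,
        is_responses=is_responses,
        is_area_pure=scenario.is_area_pure,
        volumes_l=dict(scenario.volumes_l),
        truth=truth,
    )


def recovery_report(truth: pd.DataFrame, result: pd.DataFrame) -> dict[str, float]:
    """Precision/recall of species assignment and concentration error.

    ``truth`` has columns (feature_id, name, conc_ng_l); ``result`` has
    (feature_id, name) and optionally ``conc_ng_l`` per lipid. A feature
    annotated to the wrong species counts as one false positive and one
    false negative.
    """
    t = truth.set_index("feature_id")
    if result.empty:
        return {"precision": 0.0, "recall": 0.0, "n_correct": 0,
                "rmse_ng_l": float("nan"), "median_rel_err": float("nan")}
    r = result.set_index("feature_id")
    shared = t.index.intersection(r.index)
    if len(shared) == 0 and len(r):
        raise ValueError("truth and result share no feature identifiers")
    correct = sum(t.loc[f, "name"] == r.loc[f, "name"] for f in shared)
    n_pred = int((r["name"] != "").sum())
    precision = correct / n_pred if n_pred else 0.0
    recall = correct / len(t)
    out = {
        "precision": float(precision),
        "recall": float(recall),
        "n_correct": int(correct),
    }
    if "conc_ng_l" in r.columns:
        merged = t.loc[shared].join(r.loc[shared], rsuffix="_est")
        merged = merged[merged["name"] == merged["name_est"]]
        err = merged["conc_ng_l_est"] - merged["conc_ng_l"]
        rel = np.abs(err) / merged["conc_ng_l"]
        out["rmse_ng_l"] = float(np.sqrt(np.mean(err**2))) if len(err) else float("nan")
        out["median_rel_err"] = float(np.median(rel)) if len(rel) else float("nan")
    return out
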