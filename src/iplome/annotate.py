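"""MS1/MS2 annotation of LC-MS features against a theoretical database.

The annotation strategy mirrors untargeted HILIC-Orbitrap lipidomics
practice. Features are first screened at MS1 level by accurate mass
(ppm tolerance, polarity-aware). Positively ionized MS2 spectra
characterize the headgroup (diagnostic fragments and neutral losses);
negatively ionized MS2 probe the core structure, because ester-linked
fatty acids are released as carboxylate anions at the collision
energies used, while diether lipids diagnostically lack fragmentation
as negative adducts.

Because a combinatorial database holds many structural isomers per
chemical formula, unresolved isomer sets are settled by a fixed
procedure: (1) negative-mode chain evidence fixes the structure
directly; (2) otherwise the linkage of a confirmed same-headgroup lipid
eluting within 15 s is adopted (nearest retention time wins); (3)
otherwise the isomer that requires no hydroxylation is chosen. Only
features with MS2 evidence are carried into quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import (
    ELECTRON_MASS,
    ElementalFormula,
    monoisotopic_mass,
    parse_formula,
)
from .database import LipidDatabase

__all__ = [
    "Feature",
    "MS2Spectrum",
    "DiagnosticRule",
    "AnnotatedLipid",
    "read_rules",
    "default_rules_path",
    "match_ms1",
    "annotate_ms2",
    "confirmed_chain_evidence",
    "resolve_isomers",
    "annotate_features",
    "combine_spectra",
    "read_features_csv",
    "write_features_csv",
    "read_ms2_mgf",
    "write_ms2_mgf",
]

DEFAULT_MS1_PPM = 2.5
DEFAULT_MS2_PPM = 10.0
MS2_DA_FLOOR = 0.001
NEIGHBOR_RT_WINDOW_S = 15.0


@dataclass(frozen=True)
class Feature:
    """An aligned LC-MS feature (peak group) with per-sample areas."""

    feature_id: str
    mz: float
    rt_s: float
    polarity: str
    areas: Mapping[str, float] = field(default_factory=dict)
    is_isotope: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be positive")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError(f"feature {self.feature_id}: negative peak area")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"feature {self.feature_id}: bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class MS2Spectrum:
    """A fragmentation spectrum; peaks is an (n, 2) array of (m/z, intensity)."""

    feature_id: str
    precursor_mz: float
    rt_s: float
    polarity: str
    peaks: np.ndarray
    composite: bool = False

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if (peaks[:, 1] < 0).any():
            raise ValueError(f"spectrum {self.feature_id}: negative intensity")
        object.__setattr__(self, "peaks", peaks[np.argsort(peaks[:, 0])])


@dataclass(frozen=True)
class DiagnosticRule:
    """A diagnostic MS2 fragment or neutral loss.

    ``formula`` for a fragment rule is the ion's atomic composition (the
    charge implied by polarity); for a neutral-loss rule it is the
    neutral lost moiety. Exactly one of formula / fixed m/z is set; the
    other is computed by formula arithmetic at load time.
    """

    rule_id: str
    level: str  # headgroup | backbone-linkage | chain
    evidence: str  # fragment | neutral_loss
    target: str  # headgroup (or backbone) class confirmed when the rule fires
    polarity: str
    formula: ElementalFormula | None = None
    fixed_mz: float | None = None
    tol_ppm: float = DEFAULT_MS2_PPM

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.fixed_mz is None):
            raise ValueError(f"rule {self.rule_id}: exactly one of formula/mz must be set")
        if self.evidence not in ("fragment", "neutral_loss"):
            raise ValueError(f"rule {self.rule_id}: bad evidence type {self.evidence!r}")

    @property
    def mz(self) -> float:
        """Fragment ion m/z, or the neutral-loss mass for loss rules."""
        if self.fixed_mz is not None:
            return self.fixed_mz
        m = monoisotopic_mass(self.formula)
        if self.evidence == "neutral_loss":
            return m
        return m - ELECTRON_MASS if self.polarity == "positive" else m + ELECTRON_MASS


def default_rules_path() -> Path:
    from .database import _data_path

    return _data_path("diagnostic_rules.tsv")


def read_rules(path: str | Path) -> list[DiagnosticRule]:
    """Read a diagnostic-rule table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rules: list[DiagnosticRule] = []
    for row in df.itertuples(index=False):
        has_formula = isinstance(row.formula, str) and row.formula.strip()
        has_mz = isinstance(row.mz, str) and row.mz.strip()
        rules.append(
            DiagnosticRule(
                rule_id=row.rule_id,
                level=row.level,
                evidence=row.evidence,
                target=row.target,
                polarity=row.polarity,
                formula=parse_formula(row.formula) if has_formula else None,
                fixed_mz=float(row.mz) if has_mz else None,
                tol_ppm=float(row.tol_ppm),
            )
        )
    return rules


def _ms2_tol(mz: float, tol_ppm: float) -> float:
    return max(mz * tol_ppm * 1e-6, MS2_DA_FLOOR)


def match_ms1(
    features: Sequence[Feature],
    db: LipidDatabase,
    tol_ppm: float = DEFAULT_MS1_PPM,
) -> dict[str, pd.DataFrame]:
    """Database candidates per feature within the ppm window.

    All isomers (entries sharing the matched m/z within tolerance and the
    feature's polarity) are returned; secondary-isotope features are
    skipped.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out: dict[str, pd.DataFrame] = {}
    for f in features:
        if f.is_isotope:
            continue
        out[f.feature_id] = db.search_mz(f.mz, tol_ppm, polarity=f.polarity)
    return out


def annotate_ms2(
    spectrum: MS2Spectrum,
    rules: Sequence[DiagnosticRule],
    tol_ppm: float | None = None,
) -> list[DiagnosticRule]:
    """Rules that fire on a spectrum.

    Fragment rules fire when any peak lies within tolerance of the rule
    m/z; neutral-loss rules fire when a peak sits at (precursor - loss).
    The tolerance is the rule's own ppm unless overridden, with an
    absolute floor of 1 mDa.
    """
    if not rules:
        raise ValueError("empty rule set")
    mzs = spectrum.peaks[:, 0]
    fired: list[DiagnosticRule] = []
    for rule in rules:
        if rule.polarity != spectrum.polarity:
            continue
        tol = _ms2_tol(
            rule.mz if rule.evidence == "fragment" else spectrum.precursor_mz,
            tol_ppm if tol_ppm is not None else rule.tol_ppm,
        )
        target_mz = (
            rule.mz
            if rule.evidence == "fragment"
            else spectrum.precursor_mz - rule.mz
        )
        if target_mz <= 0:
            continue
        if mzs.size and np.min(np.abs(mzs - target_mz)) <= tol:
            fired.append(rule)
    return fired


def _fa_anion_mass(c: int, db: int) -> float:
    """m/z of a fatty-acid carboxylate anion CcH(2c-1-2db)O2-."""
    h = 2 * c - 1 - 2 * db
    if h < 0:
        return np.nan
    f = ElementalFormula({"C": c, "H": h, "O": 2})
    return monoisotopic_mass(f) + ELECTRON_MASS


def confirmed_chain_evidence(
    spectrum: MS2Spectrum,
    candidate: pd.Series,
    tol_ppm: float = DEFAULT_MS2_PPM,
    cc_max_c: int = 30,
    cc_max_db: int = 6,
) -> bool:
    """Does a negative-mode spectrum confirm a candidate's chain makeup?

    Ester (and amide) chains are released as fatty-acid carboxylate
    anions. For a two-acyl candidate the totals (C, db) must decompose
    into two observed anions; one-acyl candidates need a single matching
    anion. Pure-ether candidates (DEG, MEG) diagnostically lack negative
    fragmentation and can never be confirmed (nor ruled out) this way.
    """
    if spectrum.polarity != "negative":
        return False
    bb = str(candidate["backbone"])
    n_acyl = {"MAG": 1, "DAG": 2, "TAG": 3, "CL": 4, "AEG": 1, "Cer": 1, "AD": 1, "FA": 1}.get(bb)
    if n_acyl is None:
        return False
    mzs = spectrum.peaks[:, 0]
    if not mzs.size:
        return False
    total_c, total_db = int(candidate["c"]), int(candidate["db"])

    def seen(c: int, db: int) -> bool:
        m = _fa_anion_mass(c, db)
        return bool(np.isfinite(m) and np.min(np.abs(mzs - m)) <= _ms2_tol(m, tol_ppm))

    if n_acyl == 1:
        search = (
            [(total_c, total_db)]
            if bb in ("MAG", "FA")
            # mixed backbones: the acyl chain carries an unknown share
            else [(c, d) for c in range(2, min(total_c, cc_max_c) + 1)
                  for d in range(0, min(total_db, cc_max_db) + 1)]
        )
        return any(seen(c, d) for c, d in search)
    if n_acyl == 2:
        for c1 in range(2, total_c - 1):
            for d1 in range(0, total_db + 1):
                c2, d2 = total_c - c1, total_db - d1
                if not (2 <= c2 <= cc_max_c and c1 <= cc_max_c):
                    continue
                if d1 <= cc_max_db and d2 <= cc_max_db and seen(c1, d1) and seen(c2, d2):
                    return True
        return False
    # 3- and 4-acyl: require any two complementary-looking anions
    hits = [(c, d) for c in range(2, cc_max_c + 1) for d in range(0, cc_max_db + 1) if seen(c, d)]
    return len(hits) >= 2


@dataclass(frozen=True)
class AnnotatedLipid:
    """A feature assigned to a database species, with provenance."""

    feature_id: str
    name: str
    headgroup: str
    backbone: str
    adduct: str
    mz: float
    rt_s: float
    confidence: str  # MS1-only | MS2-headgroup | MS2-full
    provenance: str  # direct | neighbor-transfer | no-hydroxylation-default | unresolved


def resolve_isomers(
    feature: Feature,
    candidates: pd.DataFrame,
    neg_confirmed: pd.DataFrame | None = None,
    neighbors: Sequence[tuple[float, str, str]] = (),
) -> tuple[pd.Series | None, str]:
    """Choose one structural isomer from an MS1 candidate set.

    ``neg_confirmed`` is the subset of candidates whose chain makeup a
    negative-mode spectrum confirmed (direct assignment).  ``neighbors``
    are (rt_s, headgroup, backbone) triples of already-confirmed lipids;
    a same-headgroup neighbor within 15 s donates its backbone linkage
    (nearest |dRT| wins, ties by lexicographic name). Failing both, the
    isomer requiring no hydroxylation is chosen. Returns (row or None,
    provenance).
    """
    if candidates.empty:
        return None, "unresolved"
    if neg_confirmed is not None and len(neg_confirmed):
        row = neg_confirmed.sort_values(["oh", "name"]).iloc[0]
        return row, "direct"
    if len(candidates) == 1:
        row = candidates.iloc[0]
        return row, "direct"
    same_hg = [
        (abs(feature.rt_s - rt), hg, bb)
        for rt, hg, bb in neighbors
        if hg in set(candidates["headgroup"]) and abs(feature.rt_s - rt) < NEIGHBOR_RT_WINDOW_S
    ]
    if same_hg:
        same_hg.sort()
        for _, hg, bb in same_hg:
            sub = candidates[
                (candidates["headgroup"] == hg) & (candidates["backbone"] == bb)
            ]
            if len(sub):
                return sub.sort_values(["oh", "name"]).iloc[0], "neighbor-transfer"
    no_oh = candidates[candidates["oh"] == 0]
    if len(no_oh):
        # Residual ties between exact isomers: a pure-ether (diether)
        # structure is silent as a negative adduct, so the absence of
        # ester-chain fragments argues for it over an ester-bearing twin.
        no_oh = no_oh.copy()
        no_oh["_ester"] = ~no_oh["backbone"].isin(("DEG", "MEG"))
        return no_oh.sort_values(["_ester", "name"]).iloc[0].drop("_ester"), "no-hydroxylation-default"
    return None, "unresolved"


def annotate_features(
    features: Sequence[Feature],
    spectra: Sequence[MS2Spectrum],
    db: LipidDatabase,
    rules: Sequence[DiagnosticRule],
    tol_ppm: float = DEFAULT_MS1_PPM,
    ms2_tol_ppm: float = DEFAULT_MS2_PPM,
) -> pd.DataFrame:
    """Full annotation pipeline over a feature table.

    Positive-mode spectra narrow candidates to headgroups with diagnostic
    evidence; negative-mode spectra of the same feature group (matched by
    feature id) give direct chain confirmation. A second pass transfers
    linkage assignments from confirmed neighbors. Features without MS2
    are reported MS1-only (excluded from quantification downstream).
    """
    cand_map = match_ms1(features, db, tol_ppm)
    spec_by_feature: dict[str, list[MS2Spectrum]] = {}
    for sp in spectra:
        spec_by_feature.setdefault(sp.feature_id, []).append(sp)

    records: list[AnnotatedLipid] = []
    pending: list[tuple[Feature, pd.DataFrame, str]] = []
    neighbors: list[tuple[float, str, str]] = []

    for f in features:
        if f.is_isotope:
            continue
        cands = cand_map.get(f.feature_id, pd.DataFrame())
        specs = spec_by_feature.get(f.feature_id, [])
        if cands.empty:
            continue
        if not specs:
            row = cands.sort_values(["oh", "name"]).iloc[0]
            records.append(_record(f, row, "MS1-only", "unresolved"))
            continue
        fired: list[DiagnosticRule] = []
        for sp in specs:
            fired.extend(annotate_ms2(sp, rules, ms2_tol_ppm))
        hg_evidence = {r.target for r in fired if r.level == "headgroup"}
        if hg_evidence:
            narrowed = cands[cands["headgroup"].isin(hg_evidence)]
            if len(narrowed):
                cands = narrowed
        # backbone-level positive-mode evidence (e.g. sphingoid dehydration
        # marking ceramides) settles ion twins like Cer [M+H]+ vs AD [M+NH4]+
        bb_evidence = {r.target for r in fired if r.level == "backbone-linkage"}
        if bb_evidence:
            narrowed = cands[cands["backbone"].isin(bb_evidence)]
            if len(narrowed):
                cands = narrowed
        # MS2 present but silent on every rule confirms nothing: stays MS1-only
        confidence = "MS2-headgroup" if hg_evidence else "MS1-only"
        neg_specs = [sp for sp in specs if sp.polarity == "negative"]
        neg_confirmed = None
        if neg_specs:
            mask = cands.apply(
                lambda row: any(
                    confirmed_chain_evidence(sp, row, ms2_tol_ppm) for sp in neg_specs
                ),
                axis=1,
            )
            if mask.any():
                neg_confirmed = cands[mask]
        if neg_confirmed is not None or len(cands) == 1:
            row, prov = resolve_isomers(f, cands, neg_confirmed)
            if row is not None:
                conf = "MS2-full" if (neg_confirmed is not None and prov == "direct") else confidence
                records.append(_record(f, row, conf, prov))
                neighbors.append((f.rt_s, str(row["headgroup"]), str(row["backbone"])))
                continue
        pending.append((f, cands, confidence))

    # second pass: neighbor transfer against the confirmed set
    for f, cands, confidence in pending:
        row, prov = resolve_isomers(f, cands, None, neighbors)
        if row is None:
            records.append(
                AnnotatedLipid(f.feature_id, "", "", "", "", f.mz, f.rt_s, confidence, "unresolved")
            )
        else:
            records.append(_record(f, row, confidence, prov))

    df = pd.DataFrame([r.__dict__ for r in records])
    return df.sort_values("feature_id", kind="mergesort").reset_index(drop=True) if len(df) else df


def _record(f: Feature, row: pd.Series, confidence: str, provenance: str) -> AnnotatedLipid:
    return AnnotatedLipid(
        feature_id=f.feature_id,
        name=str(row["name"]),
        headgroup=str(row["headgroup"]),
        backbone=str(row["backbone"]),
        adduct=str(row["adduct"]),
        mz=float(f.mz),
        rt_s=float(f.rt_s),
        confidence=confidence,
        provenance=provenance,
    )


def combine_spectra(spectra: Sequence[MS2Spectrum], tol_ppm: float = DEFAULT_MS2_PPM) -> MS2Spectrum:
    """Merge spectra of one feature into a composite spectrum.

    Peaks are clustered greedily along m/z at the MS2 tolerance;
    clusters are intensity-summed at the intensity-weighted mean m/z.
    """
    if not spectra:
        raise ValueError("no spectra to combine")
    first = spectra[0]
    if len(spectra) == 1:
        return MS2Spectrum(
            first.feature_id, first.precursor_mz, first.rt_s, first.polarity,
            first.peaks, composite=True,
        )
    allpk = np.vstack([sp.peaks for sp in spectra])
    allpk = allpk[np.argsort(allpk[:, 0])]
    merged: list[tuple[float, float]] = []
    cur_mz = [allpk[0, 0]]
    cur_int = [allpk[0, 1]]
    for mz, inten in allpk[1:]:
        if mz - cur_mz[-1] <= _ms2_tol(mz, tol_ppm):
            cur_mz.append(mz)
            cur_int.append(inten)
        else:
            w = np.asarray(cur_int)
            total = w.sum()
            center = np.average(cur_mz, weights=w) if total > 0 else float(np.mean(cur_mz))
            merged.append((center, total))
            cur_mz, cur_int = [mz], [inten]
    w = np.asarray(cur_int)
    total = w.sum()
    center = np.average(cur_mz, weights=w) if total > 0 else float(np.mean(cur_mz))
    merged.append((center, total))
    return MS2Spectrum(
        first.feature_id,
        float(np.mean([sp.precursor_mz for sp in spectra])),
        float(np.mean([sp.rt_s for sp in spectra])),
        first.polarity,
        np.array(merged),
        composite=True,
    )


# ---------------------------------------------------------------------------
# IO


def read_features_csv(path: str | Path) -> list[Feature]:
    """Feature table CSV: id, mz, rt_s, polarity, area_<sample> columns."""
    df = pd.read_csv(path)
    area_cols = [c for c in df.columns if c.startswith("area_")]
    feats = []
    for row in df.itertuples(index=False):
        areas = {c[len("area_"):]: float(getattr(row, c)) for c in area_cols}
        feats.append(
            Feature(
                feature_id=str(row.id),
                mz=float(row.mz),
                rt_s=float(row.rt_s),
                polarity=str(row.polarity),
                areas=areas,
                is_isotope=bool(getattr(row, "is_isotope", False)),
            )
        )
    return feats


def write_features_csv(features: Sequence[Feature], path: str | Path) -> None:
    samples = sorted({s for f in features for s in f.areas})
    rows = []
    for f in features:
        row = {
            "id": f.feature_id, "mz": f.mz, "rt_s": f.rt_s,
            "polarity": f.polarity, "is_isotope": f.is_isotope,
        }
        for s in samples:
            row[f"area_{s}"] = f.areas.get(s, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ms2_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read MS2 spectra from MGF; TITLE carries the feature id."""
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = params.get("charge")
            polarity = "negative" if charge and str(charge[0]).endswith("-") else "positive"
            peaks = np.column_stack([spec["m/z array"], spec["intensity array"]])
            spectra.append(
                MS2Spectrum(
                    feature_id=str(params["title"]),
                    precursor_mz=float(params["pepmass"][0]),
                    rt_s=float(params.get("rtinseconds", 0.0)),
                    polarity=polarity,
                    peaks=peaks,
                )
            )
    return spectra


def write_ms2_mgf(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    from pyteomics import mgf

    entries = []
    for sp in spectra:
        entries.append(
            {
                "m/z array": sp.peaks[:, 0],
                "intensity array": sp.peaks[:, 1],
                "params": {
                    "title": sp.feature_id,
                    "pepmass": sp.precursor_mz,
                    "rtinseconds": sp.rt_s,
                    "charge": "1+" if sp.polarity == "positive" else "1-",
                },
            }
        )
    mgf.write(entries, str(path), file_mode="w")
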