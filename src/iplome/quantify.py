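"""Semi-quantification of annotated lipids.

Peak areas become concentrations (ng of lipid per liter of filtered
water) in four steps:

1. **Blank filtering** — a lipid is kept in a sample only when its area
   exceeds ``ratio`` (default 10) times the mean area in solvent
   blanks; lipids retained nowhere are dropped.
2. **Matrix correction** — areas in each sample are rescaled by the
   response ratio of a deuterated internal standard (d9-DGTS) spiked
   into the sample versus the pure compound, compensating ionization
   suppression or enhancement by the sample matrix.
3. **Response factors** — the slope of peak area against injected mass
   over a 5-point dilution series (0.1, 1.0, 2.5, 5.0, 10.0 ng on
   column) of an authentic standard. Lipid classes without their own
   standard borrow one by headgroup similarity: aminolipids (OL,
   3Me-OL, DGCC) use the DGTS factor, nitrogen-bearing glycolipids
   (NAcG-G, NAcG-P, G-GA/1G-GA) the DG-Cer standard, and multi-glycosyl
   glycolipids (GAc-G, 2G) the DG-DAG standard; classes with several
   standards use the average factor.
4. **Volume normalization** — ng on column / L filtered.

Absolute accuracy is not claimed: without an authentic standard per
structure the result is semi-quantitative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "DilutionSeries",
    "ResponseFactorModel",
    "blank_filter",
    "matrix_correct",
    "fit_response_factor",
    "assign_response_factor",
    "quantify",
    "quantify_table",
    "DEFAULT_CLASS_RULES",
]

DEFAULT_BLANK_RATIO = 10.0

# Headgroup-similarity fallback: lipid class -> standard name.
DEFAULT_CLASS_RULES: Mapping[str, str] = {
    "OL": "DGTS",
    "3Me-OL": "DGTS",
    "DGCC": "DGTS",
    "NAcG-G": "DG-Cer",
    "NAcG-P": "DG-Cer",
    "G-GA": "DG-Cer",
    "1G-GA": "DG-Cer",
    "GAc-G": "DG-DAG",
    "2G": "DG-DAG",
}


@dataclass(frozen=True)
class DilutionSeries:
    """Injected masses (ng on column) and integrated peak areas for one standard."""

    standard: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = {m for m, _ in self.points}
        if len(masses) < 2:
            raise ValueError(
                f"dilution series for {self.standard}: need >=2 distinct masses"
            )


@dataclass(frozen=True)
class ResponseFactorModel:
    """Fitted response factor (peak area per ng) for one standard."""

    standard: str
    slope: float
    intercept: float = 0.0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"standard {self.standard}: slope must be positive")


def blank_filter(
    areas: pd.DataFrame,
    blank_means: pd.Series,
    ratio: float = DEFAULT_BLANK_RATIO,
) -> pd.DataFrame:
    """Zero out areas not exceeding ratio x blank mean; drop empty lipids.

    ``areas`` is lipid x sample; ``blank_means`` is indexed by lipid
    (missing lipids count as blank-free). A zero blank mean always
    retains the lipid. The operation is idempotent.
    """
    if ratio <= 0:
        raise ValueError("blank ratio must be positive")
    bm = blank_means.reindex(areas.index).fillna(0.0)
    keep = areas.gt(ratio * bm, axis=0) | (bm == 0).to_numpy()[:, None]
    filtered = areas.where(keep & (areas > 0), 0.0)
    return filtered.loc[(filtered > 0).any(axis=1)]


def matrix_correct(
    areas: pd.DataFrame,
    is_area_in_sample: Mapping[str, float] | pd.Series,
    is_area_pure: float,
    invert: bool = False,
) -> pd.DataFrame:
    """Rescale each sample's areas by the internal-standard response ratio.

    corrected = area * (pure / in-sample): ionization suppression (a
    small in-sample response) inflates areas back up. ``invert`` applies
    the reciprocal factor instead for sensitivity checks.
    """
    if not is_area_pure > 0:
        raise ValueError("pure-compound internal standard response must be positive")
    is_s = pd.Series(dict(is_area_in_sample))
    missing = [s for s in areas.columns if s not in is_s.index]
    if missing:
        raise ValueError(f"missing internal-standard response for samples: {missing}")
    if (is_s.reindex(areas.columns) <= 0).any():
        bad = is_s.reindex(areas.columns)
        bad = list(bad[bad <= 0].index)
        raise ValueError(f"non-positive internal-standard response in samples: {bad}")
    factor = is_area_pure / is_s.reindex(areas.columns)
    if invert:
        factor = 1.0 / factor
    return areas.mul(factor, axis=1)


def fit_response_factor(
    series: DilutionSeries, through_origin: bool = False
) -> ResponseFactorModel:
    """Ordinary least-squares slope of area on injected mass.

    The intercept is fitted (real series have baseline offsets) and
    reported but plays no role in quantification; ``through_origin``
    forces a zero intercept.
    """
    masses = np.array([m for m, _ in series.points], dtype=float)
    areas = np.array([a for _, a in series.points], dtype=float)
    if np.ptp(masses) == 0:
        raise ValueError(f"dilution series for {series.standard}: zero mass variance")
    if through_origin:
        slope = float(masses @ areas / (masses @ masses))
        ss_res = float(((areas - slope * masses) ** 2).sum())
        ss_tot = float(((areas - areas.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return ResponseFactorModel(series.standard, slope, 0.0, r2)
    fit = _scipy_stats.linregress(masses, areas)
    return ResponseFactorModel(
        series.standard, float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    )


def assign_response_factor(
    lipid_class: str,
    models: Mapping[str, ResponseFactorModel] | Sequence[ResponseFactorModel],
    class_rules: Mapping[str, str] = DEFAULT_CLASS_RULES,
) -> float:
    """Response-factor slope for a lipid class.

    A class with direct standards uses them (averaging when several
    standards cover the class: standards are matched by name prefix
    ``<class>`` or ``<class>-...``). Otherwise the headgroup-similarity
    rules map the class onto a measured standard. No rule and no
    standard is an error.
    """
    if not isinstance(models, Mapping):
        models = {m.standard: m for m in models}
    direct = [
        m.slope
        for name, m in models.items()
        if name == lipid_class or name.startswith(lipid_class + "-")
    ]
    if direct:
        return float(np.mean(direct))
    mapped = class_rules.get(lipid_class)
    if mapped is not None:
        if mapped in models:
            return models[mapped].slope
        prefixed = [m.slope for name, m in models.items() if name.startswith(mapped)]
        if prefixed:
            return float(np.mean(prefixed))
        raise ValueError(
            f"class {lipid_class!r} maps to standard {mapped!r} which was not measured"
        )
    raise ValueError(f"no response factor rule or standard for lipid class {lipid_class!r}")


def quantify(corrected_area: float, slope: float, volume_l: float) -> float:
    """Concentration in ng/L: (area / slope) / volume."""
    if not slope > 0:
        raise ValueError("response-factor slope must be positive")
    if not volume_l > 0:
        raise ValueError("filtered volume must be positive")
    return (corrected_area / slope) / volume_l


def quantify_table(
    areas: pd.DataFrame,
    lipid_classes: Mapping[str, str] | pd.Series,
    models: Mapping[str, ResponseFactorModel],
    volumes_l: Mapping[str, float] | pd.Series,
    class_rules: Mapping[str, str] = DEFAULT_CLASS_RULES,
) -> pd.DataFrame:
    """Vectorized quantification of a lipid x sample area matrix.

    ``lipid_classes`` maps each lipid (row) to its class (headgroup)
    for response-factor assignment; ``volumes_l`` maps each sample
    (column) to liters filtered.
    """
    classes = pd.Series(dict(lipid_classes)).reindex(areas.index)
    if classes.isna().any():
        raise ValueError(f"lipids without class: {list(classes[classes.isna()].index)}")
    slopes = classes.map(lambda c: assign_response_factor(c, models, class_rules))
    vols = pd.Series(dict(volumes_l)).reindex(areas.columns)
    if vols.isna().any() or (vols <= 0).any():
        raise ValueError("every sample needs a positive filtered volume")
    return areas.div(slopes, axis=0).div(vols, axis=1)
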