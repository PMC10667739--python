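"""Lipidome geochemistry statistics.

Relative (mole-fraction) abundances, abundance-weighted structural
properties, carbon oxidation state (Zc) of lipids and their parts,
taxa-lipid Pearson correlation with Bonferroni control, and the
Hellinger/Gower preprocessing consumed by constrained ordination.

The abundance-weighted average of a structural property is::

    Xi = sum_i Xi_ipl,i * x_i / sum_i n_component,i * x_i

where ``Xi_ipl,i`` is the property summed across components of lipid i
(e.g. 36 carbons in the chains of a 36:0 DAG), ``n_component,i`` the
number of component instances (2 chains in a DAG) and ``x_i`` the mole
fraction. Weighted Zc of a lipid part uses the same form with the
part's electron-bookkeeping numerator over its carbon count — i.e. a
carbon-weighted mean oxidation state.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .formula import ElementalFormula, FormulaError, combine, parse_formula, zc_numerator
from .database import LipidSpecies, load_part_tables, _data_path
from .nomenclature import parse_name

__all__ = [
    "AbundanceMatrix",
    "PartitionedFormula",
    "PropertySpec",
    "relative_abundance",
    "weighted_property",
    "partition_formula",
    "partition_name",
    "weighted_zc",
    "taxa_lipid_correlation",
    "hellinger",
    "gower",
]

PARTS = ("whole", "headgroup", "backbone", "chains")


@dataclass(frozen=True)
class PartitionedFormula:
    """Headgroup/backbone/chains split of a neutral species formula.

    The three parts sum exactly to the whole by construction (the chains
    part is the remainder after the tabulated headgroup and backbone
    chunks are removed).
    """

    whole: ElementalFormula
    headgroup: ElementalFormula
    backbone: ElementalFormula
    chains: ElementalFormula

    def part(self, name: str) -> ElementalFormula:
        if name not in PARTS:
            raise ValueError(f"unknown part {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class PropertySpec:
    """Per-lipid property values and component counts for weighting."""

    name: str
    per_lipid: Mapping[str, float]  # lipid name -> property summed over components
    n_component: Mapping[str, float]  # lipid name -> number of component instances

    def __post_init__(self) -> None:
        bad = [k for k, v in self.n_component.items() if v < 1]
        if bad:
            raise ValueError(f"n_component < 1 for {bad}")


class AbundanceMatrix:
    """Lipid x sample mole-fraction matrix; columns sum to 1."""

    def __init__(self, fractions: pd.DataFrame):
        if (fractions.to_numpy() < 0).any():
            raise ValueError("negative abundance")
        sums = fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"columns must sum to 1, got {sums.to_dict()}")
        self.fractions = fractions

    @property
    def lipids(self) -> pd.Index:
        return self.fractions.index

    @property
    def samples(self) -> pd.Index:
        return self.fractions.columns


def relative_abundance(
    concentrations: pd.DataFrame,
    masses: Mapping[str, float] | pd.Series | None = None,
    molar: bool = True,
) -> AbundanceMatrix:
    """Mole fractions (or mass fractions) from a concentration table.

    ``concentrations`` is lipid x sample (ng/L). When ``molar``,
    concentrations are divided by neutral monoisotopic mass before
    normalizing, giving mole fractions.
    """
    conc = concentrations.astype(float)
    if (conc.to_numpy() < 0).any():
        raise ValueError("negative concentration")
    if molar:
        if masses is None:
            raise ValueError("molar fractions need per-lipid masses")
        m = pd.Series(dict(masses)).reindex(conc.index)
        if m.isna().any():
            raise ValueError(f"missing masses for {list(m[m.isna()].index)}")
        conc = conc.div(m, axis=0)
    totals = conc.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals[totals <= 0].index)
        raise ValueError(f"all-zero samples: {empty}")
    return AbundanceMatrix(conc.div(totals, axis=1))


def weighted_property(x: AbundanceMatrix, spec: PropertySpec) -> pd.Series:
    """Abundance-weighted average property per sample."""
    frac = x.fractions
    present = frac.index[(frac > 0).any(axis=1)]
    missing = [l for l in present if l not in spec.per_lipid or l not in spec.n_component]
    if missing:
        raise ValueError(f"property {spec.name!r} undefined for abundant lipids: {missing}")
    xi = pd.Series({l: spec.per_lipid.get(l, 0.0) for l in frac.index})
    nc = pd.Series({l: spec.n_component.get(l, 1.0) for l in frac.index})
    num = frac.mul(xi, axis=0).sum(axis=0)
    den = frac.mul(nc, axis=0).sum(axis=0)
    if (den == 0).any():
        raise ValueError("zero component weight in some sample")
    out = num / den
    out.name = spec.name
    return out


def n_chains_of(name: str) -> int:
    """Number of chains of a species from its composite name."""
    p = parse_name(name)
    if p.kind == "unique":
        return 2  # archaeol, GDGT/GDD and ladderane cores carry two chains
    _, backbones = load_part_tables()
    return int(backbones.loc[p.backbone, "n_chains"])


@lru_cache(maxsize=1)
def _partition_table() -> dict[str, ElementalFormula]:
    df = pd.read_csv(_data_path("zc_partitions.tsv"), sep="\t")
    return {str(r[0]): parse_formula(str(r[1])) for r in df.itertuples(index=False)}


def _backbone_class(backbone: str) -> str:
    """Collapse unique core labels (GDGT-4, LAD3-20, ...) onto partition classes."""
    table = _partition_table()
    if backbone in table:
        return backbone
    for cls in ("brGDGT", "brGDD", "GDGT", "GDD", "LAD"):
        if backbone.startswith(cls):
            return cls
    raise KeyError(backbone)


def partition_formula(species: LipidSpecies) -> PartitionedFormula:
    """Split a species formula into headgroup, backbone and chains parts.

    The headgroup chunk is the tabulated net headgroup formula; the
    backbone chunk comes from the shipped partition table (calibrated so
    the ceramide backbone scores Zc = -0.75); chains take the remainder.
    """
    heads, _ = load_part_tables()
    try:
        bcls = _backbone_class(species.backbone)
    except KeyError:
        raise ValueError(f"no Zc partition rule for backbone {species.backbone!r}") from None
    backbone = _partition_table()[bcls]
    head = heads.get(species.headgroup, ElementalFormula()) if species.headgroup else ElementalFormula()
    try:
        chains = combine(combine(species.formula, head, -1), backbone, -1)
    except FormulaError as exc:
        raise ValueError(
            f"partition of {species.name} underflows: {exc}"
        ) from None
    return PartitionedFormula(species.formula, head, backbone, chains)


def partition_name(name: str, formula: ElementalFormula, n_chains: int = 2) -> PartitionedFormula:
    """Partition from a composite name plus neutral formula (no species object)."""
    p = parse_name(name)
    sp = LipidSpecies(
        headgroup=p.headgroup, backbone=p.backbone, c=p.c, db=p.db, oh=p.oh,
        formula=formula, kind=p.kind, n_chains=n_chains,
        uns=p.uns, me=p.me, ext=p.ext, abr=p.abr,
    )
    return partition_formula(sp)


def weighted_zc(
    x: AbundanceMatrix,
    partitions: Mapping[str, PartitionedFormula],
    part: str = "whole",
) -> pd.Series:
    """Abundance-weighted carbon oxidation state of a lipid part per sample.

    Carbon-weighted mean: sum_i x_i * e_i / sum_i x_i * c_i with e_i the
    part's Zc numerator (charge + 2o + 3n - 5p - 4s - h) and c_i its
    carbon count. Carbon-free parts (e.g. a fatty-amide backbone chunk)
    contribute their numerator with zero carbon weight; the denominator
    must stay positive.
    """
    frac = x.fractions
    present = frac.index[(frac > 0).any(axis=1)]
    missing = [l for l in present if l not in partitions]
    if missing:
        raise ValueError(f"no partition for abundant lipids: {missing}")
    e = pd.Series({l: zc_numerator(partitions[l].part(part)) if l in partitions else 0.0
                   for l in frac.index})
    c = pd.Series({l: float(partitions[l].part(part)["C"]) if l in partitions else 0.0
                   for l in frac.index})
    num = frac.mul(e, axis=0).sum(axis=0)
    den = frac.mul(c, axis=0).sum(axis=0)
    if (den <= 0).any():
        bad = list(den[den <= 0].index)
        raise ValueError(f"no carbon in part {part!r} for samples {bad}")
    out = num / den
    out.name = f"zc_{part}"
    return out


def taxa_lipid_correlation(
    lipid_x: pd.DataFrame,
    taxa_x: pd.DataFrame,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Pearson correlation of every lipid x taxon pair across samples.

    Bonferroni correction multiplies raw p-values by the number of
    testable pairs (zero-variance vectors are reported untested with NaN
    statistics and excluded from the correction count m). ``significant``
    marks p_adj < alpha; a lipid may be significantly associated with
    several taxa.
    """
    samples = lipid_x.columns.intersection(taxa_x.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    lip = lipid_x[samples].astype(float)
    tax = taxa_x[samples].astype(float)
    lip_ok = lip.std(axis=1) > 0
    tax_ok = tax.std(axis=1) > 0
    rows = []
    m = int(lip_ok.sum()) * int(tax_ok.sum())
    for lname, lrow in lip.iterrows():
        for tname, trow in tax.iterrows():
            if not (lip_ok[lname] and tax_ok[tname]):
                rows.append((lname, tname, np.nan, np.nan, np.nan, False, False))
                continue
            r, p = _scipy_stats.pearsonr(lrow.to_numpy(), trow.to_numpy())
            p_adj = min(1.0, p * m)
            rows.append((lname, tname, r, p, p_adj, p_adj < alpha, True))
    return pd.DataFrame(
        rows, columns=["lipid", "taxon", "r", "p", "p_adj", "significant", "tested"]
    )


def hellinger(x: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Hellinger transform: sqrt of row-wise proportions.

    Rows are observations (samples), columns components. Output rows
    have unit sum of squares.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values")
    sums = arr.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero row")
    out = np.sqrt(arr / sums)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def gower(x: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Gower dissimilarity: mean range-normalized absolute difference.

    d(a, b) = mean_k |a_k - b_k| / range_k over columns with non-zero
    range (zero-range columns are uninformative and excluded). Values
    lie in [0, 1]; the diagonal is zero; the matrix is symmetric.
    """
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two samples")
    rng = arr.max(axis=0) - arr.min(axis=0)
    keep = rng > 0
    if not keep.any():
        d = np.zeros((arr.shape[0], arr.shape[0]))
    else:
        sub = arr[:, keep] / rng[keep]
        d = np.abs(sub[:, None, :] - sub[None, :, :]).mean(axis=2)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(d, index=x.index, columns=x.index)
    return d
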