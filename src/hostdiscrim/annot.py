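"""Putative compound annotation of m/z bins by monoisotopic adduct mass.

Untargeted MALDI-TOF profiles report intensity per 0.2-Da m/z bin; a bin is
putatively identified by asking which small metabolites, as their protonated
molecular ion [M+H]+, would land in it.  The chain is: parse the molecular
formula, sum monoisotopic atomic masses, add the proton mass, and locate the
bin.  Bins are reported both by their 0.2-Da left edge and by the nominal
(integer, floored) m/z, which is how practitioners usually quote them.

Group comparisons (log fold change and an OLS F-test of log %TIC between two
species groups, e.g. the most *Medicago*-shifted vs the most
*Trifolium*-shifted species) quantify how a bin's abundance differs between
plant genera.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "CompoundRecord",
    "AnnotationHit",
    "GroupTestResult",
    "GroupComparisonResult",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "match_compound_to_bin",
    "annotate_bins",
    "load_compound_table",
    "group_log_fold_change",
    "group_lm_ftest",
]

#: Monoisotopic atomic masses (Da) of the elements covered by the bundled
#: compound table.  Values are the IUPAC masses of each element's most
#: abundant isotope.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

#: Mass of a proton, Da ([M+H]+ adduct shift for charge 1).
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula string cannot be parsed."""


@dataclass(frozen=True)
class CompoundRecord:
    """A candidate metabolite: name, Hill-notation formula, neutral mass."""

    name: str
    formula: str
    pathway: str | None = None
    monoisotopic: float = field(init=False)

    def __post_init__(self) -> None:
        mass = monoisotopic_mass(parse_formula(self.formula))
        if mass <= 0:
            raise ValueError(f"non-positive mass for formula {self.formula!r}")
        object.__setattr__(self, "monoisotopic", mass)


@dataclass(frozen=True)
class AnnotationHit:
    """A compound whose adduct m/z lands in (or near) a queried bin."""

    compound: CompoundRecord
    adduct: str
    theoretical_mz: float
    bin_label: float      # left edge of the 0.2-Da bin, 1 decimal
    nominal_bin: int      # floor(theoretical m/z)
    mass_error_da: float  # theoretical minus query m/z (0 for forward match)


@dataclass(frozen=True)
class GroupTestResult:
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class GroupComparisonResult:
    bin_label: float
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    log_fold_change: float
    test: GroupTestResult


def parse_formula(s: str) -> dict[str, int]:
    """Parse a molecular formula like ``"C9H11NO2"`` into element counts.

    Only flat formulas (element symbol + optional integer count) are
    supported; unknown elements and malformed strings raise
    :class:`FormulaError` with the offending position.
    """
    if not s or not isinstance(s, str):
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {s!r} at position {pos}")
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element {elem!r} in {s!r} at position {pos}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) from parsed element counts."""
    try:
        return float(sum(MONOISOTOPIC_MASSES[el] * n for el, n in counts.items()))
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"element {exc.args[0]!r} missing from mass table") from exc


def protonated_mz(neutral_mass: float, n_protons: int = 1) -> float:
    """m/z of the [M+nH]n+ ion; default [M+H]+ (positive-mode MALDI)."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + n_protons * PROTON_MASS) / max(n_protons, 1)


_ADDUCT_SHIFTS = {
    "[M+H]+": ("H", 1),
    "[M+2H]+": ("2H", 2),   # mass + 2 protons, reported at charge 1 (proton pair)
    "[M+Na]+": ("Na", 1),
    "[M+K]+": ("K", 1),
}


def _adduct_mz(neutral_mass: float, adduct: str) -> float:
    if adduct == "[M+H]+":
        return neutral_mass + PROTON_MASS
    if adduct == "[M+2H]+":
        # the one-proton-heavier neighbour ion, singly charged
        return neutral_mass + 2 * PROTON_MASS
    if adduct == "[M+Na]+":
        return neutral_mass + MONOISOTOPIC_MASSES["Na"] - MONOISOTOPIC_MASSES["H"] + PROTON_MASS
    if adduct == "[M+K]+":
        return neutral_mass + MONOISOTOPIC_MASSES["K"] - MONOISOTOPIC_MASSES["H"] + PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}")


def _bin_left_edge(mz: float, bin_width: float = 0.2, range_min: float = 50.0) -> float:
    idx = math.floor((mz - range_min) / bin_width)
    return round(range_min + idx * bin_width, 1)


def match_compound_to_bin(
    compound: CompoundRecord,
    bin_width: float = 0.2,
    range_min: float = 50.0,
    adducts: tuple[str, ...] = ("[M+H]+",),
) -> list[AnnotationHit]:
    """Forward query: which bins does each adduct of ``compound`` land in."""
    hits = []
    for adduct in adducts:
        mz = _adduct_mz(compound.monoisotopic, adduct)
        hits.append(
            AnnotationHit(
                compound=compound,
                adduct=adduct,
                theoretical_mz=mz,
                bin_label=_bin_left_edge(mz, bin_width, range_min),
                nominal_bin=math.floor(mz),
                mass_error_da=0.0,
            )
        )
    return hits


def annotate_bins(
    bin_mzs,
    compounds,
    tolerance_da: float = 0.1,
    adducts: tuple[str, ...] = ("[M+H]+",),
    bin_width: float = 0.2,
    range_min: float = 50.0,
) -> list[AnnotationHit]:
    """Reverse query: compounds whose adduct m/z falls inside (or within
    ``tolerance_da`` of) a queried bin.  An integer-valued query is treated
    as a nominal bin (the 1-Da interval [q, q+1)); a fractional query as a
    0.2-Da bin left edge ([q, q+bin_width)).
    """
    hits: list[AnnotationHit] = []
    for q in np.atleast_1d(np.asarray(bin_mzs, dtype=float)):
        q = float(q)
        lo, hi = (q, q + 1.0) if q.is_integer() else (q, q + bin_width)
        for comp in compounds:
            for adduct in adducts:
                mz = _adduct_mz(comp.monoisotopic, adduct)
                # signed distance from the queried bin interval
                err = mz - lo if mz < lo else (mz - hi if mz >= hi else 0.0)
                if abs(err) <= tolerance_da:
                    hits.append(
                        AnnotationHit(
                            compound=comp,
                            adduct=adduct,
                            theoretical_mz=mz,
                            bin_label=_bin_left_edge(mz, bin_width, range_min),
                            nominal_bin=math.floor(mz),
                            mass_error_da=float(err),
                        )
                    )
    return hits


def load_compound_table(path=None) -> list[CompoundRecord]:
    """Load a compound table CSV (``name,formula,pathway``).

    Without a path, the bundled table of phenylalanine/tyrosine-pathway
    metabolites is used.
    """
    if path is None:
        ref = resources.files("hostdiscrim").joinpath("data/compounds.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"name", "formula"}.issubset(df.columns):
        raise ValueError("compound table needs columns name,formula[,pathway]")
    return [
        CompoundRecord(
            name=row["name"],
            formula=row["formula"],
            pathway=row.get("pathway") if isinstance(row.get("pathway"), str) else None,
        )
        for _, row in df.iterrows()
    ]


_LOG_EPS = 1e-6  # pseudo-count in %TIC units for logs of zero means


def group_log_fold_change(
    matrix: pd.DataFrame,
    bin_label,
    group_a,
    group_b,
    species: pd.Series | None = None,
    log_base: float = 2.0,
) -> float:
    """log(mean %TIC in group A / mean %TIC in group B) for one bin.

    ``matrix`` is plants x bins; ``species`` maps rows to species names
    (defaults to a ``species`` column level or index).  A pseudo-count of
    1e-6 %TIC is added when a group mean is zero.
    """
    a_vals, b_vals = _group_values(matrix, bin_label, group_a, group_b, species)
    mean_a, mean_b = float(np.mean(a_vals)), float(np.mean(b_vals))
    if mean_a <= 0 or mean_b <= 0:
        mean_a += _LOG_EPS
        mean_b += _LOG_EPS
    return float(math.log(mean_a / mean_b, log_base))


def group_lm_ftest(
    matrix: pd.DataFrame,
    bin_label,
    group_a,
    group_b,
    species: pd.Series | None = None,
) -> GroupTestResult:
    """OLS F-test of log(%TIC + eps) on a two-group indicator across plants.

    df1 = 1 and df2 = nA + nB - 2 follow from the data, so unequal group
    availability between fractions is reflected in the degrees of freedom.
    """
    a_vals, b_vals = _group_values(matrix, bin_label, group_a, group_b, species)
    if len(a_vals) < 2 or len(b_vals) < 2:
        raise ValueError("each group needs at least 2 plants")
    y = np.log(np.concatenate([a_vals, b_vals]) + _LOG_EPS)
    g = np.concatenate([np.zeros(len(a_vals)), np.ones(len(b_vals))])
    if np.allclose(np.var(y[g == 0]), 0) and np.allclose(np.var(y[g == 1]), 0):
        raise ValueError("zero within-group variance in both groups")
    fit = sm.OLS(y, sm.add_constant(g)).fit()
    return GroupTestResult(
        F=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
    )


def _group_values(matrix, bin_label, group_a, group_b, species):
    if not len(group_a) or not len(group_b):
        raise ValueError("both species groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("species groups must be disjoint")
    if species is None:
        species = pd.Series(matrix.index, index=matrix.index)
    col = matrix.loc[:, bin_label] if bin_label in matrix.columns else None
    if col is None:
        raise KeyError(f"bin {bin_label!r} not in matrix columns")
    a = col[np.asarray(species.isin(group_a))].to_numpy(dtype=float)
    b = col[np.asarray(species.isin(group_b))].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("a species group matched no plants")
    return a, b
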