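"""Composition statistics: mol%, saturation/chain-length shares, ratios.

mol% is computed within a lipid class: a species' standard-normalized
ratio divided by the class total in the same sample, x100.  Because each
class has its own internal standard the ratios are only comparable
within a class, so cross-class mol% is deliberately undefined.

Category mol% aggregates species shares by saturation (SFA/MUFA/PUFA)
or chain length (SHORT/MEDIUM/LONG); each scheme partitions the class,
so category shares sum to 100 per sample.  Carnitine energy ratios
(C18/C2 and (C16+C18)/C2) proxy the flux balance of mitochondrial
beta-oxidation: long-chain acyl-carnitines accumulate relative to
acetyl-carnitine when fatty-acid turnover is impaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, UndefinedCompositionError
from .quantify import NormalizedProfile
from .species import (
    CarnitineCategory,
    ChainLengthBins,
    LipidClass,
    carnitine_category,
    chain_length_category,
    parse_species,
    saturation_category,
)

__all__ = [
    "CompositionProfile",
    "CarnitineRatios",
    "molpct",
    "category_molpct",
    "saturation_ratios",
    "carnitine_ratios",
]

logger = logging.getLogger(__name__)

RATIO_NAMES = ["SFA/MUFA", "SFA/PUFA", "MUFA/PUFA"]


@dataclass
class CompositionProfile:
    """Per-class mol% fragment: species (rows) x samples (columns)."""

    lipid_class: LipidClass
    species_molpct: pd.DataFrame


def molpct(profile: NormalizedProfile, lipid_class: LipidClass) -> CompositionProfile:
    """Species shares of the class total per sample, in mol percent."""
    members = [s for s, c in profile.species_classes.items() if c is lipid_class]
    if not members:
        raise MissingDataError(f"no species of class {lipid_class.value} in profile")
    values = profile.values.loc[members]
    totals = values.sum(axis=0)
    zero = totals[totals == 0.0]
    if len(zero):
        raise UndefinedCompositionError(
            f"class {lipid_class.value} total is zero in sample(s) "
            f"{list(zero.index)}"
        )
    return CompositionProfile(lipid_class, 100.0 * values / totals)


def category_molpct(composition: CompositionProfile, scheme: str,
                    bins: ChainLengthBins | None = None) -> pd.DataFrame:
    """Sum species mol% into category mol% (rows = categories).

    ``scheme`` is ``"saturation"`` or ``"chain_length"``.  Saturation
    applies to every class except carnitines; chain length only to the
    classes with defined carbon bins.
    """
    bins = bins if bins is not None else ChainLengthBins()
    species = {n: parse_species(n) for n in composition.species_molpct.index}
    if scheme == "saturation":
        if composition.lipid_class is LipidClass.CAR:
            raise UndefinedCompositionError(
                "saturation scheme is not defined for carnitines")
        labels = {n: saturation_category(s).value for n, s in species.items()}
        order = ["SFA", "MUFA", "PUFA"]
    elif scheme == "chain_length":
        if not bins.applicable(composition.lipid_class):
            raise UndefinedCompositionError(
                f"chain-length bins are not defined for class "
                f"{composition.lipid_class.value}"
            )
        labels = {n: chain_length_category(s, bins).value
                  for n, s in species.items()}
        order = ["SHORT", "MEDIUM", "LONG"]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = composition.species_molpct.groupby(
        composition.species_molpct.index.map(labels)).sum()
    return out.reindex(order, fill_value=0.0)


def saturation_ratios(category_df: pd.DataFrame) -> pd.DataFrame:
    """SFA/MUFA, SFA/PUFA and MUFA/PUFA per sample from category mol%.

    Zero denominators yield NaN for that sample (logged), which
    downstream group statistics drop pairwise.
    """
    sfa, mufa, pufa = (category_df.loc[c] for c in ("SFA", "MUFA", "PUFA"))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {"SFA/MUFA": sfa / mufa.replace(0.0, np.nan),
             "SFA/PUFA": sfa / pufa.replace(0.0, np.nan),
             "MUFA/PUFA": mufa / pufa.replace(0.0, np.nan)}
        ).T
    n_undef = int(out.isna().sum().sum())
    if n_undef:
        logger.warning("%d saturation ratios undefined (zero denominator)",
                       n_undef)
    return out


@dataclass
class CarnitineRatios:
    """Per-sample carnitine energy-metabolism readouts.

    ``ratios`` rows are ``C18/C2`` and ``(C16+C18)/C2``;
    ``category_totals`` rows are FREE/ACETYL/ACYL summed normalized
    ratios (the bar-chart quantities).
    """

    ratios: pd.DataFrame
    category_totals: pd.DataFrame


def carnitine_ratios(profile: NormalizedProfile,
                     include_unsaturated: bool = False) -> CarnitineRatios:
    """C18/C2 and (C16+C18)/C2 ratios plus category totals per sample.

    ``C18`` and ``C16`` mean the saturated species (C18:0, C16:0) by
    default; ``include_unsaturated`` adds every C18:X / C16:X
    acyl-carnitine to the numerators.
    """
    members = [s for s, c in profile.species_classes.items()
               if c is LipidClass.CAR]
    if not members:
        raise MissingDataError("no carnitine species in profile")
    values = profile.values.loc[members]
    parsed = {n: parse_species(n) for n in members}

    c2_rows = [n for n, s in parsed.items()
               if s.total_carbons == 2 and not s.hydroxylated]
    if not c2_rows:
        raise MissingDataError("acetyl-carnitine (C2) missing from profile")
    c2 = values.loc[c2_rows].sum(axis=0)
    if (c2 == 0.0).any():
        bad = list(c2[c2 == 0.0].index)
        raise MissingDataError(f"acetyl-carnitine (C2) is zero in sample(s) {bad}")

    def _chain(carbons: int) -> pd.Series:
        rows = [n for n, s in parsed.items()
                if s.total_carbons == carbons and not s.hydroxylated
                and (include_unsaturated or s.double_bonds == 0)]
        return values.loc[rows].sum(axis=0)

    c18, c16 = _chain(18), _chain(16)
    ratios = pd.DataFrame(
        {"C18/C2": c18 / c2, "(C16+C18)/C2": (c16 + c18) / c2}).T

    cats = values.groupby(
        values.index.map(lambda n: carnitine_category(parsed[n]).value)).sum()
    cats = cats.reindex([c.value for c in CarnitineCategory], fill_value=0.0)
    return CarnitineRatios(ratios, cats)
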