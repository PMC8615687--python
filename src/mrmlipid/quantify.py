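"""Raw MRM intensity ingestion, internal-standard normalization and QC.

A targeted shotgun-lipidomics acquisition yields counts-per-second for
each MRM transition.  Semiquantification divides every species intensity
by the intensity of its lipid-class internal standard measured in the
same injection (same sample, same technical replicate), then averages
the technical triplicates to one ratio per biological sample.

Matrix-effect QC compares raw internal-standard intensities between the
two experimental groups: because the standards are spiked at a constant
amount, any systematic group difference in their response reflects ion
suppression/enhancement by co-extracted matrix, not biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingDataError, NormalizationError, SchemaError
from .species import LipidClass, LipidSpecies, parse_species

__all__ = [
    "RAW_COLUMNS",
    "StandardMap",
    "NormalizedProfile",
    "MatrixEffectReport",
    "read_raw_table",
    "validate_raw_table",
    "normalize_to_standard",
    "aggregate_technical",
    "matrix_effect",
]

logger = logging.getLogger(__name__)

RAW_COLUMNS = [
    "sample_id", "group", "bio_replicate", "tech_replicate",
    "analyte", "role", "lipid_class", "intensity",
]


def _default_entries() -> dict[LipidClass, str]:
    return {
        LipidClass.PC_AA: "06:0 PC (DHPC)",
        LipidClass.PC_AE: "C18(Plasm)-18:1(d9) PC",
        LipidClass.LPC: "19:0 Lyso-PC",
        LipidClass.PE_AA: "08:0 PE",
        LipidClass.PE_AE: "08:0 PE",
        LipidClass.LPE: "08:0 PE",
        LipidClass.TAG: "15:0-18:1(d7)-15:0 TG",
    }


@dataclass(frozen=True)
class StandardMap:
    """Mapping from lipid class to its spiked internal standard.

    Carnitines use two deuterated standards split by acyl carbon count:
    species with <= ``carnitine_threshold`` carbons (including free and
    acetyl-carnitine) normalize to the octanoyl standard, longer chains
    to the palmitoyl standard.
    """

    entries: dict[LipidClass, str] = field(default_factory=_default_entries)
    carnitine_short: str = "octanoyl-L-carnitine d3"
    carnitine_long: str = "palmitoyl-L-carnitine d3"
    carnitine_threshold: int = 10

    def standard_for(self, species: LipidSpecies) -> str:
        if species.lipid_class is LipidClass.CAR:
            if species.total_carbons <= self.carnitine_threshold:
                return self.carnitine_short
            return self.carnitine_long
        try:
            return self.entries[species.lipid_class]
        except KeyError:
            raise NormalizationError(
                f"no internal standard mapped for class "
                f"{species.lipid_class.value}"
            ) from None

    def standard_names(self) -> list[str]:
        names = sorted(set(self.entries.values()))
        return names + [self.carnitine_short, self.carnitine_long]

    def class_of_standard(self, name: str) -> LipidClass:
        if name in (self.carnitine_short, self.carnitine_long):
            return LipidClass.CAR
        for cls, std in self.entries.items():
            if std == name:
                return cls
        raise KeyError(name)

    @classmethod
    def from_csv(cls, path: str | Path,
                 carnitine_threshold: int = 10) -> "StandardMap":
        """Read ``lipid_class,standard_name`` rows.

        ``CAR`` may appear twice; the first row is the short-chain
        standard, the second the long-chain one.  A single ``CAR`` row
        uses that standard for every carnitine.
        """
        df = pd.read_csv(path)
        if list(df.columns) != ["lipid_class", "standard_name"]:
            raise SchemaError(
                "standards map must have header lipid_class,standard_name"
            )
        entries: dict[LipidClass, str] = {}
        car: list[str] = []
        for code, name in zip(df["lipid_class"], df["standard_name"]):
            try:
                lipid_class = LipidClass(code)
            except ValueError:
                raise SchemaError(f"unknown lipid class {code!r}") from None
            if lipid_class is LipidClass.CAR:
                car.append(str(name))
            else:
                entries[lipid_class] = str(name)
        missing = [c.value for c in LipidClass
                   if c is not LipidClass.CAR and c not in entries]
        if missing or not car:
            missing += ["CAR"] if not car else []
            raise SchemaError(f"standards map missing classes: {missing}")
        short = car[0]
        long = car[1] if len(car) > 1 else car[0]
        return cls(entries=entries, carnitine_short=short, carnitine_long=long,
                   carnitine_threshold=carnitine_threshold)

    def to_csv(self, path: str | Path) -> None:
        rows = [(c.value, n) for c, n in self.entries.items()]
        rows += [("CAR", self.carnitine_short), ("CAR", self.carnitine_long)]
        pd.DataFrame(rows, columns=["lipid_class", "standard_name"]).to_csv(
            path, index=False)


@dataclass
class NormalizedProfile:
    """Species x biological-sample matrix of lipid/standard ratios.

    ``values`` is indexed by canonical species name with one column per
    biological sample (technical replicates already averaged);
    ``sample_groups`` maps sample id to its experimental group;
    ``replicate_counts`` records how many technical replicates
    contributed to each cell.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    replicate_counts: pd.DataFrame
    species_classes: dict[str, LipidClass]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "species"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path,
                 sample_groups: dict[str, str]) -> "NormalizedProfile":
        df = pd.read_csv(path, index_col=0)
        if df.index.name != "species":
            raise SchemaError("normalized profile must have first column 'species'")
        missing = [s for s in df.columns if s not in sample_groups]
        if missing:
            raise SchemaError(f"no group assignment for samples {missing}")
        classes = {n: parse_species(n).lipid_class for n in df.index}
        counts = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
        return cls(df.astype(float), dict(sample_groups), counts, classes)


def validate_raw_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format raw intensity table in place."""
    if list(df.columns) != RAW_COLUMNS:
        raise SchemaError(
            f"raw table header must be exactly {','.join(RAW_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    bad_role = set(df["role"].unique()) - {"species", "standard"}
    if bad_role:
        raise SchemaError(f"role must be species|standard, got {sorted(bad_role)}")
    intens = pd.to_numeric(df["intensity"], errors="coerce")
    if intens.isna().any():
        raise SchemaError("non-numeric intensity values present")
    if (intens < 0).any():
        raise SchemaError("negative intensity values present")
    reps = pd.to_numeric(df["tech_replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.round()).any():
        raise SchemaError("tech_replicate must be an integer >= 1")
    dup = df.duplicated(subset=["sample_id", "tech_replicate", "analyte"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise SchemaError(
            "duplicate (sample_id, tech_replicate, analyte) key: "
            f"({first['sample_id']}, {first['tech_replicate']}, "
            f"{first['analyte']})"
        )
    for code in df["lipid_class"].unique():
        try:
            LipidClass(code)
        except ValueError:
            raise SchemaError(f"unknown lipid class {code!r}") from None
    # Species analytes must parse and agree with the declared class.
    for name, code in (
        df.loc[df["role"] == "species", ["analyte", "lipid_class"]]
        .drop_duplicates()
        .itertuples(index=False)
    ):
        spec = parse_species(str(name))
        if spec.lipid_class.value != code:
            raise SchemaError(
                f"species {name!r} declared as {code} but parses as "
                f"{spec.lipid_class.value}"
            )
    df = df.copy()
    df["intensity"] = intens.astype(float)
    df["tech_replicate"] = reps.astype(int)
    return df


def read_raw_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format raw MRM intensity CSV."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    return validate_raw_table(df)


def normalize_to_standard(records: pd.DataFrame,
                          standards: StandardMap | None = None) -> pd.DataFrame:
    """Divide each species intensity by its class standard, per injection.

    Returns per-replicate ratio records with columns
    ``sample_id, group, bio_replicate, tech_replicate, species,
    lipid_class, ratio``.  Standards themselves are not normalized (they
    remain available in ``records`` for matrix-effect QC).
    """
    standards = standards if standards is not None else StandardMap()
    species_rows = records[records["role"] == "species"].copy()
    std_rows = records[records["role"] == "standard"]

    name_map: dict[str, tuple[str, str]] = {}
    for analyte in species_rows["analyte"].unique():
        spec = parse_species(str(analyte))
        name_map[analyte] = (spec.canonical_name, standards.standard_for(spec))
    species_rows["species"] = species_rows["analyte"].map(
        lambda a: name_map[a][0])
    species_rows["standard_name"] = species_rows["analyte"].map(
        lambda a: name_map[a][1])

    std_lookup = std_rows.set_index(
        ["sample_id", "tech_replicate", "analyte"])["intensity"]
    if std_lookup.index.has_duplicates:
        raise SchemaError("duplicate standard rows per injection")

    keys = pd.MultiIndex.from_frame(
        species_rows[["sample_id", "tech_replicate", "standard_name"]])
    std_intensity = std_lookup.reindex(keys).to_numpy()
    missing = np.isnan(std_intensity) | (std_intensity == 0.0)
    if missing.any():
        bad = species_rows.iloc[int(np.argmax(missing))]
        raise NormalizationError(
            "standard intensity missing or zero for sample "
            f"{bad['sample_id']!r}, replicate {bad['tech_replicate']}, "
            f"class {bad['lipid_class']}"
        )
    species_rows["ratio"] = species_rows["intensity"].to_numpy() / std_intensity
    return species_rows[
        ["sample_id", "group", "bio_replicate", "tech_replicate",
         "species", "lipid_class", "ratio"]
    ].reset_index(drop=True)


def aggregate_technical(ratios: pd.DataFrame,
                        expected_replicates: int = 3,
                        drop_missing: bool = False) -> NormalizedProfile:
    """Average technical replicates to one ratio per biological sample.

    Logs a warning whenever fewer than ``expected_replicates`` replicates
    contribute to a cell.  A (sample, species) pair with zero replicates
    raises :class:`MissingDataError` unless ``drop_missing`` is set.
    """
    if ratios.empty:
        raise MissingDataError("no ratio records to aggregate")
    grouped = ratios.groupby(["species", "sample_id"])["ratio"]
    values = grouped.mean().unstack("sample_id")
    counts = grouped.size().unstack("sample_id")

    n_missing = int(values.isna().sum().sum())
    if n_missing and not drop_missing:
        cell = values.stack(future_stack=True)
        cell = cell[cell.isna()].index[0]
        raise MissingDataError(
            f"no replicates for species {cell[0]!r} in sample {cell[1]!r} "
            f"({n_missing} empty cells total)"
        )
    counts = counts.fillna(0).astype(int)
    short = int((counts.to_numpy() < expected_replicates).sum())
    if short:
        logger.warning(
            "%d (sample, species) cells averaged fewer than %d technical "
            "replicates", short, expected_replicates)

    sample_groups = (
        ratios.drop_duplicates("sample_id")
        .set_index("sample_id")["group"].to_dict()
    )
    classes = {
        s: parse_species(s).lipid_class for s in values.index
    }
    # Stable ordering: species in first-appearance order, samples sorted.
    species_order = list(dict.fromkeys(ratios["species"]))
    sample_order = sorted(values.columns)
    values = values.loc[species_order, sample_order]
    counts = counts.loc[species_order, sample_order]
    return NormalizedProfile(values, sample_groups, counts, classes)


@dataclass
class MatrixEffectReport:
    """Percent change of mean standard intensity between groups.

    ``per_standard`` holds the signed change for each internal standard,
    ``(mean_b / mean_a - 1) * 100``; ``mean_abs_change`` is the
    arithmetic mean of the absolute per-standard changes.
    """

    per_standard: dict[str, float]
    mean_abs_change: float
    group_a: str
    group_b: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"standard": list(self.per_standard),
             "percent_change": list(self.per_standard.values())}
        )


def matrix_effect(records: pd.DataFrame, group_a: str,
                  group_b: str) -> MatrixEffectReport:
    """Quantify group-wise suppression/enhancement of the spiked standards."""
    std = records[records["role"] == "standard"]
    per_standard: dict[str, float] = {}
    for name, sub in std.groupby("analyte", sort=True):
        mean_a = sub.loc[sub["group"] == group_a, "intensity"].mean()
        mean_b = sub.loc[sub["group"] == group_b, "intensity"].mean()
        if np.isnan(mean_a) or np.isnan(mean_b):
            raise MissingDataError(
                f"standard {name!r} has no records in one of the groups "
                f"({group_a!r}, {group_b!r})"
            )
        per_standard[str(name)] = (mean_b / mean_a - 1.0) * 100.0
    if not per_standard:
        raise MissingDataError("no standard records present")
    mean_abs = float(np.mean([abs(v) for v in per_standard.values()]))
    return MatrixEffectReport(per_standard, mean_abs, group_a, group_b)
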