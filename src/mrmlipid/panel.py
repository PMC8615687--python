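"""The default 240-species analyte panel and panel file I/O.

The panel mirrors the class sizes of a targeted brain/neuroblastoma MRM
assay: 43 diacyl PC, 39 PC plasmalogens, 22 lyso-PC, 41 carnitines, 14
TAG, 35 diacyl PE, 37 PE plasmalogens and 9 lyso-PE species.  A small set
of species that the assay is known to contain (e.g. PC aa C48:0,
PC ae C42:0, C0, C2, C03 OH, C16:0, C18:0, C18:1) is placed explicitly;
the remainder is filled deterministically from plausible sum-composition
grids, so the panel is identical on every call.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .species import LipidClass, LipidSpecies, parse_species

__all__ = ["PANEL_CLASS_COUNTS", "default_panel", "read_panel", "write_panel"]

PANEL_CLASS_COUNTS: dict[LipidClass, int] = {
    LipidClass.PC_AA: 43,
    LipidClass.PC_AE: 39,
    LipidClass.LPC: 22,
    LipidClass.CAR: 41,
    LipidClass.TAG: 14,
    LipidClass.PE_AA: 35,
    LipidClass.PE_AE: 37,
    LipidClass.LPE: 9,
}


def _fill(cls: LipidClass, required, candidates, count) -> list[LipidSpecies]:
    """Required species first, then candidates in order, up to ``count``.

    Entries are (carbons, double_bonds) or (carbons, double_bonds, oh).
    """
    out: list[LipidSpecies] = []
    seen: set[tuple] = set()
    for entry in list(required) + list(candidates):
        carbons, db = entry[0], entry[1]
        oh = bool(entry[2]) if len(entry) > 2 else False
        key = (carbons, db, oh)
        if key in seen:
            continue
        seen.add(key)
        out.append(LipidSpecies(cls, carbons, db, oh))
        if len(out) == count:
            return out
    raise AssertionError(f"candidate grid too small for {cls.value}")


def _glycero(required: list[tuple[int, int]], count: int,
             cls: LipidClass) -> list[LipidSpecies]:
    grid = [(c, d) for c in range(30, 49, 2) for d in range(0, 7)]
    return _fill(cls, required, grid, count)


def default_panel() -> list[LipidSpecies]:
    """The fixed 240-species panel (deterministic, no randomness)."""
    panel: list[LipidSpecies] = []
    panel += _glycero(
        [(32, 1), (34, 1), (34, 2), (34, 3), (42, 0), (42, 1), (48, 0)],
        43, LipidClass.PC_AA)
    panel += _glycero([(42, 0), (38, 4)], 39, LipidClass.PC_AE)
    panel += _fill(
        LipidClass.LPC,
        [(16, 0), (18, 0), (18, 1), (18, 2)],
        [(c, d) for c in range(14, 23) for d in range(0, 3)],
        22)
    # Carnitines: free (C0), acetyl (C2), then saturated, monounsaturated
    # and hydroxylated acyl chains.
    car_candidates = (
        [(c, 0, False) for c in range(3, 19)]
        + [(c, 1, False) for c in range(10, 19)]
        + [(c, 0, True) for c in range(3, 19)]
        + [(c, 2, False) for c in range(12, 19)]
    )
    panel += _fill(
        LipidClass.CAR,
        [(0, 0, False), (2, 0, False), (3, 0, False), (3, 0, True),
         (16, 0, False), (18, 0, False), (18, 1, False)],
        car_candidates, 41)
    panel += _fill(
        LipidClass.TAG, [],
        [(c, d) for c in range(44, 57, 2) for d in (0, 1)],
        14)
    panel += _glycero([(40, 0)], 35, LipidClass.PE_AA)
    panel += _glycero([(44, 6), (38, 4)], 37, LipidClass.PE_AE)
    panel += _fill(
        LipidClass.LPE, [(18, 0), (18, 1)],
        [(c, d) for c in range(16, 23) for d in range(0, 2)],
        9)
    assert len(panel) == sum(PANEL_CLASS_COUNTS.values())
    return panel


def read_panel(path: str | Path) -> list[LipidSpecies]:
    """Read a panel CSV with columns ``name,lipid_class``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["name", "lipid_class"]:
        raise SchemaError(
            f"panel file {path} must have header name,lipid_class, "
            f"got {list(df.columns)}"
        )
    out = []
    for name, cls in zip(df["name"], df["lipid_class"]):
        spec = parse_species(str(name))
        if spec.lipid_class.value != cls:
            raise SchemaError(
                f"panel row {name!r} declares class {cls} but parses as "
                f"{spec.lipid_class.value}"
            )
        out.append(spec)
    return out


def write_panel(panel: list[LipidSpecies], path: str | Path) -> None:
    pd.DataFrame(
        {"name": [s.canonical_name for s in panel],
         "lipid_class": [s.lipid_class.value for s in panel]}
    ).to_csv(path, index=False)
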