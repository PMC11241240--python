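"""BW-indexed interaction profiles and labeled feature tables.

Five items are extracted per indexed residue position: the energy sum over
all its contacts, and the type/energy of the two most favorable contacts.
The NA/None/0 distinction is load-bearing:

* position absent from the receptor      -> numeric NaN, categorical 'NA'
* position present but with no contacts  -> numeric 0,   categorical 'None'
* single contact                         -> type2 'None', energy2 0
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bw import BWPosition, parse_bw
from .complex_io import LigandReceptorComplex
from .interactions import Contact, type_priority

__all__ = [
    "PositionFeatures",
    "InteractionProfile",
    "FeatureTable",
    "extract_profile",
    "retained_positions",
    "assemble_table",
    "summarize_by_class",
    "feature_columns",
    "table_to_frame",
    "frame_to_table",
]

NA_TYPE = "NA"
NONE_TYPE = "None"
FIELD_SUFFIXES = ("sum", "type1", "e1", "type2", "e2")


@dataclass(frozen=True)
class PositionFeatures:
    energy_sum: float  # NaN when position absent
    type1: str
    energy1: float
    type2: str
    energy2: float

    @classmethod
    def absent(cls) -> "PositionFeatures":
        return cls(math.nan, NA_TYPE, math.nan, NA_TYPE, math.nan)

    @classmethod
    def empty(cls) -> "PositionFeatures":
        return cls(0.0, NONE_TYPE, 0.0, NONE_TYPE, 0.0)

    @property
    def is_na(self) -> bool:
        return self.type1 == NA_TYPE


@dataclass
class InteractionProfile:
    complex_id: str
    features: dict[BWPosition, PositionFeatures]
    is_modeled: int = 0
    function_label: str = "unlabeled"

    def at(self, pos: BWPosition) -> PositionFeatures:
        return self.features.get(pos, PositionFeatures.absent())


@dataclass
class FeatureTable:
    rows: list[InteractionProfile]
    retained_positions: list[BWPosition] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [p.function_label for p in self.rows]


def _contact_rank_key(c: Contact) -> tuple:
    # most negative energy first; ties by type priority, then names
    return (c.energy, type_priority(c.interaction_type), c.residue_atom, c.ligand_atom)


def extract_profile(
    cplx: LigandReceptorComplex,
    contacts: list[Contact],
    registry: list[BWPosition] | None = None,
) -> InteractionProfile:
    """Fold a contact list into per-position features.

    ``registry`` fixes which positions appear in the profile; positions the
    receptor lacks become NA entries. By default the profile covers exactly
    the complex's own annotated positions.
    """
    present = cplx.bw_positions()
    unknown = {c.bw_position for c in contacts} - present
    if unknown:
        raise ValueError(
            f"contacts reference positions absent from the complex: {sorted(map(str, unknown))}"
        )
    positions = registry if registry is not None else sorted(present)

    by_pos: dict[BWPosition, list[Contact]] = {}
    for c in contacts:
        by_pos.setdefault(c.bw_position, []).append(c)

    features: dict[BWPosition, PositionFeatures] = {}
    for pos in positions:
        if pos not in present:
            features[pos] = PositionFeatures.absent()
            continue
        here = sorted(by_pos.get(pos, []), key=_contact_rank_key)
        if not here:
            features[pos] = PositionFeatures.empty()
            continue
        first = here[0]
        if len(here) >= 2:
            second_type, second_energy = here[1].interaction_type, here[1].energy
        else:
            second_type, second_energy = NONE_TYPE, 0.0
        features[pos] = PositionFeatures(
            energy_sum=sum(c.energy for c in here),
            type1=first.interaction_type,
            energy1=first.energy,
            type2=second_type,
            energy2=second_energy,
        )
    return InteractionProfile(
        complex_id=cplx.complex_id,
        features=features,
        is_modeled=cplx.is_modeled,
        function_label=cplx.function_label,
    )


def retained_positions(
    profiles: list[InteractionProfile],
    min_count: int = 10,
    strict: bool = True,
) -> list[BWPosition]:
    """Positions where enough complexes have a non-NA, nonzero energy sum.

    ``strict=True`` requires the interacting count to *exceed* ``min_count``
    (the default rule); ``strict=False`` accepts counts >= ``min_count``.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    all_positions: set[BWPosition] = set()
    for p in profiles:
        all_positions |= set(p.features)
    kept = []
    for pos in all_positions:
        n = sum(
            1
            for p in profiles
            if not math.isnan(p.at(pos).energy_sum) and p.at(pos).energy_sum != 0
        )
        if n > min_count if strict else n >= min_count:
            kept.append(pos)
    return sorted(kept)


def feature_columns(positions: list[BWPosition]) -> list[str]:
    """Deterministic layout: 5 columns per position, then is_modeled."""
    cols = [f"{pos}_{suffix}" for pos in positions for suffix in FIELD_SUFFIXES]
    return cols + ["is_modeled"]


def assemble_table(
    profiles: list[InteractionProfile],
    positions: list[BWPosition],
) -> FeatureTable:
    """Project profiles onto a retained-position list (missing -> NA)."""
    return FeatureTable(rows=list(profiles), retained_positions=sorted(positions))


def table_to_frame(table: FeatureTable) -> pd.DataFrame:
    """Feature table as a DataFrame: id/label/is_modeled + 5 cols per position."""
    records = []
    for prof in table.rows:
        rec: dict[str, object] = {
            "complex_id": prof.complex_id,
            "label": prof.function_label,
            "is_modeled": prof.is_modeled,
        }
        for pos in table.retained_positions:
            f = prof.at(pos)
            rec[f"{pos}_sum"] = f.energy_sum
            rec[f"{pos}_type1"] = f.type1
            rec[f"{pos}_e1"] = f.energy1
            rec[f"{pos}_type2"] = f.type2
            rec[f"{pos}_e2"] = f.energy2
        records.append(rec)
    columns = ["complex_id", "label", "is_modeled"] + [
        f"{pos}_{suffix}"
        for pos in table.retained_positions
        for suffix in FIELD_SUFFIXES
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def write_feature_csv(frame: pd.DataFrame, path) -> None:
    """Write features with NA as empty cells (numeric) / literal 'NA' (text)."""
    frame.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature CSV preserving the 'NA'/'None' categorical strings.

    Only empty cells become NaN, so the NA-vs-0 distinction survives a
    write/read round trip bit-exactly.
    """
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def frame_to_table(frame: pd.DataFrame) -> FeatureTable:
    """Inverse of :func:`table_to_frame` (NA cells round-trip exactly)."""
    pos_names: list[str] = []
    for col in frame.columns:
        if col.endswith("_sum"):
            pos_names.append(col[: -len("_sum")])
    positions = [parse_bw(name) for name in pos_names]
    rows = []
    for _, row in frame.iterrows():
        features = {}
        for name, pos in zip(pos_names, positions):
            features[pos] = PositionFeatures(
                energy_sum=float(row[f"{name}_sum"]),
                type1=str(row[f"{name}_type1"]),
                energy1=float(row[f"{name}_e1"]),
                type2=str(row[f"{name}_type2"]),
                energy2=float(row[f"{name}_e2"]),
            )
        rows.append(
            InteractionProfile(
                complex_id=str(row["complex_id"]),
                features=features,
                is_modeled=int(row["is_modeled"]),
                function_label=str(row["label"]),
            )
        )
    return FeatureTable(rows=rows, retained_positions=sorted(positions))


def summarize_by_class(table: FeatureTable) -> pd.DataFrame:
    """Per-position, per-class mean energy sums and interaction percentages.

    Means exclude NA entries; percentages are over complexes that possess
    the position. Per-type percentages count complexes whose top-2 types at
    the position include the type. Classes with zero rows yield NA rows.
    """
    frame = table_to_frame(table)
    classes = sorted(set(frame["label"]))
    types_seen = set()
    for pos in table.retained_positions:
        for suffix in ("type1", "type2"):
            types_seen |= set(frame[f"{pos}_{suffix}"].unique())
    types_seen -= {NA_TYPE, NONE_TYPE}

    records = []
    for pos in table.retained_positions:
        sums = frame[f"{pos}_sum"]
        possessed = sums.notna()
        if not possessed.any():
            continue  # all-NA position carries no summary information
        for cls in classes:
            in_cls = (frame["label"] == cls) & possessed
            n = int(in_cls.sum())
            rec = {"bw_position": str(pos), "label": cls, "n_possessing": n}
            if n == 0:
                rec["mean_energy_sum"] = math.nan
                rec["interaction_pct"] = math.nan
                warnings.warn(
                    f"class {cls!r} has no complexes possessing {pos}", stacklevel=2
                )
            else:
                rec["mean_energy_sum"] = float(sums[in_cls].mean())
                rec["interaction_pct"] = 100.0 * float(
                    (sums[in_cls] != 0).sum()
                ) / n
            for t in sorted(types_seen):
                if n == 0:
                    rec[f"pct_{t}"] = math.nan
                else:
                    has_type = (
                        (frame.loc[in_cls, f"{pos}_type1"] == t)
                        | (frame.loc[in_cls, f"{pos}_type2"] == t)
                    )
                    rec[f"pct_{t}"] = 100.0 * float(has_type.sum()) / n
            records.append(rec)
    return pd.DataFrame.from_records(records)
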