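"""Phenotype records and contemporary-group formation.

A :class:`RecordSet` wraps a pandas DataFrame with one row per recorded
animal: identification, the environmental factors (farm, birth year, sex,
collection year YC, age class AC, animal category CAT) and the trait
observations — ordinal scores coded 1..K or continuous measurements.
Contemporary groups (CG) are formed from animals born on the same farm, in
the same year and of the same sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RecordSet", "make_contemporary_groups", "read_records", "write_records"]

#: columns every record file must carry besides traits
BASE_COLUMNS = ["animal", "farm", "birth_year", "sex", "yc", "ac", "cat"]


@dataclass
class RecordSet:
    """Records plus trait typing metadata.

    Parameters
    ----------
    data : DataFrame with the :data:`BASE_COLUMNS` and one column per trait.
    ordinal_traits : mapping trait name -> number of categories K; every
        non-missing value of such a trait must lie in 1..K.
    """

    data: pd.DataFrame
    ordinal_traits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"record table lacks columns: {missing}")
        if self.data["animal"].duplicated().any():
            dup = self.data.loc[self.data["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(
                f"animal {dup!r} has more than one record; each trait is "
                "measured once per animal"
            )
        for trait, k in self.ordinal_traits.items():
            vals = self.data[trait].dropna()
            ok = vals.isin(range(1, int(k) + 1))
            if not ok.all():
                bad = vals[~ok].iloc[0]
                raise ValueError(f"ordinal trait {trait!r} has code {bad} outside 1..{k}")

    @property
    def traits(self) -> list:
        return [c for c in self.data.columns if c not in BASE_COLUMNS and c != "cg"]

    @property
    def n_records(self) -> int:
        return len(self.data)

    def validate_against(self, ped) -> None:
        """Check that every recorded animal exists in the pedigree."""
        idx = ped.index_of
        unknown = [a for a in self.data["animal"] if a not in idx]
        if unknown:
            raise ValueError(f"recorded animals absent from pedigree: {unknown[:5]}")


def make_contemporary_groups(records: RecordSet) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign contemporary groups: one level per (farm, birth_year, sex).

    Returns the per-record 0-based level index and a level table, and stores
    the label in a ``cg`` column on the record data.
    """
    df = records.data
    bad = df[["farm", "birth_year", "sex"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            "missing farm/birth_year/sex in rows: " f"{list(df.index[bad][:10])}"
        )
    keys = list(zip(df["farm"], df["birth_year"], df["sex"]))
    codes, levels = pd.factorize(pd.Series(keys), sort=True)
    table = pd.DataFrame(
        [lv for lv in levels], columns=["farm", "birth_year", "sex"]
    )
    df["cg"] = codes
    return codes, table


def read_records(path, ordinal_traits: dict | None = None) -> RecordSet:
    """Read a CSV record file with a named header; empty/NA fields = missing."""
    df = pd.read_csv(path, na_values=["NA", ""])
    return RecordSet(df, ordinal_traits=dict(ordinal_traits or {}))


def write_records(records: RecordSet, path) -> None:
    cols = [c for c in records.data.columns if c != "cg"]
    records.data[cols].to_csv(path, index=False, na_rep="NA")
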