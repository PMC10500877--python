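"""Pedigree container shared by the gene-drop simulator and the breeding generator.

A pedigree is a table of (id, sire, dam, birth_month, population, generation)
rows. Founders have generation 0 and unknown parents; every non-founder's
parents must appear earlier in topological order (enforced at construction).
Unknown parents are encoded as the empty string / NaN / "0".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN = ""

_COLUMNS = ["id", "sire", "dam", "birth_month", "population", "generation"]


def _normalize_parent(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value)
    return UNKNOWN if s in ("", "0", "nan", "None") else s


class Pedigree:
    """Acyclic parent-offspring table with birth dates and population labels."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["id"] = df["id"].astype(str)
        df["sire"] = df["sire"].map(_normalize_parent)
        df["dam"] = df["dam"].map(_normalize_parent)
        df["generation"] = df["generation"].astype(int)
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        ids = self.df["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate pedigree id: {dup}")
        gen = dict(zip(ids, self.df["generation"]))
        for col in ("sire", "dam"):
            for child, parent, g in zip(ids, self.df[col], self.df["generation"]):
                if parent == UNKNOWN:
                    continue
                if parent == child:
                    raise ValueError(f"individual {child} is its own {col}")
                if parent in gen and gen[parent] >= g:
                    raise ValueError(
                        f"{col} {parent} of {child} does not precede it "
                        f"(generations {gen[parent]} >= {g})"
                    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def founders(self) -> pd.DataFrame:
        """Rows whose parents are both unknown."""
        m = (self.df["sire"] == UNKNOWN) & (self.df["dam"] == UNKNOWN)
        return self.df[m]

    def topological(self) -> pd.DataFrame:
        """Rows sorted so parents precede offspring (stable sort by generation)."""
        return self.df.sort_values("generation", kind="stable").reset_index(drop=True)

    def subset(self, ids) -> "Pedigree":
        keep = set(map(str, ids))
        return Pedigree(self.df[self.df["id"].isin(keep)], validate=False)

    # -- text round trip -----------------------------------------------------
    def to_table(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
        return cls(df)

    def __repr__(self) -> str:
        ngen = self.df["generation"].max() + 1 if len(self.df) else 0
        return f"<Pedigree: {len(self.df)} individuals, {ngen} generations>"
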