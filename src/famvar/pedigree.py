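"""Pedigree container for family cohorts.

A pedigree is a table of individuals with family, parental and couple links.
Founders carry ``"0"`` for both parental IDs; spouses in a couple share a
non-``"0"`` ``couple_id``.  This is the backbone from which the pedigree
(numerator) relationship matrix and the nuclear-family / couple / sibling
environment matrices are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PED_COLUMNS = ["fid", "iid", "father", "mother", "sex", "couple_id"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate IDs...)."""


@dataclass
class Pedigree:
    """Individuals with family / parental / couple structure.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``fid, iid, father, mother, sex, couple_id``.  ``father`` /
        ``mother`` are ``"0"`` for founders; ``couple_id`` is ``"0"`` for
        individuals not in a couple.  ``sex`` uses the PLINK coding
        (1 = male, 2 = female, 0 = unknown).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PED_COLUMNS if c not in self.df.columns]
        if missing:
            raise PedigreeError(f"pedigree missing columns: {missing}")
        self.df = self.df.reset_index(drop=True).copy()
        for col in ("fid", "iid", "father", "mother", "couple_id"):
            self.df[col] = self.df[col].astype(str)
        ids = self.df["iid"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique().tolist()
            raise PedigreeError(f"duplicate individual IDs: {dups[:5]}")
        known = set(ids)
        for col in ("father", "mother"):
            bad = set(self.df[col]) - known - {"0"}
            if bad:
                raise PedigreeError(f"unknown {col} IDs: {sorted(bad)[:5]}")
        # a child must have either two known parents or none
        one_parent = (self.df["father"] == "0") != (self.df["mother"] == "0")
        if one_parent.any():
            raise PedigreeError("individuals with exactly one known parent")
        counts = self.df.loc[self.df["couple_id"] != "0", "couple_id"].value_counts()
        if (counts != 2).any():
            bad = counts.index[counts != 2].tolist()
            raise PedigreeError(f"couple IDs without exactly two members: {bad[:5]}")

    # ------------------------------------------------------------------ views
    @property
    def ids(self) -> list[str]:
        return self.df["iid"].tolist()

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.df["father"] == "0").to_numpy()

    def index_of(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.df["iid"])}

    # ------------------------------------------------------------- structure
    def topological_order(self) -> np.ndarray:
        """Row indices ordered parents-before-children.

        Raises
        ------
        PedigreeError
            If the parent graph contains a cycle (an individual is its own
            ancestor).
        """
        idx = self.index_of()
        father = np.array([idx.get(f, -1) for f in self.df["father"]])
        mother = np.array([idx.get(m, -1) for m in self.df["mother"]])
        placed = np.zeros(self.n, dtype=bool)
        order: list[int] = []
        remaining = set(range(self.n))
        while remaining:
            ready = [
                i
                for i in remaining
                if (father[i] < 0 or placed[father[i]])
                and (mother[i] < 0 or placed[mother[i]])
            ]
            if not ready:
                raise PedigreeError("pedigree contains a cycle")
            for i in sorted(ready):
                placed[i] = True
                order.append(i)
            remaining -= set(ready)
        return np.asarray(order)

    def couples(self) -> list[tuple[str, str]]:
        """Spouse pairs as (iid, iid) tuples, one per couple."""
        pairs = []
        grouped = self.df.loc[self.df["couple_id"] != "0"].groupby("couple_id")
        for _, grp in grouped:
            a, b = grp["iid"].tolist()
            pairs.append((a, b))
        return pairs

    def sibships(self) -> list[list[str]]:
        """Groups of full siblings (same father and mother), size >= 2."""
        kids = self.df.loc[~self.is_founder]
        out = []
        for _, grp in kids.groupby(["father", "mother"]):
            if len(grp) >= 2:
                out.append(grp["iid"].tolist())
        return out

    def nuclear_families(self) -> list[list[str]]:
        """Nuclear-family groups: each couple with their children.

        Individuals belonging to no couple and with no parents in the
        pedigree form singleton groups.
        """
        couple_of: dict[str, str] = {}
        for a, b in self.couples():
            couple_of[a] = a + "|" + b
            couple_of[b] = a + "|" + b
        groups: dict[str, list[str]] = {}
        singles: list[list[str]] = []
        for _, row in self.df.iterrows():
            if row["iid"] in couple_of:
                key = couple_of[row["iid"]]
            elif row["father"] != "0":
                key = row["father"] + "|" + row["mother"]
            else:
                singles.append([row["iid"]])
                continue
            groups.setdefault(key, []).append(row["iid"])
        return list(groups.values()) + singles

    def n_couple_pairs(self) -> int:
        return len(self.couples())

    def n_fullsib_pairs(self) -> int:
        return sum(len(s) * (len(s) - 1) // 2 for s in self.sibships())

    def n_nuclear_families(self, min_size: int = 2) -> int:
        return sum(1 for g in self.nuclear_families() if len(g) >= min_size)
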