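"""Long-format panel container for directed dyadic observations.

A :class:`PanelDataset` holds one record per (family, actor role, partner
role, snapshot).  Missing responses stay in the table as rows with
``observed = False`` so that each directed dyad's snapshot index always runs
consecutively from 1 to its duration.  Estimation requires the
*both-or-neither* rule: at any snapshot, either both directed responses of an
undirected dyad are observed or both are treated as missing;
:func:`apply_pair_deletion` enforces it the way observational studies of
dyadic interaction report it (flagging the surviving member of a broken pair
as missing and counting the extra deletions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .roles import ROLES, DirectedDyad, UndirectedDyad, check_composition

COLUMNS = ["family_id", "actor", "partner", "snapshot", "y", "observed"]


@dataclass
class PanelDataset:
    """Directed dyadic panel records plus response metadata.

    Parameters
    ----------
    df : DataFrame with columns family_id, actor, partner, snapshot, y, observed.
    response_kind : "continuous" or "ordinal".
    n_categories : number of ordinal categories C (ordinal only).
    category_labels : optional mapping from internal codes 1..C to the
        original instrument labels (kept when relabelling a non-contiguous
        scale onto 1..C).
    """

    df: pd.DataFrame
    response_kind: str = "continuous"
    n_categories: int | None = None
    category_labels: dict[int, object] | None = None

    def __post_init__(self) -> None:
        df = self.df.loc[:, COLUMNS].copy()
        df["family_id"] = df["family_id"].astype(str)
        df["snapshot"] = df["snapshot"].astype(int)
        df["observed"] = df["observed"].astype(bool)
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
        df = df.sort_values(["family_id", "actor", "partner", "snapshot"], kind="stable")
        self.df = df.reset_index(drop=True)

    # -- structure --------------------------------------------------------
    @property
    def n_families(self) -> int:
        return self.df["family_id"].nunique()

    @property
    def families(self) -> list[str]:
        return sorted(self.df["family_id"].unique())

    def composition(self, family_id: str) -> tuple[str, ...]:
        sub = self.df[self.df["family_id"] == str(family_id)]
        return check_composition(set(sub["actor"]) | set(sub["partner"]))

    def durations(self) -> pd.Series:
        """Snapshot count per (family_id, actor, partner)."""
        return self.df.groupby(["family_id", "actor", "partner"])["snapshot"].max()

    def validate(self) -> None:
        """Raise ValueError on any structural violation."""
        df = self.df
        bad_roles = set(df["actor"]) | set(df["partner"])
        if not bad_roles <= set(ROLES):
            raise ValueError(f"unknown role codes: {sorted(bad_roles - set(ROLES))}")
        if (df["actor"] == df["partner"]).any():
            raise ValueError("records with actor == partner")
        key = ["family_id", "actor", "partner", "snapshot"]
        dup = df.duplicated(key)
        if dup.any():
            raise ValueError(f"duplicate (family, actor, partner, snapshot) keys, e.g. rows {list(df.index[dup][:3])}")
        if (df["snapshot"] < 1).any():
            raise ValueError("snapshot indices must be >= 1")
        for (fam, a, p), g in df.groupby(["family_id", "actor", "partner"]):
            t = np.sort(g["snapshot"].to_numpy())
            if not np.array_equal(t, np.arange(1, len(t) + 1)):
                raise ValueError(
                    f"snapshots for dyad {a}->{p} in family {fam} are not consecutive from 1"
                )
        if df.loc[df["observed"], "y"].isna().any():
            raise ValueError("observed records with missing y")
        for fam in self.families:
            self.composition(fam)
        if self.response_kind == "ordinal":
            if not self.n_categories or self.n_categories < 2:
                raise ValueError("ordinal data requires n_categories >= 2")
            y = df.loc[df["observed"], "y"]
            if not ((y >= 1) & (y <= self.n_categories) & (y == y.round())).all():
                raise ValueError(f"ordinal responses must be integers in 1..{self.n_categories}")

    def satisfies_pair_rule(self) -> bool:
        return _broken_pairs(self.df).sum() == 0

    def observed_fraction(self) -> float:
        return float(self.df["observed"].mean())

    def copy(self) -> "PanelDataset":
        return replace(self, df=self.df.copy())


def _broken_pairs(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of records observed while their partner record is not."""
    key = ["family_id", "actor", "partner", "snapshot"]
    mirror = df[key + ["observed"]].rename(
        columns={"actor": "partner", "partner": "actor", "observed": "partner_observed"}
    )
    merged = df[key + ["observed"]].merge(mirror, on=key, how="left")
    partner_obs = merged["partner_observed"].fillna(False).to_numpy(bool)
    return df["observed"].to_numpy(bool) & ~partner_obs


def apply_pair_deletion(data: PanelDataset) -> tuple[PanelDataset, int]:
    """Enforce the both-or-neither rule.

    Any record whose within-dyad partner record at the same snapshot is
    missing (or absent from the table) is flagged missing.  Returns the
    cleaned dataset and the number of newly flagged records.  Idempotent.
    """
    out = data.copy()
    broken = _broken_pairs(out.df)
    n_extra = int(broken.sum())
    if n_extra:
        out.df.loc[broken, "observed"] = False
        out.df.loc[broken, "y"] = np.nan
    return out, n_extra


def relabel_categories(data: PanelDataset) -> PanelDataset:
    """Map observed ordinal labels onto contiguous internal codes 1..C.

    Thresholds are defined per gap between adjacent *used* categories, so
    unused labels (e.g. a never-observed bottom category of an instrument)
    are dropped from the coding; the original labels are kept in
    ``category_labels``.
    """
    if data.response_kind != "ordinal":
        raise ValueError("relabelling applies to ordinal data only")
    out = data.copy()
    obs = out.df["observed"]
    used = np.sort(out.df.loc[obs, "y"].dropna().unique())
    mapping = {old: new for new, old in enumerate(used, start=1)}
    out.df.loc[obs, "y"] = out.df.loc[obs, "y"].map(mapping)
    out.n_categories = len(used)
    out.category_labels = {new: old for old, new in mapping.items()}
    return out
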