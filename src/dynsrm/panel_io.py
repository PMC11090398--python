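"""Panel CSV reading/writing.

Schema: header row with columns ``family_id, actor, partner, snapshot, y,
observed``; role codes in {M, F, S1, S2}; ``snapshot`` an integer >= 1;
``y`` empty for unobserved records; ``observed`` 0/1.  The
(family_id, actor, partner, snapshot) key must be unique and snapshots
consecutive from 1 within each directed dyad.  Reading applies the
both-or-neither pair-deletion rule and logs how many records it removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import COLUMNS, PanelDataset, apply_pair_deletion

logger = logging.getLogger("dynsrm")


def read_panel_csv(
    path,
    response_kind: str = "continuous",
    n_categories: int | None = None,
    pair_deletion: bool = True,
) -> PanelDataset:
    """Parse a panel CSV into a validated PanelDataset.

    Malformed files raise ValueError naming the offending rows (2-based,
    counting the header as row 1).
    """
    df = pd.read_csv(path, dtype={"family_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COLUMNS]
    key = ["family_id", "actor", "partner", "snapshot"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"{path}: duplicate (family, actor, partner, snapshot) keys at rows {rows}")
    bad_snap = ~np.isfinite(pd.to_numeric(df["snapshot"], errors="coerce"))
    if bad_snap.any():
        rows = (df.index[bad_snap] + 2).tolist()[:5]
        raise ValueError(f"{path}: non-numeric snapshot at rows {rows}")
    ds = PanelDataset(df, response_kind=response_kind, n_categories=n_categories)
    ds.validate()
    if pair_deletion:
        ds, n_extra = apply_pair_deletion(ds)
        if n_extra:
            logger.info("%s: pair deletion flagged %d additional records missing", path, n_extra)
    return ds


def write_panel_csv(data: PanelDataset, path) -> None:
    df = data.df.copy()
    df["observed"] = df["observed"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")
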