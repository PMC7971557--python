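"""CO2-normalized breathomics: background subtraction, minute-volume
normalization, timepoint pooling, and per-species group comparison.

Exhaled volatile organic compounds are collected in canisters at 1, 5 and
10 minutes post-injection alongside room-air backgrounds.  Because a
smaller or hyperventilating animal dilutes or concentrates every species
alike, excess mixing ratios are divided by the canister's excess CO2 —
normalization for minute volume by the rate of CO2 production — before
groups are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_fdr

logger = logging.getLogger(__name__)

#: Column holding the CO2 mixing ratio (ppm); all other species are ppb.
CO2_COLUMN = "CO2"
META_COLUMNS = ("animal", "group", "timepoint", "is_background")


def species_columns(samples: pd.DataFrame) -> list[str]:
    return [c for c in samples.columns if c not in META_COLUMNS]


def background_mean(samples: pd.DataFrame) -> pd.Series:
    """Mean room-air mixing ratio per species over background rows."""
    bg = samples.loc[samples["is_background"].astype(bool)]
    if bg.empty:
        raise ValueError("no background (room air) samples present")
    return bg[species_columns(samples)].mean(axis=0)


def background_subtract(
    samples: pd.DataFrame,
    background: pd.Series | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Excess mixing ratios: animal samples minus the room-air background.

    Negative excesses are clipped to zero (physical non-negativity) with a
    logged count; pass ``clip=False`` to keep signed excess.
    """
    if background is None:
        background = background_mean(samples)
    species = species_columns(samples)
    missing = [s for s in species if s not in background.index or
               pd.isna(background[s])]
    if missing:
        raise ValueError(f"species missing from background: {missing}")
    animals = samples.loc[~samples["is_background"].astype(bool)].copy()
    excess = animals[species] - background[species]
    if clip:
        n_neg = int((excess.to_numpy() < 0).sum())
        if n_neg:
            logger.warning("clipped %d negative excess values to 0", n_neg)
        excess = excess.clip(lower=0.0)
    out = animals[list(META_COLUMNS)].copy()
    out[species] = excess
    return out


def normalize_by_co2(excess: pd.DataFrame) -> pd.DataFrame:
    """Divide each species' excess by the canister's excess CO2.

    Results are ppb per ppm CO2.  Canisters with zero excess CO2 carry no
    usable breath signal and are excluded with a warning.
    """
    if CO2_COLUMN not in excess.columns:
        raise ValueError(f"missing {CO2_COLUMN!r} column")
    co2 = excess[CO2_COLUMN].to_numpy(dtype=float)
    keep = co2 > 0
    if not keep.all():
        logger.warning("excluding %d canister(s) with zero excess CO2",
                       int((~keep).sum()))
    sub = excess.loc[keep].copy()
    species = [s for s in species_columns(excess) if s != CO2_COLUMN]
    sub[species] = sub[species].div(sub[CO2_COLUMN], axis=0)
    return sub.drop(columns=CO2_COLUMN)


def pool_and_compare(
    normalized: pd.DataFrame, group_a: str, group_b: str
) -> pd.DataFrame:
    """Pool the 1/5/10-minute canisters per animal, then compare groups.

    Each animal contributes the mean of its normalized values over the
    three timepoints; groups are compared per species by Welch's t test,
    two-sided, with Benjamini-Hochberg correction across species.
    """
    species = [s for s in species_columns(normalized) if s != CO2_COLUMN]
    per_animal = (
        normalized.groupby(["animal", "group"], sort=True)[species]
        .mean()
        .reset_index()
    )
    if per_animal[species].isna().any().any():
        bad = per_animal[species].columns[per_animal[species].isna().any()][0]
        raise ValueError(f"species {bad!r} missing for some animal")
    a = per_animal.loc[per_animal["group"] == group_a]
    b = per_animal.loc[per_animal["group"] == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 animals per group")
    rows = []
    for sp in species:
        va, vb = a[sp].to_numpy(dtype=float), b[sp].to_numpy(dtype=float)
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
            p = 1.0  # identical constant groups; Welch is 0/0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        rows.append(
            {
                "species": sp,
                f"mean_{group_a}": float(va.mean()),
                f"sd_{group_a}": float(va.std(ddof=1)),
                f"mean_{group_b}": float(vb.mean()),
                f"sd_{group_b}": float(vb.std(ddof=1)),
                "welch_p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["welch_p"].to_numpy())
    return out
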