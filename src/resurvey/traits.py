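"""Species trait tables, z-scaling, community-weighted means and tests."""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from resurvey.stats import RankTestResult, adjust_pvalues, kruskal_wallis

logger = logging.getLogger(__name__)

#: Canonical trait columns (indicator pairs for the categorical traits).
TRAIT_COLUMNS = [
    "proboscis_length",
    "body_size",
    "nest_above",
    "nest_below",
    "socio_parasitic",
    "habitat_open",
    "habitat_forest_edge",
    "STI",
    "micro_wide",
    "micro_cold",
    "macro_indiscriminate",
    "macro_alpine",
]


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    out = table[TRAIT_COLUMNS].astype(float)
    if out.isna().any().any():
        raise ValueError("trait table contains missing values")
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("trait table contains non-finite values")
    return out


def merge_complex_traits(
    table: pd.DataFrame, members: Sequence[str], label: str
) -> pd.DataFrame:
    """Replace member species rows by one row of arithmetic trait means.

    Binary traits may become fractional (e.g. 0.5 when the members differ).
    """
    for m in members:
        if m not in table.index:
            raise KeyError(f"complex member {m!r} missing from trait table")
    merged = table.loc[list(members)].mean(axis=0)
    out = table.drop(index=list(members))
    out.loc[label] = merged
    return out


def scale_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each trait column to mean 0 and unit sample SD.

    Constant columns are centered to zero (no division) with a warning.
    Idempotent on already-scaled data.
    """
    if len(table) < 2:
        raise ValueError("scaling needs at least two species")
    out = table.astype(float).copy()
    for col in out.columns:
        sd = out[col].std(ddof=1)
        centered = out[col] - out[col].mean()
        if sd == 0 or not np.isfinite(sd):
            logger.warning("scale_traits: column %s is constant", col)
            out[col] = centered
        else:
            out[col] = centered / sd
    return out


def cwm(incidence: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Community-weighted trait means per sampling unit.

    With a binary incidence matrix every present species gets equal weight,
    so each CWM is the plain mean of the trait over the species present.
    Units with no species yield an all-NaN row and a warning.
    """
    missing = [s for s in incidence.columns if s not in traits.index]
    if missing:
        raise KeyError(f"species without trait rows: {missing}")
    w = incidence.to_numpy(dtype=float)
    tvals = traits.loc[list(incidence.columns)].to_numpy(dtype=float)
    richness = w.sum(axis=1)
    empty = richness == 0
    if empty.any():
        logger.warning("cwm: %d unit(s) have no species", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (w @ tvals) / richness[:, None]
    return pd.DataFrame(vals, index=incidence.index, columns=traits.columns)


def compare_traits(
    cwm_table: pd.DataFrame,
    cluster_groups: pd.DataFrame,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Between-period Kruskal-Wallis tests of CWM values per trait x cluster.

    ``cluster_groups`` must carry ``cluster`` and ``period`` columns indexed
    by unit id.  Multiplicity is adjusted within each elevation cluster's
    family of trait tests.  Clusters missing one of the periods are skipped
    with a log entry.
    """
    rows = []
    groups = cluster_groups.loc[cwm_table.index]
    for cluster, sub in groups.groupby("cluster"):
        if sub["period"].nunique() < 2:
            logger.warning(
                "compare_traits: cluster %s has a single period; skipped",
                cluster,
            )
            continue
        family = []
        for trait in cwm_table.columns:
            vals = cwm_table.loc[sub.index, trait]
            ok = vals.notna()
            res: RankTestResult = kruskal_wallis(
                vals[ok].to_numpy(), sub.loc[ok.index[ok], "period"].to_numpy()
            )
            family.append(
                {"cluster": cluster, "trait": trait, "h": res.h,
                 "df": res.df, "p": res.p}
            )
        padj = adjust_pvalues([r["p"] for r in family], method=adjust)
        for r, pa in zip(family, padj):
            r["p_adjusted"] = float(pa)
        rows.extend(family)
    return pd.DataFrame(rows)
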