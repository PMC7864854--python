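"""Cell counts, unknown-parity redistribution and cohort fertility rates.

The cohort fertility rate (CFR) of a cell — a (country, region, education)
group of women observed at the end of the reproductive lifespan — is the
mean total number of children per woman, B/N, where N counts women with
known parity and B sums their parities.  (N, B) are the sufficient
statistics for everything downstream, including the Poisson-Gamma smoother.

Census- and survey-based sources contain small numbers of women with
unknown parity; these are redistributed by assigning them the mean parity
of a reference group before rates are computed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import EDUCATIONS

logger = logging.getLogger("fertgrad")

CELL_COLUMNS = [
    "country_id",
    "region_id",
    "education",
    "n_women",
    "total_children",
    "n_unknown",
]


def aggregate(microdata: pd.DataFrame) -> pd.DataFrame:
    """Collapse woman-level records to per-cell sufficient statistics.

    One row per observed (country, region, education) cell with N = women
    with known parity, B = total children of those women, and the count of
    unknown-parity women.  Cells with no records are absent.
    """
    if len(microdata) == 0:
        return pd.DataFrame(columns=CELL_COLUMNS).astype(
            {"n_women": int, "total_children": int, "n_unknown": int}
        )
    parity = microdata["parity"]
    if (parity.dropna() < 0).any():
        raise ValueError("negative parity in microdata")
    df = microdata.assign(
        _known=parity.notna().astype(int),
        _children=parity.fillna(0).astype(int) * parity.notna().astype(int),
        _unknown=parity.isna().astype(int),
    )
    cells = (
        df.groupby(["country_id", "region_id", "education"], sort=True, observed=True)
        .agg(
            n_women=("_known", "sum"),
            total_children=("_children", "sum"),
            n_unknown=("_unknown", "sum"),
        )
        .reset_index()
    )
    return cells[CELL_COLUMNS]


def redistribute_unknown(
    cells: pd.DataFrame, level: str = "country_education"
) -> pd.DataFrame:
    """Assign unknown-parity women the mean parity of a reference group.

    ``level='country_education'`` (default) pools the same education over all
    regions of the country; ``level='cell'`` uses the cell itself.  Each cell
    gains B += round(n_unknown * mean_ref) and N += n_unknown; total woman
    counts are conserved.  A reference group with no known-parity women
    contributes mean 0 (logged).
    """
    if level not in ("cell", "country_education"):
        raise ValueError("level must be 'cell' or 'country_education'")
    out = cells.copy()
    if len(out) == 0 or (out["n_unknown"] == 0).all():
        out["n_unknown"] = 0
        return out

    if level == "cell":
        ref_n = out["n_women"].to_numpy(dtype=float)
        ref_b = out["total_children"].to_numpy(dtype=float)
    else:
        grp = out.groupby(["country_id", "education"], observed=True)
        ref_n = grp["n_women"].transform("sum").to_numpy(dtype=float)
        ref_b = grp["total_children"].transform("sum").to_numpy(dtype=float)

    mean_ref = np.zeros(len(out))
    ok = ref_n > 0
    mean_ref[ok] = ref_b[ok] / ref_n[ok]
    bad = (~ok) & (out["n_unknown"].to_numpy() > 0)
    if bad.any():
        logger.warning(
            "%d cell(s) have unknown-parity women but an empty reference "
            "group; assigning parity 0",
            int(bad.sum()),
        )
    out["total_children"] = (
        out["total_children"] + np.rint(out["n_unknown"] * mean_ref).astype(int)
    )
    out["n_women"] = out["n_women"] + out["n_unknown"]
    out["n_unknown"] = 0
    return out


def raw_cfr(n_women: int, total_children: int) -> Optional[float]:
    """B/N for one cell, or None when the cell has no known-parity women."""
    if n_women < 0 or total_children < 0:
        raise ValueError("cell counts must be non-negative")
    if n_women == 0:
        return None
    return total_children / n_women


def raw_cfr_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Raw (unsmoothed) CFR estimates, one row per cell with N > 0.

    Cells with N = 0 carry no rate information and are omitted; the EB
    smoother handles them instead.  Requires unknowns to be redistributed.
    """
    if (cells["n_unknown"] != 0).any():
        raise ValueError("redistribute unknown parity before computing rates")
    est = cells[cells["n_women"] > 0].copy()
    n_dropped = len(cells) - len(est)
    if n_dropped:
        logger.info("raw_cfr_table: %d empty cell(s) omitted", n_dropped)
    est["cfr"] = est["total_children"] / est["n_women"]
    est["method"] = "raw"
    est["ci_low"] = np.nan
    est["ci_high"] = np.nan
    return est[
        ["country_id", "region_id", "education", "cfr", "method", "ci_low", "ci_high"]
    ].reset_index(drop=True)


def _deltas(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["delta_high_medium"] = df["cfr_high"] - df["cfr_medium"]
    df["delta_medium_low"] = df["cfr_medium"] - df["cfr_low"]
    df["delta_high_low"] = df["cfr_high"] - df["cfr_low"]
    return df


SUMMARY_COLUMNS = [
    "cfr_high",
    "cfr_medium",
    "cfr_low",
    "cfr_total",
    "delta_high_medium",
    "delta_medium_low",
    "delta_high_low",
]


def country_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Country-level CFR by education with gradients and a Mean row.

    Country CFRs pool women over the country's regions (B summed / N summed
    — the rate of the national population, not a mean of regional rates);
    ``cfr_total`` pools all education groups.  Deltas are differences of the
    unrounded CFRs; rounding to the 2 decimals of display happens only when
    the table is written out.  The ``Mean`` row holds unweighted arithmetic
    column means across countries.  A country missing an education group
    gets NaN for that CFR and the affected deltas.
    """
    if len(cells) == 0:
        raise ValueError("country_summary requires at least one cell")
    if (cells["n_unknown"] != 0).any():
        raise ValueError("redistribute unknown parity before summarising")
    by_edu = (
        cells.groupby(["country_id", "education"], observed=True)[
            ["n_women", "total_children"]
        ]
        .sum()
        .reset_index()
    )
    by_edu = by_edu[by_edu["n_women"] > 0]
    by_edu["cfr"] = by_edu["total_children"] / by_edu["n_women"]
    wide = by_edu.pivot(index="country_id", columns="education", values="cfr")
    for e in EDUCATIONS:
        if e not in wide.columns:
            wide[e] = np.nan
    wide = wide.rename(columns={e: f"cfr_{e}" for e in EDUCATIONS})

    total = cells.groupby("country_id", observed=True)[
        ["n_women", "total_children"]
    ].sum()
    wide["cfr_total"] = total["total_children"] / total["n_women"]
    wide = _deltas(wide)[SUMMARY_COLUMNS]
    wide.index.name = "country"
    return append_mean_row(wide)


def append_mean_row(table: pd.DataFrame) -> pd.DataFrame:
    """Append an unweighted column-mean row labelled ``Mean``."""
    table = table.loc[table.index != "Mean"]
    mean_row = table.mean(axis=0, skipna=True)
    out = pd.concat([table, mean_row.to_frame("Mean").T])
    out.index.name = table.index.name or "country"
    return out


def summarize_country_table(table: pd.DataFrame) -> pd.DataFrame:
    """Re-derive deltas and the Mean row from a country-level CFR table.

    Accepts a table indexed by country with at least the four CFR columns
    (as in the packaged reference table); any delta columns present are kept
    as given — printed gradients are authoritative because they were formed
    from higher-precision rates before rounding — while missing delta
    columns are derived from the CFR columns.  The Mean row is always
    recomputed as the unweighted column mean over countries.
    """
    body = table.loc[table.index != "Mean"].copy()
    for col in ("delta_high_medium", "delta_medium_low", "delta_high_low"):
        if col not in body.columns:
            body = _deltas(body)
            break
    cols = [c for c in SUMMARY_COLUMNS if c in body.columns]
    return append_mean_row(body[cols])


def round_for_display(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display rounding, applied only at output time."""
    return table.round(decimals)
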