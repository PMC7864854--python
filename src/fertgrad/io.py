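"""CSV readers/writers and the packaged country reference table.

All tabular interchange is plain CSV with header rows; unknown parity is a
blank field in microdata files.  The packaged ``table2.csv`` holds the
published country-level CFRs by education for 15 European countries,
including the printed gradients and the printed Mean row, exactly as
printed (2 decimals); gradients in it were formed from higher-precision
rates before rounding, so they are kept as given rather than re-derived.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .cfr import CELL_COLUMNS

ESTIMATE_COLUMNS = [
    "country_id", "region_id", "education", "cfr", "method", "ci_low", "ci_high",
]


def write_microdata(micro: pd.DataFrame, path: str | Path) -> None:
    micro.to_csv(path, index=False, na_rep="")


def read_microdata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"country_id": str, "region_id": str, "education": str}
    )
    df["parity"] = df["parity"].astype("Int64")
    return df


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    regions[["region_id", "country_id", "gdp_pc"]].to_csv(path, index=False)


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region_id": str, "country_id": str})
    # column order used internally
    return df[["region_id", "country_id", "gdp_pc"]]


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells[CELL_COLUMNS].to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"country_id": str, "region_id": str, "education": str}
    )
    df[["n_women", "total_children", "n_unknown"]] = df[
        ["n_women", "total_children", "n_unknown"]
    ].astype(int)
    return df[CELL_COLUMNS]


def write_estimates(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates[ESTIMATE_COLUMNS].to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"country_id": str, "region_id": str, "education": str}
    )


def write_summary(summary: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    summary.round(decimals).to_csv(path, index=True)


def load_reference_table(include_mean: bool = True) -> pd.DataFrame:
    """The packaged published country table (15 countries + Mean row).

    Indexed by country name; columns cfr_high/cfr_medium/cfr_low/cfr_total
    and the three printed gradient columns.  ``include_mean=False`` drops
    the printed Mean row, leaving the 15 country rows.
    """
    with resources.files("fertgrad.data").joinpath("table2.csv").open() as fh:
        table = pd.read_csv(fh, index_col="country")
    if not include_mean:
        table = table.loc[table.index != "Mean"]
    return table
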