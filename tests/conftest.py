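import numpy as np
import pandas as pd
import pytest

from fertgrad import SyntheticConfig


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """3 countries x 4 regions, small cohorts: fast full-pipeline runs."""
    return SyntheticConfig(
        n_countries=3,
        regions_per_country=4,
        women_per_region=500,
        seed=42,
    )


def make_regions(gdp_by_region: dict[str, float], country_of=None) -> pd.DataFrame:
    """Region table from a {region_id: gdp_pc} mapping.

    Country is the region id's prefix before 'R' unless given explicitly.
    """
    rows = []
    for rid, gdp in gdp_by_region.items():
        cid = country_of[rid] if country_of else rid.split("R")[0]
        rows.append({"region_id": rid, "country_id": cid, "gdp_pc": float(gdp)})
    return pd.DataFrame(rows, columns=["region_id", "country_id", "gdp_pc"])


def make_cells(records: list[tuple]) -> pd.DataFrame:
    """Cell table from (country, region, education, N, B[, n_unknown]) tuples."""
    rows = []
    for rec in records:
        c, r, e, n, b, *rest = rec
        rows.append(
            {
                "country_id": c,
                "region_id": r,
                "education": e,
                "n_women": int(n),
                "total_children": int(b),
                "n_unknown": int(rest[0]) if rest else 0,
            }
        )
    return pd.DataFrame(rows)
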