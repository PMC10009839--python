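import pandas as pd
import pytest

from shortcast import SimConfig, simulate_world
from shortcast.config import PARSEABLE_DIALECTS


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete world: 8 IGs over 30 months."""
    return SimConfig(
        n_igs=8,
        dins_per_ig=(2, 5),
        months=("2017-01", "2019-06"),
        shortage_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate_world(small_config)


@pytest.fixture(scope="session")
def clean_config(small_config):
    """Defect-free reports with parseable pack texts (round-trip conditions)."""
    return small_config.with_(
        text_dialects=PARSEABLE_DIALECTS,
        missing_date_rate=0.0,
        inverted_date_rate=0.0,
        spurious_report_rate=0.0,
        seed=13,
    )


@pytest.fixture(scope="session")
def clean_world(clean_config):
    return simulate_world(clean_config)


def make_packs(spec: dict[str, list[tuple[str, int]]]) -> pd.DataFrame:
    """Pack table from {din: [(listing_id, size), ...]}."""
    rows = [
        {"din": din, "listing_id": lid, "pack_size": size}
        for din, listings in spec.items()
        for lid, size in listings
    ]
    return pd.DataFrame(rows)


def make_catalog(ig_to_dins: dict[str, list[str]], tc: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for ig, dins in ig_to_dins.items():
        for din in dins:
            rows.append(
                {"din": din, "ig_code": ig, "tc_code": (tc or {}).get(ig, "84:04.08.28"),
                 "strength": "40MG", "common_name": f"DRUG {din}"}
            )
    return pd.DataFrame(rows)


def make_dispense(rows: list[tuple[str, str, str, int, int]]) -> pd.DataFrame:
    """Dispense table from (din, ig, month, tot_dos, tot_patients) tuples."""
    df = pd.DataFrame(rows, columns=["din", "ig_code", "month", "tot_dos", "tot_patients"])
    df["tot_qty_disp"] = df["tot_dos"]
    df["tot_rx"] = df["tot_patients"]
    import numpy as np

    df["avgdos_pat"] = np.where(
        df["tot_patients"] > 0, df["tot_dos"] / df["tot_patients"].replace(0, 1), 0.0
    )
    return df


def make_intervals(rows: list[tuple[str, set[str], str, str]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["din", "listing_ids", "start", "end"])
    df["listing_ids"] = df["listing_ids"].map(frozenset)
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df
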