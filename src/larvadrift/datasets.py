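"""Small bundled datasets from the published survey record."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def chiton_survey_table() -> pd.DataFrame:
    """Per-species station counts of the deep-sea chiton survey.

    Columns: species, number of collecting stations per archipelago
    (New Caledonia, Vanuatu, Solomon Islands), and the species' recorded
    depth range in metres.
    """
    with resources.files("larvadrift.data").joinpath(
        "chiton_station_counts.csv"
    ).open() as f:
        return pd.read_csv(f)


def species_richness(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Species present (>= 1 station) in each archipelago."""
    if table is None:
        table = chiton_survey_table()
    return {
        "New Caledonia": int((table["n_stations_new_caledonia"] > 0).sum()),
        "Vanuatu": int((table["n_stations_vanuatu"] > 0).sum()),
        "Solomon Islands": int((table["n_stations_solomon_islands"] > 0).sum()),
    }
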