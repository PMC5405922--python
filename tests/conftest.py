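import numpy as np
import pandas as pd
import pytest

from reefkrige.grid import ReefGrid
from reefkrige.synth import EventSpec, SynthConfig, generate_dataset


def small_synth_config(**overrides) -> SynthConfig:
    """A reduced synthetic world for fast tests: 3 years, ~250 cells."""
    defaults = dict(
        seed=11,
        n_reef_cells=250,
        years=(1997, 1999),
        events={1998: EventSpec(fraction=0.15, amplitude_c=2.0)},
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_synth_config())


@pytest.fixture()
def toy_grid() -> ReefGrid:
    """A hand-built 5-cell reef grid near the origin, with one land cell."""
    proto = ReefGrid(cells=pd.DataFrame(columns=["row", "col", "lat", "lon", "reef_area", "region"]))
    lats = np.array([0.02, 0.02, 0.06, 0.10, 0.14])
    lons = np.array([0.02, 0.06, 0.06, 0.10, 0.14])
    ids = proto.cell_index(lats, lons)
    clat, clon = proto.cell_centre(ids)
    cells = pd.DataFrame(
        {
            "row": ids // proto.ncols,
            "col": ids % proto.ncols,
            "lat": clat,
            "lon": clon,
            "reef_area": [1.5, 2.5, 3.0, 4.0, 5.0],
            "region": "indian",
        },
        index=pd.Index(ids, name="cell_id"),
    )
    land_id = int(proto.cell_index(np.array([0.02]), np.array([0.30]))[0])
    return ReefGrid(cells=cells, land_cells=frozenset({land_id}))


def make_report_row(**overrides) -> dict:
    row = {
        "country": "Fiji", "location": "Viti Levu", "site_name": "reef A",
        "latitude": 0.02, "longitude": 0.02, "date": "", "month": 3,
        "year": 1998, "depth": 5.0, "severity_code": "", "percent_bleached": 55.0,
        "mortality_code": "", "percent_mortality": "", "survey_type": "random swim",
        "source": "test", "name": "", "citation": "", "comments": "",
        "entry_code": "T", "database_code": 2,
    }
    row.update(overrides)
    return row


def write_report_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
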