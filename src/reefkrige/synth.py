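"""Synthetic reef worlds with known latent bleaching structure.

The generator builds everything the pipeline consumes — a clustered
archipelago reef grid, twice-weekly SST series with planted warm anomaly
events, a spatially autocorrelated latent bleaching-probability field with
a configured variogram, and effort-biased severity-coded report tables —
so that every stage, and the end-to-end probability maps, can be tested
against known ground truth without any external data.

Emulated properties of the real observational record:

* observation effort is spatially clustered (survey hubs), so reports are
  dense in some archipelagos and absent in others;
* bleaching presence is driven by a latent probability field that is high
  inside contiguous "event" patches in event years and near zero elsewhere;
* SST anomalies are co-located with the event patches, so annual maximum
  DHW is positive exactly there and zero elsewhere (background noise is
  capped below the accumulation threshold by construction);
* a configurable fraction of reports is contaminated: mild-severity coding
  of truly bleached cells, non-thermal-cause comments, and reports placed
  on land cells, exercising the QC path.

The default event schedule plants four large late-period events
(1999-2010) and two small early-period events (1985-1996) whose latent
>50%-probability extents differ by a factor of eight, mirroring the
magnitude of the increase in bleaching extent across the 1997/98 El Nino
that the analysis is designed to detect, plus a large 1998 event outside
both periods.

All randomness flows from ``SynthConfig.seed`` through named child
generators; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geostat import _STRUCTURES, haversine, pairwise_haversine
from .grid import ReefGrid
from .observations import REPORT_COLUMNS, assign_severity


@dataclass(frozen=True)
class EventSpec:
    """One planted bleaching/thermal-stress event.

    fraction: fraction of all reef cells in the contiguous event patch;
    prob: latent bleaching probability inside the patch;
    amplitude_c: SST excess over MMM during the event window (degC);
    duration_days: event length (84 d = one full DHW window).
    """

    fraction: float
    prob: float = 0.9
    amplitude_c: float = 2.5
    duration_days: float = 84.0


def default_events() -> dict[int, EventSpec]:
    # Early period (1985-96): two small events; late period (1999-2010):
    # four larger ones with 8x the summed extent; 1998 sits between periods.
    return {
        1987: EventSpec(0.02),
        1995: EventSpec(0.02),
        1998: EventSpec(0.25),
        1999: EventSpec(0.06),
        2002: EventSpec(0.08),
        2005: EventSpec(0.12),
        2010: EventSpec(0.06),
    }


def default_clusters() -> list[tuple[str, float, float, float, float]]:
    """(region, centre lat, centre lon, spread degrees, weight) archipelagos."""
    return [
        ("caribbean", 18.0, -67.0, 3.0, 1.0),
        ("indian", -5.0, 72.0, 4.0, 1.2),
        ("east_pacific", -1.0, -91.0, 2.0, 0.6),
        ("pacific_west", 8.0, 140.0, 5.0, 1.2),
        ("pacific_central", 0.0, 178.0, 5.0, 1.0),
        ("pacific_east", -16.0, -146.0, 4.0, 1.0),
    ]


@dataclass
class SynthConfig:
    seed: int = 0
    n_reef_cells: int = 1200
    years: tuple[int, int] = (1985, 2010)
    resolution: float = 0.04
    clusters: list = field(default_factory=default_clusters)
    n_land_cells_per_cluster: int = 3
    # latent spatial structure (indicator scale); the background level is
    # deliberately near zero: moderate/severe warm-water bleaching without
    # any thermal stress is misreport-level noise, and a low background is
    # what makes most non-event region-years un-krigeable, as in the real
    # observational record
    latent_family: str = "spherical"
    latent_nugget: float = 1e-6
    latent_partial_sill: float = 1e-4
    latent_range_km: float = 400.0
    base_probability: float = 0.002
    events: dict = field(default_factory=default_events)
    # SST model
    sst_cadence_days: float = 3.5
    sst_start_year_offset: int = 1   # series starts Jan 1 of (first year - offset)
    mmm_base_c: float = 28.0
    seasonal_amplitude_c: float = 1.5
    sst_noise_sd_c: float = 0.1
    dhw_threshold_c: float = 1.0
    # observation effort
    effort_fraction: float = 0.6
    effort_floor: float = 0.2       # minimum survey probability anywhere
    n_effort_hubs: int = 12
    effort_scale_km: float = 1500.0
    severity_noise: float = 0.05      # bleached cell reported at severity 1
    qc_contamination: float = 0.01    # reports given a non-thermal comment
    n_land_reports_per_year: int = 1  # reports planted on land cells


def _rng(seed: int, *names) -> np.random.Generator:
    keys = [seed & 0x7FFFFFFF] + [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def make_reef_grid(cfg: SynthConfig) -> ReefGrid:
    """Clustered archipelago reef grid with per-cell areas and land cells."""
    if cfg.n_reef_cells < 1:
        raise ValueError("n_reef_cells must be >= 1")
    rng = _rng(cfg.seed, "grid")
    weights = np.array([c[4] for c in cfg.clusters], dtype=float)
    quota = np.maximum(np.round(weights / weights.sum() * cfg.n_reef_cells).astype(int), 1)
    # adjust rounding drift onto the largest cluster
    quota[np.argmax(quota)] += cfg.n_reef_cells - quota.sum()
    proto = ReefGrid(cells=pd.DataFrame(columns=["row", "col", "lat", "lon", "reef_area", "region"]),
                     resolution=cfg.resolution)
    records: dict[int, tuple] = {}
    land: set[int] = set()
    for (region, clat, clon, spread, _w), n_target in zip(cfg.clusters, quota):
        got = 0
        for _ in range(200):
            if got >= n_target:
                break
            lat = np.clip(rng.normal(clat, spread, size=4 * n_target), -89.9, 89.9)
            lon = clon + rng.normal(0.0, spread, size=4 * n_target)
            lon = (lon + 180.0) % 360.0 - 180.0
            ids = proto.cell_index(lat, lon)
            for cid in ids:
                if got >= n_target:
                    break
                cid = int(cid)
                if cid not in records and cid not in land:
                    records[cid] = (region,)
                    got += 1
        # land cells: a short strip east of the cluster centre
        base = proto.cell_index(np.array([clat]), np.array([clon + 3 * spread]))[0]
        for j in range(cfg.n_land_cells_per_cluster):
            cid = int(base) + j
            if cid not in records:
                land.add(cid)
    ids = np.array(sorted(records), dtype=np.int64)
    lat, lon = proto.cell_centre(ids)
    areas = rng.uniform(1.0, 15.0, size=ids.size).round(3)
    cells = pd.DataFrame(
        {
            "row": ids // proto.ncols,
            "col": ids % proto.ncols,
            "lat": lat,
            "lon": lon,
            "reef_area": areas,
            "region": [records[int(c)][0] for c in ids],
        },
        index=pd.Index(ids, name="cell_id"),
    )
    return ReefGrid(cells=cells, resolution=cfg.resolution, land_cells=frozenset(land))


def event_patch(grid: ReefGrid, cfg: SynthConfig, year: int) -> np.ndarray:
    """Cell ids of the contiguous event patch for an event year (empty otherwise)."""
    ev = cfg.events.get(year)
    if ev is None or ev.fraction <= 0:
        return np.empty(0, dtype=np.int64)
    rng = _rng(cfg.seed, "patch", year)
    ids = grid.reef_cell_ids
    n_patch = max(1, int(round(ev.fraction * ids.size)))
    seed_idx = int(rng.integers(ids.size))
    lat = grid.cells["lat"].to_numpy()
    lon = grid.cells["lon"].to_numpy()
    d = haversine(lat[seed_idx], lon[seed_idx], lat, lon)
    return ids[np.argsort(d, kind="stable")[:n_patch]]


def _times(cfg: SynthConfig) -> np.ndarray:
    y0, y1 = cfg.years
    start = np.datetime64(f"{y0 - cfg.sst_start_year_offset}-01-01", "h")
    stop = np.datetime64(f"{y1 + 1}-01-01", "h")
    step = np.timedelta64(int(cfg.sst_cadence_days * 24), "h")
    return np.arange(start, stop, step)


def simulate_sst(grid: ReefGrid, cfg: SynthConfig):
    """Twice-weekly SST series and MMM climatology for every reef cell.

    Returns ``(times, sst, mmm)`` with ``sst`` of shape (n_cells, n_times).
    Outside event windows SST is clipped below MMM + 0.9 x accumulation
    threshold, so annual maximum DHW is positive exactly at event-patch
    cells in event years.  Inside an event window SST is exactly
    MMM + amplitude, so patch DHW has the closed form
    amplitude x duration / 7 degC-weeks.
    """
    times = _times(cfg)
    t_days = times.astype("datetime64[s]").astype(float) / 86400.0
    lat = grid.cells["lat"].to_numpy()
    mmm = cfg.mmm_base_c - 0.05 * np.abs(lat)
    rng = _rng(cfg.seed, "sst")
    phase = 2.0 * np.pi * (t_days % 365.25) / 365.25
    seasonal = -0.5 - cfg.seasonal_amplitude_c * 0.5 * (1.0 - np.cos(phase))
    sst = mmm[:, None] + seasonal[None, :] + rng.normal(0.0, cfg.sst_noise_sd_c, size=(lat.size, times.size))
    np.minimum(sst, mmm[:, None] + 0.9 * cfg.dhw_threshold_c, out=sst)
    id_pos = {int(c): i for i, c in enumerate(grid.reef_cell_ids)}
    for year, ev in sorted(cfg.events.items()):
        if not (cfg.years[0] <= year <= cfg.years[1]):
            raise ValueError(f"event year {year} outside simulated span {cfg.years}")
        patch = event_patch(grid, cfg, year)
        if patch.size == 0:
            continue
        rows = np.array([id_pos[int(c)] for c in patch])
        start = np.datetime64(f"{year}-05-01", "h")
        end = start + np.timedelta64(int(ev.duration_days * 24), "h")
        window = (times >= start) & (times < end)
        sst[np.ix_(rows, np.where(window)[0])] = (mmm[rows] + ev.amplitude_c)[:, None]
    return times, sst, mmm


def _latent_cholesky(grid: ReefGrid, cfg: SynthConfig) -> Optional[np.ndarray]:
    total = cfg.latent_partial_sill + cfg.latent_nugget
    if total == 0.0:
        return None  # spatially constant field
    d = pairwise_haversine(grid.cells["lat"].to_numpy(), grid.cells["lon"].to_numpy())
    corr = 1.0 - _STRUCTURES[cfg.latent_family](d, cfg.latent_range_km, 0.5)
    cov = cfg.latent_partial_sill * corr
    cov[np.diag_indices_from(cov)] += cfg.latent_nugget + 1e-9 * total
    return np.linalg.cholesky(cov)


def simulate_latent_field(
    grid: ReefGrid,
    cfg: SynthConfig,
    year: int,
    chol: Optional[np.ndarray] = None,
) -> pd.Series:
    """Ground-truth bleaching probability per reef cell for one year.

    A Gaussian random field with the configured variogram (plus nugget as
    white noise) is added to the base probability and clipped to [0, 1];
    event-patch cells are then raised to the event probability.
    """
    if chol is None and (cfg.latent_partial_sill + cfg.latent_nugget) > 0.0:
        chol = _latent_cholesky(grid, cfg)
    rng = _rng(cfg.seed, "latent", year)
    z = chol @ rng.standard_normal(len(grid.cells)) if chol is not None else 0.0
    p = np.clip(cfg.base_probability + z, 0.0, 1.0)
    out = pd.Series(p, index=grid.cells.index, name=year)
    patch = event_patch(grid, cfg, year)
    if patch.size:
        out.loc[patch] = cfg.events[year].prob
    return out


def _survey_probability(grid: ReefGrid, cfg: SynthConfig) -> np.ndarray:
    rng = _rng(cfg.seed, "hubs")
    lat = grid.cells["lat"].to_numpy()
    lon = grid.cells["lon"].to_numpy()
    hubs = rng.choice(lat.size, size=min(cfg.n_effort_hubs, lat.size), replace=False)
    d = haversine(lat[:, None], lon[:, None], lat[hubs][None, :], lon[hubs][None, :]).min(axis=1)
    raw = np.exp(-d / cfg.effort_scale_km)
    raw = raw / raw.mean() if raw.mean() > 0 else raw
    # clustered effort on top of a uniform survey-probability floor, so the
    # overall mean surveyed fraction is about effort_fraction
    p = cfg.effort_floor + max(cfg.effort_fraction - cfg.effort_floor, 0.0) * raw
    return np.clip(p, 0.0, 1.0)


def sample_reports(
    latent: pd.Series,
    grid: ReefGrid,
    cfg: SynthConfig,
    year: int,
) -> pd.DataFrame:
    """Effort-biased severity-coded reports for one year, in the report schema.

    Surveyed cells are drawn with probability decaying away from fixed
    survey hubs; each surveyed cell reports bleaching with its latent
    probability.  Bleached cells draw percent bleached in (10, 100]
    (severity 2/3) except for a configured contamination fraction reported
    mild (severity 1); unbleached surveyed cells file a zero-percent
    report.  A small number of QC contaminants (non-thermal comments, land
    coordinates) is included.
    """
    rng = _rng(cfg.seed, "reports", year)
    p_survey = _survey_probability(grid, cfg)
    surveyed = rng.random(len(grid.cells)) < p_survey
    cells = grid.cells.loc[surveyed]
    probs = latent.loc[cells.index].to_numpy()
    bleached = rng.random(len(cells)) < probs
    rows = []
    jitter = 0.2 * grid.resolution
    for (cid, cell), bl in zip(cells.iterrows(), bleached):
        u, v = rng.uniform(-jitter, jitter, size=2)
        if bl:
            if rng.random() < cfg.severity_noise:
                pct = float(np.round(rng.uniform(1.0, 10.0), 1))
            else:
                pct = float(np.round(rng.uniform(11.0, 100.0), 1))
        else:
            pct = 0.0
        comments = ""
        if rng.random() < cfg.qc_contamination:
            comments = "bleaching attributed to freshwater runoff"
        rows.append(
            {
                "country": "Synthetica", "location": str(cell["region"]),
                "site_name": f"cell-{cid}", "latitude": round(cell["lat"] + u, 6),
                "longitude": round(cell["lon"] + v, 6), "date": "",
                "month": int(rng.integers(1, 13)), "year": year, "depth": 5.0,
                "severity_code": assign_severity(pct), "percent_bleached": pct,
                "mortality_code": np.nan, "percent_mortality": np.nan,
                "survey_type": "random swim", "source": "synthetic generator",
                "name": "", "citation": "", "comments": comments,
                "entry_code": "SYN", "database_code": 2,
            }
        )
    # a few reports with land coordinates, to exercise the off-reef QC rule
    land = sorted(grid.land_cells)
    for j in range(min(cfg.n_land_reports_per_year, len(land))):
        cid = land[int(rng.integers(len(land)))]
        lat, lon = grid.cell_centre(np.array([cid]))
        rows.append(
            {
                "country": "Synthetica", "location": "land", "site_name": f"land-{cid}",
                "latitude": round(float(lat[0]), 6), "longitude": round(float(lon[0]), 6),
                "date": "", "month": int(rng.integers(1, 13)), "year": year, "depth": 0.0,
                "severity_code": 2, "percent_bleached": 25.0, "mortality_code": np.nan,
                "percent_mortality": np.nan, "survey_type": "random swim",
                "source": "synthetic generator", "name": "", "citation": "",
                "comments": "", "entry_code": "SYN", "database_code": 2,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


@dataclass
class SynthDataset:
    """Everything the pipeline consumes, plus the latent ground truth."""

    config: SynthConfig
    grid: ReefGrid
    times: np.ndarray
    sst: np.ndarray
    mmm: np.ndarray
    latent: pd.DataFrame          # cells x years, true probabilities
    reports: pd.DataFrame
    patches: dict                 # year -> event cell ids

    @property
    def years(self) -> list[int]:
        return list(range(self.config.years[0], self.config.years[1] + 1))


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate the full synthetic study: grid, SST, latent fields, reports."""
    grid = make_reef_grid(cfg)
    times, sst, mmm = simulate_sst(grid, cfg)
    chol = _latent_cholesky(grid, cfg)
    years = list(range(cfg.years[0], cfg.years[1] + 1))
    latent = pd.DataFrame({y: simulate_latent_field(grid, cfg, y, chol=chol) for y in years})
    reports = pd.concat([sample_reports(latent[y], grid, cfg, y) for y in years], ignore_index=True)
    patches = {y: event_patch(grid, cfg, y) for y in years if y in cfg.events}
    return SynthDataset(cfg, grid, times, sst, mmm, latent, reports, patches)
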