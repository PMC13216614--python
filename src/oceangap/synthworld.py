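"""Synthetic ocean world with known ground truth.

Generates a bathymetry raster with contiguous land, environmental covariate
layers per realm (surface / mesopelagic / benthic), a species pool with a
configurable latitudinal richness structure (flat, unimodal or bimodal), a
spatially clustered sampling-effort surface with northern-hemisphere bias and
an equatorial deficit, and finally occurrence records with Darwin-Core-style
fields and controlled corruptions (duplicates, fossils, absences, on-land
points, depth-bathymetry conflicts, missing depths, synonyms, inflated
coordinate uncertainty).

Everything downstream — QC, binning, richness estimation, gradient modality,
driver models — can therefore be validated against exact ground truth.
Species ranges are rectangles in (latitude, longitude) aligned to 5° bands
with Gaussian-tapered abundance; species abundances are log-normal (the
standard skewed species-abundance stand-in); corruptions mutate otherwise
valid records after sampling, so the per-rule truth is exact and carried in
a hidden ``_qc_truth`` column.  One root seed feeds independent derived
streams per component, so adding a corruption type does not perturb earlier
draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geogrid import DEPTH_ZONES, N_BANDS, BAND_WIDTH
from .rasters import Raster, cell_areas_km2

__all__ = [
    "WorldConfig", "GroundTruth", "PHYLA",
    "generate_world", "generate_species_pool", "sample_occurrences",
    "generate_dataset", "CORRUPTION_RULES",
]

PHYLA = ("Annelida", "Arthropoda", "Chordata", "Cnidaria",
         "Echinodermata", "Mollusca", "Porifera")
_PHYLUM_W = np.array([0.12, 0.22, 0.25, 0.10, 0.08, 0.18, 0.05])

#: corruption rules in application order (fixed so that a given config+seed
#: always yields byte-identical tables)
CORRUPTION_RULES = ("duplicate", "fossil", "absent", "on_land",
                    "depth_conflict", "missing_depth", "synonym",
                    "high_uncertainty")

_STREAMS = {"world": 1, "pool": 2, "effort": 3, "sample": 4, "corrupt": 5}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass
class WorldConfig:
    """Study conditions for the synthetic world (all defaults are the
    conditions used throughout the test-suite and acceptance runs)."""

    raster_resolution: float = 2.5        # degrees; must divide 180
    land_fraction: float = 0.3
    n_species: int = 300
    abundance_sd: float = 1.0             # log-scale SAD dispersion
    gradient_shape: str = "bimodal"       # flat | unimodal | bimodal
    gradient_peaks: tuple = (-25.0, 25.0)  # degrees latitude
    gradient_width: float = 10.0          # degrees (Gaussian width per peak)
    range_width_bands: int = 4            # species latitude range, in 5° bands
    depth_mix: tuple = (0.6, 0.25, 0.15)  # shallow/meso/deep specialists
    effort_north_bias: float = 2.0        # effort multiplier for lat > 0
    equatorial_deficit: float = 0.15      # effort multiplier for |lat| <= 5
    n_records: int = 20000
    synonym_rate: float = 0.2             # registry synonym rows / species
    corruption_rates: dict = field(default_factory=lambda: {
        "duplicate": 0.02, "fossil": 0.01, "absent": 0.01, "on_land": 0.01,
        "depth_conflict": 0.01, "missing_depth": 0.07, "synonym": 0.05,
        "high_uncertainty": 0.01})
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(180.0 / self.raster_resolution - round(180.0 / self.raster_resolution)) > 1e-9:
            raise ValueError("raster_resolution must divide 180 evenly")
        for name, v in [("land_fraction", self.land_fraction),
                        ("synonym_rate", self.synonym_rate),
                        ("equatorial_deficit", self.equatorial_deficit)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_species < 1 or self.n_records < 1:
            raise ValueError("n_species and n_records must be >= 1")
        if self.gradient_shape not in {"flat", "unimodal", "bimodal"}:
            raise ValueError("gradient_shape must be flat|unimodal|bimodal")
        rates = dict(self.corruption_rates)
        unknown = set(rates) - set(CORRUPTION_RULES)
        if unknown:
            raise ValueError(f"unknown corruption rules: {sorted(unknown)}")
        if any(not 0 <= r <= 1 for r in rates.values()) or sum(rates.values()) > 1:
            raise ValueError("corruption rates must be in [0,1] and sum to <= 1")
        if abs(sum(self.depth_mix) - 1.0) > 1e-9:
            raise ValueError("depth_mix must sum to 1")


@dataclass
class GroundTruth:
    true_richness_per_band: dict          # zone -> np.ndarray(36)
    species_ranges: pd.DataFrame
    true_effect_sizes: dict
    effort_surface: Raster | None = None

    def to_json(self, path: str | Path) -> None:
        out = {
            "true_richness_per_band": {z: list(map(int, v))
                                       for z, v in self.true_richness_per_band.items()},
            "species_ranges": self.species_ranges.to_dict(orient="records"),
            "true_effect_sizes": self.true_effect_sizes,
        }
        with open(path, "w") as fh:
            json.dump(out, fh)


# ---------------------------------------------------------------------------
# world

def _blob_field(lat2d, lon2d, rng, n_blobs=15, width_range=(15.0, 45.0)) -> np.ndarray:
    """Smooth random field: sum of Gaussian bumps on the sphere."""
    la = np.deg2rad(lat2d)
    lo = np.deg2rad(lon2d)
    xyz = np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1)
    u = rng.normal(size=(n_blobs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    widths = np.deg2rad(rng.uniform(*width_range, n_blobs))
    amps = rng.normal(0.0, 1.0, n_blobs)
    fld = np.zeros(lat2d.shape)
    for c, w, a in zip(u, widths, amps):
        ang = np.arccos(np.clip(xyz @ c, -1, 1))
        fld += a * np.exp(-0.5 * (ang / w) ** 2)
    return fld


def generate_world(config: WorldConfig) -> tuple[Raster, dict]:
    """Bathymetry plus environmental layers.

    Bathymetry is positive ocean depth in metres (NaN on land); land is the
    top ``land_fraction`` quantile of a smooth random field, hence a few
    contiguous continents.  Depth increases away from land (so continental
    shelves of <=140 m exist) up to abyssal values.  Layers are generated per
    realm: ``surface`` and ``mesopelagic`` (pelagic) and ``benthic``
    (sea-floor), tagged via ``Raster.realm``.  Surface/mesopelagic O2 is an
    exact affine function of temperature (their near-perfect anticorrelation
    in real climatologies is what forces O2 out of shallow/mesopelagic driver
    models); benthic O2 is an independent field.
    """
    res = config.raster_resolution
    nrows = int(round(180.0 / res))
    ncols = int(round(360.0 / res))
    rng = _rng(config.seed, "world")
    lat_c = -90.0 + (np.arange(nrows) + 0.5) * res
    lon_c = -180.0 + (np.arange(ncols) + 0.5) * res
    lon2d, lat2d = np.meshgrid(lon_c, lat_c)

    fld = _blob_field(lat2d, lon2d, rng)
    if config.land_fraction > 0:
        thr = float(np.quantile(fld, 1.0 - config.land_fraction))
    else:
        thr = float(fld.max()) + 1.0
    land = fld >= thr
    # depth grows with "distance" below the land threshold in field units
    rel = np.clip((thr - fld) / max(thr - fld.min(), 1e-9), 0.0, 1.0)
    depth = 10999.0 * rel ** 1.6 + 1.0 + rng.uniform(0, 10, fld.shape)
    depth = np.clip(depth, 1.0, 11000.0)
    depth[land] = np.nan
    bathy = Raster(depth, resolution=res)

    def ocean_only(vals):
        v = np.asarray(vals, dtype=float).copy()
        v[land] = np.nan
        return v

    noise = lambda s: rng.normal(0.0, s, fld.shape)
    t_surf = 28.0 * np.cos(np.deg2rad(lat2d)) ** 1.5 - 1.0 + noise(0.8)
    t_meso = np.clip(t_surf - 8.0, -1.5, None) + noise(0.5)
    t_benth = 1.5 + 20.0 * np.exp(-depth_filled(depth) / 400.0) + noise(0.4)

    layers: dict[str, Raster] = {}

    def add(name, realm, vals):
        layers[f"{name}_{realm}"] = Raster(ocean_only(vals), resolution=res, realm=realm)

    add("temperature", "surface", t_surf)
    add("temperature", "mesopelagic", t_meso)
    add("temperature", "benthic", t_benth)
    # O2 ~ affine in temperature for pelagic realms (r = -1 by construction)
    add("o2", "surface", 350.0 - 5.0 * t_surf)
    add("o2", "mesopelagic", 330.0 - 5.0 * t_meso)
    add("o2", "benthic", 180.0 + 30.0 * _blob_field(lat2d, lon2d, rng, 10) + noise(3.0))
    # nitrate increases with depth (remineralisation at depth)
    n_surf = np.clip(2.0 + 0.12 * np.abs(lat2d) + noise(0.6), 0.0, None)
    add("nitrate", "surface", n_surf)
    add("nitrate", "mesopelagic", n_surf + 8.0 + noise(0.8))
    add("nitrate", "benthic", 6.0 + 28.0 * (1.0 - np.exp(-depth_filled(depth) / 1200.0)) + noise(1.0))
    prod = np.clip(8.0 + 6.0 * np.cos(np.deg2rad(2.5 * lat2d))
                   + 2.0 * _blob_field(lat2d, lon2d, rng, 8) + noise(0.7), 0.1, None)
    add("productivity", "surface", prod)
    add("productivity", "mesopelagic", prod * 0.35)
    add("productivity", "benthic", prod * np.exp(-depth_filled(depth) / 2500.0))
    rad = np.clip(55.0 * np.cos(np.deg2rad(lat2d)) + noise(1.5), 0.0, None)
    add("radiation", "surface", rad)
    add("radiation", "mesopelagic", rad * 0.05)
    add("radiation", "benthic", rad * 0.01)
    cur = np.clip(0.15 + 0.1 * _blob_field(lat2d, lon2d, rng, 12) + noise(0.02), 0.0, None)
    add("current_velocity", "surface", cur)
    add("current_velocity", "mesopelagic", cur * 0.6)
    add("current_velocity", "benthic", cur * 0.3)
    ice = np.clip((np.abs(lat2d) - 60.0) / 25.0 + noise(0.05), 0.0, 1.0)
    add("ice_cover", "surface", ice)
    # human influence: stronger near land and in the north
    hii_f = _blob_field(lat2d, lon2d, rng, 10)
    hii = np.clip(20.0 + 15.0 * hii_f + 10.0 * (lat2d > 0) + noise(2.0), 0.0, 64.0)
    add("hii", "surface", hii)
    return bathy, layers


def depth_filled(depth: np.ndarray) -> np.ndarray:
    """Depth with land squashed to 0 for layer formulas."""
    return np.where(np.isfinite(depth), depth, 0.0)


# ---------------------------------------------------------------------------
# species pool

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas proportional to weights, summing exactly to total."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    quota = w * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        base[np.argsort(-(quota - base))[:rem]] += 1
    return base


def _band_starts(config: WorldConfig, n_zone: int, rng) -> np.ndarray:
    """Starting band index of each species' latitude block in one zone."""
    w = config.range_width_bands
    if config.gradient_shape == "flat":
        # tile the 36 bands with contiguous blocks and deal species
        # round-robin: every band gets exactly ceil/floor(n/blocks) species
        wf = 6
        starts = np.arange(0, N_BANDS, wf)
        return starts[np.arange(n_zone) % starts.size]
    centers = -90.0 + BAND_WIDTH * (np.arange(N_BANDS) + 0.5)
    if config.gradient_shape == "unimodal":
        peaks = [0.0]
    else:
        peaks = list(config.gradient_peaks)
    weight = sum(np.exp(-0.5 * ((centers - p) / config.gradient_width) ** 2) for p in peaks)
    weight = weight + 0.01
    quota = _largest_remainder(weight, n_zone)
    center_bands = np.repeat(np.arange(N_BANDS), quota)
    rng.shuffle(center_bands)
    return np.clip(center_bands - w // 2, 0, N_BANDS - w)


def generate_species_pool(config: WorldConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Species pool, name registry and exact ground truth.

    Species are assigned to the 7 dominant marine animal phyla, to a depth
    zone (specialists, per ``depth_mix``), and to a latitude block whose
    placement realises ``gradient_shape``; per-band true richness is the
    count of species blocks covering each band.  The registry has one
    accepted row per species plus ``synonym_rate * n_species`` synonym rows,
    and a few non-marine / non-animal decoy rows for QC exercises.
    """
    rng = _rng(config.seed, "pool")
    n = config.n_species
    w = config.range_width_bands

    zone_names = list(DEPTH_ZONES)
    zone_quota = _largest_remainder(np.array(config.depth_mix), n)
    zones = np.repeat(zone_names, zone_quota)

    starts = np.empty(n, dtype=int)
    pos = 0
    for zname, nq in zip(zone_names, zone_quota):
        starts[pos:pos + nq] = _band_starts(config, nq, rng)
        pos += nq
    widths = np.where(
        np.array([config.gradient_shape == "flat"] * n), 6, w)
    lat_lo = -90.0 + BAND_WIDTH * starts
    lat_hi = lat_lo + BAND_WIDTH * widths

    phyla = rng.choice(PHYLA, size=n, p=_PHYLUM_W / _PHYLUM_W.sum())
    names = np.array([f"Genus{i // 10:03d} species{i % 10}{chr(97 + i % 26)}{i:04d}"
                      for i in range(n)])
    pool = pd.DataFrame({
        "species_id": np.arange(n),
        "accepted_name": names,
        "phylum": phyla,
        "zone": zones,
        "lat_lo": lat_lo,
        "lat_hi": lat_hi,
        "lat_center": (lat_lo + lat_hi) / 2.0,
        "lat_sigma": (lat_hi - lat_lo) / 4.0,
        "lon_center": rng.uniform(-180.0, 180.0, n),
        "lon_halfwidth": rng.uniform(30.0, 90.0, n),
        "mean_abundance": rng.lognormal(2.0, config.abundance_sd, n),
    })

    richness = {}
    band_lo = -90.0 + BAND_WIDTH * np.arange(N_BANDS)
    for zname in zone_names:
        sub = pool[pool["zone"] == zname]
        cov = ((sub["lat_lo"].to_numpy()[:, None] <= band_lo[None, :])
               & (band_lo[None, :] < sub["lat_hi"].to_numpy()[:, None]))
        richness[zname] = cov.sum(axis=0).astype(int)

    rows = [{"raw_name": nm, "accepted_name": nm, "status": "accepted",
             "is_marine": True, "is_brackish": bool(b), "kingdom": "Animalia"}
            for nm, b in zip(names, rng.random(n) < 0.1)]
    n_syn = int(round(config.synonym_rate * n))
    targets = rng.choice(n, size=n_syn, replace=n_syn > n)
    for j, t in enumerate(targets):
        rows.append({"raw_name": f"Synonymus obsoletum{j:04d}",
                     "accepted_name": names[t], "status": "synonym",
                     "is_marine": True, "is_brackish": False, "kingdom": "Animalia"})
    for j in range(4):      # freshwater decoys
        rows.append({"raw_name": f"Limnius fluviatilis{j}",
                     "accepted_name": f"Limnius fluviatilis{j}", "status": "accepted",
                     "is_marine": False, "is_brackish": False, "kingdom": "Animalia"})
    for j in range(3):      # non-animal decoys
        rows.append({"raw_name": f"Phycus planta{j}",
                     "accepted_name": f"Phycus planta{j}", "status": "accepted",
                     "is_marine": True, "is_brackish": False, "kingdom": "Plantae"})
    registry = pd.DataFrame(rows)

    truth = GroundTruth(true_richness_per_band=richness, species_ranges=pool,
                        true_effect_sizes={})
    return registry, truth


# ---------------------------------------------------------------------------
# occurrence sampling

_ZONE_LO = {z: b[0] for z, b in DEPTH_ZONES.items()}
_ZONE_HI = {z: b[1] for z, b in DEPTH_ZONES.items()}

_DATASETS = [f"synthetic-dataset-{k:02d}" for k in range(8)]
_DATASET_W = np.array([0.3, 0.2, 0.15, 0.12, 0.1, 0.06, 0.04, 0.03])


def make_effort_surface(bathy: Raster, config: WorldConfig) -> Raster:
    """Clustered sampling-effort surface, independent of true richness.

    Log-normal spatial clustering times a northern-hemisphere bias factor and
    an equatorial (|lat| <= 5°) deficit factor; zero on land.
    """
    rng = _rng(config.seed, "effort")
    lat_c = bathy.lat_centers
    lon_c = bathy.lon_centers
    lon2d, lat2d = np.meshgrid(lon_c, lat_c)
    base = np.exp(1.2 * _blob_field(lat2d, lon2d, rng, 20, (10.0, 30.0)))
    base *= np.where(lat2d > 0, config.effort_north_bias, 1.0)
    base *= np.where(np.abs(lat2d) <= 5.0, config.equatorial_deficit, 1.0)
    base[~(np.isfinite(bathy.values) & (bathy.values > 0))] = 0.0
    return bathy.copy_with(base)


def sample_occurrences(world, pool: GroundTruth, config: WorldConfig) -> pd.DataFrame:
    """Draw occurrence records and inject corruptions.

    Locations are drawn first, proportional to effort times raster-cell
    area times the locally available abundance; the species at a location
    is drawn among species whose range fully covers the raster cell
    (latitude/longitude rectangle, and zone reachable given local
    bathymetry) with probability proportional to mean abundance times the
    Gaussian latitude taper.  Record depth is the zone
    midpoint plus noise truncated to the zone and the local bathymetry.
    Corruptions then mutate disjoint record subsets at the configured rates
    and are flagged in the hidden ``_qc_truth`` column (duplicates are
    appended copies flagged on the copy).
    """
    bathy, _layers = world if isinstance(world, tuple) else (world, None)
    effort = make_effort_surface(bathy, config)
    pool.effort_surface = effort
    sp = pool.species_ranges
    rng = _rng(config.seed, "sample")

    lat_c = bathy.lat_centers
    lon_c = bathy.lon_centers
    lon2d, lat2d = np.meshgrid(lon_c, lat_c)
    flat_lat = lat2d.ravel()
    flat_lon = lon2d.ravel()
    flat_depth = bathy.values.ravel()
    flat_eff = (effort.values * cell_areas_km2(bathy)).ravel()
    res = bathy.resolution

    # species x cell eligibility: cell fully inside the range rectangle and
    # the species' zone reachable at the cell's bathymetry
    lat_ok = ((sp["lat_lo"].to_numpy()[:, None] <= flat_lat[None, :] - res / 2)
              & (flat_lat[None, :] + res / 2 <= sp["lat_hi"].to_numpy()[:, None]))
    dlon = (flat_lon[None, :] - sp["lon_center"].to_numpy()[:, None] + 180.0) % 360.0 - 180.0
    lon_ok = np.abs(dlon) <= (sp["lon_halfwidth"].to_numpy()[:, None] - res / 2)
    zone_lo = sp["zone"].map(_ZONE_LO).to_numpy()
    depth_ok = np.where(np.isfinite(flat_depth[None, :]),
                        flat_depth[None, :] > zone_lo[:, None], False)
    elig = lat_ok & lon_ok & depth_ok
    taper = np.exp(-0.5 * ((flat_lat[None, :] - sp["lat_center"].to_numpy()[:, None])
                           / sp["lat_sigma"].to_numpy()[:, None]) ** 2)
    weight = elig * taper * sp["mean_abundance"].to_numpy()[:, None]

    # location draw: effort x cell area x locally available abundance, so
    # record density reflects both sampling pressure and how much there is
    # to record (under a flat gradient the abundance factor is latitude-
    # independent, keeping record counts effort-driven by construction)
    avail = weight.sum(axis=0)
    p = flat_eff * avail
    if p.sum() <= 0:
        raise RuntimeError("no sampleable ocean cells (all effort zero)")
    p = p / p.sum()
    cells = rng.choice(p.size, size=config.n_records, p=p)

    # categorical draw per record via the Gumbel-max trick (vectorized)
    with np.errstate(divide="ignore"):
        logw = np.log(weight[:, cells])
    gumbel = -np.log(-np.log(rng.random(logw.shape)))
    spid = np.argmax(logw + gumbel, axis=0)

    lat = flat_lat[cells] + rng.uniform(-res / 2, res / 2, config.n_records)
    lon = flat_lon[cells] + rng.uniform(-res / 2, res / 2, config.n_records)
    lon = (lon + 180.0) % 360.0 - 180.0
    zlo = sp["zone"].map(_ZONE_LO).to_numpy()[spid]
    zhi = np.minimum(sp["zone"].map(_ZONE_HI).to_numpy()[spid], flat_depth[cells])
    mid = (zlo + zhi) / 2.0
    depth = np.clip(rng.normal(mid, np.maximum((zhi - zlo) / 4.0, 1e-3)),
                    zlo + 1e-3, zhi)

    days = rng.integers(0, 22280, config.n_records)   # 1960-01-01 .. 2020-12-31
    dates = (np.datetime64("1960-01-01") + days.astype("timedelta64[D]")).astype(str)
    df = pd.DataFrame({
        "raw_name": sp["accepted_name"].to_numpy()[spid],
        "latitude": lat, "longitude": lon, "depth": depth,
        "coord_uncertainty": np.clip(rng.lognormal(np.log(500.0), 1.0,
                                                   config.n_records), 10.0, 50000.0),
        "basis": rng.choice(["HumanObservation", "PreservedSpecimen",
                             "MachineObservation"], config.n_records, p=[0.6, 0.3, 0.1]),
        "status": "present",
        "phylum": sp["phylum"].to_numpy()[spid],
        "kingdom": "Animalia",
        "dataset_id": rng.choice(_DATASETS, config.n_records, p=_DATASET_W),
        "event_date": dates,
        "_qc_truth": "",
        "_species_id": spid,
    })
    return _corrupt(df, bathy, pool, config)


def _corrupt(df: pd.DataFrame, bathy: Raster, pool: GroundTruth,
             config: WorldConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "corrupt")
    n = len(df)
    u = rng.random(n)
    edges = np.cumsum([0.0] + [config.corruption_rates.get(r, 0.0) for r in CORRUPTION_RULES])
    assign = np.full(n, -1)
    for k in range(len(CORRUPTION_RULES)):
        assign[(u >= edges[k]) & (u < edges[k + 1])] = k

    land = ~(np.isfinite(bathy.values) & (bathy.values > 0))
    land_idx = np.flatnonzero(land.ravel())
    lat_c = bathy.lat_centers
    lon_c = bathy.lon_centers
    ncols = bathy.ncols
    res = bathy.resolution

    # synonym aliases per accepted name, from the registry stored on the pool
    aliases: dict[str, list[str]] = {}
    reg = getattr(pool, "_registry", None)
    if reg is not None:
        for _, r in reg[reg["status"] == "synonym"].iterrows():
            aliases.setdefault(r["accepted_name"], []).append(r["raw_name"])

    for k, rule in enumerate(CORRUPTION_RULES):
        idx = np.flatnonzero(assign == k)
        if idx.size == 0:
            continue
        if rule == "duplicate":
            continue            # handled after mutation, by appending copies
        elif rule == "fossil":
            df.loc[idx, "basis"] = "FossilSpecimen"
        elif rule == "absent":
            df.loc[idx, "status"] = "absent"
        elif rule == "on_land":
            if land_idx.size == 0:
                continue
            tgt = rng.choice(land_idx, idx.size)
            df.loc[idx, "latitude"] = lat_c[tgt // ncols] + rng.uniform(-res / 4, res / 4, idx.size)
            df.loc[idx, "longitude"] = lon_c[tgt % ncols] + rng.uniform(-res / 4, res / 4, idx.size)
        elif rule == "depth_conflict":
            local = bathy.sample(df.loc[idx, "latitude"], df.loc[idx, "longitude"])
            df.loc[idx, "depth"] = local + 100.0    # beyond the 50 m margin
        elif rule == "missing_depth":
            df.loc[idx, "depth"] = np.nan
        elif rule == "synonym":
            applied = []
            for i in idx:
                al = aliases.get(df.at[i, "raw_name"])
                if al:
                    df.at[i, "raw_name"] = al[0]
                    applied.append(i)
            idx = np.array(applied, dtype=int)
        elif rule == "high_uncertainty":
            df.loc[idx, "coord_uncertainty"] = rng.uniform(100001.0, 500000.0, idx.size)
        df.loc[idx, "_qc_truth"] = rule

    dup_idx = np.flatnonzero(assign == CORRUPTION_RULES.index("duplicate"))
    if dup_idx.size:
        dups = df.iloc[dup_idx].copy()
        dups["_qc_truth"] = "duplicate"
        df = pd.concat([df, dups], ignore_index=True)
    return df


def generate_dataset(config: WorldConfig):
    """One call for the full synthetic bundle.

    Returns (bathymetry, layers, registry, truth, occurrences).
    """
    bathy, layers = generate_world(config)
    registry, truth = generate_species_pool(config)
    truth._registry = registry            # synonym aliases for corruption
    occ = sample_occurrences((bathy, layers), truth, config)
    return bathy, layers, registry, truth, occ
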