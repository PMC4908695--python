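"""Seed fan-out and coordinate helpers."""

from __future__ import annotations

import zlib

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    Hashes the stage name with CRC32 and mixes it with the master seed via a
    SeedSequence, so adding a stage never perturbs the streams of the others.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


def project_equirectangular(
    lat: np.ndarray, lon: np.ndarray, center: tuple[float, float] | None = None
) -> np.ndarray:
    """Project lat/lon (degrees) to planar x/y kilometres.

    Equirectangular projection about the centroid (or the given ``center``):
    adequate for study areas tens of kilometres across, where the projection
    error is far below the inter-lek distances of interest.
    Returns an (n, 2) array of (x_east, y_north) in km.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if center is None:
        center = (float(np.mean(lat)), float(np.mean(lon)))
    lat0, lon0 = np.radians(center[0]), np.radians(center[1])
    x = EARTH_RADIUS_KM * (np.radians(lon) - lon0) * np.cos(lat0)
    y = EARTH_RADIUS_KM * (np.radians(lat) - lat0)
    return np.column_stack([x, y])


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
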