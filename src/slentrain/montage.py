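"""Synthetic 128-channel sensor layout, sectors, ROIs and adjacency.

The layout is a Fibonacci spiral over the upper hemisphere of a sphere
(default radius 10 cm), a stand-in for a geodesic sensor net. It is
synthetic: channel indices do not correspond to any vendor's electrode
numbering, but the seven regions of interest (Central, Frontal L/R,
Occipital, Prefrontal, Temporal L/R) tile the head the way the ERP
analysis expects. Real net coordinates can be substituted via
``positions`` arguments everywhere they are consumed.

Axes: +x right, +y anterior, +z vertex.
"""

from __future__ import annotations

import json

import numpy as np

ROI_NAMES = (
    "Central",
    "Frontal L",
    "Frontal R",
    "Occipital",
    "Prefrontal",
    "Temporal L",
    "Temporal R",
)

HEAD_RADIUS_CM = 10.0


def make_montage(n_channels: int = 128, radius_cm: float = HEAD_RADIUS_CM) -> np.ndarray:
    """Channel positions (n_channels, 3) in cm on the upper hemisphere.

    Polar angles run from the vertex down to slightly below the equator,
    as high-density infant nets do.
    """
    k = np.arange(n_channels)
    # cos(theta) from ~1 down to -0.10 (just below the equator rim)
    cos_t = 1.0 - 1.10 * (k + 0.5) / n_channels
    theta = np.arccos(np.clip(cos_t, -1, 1))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    x = radius_cm * np.sin(theta) * np.sin(phi)
    y = radius_cm * np.sin(theta) * np.cos(phi)
    z = radius_cm * np.cos(theta)
    return np.column_stack([x, y, z])


def roi_labels(positions: np.ndarray) -> np.ndarray:
    """Assign each channel to one of the seven named ROIs (disjoint, exhaustive)."""
    x, y, z = positions.T
    r = np.linalg.norm(positions, axis=1)
    theta = np.degrees(np.arccos(np.clip(z / r, -1, 1)))  # 0 = vertex
    az = np.degrees(np.arctan2(x, y))  # 0 = anterior, +right, ±180 posterior

    labels = np.empty(len(positions), dtype=object)
    for i in range(len(positions)):
        t, a = theta[i], az[i]
        if t <= 35:
            labels[i] = "Central"
        elif abs(a) <= 60:
            if t >= 70 and abs(a) <= 35:
                labels[i] = "Prefrontal"
            else:
                labels[i] = "Frontal R" if x[i] > 0 else "Frontal L"
        elif abs(a) >= 125:
            labels[i] = "Occipital"
        else:
            labels[i] = "Temporal R" if x[i] > 0 else "Temporal L"
    return labels


def default_rois(positions: np.ndarray) -> dict[str, np.ndarray]:
    """Seven named ROIs as channel-index arrays (disjoint)."""
    labels = roi_labels(positions)
    return {name: np.flatnonzero(labels == name) for name in ROI_NAMES}


def adjacency(positions: np.ndarray, max_dist_cm: float = 2.5) -> np.ndarray:
    """Boolean channel-adjacency matrix: centre-to-centre distance <= max_dist_cm."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = d <= max_dist_cm
    np.fill_diagonal(adj, False)
    return adj


def gaussian_topography(
    positions: np.ndarray, centre: np.ndarray, fwhm_cm: float = 8.0
) -> np.ndarray:
    """Smooth unit-peak gain map centred on a scalp location."""
    sigma = fwhm_cm / 2.3548
    d2 = np.sum((positions - np.asarray(centre)) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma**2))


def rois_to_json(rois: dict[str, np.ndarray]) -> str:
    return json.dumps({k: list(map(int, v)) for k, v in rois.items()}, indent=1)


def rois_from_json(text: str) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=int) for k, v in json.loads(text).items()}
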