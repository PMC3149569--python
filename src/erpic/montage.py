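"""Electrode montages on the unit sphere.

The pipeline works with averaged ERPs recorded with a 19-channel cap placed
according to the international 10-20 system.  Channel positions are only used
to impose spatial smoothness on synthetic source topographies, so idealized
spherical coordinates are sufficient (no individual head geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Channel order used throughout the package (10-20 system, 19 channels).
STANDARD_1020_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# Idealized spherical coordinates (colatitude from vertex, azimuth from the
# right pre-auricular axis, counter-clockwise; nasion at +90 deg).
_SPHERICAL: dict[str, tuple[float, float]] = {
    "Fp1": (90, 108), "Fp2": (90, 72),
    "F7": (90, 144), "F8": (90, 36),
    "T3": (90, 180), "T4": (90, 0),
    "T5": (90, 216), "T6": (90, -36),
    "O1": (90, 252), "O2": (90, -72),
    "F3": (54, 129), "Fz": (45, 90), "F4": (54, 51),
    "C3": (45, 180), "Cz": (0, 0), "C4": (45, 0),
    "P3": (54, 231), "Pz": (45, -90), "P4": (54, -51),
}


def _sph_to_cart(colat_deg: float, az_deg: float) -> np.ndarray:
    colat = np.deg2rad(colat_deg)
    az = np.deg2rad(az_deg)
    return np.array(
        [np.sin(colat) * np.cos(az), np.sin(colat) * np.sin(az), np.cos(colat)]
    )


@dataclass(frozen=True)
class Montage:
    """An ordered set of scalp electrodes with unit-sphere positions.

    Parameters
    ----------
    labels
        Channel names, unique, in recording order.
    positions
        Array of shape ``(n_channels, 3)``; normalized to unit norm on
        construction.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 3):
            raise InvalidParameterError(
                f"positions must have shape ({len(labels)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise InvalidParameterError("positions must be non-zero")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos / norms[:, None])

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Channel index of ``label``; raises ``InvalidParameterError`` if absent."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise InvalidParameterError(f"unknown channel label {label!r}") from None

    def distances(self) -> np.ndarray:
        """Pairwise chord distances between electrode positions."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)


def standard_1020() -> Montage:
    """The default 19-channel 10-20 montage."""
    pos = np.stack([_sph_to_cart(*_SPHERICAL[ch]) for ch in STANDARD_1020_LABELS])
    return Montage(STANDARD_1020_LABELS, pos)
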