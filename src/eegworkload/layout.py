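"""Electrode layout for a 31-channel 10-20/10-10 montage.

Positions live on an idealized unit sphere with the head-centred frame
``x`` toward the right preauricular point, ``y`` toward the nasion and
``z`` toward the vertex.  The classic 10-20 sites sit on exact arcs of
that sphere; the intermediate 10-10 sites (FC*, CP*, POz) are spherical
interpolations of their neighbours, which is how they are defined on an
idealized head anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelLayout", "make_layout", "MIRROR_PAIRS"]

#: Left/right homologous electrode pairs (midline sites map to themselves).
MIRROR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"),
    ("F7", "F8"),
    ("F3", "F4"),
    ("FC5", "FC6"),
    ("FC1", "FC2"),
    ("T7", "T8"),
    ("C3", "C4"),
    ("CP5", "CP6"),
    ("CP1", "CP2"),
    ("P7", "P8"),
    ("P3", "P4"),
    ("O1", "O2"),
)

_MIDLINE = ("Fpz", "Fz", "Cz", "CPz", "Pz", "POz", "Oz")


@dataclass(frozen=True)
class ChannelLayout:
    """Named scalp electrodes with unit-sphere 3D positions."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows
    montage_name: str = "standard-10-20-31ch"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must be unit-norm")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mirror_indices(self) -> np.ndarray:
        """Channel permutation that swaps left and right hemispheres."""
        mapping = {n: n for n in _MIDLINE}
        for left, right in MIRROR_PAIRS:
            mapping[left] = right
            mapping[right] = left
        return np.array([self.names.index(mapping[n]) for n in self.names])


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector from inclination (from vertex) and azimuth (from nasion,
    positive toward the right ear, seen from above)."""
    incl = np.deg2rad(incl_deg)
    az = np.deg2rad(az_deg)
    return np.array(
        [np.sin(incl) * np.sin(az), np.sin(incl) * np.cos(az), np.cos(incl)]
    )


def _mid(*vecs: np.ndarray) -> np.ndarray:
    v = np.sum(vecs, axis=0)
    return v / np.linalg.norm(v)


def make_layout() -> ChannelLayout:
    """Build the 31-channel montage used throughout the package."""
    p: dict[str, np.ndarray] = {}
    # Equatorial ring (10% line), inclination 90 deg.
    for name, az in [
        ("Fpz", 0), ("Fp1", -18), ("Fp2", 18),
        ("F7", -54), ("F8", 54),
        ("T7", -90), ("T8", 90),
        ("P7", -126), ("P8", 126),
        ("O1", -162), ("O2", 162), ("Oz", 180),
    ]:
        p[name] = _sph(90, az)
    # Midline and central coronal 10-20 sites.
    p["Cz"] = _sph(0, 0)
    p["Fz"] = _sph(45, 0)
    p["Pz"] = _sph(45, 180)
    p["C3"] = _sph(45, -90)
    p["C4"] = _sph(45, 90)
    # 10-20 sites defined as arc midpoints.
    p["F3"] = _mid(p["Fz"], p["F7"])
    p["F4"] = _mid(p["Fz"], p["F8"])
    p["P3"] = _mid(p["Pz"], p["P7"])
    p["P4"] = _mid(p["Pz"], p["P8"])
    # 10-10 intermediates as spherical interpolations of neighbours.
    p["FC1"] = _mid(p["Fz"], p["Cz"], p["C3"])
    p["FC2"] = _mid(p["Fz"], p["Cz"], p["C4"])
    p["FC5"] = _mid(p["F7"], p["T7"], p["C3"])
    p["FC6"] = _mid(p["F8"], p["T8"], p["C4"])
    p["CP1"] = _mid(p["Pz"], p["Cz"], p["C3"])
    p["CP2"] = _mid(p["Pz"], p["Cz"], p["C4"])
    p["CP5"] = _mid(p["P7"], p["T7"], p["C3"])
    p["CP6"] = _mid(p["P8"], p["T8"], p["C4"])
    p["CPz"] = _mid(p["Cz"], p["Pz"])
    p["POz"] = _mid(p["Pz"], p["Oz"])

    names = (
        "Fp1", "Fp2", "Fpz", "F7", "F8", "F3", "F4", "Fz",
        "FC5", "FC6", "FC1", "FC2", "T7", "T8", "C3", "C4", "Cz",
        "CP5", "CP6", "CP1", "CP2", "CPz", "P7", "P8", "P3", "P4",
        "Pz", "POz", "O1", "O2", "Oz",
    )
    positions = np.stack([p[n] for n in names])
    return ChannelLayout(names=names, positions=positions)
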