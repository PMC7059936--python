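"""List-mode Compton event containers, detector geometry, and event file I/O.

A Compton event is one scatter–absorption coincidence: interaction
position and deposited energy E1 in the Si scatterer, plus interaction
position and deposited energy E2 in one of the CdTe absorber layers.
Events are kept in list mode (ordered, one record per coincidence);
the order is load-bearing — ordered-subset partitioning and the SOE
Markov chain sweep both key off it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ComptonEvent",
    "EventList",
    "DetectorSpec",
    "read_events",
    "write_events",
]

_COLUMNS = ["sx", "sy", "sz", "ax", "ay", "az", "e1", "e2"]


@dataclass(frozen=True)
class ComptonEvent:
    """One list-mode coincidence (positions in mm, energies in keV)."""

    scatter_pos: tuple[float, float, float]
    absorber_pos: tuple[float, float, float]
    e1: float
    e2: float

    def __post_init__(self) -> None:
        if self.e1 <= 0 or self.e2 <= 0:
            raise ValueError("deposited energies must be positive")
        if tuple(self.scatter_pos) == tuple(self.absorber_pos):
            raise ValueError("scatter and absorber positions must differ")
        if self.absorber_pos[2] >= 0:
            raise ValueError("absorber position must lie behind the scatterer plane (z < 0)")

    @property
    def e_sum(self) -> float:
        return self.e1 + self.e2


class EventList:
    """Ordered list-mode event set, stored columnar for vector operations.

    Attributes
    ----------
    scatter, absorber : (n, 3) float arrays, mm
    e1, e2 : (n,) float arrays, keV
    source_energy : assumed photo-peak energy of the source, keV
    """

    def __init__(
        self,
        scatter: np.ndarray,
        absorber: np.ndarray,
        e1: np.ndarray,
        e2: np.ndarray,
        source_energy: float = 511.0,
    ) -> None:
        self.scatter = np.atleast_2d(np.asarray(scatter, dtype=float))
        self.absorber = np.atleast_2d(np.asarray(absorber, dtype=float))
        self.e1 = np.atleast_1d(np.asarray(e1, dtype=float))
        self.e2 = np.atleast_1d(np.asarray(e2, dtype=float))
        self.source_energy = float(source_energy)
        n = len(self.e1)
        if not (self.scatter.shape == (n, 3) and self.absorber.shape == (n, 3) and self.e2.shape == (n,)):
            raise ValueError("inconsistent event array shapes")

    @classmethod
    def from_events(cls, events: list[ComptonEvent], source_energy: float = 511.0) -> "EventList":
        return cls(
            np.array([e.scatter_pos for e in events], dtype=float).reshape(-1, 3),
            np.array([e.absorber_pos for e in events], dtype=float).reshape(-1, 3),
            np.array([e.e1 for e in events], dtype=float),
            np.array([e.e2 for e in events], dtype=float),
            source_energy,
        )

    def __len__(self) -> int:
        return len(self.e1)

    def __getitem__(self, i: int) -> ComptonEvent:
        return ComptonEvent(
            tuple(self.scatter[i]), tuple(self.absorber[i]), float(self.e1[i]), float(self.e2[i])
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def e_sum(self) -> np.ndarray:
        return self.e1 + self.e2

    def select(self, mask: np.ndarray) -> "EventList":
        """Subset by boolean mask or index array; order preserved."""
        return EventList(
            self.scatter[mask], self.absorber[mask], self.e1[mask], self.e2[mask],
            self.source_energy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sx": self.scatter[:, 0], "sy": self.scatter[:, 1], "sz": self.scatter[:, 2],
                "ax": self.absorber[:, 0], "ay": self.absorber[:, 1], "az": self.absorber[:, 2],
                "e1": self.e1, "e2": self.e2,
            }
        )


@dataclass(frozen=True)
class DetectorSpec:
    """Geometry of the Si-scatterer / stacked-CdTe Compton camera.

    One 32 x 32 mm^2 double-sided Si strip detector (128 strips per side)
    backed by three CdTe layers of the same active area; thicknesses
    500 um (Si) and 750 um (CdTe) with 4 mm gaps between facing surfaces.
    The Si centre is the coordinate origin.
    """

    active_extent: float = 32.0  # mm, square side
    n_strips: int = 128
    si_thickness: float = 0.5  # mm
    cdte_thickness: float = 0.75  # mm
    layer_gap: float = 4.0  # mm, between facing surfaces
    n_absorber_layers: int = 3

    @property
    def strip_pitch(self) -> float:
        return self.active_extent / self.n_strips

    @property
    def half_extent(self) -> float:
        return self.active_extent / 2.0

    def absorber_layer_z(self) -> np.ndarray:
        """z of absorber layer centres (strictly decreasing).

        First gap is measured from the Si bottom surface to the first CdTe
        top surface, subsequent gaps between CdTe faces: centres at
        -(si/2 + gap + cdte/2) - k*(cdte + gap).
        """
        z0 = -(self.si_thickness / 2.0 + self.layer_gap + self.cdte_thickness / 2.0)
        step = self.cdte_thickness + self.layer_gap
        return z0 - step * np.arange(self.n_absorber_layers)

    def strip_centers(self) -> np.ndarray:
        """Strip-centre coordinates along one axis (length n_strips)."""
        p = self.strip_pitch
        return -self.half_extent + (np.arange(self.n_strips) + 0.5) * p

    def snap_to_strips(self, xy: np.ndarray) -> np.ndarray:
        """Quantize transverse coordinates to the nearest strip centre."""
        p = self.strip_pitch
        idx = np.clip(np.floor((xy + self.half_extent) / p), 0, self.n_strips - 1)
        return -self.half_extent + (idx + 0.5) * p


# ---------------------------------------------------------------------------
# event file I/O
#
# Text format: header `sx sy sz ax ay az e1 e2`, tab- or comma-separated,
# one event per row, positions in mm, energies in keV. A Parquet container
# with the same column names is accepted for large lists.


class EventParseError(ValueError):
    pass


def _validate_frame(df: pd.DataFrame, path: Path) -> None:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise EventParseError(f"{path}: missing columns {missing}")
    for col in _COLUMNS:
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise EventParseError(f"{path}: non-numeric value in column '{col}' at data row {row}")
    for col in ("e1", "e2"):
        bad = df[col].to_numpy(dtype=float) <= 0
        if bad.any():
            row = int(np.argmax(bad))
            raise EventParseError(f"{path}: non-positive energy '{col}' at data row {row}")


def read_events(path: str | Path, source_energy: float = 511.0) -> EventList:
    """Read a list-mode event file (text or .parquet); file order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing: pandas' default float reader is off by 1 ulp
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        df.columns = [c.strip() for c in df.columns]
    _validate_frame(df, path)
    return EventList(
        df[["sx", "sy", "sz"]].to_numpy(dtype=float),
        df[["ax", "ay", "az"]].to_numpy(dtype=float),
        df["e1"].to_numpy(dtype=float),
        df["e2"].to_numpy(dtype=float),
        source_energy,
    )


def write_events(events: EventList, path: str | Path) -> None:
    """Write events losslessly (17 significant digits in text mode)."""
    path = Path(path)
    df = events.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        # %.17g round-trips doubles exactly
        np.savetxt(
            path, df.to_numpy(), fmt="%.17g", delimiter="\t",
            header="\t".join(df.columns), comments="",
        )
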