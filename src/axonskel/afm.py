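"""AFM force-indentation analysis.

Closed-form force-indentation power laws for a blunt conical indenter
(semi-included angle 20 deg, 20 nm tip radius) pressing into a neo-Hookean
body, as fitted by finite-element analysis:

* thin-walled cylinder (axon/dendrite geometry, 10 nm wall):
  ``F = 4.41e-3 * E * d**1.37``
* rectangular cuboid (soma geometry): ``F = 7.95e-3 * E * d**1.46``

with d in nm, E in kPa, F in pN.  The prefactor is linear in E, so fitting
a measured curve reduces to one linear least-squares coefficient; grids of
fits are summarised by their median, as in force-map practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

GEOMETRIES = {
    "thin_cylinder": (4.41e-3, 1.37),
    "cuboid": (7.95e-3, 1.46),
}


def predict_force(E_kPa: float, d_nm, geometry: str):
    """Predicted force (pN) at indentation d (nm) for Young's modulus E (kPa)."""
    try:
        amp, alpha = GEOMETRIES[geometry]
    except KeyError:
        raise ValueError(
            f"unknown geometry {geometry!r}; expected one of {sorted(GEOMETRIES)}"
        ) from None
    return amp * E_kPa * np.asarray(d_nm, float) ** alpha


@dataclass
class ForceCurve:
    """One indentation record: d (nm, increasing) and F (pN)."""

    d_nm: np.ndarray
    F_pN: np.ndarray
    geometry: str = "thin_cylinder"
    E_kPa: float | None = None
    residual: float | None = None

    def __post_init__(self):
        self.d_nm = np.asarray(self.d_nm, float)
        self.F_pN = np.asarray(self.F_pN, float)
        if self.d_nm.shape != self.F_pN.shape:
            raise ValueError("d and F must have the same length")
        if np.any(self.d_nm < 0):
            raise ValueError("indentation must be non-negative")


def fit_modulus(
    curve: ForceCurve,
    geometry: str | None = None,
    d_window_nm: tuple[float, float] = (0.0, 100.0),
) -> float:
    """Least-squares Young's modulus with the exponent fixed by geometry.

    Only points with d inside ``d_window_nm`` (default the first 100 nm of
    indentation) enter the fit.  The fitted E and RMS residual are stored on
    the curve and E (kPa) returned.
    """
    geometry = geometry or curve.geometry
    amp, alpha = GEOMETRIES[geometry]
    d, F = curve.d_nm, curve.F_pN
    if np.any(np.diff(d) <= 0):
        raise ValueError("indentation values must be strictly increasing")
    m = (d >= d_window_nm[0]) & (d <= d_window_nm[1])
    if m.sum() < 10:
        raise ValueError(f"only {int(m.sum())} points in the fit window; need >= 10")
    if not np.any(F[m] != 0):
        raise ValueError("all-zero force curve")
    basis = amp * d[m] ** alpha
    E = float(np.dot(F[m], basis) / np.dot(basis, basis))
    curve.geometry = geometry
    curve.E_kPa = E
    curve.residual = float(np.sqrt(np.mean((F[m] - E * basis) ** 2)))
    return E


@dataclass
class GridSummary:
    median_kPa: float
    spread_kPa: float            # robust: 1.4826 * MAD
    bin_edges_kPa: np.ndarray
    frequency_percent: np.ndarray
    n_curves: int


def summarize_grid(fits, bins: int = 20) -> GridSummary:
    """Median +/- robust spread and a percentage histogram of fitted moduli.

    ``fits`` may be an iterable of fitted :class:`ForceCurve` or of floats.
    """
    values = np.asarray(
        [c.E_kPa if isinstance(c, ForceCurve) else float(c) for c in fits], float
    )
    if values.size == 0:
        raise ValueError("no fitted curves to summarise")
    if np.any(np.isnan(values)):
        raise ValueError("unfitted curve in the grid (E is None)")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    counts, edges = np.histogram(values, bins=bins)
    return GridSummary(
        median_kPa=med,
        spread_kPa=1.4826 * mad,
        bin_edges_kPa=edges,
        frequency_percent=100.0 * counts / values.size,
        n_curves=values.size,
    )


# ---------------------------------------------------------------------------
# two-column text I/O
# ---------------------------------------------------------------------------


def read_curve(path: str | Path, geometry: str = "thin_cylinder") -> ForceCurve:
    """Read a two-column (d in nm, F in pN) delimited text file with header."""
    data = np.loadtxt(path, skiprows=1, delimiter=None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two numeric columns (d_nm, F_pN)")
    return ForceCurve(data[:, 0], data[:, 1], geometry=geometry)


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    header = "d_nm\tF_pN"
    np.savetxt(path, np.column_stack([curve.d_nm, curve.F_pN]),
               header=header, comments="", delimiter="\t")
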