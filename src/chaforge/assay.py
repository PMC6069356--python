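"""Assay quantification: signal transduction, calibration and detection limit.

The assembled H1:H2 duplex carries a quadruplex-forming tail at each end, so
signal is modelled as an affine (linear + background) function of duplex
concentration with 2 signalling quadruplexes per duplex by default. The
calibration follows the assay's log-linear law

    Y = a * lg X + b

(Y signal, X target concentration in nM, lg = log10), fitted by ordinary
least squares on per-concentration replicate means, with blanks (X = 0)
excluded. The limit of detection uses the 3*sigma/S rule, sigma being the
blank standard deviation and S the calibration slope. Because the slope is
per *decade* of concentration, the literal quotient is in decades; the
inversion form maps the signal F0 + 3*sigma back through the calibration to
a concentration. Both are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReadoutTable",
    "CalibrationFit",
    "BlankStats",
    "LimitOfDetection",
    "signal_from_species",
    "delta_f",
    "f_over_f0",
    "fit_log_linear",
    "predict_signal",
    "lod_3sigma",
]

_COLUMNS = ["concentration_nM", "replicate", "signal", "channel"]


@dataclass
class ReadoutTable:
    """Replicate signal readings per target concentration.

    Columns: ``concentration_nM`` (0 marks a blank), ``replicate``,
    ``signal`` (arbitrary units), ``channel`` (fluorescence | absorbance).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"readout table missing columns {missing}")
        if (self.data["concentration_nM"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        channels = self.data["channel"].unique()
        if len(channels) > 1:
            raise ValueError(f"mixed channels in one table: {list(channels)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReadoutTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def blanks(self) -> np.ndarray:
        return self.data.loc[
            self.data["concentration_nM"] == 0, "signal"
        ].to_numpy()

    def replicate_means(self) -> pd.DataFrame:
        return (
            self.data[self.data["concentration_nM"] > 0]
            .groupby("concentration_nM", as_index=False)["signal"]
            .mean()
        )


@dataclass(frozen=True)
class CalibrationFit:
    """Log-linear calibration Y = slope * lg X + intercept."""

    slope: float
    intercept: float
    r: float
    residual_sd: float
    x_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class BlankStats:
    """Blank-signal statistics used by the detection-limit rule."""

    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, values) -> "BlankStats":
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError("need >= 2 blank readings for a standard deviation")
        return cls(float(values.mean()), float(values.std(ddof=1)), int(values.size))


@dataclass(frozen=True)
class LimitOfDetection:
    """Both readings of the 3*sigma/S rule for a lg-scale calibration."""

    decades: float  # literal 3*sigma / slope (slope is signal per decade)
    concentration_nM: float  # signal F0 + 3*sigma inverted through the fit


def signal_from_species(
    duplex_conc: float,
    hairpin_conc: float = 0.0,
    gain: float = 1.0,
    per_duplex_g4: float = 2.0,
    background: float = 0.0,
    leak_weight: float = 0.0,
) -> float:
    """Affine transduction of species concentrations to optical signal.

    Each assembled duplex carries ``per_duplex_g4`` signalling quadruplexes
    (default 2, one at each end); free hairpins may contribute weakly via
    ``leak_weight``. Superposition holds exactly.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if duplex_conc < 0 or hairpin_conc < 0:
        raise ValueError("concentrations must be >= 0")
    return gain * (per_duplex_g4 * duplex_conc + leak_weight * hairpin_conc) + background


def delta_f(F: float, F0: float) -> float:
    """Signal change over blank, dF = F - F0."""
    return F - F0


def f_over_f0(F: float, F0: float) -> float:
    """Signal-to-noise ratio F / F0."""
    if F0 <= 0:
        raise ValueError("F0 must be positive for the F/F0 ratio")
    return F / F0


def fit_log_linear(
    readouts: ReadoutTable,
    x_range: tuple[float, float] | None = None,
    per_replicate: bool = False,
) -> CalibrationFit:
    """Ordinary least squares of signal on lg(concentration).

    By default the regression runs on per-concentration replicate means (the
    way calibration points with error bars are presented); set
    ``per_replicate`` to fit all individual readings. Blanks are excluded;
    a zero or negative concentration inside ``x_range`` is a domain error.
    """
    if per_replicate:
        df = readouts.data[readouts.data["concentration_nM"] > 0][
            ["concentration_nM", "signal"]
        ]
    else:
        df = readouts.replicate_means()
    if x_range is not None:
        lo, hi = x_range
        if lo <= 0:
            raise ValueError("calibration range must be strictly positive")
        df = df[(df["concentration_nM"] >= lo) & (df["concentration_nM"] <= hi)]
    x = df["concentration_nM"].to_numpy(dtype=float)
    y = df["signal"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct positive concentrations to fit")
    lg = np.log10(x)
    res = stats.linregress(lg, y)
    fitted = res.slope * lg + res.intercept
    dof = len(x) - 2
    resid_sd = float(np.sqrt(np.sum((y - fitted) ** 2) / dof)) if dof > 0 else 0.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        residual_sd=resid_sd,
        x_range=(float(x.min()), float(x.max())),
        n_points=int(len(x)),
    )


def predict_signal(fit: CalibrationFit, concentration_nM: float) -> float:
    """Y = slope * lg X + intercept; X must be positive."""
    if concentration_nM <= 0:
        raise ValueError("concentration must be positive on a lg scale")
    return fit.slope * math.log10(concentration_nM) + fit.intercept


def lod_3sigma(blanks: BlankStats, fit: CalibrationFit) -> LimitOfDetection:
    """Limit of detection by the 3*sigma/S rule.

    ``decades`` is the literal quotient (the slope is signal per decade of
    concentration); ``concentration_nM`` inverts the calibration at the
    decision level F0 + 3*sigma.
    """
    if fit.slope == 0:
        raise ValueError("degenerate fit: slope is zero")
    decades = 3.0 * blanks.sd / abs(fit.slope)
    conc = 10.0 ** (
        (blanks.mean + 3.0 * blanks.sd - fit.intercept) / fit.slope
    )
    return LimitOfDetection(decades=float(decades), concentration_nM=float(conc))
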