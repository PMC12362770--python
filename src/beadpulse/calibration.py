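"""Four-parameter logistic (4PL) calibration and limit of detection.

The assay readout for a sample is the normalised mean peak area F1/F0.  A
sigmoidal 4PL curve is fitted to (concentration, ratio) replicates,

    y(x) = d0 + (dmax - d0) / (1 + (c50 / x) ** b),        y(0) = d0,

with lower asymptote d0, upper asymptote dmax, midpoint c50 (pM) and slope
factor b; the increasing form (b > 0) is strictly monotone in x, so it has a
closed-form inverse on (d0, dmax) used to read concentrations back from
ratios.  The limit of detection follows the 3.3-sigma convention,

    LOD = 3.3 * SD_blank / S,

where SD_blank is the standard deviation of blank-replicate ratios and S a
calibration slope.  Where on the curve that slope is taken is a convention;
by default S is the ordinary least-squares slope through the blank and the
two lowest non-zero concentrations (the region where the LOD lives), with
the 4PL derivative at c50 available as an alternative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "CalibrationData",
    "CalibrationModel",
    "four_pl",
    "fit_4pl",
    "invert",
    "lod",
]


def four_pl(x, d0, dmax, c50, b):
    """Increasing 4PL curve; continuous extension y(0) = d0."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, d0, dtype=float)
    pos = x > 0
    out[pos] = d0 + (dmax - d0) / (1.0 + (c50 / x[pos]) ** b)
    return out


@dataclass
class CalibrationData:
    """Replicate (concentration, signal-ratio) measurements for one analyte."""

    analyte: str
    concentrations: np.ndarray  # pM, one entry per replicate measurement
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations.shape != self.ratios.shape or self.concentrations.ndim != 1:
            raise ValueError("concentrations and ratios must be 1-D arrays of equal length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> dict[str, "CalibrationData"]:
        """Split a tidy table (analyte, concentration_pM, ratio) per analyte."""
        required = {"analyte", "concentration_pM", "ratio"}
        if not required.issubset(table.columns):
            raise ValueError(f"calibration table needs columns {sorted(required)}")
        out = {}
        for analyte, grp in table.groupby("analyte"):
            out[str(analyte)] = cls(
                analyte=str(analyte),
                concentrations=grp["concentration_pM"].to_numpy(float),
                ratios=grp["ratio"].to_numpy(float),
            )
        return out


@dataclass
class CalibrationModel:
    """Fitted 4PL parameters plus blank SD, low-range slope and LOD."""

    analyte: str
    d0: float
    dmax: float
    c50: float
    b: float
    blank_sd: float = math.nan
    lin_slope: float = math.nan  # signal-ratio per pM
    lod_pM: float = math.nan
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.d0, self.dmax, self.c50, self.b)

    def invert(self, ratio: float) -> tuple[float, str]:
        """Closed-form inverse; returns (concentration_pM, flag).

        Flags: ``ok`` inside the open response range, ``below_range`` for
        ratios at or below d0 (mapped to 0 pM), ``saturated`` for ratios at
        or above dmax (mapped to +inf's stand-in, NaN).
        """
        if ratio <= self.d0:
            return 0.0, "below_range"
        if ratio >= self.dmax:
            return math.nan, "saturated"
        conc = self.c50 * ((ratio - self.d0) / (self.dmax - ratio)) ** (1.0 / self.b)
        return float(conc), "ok"

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def fit_4pl(data: CalibrationData, lod_slope_mode: str = "low_range") -> CalibrationModel:
    """Least-squares 4PL fit of replicate (concentration, ratio) data.

    Requires >= 4 distinct concentrations.  The blank SD is computed from
    replicates at 0 pM (NaN when fewer than 2); the LOD slope S is either the
    OLS slope through the blank and two lowest non-zero concentrations
    (``low_range``, default) or the 4PL derivative at c50 (``c50``).

    Raises on non-convergence with the initial-guess report in the message;
    an essentially flat response is fitted but flagged ``degenerate``.
    """
    x, y = data.concentrations, data.ratios
    distinct = np.unique(x)
    if len(distinct) < 4:
        raise ValueError(
            f"4PL fit needs >= 4 distinct concentrations, got {len(distinct)}"
        )

    pos = distinct[distinct > 0]
    guess = {
        "d0": float(np.min(y)),
        "delta": float(max(np.max(y) - np.min(y), 1e-12)),
        "c50": float(np.median(pos)),
        "b": 1.0,
    }

    def model_fn(x, d0, delta, c50, b):
        return four_pl(x, d0, d0 + delta, c50, b)

    model = Model(model_fn)
    params = model.make_params(
        d0=guess["d0"],
        delta=dict(value=guess["delta"], min=0.0),
        c50=dict(value=guess["c50"], min=1e-6 * max(guess["c50"], 1.0)),
        b=dict(value=guess["b"], min=0.05, max=50.0),
    )
    result = model.fit(y, params, x=x)
    if not result.success:
        raise RuntimeError(
            f"4PL fit for {data.analyte!r} did not converge "
            f"(initial guesses {guess}): {result.message}"
        )

    d0 = float(result.params["d0"].value)
    delta = float(result.params["delta"].value)
    c50 = float(result.params["c50"].value)
    b = float(result.params["b"].value)
    scale = max(1.0, float(np.max(np.abs(y))))
    degenerate = bool(delta < 1e-6 * scale or float(np.ptp(y)) == 0.0)

    blanks = y[x == 0]
    blank_sd = float(np.std(blanks, ddof=1)) if len(blanks) >= 2 else math.nan

    if lod_slope_mode == "low_range":
        low = np.sort(pos)[:2]
        mask = (x == 0) | np.isin(x, low)
        lin_slope = float(np.polyfit(x[mask], y[mask], 1)[0]) if mask.sum() >= 2 else math.nan
    elif lod_slope_mode == "c50":
        # d/dx of the 4PL at x = c50 is b * (dmax - d0) / (4 * c50).
        lin_slope = b * delta / (4.0 * c50)
    else:
        raise ValueError(f"unknown lod_slope_mode {lod_slope_mode!r}")

    lod_pM = (
        lod(blank_sd, lin_slope)
        if (not math.isnan(blank_sd) and not math.isnan(lin_slope) and lin_slope > 0)
        else math.nan
    )

    return CalibrationModel(
        analyte=data.analyte,
        d0=d0,
        dmax=d0 + delta,
        c50=c50,
        b=b,
        blank_sd=blank_sd,
        lin_slope=lin_slope,
        lod_pM=lod_pM,
        degenerate=degenerate,
        diagnostics={
            "success": bool(result.success),
            "redchi": float(result.redchi) if result.redchi is not None else math.nan,
            "nfev": int(result.nfev),
            "initial_guess": guess,
        },
    )


def invert(model: CalibrationModel, ratio: float) -> tuple[float, str]:
    """Module-level convenience wrapper for :meth:`CalibrationModel.invert`."""
    return model.invert(ratio)


def lod(blank_sd: float, S: float) -> float:
    """Limit of detection, 3.3 * SD / S (pM when S is ratio per pM)."""
    if S <= 0:
        raise ValueError(f"calibration slope S must be > 0, got {S!r}")
    if blank_sd < 0:
        raise ValueError("blank SD must be >= 0")
    return 3.3 * blank_sd / S
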