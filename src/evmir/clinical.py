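"""Clinical derived measures used in the correlation analyses.

K_FFA — the rate of free-fatty-acid disappearance during an IVGTT: the
ordinary least-squares slope of ln(FFA) on time over the 19–40 minute
window, multiplied by −100 (units %/min).  Adipo-IR — the adipose-tissue
insulin-resistance index: fasting FFA (mmol/L) × fasting insulin (pmol/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FfaSeries", "k_ffa", "adipo_ir", "clinical_indices_table"]

KFFA_WINDOW = (19.0, 40.0)


@dataclass
class FfaSeries:
    """FFA concentration time course for one subject-visit.

    ``time`` in minutes (strictly increasing), ``ffa`` in mmol/L (> 0,
    a logarithm is taken).
    """

    time: np.ndarray
    ffa: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ffa = np.asarray(self.ffa, dtype=float)
        if self.time.shape != self.ffa.shape:
            raise ValueError("time and ffa must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.ffa <= 0):
            raise ValueError("FFA concentrations must be positive")


def k_ffa(series: FfaSeries, window: tuple[float, float] = KFFA_WINDOW) -> float:
    """FFA disappearance rate: −100 × OLS slope of ln(FFA) vs time.

    Window endpoints are inclusive; points outside never enter the fit.
    Returns NaN when fewer than two points fall in the window.
    """
    lo, hi = window
    mask = (series.time >= lo) & (series.time <= hi)
    if mask.sum() < 2:
        return float("nan")
    t = series.time[mask]
    y = np.log(series.ffa[mask])
    slope = np.polyfit(t, y, 1)[0]
    return float(-100.0 * slope)


def adipo_ir(ffa_fasting: float, insulin_fasting: float) -> float:
    """Adipose insulin-resistance index: fasting FFA × fasting insulin."""
    if ffa_fasting < 0 or insulin_fasting < 0:
        raise ValueError("fasting concentrations must be nonnegative")
    return float(ffa_fasting * insulin_fasting)


def clinical_indices_table(ffa_curves: pd.DataFrame,
                           fasting: pd.DataFrame) -> pd.DataFrame:
    """Per subject-visit K_FFA and Adipo-IR.

    ``ffa_curves``: columns subject_id, visit, time_min, ffa_mmol_l.
    ``fasting``: columns subject_id, visit, ffa_fasting, insulin_fasting.
    """
    rows = []
    for (subj, visit), grp in ffa_curves.groupby(["subject_id", "visit"]):
        grp = grp.sort_values("time_min")
        try:
            series = FfaSeries(grp["time_min"].to_numpy(),
                               grp["ffa_mmol_l"].to_numpy())
            k = k_ffa(series)
            note = "" if np.isfinite(k) else "fewer than 2 points in window"
        except ValueError as exc:
            k, note = float("nan"), str(exc)
        rows.append((subj, visit, k, note))
    kf = pd.DataFrame(rows, columns=["subject_id", "visit", "k_ffa", "note"])
    fa = fasting.copy()
    fa["adipo_ir"] = [adipo_ir(f, i) for f, i in
                      zip(fa["ffa_fasting"], fa["insulin_fasting"])]
    out = kf.merge(fa[["subject_id", "visit", "adipo_ir"]],
                   on=["subject_id", "visit"], how="outer")
    return out.sort_values(["subject_id", "visit"]).reset_index(drop=True)
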