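"""Short-chain fatty acid (SCFA) calibration, quantification and association.

GC-MS peak areas are converted to concentrations through a per-acid linear
standard curve (area regressed on concentration over a dilution series,
classically 1-200 μg/ml). Back-calculated concentrations below zero are
clipped to zero and flagged; values below the lowest calibration level are
flagged as below the limit of quantification (LOQ) but reported.

Group comparison uses a two-sample t-test per acid (Welch by default) and
species-SCFA association uses Pearson correlation with the two-sided
t-distribution p-value on n-2 degrees of freedom, pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, DataError
from .profile_io import AbundanceTable, SampleMetadata

#: the seven acids of the panel, in reporting order
ACIDS = (
    "acetic",
    "propanoic",
    "butyric",
    "isobutyric",
    "n_valeric",
    "isovaleric",
    "caproic",
)

#: classical calibration dilution series, μg/ml
STANDARD_LEVELS = (1.0, 2.0, 5.0, 10.0, 50.0, 100.0, 200.0)


@dataclass
class StandardCurve:
    """Linear calibration of peak area on concentration for one acid."""

    acid: str
    concentrations: np.ndarray
    areas: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def back_calculate(self, area) -> np.ndarray:
        if self.slope == 0:
            raise CalibrationError(f"{self.acid}: zero calibration slope")
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope

    @property
    def loq(self) -> float:
        """Lowest calibrated concentration; values below it are extrapolations."""
        return float(np.min(self.concentrations))


@dataclass
class SCFAPanel:
    """Per-sample SCFA concentrations in μg/ml, with clipping/LOQ flags."""

    data: pd.DataFrame  # samples x acids
    clipped: pd.DataFrame | None = None  # True where a negative value was clipped to 0
    below_loq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("panel concentrations must be >= 0 (clip before wrapping)")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def acids(self) -> list[str]:
        return list(self.data.columns)


def fit_standard_curve(points: pd.DataFrame | None = None, acid: str = "", concentrations=None, areas=None) -> StandardCurve:
    """Ordinary least-squares fit of peak area on concentration.

    ``points`` may be a DataFrame with ``concentration`` and ``area``
    columns, or the two arrays can be passed directly. Duplicate calibration
    points are legitimate replicates and enter the fit individually.
    """
    if points is not None:
        concentrations = points["concentration"].to_numpy(dtype=float)
        areas = points["area"].to_numpy(dtype=float)
        acid = acid or str(points.get("acid", pd.Series([""])).iloc[0])
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise CalibrationError("need at least two distinct concentration levels")
    res = stats.linregress(conc, area)
    return StandardCurve(
        acid=acid,
        concentrations=conc,
        areas=area,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify(areas: pd.DataFrame, curves: dict[str, StandardCurve]) -> SCFAPanel:
    """Back-calculate concentrations from peak areas through the standard curves.

    ``areas`` is samples x acids; every acid column needs a fitted curve.
    Negative back-calculations are clipped to 0 and flagged; concentrations
    below the curve's lowest calibration level are flagged below-LOQ.
    """
    missing = [a for a in areas.columns if a not in curves]
    if missing:
        raise CalibrationError(f"no standard curve for acid(s): {missing}")
    conc = pd.DataFrame(index=areas.index, columns=areas.columns, dtype=float)
    for acid in areas.columns:
        conc[acid] = curves[acid].back_calculate(areas[acid].to_numpy())
    clipped = conc < 0
    loq = pd.DataFrame(
        {a: conc[a] < curves[a].loq for a in areas.columns}, index=areas.index
    )
    return SCFAPanel(conc.clip(lower=0.0), clipped=clipped, below_loq=loq)


def compare_groups(
    panel: SCFAPanel, metadata: SampleMetadata, equal_var: bool = False
) -> pd.DataFrame:
    """Two-sample t-test per acid between case and control (Welch by default)."""
    case = [s for s in metadata.case_ids() if s in panel.data.index]
    control = [s for s in metadata.control_ids() if s in panel.data.index]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least two samples for a t-test")
    rows = []
    for acid in panel.acids:
        x = panel.data.loc[case, acid].to_numpy(dtype=float)
        y = panel.data.loc[control, acid].to_numpy(dtype=float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append(
            {
                "acid": acid,
                "t": float(t),
                "p": float(p),
                "mean_case": float(x.mean()),
                "mean_control": float(y.mean()),
                "sd_case": float(x.std(ddof=1)),
                "sd_control": float(y.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("acid")


def species_scfa_correlation(
    taxa: AbundanceTable,
    panel: SCFAPanel,
    min_pairs: int = 3,
    adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of species abundance against acid concentrations.

    Pairwise-complete over shared samples; two-sided p from the
    t-distribution with n-2 df. Zero-variance columns give NaN. With
    ``adjust`` the p matrix is BH-adjusted across all species x acid pairs.
    """
    common = [s for s in taxa.samples if s in panel.data.index]
    if len(common) < min_pairs:
        raise DataError("fewer than min_pairs shared samples")
    r = pd.DataFrame(np.nan, index=taxa.features, columns=panel.acids)
    p = pd.DataFrame(np.nan, index=taxa.features, columns=panel.acids)
    for species in taxa.features:
        sv = taxa.data.loc[species, common].to_numpy(dtype=float)
        for acid in panel.acids:
            av = panel.data.loc[common, acid].to_numpy(dtype=float)
            mask = ~(np.isnan(sv) | np.isnan(av))
            if mask.sum() < min_pairs:
                continue
            a, b = sv[mask], av[mask]
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            rr, pp = stats.pearsonr(a, b)
            r.loc[species, acid] = rr
            p.loc[species, acid] = pp
    if adjust:
        from .diffabund import bh_adjust

        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full(flat.shape, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(flat[ok])
        p = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return r, p
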