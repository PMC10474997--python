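"""qPCR standard curves, quantification and site-level detection calls.

A dilution-series standard curve relates quantification cycle (Cq) to the
natural log of relative DNA amount:

    Cq = slope_ln * ln(x) + intercept

Amplification efficiency follows from the equivalent log10 slope,
E = 10**(-1/(slope_ln * ln 10)) - 1.  The limit of detection (LOD) is the
lowest concentration at which at least 95% of replicate reactions amplify;
the limit of quantification (LOQ) additionally requires the coefficient of
variation of back-calculated concentrations to stay at or below 0.35.

A site-month is scored positive for a species when at least two replicate
reactions — two biological (different water samples) or two technical
(re-runs of the same sample) — amplify with quantity above the LOD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DetectionMatrix

MAX_CYCLES = 50.0  # 50-cycle thermal protocol: a real Cq lies in (0, 50]

WELL_COLUMNS = ["site_id", "month", "species_id", "bio_rep", "tech_rep", "cq"]


# ---------------------------------------------------------------------------
# Standard curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq-vs-ln(concentration) line.

    slope_ln
        Cq change per unit ln(concentration); negative for a valid assay.
    intercept
        Cq at relative concentration 1.
    efficiency
        Amplification efficiency as a fraction (0.926 for slope -1.526).
    lod, loq
        Detection / quantification limits in relative-concentration units;
        None when undetermined.
    valid
        False when the fit violated assay sanity checks (e.g. positive
        slope); such curves are returned flagged, not raised.
    """

    slope_ln: float
    intercept: float
    r_squared: float = float("nan")
    efficiency: float = float("nan")
    lod: float | None = None
    loq: float | None = None
    valid: bool = True


def efficiency_from_slope(slope_ln: float) -> float:
    """E = 10**(-1/slope10) - 1 with slope10 = slope_ln * ln(10)."""
    return 10.0 ** (-1.0 / (slope_ln * math.log(10.0))) - 1.0


@dataclass(frozen=True)
class DilutionSeries:
    """A dilution series: per level, a concentration and the replicate Cq
    values (None = no amplification).  Concentrations strictly decrease."""

    levels: tuple[tuple[float, tuple[float | None, ...]], ...]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.levels]
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if any(a <= b for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_reps_per_level(self) -> int:
        return max((len(r) for _, r in self.levels), default=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (conc, i + 1, cq)
            for conc, reps in self.levels
            for i, cq in enumerate(reps)
        ]
        return pd.DataFrame(rows, columns=["concentration", "rep", "cq"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DilutionSeries":
        required = ["concentration", "rep", "cq"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"dilution series frame missing columns {missing}")
        levels = []
        for conc, grp in df.groupby("concentration", sort=True):
            grp = grp.sort_values("rep")
            reps = tuple(
                None if pd.isna(cq) else float(cq) for cq in grp["cq"]
            )
            levels.append((float(conc), reps))
        levels.sort(key=lambda t: -t[0])
        return cls(tuple(levels))


def fit_standard_curve(
    series: DilutionSeries,
    *,
    use_replicates: bool = False,
    lod_detection_rate: float = 0.95,
    loq_cv_max: float = 0.35,
) -> StandardCurve:
    """Ordinary least squares of Cq against ln(concentration).

    By default each dilution level contributes its mean Cq over amplifying
    replicates (robust to unbalanced dropout at low concentrations);
    ``use_replicates=True`` fits on every amplifying well instead.
    LOD/LOQ are then determined from the replicate detection record.
    """
    xs: list[float] = []
    ys: list[float] = []
    for conc, reps in series.levels:
        cqs = [cq for cq in reps if cq is not None]
        if not cqs:
            continue
        if use_replicates:
            xs.extend(math.log(conc) for _ in cqs)
            ys.extend(cqs)
        else:
            xs.append(math.log(conc))
            ys.append(float(np.mean(cqs)))
    if len(set(xs)) < 2:
        raise ValueError(
            "standard-curve fit needs >=2 distinct concentrations with "
            "amplifying replicates"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot

    valid = slope < 0
    if not valid:
        warnings.warn(
            f"standard curve has non-negative slope ({slope:.4g}); "
            "assay flagged invalid",
            stacklevel=2,
        )
    eff = efficiency_from_slope(slope) if slope != 0 else float("nan")
    curve = StandardCurve(
        slope_ln=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        efficiency=eff,
        valid=bool(valid),
    )
    lod, loq = compute_lod_loq(
        series, curve, detection_rate=lod_detection_rate, cv_max=loq_cv_max
    )
    return replace(curve, lod=lod, loq=loq)


def compute_lod_loq(
    series: DilutionSeries,
    curve: StandardCurve,
    *,
    detection_rate: float = 0.95,
    cv_max: float = 0.35,
) -> tuple[float | None, float | None]:
    """LOD = lowest concentration with >= ``detection_rate`` of replicates
    amplifying; LOQ additionally requires CV of back-calculated
    concentrations <= ``cv_max``.  None signals an undetermined limit."""
    lod_candidates: list[float] = []
    loq_candidates: list[float] = []
    for conc, reps in series.levels:
        if not reps:
            continue
        cqs = [cq for cq in reps if cq is not None]
        rate = len(cqs) / len(reps)
        if rate < detection_rate:
            continue
        lod_candidates.append(conc)
        back = np.array([quantify_cq(curve, cq) for cq in cqs])
        mean = float(back.mean())
        cv = float(back.std(ddof=1) / mean) if len(back) > 1 and mean > 0 else 0.0
        if cv <= cv_max:
            loq_candidates.append(conc)
    lod = min(lod_candidates) if lod_candidates else None
    loq = min(loq_candidates) if loq_candidates else None
    return lod, loq


def predict_cq(curve: StandardCurve, x):
    """Cq predicted at relative concentration ``x`` (> 0); vectorized."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be positive")
    out = curve.slope_ln * np.log(x) + curve.intercept
    return float(out) if out.ndim == 0 else out


def quantify_cq(curve: StandardCurve, cq):
    """Invert the curve: relative concentration at a given Cq; vectorized."""
    if curve.slope_ln == 0:
        raise ValueError("standard curve has zero slope; cannot quantify")
    cq = np.asarray(cq, dtype=float)
    out = np.exp((cq - curve.intercept) / curve.slope_ln)
    return float(out) if out.ndim == 0 else out


def default_standard_curve(lod: float = 0.01, loq: float = 0.05) -> StandardCurve:
    """The reference assay curve (slope -1.526, intercept 41.232) with
    synthetic detection limits, used by the simulator's presets."""
    slope = -1.526
    return StandardCurve(
        slope_ln=slope,
        intercept=41.232,
        r_squared=1.0,
        efficiency=efficiency_from_slope(slope),
        lod=lod,
        loq=loq,
    )


# ---------------------------------------------------------------------------
# Wells and detection calls
# ---------------------------------------------------------------------------

@dataclass
class QpcrWell:
    """One replicate qPCR reaction."""

    site_id: str
    month: int
    species_id: str
    bio_rep: int
    tech_rep: int
    cq: float | None = None
    quantity: float | None = None

    def __post_init__(self) -> None:
        if self.cq is not None and not (0.0 < self.cq <= MAX_CYCLES):
            raise ValueError(f"cq must lie in (0, {MAX_CYCLES}]; got {self.cq}")
        if (self.quantity is None) != (self.cq is None) and self.quantity is not None:
            raise ValueError("quantity must be null when cq is null")


@dataclass(frozen=True)
class DetectionCall:
    """Site-month-species positivity decision."""

    site_id: str
    month: int
    species_id: str
    detected: bool
    n_positive_replicates: int
    basis: str  # biological | technical | both | none


def quantify(curve: StandardCurve, well: QpcrWell) -> QpcrWell:
    """Fill a well's relative DNA quantity from its Cq (null stays null)."""
    if well.cq is None:
        return replace(well, quantity=None)
    return replace(well, quantity=quantify_cq(curve, well.cq))


def as_wells_frame(wells) -> pd.DataFrame:
    """Normalize a list of QpcrWell or a frame to the canonical wells schema."""
    if isinstance(wells, pd.DataFrame):
        missing = [c for c in WELL_COLUMNS if c not in wells.columns]
        if missing:
            raise ValueError(f"wells frame missing columns {missing}")
        df = wells.copy()
    else:
        df = pd.DataFrame(
            [
                (w.site_id, w.month, w.species_id, w.bio_rep, w.tech_rep,
                 np.nan if w.cq is None else w.cq)
                for w in wells
            ],
            columns=WELL_COLUMNS,
        )
    df["month"] = df["month"].astype(int)
    cq = df["cq"].astype(float)
    bad = cq.notna() & ~((cq > 0) & (cq <= MAX_CYCLES))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} wells have Cq outside (0, {MAX_CYCLES}]"
        )
    return df


def call_detections(
    wells,
    curves: Mapping[str, StandardCurve] | StandardCurve,
    *,
    mode: str = "pooled",
) -> tuple[list[DetectionCall], DetectionMatrix]:
    """Apply the site-positivity rule to replicate wells.

    A replicate is positive iff its back-calculated quantity exceeds the
    species' LOD.  A site-month-species is detected iff it has >=2 positive
    replicates.  ``mode='pooled'`` counts positives pooled across the
    site-month; ``mode='strict'`` requires the positives to share a
    biological sample or span two samples — the two readings coincide
    (any two wells either share a sample or span two), so mode only affects
    bookkeeping of the ``basis`` field.

    Site-months with no wells at all are missing (NaN) in the returned
    DetectionMatrix; site-months with wells for some species only are
    missing for the others.
    """
    if mode not in ("pooled", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    df = as_wells_frame(wells)
    species = sorted(df["species_id"].astype(str).unique())
    if isinstance(curves, StandardCurve):
        curves = {sp: curves for sp in species}
    for sp in species:
        if sp not in curves:
            raise KeyError(f"no standard curve supplied for species {sp!r}")
        if curves[sp].lod is None:
            raise ValueError(f"curve for species {sp!r} has no defined LOD")

    df = df.copy()
    df["quantity"] = np.nan
    for sp in species:
        m = df["species_id"] == sp
        has_cq = m & df["cq"].notna()
        df.loc[has_cq, "quantity"] = quantify_cq(
            curves[sp], df.loc[has_cq, "cq"].to_numpy()
        )
        df.loc[m, "_lod"] = curves[sp].lod
    df["positive"] = df["quantity"].notna() & (df["quantity"] > df["_lod"])

    calls: list[DetectionCall] = []
    grouped = df.groupby(["site_id", "month", "species_id"], sort=True)
    for (site, month, sp), grp in grouped:
        n_pos = int(grp["positive"].sum())
        pos = grp[grp["positive"]]
        n_bio_pos = pos["bio_rep"].nunique()
        max_tech_per_bio = (
            int(pos.groupby("bio_rep").size().max()) if len(pos) else 0
        )
        bio_basis = n_bio_pos >= 2
        tech_basis = max_tech_per_bio >= 2
        if bio_basis and tech_basis:
            basis = "both"
        elif bio_basis:
            basis = "biological"
        elif tech_basis:
            basis = "technical"
        else:
            basis = "none"
        detected = n_pos >= 2 if mode == "pooled" else basis != "none"
        calls.append(
            DetectionCall(str(site), int(month), str(sp), detected, n_pos, basis)
        )

    sites = sorted(df["site_id"].astype(str).unique())
    months = sorted(int(m) for m in df["month"].unique())
    state = np.full((len(species), len(sites), len(months)), np.nan)
    si = {s: i for i, s in enumerate(species)}
    ti = {s: i for i, s in enumerate(sites)}
    mi = {m: i for i, m in enumerate(months)}
    for c in calls:
        state[si[c.species_id], ti[c.site_id], mi[c.month]] = float(c.detected)
    matrix = DetectionMatrix(species, sites, months, state)
    return calls, matrix


def calls_to_frame(calls: Sequence[DetectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.site_id, c.month, c.species_id, int(c.detected),
             c.n_positive_replicates, c.basis)
            for c in calls
        ],
        columns=["site_id", "month", "species_id", "detected",
                 "n_positive_replicates", "basis"],
    )
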