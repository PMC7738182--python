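"""Growth-inhibition dose-response analysis and EC50 estimation.

Bacterial cultures are challenged with a dilution series of drug (typically
1.5-fold steps); growth is read as the OD600 increase over the incubation
relative to an unchallenged control well, giving percent inhibition per
concentration. The EC50 is estimated by least-squares fitting of the
four-parameter variable-slope logistic

    y = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 x) * hill))

in log10-concentration space. Technical-replicate fits are averaged within
each biological replicate, and biological replicates averaged to the final
EC50 mean/SD/n that feeds the fitness landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "percent_inhibition",
    "four_pl",
    "fit_4pl",
    "fit_plate",
    "read_plate",
    "ec50_summary",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """One inhibition curve: concentrations (uM) and % inhibition responses."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    genotype: str = ""
    bio_rep: str | int = 0
    tech_rep: str | int = 0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        resp = tuple(float(r) for r in self.responses)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses differ in length")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        if len(set(conc)) != len(conc):
            raise ValueError("concentrations must be distinct")
        if any(not math.isfinite(r) for r in resp):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class FourPLFit:
    """Fitted four-parameter logistic with convergence diagnostics.

    ``converged`` is False when the optimiser failed; ``ec50_in_range``
    is False when the fitted EC50 falls outside the tested concentration
    span; ``plateaus_in_range`` is False when the fitted plateaus lie far
    outside the observed responses (the degenerate fit a plateau-free,
    monotone curve produces). Flagged fits are reported, never silently
    trusted.
    """

    bottom: float
    top: float
    log_ec50: float
    hill: float
    rss: float
    converged: bool
    ec50_in_range: bool
    plateaus_in_range: bool = True

    @property
    def ec50(self) -> float:
        return 10.0**self.log_ec50

    @property
    def ok(self) -> bool:
        return self.converged and self.ec50_in_range and self.plateaus_in_range


def percent_inhibition(delta_od_challenged: float, delta_od_control: float) -> float:
    """Percent growth inhibition from OD600 gains of challenged vs control wells.

    Each delta is OD600(post-challenge) - OD600(pre-challenge). Inhibition
    is 100 * (1 - challenged/control): 0% when growth matches the control,
    100% when the challenged well did not grow at all. A control that did
    not grow means the assay failed and is rejected.
    """
    if not delta_od_control > 0:
        raise ValueError(
            f"control well did not grow (delta OD = {delta_od_control}); assay failure"
        )
    return 100.0 * (1.0 - delta_od_challenged / delta_od_control)


def four_pl(x: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    """Variable-slope logistic response at concentrations x (linear scale)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - np.log10(x)) * hill))


def fit_4pl(curve: DoseResponseCurve, constrain: bool = False) -> FourPLFit:
    """Least-squares fit of the four-parameter logistic to one curve.

    Initialisation is deterministic: top = max response, bottom = min
    response, hill = 1, logEC50 = log10 of the concentration whose response
    lies nearest the half-way point. ``constrain`` bounds the plateaus to
    [0, 100]% (off by default, as unconstrained fitting matches common
    practice).
    """
    x = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 distinct concentrations to fit, got {len(x)}")
    order = np.argsort(x)
    x, y = x[order], y[order]
    top0, bottom0 = float(y.max()), float(y.min())
    if top0 == bottom0:
        top0 = bottom0 + 1.0
    half = (top0 + bottom0) / 2.0
    log_ec50_0 = float(np.log10(x[np.argmin(np.abs(y - half))]))
    p0 = [bottom0, top0, log_ec50_0, 1.0]
    if constrain:
        bounds = ([0.0, 0.0, -np.inf, -np.inf], [100.0, 100.0, np.inf, np.inf])
        p0[0] = min(max(p0[0], 0.0), 100.0)
        p0[1] = min(max(p0[1], 0.0), 100.0)
    else:
        bounds = (-np.inf, np.inf)
    try:
        popt, _ = curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=10000)
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        popt = np.array(p0, dtype=float)
        converged = False
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    rss = float(np.sum((y - four_pl(x, *popt)) ** 2))
    in_range = bool(np.log10(x.min()) <= log_ec50 <= np.log10(x.max()))
    # plateaus wildly outside the observed responses mean the asymptotes were
    # never approached within the tested range (e.g. monotone, plateau-free data)
    span = float(y.max() - y.min()) or 1.0
    margin = 0.5 * span
    plateaus_ok = bool(
        min(bottom, top) >= y.min() - margin and max(bottom, top) <= y.max() + margin
    )
    return FourPLFit(
        bottom=bottom,
        top=top,
        log_ec50=log_ec50,
        hill=hill,
        rss=rss,
        converged=converged,
        ec50_in_range=in_range,
        plateaus_in_range=plateaus_ok,
    )


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate CSV (``genotype,bio_rep,tech_rep,conc_uM,od_pre,od_4h,is_control``)
    and compute percent inhibition per challenged well.

    Each (genotype, bio_rep, tech_rep) group must contain at least one
    zero-drug control well; its OD gain (averaged if several) is the
    denominator for that group's challenged wells.
    """
    df = pd.read_csv(path)
    required = {"genotype", "bio_rep", "tech_rep", "conc_uM", "od_pre", "od_4h", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate CSV missing columns {sorted(missing)}")
    df = df.copy()
    df["delta_od"] = df["od_4h"] - df["od_pre"]
    df["is_control"] = df["is_control"].astype(bool)
    rows = []
    for (genotype, bio, tech), grp in df.groupby(["genotype", "bio_rep", "tech_rep"]):
        controls = grp[grp["is_control"]]
        if controls.empty:
            raise ValueError(f"{path}: no control well for ({genotype}, {bio}, {tech})")
        control_delta = float(controls["delta_od"].mean())
        for _, well in grp[~grp["is_control"]].iterrows():
            rows.append(
                {
                    "genotype": genotype,
                    "bio_rep": bio,
                    "tech_rep": tech,
                    "conc_uM": float(well["conc_uM"]),
                    "inhibition": percent_inhibition(float(well["delta_od"]), control_delta),
                }
            )
    return pd.DataFrame(rows)


def fit_plate(inhibition: pd.DataFrame, constrain: bool = False) -> pd.DataFrame:
    """Fit one 4PL per (genotype, bio_rep, tech_rep) curve.

    Input is the long table from :func:`read_plate`. Returns one row per
    fit with the EC50 and diagnostic flags.
    """
    rows = []
    for (genotype, bio, tech), grp in inhibition.groupby(["genotype", "bio_rep", "tech_rep"]):
        curve = DoseResponseCurve(
            concentrations=tuple(grp["conc_uM"]),
            responses=tuple(grp["inhibition"]),
            genotype=str(genotype),
            bio_rep=bio,
            tech_rep=tech,
        )
        fit = fit_4pl(curve, constrain=constrain)
        rows.append(
            {
                "genotype": genotype,
                "bio_rep": bio,
                "tech_rep": tech,
                "ec50_uM": fit.ec50,
                "hill": fit.hill,
                "converged": fit.converged,
                "ec50_in_range": fit.ec50_in_range,
                "plateaus_in_range": fit.plateaus_in_range,
            }
        )
    return pd.DataFrame(rows)


def ec50_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-fit EC50s to per-genotype mean, SD and replicate count.

    Technical replicates are averaged first within each biological
    replicate; the summary statistics are then taken across biological
    replicates (sample SD; 0 with a single replicate, flagged by n=1).
    """
    required = {"genotype", "bio_rep", "ec50_uM"}
    if not required.issubset(fits.columns):
        raise ValueError(f"fit table needs columns {sorted(required)}")
    per_bio = (
        fits.groupby(["genotype", "bio_rep"])["ec50_uM"].mean().reset_index()
    )
    rows = []
    for genotype, grp in per_bio.groupby("genotype"):
        vals = grp["ec50_uM"].to_numpy(dtype=float)
        rows.append(
            {
                "genotype": genotype,
                "ec50_mean_uM": float(vals.mean()),
                "ec50_sd_uM": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows, columns=["genotype", "ec50_mean_uM", "ec50_sd_uM", "n"])
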