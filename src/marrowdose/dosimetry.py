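"""Internal dosimetry: time–activity curves to residence times and RM dose.

Follows the MIRD schema as applied with OLINDA/EXM-style S values:

* Cumulated activity concentration: trapezoidal integration of the measured
  time–activity curve (TAC), plus a physical-decay tail after the last
  measurement, C(t_last)/lambda.  The unmeasured lead-in [0, t1] is covered
  by constant back-extrapolation by default (for a 1 h first scan and Zr-89
  kinetics this contributes well under 1 % of the integral).
* Residence time: tau = cumulated activity / injected activity (hours).
  For red marrow, the concentration integral is scaled by the reference
  red-marrow volume.
* Remainder of body closes the balance: tau_RB = T_half/ln2 - sum(tau_organ),
  the maximum possible residence time under physical decay alone minus what
  is assigned to explicit source organs.
* Dose: self RM dose = S(RM<-RM) * tau_RM; total adds every source organ and
  the remainder term, all in mGy/MBq.

The plasma comparator scales a plasma TAC by the fixed red-marrow-to-plasma
ratio 0.19.  The effective half-life of a region (physical decay plus
biological clearance) is fitted by least squares on the log-concentrations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError, InconsistencyError

__all__ = [
    "ZR89_HALF_LIFE_H",
    "RadionuclideConstants",
    "TimeActivityCurve",
    "ResidenceTimeSet",
    "SValueTable",
    "DoseReport",
    "cumulated_concentration",
    "residence_time",
    "remainder_residence",
    "scale_by_weight",
    "rm_dose",
    "plasma_rm_tac",
    "fit_effective_half_life",
    "extract_tac",
]

#: Physical half-life of Zr-89 in hours.
ZR89_HALF_LIFE_H = 78.41

#: Conventional fixed red-marrow-to-plasma activity concentration ratio.
RM_PLASMA_FACTOR = 0.19

BQ_PER_MBQ = 1.0e6


@dataclass(frozen=True)
class RadionuclideConstants:
    half_life_h: float = ZR89_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise DomainError("half-life must be > 0")

    @property
    def decay_constant_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    @property
    def max_residence_time_h(self) -> float:
        """Residence time of the whole injection under physical decay only."""
        return self.half_life_h / math.log(2.0)


@dataclass
class TimeActivityCurve:
    """(time h, activity concentration Bq/mL) samples for one source region."""

    region: str
    times_h: np.ndarray
    conc_Bq_per_mL: np.ndarray
    region_volume_mL: float = 1.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_Bq_per_mL = np.asarray(self.conc_Bq_per_mL, dtype=float)
        if self.times_h.shape != self.conc_Bq_per_mL.shape or self.times_h.ndim != 1:
            raise DataError("times and concentrations must be 1D arrays of equal length")
        if self.times_h.size and (np.any(self.times_h < 0) or np.any(np.diff(self.times_h) <= 0)):
            raise DataError("times must be non-negative and strictly increasing")
        if np.any(self.conc_Bq_per_mL < 0):
            raise DataError("activity concentrations must be >= 0")
        if self.region_volume_mL <= 0:
            raise DomainError("region volume must be > 0 mL")

    def __len__(self) -> int:
        return int(self.times_h.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "time_h": self.times_h,
                "conc_Bq_per_mL": self.conc_Bq_per_mL,
                "volume_mL": self.region_volume_mL,
            }
        )

    @classmethod
    def from_csv(cls, path: str | Path, region: str | None = None) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        if region is not None:
            df = df[df["region"] == region]
        elif "region" in df.columns:
            region = str(df["region"].iloc[0])
            df = df[df["region"] == region]
        df = df.sort_values("time_h")
        vol = float(df["volume_mL"].iloc[0]) if "volume_mL" in df.columns else 1.0
        return cls(
            region=region or "region",
            times_h=df["time_h"].to_numpy(),
            conc_Bq_per_mL=df["conc_Bq_per_mL"].to_numpy(),
            region_volume_mL=vol,
        )


@dataclass
class ResidenceTimeSet:
    """Per-source residence times (h) plus the remainder-of-body closure."""

    tau_h: dict[str, float]
    tau_remainder_h: float
    injected_MBq: float

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.tau_h.values()) or self.tau_remainder_h < 0:
            raise DomainError("residence times must be >= 0")
        if self.injected_MBq <= 0:
            raise DomainError("injected activity must be > 0")


@dataclass
class SValueTable:
    """Dose conversion factors S(target <- source) in mGy/(MBq h).

    S values and the reference anatomy (red-marrow volume, body weight) are
    user-supplied configuration: they come from tabulations such as
    OLINDA/EXM and are not computed here.  The table must contain at least
    the (RM, RM) self term and the (RM, RB) remainder-of-body term.
    """

    s_mGy_per_MBq_h: dict[tuple[str, str], float]
    reference_rm_volume_mL: float
    reference_body_weight_kg: float

    def __post_init__(self) -> None:
        if ("RM", "RM") not in self.s_mGy_per_MBq_h or ("RM", "RB") not in self.s_mGy_per_MBq_h:
            raise ConfigurationError("S-value table must contain (RM, RM) and (RM, RB) entries")
        if any(v < 0 for v in self.s_mGy_per_MBq_h.values()):
            raise ConfigurationError("S values must be >= 0")
        if self.reference_rm_volume_mL <= 0 or self.reference_body_weight_kg <= 0:
            raise ConfigurationError("reference RM volume and body weight must be > 0")

    def s(self, target: str, source: str) -> float:
        try:
            return self.s_mGy_per_MBq_h[(target, source)]
        except KeyError:
            raise ConfigurationError(f"missing S value for (target={target}, source={source})") from None

    @classmethod
    def from_json(cls, path: str | Path) -> "SValueTable":
        d = json.loads(Path(path).read_text())
        table = {(e["target"], e["source"]): float(e["value"]) for e in d["s_values"]}
        return cls(
            s_mGy_per_MBq_h=table,
            reference_rm_volume_mL=float(d["reference_rm_volume_mL"]),
            reference_body_weight_kg=float(d["reference_body_weight_kg"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "s_values": [
                        {"target": t, "source": s, "value": v}
                        for (t, s), v in self.s_mGy_per_MBq_h.items()
                    ],
                    "reference_rm_volume_mL": self.reference_rm_volume_mL,
                    "reference_body_weight_kg": self.reference_body_weight_kg,
                },
                indent=1,
            )
        )


def svalue_template() -> SValueTable:
    """A placeholder S-value table (unit S values, nominal reference anatomy).

    Real studies must replace these with tabulated values for the
    radionuclide and reference phantom in use; no published S values are
    bundled.
    """
    return SValueTable(
        s_mGy_per_MBq_h={("RM", "RM"): 1.0, ("RM", "RB"): 1.0},
        reference_rm_volume_mL=1120.0,
        reference_body_weight_kg=73.7,
    )


@dataclass
class DoseReport:
    self_rm_dose_mGy_per_MBq: float
    total_rm_dose_mGy_per_MBq: float
    contributions_mGy_per_MBq: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "self_rm_dose_mGy_per_MBq": self.self_rm_dose_mGy_per_MBq,
                    "total_rm_dose_mGy_per_MBq": self.total_rm_dose_mGy_per_MBq,
                    "contributions_mGy_per_MBq": self.contributions_mGy_per_MBq,
                },
                indent=1,
            )
        )


def cumulated_concentration(
    tac: TimeActivityCurve,
    rc: RadionuclideConstants | None = None,
    lead_in: str = "constant",
    tail: bool = True,
) -> float:
    """Time integral of the activity concentration, in Bq·h/mL.

    Trapezoidal rule over the samples, plus (i) a lead-in for the unmeasured
    interval [0, t1] — ``"constant"`` back-extrapolates C(t1) (default),
    ``"linear"`` ramps from zero, ``"none"`` excludes it — and (ii) an
    analytic physical-decay tail C(t_last)/lambda after the last sample
    (``tail=True``).
    """
    rc = rc or RadionuclideConstants()
    if len(tac) < 2:
        raise DataError("need at least two samples to integrate a TAC")
    t, c = tac.times_h, tac.conc_Bq_per_mL
    total = float(np.trapezoid(c, t))
    if t[0] > 0:
        if lead_in == "constant":
            total += float(c[0] * t[0])
        elif lead_in == "linear":
            total += float(0.5 * c[0] * t[0])
        elif lead_in != "none":
            raise DataError(f"unknown lead_in rule {lead_in!r}")
    if tail:
        total += float(c[-1]) / rc.decay_constant_per_h
    return total


def residence_time(cumc_Bq_h_per_mL: float, region_volume_mL: float, injected_MBq: float) -> float:
    """Residence time tau (h) = cumulated activity / injected activity.

    The cumulated concentration (Bq·h/mL) is converted to cumulated activity
    by the region volume (for red marrow, the reference RM volume) and to
    MBq·h before dividing by the injected activity.
    """
    if cumc_Bq_h_per_mL <= 0 or region_volume_mL <= 0 or injected_MBq <= 0:
        raise DomainError("cumulated concentration, volume and injected activity must be > 0")
    return cumc_Bq_h_per_mL * region_volume_mL / BQ_PER_MBQ / injected_MBq


def remainder_residence(
    taus: Mapping[str, float], rc: RadionuclideConstants | None = None
) -> float:
    """Remainder-of-body residence time closing the activity balance.

    The maximum possible residence time under physical decay alone is
    T_half/ln2; the remainder is that maximum minus the residence times
    already assigned to explicit source organs.
    """
    rc = rc or RadionuclideConstants()
    total = float(sum(taus.values()))
    max_tau = rc.max_residence_time_h
    if total > max_tau:
        raise InconsistencyError(
            f"source residence times sum to {total:.4f} h, exceeding the physical "
            f"maximum {max_tau:.4f} h by {total - max_tau:.4f} h"
        )
    return max_tau - total


def scale_by_weight(tau_h: float, patient_weight_kg: float, reference_weight_kg: float) -> float:
    """Scale a residence time to patient weight: tau * (reference / patient)."""
    if patient_weight_kg <= 0 or reference_weight_kg <= 0:
        raise DomainError("weights must be > 0 kg")
    return tau_h * (reference_weight_kg / patient_weight_kg)


def rm_dose(taus: ResidenceTimeSet, s: SValueTable) -> DoseReport:
    """Self and total red-marrow absorbed dose, mGy/MBq.

    self  = S(RM<-RM) * tau_RM
    total = sum over sources S(RM<-source) * tau_source + S(RM<-RB) * tau_RB
    """
    contributions: dict[str, float] = {}
    for source, tau in taus.tau_h.items():
        contributions[source] = s.s("RM", source) * tau
    contributions["RB"] = s.s("RM", "RB") * taus.tau_remainder_h
    self_dose = contributions.get("RM", 0.0)
    total = float(sum(contributions.values()))
    return DoseReport(
        self_rm_dose_mGy_per_MBq=self_dose,
        total_rm_dose_mGy_per_MBq=total,
        contributions_mGy_per_MBq=contributions,
    )


def plasma_rm_tac(plasma: TimeActivityCurve, factor: float = RM_PLASMA_FACTOR) -> TimeActivityCurve:
    """Plasma-based red-marrow TAC: plasma concentrations times a fixed ratio."""
    if factor <= 0:
        raise DomainError("plasma factor must be > 0")
    return TimeActivityCurve(
        region="RM-plasma-method",
        times_h=plasma.times_h.copy(),
        conc_Bq_per_mL=plasma.conc_Bq_per_mL * factor,
        region_volume_mL=plasma.region_volume_mL,
    )


def fit_effective_half_life(tac: TimeActivityCurve) -> float:
    """Mono-exponential effective half-life (h) by log-linear least squares.

    Fits ln C(t) = ln C0 - lambda_eff * t over all samples and returns
    ln2 / lambda_eff.  A non-decreasing curve (lambda_eff <= 0) returns
    ``inf`` with a warning rather than raising: it signals no measurable
    clearance within the sampled window.
    """
    if len(tac) < 2:
        raise DataError("need at least two samples to fit a half-life")
    if np.any(tac.conc_Bq_per_mL <= 0):
        raise DomainError("all concentrations must be > 0 for a log-linear fit")
    slope, _ = np.polyfit(tac.times_h, np.log(tac.conc_Bq_per_mL), 1)
    lam = -float(slope)
    if lam <= 1e-10:  # slower than ~8e9 h half-life: numerically no clearance
        warnings.warn(
            "fitted effective decay constant is <= 0 (no clearance): returning inf",
            stacklevel=2,
        )
        return math.inf
    return math.log(2.0) / lam


def extract_tac(mask, pet_series, region: str = "RM", region_volume_mL: float | None = None):
    """Build a TAC by sampling a mask over a PET time series.

    ``pet_series`` is a sequence of PET :class:`~marrowdose.imaging.ImageVolume`
    objects, each carrying ``time_post_injection_h``.  The region volume
    defaults to the mask volume.
    """
    from .voi import mean_concentration  # local import: avoids a cycle

    times, concs = [], []
    for pet in pet_series:
        if pet.time_post_injection_h is None:
            raise DataError("every PET volume needs time_post_injection_h")
        times.append(pet.time_post_injection_h)
        concs.append(mean_concentration(mask, pet))
    order = np.argsort(times)
    return TimeActivityCurve(
        region=region,
        times_h=np.asarray(times)[order],
        conc_Bq_per_mL=np.asarray(concs)[order],
        region_volume_mL=region_volume_mL if region_volume_mL is not None else mask.volume_mL,
    )
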