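"""FLIM-FRET derived quantities and per-ROI aggregation.

From a fitted two-species donor decay (unquenched donor UD, quenched donor
QD) this module computes:

* FLIM-FRET efficiency       E   = (tau_UD - tau_QD) / tau_UD
* apparent FRET efficiency   E_app = (I_QD / sum I) * E
* donor-acceptor binding     B%  = 100 * A_QD / (A_UQ + A_QD)
* donor-acceptor distance    r   = R0 * ((1 - E) / E)^(1/6)
* acceptor:donor ratio       A:D = acceptor intensity / donor intensity

E reports the donor-acceptor distance of the bound population only; B%
reports how much of the donor is bound; E_app mixes the two (it is what
intensity-based FRET measures).  Species intensities in E_app are taken as
I_i = A_i * tau_i, the steady-state intensity of an exponential species
(an amplitude-fraction variant is available via ``intensity_mode``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedBindingError
from .fitting import FitResult

__all__ = [
    "FORSTER_RADIUS_NM",
    "RoiMeasurement",
    "flim_fret_efficiency",
    "binding_ratio",
    "apparent_fret",
    "donor_acceptor_distance",
    "ad_ratio",
    "aggregate_roi",
    "measurement_from_components",
    "measurement_from_fit",
    "measurements_table",
]

#: Förster radius of the mNeonGreen / mRuby3 donor-acceptor pair, in nm.
FORSTER_RADIUS_NM = 6.417


@dataclass(frozen=True)
class RoiMeasurement:
    """Derived FRET quantities for one ROI (cell or compartment)."""

    roi_id: str
    condition: str
    compartment: str
    tau_ud_ns: float
    tau_qd_ns: Optional[float] = None
    efficiency_E: Optional[float] = None
    apparent_E: Optional[float] = None
    binding_pct: Optional[float] = None
    distance_r_nm: Optional[float] = None
    ad_ratio: Optional[float] = None
    qc_flags: tuple = ()

    @property
    def flagged(self) -> bool:
        return len(self.qc_flags) > 0


def flim_fret_efficiency(tau_ud: float, tau_qd: float) -> float:
    """FLIM-FRET efficiency E = 1 - tau_QD / tau_UD, clamped to [0, 1].

    Out-of-order lifetimes (tau_QD > tau_UD, possible from fit noise) clamp
    to 0; callers that need to know attach a qc flag.
    """
    if tau_ud <= 0:
        raise DomainError("tau_ud must be positive")
    if tau_qd < 0:
        raise DomainError("tau_qd must be non-negative")
    return float(np.clip(1.0 - tau_qd / tau_ud, 0.0, 1.0))


def binding_ratio(a_qd: float, a_uq: float) -> float:
    """Donor-acceptor binding ratio B% = 100 * A_QD / (A_UQ + A_QD)."""
    if a_qd < 0 or a_uq < 0:
        raise DomainError("amplitudes must be non-negative")
    total = a_qd + a_uq
    if total == 0:
        raise UndefinedBindingError("both donor-species amplitudes are zero")
    return 100.0 * a_qd / total


def apparent_fret(
    a_uq: float,
    a_qd: float,
    tau_ud: float,
    tau_qd: float,
    intensity_mode: str = "lifetime",
) -> float:
    """Apparent FRET efficiency E_app = (I_QD / sum I) * E.

    ``intensity_mode="lifetime"`` (default) uses species steady-state
    intensities I_i = A_i * tau_i; ``"amplitude"`` uses the raw amplitude
    fractions as a sensitivity variant.
    """
    e = flim_fret_efficiency(tau_ud, tau_qd)
    if intensity_mode == "lifetime":
        i_qd, i_uq = a_qd * tau_qd, a_uq * tau_ud
    elif intensity_mode == "amplitude":
        i_qd, i_uq = a_qd, a_uq
    else:
        raise DomainError(f"unknown intensity_mode {intensity_mode!r}")
    total = i_qd + i_uq
    if total == 0:
        raise UndefinedBindingError("both species intensities are zero")
    return float(i_qd / total * e)


def donor_acceptor_distance(
    efficiency_E: float, r0_nm: float = FORSTER_RADIUS_NM
) -> float:
    """Invert the sixth-power transfer law: r = R0 * ((1 - E) / E)^(1/6).

    E = 0 returns +inf and E = 1 returns 0.0 as sentinels (no finite
    distance); E outside [0, 1] is a domain error.
    """
    if r0_nm <= 0:
        raise DomainError("r0_nm must be positive")
    if not 0.0 <= efficiency_E <= 1.0:
        raise DomainError("efficiency_E must be in [0, 1]")
    if efficiency_E == 0.0:
        return float("inf")
    if efficiency_E == 1.0:
        return 0.0
    return float(r0_nm * ((1.0 - efficiency_E) / efficiency_E) ** (1.0 / 6.0))


def ad_ratio(acceptor_intensity: float, donor_intensity: float) -> float:
    """Acceptor-to-donor intensity ratio (expression-stoichiometry proxy)."""
    if donor_intensity <= 0:
        raise DomainError("donor_intensity must be positive")
    if acceptor_intensity < 0:
        raise DomainError("acceptor_intensity must be non-negative")
    return float(acceptor_intensity / donor_intensity)


def measurement_from_components(
    roi_id: str,
    condition: str,
    compartment: str,
    tau_ud_ns: float,
    tau_qd_ns: Optional[float],
    a_uq: float,
    a_qd: float,
    donor_intensity: Optional[float] = None,
    acceptor_intensity: Optional[float] = None,
    r0_nm: float = FORSTER_RADIUS_NM,
    intensity_mode: str = "lifetime",
    qc_flags: Sequence[str] = (),
) -> RoiMeasurement:
    """Assemble a RoiMeasurement from fitted decay components.

    Mono-exponential input (``tau_qd_ns`` None) means no quenched species
    was detectable: the binding ratio and apparent efficiency are 0 by the
    defining equations (A_QD = 0), while the FLIM-FRET efficiency and
    distance — properties of the bound population — stay absent.
    Out-of-range fitted values are clamped and qc-flagged, not dropped.
    """
    flags = list(qc_flags)
    ratio = None
    if donor_intensity is not None and donor_intensity > 0:
        ratio = ad_ratio(acceptor_intensity or 0.0, donor_intensity)

    if tau_qd_ns is None:
        return RoiMeasurement(
            roi_id=roi_id,
            condition=condition,
            compartment=compartment,
            tau_ud_ns=tau_ud_ns,
            binding_pct=0.0,
            apparent_E=0.0,
            ad_ratio=ratio,
            qc_flags=tuple(flags),
        )

    if tau_qd_ns > tau_ud_ns:
        flags.append("tau_order_clamped")
    e = flim_fret_efficiency(tau_ud_ns, tau_qd_ns)
    e_app = apparent_fret(a_uq, a_qd, tau_ud_ns, min(tau_qd_ns, tau_ud_ns), intensity_mode)
    b = binding_ratio(a_qd, a_uq)
    if e <= 0.0 or e >= 1.0:
        flags.append("distance_undefined")
    r = donor_acceptor_distance(e, r0_nm)
    return RoiMeasurement(
        roi_id=roi_id,
        condition=condition,
        compartment=compartment,
        tau_ud_ns=tau_ud_ns,
        tau_qd_ns=tau_qd_ns,
        efficiency_E=e,
        apparent_E=e_app,
        binding_pct=b,
        distance_r_nm=r,
        ad_ratio=ratio,
        qc_flags=tuple(flags),
    )


def measurement_from_fit(
    fit: FitResult,
    roi_id: str,
    condition: str,
    compartment: str = "whole_cell",
    donor_intensity: Optional[float] = None,
    acceptor_intensity: Optional[float] = None,
    r0_nm: float = FORSTER_RADIUS_NM,
    intensity_mode: str = "lifetime",
) -> RoiMeasurement:
    """Derive the FRET quantities of one ROI from its reconvolution fit."""
    flags = []
    if not fit.converged:
        flags.append("not_converged")
    if fit.degenerate:
        flags.append("degenerate_fit")
    if fit.at_bound:
        flags.append("at_bound")
    return measurement_from_components(
        roi_id=roi_id,
        condition=condition,
        compartment=compartment,
        tau_ud_ns=fit.tau_ud,
        tau_qd_ns=fit.tau_qd,
        a_uq=fit.a_uq,
        a_qd=fit.a_qd,
        donor_intensity=donor_intensity,
        acceptor_intensity=acceptor_intensity,
        r0_nm=r0_nm,
        intensity_mode=intensity_mode,
        qc_flags=flags,
    )


_NUMERIC_FIELDS = (
    "tau_ud_ns",
    "tau_qd_ns",
    "efficiency_E",
    "apparent_E",
    "binding_pct",
    "distance_r_nm",
    "ad_ratio",
)


def aggregate_roi(measurements: Sequence[RoiMeasurement]) -> RoiMeasurement:
    """Average repeated acquisitions of the same ROI into one measurement.

    Each metric is the arithmetic mean over the acquisitions where it is
    present; qc flags are unioned.
    """
    if not measurements:
        raise ValueError("aggregate_roi requires at least one measurement")
    first = measurements[0]
    if any(m.roi_id != first.roi_id for m in measurements):
        raise ValueError("aggregate_roi mixes different ROI ids")
    means = {}
    for name in _NUMERIC_FIELDS:
        vals = [getattr(m, name) for m in measurements if getattr(m, name) is not None]
        means[name] = float(np.mean(vals)) if vals else None
    flags = tuple(sorted({f for m in measurements for f in m.qc_flags}))
    return RoiMeasurement(
        roi_id=first.roi_id,
        condition=first.condition,
        compartment=first.compartment,
        qc_flags=flags,
        **means,
    )


def measurements_table(measurements: Iterable[RoiMeasurement]) -> pd.DataFrame:
    """Tidy per-ROI metrics table, one row per ROI, sorted for determinism."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "roi_id": m.roi_id,
                "condition": m.condition,
                "compartment": m.compartment,
                "tau_ud_ns": m.tau_ud_ns,
                "tau_qd_ns": m.tau_qd_ns,
                "efficiency_E": m.efficiency_E,
                "apparent_E": m.apparent_E,
                "binding_pct": m.binding_pct,
                "distance_r_nm": m.distance_r_nm,
                "ad_ratio": m.ad_ratio,
                "qc_flags": ";".join(m.qc_flags),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["condition", "compartment", "roi_id"]).reset_index(drop=True)
    return df
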