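"""Binding-titration analysis: 1:1 isotherm fits, binding check, assay utilities.

Thermophoresis-style titrations report a normalised signal R against
ligand concentration [L].  The model is the one-site law of mass action

    R([L]) = r_free + (r_bound − r_free) · [L] / (Kd + [L])

fitted by bounded nonlinear least squares over (Kd, r_free, r_bound).
A Hill coefficient is deliberately not fitted: with ≤ 16 points a fourth
parameter is overparameterised and the single-Kd readout implies one site.

Concentration units are nM throughout; the response is in arbitrary units
and may be affinely rescaled without affecting the fitted Kd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingSeries",
    "BindingFit",
    "isotherm",
    "fit_binding_isotherm",
    "binding_check",
    "tumor_volume",
    "read_titration",
]


@dataclass(frozen=True)
class BindingSeries:
    """Paired (concentration, response) titration data.

    Concentrations are nM, strictly positive and strictly increasing;
    at least 4 points are required for the 3-parameter fit.
    """

    ligand_conc: tuple[float, ...]
    response: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.ligand_conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if conc.size != resp.size:
            raise ValueError("concentration and response lengths differ")
        if conc.size < 4:
            raise ValueError(f"need ≥ 4 titration points, got {conc.size}")
        if not np.all(conc > 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(resp))):
            raise ValueError("non-finite values in titration data")

    @classmethod
    def from_arrays(cls, conc: Sequence[float], resp: Sequence[float]) -> "BindingSeries":
        return cls(tuple(float(c) for c in conc), tuple(float(r) for r in resp))

    @property
    def conc(self) -> np.ndarray:
        return np.asarray(self.ligand_conc, dtype=float)

    @property
    def resp(self) -> np.ndarray:
        return np.asarray(self.response, dtype=float)


@dataclass
class BindingFit:
    """Fitted 1:1 isotherm: Kd (nM), plateaus, residuals and verdict."""

    kd: float | None
    r_free: float
    r_bound: float
    rss: float
    kd_ci: tuple[float, float] | None
    binds: bool
    residual_sd: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def amplitude(self) -> float:
        return abs(self.r_bound - self.r_free)

    def to_json(self, dest: str | Path) -> None:
        payload = {
            "kd_nM": self.kd,
            "kd_ci95_nM": list(self.kd_ci) if self.kd_ci else None,
            "r_free": self.r_free,
            "r_bound": self.r_bound,
            "rss": self.rss,
            "residual_sd": self.residual_sd,
            "binds": self.binds,
            **self.provenance,
        }
        Path(dest).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def isotherm(conc, kd: float, r_free: float, r_bound: float):
    """One-site binding curve R([L]) = r_free + (r_bound − r_free)·[L]/(Kd+[L])."""
    conc = np.asarray(conc, dtype=float)
    return r_free + (r_bound - r_free) * conc / (kd + conc)


def fit_binding_isotherm(series: BindingSeries, k_sigma: float = 3.0) -> BindingFit:
    """Least-squares fit of the 1:1 isotherm to a titration.

    Initialisation: r_free = first response, r_bound = last, Kd = the
    concentration closest to half-amplitude.  Kd is bounded to
    (0, 10^4 × max concentration].  The 95% CI comes from the parameter
    covariance at the optimum (t quantile, n − 3 df).

    A flat response (zero amplitude, no information) yields a non-binding
    result (binds=False, kd=None) rather than a fit error.
    """
    conc, resp = series.conc, series.resp
    if np.ptp(resp) == 0:
        return BindingFit(
            kd=None,
            r_free=float(resp[0]),
            r_bound=float(resp[0]),
            rss=0.0,
            kd_ci=None,
            binds=False,
        )

    half = (resp[0] + resp[-1]) / 2.0
    kd0 = float(conc[int(np.argmin(np.abs(resp - half)))])
    kd_hi = 1e4 * float(conc.max())
    kd0 = min(max(kd0, 1e-12), kd_hi)
    p0 = [kd0, float(resp[0]), float(resp[-1])]
    lo = [1e-12, -np.inf, -np.inf]
    hi = [kd_hi, np.inf, np.inf]
    popt, pcov = optimize.curve_fit(
        isotherm, conc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    kd, r_free, r_bound = (float(v) for v in popt)
    residuals = resp - isotherm(conc, *popt)
    rss = float(residuals @ residuals)
    dof = max(len(conc) - 3, 1)
    residual_sd = float(np.sqrt(rss / dof))
    kd_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    tq = float(stats.t.ppf(0.975, dof))
    kd_ci = (max(kd - tq * kd_se, 0.0), kd + tq * kd_se)
    binds = abs(r_bound - r_free) > k_sigma * residual_sd
    return BindingFit(
        kd=kd,
        r_free=r_free,
        r_bound=r_bound,
        rss=rss,
        kd_ci=kd_ci,
        binds=binds,
        residual_sd=residual_sd,
        provenance={"n_points": int(len(conc)), "k_sigma": k_sigma},
    )


def binding_check(series: BindingSeries, k_sigma: float = 3.0) -> bool:
    """True iff the fitted amplitude exceeds k_sigma × residual noise (strict >)."""
    return fit_binding_isotherm(series, k_sigma=k_sigma).binds


def tumor_volume(
    l: float, w: float, variant: Literal["printed", "conventional"] = "printed"
) -> float:
    """Xenograft tumour volume (mm³) from caliper length and width (mm).

    The "printed" variant is π/6·l·w·(1+w)/2 as published; "conventional"
    is the usual ellipsoid approximation π/6·l·w·(l+w)/2.  The two agree
    when l = w = 1.
    """
    if l <= 0 or w <= 0:
        raise ValueError(f"dimensions must be positive, got l={l}, w={w}")
    if variant == "printed":
        return np.pi / 6.0 * l * w * (1.0 + w) / 2.0
    if variant == "conventional":
        return np.pi / 6.0 * l * w * (l + w) / 2.0
    raise ValueError(f"unknown variant {variant!r}")


def read_titration(path: str | Path) -> BindingSeries:
    """Read a TSV/CSV titration table with columns conc_nM, response."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in frame.columns}
    try:
        conc = frame[cols["conc_nm"]]
        resp = frame[cols["response"]]
    except KeyError:
        raise ValueError(
            f"{path}: expected columns conc_nM and response, got {list(frame.columns)}"
        ) from None
    return BindingSeries.from_arrays(conc.to_numpy(), resp.to_numpy())
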