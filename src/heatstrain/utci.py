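"""Universal Thermal Climate Index (UTCI) and thermal-stress categories.

UTCI is an equivalent temperature (°C): the air temperature of a reference
environment (calm 0.5 m·s⁻¹ wind at 10 m, Tmrt = ta, 50 % relative
humidity) that would provoke the same dynamic thermophysiological response
as the actual environment.  Operationally it is evaluated with the
published 6th-order polynomial regression of the underlying
physiological-model response in the four drivers

    ta (°C), va (10-m wind, m·s⁻¹), ΔTmrt = tmrt − ta (K), pa (kPa).

The polynomial is only valid inside the fitting domain
(ta ∈ [−50, 50] °C, va ∈ [0.5, 17] m·s⁻¹, ΔTmrt ∈ [−30, 70] K,
pa ≤ 5 kPa); station data routinely contain calm winds below 0.5 m·s⁻¹,
so out-of-domain inputs are clipped to the boundary and flagged rather
than rejected.

Assessment-scale categories follow the standard band table; bands are
half-open on the left and closed on the right, so a printed one-decimal
bound like 26.0 °C still classifies as the band below (26.0 → NTS,
26.1 → MHS).  The cold half of the scale is collapsed to a single
"below SCS" label, which a June analysis never uses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: operational polynomial coefficient set, version a 0.002 (October 2009).
#: One row per term: coefficient, then exponents of ta, va, ΔTmrt, pa.
#: Ordering: pa power ascending, then ΔTmrt, then va, then ta.
_UTCI_COEFFICIENT_TABLE = """\
 6.07562052e-01 0 0 0 0
-2.27712343e-02 1 0 0 0
 8.06470249e-04 2 0 0 0
-1.54271372e-04 3 0 0 0
-3.24651735e-06 4 0 0 0
 7.32602852e-08 5 0 0 0
 1.35959073e-09 6 0 0 0
-2.25836520e+00 0 1 0 0
 8.80326035e-02 1 1 0 0
 2.16844454e-03 2 1 0 0
-1.53347087e-05 3 1 0 0
-5.72983704e-07 4 1 0 0
-2.55090145e-09 5 1 0 0
-7.51269505e-01 0 2 0 0
-4.08350271e-03 1 2 0 0
-5.21670675e-05 2 2 0 0
 1.94544667e-06 3 2 0 0
 1.14099531e-08 4 2 0 0
 1.58137256e-01 0 3 0 0
-6.57263143e-05 1 3 0 0
 2.22697524e-07 2 3 0 0
-4.16117031e-08 3 3 0 0
-1.27762753e-02 0 4 0 0
 9.66891875e-06 1 4 0 0
 2.52785852e-09 2 4 0 0
 4.56306672e-04 0 5 0 0
-1.74202546e-07 1 5 0 0
-5.91491269e-06 0 6 0 0
 3.98374029e-01 0 0 1 0
 1.83945314e-04 1 0 1 0
-1.73754510e-04 2 0 1 0
-7.60781159e-07 3 0 1 0
 3.77830287e-08 4 0 1 0
 5.43079673e-10 5 0 1 0
-2.00518269e-02 0 1 1 0
 8.92859837e-04 1 1 1 0
 3.45433048e-06 2 1 1 0
-3.77925774e-07 3 1 1 0
-1.69699377e-09 4 1 1 0
 1.69992415e-04 0 2 1 0
-4.99204314e-05 1 2 1 0
 2.47417178e-07 2 2 1 0
 1.07596466e-08 3 2 1 0
 8.49242932e-05 0 3 1 0
 1.35191328e-06 1 3 1 0
-6.21531254e-09 2 3 1 0
-4.99410301e-06 0 4 1 0
-1.89489258e-08 1 4 1 0
 8.15300114e-08 0 5 1 0
 7.55043090e-04 0 0 2 0
-5.65095215e-05 1 0 2 0
-4.52166564e-07 2 0 2 0
 2.46688878e-08 3 0 2 0
 2.42674348e-10 4 0 2 0
 1.54547250e-04 0 1 2 0
 5.24110970e-06 1 1 2 0
-8.75874982e-08 2 1 2 0
-1.50743064e-09 3 1 2 0
-1.56236307e-05 0 2 2 0
-1.33895614e-07 1 2 2 0
 2.49709824e-09 2 2 2 0
 6.51711721e-07 0 3 2 0
 1.94960053e-09 1 3 2 0
-1.00361113e-08 0 4 2 0
-1.21206673e-05 0 0 3 0
-2.18203660e-07 1 0 3 0
 7.51269482e-09 2 0 3 0
 9.79063848e-11 3 0 3 0
 1.25006734e-06 0 1 3 0
-1.81584736e-09 1 1 3 0
-3.52197671e-10 2 1 3 0
-3.36514630e-08 0 2 3 0
 1.35908359e-10 1 2 3 0
 4.17032620e-10 0 3 3 0
-1.30369025e-09 0 0 4 0
 4.13908461e-10 1 0 4 0
 9.22652254e-12 2 0 4 0
-5.08220384e-09 0 1 4 0
-2.24730961e-11 1 1 4 0
 1.17139133e-10 0 2 4 0
 6.62154879e-10 0 0 5 0
 4.03863260e-13 1 0 5 0
 1.95087203e-12 0 1 5 0
-4.73602469e-12 0 0 6 0
-2.80626406e+00 0 0 0 1
 5.48712484e-01 1 0 0 1
-3.99428410e-03 2 0 0 1
-9.54009191e-04 3 0 0 1
 1.93090978e-05 4 0 0 1
-3.08806365e-01 0 1 0 1
 1.16952364e-02 1 1 0 1
 4.95271903e-04 2 1 0 1
-1.90710882e-05 3 1 0 1
 2.10787756e-03 0 2 0 1
-6.98445738e-04 1 2 0 1
 2.30109073e-05 2 2 0 1
 4.17856590e-04 0 3 0 1
-1.27043871e-05 1 3 0 1
-3.04620472e-06 0 4 0 1
 5.14507424e-02 0 0 1 1
-4.32510997e-03 1 0 1 1
 8.99281156e-05 2 0 1 1
-7.14663943e-07 3 0 1 1
-2.66016305e-04 0 1 1 1
 2.63789586e-04 1 1 1 1
-7.01199003e-06 2 1 1 1
-1.06823306e-04 0 2 1 1
 3.61341136e-06 1 2 1 1
 2.29748967e-07 0 3 1 1
 3.04788893e-04 0 0 2 1
-6.42070836e-05 1 0 2 1
 1.16257971e-06 2 0 2 1
 7.68023384e-06 0 1 2 1
-5.47446896e-07 1 1 2 1
-3.59937910e-08 0 2 2 1
-4.36497725e-06 0 0 3 1
 1.68737969e-07 1 0 3 1
 2.67489271e-08 0 1 3 1
 3.23926897e-09 0 0 4 1
-3.53874123e-02 0 0 0 2
-2.21201190e-01 1 0 0 2
 1.55126038e-02 2 0 0 2
-2.63917279e-04 3 0 0 2
 4.53433455e-02 0 1 0 2
-4.32943862e-03 1 1 0 2
 1.45389826e-04 2 1 0 2
 2.17508610e-04 0 2 0 2
-6.66724702e-05 1 2 0 2
 3.33217140e-05 0 3 0 2
-2.26921615e-03 0 0 1 2
 3.80261982e-04 1 0 1 2
-5.45314314e-09 2 0 1 2
-7.96355448e-04 0 1 1 2
 2.53458034e-05 1 1 1 2
-6.31223658e-06 0 2 1 2
 3.02122035e-04 0 0 2 2
-4.77403547e-06 1 0 2 2
 1.73825715e-06 0 1 2 2
-4.09087898e-07 0 0 3 2
 6.14155345e-01 0 0 0 3
-6.16755931e-02 1 0 0 3
 1.33374846e-03 2 0 0 3
 3.55375387e-03 0 1 0 3
-5.13027851e-04 1 1 0 3
 1.02449757e-04 0 2 0 3
-1.48526421e-03 0 0 1 3
-4.11469183e-05 1 0 1 3
-6.80434415e-06 0 1 1 3
-9.77675906e-06 0 0 2 3
 8.82773108e-02 0 0 0 4
-3.01859306e-03 1 0 0 4
 1.04452989e-03 0 1 0 4
 2.47090539e-04 0 0 1 4
 1.48348065e-03 0 0 0 6
"""

UTCI_COEFFICIENT_VERSION = "a 0.002 (October 2009)"
#: checksum of the shipped coefficient table (verified at import)
UTCI_COEFFICIENT_SHA256 = (
    "ec73f33c0f18d0482d3787d0abe4aaf2b160d99757c03135f44a38ee978b3600"
)


def _parse_table(text: str):
    coefs, exps = [], []
    for line in text.strip().splitlines():
        parts = line.split()
        coefs.append(float(parts[0]))
        exps.append(tuple(int(p) for p in parts[1:5]))
    return np.asarray(coefs), np.asarray(exps, dtype=int)


_digest = hashlib.sha256(_UTCI_COEFFICIENT_TABLE.encode()).hexdigest()
if _digest != UTCI_COEFFICIENT_SHA256:  # pragma: no cover - guards corruption
    raise RuntimeError(
        "UTCI coefficient table does not match its shipped checksum "
        f"({_digest} != {UTCI_COEFFICIENT_SHA256})"
    )

_COEFS, _EXPONENTS = _parse_table(_UTCI_COEFFICIENT_TABLE)

#: polynomial validity domain (clip-and-flag boundaries)
DOMAIN = {
    "ta": (-50.0, 50.0),
    "va": (0.5, 17.0),
    "d_tmrt": (-30.0, 70.0),
    "pa": (0.0, 5.0),
}

CATEGORY_BOUNDS = [-np.inf, 0.0, 9.0, 26.0, 32.0, 38.0, 46.0, np.inf]
CATEGORY_LABELS = ["below SCS", "SCS", "NTS", "MHS", "SHS", "VSHS", "above scale"]
#: categories counted as strong-heat days in the mortality model (UTCI > 32 °C)
HEAT_STRESS_CATEGORIES = frozenset({"SHS", "VSHS", "above scale"})


@dataclass(frozen=True)
class UtciRecord:
    """UTCI value, its stress category, and whether inputs were clipped."""

    utci: float
    category: str
    clamped: bool


def saturation_vapour_pressure(ta) -> np.ndarray:
    """Saturation vapour pressure over water (hPa), Magnus formula."""
    t = np.asarray(ta, dtype=float)
    return 6.112 * np.exp(17.62 * t / (243.12 + t))


def vapour_pressure_from_rh(ta, rh) -> np.ndarray:
    """Vapour pressure (hPa) from air temperature (°C) and RH (%)."""
    return np.asarray(rh, dtype=float) / 100.0 * saturation_vapour_pressure(ta)


def _polynomial(ta, va, d_tmrt, pa):
    """Evaluate the regression offset; UTCI = ta + offset."""
    # powers 0..6 of each driver, combined per the term table
    pow_ta = np.stack([ta**p for p in range(7)])
    pow_va = np.stack([va**p for p in range(7)])
    pow_d = np.stack([d_tmrt**p for p in range(7)])
    pow_pa = np.stack([pa**p for p in range(7)])
    i, j, k, l = (_EXPONENTS[:, c] for c in range(4))
    terms = _COEFS[:, None] * pow_ta[i] * pow_va[j] * pow_d[k] * pow_pa[l]
    return terms.sum(axis=0)


def compute_utci(ta, tmrt, v10, vp, return_flags: bool = False):
    """UTCI (°C) from air temperature, Tmrt, 10-m wind and vapour pressure.

    Parameters
    ----------
    ta, tmrt : °C;  v10 : m·s⁻¹ at 10 m;  vp : hPa.
    return_flags
        Also return a boolean array marking records whose inputs were
        clipped to the polynomial's validity domain.

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    ta = np.atleast_1d(np.asarray(ta, dtype=float))
    tmrt = np.atleast_1d(np.asarray(tmrt, dtype=float))
    v10 = np.atleast_1d(np.asarray(v10, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    ta, tmrt, v10, vp = np.broadcast_arrays(ta, tmrt, v10, vp)
    for name, arr in (("ta", ta), ("tmrt", tmrt), ("v10", v10), ("vp", vp)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} passed to compute_utci")

    d_tmrt = tmrt - ta
    pa = vp / 10.0  # hPa -> kPa

    ta_c = np.clip(ta, *DOMAIN["ta"])
    va_c = np.clip(v10, *DOMAIN["va"])
    d_c = np.clip(d_tmrt, *DOMAIN["d_tmrt"])
    pa_c = np.clip(pa, *DOMAIN["pa"])
    clamped = (ta_c != ta) | (va_c != v10) | (d_c != d_tmrt) | (pa_c != pa)

    utci = ta_c + _polynomial(ta_c, va_c, d_c, pa_c)

    if utci.ndim == 0 or utci.size == 1:
        scalar = float(utci.reshape(-1)[0])
        flag = bool(clamped.reshape(-1)[0])
        return (scalar, flag) if return_flags else scalar
    return (utci, clamped) if return_flags else utci


def classify_stress(utci):
    """Map UTCI values to assessment-scale categories.

    Bands partition the real line: (−∞,0] below SCS, (0,9] SCS, (9,26] NTS,
    (26,32] MHS, (32,38] SHS, (38,46] VSHS, (46,∞) above scale.
    """
    values = np.atleast_1d(np.asarray(utci, dtype=float))
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite UTCI passed to classify_stress")
    idx = np.searchsorted(CATEGORY_BOUNDS[1:-1], values, side="left")
    labels = np.asarray(CATEGORY_LABELS, dtype=object)[idx]
    if np.ndim(utci) == 0:
        return str(labels[0])
    return labels


def utci_record(ta: float, tmrt: float, v10: float, vp: float) -> UtciRecord:
    """Scalar convenience wrapper returning value, category and clip flag."""
    value, clamped = compute_utci(ta, tmrt, v10, vp, return_flags=True)
    return UtciRecord(utci=value, category=classify_stress(value), clamped=clamped)
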