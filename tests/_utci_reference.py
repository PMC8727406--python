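"""Independently coded reference evaluation of the UTCI regression offset.

This module exists solely as a cross-check oracle for the table-driven
evaluator in ``heatstrain.utci``: the same operational coefficient listing
typed a second time, as one explicit literal expression (scalar arithmetic,
no table, no loops).  Any transcription slip in either encoding shows up as
a disagreement between the two on random in-domain points.
"""


def utci_reference(ta: float, va: float, d_tmrt: float, pa: float) -> float:
    """UTCI (°C) for air temperature ta (°C), 10-m wind va (m/s),
    radiant excess d_tmrt = tmrt - ta (K) and vapour pressure pa (kPa).
    Inputs are assumed to lie inside the polynomial's validity domain."""
    t = ta
    v = va
    d = d_tmrt
    p = pa
    return ta + (
        6.07562052e-01
        + -2.27712343e-02 * t
        + 8.06470249e-04 * t * t
        + -1.54271372e-04 * t * t * t
        + -3.24651735e-06 * t * t * t * t
        + 7.32602852e-08 * t * t * t * t * t
        + 1.35959073e-09 * t * t * t * t * t * t
        + -2.25836520e00 * v
        + 8.80326035e-02 * t * v
        + 2.16844454e-03 * t * t * v
        + -1.53347087e-05 * t * t * t * v
        + -5.72983704e-07 * t * t * t * t * v
        + -2.55090145e-09 * t * t * t * t * t * v
        + -7.51269505e-01 * v * v
        + -4.08350271e-03 * t * v * v
        + -5.21670675e-05 * t * t * v * v
        + 1.94544667e-06 * t * t * t * v * v
        + 1.14099531e-08 * t * t * t * t * v * v
        + 1.58137256e-01 * v * v * v
        + -6.57263143e-05 * t * v * v * v
        + 2.22697524e-07 * t * t * v * v * v
        + -4.16117031e-08 * t * t * t * v * v * v
        + -1.27762753e-02 * v * v * v * v
        + 9.66891875e-06 * t * v * v * v * v
        + 2.52785852e-09 * t * t * v * v * v * v
        + 4.56306672e-04 * v * v * v * v * v
        + -1.74202546e-07 * t * v * v * v * v * v
        + -5.91491269e-06 * v * v * v * v * v * v
        + 3.98374029e-01 * d
        + 1.83945314e-04 * t * d
        + -1.73754510e-04 * t * t * d
        + -7.60781159e-07 * t * t * t * d
        + 3.77830287e-08 * t * t * t * t * d
        + 5.43079673e-10 * t * t * t * t * t * d
        + -2.00518269e-02 * v * d
        + 8.92859837e-04 * t * v * d
        + 3.45433048e-06 * t * t * v * d
        + -3.77925774e-07 * t * t * t * v * d
        + -1.69699377e-09 * t * t * t * t * v * d
        + 1.69992415e-04 * v * v * d
        + -4.99204314e-05 * t * v * v * d
        + 2.47417178e-07 * t * t * v * v * d
        + 1.07596466e-08 * t * t * t * v * v * d
        + 8.49242932e-05 * v * v * v * d
        + 1.35191328e-06 * t * v * v * v * d
        + -6.21531254e-09 * t * t * v * v * v * d
        + -4.99410301e-06 * v * v * v * v * d
        + -1.89489258e-08 * t * v * v * v * v * d
        + 8.15300114e-08 * v * v * v * v * v * d
        + 7.55043090e-04 * d * d
        + -5.65095215e-05 * t * d * d
        + -4.52166564e-07 * t * t * d * d
        + 2.46688878e-08 * t * t * t * d * d
        + 2.42674348e-10 * t * t * t * t * d * d
        + 1.54547250e-04 * v * d * d
        + 5.24110970e-06 * t * v * d * d
        + -8.75874982e-08 * t * t * v * d * d
        + -1.50743064e-09 * t * t * t * v * d * d
        + -1.56236307e-05 * v * v * d * d
        + -1.33895614e-07 * t * v * v * d * d
        + 2.49709824e-09 * t * t * v * v * d * d
        + 6.51711721e-07 * v * v * v * d * d
        + 1.94960053e-09 * t * v * v * v * d * d
        + -1.00361113e-08 * v * v * v * v * d * d
        + -1.21206673e-05 * d * d * d
        + -2.18203660e-07 * t * d * d * d
        + 7.51269482e-09 * t * t * d * d * d
        + 9.79063848e-11 * t * t * t * d * d * d
        + 1.25006734e-06 * v * d * d * d
        + -1.81584736e-09 * t * v * d * d * d
        + -3.52197671e-10 * t * t * v * d * d * d
        + -3.36514630e-08 * v * v * d * d * d
        + 1.35908359e-10 * t * v * v * d * d * d
        + 4.17032620e-10 * v * v * v * d * d * d
        + -1.30369025e-09 * d * d * d * d
        + 4.13908461e-10 * t * d * d * d * d
        + 9.22652254e-12 * t * t * d * d * d * d
        + -5.08220384e-09 * v * d * d * d * d
        + -2.24730961e-11 * t * v * d * d * d * d
        + 1.17139133e-10 * v * v * d * d * d * d
        + 6.62154879e-10 * d * d * d * d * d
        + 4.03863260e-13 * t * d * d * d * d * d
        + 1.95087203e-12 * v * d * d * d * d * d
        + -4.73602469e-12 * d * d * d * d * d * d
        + -2.80626406e00 * p
        + 5.48712484e-01 * t * p
        + -3.99428410e-03 * t * t * p
        + -9.54009191e-04 * t * t * t * p
        + 1.93090978e-05 * t * t * t * t * p
        + -3.08806365e-01 * v * p
        + 1.16952364e-02 * t * v * p
        + 4.95271903e-04 * t * t * v * p
        + -1.90710882e-05 * t * t * t * v * p
        + 2.10787756e-03 * v * v * p
        + -6.98445738e-04 * t * v * v * p
        + 2.30109073e-05 * t * t * v * v * p
        + 4.17856590e-04 * v * v * v * p
        + -1.27043871e-05 * t * v * v * v * p
        + -3.04620472e-06 * v * v * v * v * p
        + 5.14507424e-02 * d * p
        + -4.32510997e-03 * t * d * p
        + 8.99281156e-05 * t * t * d * p
        + -7.14663943e-07 * t * t * t * d * p
        + -2.66016305e-04 * v * d * p
        + 2.63789586e-04 * t * v * d * p
        + -7.01199003e-06 * t * t * v * d * p
        + -1.06823306e-04 * v * v * d * p
        + 3.61341136e-06 * t * v * v * d * p
        + 2.29748967e-07 * v * v * v * d * p
        + 3.04788893e-04 * d * d * p
        + -6.42070836e-05 * t * d * d * p
        + 1.16257971e-06 * t * t * d * d * p
        + 7.68023384e-06 * v * d * d * p
        + -5.47446896e-07 * t * v * d * d * p
        + -3.59937910e-08 * v * v * d * d * p
        + -4.36497725e-06 * d * d * d * p
        + 1.68737969e-07 * t * d * d * d * p
        + 2.67489271e-08 * v * d * d * d * p
        + 3.23926897e-09 * d * d * d * d * p
        + -3.53874123e-02 * p * p
        + -2.21201190e-01 * t * p * p
        + 1.55126038e-02 * t * t * p * p
        + -2.63917279e-04 * t * t * t * p * p
        + 4.53433455e-02 * v * p * p
        + -4.32943862e-03 * t * v * p * p
        + 1.45389826e-04 * t * t * v * p * p
        + 2.17508610e-04 * v * v * p * p
        + -6.66724702e-05 * t * v * v * p * p
        + 3.33217140e-05 * v * v * v * p * p
        + -2.26921615e-03 * d * p * p
        + 3.80261982e-04 * t * d * p * p
        + -5.45314314e-09 * t * t * d * p * p
        + -7.96355448e-04 * v * d * p * p
        + 2.53458034e-05 * t * v * d * p * p
        + -6.31223658e-06 * v * v * d * p * p
        + 3.02122035e-04 * d * d * p * p
        + -4.77403547e-06 * t * d * d * p * p
        + 1.73825715e-06 * v * d * d * p * p
        + -4.09087898e-07 * d * d * d * p * p
        + 6.14155345e-01 * p * p * p
        + -6.16755931e-02 * t * p * p * p
        + 1.33374846e-03 * t * t * p * p * p
        + 3.55375387e-03 * v * p * p * p
        + -5.13027851e-04 * t * v * p * p * p
        + 1.02449757e-04 * v * v * p * p * p
        + -1.48526421e-03 * d * p * p * p
        + -4.11469183e-05 * t * d * p * p * p
        + -6.80434415e-06 * v * d * p * p * p
        + -9.77675906e-06 * d * d * p * p * p
        + 8.82773108e-02 * p * p * p * p
        + -3.01859306e-03 * t * p * p * p * p
        + 1.04452989e-03 * v * p * p * p * p
        + 2.47090539e-04 * d * p * p * p * p
        + 1.48348065e-03 * p * p * p * p * p * p
    )
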