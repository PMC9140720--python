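"""Shared oracles for the test suite.

The Panama 1976 tallies are the classic worked application of the
children-ever-born/children-dead method (West family); the expected k and
q values were recomputed by literal hand arithmetic from the tallies
(P1 = 278/2695, P2 = 1380/2095, P3 = 2395/1828; k_i = a_i + b_i*(P1/P2)
+ c_i*(P2/P3); q_i = k_i * D_i/B_i) and frozen here, independent of the
package's code path.
"""


# women, children ever born, children dead per maternal age group 15-19..45-49
PANAMA_W = [2695, 2095, 1828, 1605, 1362, 1128, 930]
PANAMA_B = [278, 1380, 2395, 3097, 3444, 3274, 2682]
PANAMA_D = [24, 77, 172, 236, 348, 394, 354]

PANAMA_K = [1.1029, 1.0395, 0.9850, 0.9939, 1.0109, 0.9984, 0.9909]
PANAMA_Q = [0.0952, 0.0580, 0.0707, 0.0757, 0.1021, 0.1201, 0.1308]


def brute_force_ice(table, stratifier, weighted):
    """Row-loop ICE oracle: no grouping machinery, one pass over rows."""
    out = {}
    for _, row in table.iterrows():
        key = (row["wave_year"], row[stratifier])
        w = row["weight"] if weighted else 1.0
        H, L, T = out.get(key, (0.0, 0.0, 0.0))
        if row["bmi_category"] == "obese":
            H += w
        if row["bmi_category"] == "underweight":
            L += w
        out[key] = (H, L, T + w)
    return {k: (H - L) / T for k, (H, L, T) in out.items()}
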