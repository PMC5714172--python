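"""One-off calibration of the idealized-duplex phosphate placement.

With twist 36 deg and rise 3.38 A fixed at canonical B-form fiber
values, the three free constants (phosphorus radius, azimuth offset off
the base-pair dyad, axial offset per strand) are fitted to the three
benchmark inter-strand scissile-phosphate distances

    11.9 A at stagger +3 (mariner, across the minor groove)
    16.9 A at stagger  0 (Tn10/Tn5 blunt cut, through the helix)
    18.3 A at stagger -4 (PiggyBac TTAA, across the major groove)

subject to the pair at +3 being the unique global minimum over staggers
-10..+10 and the profile increasing monotonically from stagger 5 up to
half a helical turn.  Solving the three distance equations exactly
misplaces the global minimum (argmin 2 or 4 by ~0.2 A), so the
committed constants are the least-squares solution under the
argmin-margin constraint; all three distances land within 0.2 A.

Run from the repository root:  python scripts/calibrate_helix.py
The printed constants are the ones committed in
marinersim.bdna_geometry.HelixModel.
"""

import numpy as np
from scipy.optimize import minimize

TWIST = np.deg2rad(36.0)
RISE = 3.38
TARGETS = {3: 11.9, 0: 16.9, -4: 18.3}
MIN_MARGIN = 0.15  # A, required gap between d(3) and every other stagger


def dist(s, r, delta, zz):
    """Inter-strand P-P distance at stagger s.

    delta = 2 * azimuth offset, zz = 2 * per-strand z offset (the dyad
    doubles both when the strands are superposed).
    """
    return np.sqrt(2 * r * r * (1 - np.cos(delta - s * TWIST))
                   + (zz - s * RISE) ** 2)


def objective(x):
    r, delta, zz = x
    err = sum((dist(s, r, delta, zz) - d) ** 2 for s, d in TARGETS.items())
    d3 = dist(3, r, delta, zz)
    pen = 0.0
    for s in range(-10, 11):
        if s == 3:
            continue
        margin = dist(s, r, delta, zz) - d3
        if margin < MIN_MARGIN:
            pen += 100.0 * (MIN_MARGIN - margin) ** 2
    for s in range(5, 10):  # monotone approach to the half-turn maximum
        gap = dist(s + 1, r, delta, zz) - dist(s, r, delta, zz)
        if gap < 0.01:
            pen += 100.0 * (0.01 - gap) ** 2
    return err + pen


def main():
    best = None
    for d0 in np.deg2rad(np.arange(100, 260, 10)):
        for z0 in (-3.0, -1.5, 0.0, 1.5, 3.0, 4.5):
            res = minimize(objective, (9.2, d0, z0), method="Nelder-Mead",
                           options=dict(xatol=1e-12, fatol=1e-16,
                                        maxiter=50000, maxfev=50000))
            if best is None or res.fun < best.fun:
                best = res
    r, delta, zz = best.x
    print(f"p_radius         = {r:.6f}  # A")
    print(f"p_azimuth_offset = {np.rad2deg(delta) / 2:.6f}  # deg")
    print(f"p_z_offset       = {zz / 2:.6f}  # A")
    for s, d in TARGETS.items():
        print(f"  d({s:+d}) = {dist(s, r, delta, zz):.3f} A (target {d})")
    ds = {s: dist(s, r, delta, zz) for s in range(-10, 11)}
    print(f"  argmin over -10..10: {min(ds, key=ds.get)}")


if __name__ == "__main__":
    main()
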