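"""Compiled inner loop for the AES integrator.

Numerically identical to the pure-numpy :func:`polarweave.simulate.step`
(same operation order per particle up to floating-point associativity in
the force accumulation); used by ``run`` for long integrations. Falls
back silently if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def euler_steps(pos, pol, edges_i, edges_j, rest, n_steps, dt,
                V_c, zeta, K, B, gamma, R, k_b, turn_rate, shell,
                confined, slip_mode):
    """Advance n_steps explicit Euler steps in place; returns (vel, max_disp).

    vel is the velocity used in the final step; max_disp is the largest
    single-step displacement over the whole chunk (instability guard).
    """
    n = pos.shape[0]
    m = edges_i.shape[0]
    vel = np.zeros((n, 2))
    forces = np.zeros((n, 2))
    max_disp = 0.0
    for _ in range(n_steps):
        for k in range(n):
            forces[k, 0] = 0.0
            forces[k, 1] = 0.0
        for e in range(m):
            i = edges_i[e]
            j = edges_j[e]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            r = np.sqrt(dx * dx + dy * dy)
            if r <= 0.0:
                return vel, -1.0          # coincident particles: caller raises
            s = rest[e] - r
            fmag = -(K * s + 4.0 * B * s * s * s) / r
            fx = fmag * dx
            fy = fmag * dy
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy
        for k in range(n):
            fx = forces[k, 0]
            fy = forces[k, 1]
            omega = 0.0
            near_rim = False
            rhx = 0.0
            rhy = 0.0
            if confined:
                rad = np.sqrt(pos[k, 0] ** 2 + pos[k, 1] ** 2)
                if rad > R:
                    scale = k_b * (rad - R) / rad
                    fx -= scale * pos[k, 0]
                    fy -= scale * pos[k, 1]
                if rad > R - shell and rad > 1e-12:
                    near_rim = True
                    rhx = pos[k, 0] / rad
                    rhy = pos[k, 1] / rad
                    if not slip_mode:
                        # rotate toward the inward normal (−r̂)
                        omega = turn_rate * (-pol[k, 0] * rhy
                                             + pol[k, 1] * rhx)
            vx = V_c * pol[k, 0] + fx / zeta
            vy = V_c * pol[k, 1] + fy / zeta
            vel[k, 0] = vx
            vel[k, 1] = vy
            disp = np.sqrt(vx * vx + vy * vy) * dt
            if disp > max_disp:
                max_disp = disp
            pos[k, 0] += vx * dt
            pos[k, 1] += vy * dt
            pdotv = pol[k, 0] * vx + pol[k, 1] * vy
            px = pol[k, 0] + gamma * (vx - pdotv * pol[k, 0]) * dt \
                - omega * dt * pol[k, 1]
            py = pol[k, 1] + gamma * (vy - pdotv * pol[k, 1]) * dt \
                + omega * dt * pol[k, 0]
            if slip_mode and near_rim:
                dot = px * rhx + py * rhy
                if dot > 0.0:
                    px -= dot * rhx
                    py -= dot * rhy
                    if np.sqrt(px * px + py * py) < 1e-12:
                        px = -rhx
                        py = -rhy
            norm = np.sqrt(px * px + py * py)
            if norm <= 0.0 or not np.isfinite(norm):
                return vel, -1.0
            pol[k, 0] = px / norm
            pol[k, 1] = py / norm
    return vel, max_disp
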