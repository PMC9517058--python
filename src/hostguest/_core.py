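"""Numba inner loop for overdamped-Langevin / metadynamics propagation.

One compiled kernel serves unbiased dynamics, well-tempered metadynamics and
infrequent (stop-on-commitment) metadynamics; the Python-facing wrappers in
``sampler`` select the mode through integer flags.  The bias potential and
its force are tabulated on the same uniform grid as the physical force and
updated analytically at every hill deposition (periodic images included).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STEP_DIVERGED = 1


@njit(cache=False)
def run_core(pot_force, lo, hi, periodic,
             dt, beta, diffusion, n_steps, seed, s0,
             metad_on, h0, sigma, stride, kbdT,
             bias, bias_force,
             hills_t, hills_c, hills_h,
             stop_on_target, t_lo, t_hi, track_alpha,
             save_stride, traj_t, traj_s, traj_v):
    n_grid = pot_force.shape[0]
    L = hi - lo
    if periodic == 1:
        dx = L / n_grid
    else:
        dx = L / (n_grid - 1)
    np.random.seed(seed)
    s = s0
    t = 0.0
    alpha = 0.0
    n_hills = 0
    n_saved = 0
    status = STATUS_OK
    steps_done = n_steps
    exited = 0
    pref = np.sqrt(2.0 * diffusion * dt)
    inv_s2 = 0.0
    if metad_on == 1:
        inv_s2 = 1.0 / (sigma * sigma)
    for step in range(n_steps):
        # linear interpolation of physical force, bias and bias force
        x = (s - lo) / dx
        i0 = int(np.floor(x))
        w1 = x - i0
        if periodic == 1:
            ia = i0 % n_grid
            ib = (ia + 1) % n_grid
        else:
            if i0 < 0:
                i0 = 0
            if i0 > n_grid - 2:
                i0 = n_grid - 2
            w1 = x - i0
            if w1 < 0.0:
                w1 = 0.0
            if w1 > 1.0:
                w1 = 1.0
            ia = i0
            ib = i0 + 1
        fpot = pot_force[ia] * (1.0 - w1) + pot_force[ib] * w1
        vb = bias[ia] * (1.0 - w1) + bias[ib] * w1
        fb = bias_force[ia] * (1.0 - w1) + bias_force[ib] * w1

        if stop_on_target == 1:
            inside = 0
            if t_lo <= t_hi:
                if t_lo <= s <= t_hi:
                    inside = 1
            else:  # wrapped interval on a periodic domain
                if s >= t_lo or s <= t_hi:
                    inside = 1
            if inside == 1:
                exited = 1
                steps_done = step
                break

        if track_alpha == 1:
            # acceleration-factor bookkeeping: t* = sum dt * exp(beta V(s,t))
            alpha += dt * np.exp(beta * vb)

        if save_stride > 0 and step % save_stride == 0:
            traj_t[n_saved] = t
            traj_s[n_saved] = s
            traj_v[n_saved] = vb
            n_saved += 1

        # hills are deposited only while still uncommitted (stop-on-event)
        if metad_on == 1 and step > 0 and step % stride == 0:
            if kbdT > 0.0:
                h = h0 * np.exp(-vb / kbdT)
            else:
                h = h0
            hills_t[n_hills] = t
            hills_c[n_hills] = s
            hills_h[n_hills] = h
            n_hills += 1
            for j in range(n_grid):
                xg = lo + j * dx
                if periodic == 1:
                    for k in range(-1, 2):
                        d = xg - s + k * L
                        e = h * np.exp(-0.5 * d * d * inv_s2)
                        bias[j] += e
                        bias_force[j] += d * inv_s2 * e
                else:
                    d = xg - s
                    e = h * np.exp(-0.5 * d * d * inv_s2)
                    bias[j] += e
                    bias_force[j] += d * inv_s2 * e

        ds = beta * diffusion * (fpot + fb) * dt + pref * np.random.normal()
        if np.abs(ds) > 0.5 * L:
            status = STATUS_STEP_DIVERGED
            steps_done = step
            break
        s += ds
        if periodic == 1:
            s = lo + ((s - lo) % L)
        else:
            if s < lo:
                s = 2.0 * lo - s
            if s > hi:
                s = 2.0 * hi - s
            if s < lo:
                s = lo
            if s > hi:
                s = hi
        t += dt
    return status, steps_done, n_saved, n_hills, s, alpha, exited
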