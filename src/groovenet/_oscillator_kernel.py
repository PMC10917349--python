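"""Numba-compiled fixed-step RK4 core for the oscillator network.

The math here mirrors the reference functions in :mod:`groovenet.oscillators`
(`oscillator_derivative`, `coupling_input`, `hebbian_derivative`); tests
assert one-step agreement between the two routes.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _rhs(z, c, stim, tgt, src, ke, me, freqs, lp,
         w23, w13, lam, mu1, mu2, kappa, tau, fscale, hebb_fscale, dz, dc):
    n = z.shape[1]
    nnz = c.shape[0]
    x1 = np.zeros(n, dtype=np.complex128)
    for e in range(nnz):
        i = tgt[e]
        j = src[e]
        term = c[e]
        zj = z[0, j]
        for _ in range(ke[e]):
            term *= zj
        zi_c = np.conj(z[1, i])
        for _ in range(me[e] - 1):
            term *= zi_c
        x1[i] += term
    for layer in range(3):
        al = lp[layer, 0]
        bb = complex(lp[layer, 1], lp[layer, 3])
        dd = complex(lp[layer, 2], lp[layer, 4])
        for i in range(n):
            zi = z[layer, i]
            az = zi.real * zi.real + zi.imag * zi.imag
            if az >= 1.0:
                return 1
            if layer == 0:
                x = stim
            elif layer == 1:
                x = x1[i]
            else:
                x = w23 * z[1, i] + w13 * z[0, i]
            if fscale:
                a = complex(al, TWO_PI)
                scale = freqs[i]
            else:
                a = complex(al, TWO_PI * freqs[i])
                scale = 1.0
            dz[layer, i] = scale * (zi * (a + bb * az + dd * az * az / (1.0 - az)) + x)
    for e in range(nnz):
        ce = c[e]
        ac = ce.real * ce.real + ce.imag * ce.imag
        if ac >= 1.0:
            return 2
        i = tgt[e]
        j = src[e]
        heb = complex(kappa, 0.0)
        zt = z[1, i]
        for _ in range(me[e]):
            heb *= zt
        zs = np.conj(z[0, j])
        for _ in range(ke[e]):
            heb *= zs
        if hebb_fscale:
            cs = np.sqrt(freqs[i] * freqs[j])
        else:
            cs = 1.0
        dc[e] = cs * (ce * (lam + mu1 * ac + mu2 * ac * ac / (1.0 - ac)) + heb) / tau
    return 0


@njit(cache=True)
def rk4_network(z0, c0, tgt, src, ke, me, freqs, lp,
                w23, w13, lam, mu1, mu2, kappa, tau,
                stim, dt, n_steps, fscale, hebb_fscale, traj_stride):
    n = z0.shape[1]
    nnz = c0.shape[0]
    z = z0.copy()
    c = c0.copy()
    mf = np.zeros((3, n_steps + 1), dtype=np.complex128)
    if traj_stride > 0:
        n_kept = n_steps // traj_stride + 1
    else:
        n_kept = 1
    traj = np.zeros((3, n, n_kept), dtype=np.complex128)

    k1z = np.zeros((3, n), dtype=np.complex128)
    k2z = np.zeros((3, n), dtype=np.complex128)
    k3z = np.zeros((3, n), dtype=np.complex128)
    k4z = np.zeros((3, n), dtype=np.complex128)
    k1c = np.zeros(nnz, dtype=np.complex128)
    k2c = np.zeros(nnz, dtype=np.complex128)
    k3c = np.zeros(nnz, dtype=np.complex128)
    k4c = np.zeros(nnz, dtype=np.complex128)

    for layer in range(3):
        acc = 0.0 + 0.0j
        for i in range(n):
            acc += z[layer, i]
        mf[layer, 0] = acc / n
    if traj_stride > 0:
        traj[:, :, 0] = z

    status = 0
    t_fail = -1
    for s in range(n_steps):
        s0 = stim[2 * s]
        sm = stim[2 * s + 1]
        s1 = stim[2 * s + 2]

        status = _rhs(z, c, s0, tgt, src, ke, me, freqs, lp,
                      w23, w13, lam, mu1, mu2, kappa, tau, fscale, hebb_fscale, k1z, k1c)
        if status != 0:
            t_fail = s
            break
        status = _rhs(z + 0.5 * dt * k1z, c + 0.5 * dt * k1c, sm, tgt, src, ke, me,
                      freqs, lp, w23, w13, lam, mu1, mu2, kappa, tau, fscale, hebb_fscale, k2z, k2c)
        if status != 0:
            t_fail = s
            break
        status = _rhs(z + 0.5 * dt * k2z, c + 0.5 * dt * k2c, sm, tgt, src, ke, me,
                      freqs, lp, w23, w13, lam, mu1, mu2, kappa, tau, fscale, hebb_fscale, k3z, k3c)
        if status != 0:
            t_fail = s
            break
        status = _rhs(z + dt * k3z, c + dt * k3c, s1, tgt, src, ke, me,
                      freqs, lp, w23, w13, lam, mu1, mu2, kappa, tau, fscale, hebb_fscale, k4z, k4c)
        if status != 0:
            t_fail = s
            break

        z = z + (dt / 6.0) * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
        c = c + (dt / 6.0) * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)

        check = 0.0
        for layer in range(3):
            acc = 0.0 + 0.0j
            for i in range(n):
                acc += z[layer, i]
            mf[layer, s + 1] = acc / n
            check += mf[layer, s + 1].real + mf[layer, s + 1].imag
        if not np.isfinite(check):
            status = 3
            t_fail = s
            break
        if traj_stride > 0 and (s + 1) % traj_stride == 0:
            traj[:, :, (s + 1) // traj_stride] = z

    return mf, z, c, traj, status, t_fail
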