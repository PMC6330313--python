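"""Numba-compiled inner loops for the stochastic dynamics engines.

The kernels are deliberately dumb: they take flat float64/int64 arrays,
pre-generated Gaussian noise, and return arrays. All validation, RNG
management and object plumbing happens in the calling modules, so
determinism is a property of the numpy Generator seeding, not of numba
internals.

Conventions shared with the rest of the package:
  * angles wrapped to (-pi, pi]
  * overdamped Langevin update
      x <- x - (dt/friction) * grad(U + V_bias) + sqrt(2*kT*dt/friction) * xi
  * well mixture potential
      U(x) = -kT * log sum_k exp(depth_k - sum_j d_ang(x_j, c_kj)^2 / (2 s_k^2))
  * collective variables are either linear sin/cos combinations over a set
    of torsions (kind 0, non-periodic in CV space) or a single raw torsion
    (kind 1, periodic in CV space).
"""

import numpy as np
from numba import njit

PI = np.pi
TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _wrap(x):
    return PI - ((PI - x) % TWO_PI)


@njit(cache=True)
def well_energy(centers, depths, widths, kT, x):
    """U(x) for the Gaussian well mixture, in units of kT*[energy]."""
    n_wells = centers.shape[0]
    n = x.shape[0]
    # log-sum-exp over wells
    m = -1.0e300
    e = np.empty(n_wells)
    for k in range(n_wells):
        d2 = 0.0
        for j in range(n):
            d = _wrap(x[j] - centers[k, j])
            d2 += d * d
        e[k] = depths[k] - d2 / (2.0 * widths[k] * widths[k])
        if e[k] > m:
            m = e[k]
    s = 0.0
    for k in range(n_wells):
        s += np.exp(e[k] - m)
    return -kT * (m + np.log(s))


@njit(cache=True)
def well_gradient(centers, depths, widths, kT, x, out):
    """dU/dx into ``out``; softmax-weighted pull toward each well center."""
    n_wells = centers.shape[0]
    n = x.shape[0]
    e = np.empty(n_wells)
    m = -1.0e300
    for k in range(n_wells):
        d2 = 0.0
        for j in range(n):
            d = _wrap(x[j] - centers[k, j])
            d2 += d * d
        e[k] = depths[k] - d2 / (2.0 * widths[k] * widths[k])
        if e[k] > m:
            m = e[k]
    z = 0.0
    for k in range(n_wells):
        e[k] = np.exp(e[k] - m)
        z += e[k]
    for j in range(n):
        g = 0.0
        for k in range(n_wells):
            d = _wrap(x[j] - centers[k, j])
            g += (e[k] / z) * d / (widths[k] * widths[k])
        out[j] = kT * g
    return out


@njit(cache=True)
def langevin_run(centers, depths, widths, kT, friction, dt,
                 x0, n_steps, save_stride, noise):
    """Unbiased overdamped Langevin on the well mixture.

    Returns (frames, fail_step); fail_step == -1 on success, otherwise the
    1-based step at which a non-finite force first appeared.
    """
    n = x0.shape[0]
    n_saved = n_steps // save_stride + 1
    frames = np.empty((n_saved, n))
    x = x0.copy()
    for j in range(n):
        frames[0, j] = x[j]
    grad = np.empty(n)
    mob = dt / friction
    amp = np.sqrt(2.0 * kT * dt / friction)
    idx = 1
    for step in range(1, n_steps + 1):
        well_gradient(centers, depths, widths, kT, x, grad)
        for j in range(n):
            if not np.isfinite(grad[j]):
                return frames[:idx], step
            x[j] = _wrap(x[j] - mob * grad[j] + amp * noise[step - 1, j])
        if step % save_stride == 0:
            for j in range(n):
                frames[idx, j] = x[j]
            idx += 1
    return frames, -1


@njit(cache=True)
def _cv_values_and_jac(cv_kind, cv_ptr, cv_idx, cv_a, cv_b, x, s, jac):
    """Evaluate all CVs and their Jacobian d s_d / d x_j (dense)."""
    n_cv = cv_kind.shape[0]
    n = x.shape[0]
    for d in range(n_cv):
        for j in range(n):
            jac[d, j] = 0.0
        if cv_kind[d] == 1:  # raw torsion
            j = cv_idx[cv_ptr[d]]
            s[d] = x[j]
            jac[d, j] = 1.0
        else:  # sin/cos linear combination
            val = 0.0
            for p in range(cv_ptr[d], cv_ptr[d + 1]):
                j = cv_idx[p]
                val += cv_a[p] * np.sin(x[j]) + cv_b[p] * np.cos(x[j])
                jac[d, j] += cv_a[p] * np.cos(x[j]) - cv_b[p] * np.sin(x[j])
            s[d] = val


@njit(cache=True)
def hills_bias_and_deriv(hill_centers, hill_heights, sigmas, periodic,
                         n_hills, s, dV):
    """Bias V(s) from the first ``n_hills`` hills; dV/ds into ``dV``."""
    n_cv = s.shape[0]
    V = 0.0
    for d in range(n_cv):
        dV[d] = 0.0
    for k in range(n_hills):
        arg = 0.0
        for d in range(n_cv):
            diff = s[d] - hill_centers[k, d]
            if periodic[d]:
                diff = _wrap(diff)
            arg += diff * diff / (2.0 * sigmas[d] * sigmas[d])
        g = hill_heights[k] * np.exp(-arg)
        V += g
        for d in range(n_cv):
            diff = s[d] - hill_centers[k, d]
            if periodic[d]:
                diff = _wrap(diff)
            dV[d] += -g * diff / (sigmas[d] * sigmas[d])
    return V


@njit(cache=True)
def wtmetad_run(centers, depths, widths, kT, friction, dt,
                cv_kind, cv_ptr, cv_idx, cv_a, cv_b,
                sigmas, periodic, w0, stride, biasfactor,
                x0, n_steps, save_stride, noise):
    """Well-tempered metadynamics with direct hill summation.

    Hills are deposited every ``stride`` integration steps at the current
    CV value with the tempered height w0 * exp(-V(s) / ((gamma - 1) kT)).

    Returns (frames, hill_times, hill_centers, hill_heights, n_hills,
    fail_step).
    """
    n = x0.shape[0]
    n_cv = cv_kind.shape[0]
    max_hills = n_steps // stride + 1
    hill_centers = np.zeros((max_hills, n_cv))
    hill_heights = np.zeros(max_hills)
    hill_times = np.zeros(max_hills, dtype=np.int64)
    n_hills = 0

    n_saved = n_steps // save_stride + 1
    frames = np.empty((n_saved, n))
    x = x0.copy()
    for j in range(n):
        frames[0, j] = x[j]
    idx = 1

    grad = np.empty(n)
    s = np.empty(n_cv)
    jac = np.empty((n_cv, n))
    dV = np.empty(n_cv)
    mob = dt / friction
    amp = np.sqrt(2.0 * kT * dt / friction)

    for step in range(1, n_steps + 1):
        well_gradient(centers, depths, widths, kT, x, grad)
        _cv_values_and_jac(cv_kind, cv_ptr, cv_idx, cv_a, cv_b, x, s, jac)
        hills_bias_and_deriv(hill_centers, hill_heights, sigmas, periodic,
                             n_hills, s, dV)
        for j in range(n):
            f = grad[j]
            for d in range(n_cv):
                f += dV[d] * jac[d, j]
            if not np.isfinite(f):
                return (frames[:idx], hill_times[:n_hills],
                        hill_centers[:n_hills], hill_heights[:n_hills],
                        n_hills, step)
            x[j] = _wrap(x[j] - mob * f + amp * noise[step - 1, j])
        if step % stride == 0:
            _cv_values_and_jac(cv_kind, cv_ptr, cv_idx, cv_a, cv_b, x, s, jac)
            V = hills_bias_and_deriv(hill_centers, hill_heights, sigmas,
                                     periodic, n_hills, s, dV)
            h = w0 * np.exp(-V / ((biasfactor - 1.0) * kT))
            for d in range(n_cv):
                hill_centers[n_hills, d] = s[d]
            hill_heights[n_hills] = h
            hill_times[n_hills] = step
            n_hills += 1
        if step % save_stride == 0:
            for j in range(n):
                frames[idx, j] = x[j]
            idx += 1
    return (frames, hill_times[:n_hills], hill_centers[:n_hills],
            hill_heights[:n_hills], n_hills, -1)


@njit(cache=True)
def markov_chain_run(cum_rows, start, uniforms):
    """Sample a discrete chain from row-wise cumulative probabilities."""
    n_steps = uniforms.shape[0]
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = start
    state = start
    n_states = cum_rows.shape[1]
    for t in range(n_steps):
        u = uniforms[t]
        row = cum_rows[state]
        nxt = n_states - 1
        for j in range(n_states):
            if u <= row[j]:
                nxt = j
                break
        out[t + 1] = nxt
        state = nxt
    return out
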