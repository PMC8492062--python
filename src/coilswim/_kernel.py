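"""Numba inner loop of the network simulation.

All state variables advance by forward Euler at a fixed dt (0.1 ms).  Chemical
synapses are event-triggered: an upward crossing of the synaptic threshold by
the presynaptic neuron starts (or, in renewal mode, restarts) the
double-exponential kernel after the axonal conduction delay.  Gap junctions
read the delayed presynaptic potential from a ring buffer.

The kernel returns the number of spikes recorded, or ``-(step + 1)`` if the
membrane potential of any neuron became non-finite at ``step``.
"""

import numpy as np
from numba import njit

#: events older than this (ms) contribute < 4e-7 of the kernel peak and are skipped
KERNEL_CUTOFF_MS = 16.0

#: per-neuron ring of recent threshold-crossing times used for delayed lookup
N_CROSS = 8


@njit(cache=True)
def _kernel_value(s, tau_r, tau_f):
    # negative for tau_r < tau_f; multiplied by (Vpost - Erev) this depolarizes
    # toward Erev
    return np.exp(-s / tau_r) - np.exp(-s / tau_f)


@njit(cache=True)
def step_loop(
    n_steps,
    dt,
    # neuron state and parameters (length n arrays)
    V,
    u,
    pa,
    pb,
    pc,
    pd_,
    pvmax,
    pvr,
    pvt,
    pk,
    pC,
    drive_amp,
    drive_onset,
    sigma_d,
    noise_seed,
    # gap junctions
    g_pre,
    g_post,
    g_w,
    g_del,  # delays in steps
    gap_mode,  # 0 difference, 1 printed, 2 deviation-from-rest
    # chemical synapses (neuron -> neuron)
    c_pre,
    c_post,
    c_w,
    c_del_ms,
    c_erev,
    c_is_gly,
    tau_r,
    tau_f,
    v_thr,
    chem_off_ms,
    sum_kernels,
    # neuromuscular synapses
    m_pre,
    m_idx,
    m_w,
    # perturbations
    sil_mask,  # (E, n) bool
    sil_epochs,  # (E, 2) ms
    sil_gap_too,
    gly_epochs,  # (Eg, 2)
    glut_epochs,  # (Eu, 2)
    # outputs / buffers
    v_buf,  # (L, n) ring of past V
    v_out,  # (n_stored, n) float32, row 0 pre-filled with V
    out_stride,
    musc_out,  # (n_mus, n_steps) float32 input currents
    spike_t,
    spike_id,
):
    n = V.shape[0]
    L = v_buf.shape[0]
    n_gap = g_pre.shape[0]
    n_chem = c_pre.shape[0]
    n_mus = m_pre.shape[0]
    max_spikes = spike_t.shape[0]
    np.random.seed(noise_seed)

    cross_t = np.full((n, N_CROSS), -1.0e18)
    cross_ptr = np.zeros(n, dtype=np.int64)

    isyn = np.zeros(n)
    silenced = np.zeros(n, dtype=np.bool_)
    n_spikes = 0

    for s in range(n_steps):
        t = s * dt

        # active perturbation windows
        for i in range(n):
            silenced[i] = False
        for e in range(sil_epochs.shape[0]):
            if sil_epochs[e, 0] <= t < sil_epochs[e, 1]:
                for i in range(n):
                    if sil_mask[e, i]:
                        silenced[i] = True
        gly_blocked = False
        for e in range(gly_epochs.shape[0]):
            if gly_epochs[e, 0] <= t < gly_epochs[e, 1]:
                gly_blocked = True
        glut_blocked = False
        for e in range(glut_epochs.shape[0]):
            if glut_epochs[e, 0] <= t < glut_epochs[e, 1]:
                glut_blocked = True

        # synaptic currents from the state at the start of the step
        for i in range(n):
            isyn[i] = 0.0

        for ci in range(n_gap):
            post = g_post[ci]
            if silenced[post] and sil_gap_too:
                continue
            d = g_del[ci]
            if d == 0:
                vpre = V[g_pre[ci]]
            else:
                vpre = v_buf[(s - d) % L, g_pre[ci]]
            if gap_mode == 1:  # printed Ohmic form
                isyn[post] += vpre * g_w[ci]
            elif gap_mode == 2:  # presynaptic deviation from rest
                isyn[post] += (vpre - pvr[g_pre[ci]]) * g_w[ci]
            elif gap_mode == 3:  # difference of deviations from rest
                isyn[post] += (
                    (vpre - pvr[g_pre[ci]]) - (V[post] - pvr[post])
                ) * g_w[ci]
            else:  # conventional transjunctional difference
                isyn[post] += (vpre - V[post]) * g_w[ci]

        if t >= chem_off_ms:
            for ci in range(n_chem):
                post = c_post[ci]
                if silenced[post]:
                    continue
                if c_is_gly[ci]:
                    if gly_blocked:
                        continue
                elif glut_blocked:
                    continue
                pre = c_pre[ci]
                d = c_del_ms[ci]
                ptr = cross_ptr[pre]
                if sum_kernels:
                    acc = 0.0
                    for kk in range(N_CROSS):
                        ck = cross_t[pre, (ptr - 1 - kk) % N_CROSS]
                        sk = t - ck - d
                        if sk < 0.0:
                            continue
                        if sk > KERNEL_CUTOFF_MS:
                            break
                        acc += _kernel_value(sk, tau_r, tau_f)
                    if acc != 0.0:
                        isyn[post] += (V[post] - c_erev[ci]) * acc * c_w[ci]
                else:
                    for kk in range(N_CROSS):
                        ck = cross_t[pre, (ptr - 1 - kk) % N_CROSS]
                        sk = t - ck - d
                        if sk >= 0.0:
                            if sk <= KERNEL_CUTOFF_MS:
                                isyn[post] += (
                                    (V[post] - c_erev[ci])
                                    * _kernel_value(sk, tau_r, tau_f)
                                    * c_w[ci]
                                )
                            break

        # tonic drives; the motor-command amplitude is one quantity, so its
        # per-step multiplicative noise is a single shared draw
        noise_fac = 1.0
        if sigma_d > 0.0:
            noise_fac = 1.0 + sigma_d * np.random.normal()
        for i in range(n):
            if drive_amp[i] != 0.0 and t >= drive_onset[i] and not silenced[i]:
                isyn[i] += drive_amp[i] * noise_fac

        # neuromuscular input currents (kernel-only, positive)
        if t >= chem_off_ms:
            for ci in range(n_mus):
                pre = m_pre[ci]
                ptr = cross_ptr[pre]
                for kk in range(N_CROSS):
                    ck = cross_t[pre, (ptr - 1 - kk) % N_CROSS]
                    sk = t - ck
                    if sk >= 0.0:
                        if sk <= KERNEL_CUTOFF_MS:
                            musc_out[m_idx[ci], s] += np.float32(
                                -m_w[ci] * _kernel_value(sk, tau_r, tau_f)
                            )
                        break

        # integrate neurons
        store = (s + 1) % out_stride == 0
        row = (s + 1) // out_stride
        for i in range(n):
            # chem/drive already withheld from silenced neurons above; isyn
            # holds at most their residual gap input (when sil_gap_too=False)
            cur = isyn[i]
            vold = V[i]
            vnew = vold + dt * (
                (pk[i] * (vold - pvr[i]) * (vold - pvt[i]) - u[i] + cur) / pC[i]
            )
            unew = u[i] + dt * pa[i] * (pb[i] * (vold - pvr[i]) - u[i])
            if not np.isfinite(vnew):
                return -(s + 1)
            trace = vnew
            if vnew >= pvmax[i]:
                trace = pvmax[i]
                if n_spikes < max_spikes:
                    spike_t[n_spikes] = t + dt
                    spike_id[n_spikes] = i
                n_spikes += 1
                vnew = pc[i]
                unew = unew + pd_[i]
            if vold < v_thr and trace >= v_thr:
                cross_t[i, cross_ptr[i] % N_CROSS] = t + dt
                cross_ptr[i] += 1
            V[i] = vnew
            u[i] = unew
            v_buf[(s + 1) % L, i] = trace
            if store and row < v_out.shape[0]:
                v_out[row, i] = np.float32(trace)

    return n_spikes
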