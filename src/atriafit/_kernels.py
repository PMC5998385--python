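"""Numba kernels for the reaction sub-steps of the operator-split monodomain
solvers.  The diffusion half-step stays in scipy (banded / sparse LU); only the
pointwise ionic update is hot enough to compile."""

import numba


@numba.njit(cache=True)
def react_uniform(vm, h, tau_in, tau_out, tau_open, tau_close, v_gate,
                  dt, nsub, stim_amp, stim_n):
    """Forward-Euler reaction sub-steps with uniform parameters (1D cable).

    ``stim_amp`` (1/ms) is added to the first ``stim_n`` nodes.
    """
    n = vm.shape[0]
    for _ in range(nsub):
        for i in range(n):
            v = vm[i]
            hh = h[i]
            dv = hh * v * (v - v_gate) * (1.0 - v) / tau_in - v / tau_out
            if i < stim_n:
                dv += stim_amp
            if v < v_gate:
                dh = (1.0 - hh) / tau_open
            else:
                dh = -hh / tau_close
            vm[i] = v + dt * dv
            h[i] = hh + dt * dh


@numba.njit(cache=True)
def react_hetero(vm, h, tau_in, tau_out, tau_open, tau_close, v_gate,
                 dt, nsub, stim_amp, stim_idx):
    """Reaction sub-steps with per-node parameters (surface model).

    ``stim_idx`` is an integer index array of stimulated vertices.
    """
    n = vm.shape[0]
    for _ in range(nsub):
        for i in range(n):
            v = vm[i]
            hh = h[i]
            dv = hh * v * (v - v_gate) * (1.0 - v) / tau_in[i] - v / tau_out[i]
            if v < v_gate:
                dh = (1.0 - hh) / tau_open[i]
            else:
                dh = -hh / tau_close[i]
            vm[i] = v + dt * dv
            h[i] = hh + dt * dh
        if stim_amp != 0.0:
            for k in range(stim_idx.shape[0]):
                vm[stim_idx[k]] += dt * stim_amp
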