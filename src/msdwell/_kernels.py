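"""Numba kernels for Euler-Maruyama integration.

Kept free of package imports so the JIT signatures stay simple; all state is
passed explicitly and noise increments are pre-drawn from a seeded numpy
Generator by the callers, preserving bit-for-bit reproducibility.
"""

import numba
import numpy as np


@numba.njit
def em_path(x0, alpha, beta, dt, noise, out):
    """Integrate one trajectory; returns the step index of divergence or -1.

    ``noise`` holds the pre-scaled increments sqrt(epsilon*dt)*z_k; ``out``
    must have length len(noise)+1 and receives the path including x0.
    """
    x = x0
    out[0] = x
    for k in range(noise.shape[0]):
        x = x + (x * (1.0 - alpha * x * x) - beta) * dt + noise[k]
        out[k + 1] = x
        if x > 10.0 or x < -10.0:
            return k + 1
    return -1


@numba.njit
def first_passage_chunk(x, t, alpha, beta, dt, noise, target, direction, reset, times, count):
    """Advance a renewal first-passage sampler through one noise chunk.

    The walker evolves under the double-well drift; whenever
    ``direction * (x - target) >= 0`` (commitment to the opposite well) the
    elapsed time ``t`` is recorded in ``times[count]``, the walker is reset
    to ``reset`` and the clock to zero.  Stops early once ``times`` is full.
    Returns the updated ``(x, t, count)``.
    """
    for k in range(noise.shape[0]):
        x = x + (x * (1.0 - alpha * x * x) - beta) * dt + noise[k]
        t += dt
        if direction * (x - target) >= 0.0:
            times[count] = t
            count += 1
            x = reset
            t = 0.0
            if count == times.shape[0]:
                break
    return x, t, count
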