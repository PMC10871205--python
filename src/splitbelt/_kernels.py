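"""Numba kernels for the stride-by-stride state-space recursions.

These loops are called thousands of times inside the least-squares
objective, so they are compiled. The public model surface lives in
:mod:`splitbelt.models`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def vc_loop(a_fast, b_fast, a_slow, b_slow, b_explicit, pert, feedback):
    """Voluntary-correction recursion.

    States start at 0. On each stride the total output is the sum of the
    explicit state and the two implicit states; all states correct for the
    same error, error[s] = perturbation[s] - x_implicit[s]. The explicit
    state is memoryless: x_explicit[s+1] = b_explicit * error[s] on strides
    where the feedback is on, 0 otherwise (and 0 on the first stride, where
    there is no prior error).
    """
    n = pert.shape[0]
    x = np.zeros(n)
    xf = np.zeros(n)
    xs = np.zeros(n)
    xe = np.zeros(n)
    xi = np.zeros(n)
    err = np.zeros(n)
    for s in range(n):
        xi[s] = xf[s] + xs[s]
        x[s] = xe[s] + xi[s]
        err[s] = pert[s] - xi[s]
        if s + 1 < n:
            xf[s + 1] = a_fast * xf[s] + b_fast * err[s]
            xs[s + 1] = a_slow * xs[s] + b_slow * err[s]
            if feedback[s + 1]:
                xe[s + 1] = b_explicit * err[s]
            else:
                xe[s + 1] = 0.0
    return x, xf, xs, xe, xi, err


@njit(cache=True)
def single_loop(a, b, pert):
    """Single-rate recursion x[s+1] = a*x[s] + b*error[s]."""
    n = pert.shape[0]
    x = np.zeros(n)
    err = np.zeros(n)
    for s in range(n):
        err[s] = pert[s] - x[s]
        if s + 1 < n:
            x[s + 1] = a * x[s] + b * err[s]
    return x, err


@njit(cache=True)
def vc_sse(a_fast, b_fast, a_slow, b_slow, b_explicit, pert, feedback, y, mask):
    """Sum of squared errors of the voluntary-correction model on retained strides."""
    n = pert.shape[0]
    xf = 0.0
    xs = 0.0
    xe = 0.0
    sse = 0.0
    for s in range(n):
        xi = xf + xs
        x = xe + xi
        if mask[s]:
            d = y[s] - x
            sse += d * d
        err = pert[s] - xi
        xf = a_fast * xf + b_fast * err
        xs = a_slow * xs + b_slow * err
        if s + 1 < n and feedback[s + 1]:
            xe = b_explicit * err
        else:
            xe = 0.0
    return sse


@njit(cache=True)
def single_sse(a, b, pert, y, mask):
    """Sum of squared errors of the single-rate model on retained strides."""
    n = pert.shape[0]
    x = 0.0
    sse = 0.0
    for s in range(n):
        if mask[s]:
            d = y[s] - x
            sse += d * d
        err = pert[s] - x
        x = a * x + b * err
    return sse
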