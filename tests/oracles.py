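"""Independent stride-loop oracles, coded plainly and separately from the package.

Pure-Python float recursions of the three learning models, used to
cross-check the package's compiled simulators.
"""


def vc_oracle(a_fast, b_fast, a_slow, b_slow, b_explicit, n_adapt, n_dead,
              fb_lo, fb_hi):
    """Voluntary-correction model: returns the list of total outputs x."""
    n = n_adapt + n_dead
    xf, xs, xe = 0.0, 0.0, 0.0
    xs_out = []
    for s in range(n):
        pert = 1.0 if s < n_adapt else 0.0
        xi = xf + xs
        xs_out.append(xe + xi)
        err = pert - xi
        xf_new = a_fast * xf + b_fast * err
        xs_new = a_slow * xs + b_slow * err
        next_feedback_on = (s + 1 < n_adapt) and (fb_lo - 1 <= s + 1 <= fb_hi - 1)
        xe_new = b_explicit * err if next_feedback_on else 0.0
        xf, xs, xe = xf_new, xs_new, xe_new
    return xs_out


def dual_oracle(a_fast, b_fast, a_slow, b_slow, n_adapt, n_dead):
    return vc_oracle(a_fast, b_fast, a_slow, b_slow, 0.0, n_adapt, n_dead, 1, 0)


def single_oracle(a, b, n_adapt, n_dead):
    x = 0.0
    out = []
    for s in range(n_adapt + n_dead):
        pert = 1.0 if s < n_adapt else 0.0
        out.append(x)
        err = pert - x
        x = a * x + b * err
    return out
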