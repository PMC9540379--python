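"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops and scalar math, sharing no
code with the package, so that agreement between the two is meaningful.
"""

import math


def wrap(a):
    out = math.remainder(a, 2 * math.pi)
    return math.pi if out == -math.pi else out


def reference_segment_cost(frame, start, theta, ctx, cfg, fill):
    """Scalar re-implementation of the per-segment penalized cost."""
    n_along, n_across = cfg.probe_samples
    ds, w = cfg.segment_length_px, cfg.probe_width_px
    h, wid = frame.shape
    num = 0.0
    den = 0.0
    for j in range(n_along):
        a = (j + 0.5) * ds / n_along
        for m in range(n_across):
            c = -w / 2 + m * (w / (n_across - 1)) if n_across > 1 else 0.0
            if cfg.transverse_weight_profile == "gaussian":
                wt = math.exp(-(c**2) / (2 * (w / 4) ** 2))
            else:
                wt = 1.0
            x = start[0] + a * math.cos(theta) - c * math.sin(theta)
            y = start[1] + a * math.sin(theta) + c * math.cos(theta)
            if 0 <= x <= wid - 1 and 0 <= y <= h - 1:
                x0 = int(math.floor(min(x, wid - 2)))
                y0 = int(math.floor(min(y, h - 2)))
                fx, fy = x - x0, y - y0
                v = (
                    frame[y0, x0] * (1 - fx) * (1 - fy)
                    + frame[y0, x0 + 1] * fx * (1 - fy)
                    + frame[y0 + 1, x0] * (1 - fx) * fy
                    + frame[y0 + 1, x0 + 1] * fx * fy
                )
            else:
                v = fill
            num += wt * v
            den += wt

    dt2 = ctx.dt_s**2
    ex = start[0] + ds * math.cos(theta)
    ey = start[1] + ds * math.sin(theta)
    cost = -cfg.w_intensity * num / den
    cost += cfg.w_curvature * wrap(theta - ctx.prev_theta_in_frame) ** 2
    cost += (
        cfg.w_tvel
        * ((ex - ctx.prev_frame_node[0]) ** 2 + (ey - ctx.prev_frame_node[1]) ** 2)
        / dt2
    )
    cost += cfg.w_rvel * wrap(theta - ctx.prev_frame_theta) ** 2 / dt2
    cost += (
        cfg.w_dcurv
        * (
            wrap(theta - ctx.prev_theta_in_frame)
            - wrap(ctx.prev_frame_theta - ctx.prev_frame_theta_prev)
        )
        ** 2
        / dt2
    )
    return cost
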