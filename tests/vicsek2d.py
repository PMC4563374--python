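"""Independent 2D Vicsek-with-adaptive-velocity oracle (test support only).

One synchronous step of the planar model: agents move straight by v*dt,
neighbors are found by Euclidean distance at the new positions, each agent
averages its neighbors' headings into zeta, takes the normalized zeta as
its new heading (keeping the old heading when zeta vanishes), and sets
speed v0*|zeta|^alpha (v0 when alpha == 0).

Written directly from the planar model definition with explicit loops; it
shares no code with the sphere implementation so it can serve as the
flat-limit oracle.
"""

import numpy as np


def vicsek_avm_step(x, theta, v, v0, r0, alpha, dt=1.0):
    """One step of the 2D model.

    Parameters: positions ``x`` (n, 2), heading angles ``theta`` (n,),
    speeds ``v`` (n,).  Returns (x_new, theta_new, v_new, zeta_norms).
    """
    n = len(x)
    head = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    x_new = x + v[:, None] * head * dt

    zeta = np.zeros((n, 2))
    for i in range(n):
        acc = np.zeros(2)
        cnt = 0
        for j in range(n):
            if np.hypot(*(x_new[i] - x_new[j])) < r0:
                acc += head[j]
                cnt += 1
        zeta[i] = acc / cnt

    znorm = np.linalg.norm(zeta, axis=1)
    theta_new = np.where(znorm > 1e-12, np.arctan2(zeta[:, 1], zeta[:, 0]), theta)
    v_new = np.full(n, v0) if alpha == 0 else v0 * znorm**alpha
    return x_new, theta_new, v_new, znorm
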