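"""Independent oracles shared by the test modules (not collected by pytest)."""

import numpy as np


def td_gradient_oracle(net, i_prev, a_prev, reward, i_now, h=1e-6):
    """Numerical-gradient oracle for the one-step TD rule.

    Treats the update as one gradient-descent step of size ``alpha`` on the
    squared TD error 0.5 * (target - Q_theta(i_prev, a_prev))**2, with the
    bootstrapped target (reward + gamma * max_a Q(i_now, a)) held constant,
    and differentiates numerically by central differences.  Returns the
    expected (W, b) after the step.
    """
    i_prev = np.asarray(i_prev, dtype=np.float64)
    i_now = np.asarray(i_now, dtype=np.float64)
    target = reward + net.gamma * np.max(net.W @ i_now + net.b)

    def loss(W, b):
        pred = W[a_prev] @ i_prev + b[a_prev]
        return 0.5 * (target - pred) ** 2

    gW = np.zeros_like(net.W)
    gb = np.zeros_like(net.b)
    for idx in np.ndindex(net.W.shape):
        Wp, Wm = net.W.copy(), net.W.copy()
        Wp[idx] += h
        Wm[idx] -= h
        gW[idx] = (loss(Wp, net.b) - loss(Wm, net.b)) / (2 * h)
    for i in range(net.b.shape[0]):
        bp, bm = net.b.copy(), net.b.copy()
        bp[i] += h
        bm[i] -= h
        gb[i] = (loss(net.W, bp) - loss(net.W, bm)) / (2 * h)
    return net.W - net.alpha * gW, net.b - net.alpha * gb


def brute_force_landscape_optimum(q, c, pi0, step):
    """Exhaustive scan of the plastic-fitness surface, written independently
    of the package's landscape code: returns (delta*, best fitness)."""
    n = int(round(1.0 / step))
    axis = np.array([i * step for i in range(n + 1)])
    best = -np.inf
    best_delta = None
    for d in axis:
        for a in axis:
            w = (
                pi0 * min(1.0, a + d) ** q
                + (1 - pi0) * min(1.0, 1 - a + d) ** q
                - c * d
            )
            if w > best + 1e-12:
                best = w
                best_delta = d
    return best_delta, best
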