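"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the makima oracle
implements the published slope formula directly; the ERGM oracles enumerate
all graphs / maximize the exact transition likelihood with generic numerical
optimization.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

from cownet.network import DailyNetwork, dyads, from_dyad_vector
from cownet.stergm import network_statistics


# -- modified Akima (makima) interpolation ------------------------------------

def makima_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Node derivatives of the modified Akima scheme.

    With segment slopes d_i = (y_{i+1} - y_i) / (x_{i+1} - x_i), extended at
    the ends by d_{-1} = 2 d_0 - d_1 (and symmetrically), the node derivative
    is the weighted mean of the two neighbouring slopes with weights
    w1 = |d_{i+1} - d_i| + |d_{i+1} + d_i| / 2 and
    w2 = |d_{i-1} - d_{i-2}| + |d_{i-1} + d_{i-2}| / 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.diff(y) / np.diff(x)
    d = np.concatenate([[2 * d[0] - d[1], 0], d, [0, 0]])
    d[1] = 2 * d[2] - d[3]  # d_{-1}
    d[0] = 2 * d[1] - d[2]  # d_{-2}
    d[-2] = 2 * d[-3] - d[-4]
    d[-1] = 2 * d[-2] - d[-3]
    n = len(x)
    s = np.zeros(n)
    for i in range(n):
        dm2, dm1, dp0, dp1 = d[i], d[i + 1], d[i + 2], d[i + 3]
        w1 = abs(dp1 - dp0) + abs(dp1 + dp0) / 2
        w2 = abs(dm1 - dm2) + abs(dm1 + dm2) / 2
        s[i] = 0.0 if (w1 + w2) == 0 else (w1 * dm1 + w2 * dp0) / (w1 + w2)
    return s


def makima_eval(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Cubic Hermite evaluation with makima node derivatives."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = makima_slopes(x, y)
    xq = np.asarray(xq, dtype=float)
    out = np.empty_like(xq)
    idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, len(x) - 2)
    for k, (q, i) in enumerate(zip(xq, idx)):
        h = x[i + 1] - x[i]
        t = (q - x[i]) / h
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[k] = h00 * y[i] + h10 * h * s[i] + h01 * y[i + 1] + h11 * h * s[i + 1]
    return out


# -- exact ERGM distributions over free dyads ---------------------------------

def enumerate_phase_distribution(y_prev, theta, spec, cov, phase: str):
    """Exact probabilities of every reachable phase-target network.

    Enumerates all assignments of the phase's free dyads (empty dyads for
    formation, tied dyads for persistence), computing unnormalized weights
    exp(theta . g(y)) with g evaluated on the full network.  Returns a dict
    mapping free-dyad bit tuples to probabilities.
    """
    n = y_prev.n
    iu, ju = dyads(n)
    prev = y_prev.adjacency[iu, ju]
    free = np.flatnonzero(prev == 0 if phase == "formation" else prev == 1)
    theta = np.asarray(theta, dtype=float)
    weights = {}
    for bits in itertools.product((0, 1), repeat=len(free)):
        vec = prev.copy()
        vec[free] = bits
        net = from_dyad_vector(vec, y_prev.roster)
        g = network_statistics(net, spec, cov)
        weights[bits] = np.exp(float(theta @ g))
    z = sum(weights.values())
    return {bits: w / z for bits, w in weights.items()}


def exact_transition_loglik(theta_f, theta_p, transitions, spec, cov):
    """Exact pooled STERGM transition log-likelihood (enumeration; tiny n only)."""
    total = 0.0
    for tr in transitions:
        for phase, target, theta in (
            ("formation", tr.y_plus, theta_f),
            ("persistence", tr.y_minus, theta_p),
        ):
            dist = enumerate_phase_distribution(tr.y_prev, theta, spec, cov, phase)
            iu, ju = dyads(tr.y_prev.n)
            prev = tr.y_prev.adjacency[iu, ju]
            free = np.flatnonzero(prev == 0 if phase == "formation" else prev == 1)
            bits = tuple(target.adjacency[iu, ju][free])
            total += np.log(dist[bits])
    return total


def direct_transition_mle(transitions, spec, cov, x0=None):
    """Maximize the exact transition likelihood numerically (both phases)."""
    p = len(spec.terms)

    def negll(packed):
        return -exact_transition_loglik(packed[:p], packed[p:], transitions, spec, cov)

    x0 = np.zeros(2 * p) if x0 is None else np.asarray(x0, dtype=float)
    res = minimize(negll, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x[:p], res.x[p:], res


# -- misc brute force ---------------------------------------------------------

def triangle_count(adjacency: np.ndarray) -> int:
    """Count triangles by exhaustive vertex-triple enumeration."""
    n = adjacency.shape[0]
    count = 0
    for i, j, k in itertools.combinations(range(n), 3):
        if adjacency[i, j] and adjacency[j, k] and adjacency[i, k]:
            count += 1
    return count
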