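"""Numba inner loops for the direct-method SSA.

All kernels share one convention for the reaction tables produced by
``ReactionNetwork.kernel_tables()``: ``order[j]`` is the order code
(0 zeroth, 1 unimolecular, 2 homo-bimolecular, 3 hetero-bimolecular),
``s1[j]``/``s2[j]`` the reactant species indices (-1 when unused) and
``net[j]`` the state-change vector.  Randomness comes from an explicit
``numpy.random.Generator`` passed straight into nopython code, so every
caller controls its own stream.

``H_j`` integrals are accumulated with Kahan compensation (the ``hcomp``
arrays): an interval may be split into up to 1e6 waiting times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "interval_stats",
    "ensemble_interval",
    "consistent_segment",
    "interval_events",
]


@njit(cache=True, inline="always")
def _propensities(order, s1, s2, theta, x, h, a):
    a0 = 0.0
    for j in range(order.shape[0]):
        if order[j] == 0:
            hj = 1.0
        elif order[j] == 1:
            hj = float(x[s1[j]])
        elif order[j] == 2:
            n = float(x[s1[j]])
            hj = n * (n - 1.0) * 0.5
        else:
            hj = float(x[s1[j]]) * float(x[s2[j]])
        h[j] = hj
        a[j] = theta[j] * hj
        a0 += a[j]
    return a0


@njit(cache=True, inline="always")
def _accrue_h(h, tau, H, hcomp):
    for j in range(h.shape[0]):
        term = h[j] * tau - hcomp[j]
        total = H[j] + term
        hcomp[j] = (total - H[j]) - term
        H[j] = total


@njit(cache=True)
def interval_stats(order, s1, s2, net, theta, x, dt, max_events, rng, r, H, hcomp):
    """Simulate one interval of length ``dt``, accumulating (r_j, H_j).

    ``x`` is advanced in place to the state at the interval end; ``r``,
    ``H`` and ``hcomp`` accumulate in place (callers zero them to start a
    fresh tally or keep them to extend a running one).  Returns the number
    of firings, or -1 if ``max_events`` was exceeded.
    """
    M = order.shape[0]
    h = np.empty(M)
    a = np.empty(M)
    t = 0.0
    n_events = 0
    while True:
        a0 = _propensities(order, s1, s2, theta, x, h, a)
        if a0 <= 0.0:
            _accrue_h(h, dt - t, H, hcomp)
            return n_events
        tau = rng.exponential(1.0 / a0)
        if t + tau > dt:
            _accrue_h(h, dt - t, H, hcomp)
            return n_events
        t += tau
        _accrue_h(h, tau, H, hcomp)
        u = rng.random() * a0
        acc = 0.0
        jp = M - 1
        for j in range(M):
            acc += a[j]
            if u < acc:
                jp = j
                break
        for i in range(net.shape[1]):
            x[i] += net[jp, i]
        r[jp] += 1
        n_events += 1
        if n_events > max_events:
            return -1


@njit(cache=True)
def ensemble_interval(order, s1, s2, net, thetas, X, dt, max_events, rng, R, H, hcomp):
    """Advance ``K`` ensemble members through one interval.

    ``thetas`` is (K, M): each member uses its own (perturbed) rates.
    ``X`` (K, N), ``R``/``H``/``hcomp`` (K, M) are updated in place.
    Returns a (K,) event-count array with -1 marking runaway members.
    """
    K = X.shape[0]
    nev = np.empty(K, dtype=np.int64)
    for k in range(K):
        nev[k] = interval_stats(
            order, s1, s2, net, thetas[k], X[k], dt, max_events, rng, R[k], H[k], hcomp[k]
        )
    return nev


@njit(cache=True)
def consistent_segment(
    order, s1, s2, net, theta, x_start, dt, obs_idx, target,
    max_retries, max_events, max_total_events, rng, x_out, r_out, H_out,
):
    """Rejection-sample one segment that ends exactly on the observed datum.

    Repeatedly simulates ``[0, dt]`` from ``x_start`` until the end state
    matches ``target`` on the species in ``obs_idx``.  On success the end
    state is written to ``x_out`` and the accepted segment's (r_j, H_j)
    to ``r_out``/``H_out`` (overwritten, not accumulated).  Returns
    ``(status, attempts, total_events)`` with status 0 on success, -1 when
    ``max_retries`` is exhausted, -2 when a single attempt exceeded
    ``max_events``, -3 when the cumulative firing count across attempts
    exceeded ``max_total_events`` (an external event budget).
    """
    M = order.shape[0]
    hcomp = np.empty(M)
    total_events = 0
    for attempt in range(1, max_retries + 1):
        for i in range(x_start.shape[0]):
            x_out[i] = x_start[i]
        for j in range(M):
            r_out[j] = 0
            H_out[j] = 0.0
            hcomp[j] = 0.0
        nev = interval_stats(
            order, s1, s2, net, theta, x_out, dt, max_events, rng, r_out, H_out, hcomp
        )
        if nev < 0:
            return -2, attempt, total_events
        total_events += nev
        if total_events > max_total_events:
            return -3, attempt, total_events
        ok = True
        for i in range(obs_idx.shape[0]):
            if x_out[obs_idx[i]] != target[i]:
                ok = False
                break
        if ok:
            return 0, attempt, total_events
    return -1, max_retries, total_events


@njit(cache=True)
def interval_events(order, s1, s2, net, theta, x, dt, max_events, rng):
    """Simulate one interval recording the full firing sequence.

    ``x`` is advanced in place.  Returns ``(taus, js, n, residual)``; the
    arrays are valid up to ``n``, and ``n`` is -1 when ``max_events`` was
    exceeded.  Buffers grow geometrically so the RNG stream is identical
    whatever the final event count.
    """
    M = order.shape[0]
    h = np.empty(M)
    a = np.empty(M)
    cap = 1024
    taus = np.empty(cap)
    js = np.empty(cap, dtype=np.int64)
    t = 0.0
    n = 0
    while True:
        a0 = _propensities(order, s1, s2, theta, x, h, a)
        if a0 <= 0.0:
            return taus, js, n, dt - t
        tau = rng.exponential(1.0 / a0)
        if t + tau > dt:
            return taus, js, n, dt - t
        t += tau
        u = rng.random() * a0
        acc = 0.0
        jp = M - 1
        for j in range(M):
            acc += a[j]
            if u < acc:
                jp = j
                break
        for i in range(net.shape[1]):
            x[i] += net[jp, i]
        if n >= cap:
            if cap >= max_events:
                return taus, js, -1, 0.0
            cap *= 2
            new_taus = np.empty(cap)
            new_js = np.empty(cap, dtype=np.int64)
            new_taus[:n] = taus
            new_js[:n] = js
            taus = new_taus
            js = new_js
        taus[n] = tau
        js[n] = jp
        n += 1
        if n > max_events:
            return taus, js, -1, 0.0
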