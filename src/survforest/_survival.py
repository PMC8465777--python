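"""Shared survival primitives: response parsing, Nelson–Aalen / Kaplan–Meier
node estimates and log-rank scores.

These are deliberately small array routines: they run inside every tree
node, so they avoid object construction and work on plain ndarrays.
"""

from __future__ import annotations

import numpy as np


def check_time_event(y):
    """Coerce a survival response to ``(time, event)`` float/int arrays.

    Accepts a structured array with ``event``/``time`` fields (the
    scikit-survival convention, in either field order), a tuple/list
    ``(time, event)``, or an ``(n, 2)`` array with columns time, event.
    """
    if hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        ev_field = next(n for n in names if y.dtype[n].kind == "b" or "event" in n.lower() or "status" in n.lower())
        t_field = next(n for n in names if n != ev_field)
        time = np.asarray(y[t_field], dtype=float)
        event = np.asarray(y[ev_field]).astype(int)
    elif isinstance(y, (tuple, list)) and len(y) == 2:
        time = np.asarray(y[0], dtype=float)
        event = np.asarray(y[1]).astype(int)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("y must be structured, (time, event) or an (n, 2) array")
        time, event = arr[:, 0], arr[:, 1].astype(int)
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def event_time_table(time, event):
    """Distinct event times with event counts and at-risk counts.

    Returns ``(ut, d, Y)`` where ``ut`` are the distinct times at which at
    least one event occurs (ascending), ``d[k]`` the number of events at
    ``ut[k]`` and ``Y[k]`` the number of subjects with ``time >= ut[k]``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    all_ut, inv = np.unique(time, return_inverse=True)
    counts = np.bincount(inv, minlength=all_ut.size)
    d_all = np.bincount(inv, weights=event.astype(float), minlength=all_ut.size)
    n = time.size
    at_risk = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    keep = d_all > 0
    return all_ut[keep], d_all[keep], at_risk[keep].astype(float)


def chf_surv_on_grid(time, event, grid):
    """Nelson–Aalen CHF and Kaplan–Meier survival of a node, on ``grid``.

    Both are right-continuous step functions, carried forward between
    knots; before the first event the CHF is 0 and survival is 1.
    """
    ut, d, Y = event_time_table(time, event)
    if ut.size == 0:
        return np.zeros(len(grid)), np.ones(len(grid))
    chf = np.cumsum(d / Y)
    surv = np.cumprod(1.0 - d / Y)
    idx = np.searchsorted(ut, grid, side="right")
    chf_g = np.concatenate(([0.0], chf))[idx]
    surv_g = np.concatenate(([1.0], surv))[idx]
    return chf_g, surv_g


def logrank_scores(time, event):
    """Per-subject log-rank scores ``a_i = delta_i - H(t_i)``.

    ``H`` is the Nelson–Aalen cumulative hazard of the sample itself, so
    for distinct times ``a_i = delta_i - sum_{k: t_k <= t_i}
    delta_k / (n - Gamma_k + 1)`` with ``Gamma_k`` the number of
    observations up to ``t_k``; tied events share the hazard increment.
    The scores sum to zero for every censoring pattern.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    ut, inv = np.unique(time, return_inverse=True)
    counts = np.bincount(inv, minlength=ut.size)
    d = np.bincount(inv, weights=event, minlength=ut.size)
    n = time.size
    at_risk = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    cumhaz = np.cumsum(d / at_risk)
    return event - cumhaz[inv]


def km_step(time, event):
    """Kaplan–Meier estimate as ``(times, values)`` step-function knots.

    ``values[k]`` is the estimate just after ``times[k]``; the estimate is
    1 before the first knot.
    """
    ut, d, Y = event_time_table(time, event)
    return ut, np.cumprod(1.0 - d / Y)
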