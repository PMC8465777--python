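"""Prediction-accuracy metrics for right-censored data.

The time-dependent Brier score with inverse-probability-of-censoring
weights (IPCW) is

    BS(t) = 1/N sum_i [ Shat(t|X_i)^2 I(t_i <= t, d_i = 1) / Ghat(t_i-)
                      + (1 - Shat(t|X_i))^2 I(t_i > t) / Ghat(t) ]

with ``Ghat`` the Kaplan–Meier estimate of the censoring-time survival
function (marginal, i.e. covariate-free).  The event term uses the
left limit ``Ghat(t_i-)`` so the weight at the largest event time stays
positive.  The integrated Brier score averages BS over time,
``IBS = int_0^tau BS(t) dt / tau``; smaller is better.  Harrell's
c-index counts concordant comparable pairs, with risk ties worth 0.5.
"""

from __future__ import annotations

import numpy as np

from ._survival import check_time_event, km_step


class StepFunction:
    """Right-continuous step function with left-limit evaluation."""

    def __init__(self, knots, values, start=1.0):
        self.knots = np.asarray(knots, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.start = float(start)

    def __call__(self, t):
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="right")
        return np.concatenate(([self.start], self.values))[idx]

    def left(self, t):
        """Left limit, i.e. the value just before ``t``."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="left")
        return np.concatenate(([self.start], self.values))[idx]


def censoring_km(time, event):
    """Kaplan–Meier estimate of the censoring survival ``Ghat`` — KM with
    the censoring indicator ``1 - delta`` playing the event role."""
    time, event = np.asarray(time, dtype=float), np.asarray(event).astype(int)
    knots, values = km_step(time, 1 - event)
    return StepFunction(knots, values)


def brier_score(t, surv_at_t, time, event, G=None):
    """IPCW Brier score at one evaluation time.

    ``surv_at_t`` holds ``Shat(t | X_i)`` per subject.  Subjects censored
    at or before ``t`` contribute nothing.
    """
    time, event = np.asarray(time, dtype=float), np.asarray(event).astype(int)
    surv_at_t = np.asarray(surv_at_t, dtype=float)
    if G is None:
        G = censoring_km(time, event)
    n = time.size
    event_term = np.zeros(n)
    past_event = (time <= t) & (event == 1)
    if past_event.any():
        w = G.left(time[past_event])
        event_term[past_event] = surv_at_t[past_event] ** 2 / w
    at_risk = time > t
    risk_term = np.zeros(n)
    if at_risk.any():
        g_t = float(G(t))
        risk_term[at_risk] = (1.0 - surv_at_t[at_risk]) ** 2 / g_t
    return float((event_term + risk_term).mean())


def brier_curve(surv_matrix, grid, time, event, G=None):
    """BS(t) along ``grid`` for a survival-prediction matrix of shape
    ``(n_subjects, len(grid))``.  Returns ``(grid, bs, Ghat(grid))``."""
    time, event = np.asarray(time, dtype=float), np.asarray(event).astype(int)
    surv_matrix = np.atleast_2d(np.asarray(surv_matrix, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if G is None:
        G = censoring_km(time, event)
    bs = np.array([
        brier_score(t, surv_matrix[:, k], time, event, G) for k, t in enumerate(grid)
    ])
    return grid, bs, G(grid)


def integrated_brier(grid, bs, tau=None):
    """Trapezoidal time-average of the Brier curve over ``(0, tau]``.

    ``tau`` defaults to the last grid point.  When the grid starts after
    0 the first value is carried back to 0 (step-function convention), so
    a constant curve integrates to its constant.
    """
    grid = np.asarray(grid, dtype=float)
    bs = np.asarray(bs, dtype=float)
    if grid[0] > 0:
        grid = np.concatenate(([0.0], grid))
        bs = np.concatenate(([bs[0]], bs))
    tau = float(grid[-1] if tau is None else tau)
    return float(np.trapezoid(bs, grid) / tau)


def harrell_c(risk, time, event):
    """Harrell's concordance index of a risk score (higher = worse
    prognosis).

    A pair is comparable when the shorter observed time is an event (or
    an event ties a censored time); it is concordant when the
    shorter-lived subject has the larger risk, and risk ties count 0.5.
    Returns NaN when no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = np.asarray(time, dtype=float), np.asarray(event).astype(int)
    ti = time[:, None]
    tj = time[None, :]
    ev = event.astype(bool)
    comparable = ((ti < tj) & ev[:, None]) | ((ti == tj) & ev[:, None] & ~ev[None, :])
    if not comparable.any():
        return float("nan")
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = (ri > rj) & comparable
    ties = (ri == rj) & comparable
    return float((concordant.sum() + 0.5 * ties.sum()) / comparable.sum())


def evaluation_grid(time, event, G=None):
    """Distinct observed times truncated where ``Ghat`` stays positive."""
    time = np.asarray(time, dtype=float)
    if G is None:
        G = censoring_km(time, event)
    ts = np.unique(time)
    return ts[G(ts) > 0]


def evaluate_predictions(forest, X, y):
    """Test-set prediction accuracy of a fitted forest.

    Returns a dict with the IPCW Brier curve, its integrated value (IBS,
    integrated up to the last evaluable time) and Harrell's c-index of
    the ensemble risk score.
    """
    time, event = check_time_event(y)
    G = censoring_km(time, event)
    grid = evaluation_grid(time, event, G)
    surv = forest.predict_survival(X, times=grid)
    _, bs, g_vals = brier_curve(surv, grid, time, event, G)
    return {
        "grid": grid,
        "bs": bs,
        "G": g_vals,
        "ibs": integrated_brier(grid, bs),
        "cindex": harrell_c(forest.predict(X), time, event),
    }
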