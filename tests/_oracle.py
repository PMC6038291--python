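"""Deliberately naive re-implementation of the detector, used as a test oracle.

Pure-Python lists and per-month from-scratch recomputation of the reference
statistics; no shared code with the package implementation. Returns alerts as
(observation_index, direction, is_retrigger) triples over the non-missing
observations.
"""

from __future__ import annotations

import math


def _stats(segment, sigma_floor):
    mu = sum(segment) / len(segment)
    var = sum((v - mu) ** 2 for v in segment) / len(segment)
    return mu, max(math.sqrt(var), sigma_floor)


def naive_detect(
    values,
    window=12,
    k_mult=0.5,
    h_mult=5.0,
    mode="standard",
    sigma_floor=0.0,
    min_observations=None,
):
    vals = [float(v) for v in values if v == v]  # drop NaN
    if min_observations is None:
        min_observations = window + 1
    if len(vals) < min_observations:
        return []

    mu, sd = _stats(vals[:window], sigma_floor)
    cp = cn = 0.0
    running = None  # (direction, previous magnitude) while in a continuing run
    alerts = []
    for i in range(window, len(vals)):
        x = vals[i]
        if running is None:
            cp = max(0.0, x - (mu + k_mult * sd) + cp)
            cn = min(0.0, x - (mu - k_mult * sd) + cn)
            h = h_mult * sd
            trig = None
            if cp >= h and cp > 0 and -cn >= h and -cn > 0:
                trig = "increase" if cp >= -cn else "decrease"
            elif cp >= h and cp > 0:
                trig = "increase"
            elif -cn >= h and -cn > 0:
                trig = "decrease"
            if trig is not None:
                alerts.append((i, trig, False))
                mu, sd = _stats(vals[i - window + 1 : i + 1], sigma_floor)
                cp = cn = 0.0
                if mode == "continuing":
                    running = (trig, 0.0)
        else:
            direction, prev = running
            mu, sd = _stats(vals[i - window : i], sigma_floor)
            # reference was re-reset, so accumulation restarts against it
            cp = max(0.0, x - (mu + k_mult * sd))
            cn = min(0.0, x - (mu - k_mult * sd))
            mag = cp if direction == "increase" else -cn
            if mag > prev:
                alerts.append((i, direction, True))
                running = (direction, mag)
            else:
                cp = cn = 0.0
                mu, sd = _stats(vals[i - window + 1 : i + 1], sigma_floor)
                running = None
    return alerts
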