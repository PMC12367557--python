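"""Behavioural statistics: protection values, learning curves, latency
standardization and AICc ranking.

Protection of a dish within a session is derived from the attack order:
the r-th dish opened gets rank r, dishes never opened share the mean of
the remaining ranks, and ranks are rescaled to x = (rank - 1)/(n - 1) so
the first dish scores 0 (least protected) and the last scores 1.  The
bounded x is mapped to an unbounded scale with the adjusted logit

    logit(x) = ln[(x + 0.01) / (1 - x + 0.01)],

whose 0.01 adjustment keeps 0 and 1 finite.

Learning over sessions t is summarised with nonlinear least squares on one
of two three-parameter families:

* sigmoid      f(t) = a / (1 + exp(-b (t - c)))      (training phases)
* asymptotic   f(t) = a + (b - a) exp(-exp(c) t)     (testing phases)

where a is the asymptote, and for the asymptotic family b is the starting
level and exp(c) the rate.  Responses are deemed stabilised on the first
whole day t with |f(t) - a| within a fraction (default 10%) of |a|, which
has the closed form ceil(ln(|b - a| / (fraction |a|)) / exp(c)).

Chick attack latencies are standardised per trial by the linear map taking
the trial's median fly latency to 0.855 s and median wasp latency to
1.28 s (the grand medians across trials); trials whose mean wasp-fly
latency difference is below 0.1 s carry no usable discrimination signal
and are flagged for exclusion.

Candidate models supplied as (log-likelihood, k, n) triples are ranked by
AICc; scores within 2 of the minimum are treated as tied and the tie is
broken towards the fewest parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

ANCHOR_FLY = 0.855
ANCHOR_WASP = 1.28
LOGIT_ADJUST = 0.01
AICC_TIE_WINDOW = 2.0


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


# -- protection values -------------------------------------------------------

@dataclass
class AttackSequence:
    """Ordered dish attacks within one session at one feeder."""

    session_id: str
    feeder_id: str
    attacked: list
    unopened: set
    n: int

    def check(self) -> None:
        ids = list(self.attacked) + list(self.unopened)
        if len(ids) != len(set(ids)):
            raise StatsError("duplicate dish ids in attack sequence")
        if len(ids) != self.n:
            raise StatsError(
                f"attacked + unopened ({len(ids)}) must cover all {self.n} dishes"
            )
        if self.n < 2:
            raise StatsError("protection values need at least 2 dishes")


@dataclass
class ProtectionRecord:
    dish_id: object
    x: float
    logit: float | None = None


def protection_values(seq: AttackSequence) -> list[ProtectionRecord]:
    """Protection x in [0, 1] per dish from the attack order.

    Unopened dishes are placed at the end of the sequence without internal
    ordering: each takes the mean of the remaining ranks k+1 ... n, which
    is order-invariant and deterministic.
    """
    seq.check()
    n, k = seq.n, len(seq.attacked)
    records = [
        ProtectionRecord(dish, (rank - 1) / (n - 1))
        for rank, dish in enumerate(seq.attacked, start=1)
    ]
    if seq.unopened:
        mean_rank = (k + 1 + n) / 2.0
        x = (mean_rank - 1) / (n - 1)
        records += [ProtectionRecord(dish, x) for dish in sorted(seq.unopened, key=repr)]
    return records


def logit_protect(x):
    """Adjusted logit ln[(x + 0.01)/(1 - x + 0.01)]; defined on [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if ((arr < 0.0) | (arr > 1.0)).any():
        raise StatsError("protection values must lie in [0, 1]")
    out = np.log((arr + LOGIT_ADJUST) / (1.0 - arr + LOGIT_ADJUST))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def protection_table(seq: AttackSequence) -> pd.DataFrame:
    """Tidy per-dish protection table with both raw and logit values."""
    records = protection_values(seq)
    return pd.DataFrame(
        {
            "session": seq.session_id,
            "feeder": seq.feeder_id,
            "dish": [r.dish_id for r in records],
            "x": [r.x for r in records],
            "logit": [logit_protect(r.x) for r in records],
        }
    )


# -- learning curves ---------------------------------------------------------

@dataclass
class LearningCurveFit:
    family: str
    a: float
    b: float
    c: float
    rss: float
    converged: bool
    n_obs: int = 0

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "sigmoid":
            return self.a / (1.0 + np.exp(-self.b * (t - self.c)))
        return self.a + (self.b - self.a) * np.exp(-np.exp(self.c) * t)

    @property
    def parameters(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def _fit_curve(t, y, family: str, model, x0) -> LearningCurveFit:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y) or len(t) < 4:
        raise StatsError("curve fitting needs at least 4 (t, y) points")
    if np.ptp(y) == 0.0:
        raise StatsError("responses are constant; the curve is degenerate")
    result = least_squares(
        lambda p: model(t, p) - y, x0=x0, xtol=1e-10, ftol=1e-12, gtol=1e-12,
        max_nfev=500 * 3,
    )
    a, b, c = result.x
    return LearningCurveFit(
        family=family,
        a=float(a),
        b=float(b),
        c=float(c),
        rss=float(2.0 * result.cost),
        converged=bool(result.success and np.isfinite(result.x).all()),
        n_obs=len(t),
    )


def fit_sigmoid(t, y) -> LearningCurveFit:
    """NLS fit of a / (1 + exp(-b (t - c))).

    Initialisation: a = max(y), b = 1, c = median(t).
    """
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise StatsError("session indices must be non-negative")
    y_arr = np.asarray(y, dtype=float)
    x0 = [float(np.max(y_arr)), 1.0, float(np.median(t_arr))]
    return _fit_curve(
        t, y, "sigmoid", lambda tt, p: p[0] / (1.0 + np.exp(-p[1] * (tt - p[2]))), x0
    )


def fit_asymptotic(t, y) -> LearningCurveFit:
    """NLS fit of a + (b - a) exp(-exp(c) t).

    Initialisation: a = mean of the last quartile of y, b = mean of the
    first quartile, c = log(0.3).
    """
    y_arr = np.asarray(y, dtype=float)
    q = max(1, len(y_arr) // 4)
    x0 = [float(np.mean(y_arr[-q:])), float(np.mean(y_arr[:q])), math.log(0.3)]
    return _fit_curve(
        t, y, "asymptotic",
        lambda tt, p: p[0] + (p[1] - p[0]) * np.exp(-np.exp(p[2]) * tt), x0,
    )


def stabilization_day(fit: LearningCurveFit, fraction: float = 0.1) -> int:
    """First whole day t >= 1 with |f(t) - a| <= fraction * |a|.

    Only defined for the asymptotic family and a non-zero asymptote.
    Closed form: ceil(ln(|b - a| / (fraction |a|)) / exp(c)) when the
    criterion is not already met at t = 0, else day 1.
    """
    if fit.family != "asymptotic":
        raise StatsError("stabilization is defined for asymptotic fits only")
    if fit.a == 0.0:
        raise StatsError("relative stabilization criterion undefined for a = 0")
    gap = abs(fit.b - fit.a)
    threshold = fraction * abs(fit.a)
    if gap <= threshold:
        return 1
    day = math.ceil(math.log(gap / threshold) / math.exp(fit.c))
    return max(day, 1)


# -- chick latency standardization -------------------------------------------

def standardize_latencies(trial: pd.DataFrame) -> tuple[pd.Series | None, bool]:
    """Linearly rescale one trial's latencies onto the grand anchors.

    ``trial`` needs columns ``role`` (fly / wasp / probe) and ``latency``
    (seconds).  The map g sends the trial's median fly latency to 0.855 s
    and median wasp latency to 1.28 s.  Returns ``(scaled, excluded)``;
    ``scaled`` is None when the trial is excluded, which happens when the
    mean wasp latency exceeds the mean fly latency by less than 0.1 s or
    when the two medians coincide (undefined map).
    """
    for role in ("fly", "wasp"):
        if not (trial["role"] == role).any():
            raise StatsError(f"trial has no {role} presentations")
    fly = trial.loc[trial["role"] == "fly", "latency"]
    wasp = trial.loc[trial["role"] == "wasp", "latency"]
    f_med, w_med = float(fly.median()), float(wasp.median())
    excluded = (wasp.mean() - fly.mean()) < 0.1 or w_med == f_med
    if excluded:
        return None, True
    slope = (ANCHOR_WASP - ANCHOR_FLY) / (w_med - f_med)
    scaled = ANCHOR_FLY + slope * (trial["latency"] - f_med)
    return scaled, False


# -- AICc model ranking ------------------------------------------------------

@dataclass
class ModelScore:
    label: str
    loglik: float
    k: int
    n: int
    aicc_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.aicc_value = aicc(self.loglik, self.k, self.n)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise StatsError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(scores: list[ModelScore]) -> ModelScore:
    """Most parsimonious model within the AICc tie window.

    Among models within 2 AICc of the minimum, the one with the fewest
    parameters wins; remaining ties break by label order.
    """
    if not scores:
        raise StatsError("no models to rank")
    best = min(s.aicc_value for s in scores)
    tied = [s for s in scores if s.aicc_value - best < AICC_TIE_WINDOW]
    return min(tied, key=lambda s: (s.k, s.label))
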