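"""Threshold-model dynamics on weighted follow networks.

Implements the linear (single) threshold rule, the bi-threshold rule with a
lower adoption and an upper disadoption threshold, and the two empirical
extensions: *login schedules* (a user can only act at her login times
``A(t)``) and an *effective-time window* (a neighbour's engagement is visible
for ``t_effect`` hours, set ``E(t)``).

Update rule (bi-threshold, extended form)::

    y_i(t+1) = 1   iff   theta_i^lower <= s_i(t) <= theta_i^upper  and  i in A(t)

with ``s_i(t) = sum_{j in N_i ∩ E(t)} w_ij`` the influence received by *i*.
Both band ends are closed.  The linear rule replaces the band with
``s_i(t) >= theta_i``; it is the special case ``theta_upper = 1`` since
``s_i(t) <= 1`` always.

Login patterns
--------------
constant
    Logins every ``t_login`` hours from the phase offset.
linear_decay
    After the user is active at hour *a*, logins resume at gaps 1, 2, 3, ...
    until the gap reaches ``t_login``, then stay constant.  Any activity at a
    later step resets the decay; the activity hour itself is a login time.
exp_decay
    Same, with gaps 1, 2, 4, 8, ... capped at ``t_login``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network_io import ActivityLog, WeightedNetwork

PATTERNS = ("constant", "linear_decay", "exp_decay")

#: cap on the exponent of the exp_decay gap sequence (2**_MAX_EXP > any t_login)
_MAX_EXP = 40


class ConfigurationError(ValueError):
    pass


@dataclass
class ThresholdProfile:
    """Per-user threshold band ``(theta_lower, theta_upper)``.

    For the linear model only the lower threshold is meaningful; set
    ``upper = 1`` everywhere (the band then never binds from above).
    """

    users: list
    lower: np.ndarray
    upper: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.users) == len(self.lower) == len(self.upper)):
            raise ValueError("users / lower / upper length mismatch")
        if ((self.lower < 0) | (self.upper > 1) | (self.lower > self.upper)).any():
            raise ValueError("need 0 <= lower <= upper <= 1 for every user")
        self._index = {u: k for k, u in enumerate(self.users)}

    @classmethod
    def from_dict(cls, bands: dict) -> "ThresholdProfile":
        users = sorted(bands, key=str)
        lo = np.array([bands[u][0] for u in users], dtype=float)
        hi = np.array([bands[u][1] for u in users], dtype=float)
        return cls(users, lo, hi)

    @classmethod
    def uniform(cls, users: Sequence, lower: float, upper: float = 1.0) -> "ThresholdProfile":
        n = len(users)
        return cls(list(users), np.full(n, lower), np.full(n, upper))

    def band(self, user) -> tuple[float, float]:
        k = self._index[user]
        return float(self.lower[k]), float(self.upper[k])

    def aligned(self, order: Sequence) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) arrays in the given user order."""
        idx = [self._index[u] for u in order]
        return self.lower[idx], self.upper[idx]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("user_id\ttheta_lower\ttheta_upper\n")
            for u in self.users:
                lo, hi = self.band(u)
                fh.write(f"{u}\t{lo:.10g}\t{hi:.10g}\n")


class _LoginState:
    """Incremental login-schedule state machine for one user.

    Call :meth:`logged_in` with the user's activity flag for hour *t*, then
    :meth:`step` with the same arguments, for t = 0, 1, 2, ...  Activity at a
    decision hour resets the decay; the activity hour itself counts as a
    login (decay patterns only).
    """

    __slots__ = ("t_login", "pattern", "next", "decaying", "k")

    def __init__(self, t_login: int, pattern: str, phase: int = 0):
        if t_login < 1:
            raise ConfigurationError(f"t_login must be >= 1, got {t_login}")
        if pattern not in PATTERNS:
            raise ConfigurationError(f"unknown login pattern {pattern!r}")
        self.t_login = t_login
        self.pattern = pattern
        self.next = phase
        self.decaying = False
        self.k = 0

    def _gap(self) -> int:
        if self.pattern == "constant" or not self.decaying:
            return self.t_login
        self.k += 1
        if self.pattern == "linear_decay":
            raw = self.k
        else:  # exp_decay: 1, 2, 4, 8, ...
            raw = 1 << min(self.k - 1, _MAX_EXP)
        return min(raw, self.t_login)

    def logged_in(self, t: int, active: bool) -> bool:
        if t == self.next:
            return True
        return active and self.pattern != "constant"

    def step(self, t: int, active: bool) -> None:
        if active and self.pattern != "constant":
            self.decaying = True
            self.k = 0
            self.next = t + self._gap()
        elif t == self.next:
            self.next = t + self._gap()


def login_times(
    t_login: int,
    pattern: str,
    activity_times: Iterable[int] = (),
    horizon: int = 0,
    phase: int = 0,
) -> list[int]:
    """All login times in ``[0, horizon)`` for a user with the given activity.

    >>> login_times(5, "linear_decay", {10}, 36)
    [0, 5, 10, 11, 13, 16, 20, 25, 30, 35]
    >>> login_times(5, "exp_decay", {10}, 38)
    [0, 5, 10, 11, 13, 17, 22, 27, 32, 37]
    """
    acts = set(int(a) for a in activity_times)
    if any(a < 0 or a >= horizon for a in acts):
        raise ValueError("activity_times must lie in [0, horizon)")
    state = _LoginState(t_login, pattern, phase)
    out: list[int] = []
    for t in range(horizon):
        active = t in acts
        if state.logged_in(t, active):
            out.append(t)
        state.step(t, active)
    return out


def login_mask(
    t_login: int,
    pattern: str,
    activity_times: Iterable[int],
    horizon: int,
    phase: int = 0,
) -> np.ndarray:
    """Boolean membership of ``A(t)`` for t = 0..horizon-1."""
    mask = np.zeros(horizon, dtype=bool)
    mask[login_times(t_login, pattern, activity_times, horizon, phase)] = True
    return mask


def _last_active(log: ActivityLog, t: int) -> np.ndarray:
    """Most recent hour <= t at which each user was active, -1 if never."""
    sub = log.matrix[:, : t + 1]
    ever = sub.any(axis=1)
    last = np.where(ever, (t + 1) - 1 - np.argmax(sub[:, ::-1], axis=1), -1)
    return last


def effective_mask(log: ActivityLog, t: int, t_effect: float) -> np.ndarray:
    """Boolean indicator of ``E(t)`` aligned with ``log.users``.

    ``j in E(t)`` iff ``y_j(s) = 1`` for some ``s`` in
    ``[max(0, t - t_effect + 1), t]``; with infinite ``t_effect``, any past
    activity counts.
    """
    if not 0 <= t < log.T:
        raise ValueError(f"t={t} outside log horizon [0, {log.T})")
    last = _last_active(log, t)
    if math.isinf(t_effect):
        return last >= 0
    lo = max(0, t - int(t_effect) + 1)
    return last >= lo


def effective_set(log: ActivityLog, t: int, t_effect: float) -> set:
    """``E(t)`` as a user set (see :func:`effective_mask`)."""
    mask = effective_mask(log, t, t_effect)
    return {u for u, m in zip(log.users, mask) if m}


def influence_vector(
    wnet: WeightedNetwork, log: ActivityLog, t: int, t_effect: float
) -> np.ndarray:
    """``s_i(t)`` for every user, in ``wnet.user_order``."""
    aligned = log if log.users == wnet.user_order else log.reindex(wnet.user_order)
    eff = effective_mask(aligned, t, t_effect).astype(float)
    # row weights sum to 1 up to roundoff; clip so s stays in [0, 1] exactly
    return np.clip(wnet.matrix() @ eff, 0.0, 1.0)


def influence(
    wnet: WeightedNetwork, log: ActivityLog, user, t: int, t_effect: float = math.inf
) -> float:
    """Influence received by one user: ``sum_{j in N_i ∩ E(t)} w_ij``."""
    eff = effective_set(log, t, t_effect)
    raw = sum(wnet.weight(user, j) for j in wnet.followees(user) if j in eff)
    return float(min(max(raw, 0.0), 1.0))


def _step(
    model: str,
    wnet: WeightedNetwork,
    log: ActivityLog,
    profile: ThresholdProfile,
    logged_in: np.ndarray,
    t: int,
    t_effect: float,
) -> np.ndarray:
    s = influence_vector(wnet, log, t, t_effect)
    lo, hi = profile.aligned(wnet.user_order)
    if model == "linear":
        in_band = s >= lo
    elif model == "bi":
        in_band = (s >= lo) & (s <= hi)
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    return (in_band & logged_in).astype(np.uint8)


def step_bithreshold(
    wnet: WeightedNetwork,
    log: ActivityLog,
    profile: ThresholdProfile,
    logged_in: np.ndarray,
    t: int,
    t_effect: float = math.inf,
) -> np.ndarray:
    """One bi-threshold update: the activity vector ``y(t+1)``.

    ``logged_in`` is the boolean ``A(t)`` membership in ``wnet.user_order``.
    """
    return _step("bi", wnet, log, profile, logged_in, t, t_effect)


def step_linear(
    wnet: WeightedNetwork,
    log: ActivityLog,
    profile: ThresholdProfile,
    logged_in: np.ndarray,
    t: int,
    t_effect: float = math.inf,
) -> np.ndarray:
    """One linear-threshold update (``s_i(t) >= theta_i``)."""
    return _step("linear", wnet, log, profile, logged_in, t, t_effect)


@dataclass
class StateLabels:
    """Diagnostic per-user per-hour state labels from a simulation run."""

    ACTIVE = "active"
    BELOW = "below-lower"
    ABOVE = "above-upper"
    OFFLINE = "offline"


def simulate(
    model: str,
    wnet: WeightedNetwork,
    profile: ThresholdProfile,
    init_log: ActivityLog,
    *,
    t_login: int = 24,
    pattern: str = "constant",
    t_effect: float = math.inf,
    horizon: int,
    phase_mode: str = "zero",
    seed: int | None = None,
    noise: float = 0.0,
    noise_rng: np.random.Generator | None = None,
) -> ActivityLog:
    """Roll the chosen threshold rule forward to ``horizon`` hours.

    ``init_log`` supplies the observed prefix (at least one hour); its
    activity seeds both the effective-set history and the decay state of the
    login schedules.  Beyond the prefix the simulation is self-driven: it
    consumes its own predicted states, never future observations.

    ``phase_mode="random"`` draws one uniform phase in ``[0, t_login)`` per
    user from ``seed``; the default gives every user phase 0.  ``noise`` is
    the probability that a decision-maker's action is flipped after the
    deterministic update (used by the synthetic generator; 0 keeps the
    dynamics exactly deterministic).
    """
    t0 = init_log.T
    if t0 < 1:
        raise ValueError("init_log must cover at least one hour")
    if horizon <= t0:
        raise ValueError(f"horizon ({horizon}) must exceed init_log length ({t0})")

    order = wnet.user_order
    n = len(order)
    init = init_log if init_log.users == order else init_log.reindex(order)
    y = np.zeros((n, horizon), dtype=np.uint8)
    y[:, :t0] = init.matrix

    if phase_mode == "zero":
        phases = np.zeros(n, dtype=int)
    elif phase_mode == "random":
        phases = np.random.default_rng(seed).integers(0, t_login, size=n)
    else:
        raise ConfigurationError(f"unknown phase_mode {phase_mode!r}")
    states = [_LoginState(t_login, pattern, int(p)) for p in phases]

    lo, hi = profile.aligned(order)
    W = wnet.matrix()
    last_active = np.full(n, -1, dtype=int)
    if noise and noise_rng is None:
        noise_rng = np.random.default_rng(seed)

    for t in range(horizon - 1):
        active_now = y[:, t].astype(bool)
        last_active[active_now] = t
        if t + 1 >= t0:
            logged = np.fromiter(
                (st.logged_in(t, bool(a)) for st, a in zip(states, active_now)),
                dtype=bool,
                count=n,
            )
            if math.isinf(t_effect):
                eff = (last_active >= 0).astype(float)
            else:
                eff = (last_active >= max(0, t - int(t_effect) + 1)).astype(float)
            s = np.clip(W @ eff, 0.0, 1.0)
            if model == "linear":
                in_band = s >= lo
            elif model == "bi":
                in_band = (s >= lo) & (s <= hi)
            else:
                raise ConfigurationError(f"unknown model {model!r}")
            nxt = in_band & logged
            if noise:
                flips = logged & (noise_rng.random(n) < noise)
                nxt = nxt ^ flips
            y[:, t + 1] = nxt.astype(np.uint8)
        for st, a in zip(states, active_now):
            st.step(t, bool(a))

    return ActivityLog(order, y, init_log.episode_start)
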