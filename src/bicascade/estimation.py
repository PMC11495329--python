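"""Heterogeneous threshold estimation from hourly activity logs.

The fitting criterion is the empirical conditional-average-treatment-effect
(CATE) style difference: for a candidate band ``[theta_l, theta_u]``,

    J(theta_l, theta_u) = mean{ y_i(t+1) : s_i(t) in band }
                        - mean{ y_i(t+1) : s_i(t) outside band },

taken over all decision observations — logged-in users ``i in A(t)`` with the
outcome hour ``t+1`` inside the training interval.  A perfectly estimated
band makes the first term 1 and the second 0, so J attains its maximum of 1.
The single-threshold (linear) criterion is the special case with the upper
end pinned at the top of the candidate grid.

Heterogeneity across users is captured by a binary feature-partition tree:
each node splits the user population on one feature, each leaf carries the
band fitted to its sub-population's observations.  Splits are scored with an
honest penalty: the node objective fitted on an estimation subset of users is
discounted by ``lambda * |J_train - J_validation|`` on a held-out validation
subset, and a split is accepted only if it beats the parent's penalized
objective.

The objective is piecewise constant between observed influence values, so the
candidate grid — the sorted unique observed ``s`` values plus {0, 1} — loses
nothing relative to a continuous search.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import ThresholdProfile, login_times
from .network_io import (
    ActivityLog,
    EventStream,
    REPLY_ACTIONS,
    RETWEET_ACTIONS,
    WeightedNetwork,
)

_TIE_TOL = 1e-12

FEATURE_NAMES = (
    "in_degree",
    "out_degree",
    "n_retweets",
    "n_replies",
    "n_neighbor_retweets",
    "n_neighbor_replies",
)


def build_features(
    wnet: WeightedNetwork,
    events: EventStream,
    interval: tuple[float, float],
) -> pd.DataFrame:
    """Per-user features over a training interval ``[t0, t1)`` (hours).

    Columns: follower count (in_degree), followee count (out_degree), the
    user's retweet and reply counts in the interval, and the sums of those
    counts over the user's followees.
    """
    t0, t1 = interval
    users = wnet.user_order
    frame = events.frame
    sel = frame[(frame["t_hours"] >= t0) & (frame["t_hours"] < t1)]

    def _counts(actions: frozenset) -> pd.Series:
        sub = sel[sel["action"].isin(actions)]
        return sub.groupby("user_id").size()

    rt = _counts(RETWEET_ACTIONS)
    rp = _counts(REPLY_ACTIONS)
    rows = []
    for u in users:
        n_rt = int(rt.get(u, 0))
        n_rp = int(rp.get(u, 0))
        followees = wnet.followees(u)
        rows.append(
            {
                "user_id": u,
                "in_degree": wnet.graph.in_degree(u),
                "out_degree": wnet.graph.out_degree(u),
                "n_retweets": n_rt,
                "n_replies": n_rp,
                "n_neighbor_retweets": int(sum(rt.get(j, 0) for j in followees)),
                "n_neighbor_replies": int(sum(rp.get(j, 0) for j in followees)),
            }
        )
    return pd.DataFrame(rows).set_index("user_id")


def build_observations(
    wnet: WeightedNetwork,
    log: ActivityLog,
    *,
    t_login: int = 24,
    pattern: str = "constant",
    t_effect: float = math.inf,
    phase: int = 0,
    t_min: int = 0,
) -> pd.DataFrame:
    """Decision observations ``(user, t, s_i(t), y_i(t+1))`` from a log.

    Only hours at which the user is logged in contribute (``i in A(t)``); the
    login schedule is reconstructed from the user's observed activity times,
    so decay patterns reset exactly as they would have during the episode.
    The outcome hour ``t+1`` must lie inside the log.  ``t_min`` keeps only
    decisions at hours >= t_min (equal-sized trailing training sets); the
    schedule and influence history still run from hour 0.
    """
    from .dynamics import influence_vector  # local import to avoid cycle

    order = wnet.user_order
    aligned = log if log.users == order else log.reindex(order)
    T = aligned.T
    if T < 2:
        return pd.DataFrame(columns=["user_id", "t", "s", "y"])

    S = np.column_stack(
        [influence_vector(wnet, aligned, t, t_effect) for t in range(T - 1)]
    )
    records = []
    for k, u in enumerate(order):
        acts = [a for a in np.flatnonzero(aligned.matrix[k]).tolist() if a < T - 1]
        for t in login_times(t_login, pattern, acts, T - 1, phase):
            if t >= t_min:
                records.append((u, t, float(S[k, t]), int(aligned.matrix[k, t + 1])))
    return pd.DataFrame(records, columns=["user_id", "t", "s", "y"])


@dataclass(frozen=True)
class BandFit:
    """Result of a band search: the fitted band and its objective."""

    lower: float
    upper: float
    objective: float
    n_obs: int
    degenerate: bool = False


def cate_bi(
    s: np.ndarray, y: np.ndarray, lower: float, upper: float
) -> float | None:
    """Empirical in-band minus out-of-band mean outcome; None if one side is empty.

    The band is closed on both ends, matching the simulation rule.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(s) == 0:
        raise ValueError("empty observation set")
    if lower > upper:
        raise ValueError("need lower <= upper")
    inside = (s >= lower) & (s <= upper)
    n_in = int(inside.sum())
    if n_in == 0 or n_in == len(s):
        return None
    return float(y[inside].mean() - y[~inside].mean())


def _candidates(s: np.ndarray) -> np.ndarray:
    return np.unique(np.concatenate([np.asarray(s, dtype=float), [0.0, 1.0]]))


def optimal_bithresholds(
    s: np.ndarray, y: np.ndarray, *, model: str = "bi"
) -> BandFit:
    """Exhaustive band search over the candidate grid.

    Candidates are the sorted unique observed influence values plus {0, 1};
    every pair ``lower <= upper`` with both groups non-empty is scored and
    ties are broken by smallest lower, then largest upper (the most
    permissive band).  ``model="linear"`` pins the upper end at the top
    candidate, recovering the single-threshold maximizer.

    If no candidate pair yields two non-empty groups (all ``s`` identical),
    the fit degenerates to the full band (0, 1) with objective 0.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(s) == 0:
        raise ValueError("empty observation set")

    cands = _candidates(s)
    u_vals, u_inv = np.unique(s, return_inverse=True)
    n_u = np.bincount(u_inv, minlength=len(u_vals)).astype(float)
    y_u = np.bincount(u_inv, weights=y, minlength=len(u_vals))
    cum_n = np.concatenate([[0.0], np.cumsum(n_u)])
    cum_y = np.concatenate([[0.0], np.cumsum(y_u)])
    N, Y = cum_n[-1], cum_y[-1]

    lo_idx = np.searchsorted(u_vals, cands, side="left")
    hi_idx = np.searchsorted(u_vals, cands, side="right")

    best: tuple[float, float, float] | None = None
    hi_range = range(len(cands)) if model == "bi" else [len(cands) - 1]
    for a in range(len(cands)):
        for b in hi_range:
            if b < a:
                continue
            n_in = cum_n[hi_idx[b]] - cum_n[lo_idx[a]]
            if n_in == 0 or n_in == N:
                continue
            y_in = cum_y[hi_idx[b]] - cum_y[lo_idx[a]]
            obj = y_in / n_in - (Y - y_in) / (N - n_in)
            if best is None or obj > best[0] + _TIE_TOL:
                best = (obj, cands[a], cands[b])
            elif obj > best[0] - _TIE_TOL:
                _, bl, bu = best
                if cands[a] < bl - _TIE_TOL or (
                    abs(cands[a] - bl) <= _TIE_TOL and cands[b] > bu + _TIE_TOL
                ):
                    best = (best[0], cands[a], cands[b])
    if best is None:
        return BandFit(0.0, 1.0, 0.0, len(s), degenerate=True)
    obj, lo, hi = best
    if model == "linear":
        hi = 1.0
    return BandFit(float(lo), float(hi), float(obj), len(s))


def optimal_threshold(s: np.ndarray, y: np.ndarray) -> BandFit:
    """Single-threshold maximizer (linear model): band ``[theta, 1]``."""
    return optimal_bithresholds(s, y, model="linear")


@dataclass
class TreeOptions:
    """Knobs of the partition tree.

    lambda_
        Honest-penalty weight on the train/validation objective gap.
    val_fraction
        Fraction of users held out (user-wise, seeded) to validate splits;
        0 disables the penalty entirely.
    min_leaf_users, max_depth
        Structural stopping rules.
    model
        "bi" fits bands, "linear" single thresholds.
    """

    lambda_: float = 0.5
    val_fraction: float = 0.3
    min_leaf_users: int = 10
    max_depth: int = 6
    seed: int = 0
    model: str = "bi"


@dataclass
class TreeNode:
    feature: str | None = None
    split: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    fit: BandFit | None = None
    n_users: int = 0
    n_obs: int = 0
    candidates: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            assert self.fit is not None
            return {
                "leaf": True,
                "theta_lower": self.fit.lower,
                "theta_upper": self.fit.upper,
                "objective": self.fit.objective,
                "n_users": self.n_users,
                "n_obs": self.n_obs,
            }
        assert self.left is not None and self.right is not None
        return {
            "leaf": False,
            "feature": self.feature,
            "split": self.split,
            "n_users": self.n_users,
            "n_obs": self.n_obs,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(
                fit=BandFit(d["theta_lower"], d["theta_upper"], d["objective"], d["n_obs"]),
                n_users=d["n_users"],
                n_obs=d["n_obs"],
            )
        return cls(
            feature=d["feature"],
            split=d["split"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
            n_users=d["n_users"],
            n_obs=d["n_obs"],
        )


@dataclass
class ThresholdTree:
    """Recursive user partition whose leaves carry fitted threshold bands."""

    root: TreeNode
    options: TreeOptions

    def leaf_for(self, features: pd.Series) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            assert node.feature is not None and node.split is not None
            node = node.left if features[node.feature] <= node.split else node.right  # type: ignore[assignment]
        return node

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])  # type: ignore[list-item]
        return out

    @property
    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))  # type: ignore[arg-type]

        return _d(self.root)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.root.to_dict(), fh, indent=2)

    @classmethod
    def read(cls, path, options: TreeOptions | None = None) -> "ThresholdTree":
        with open(path) as fh:
            return cls(TreeNode.from_dict(json.load(fh)), options or TreeOptions())


def _penalized_objective(
    obs: pd.DataFrame, est_users: set, opts: TreeOptions
) -> float:
    """Honest node score: estimation-subset objective minus the penalty."""
    if opts.val_fraction <= 0:
        fit = optimal_bithresholds(
            obs["s"].to_numpy(), obs["y"].to_numpy(), model=opts.model
        )
        return fit.objective if not fit.degenerate else 0.0
    est = obs[obs["user_id"].isin(est_users)]
    val = obs[~obs["user_id"].isin(est_users)]
    if len(est) == 0:
        return 0.0
    fit = optimal_bithresholds(
        est["s"].to_numpy(), est["y"].to_numpy(), model=opts.model
    )
    if fit.degenerate:
        return 0.0
    obj_val = None
    if len(val):
        obj_val = cate_bi(val["s"].to_numpy(), val["y"].to_numpy(), fit.lower, fit.upper)
    if obj_val is None:
        obj_val = 0.0  # no usable validation evidence: maximal distrust
    return fit.objective - opts.lambda_ * abs(fit.objective - obj_val)


def grow_tree(
    features: pd.DataFrame,
    obs: pd.DataFrame,
    options: TreeOptions | None = None,
) -> ThresholdTree:
    """Grow the feature-partition tree by recursive binary splitting.

    At each node, candidate splits are the midpoints of consecutive sorted
    unique values of each feature; a split's score is the observation-weighted
    mean of the two children's penalized objectives and it is accepted only if
    it exceeds the node's own penalized objective.  Leaf bands are refitted on
    *all* of the leaf's observations (the estimation/validation split is used
    only to score splits), so a homogeneous population yields a depth-0 tree
    identical to a plain band search.
    """
    opts = options or TreeOptions()
    if features.empty:
        raise ValueError("empty feature table")
    obs = obs[obs["user_id"].isin(features.index)]

    rng = np.random.default_rng(opts.seed)
    users_sorted = sorted(features.index, key=str)
    est_users = {
        u for u in users_sorted if rng.random() >= opts.val_fraction
    }

    def _leaf(node_obs: pd.DataFrame, node_users: pd.Index) -> TreeNode:
        if len(node_obs):
            fit = optimal_bithresholds(
                node_obs["s"].to_numpy(), node_obs["y"].to_numpy(), model=opts.model
            )
            cands = _candidates(node_obs["s"].to_numpy())
        else:
            fit = BandFit(0.0, 1.0, 0.0, 0, degenerate=True)
            cands = np.array([0.0, 1.0])
        return TreeNode(
            fit=fit, n_users=len(node_users), n_obs=len(node_obs), candidates=cands
        )

    def _grow(node_users: pd.Index, depth: int) -> TreeNode:
        node_obs = obs[obs["user_id"].isin(node_users)]
        leaf = _leaf(node_obs, node_users)
        if depth >= opts.max_depth or len(node_obs) == 0:
            return leaf
        parent_score = _penalized_objective(node_obs, est_users, opts)

        best_score = parent_score
        best_split: tuple[str, float, pd.Index, pd.Index] | None = None
        sub_feats = features.loc[node_users]
        for feat in sub_feats.columns:
            vals = np.unique(sub_feats[feat].to_numpy(dtype=float))
            if len(vals) < 2:
                continue
            for cut in (vals[:-1] + vals[1:]) / 2.0:
                left_mask = sub_feats[feat].to_numpy(dtype=float) <= cut
                left_users = node_users[left_mask]
                right_users = node_users[~left_mask]
                if (
                    len(left_users) < opts.min_leaf_users
                    or len(right_users) < opts.min_leaf_users
                ):
                    continue
                obs_l = node_obs[node_obs["user_id"].isin(left_users)]
                obs_r = node_obs[node_obs["user_id"].isin(right_users)]
                if len(obs_l) == 0 or len(obs_r) == 0:
                    continue
                score_l = _penalized_objective(obs_l, est_users, opts)
                score_r = _penalized_objective(obs_r, est_users, opts)
                score = (len(obs_l) * score_l + len(obs_r) * score_r) / len(node_obs)
                if score > best_score + _TIE_TOL:
                    best_score = score
                    best_split = (feat, float(cut), left_users, right_users)
        if best_split is None:
            return leaf
        feat, cut, left_users, right_users = best_split
        node = TreeNode(
            feature=feat,
            split=cut,
            n_users=len(node_users),
            n_obs=len(node_obs),
            left=_grow(left_users, depth + 1),
            right=_grow(right_users, depth + 1),
        )
        return node

    root = _grow(features.index, 0)
    return ThresholdTree(root, opts)


def assign_thresholds(
    tree: ThresholdTree, features: pd.DataFrame
) -> ThresholdProfile:
    """Map every user to its leaf band.

    Raises ``KeyError`` naming the user if a required feature row is missing.
    """
    users = list(features.index)
    lo = np.empty(len(users))
    hi = np.empty(len(users))
    for k, u in enumerate(users):
        leaf = tree.leaf_for(features.loc[u])
        assert leaf.fit is not None
        lo[k], hi[k] = leaf.fit.lower, leaf.fit.upper
    return ThresholdProfile(users, lo, hi)


def fit_profile(
    wnet: WeightedNetwork,
    log: ActivityLog,
    features: pd.DataFrame,
    *,
    t_login: int = 24,
    pattern: str = "constant",
    t_effect: float = math.inf,
    options: TreeOptions | None = None,
    obs_min_hour: int = 0,
) -> tuple[ThresholdProfile, ThresholdTree]:
    """Convenience pipeline: observations -> tree -> per-user profile.

    Users present in the network but absent from ``features`` are given the
    root fit's band (they carry no feature information to route on).
    """
    obs = build_observations(
        wnet, log, t_login=t_login, pattern=pattern, t_effect=t_effect,
        t_min=obs_min_hour,
    )
    if obs.empty:
        raise ValueError("no decision observations in the training interval")
    tree = grow_tree(features, obs, options)
    profile = assign_thresholds(tree, features)
    missing = [u for u in wnet.user_order if u not in profile._index]
    if missing:
        root_fit = tree.root.fit
        if root_fit is None:  # internal root: fall back to full-band refit
            fit_all = optimal_bithresholds(
                obs["s"].to_numpy(), obs["y"].to_numpy(),
                model=(options or TreeOptions()).model,
            )
            lo0, hi0 = fit_all.lower, fit_all.upper
        else:
            lo0, hi0 = root_fit.lower, root_fit.upper
        users = profile.users + missing
        lo = np.concatenate([profile.lower, np.full(len(missing), lo0)])
        hi = np.concatenate([profile.upper, np.full(len(missing), hi0)])
        profile = ThresholdProfile(users, lo, hi)
    return profile, tree
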