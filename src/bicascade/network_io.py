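"""Network and event-stream ingestion.

Reads SNAP-style follower edge lists into directed graphs, attaches uniform
influence weights (``w_ij = 1/|N_i|`` over user *i*'s followees), and turns
timestamped reaction streams into hourly binary activity matrices.

Conventions
-----------
* An edge ``(i, j)`` means *i follows j*: influence flows from the followee
  ``j`` to the follower ``i``.  ``N_i`` is the set of accounts *i* follows.
* Hour bins are half-open, 0-based from a declared episode start:
  ``t = floor((timestamp - episode_start) / 1h)``.
* Self-follows are dropped (real scrapes contain them; dropping preserves the
  weight normalisation), duplicate edges are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: reaction vocabularies retained by default (Twitter / Weibo dialects)
DEFAULT_ACTIONS = frozenset({"tweet", "retweet", "reply", "post", "re-post", "comment"})

RETWEET_ACTIONS = frozenset({"retweet", "re-post"})
REPLY_ACTIONS = frozenset({"reply", "comment"})


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file, reported with its line number."""


def _sorted_users(users: Iterable) -> list:
    return sorted(users, key=str)


@dataclass
class SocialNetwork:
    """Directed follow graph.  Edge ``(i, j)``: *i* follows *j*."""

    graph: nx.DiGraph

    @property
    def users(self) -> list:
        return _sorted_users(self.graph.nodes)

    @property
    def n_users(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def followees(self, user) -> set:
        """``N_i`` — the accounts ``user`` follows (its influencers)."""
        return set(self.graph.successors(user))

    def followers(self, user) -> set:
        return set(self.graph.predecessors(user))

    def add_users(self, users: Iterable) -> None:
        """Extend the user universe (e.g. with event-only users, |N_i| = 0)."""
        self.graph.add_nodes_from(users)


class WeightedNetwork(SocialNetwork):
    """Follow graph with per-edge influence weights summing to 1 per follower.

    Caches a sparse row-stochastic matrix ``W`` (rows: followers, cols:
    followees) over a fixed user ordering so influence is a mat-vec:
    ``s(t) = W @ e(t)`` with ``e`` the 0/1 effective-neighbour indicator.
    """

    def __init__(self, graph: nx.DiGraph):
        super().__init__(graph)
        self._order: list | None = None
        self._index: dict | None = None
        self._W: sp.csr_matrix | None = None

    @property
    def user_order(self) -> list:
        if self._order is None:
            self._order = _sorted_users(self.graph.nodes)
            self._index = {u: k for k, u in enumerate(self._order)}
        return self._order

    @property
    def user_index(self) -> dict:
        self.user_order
        return self._index  # type: ignore[return-value]

    def weight(self, follower, followee) -> float:
        return self.graph[follower][followee]["weight"]

    def matrix(self) -> sp.csr_matrix:
        if self._W is None:
            order = self.user_order
            idx = self.user_index
            n = len(order)
            rows, cols, vals = [], [], []
            for i, j, data in self.graph.edges(data=True):
                rows.append(idx[i])
                cols.append(idx[j])
                vals.append(data["weight"])
            self._W = sp.csr_matrix(
                (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
            )
        return self._W


def read_edge_list(path, *, comment: str = "#", on_self_follow: str = "drop") -> SocialNetwork:
    """Read a whitespace-separated ``follower followee`` edge list.

    Parameters
    ----------
    path
        Text file, two tokens per non-comment line (SNAP dialect).
    on_self_follow
        ``"drop"`` (default) silently removes ``(i, i)`` edges, logging a
        count; ``"error"`` raises.
    """
    g = nx.DiGraph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two tokens, got {len(tokens)}: {stripped!r}"
                )
            follower, followee = tokens
            if follower == followee:
                if on_self_follow == "error":
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: self-follow {follower!r}"
                    )
                n_self += 1
                g.add_node(follower)
                continue
            g.add_edge(follower, followee)
    if n_self:
        logger.info("dropped %d self-follow edge(s) from %s", n_self, path)
    return SocialNetwork(g)


def uniform_weights(net: SocialNetwork) -> WeightedNetwork:
    """Attach ``w_ij = 1/|N_i|`` to every follow edge of every user *i*.

    Users with no followees keep no weighted edges; their influence sum is the
    empty sum, 0.
    """
    g = net.graph.copy()
    for i in g.nodes:
        out = g.out_degree(i)
        if out == 0:
            continue
        w = 1.0 / out
        for j in g.successors(i):
            g[i][j]["weight"] = w
    return WeightedNetwork(g)


@dataclass
class EventStream:
    """Timestamped social reactions: one row per (user, timestamp, action).

    Timestamps are hours (float) since ``episode_start``; the reader converts
    ISO-8601 datetimes or integer epoch-hours on ingestion.
    """

    frame: pd.DataFrame  # columns: user_id, t_hours, action
    episode_start: object = 0
    episode_hours: float | None = None
    n_dropped_actions: int = 0
    n_dropped_out_of_bounds: int = 0

    @property
    def users(self) -> list:
        return _sorted_users(self.frame["user_id"].unique())


def read_events(
    path,
    *,
    episode_start=None,
    episode_hours: float | None = None,
    allowed_actions: Iterable[str] = DEFAULT_ACTIONS,
    timestamp_format: str = "auto",
    sep: str = ",",
) -> EventStream:
    """Read a delimited event file with header ``user_id,timestamp,action``.

    ``timestamp_format``: ``"auto"`` (numeric columns are epoch hours,
    otherwise ISO-8601), ``"hours"`` or ``"iso"``.
    Reactions outside ``allowed_actions`` (e.g. likes, mentions) are dropped
    with a logged count.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"user_id": str, "action": str})
    missing = {"user_id", "timestamp", "action"} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    allowed = frozenset(allowed_actions)
    keep = raw["action"].isin(allowed)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d event(s) with excluded reaction types", n_dropped)
    raw = raw[keep]

    ts = raw["timestamp"]
    if timestamp_format == "auto":
        numeric = pd.to_numeric(ts, errors="coerce")
        timestamp_format = "hours" if not numeric.isna().any() else "iso"
    if timestamp_format == "hours":
        hours = pd.to_numeric(ts).astype(float)
        start = float(episode_start) if episode_start is not None else (
            float(hours.min()) if len(hours) else 0.0
        )
        t_hours = hours - start
    elif timestamp_format == "iso":
        stamps = pd.to_datetime(ts, utc=False)
        start = pd.to_datetime(episode_start) if episode_start is not None else (
            stamps.min().floor("h") if len(stamps) else pd.Timestamp(0)
        )
        t_hours = (stamps - start) / pd.Timedelta(hours=1)
    else:
        raise ValueError(f"unknown timestamp_format {timestamp_format!r}")

    frame = pd.DataFrame(
        {"user_id": raw["user_id"].to_numpy(), "t_hours": t_hours.to_numpy(), "action": raw["action"].to_numpy()}
    )
    n_oob = 0
    if episode_hours is not None:
        in_bounds = (frame["t_hours"] >= 0) & (frame["t_hours"] < episode_hours)
        n_oob = int((~in_bounds).sum())
        if n_oob:
            logger.warning("dropped %d event(s) outside the declared episode", n_oob)
        frame = frame[in_bounds]
    return EventStream(
        frame=frame.reset_index(drop=True),
        episode_start=episode_start if episode_start is not None else 0,
        episode_hours=episode_hours,
        n_dropped_actions=n_dropped,
        n_dropped_out_of_bounds=n_oob,
    )


@dataclass
class ActivityLog:
    """Binary user x hour matrix ``y_i(t)``, hours 0..T-1 from episode start.

    ``matrix[k, t] == 1`` iff user ``users[k]`` recorded at least one retained
    reaction during hour bin ``t``.
    """

    users: list
    matrix: np.ndarray  # shape (n_users, T), dtype uint8
    episode_start: object = 0
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.users):
            raise ValueError("matrix shape does not match user list")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("activity entries must be 0 or 1")
        self._index = {u: k for k, u in enumerate(self.users)}

    @property
    def T(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_users(self) -> int:
        return len(self.users)

    def row(self, user) -> np.ndarray:
        return self.matrix[self._index[user]]

    def activity_times(self, user) -> list[int]:
        """Sorted hours at which ``user`` was active."""
        return np.flatnonzero(self.row(user)).tolist()

    def prefix(self, t: int) -> "ActivityLog":
        """The log restricted to hours ``[0, t)``."""
        return ActivityLog(self.users, self.matrix[:, :t].copy(), self.episode_start)

    def reindex(self, users: Sequence) -> "ActivityLog":
        """Align rows to ``users``; unknown users get all-zero rows."""
        out = np.zeros((len(users), self.T), dtype=np.uint8)
        for k, u in enumerate(users):
            if u in self._index:
                out[k] = self.matrix[self._index[u]]
        return ActivityLog(list(users), out, self.episode_start)

    def write(self, path) -> None:
        """Sparse triplet text serialisation (round-trips bit-exactly)."""
        with open(path, "w") as fh:
            fh.write(f"# episode_start={self.episode_start}\n")
            fh.write(f"# T={self.T}\n")
            fh.write("# users=" + ",".join(str(u) for u in self.users) + "\n")
            fh.write("user_id\tt\ty\n")
            for k, u in enumerate(self.users):
                for t in np.flatnonzero(self.matrix[k]):
                    fh.write(f"{u}\t{int(t)}\t1\n")

    @classmethod
    def read(cls, path) -> "ActivityLog":
        episode_start: object = 0
        T = None
        users: list = []
        triplets: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# episode_start="):
                    raw = line.split("=", 1)[1]
                    try:
                        episode_start = int(raw)
                    except ValueError:
                        episode_start = raw
                elif line.startswith("# T="):
                    T = int(line.split("=", 1)[1])
                elif line.startswith("# users="):
                    payload = line.split("=", 1)[1]
                    users = payload.split(",") if payload else []
                elif line.startswith("#") or line.startswith("user_id") or not line:
                    continue
                else:
                    u, t, y = line.split("\t")
                    if y == "1":
                        triplets.append((u, int(t)))
        if T is None:
            raise ValueError(f"{path}: missing '# T=' header")
        mat = np.zeros((len(users), T), dtype=np.uint8)
        index = {u: k for k, u in enumerate(users)}
        for u, t in triplets:
            mat[index[u], t] = 1
        return cls(users, mat, episode_start)


def binarize_events(
    stream: EventStream,
    horizon: int,
    *,
    users: Sequence | None = None,
) -> ActivityLog:
    """Collapse an event stream into hourly 0/1 activity.

    ``y_i(t) = 1`` iff user *i* has at least one retained reaction in the
    half-open hour bin ``[t, t+1)``; duplicated records change nothing.
    ``users`` optionally fixes the row universe (event-only users are added).
    """
    frame = stream.frame
    in_bounds = (frame["t_hours"] >= 0) & (frame["t_hours"] < horizon)
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.warning("binarize_events: dropped %d out-of-bounds event(s)", n_oob)
    frame = frame[in_bounds]

    universe = list(users) if users is not None else []
    extra = set(frame["user_id"]) - set(universe)
    all_users = list(universe) + _sorted_users(extra)
    index = {u: k for k, u in enumerate(all_users)}
    mat = np.zeros((len(all_users), horizon), dtype=np.uint8)
    if len(frame):
        rows = frame["user_id"].map(index).to_numpy()
        bins = np.floor(frame["t_hours"].to_numpy()).astype(int)
        mat[rows, bins] = 1
    return ActivityLog(all_users, mat, stream.episode_start)
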