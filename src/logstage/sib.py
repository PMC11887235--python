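"""Sequential information-bottleneck (sIB) clustering by draw-and-merge.

Feature vectors are recast as a discrete joint distribution p(x, y): each
image x gets uniform mass 1/N, and its (nonnegative) feature vector is
normalized into a conditional p(y|x) over feature coordinates y.  A hard
partition T of the images is then sought that maximizes

    L = I(T; Y) - (1/lambda) * I(T; X),

i.e. keep as much of the feature information as possible (I(T;Y)) while
paying a small compression penalty (for a hard partition I(T;X) equals the
cluster entropy H(T)).  With the default lambda = 100 the compression term
is a ~1% regularizer and the optimization is dominated by information
preservation.

The optimizer is the draw-and-merge sweep: every point is drawn out of its
cluster in random order and re-merged into the cluster of minimal merger
cost

    dL = p_m * JS_w[p(y|x), p(y|t)] - (1/lambda) * p_m * H(w),

where p_m = p(x) + p(t), w = (p(x)/p_m, p(t)/p_m), JS_w is the weighted
Jensen-Shannon divergence and H(w) the binary entropy of the weights (the
JS of the disjoint membership indicators over X).  The merger cost equals
the from-scratch objective difference exactly, so each sweep step can only
increase L; the sweep converges when a full pass re-merges every point into
its own cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .backbone import FeatureMatrix

__all__ = [
    "JointDistribution", "ClusterState", "SibConfig",
    "features_to_joint", "mutual_information", "js_divergence",
    "merger_cost", "objective_from_scratch", "sib_cluster",
    "nmi", "kmeans_baseline", "DRAWN",
]

EPS = 1e-8       # mass floor added to every feature cell
MASS_TOL = 1e-9  # tolerance on "sums to one" validations

#: assignment value marking a point currently drawn out of all clusters
DRAWN = -1


@dataclass(frozen=True)
class JointDistribution:
    """Discrete joint p(x, y) with uniform p(x) and per-row conditionals."""

    p_xy: np.ndarray          # N x D, sums to 1
    p_x: np.ndarray           # N, uniform
    p_y_given_x: np.ndarray   # N x D, rows sum to 1

    def __post_init__(self) -> None:
        if abs(self.p_xy.sum() - 1.0) > 1e-12 * max(1, self.p_xy.size):
            raise ValueError("joint mass must be 1")
        if np.any(self.p_xy < 0):
            raise ValueError("joint entries must be nonnegative")
        row_sums = self.p_y_given_x.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("conditional rows must each sum to 1")

    @property
    def n(self) -> int:
        return self.p_xy.shape[0]

    @property
    def d(self) -> int:
        return self.p_xy.shape[1]


@dataclass
class ClusterState:
    """A hard partition with its sufficient statistics and objective value."""

    assignment: np.ndarray        # N ints in {0..k-1} (DRAWN while drawn)
    p_t: np.ndarray               # k cluster masses
    p_y_given_t: np.ndarray       # k x D conditionals (rows of empty clusters = 0)
    objective: float
    k: int
    objective_trace: list[float] = field(default_factory=list)
    passes: int = 0
    cost_evals: int = 0           # merger-cost evaluations (complexity bookkeeping)
    converged: bool = False

    def cluster_sizes(self) -> np.ndarray:
        valid = self.assignment[self.assignment != DRAWN]
        return np.bincount(valid, minlength=self.k)


@dataclass(frozen=True)
class SibConfig:
    """sIB hyperparameters; the staging defaults are k=4, lambda=100."""

    k: int = 4
    lam: float = 100.0
    max_passes: int = 50
    restarts: int = 5
    seed: int = 0
    tol: float = 0.0  # reserved; convergence is "no reassignment in a pass"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.max_passes < 1 or self.restarts < 1:
            raise ValueError("max_passes and restarts must be >= 1")


def features_to_joint(F: FeatureMatrix | np.ndarray) -> JointDistribution:
    """Turn an N x D nonnegative feature matrix into a joint distribution.

    Negative entries are clipped to zero, a floor of ``EPS`` is added to
    every cell (an all-zero row becomes uniform), rows are normalized into
    p(y|x), and p(x) is uniform.
    """
    v = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 2:
        raise ValueError(f"need an N x D matrix with D >= 2, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("features contain non-finite values")
    w = np.clip(v, 0.0, None) + EPS
    p_y_given_x = w / w.sum(axis=1, keepdims=True)
    n = v.shape[0]
    p_x = np.full(n, 1.0 / n)
    return JointDistribution(p_xy=p_y_given_x / n, p_x=p_x, p_y_given_x=p_y_given_x)


def mutual_information(joint: np.ndarray) -> float:
    """I(A;B) in nats of a 2D joint grid; zero-mass cells contribute zero."""
    j = np.asarray(joint, dtype=np.float64)
    if j.ndim != 2:
        raise ValueError("joint must be 2D")
    if np.any(j < 0):
        raise ValueError("joint entries must be nonnegative")
    total = j.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"joint mass {total} is not 1")
    pa = j.sum(axis=1, keepdims=True)
    pb = j.sum(axis=0, keepdims=True)
    mask = j > 0
    ratio = np.ones_like(j)
    np.divide(j, pa * pb, out=ratio, where=mask)
    return float(np.sum(j[mask] * np.log(ratio[mask])))


def js_divergence(p: np.ndarray, q: np.ndarray, w: tuple[float, float] = (0.5, 0.5)) -> float:
    """Weighted Jensen-Shannon divergence in nats.

    JS_w(p, q) = w1 KL(p || m) + w2 KL(q || m) with m = w1 p + w2 q.
    Bounded by the binary entropy H(w1, w2), attained on disjoint supports.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    w1, w2 = w
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError(f"weights must be nonnegative and sum to 1, got {w}")
    m = w1 * p + w2 * q

    def kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / m[mask])))

    return w1 * kl(p) + w2 * kl(q)


def _binary_entropy(w1: float, w2: float) -> float:
    h = 0.0
    for w in (w1, w2):
        if w > 0:
            h -= w * np.log(w)
    return h


def objective_from_scratch(
    joint: JointDistribution, assignment: np.ndarray, k: int, lam: float
) -> float:
    """L = I(T;Y) - I(T;X)/lambda recomputed from the partition alone.

    Serves as the independent oracle for the incremental merger cost:
    p(t, y) is assembled by summing member rows and fed to
    :func:`mutual_information`; for a hard partition I(T;X) reduces to the
    cluster entropy H(T).  Drawn points (assignment == DRAWN) each count as
    their own singleton cluster.
    """
    assignment = np.asarray(assignment)
    rows = [joint.p_xy[assignment == t].sum(axis=0) for t in range(k)]
    for x in np.nonzero(assignment == DRAWN)[0]:
        rows.append(joint.p_xy[x])
    p_ty = np.stack(rows)
    i_ty = mutual_information(p_ty)
    p_t = p_ty.sum(axis=1)
    h_t = -float(np.sum(p_t[p_t > 0] * np.log(p_t[p_t > 0])))
    return i_ty - h_t / lam


def merger_cost(
    state: ClusterState,
    joint: JointDistribution,
    x_index: int,
    target_cluster: int,
    lam: float,
) -> float:
    """Objective decrease from merging drawn singleton {x} into a cluster.

    Requires ``x_index`` to be drawn (``state.assignment[x_index] == DRAWN``)
    so the target cluster's statistics exclude it.  Equals the from-scratch
    difference L(drawn state) - L(after merge) exactly.
    """
    if not 0 <= x_index < len(state.assignment):
        raise IndexError(f"x_index {x_index} out of range")
    if not 0 <= target_cluster < state.k:
        raise IndexError(f"target_cluster {target_cluster} out of range")
    if state.assignment[x_index] != DRAWN:
        raise ValueError(f"point {x_index} must be drawn before costing a merge")
    px = joint.p_x[x_index]
    pt = state.p_t[target_cluster]
    p_m = px + pt
    if pt <= 0:  # merging with an empty cluster relabels the singleton: free
        return 0.0
    w = (px / p_m, pt / p_m)
    d_i2 = p_m * js_divergence(joint.p_y_given_x[x_index],
                               state.p_y_given_t[target_cluster], w)
    d_i1 = p_m * _binary_entropy(*w)
    return d_i2 - d_i1 / lam


class _SibEngine:
    """Mutable sweep state: cluster mass/row sums kept incrementally."""

    def __init__(self, joint: JointDistribution, k: int, lam: float):
        self.joint = joint
        self.k = k
        self.lam = lam
        self.assignment = np.full(joint.n, DRAWN, dtype=np.int64)
        self.sums = np.zeros((k, joint.d))   # sum of member p_xy rows
        self.p_t = np.zeros(k)
        self.counts = np.zeros(k, dtype=np.int64)
        self.cost_evals = 0

    def assign(self, x: int, t: int) -> None:
        self.assignment[x] = t
        self.sums[t] += self.joint.p_xy[x]
        self.p_t[t] += self.joint.p_x[x]
        self.counts[t] += 1

    def draw(self, x: int) -> int:
        t = self.assignment[x]
        self.assignment[x] = DRAWN
        self.sums[t] -= self.joint.p_xy[x]
        self.p_t[t] -= self.joint.p_x[x]
        self.counts[t] -= 1
        if self.counts[t] == 0:  # kill numerical residue in emptied clusters
            self.sums[t] = 0.0
            self.p_t[t] = 0.0
        return t

    def all_costs(self, x: int) -> np.ndarray:
        """Vectorized merger cost of drawn point x into each cluster."""
        self.cost_evals += self.k
        px = self.joint.p_x[x]
        py_x = self.joint.p_y_given_x[x]
        p_m = px + self.p_t
        costs = np.zeros(self.k)
        live = self.p_t > 0
        if np.any(live):
            w1 = px / p_m[live]
            w2 = self.p_t[live] / p_m[live]
            py_t = self.sums[live] / self.p_t[live][:, None]
            m = w1[:, None] * py_x[None, :] + w2[:, None] * py_t
            kl_p = np.sum(py_x[None, :] * (np.log(py_x)[None, :] - np.log(m)), axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = np.where(py_t > 0, np.log(np.where(py_t > 0, py_t, 1.0)) - np.log(m), 0.0)
            kl_q = np.sum(py_t * logr, axis=1)
            js = w1 * kl_p + w2 * kl_q
            h_w = -(w1 * np.log(w1) + w2 * np.log(w2))
            costs[live] = p_m[live] * (js - h_w / self.lam)
        return costs

    def objective(self) -> float:
        p_ty = self.sums[self.p_t > 0]
        drawn = np.nonzero(self.assignment == DRAWN)[0]
        if len(drawn):
            p_ty = np.concatenate([p_ty, self.joint.p_xy[drawn]])
        i_ty = mutual_information(p_ty)
        p_t = p_ty.sum(axis=1)
        h_t = -float(np.sum(p_t[p_t > 0] * np.log(p_t[p_t > 0])))
        return i_ty - h_t / self.lam

    def to_state(self) -> ClusterState:
        with np.errstate(invalid="ignore"):
            cond = np.where(self.p_t[:, None] > 0, self.sums / np.where(
                self.p_t[:, None] > 0, self.p_t[:, None], 1.0), 0.0)
        return ClusterState(
            assignment=self.assignment.copy(),
            p_t=self.p_t.copy(),
            p_y_given_t=cond,
            objective=self.objective(),
            k=self.k,
        )


def sib_cluster(F: FeatureMatrix | np.ndarray, cfg: SibConfig = SibConfig()) -> ClusterState:
    """Cluster feature rows into ``cfg.k`` groups by sIB draw-and-merge.

    Each restart starts from a random balanced partition and sweeps points
    in a reshuffled random order until a full pass makes no reassignment
    (or ``max_passes``).  The restart with the highest objective wins.
    The per-merge objective trace is recorded and is non-decreasing.
    """
    joint = features_to_joint(F)
    n = joint.n
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} points, got {n}")

    best: ClusterState | None = None
    for restart in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, restart)))
        eng = _SibEngine(joint, cfg.k, cfg.lam)
        order0 = rng.permutation(n)
        for i, x in enumerate(order0):  # balanced round-robin initialization
            eng.assign(int(x), i % cfg.k)

        trace = [eng.objective()]
        cur = trace[0]
        passes = 0
        converged = False
        for _ in range(cfg.max_passes):
            passes += 1
            changed = 0
            for x in rng.permutation(n):
                x = int(x)
                if eng.counts[eng.assignment[x]] == 1:
                    continue  # sole member: drawing it would drop a cluster
                t_old = eng.draw(x)
                costs = eng.all_costs(x)
                t_new = int(np.argmin(costs))  # ties -> lowest index
                eng.assign(x, t_new)
                cur += costs[t_old] - costs[t_new]
                trace.append(cur)
                if t_new != t_old:
                    changed += 1
            if changed == 0:
                converged = True
                break

        state = eng.to_state()
        state.objective_trace = trace
        state.passes = passes
        state.cost_evals = eng.cost_evals
        state.converged = converged
        if best is None or state.objective > best.objective:
            best = state
    return best


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information between two labelings (in [0, 1])."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(normalized_mutual_info_score(labels_a, labels_b))


def kmeans_baseline(F: FeatureMatrix | np.ndarray, k: int = 4, seed: int = 0) -> np.ndarray:
    """k-means cluster assignment over raw feature rows (ablation baseline)."""
    v = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(v)
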