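"""Simulation from the ERGM: MH sampling for general n, enumeration for tiny n.

The Markov chain proposes single ordered-pair (dyad) toggles, accepted with
probability ``min(1, exp(+-theta . delta(i, j)))``; an optional sparse-dyad
("tie / no tie") proposal mixture is available for low-density networks via
``SamplerControl.tnt`` and defaults off for auditability.  For networks with
``n (n - 1) <= 20`` dyads the full distribution is enumerated exactly and
serves as the oracle the chain is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.special import logsumexp

from . import _kernels
from .errors import DegeneracyError, ValidationError
from .network import DirectedNetwork, NodeAttributeTable
from .terms import ModelSpec, global_statistics, static_logodds_matrix

ENUMERATION_BOUND = 20  # max number of dyads n(n-1)


@dataclass
class SamplerControl:
    """MH chain controls.  ``burn_in``/``interval`` default to 20 n(n-1) and
    n(n-1) proposals respectively when left as None; the seed is mandatory."""

    seed: int
    burn_in: int | None = None
    interval: int | None = None
    tnt: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("SamplerControl.seed is mandatory")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValidationError("burn_in must be >= 0")
        if self.interval is not None and self.interval < 1:
            raise ValidationError("interval must be >= 1")

    def resolved(self, n_nodes: int) -> tuple:
        nd = n_nodes * (n_nodes - 1)
        burn = 20 * nd if self.burn_in is None else self.burn_in
        interval = nd if self.interval is None else self.interval
        return burn, interval


class GraphSampler:
    """Stateful MH chain over digraphs with fixed node attributes."""

    def __init__(
        self,
        spec: ModelSpec,
        theta,
        attrs: NodeAttributeTable,
        n_nodes: int | None = None,
        control: SamplerControl | None = None,
        start: DirectedNetwork | None = None,
    ):
        if control is None:
            raise ValidationError("a SamplerControl with a seed is required")
        self.spec = spec
        self.theta = spec.align_theta(theta)
        self.node_ids = tuple(attrs.frame.index)
        n = len(self.node_ids)
        if n_nodes is not None and n_nodes != n:
            raise ValidationError(f"n_nodes={n_nodes} but attribute table has {n} rows")
        if n < 2:
            raise ValidationError("sampling requires at least 2 nodes")
        self.n_nodes = n
        self.control = control
        self.X = attrs.matrix(self.node_ids)
        self.terms = spec.encode()
        names = spec.names
        self.has_mutual = "mutual" in names
        self.tmut = float(self.theta[names.index("mutual")]) if self.has_mutual else 0.0
        self.D = static_logodds_matrix(spec, self.theta, self.X)
        if start is None:
            start = DirectedNetwork(n, self.node_ids, frozenset())
        elif start.node_ids != self.node_ids:
            raise ValidationError("start network node ids do not match attributes")
        self.A = np.ascontiguousarray(start.adjacency().copy())
        self.z = global_statistics(start, attrs, spec)
        self._attrs = attrs
        self.tnt = bool(control.tnt)
        if self.tnt:
            nd = n * (n - 1)
            cap = nd if nd <= 1 << 22 else max(1 << 18, 16 * max(start.n_edges, 1024))
            self.ei = np.full(cap, -1, dtype=np.int64)
            self.ej = np.full(cap, -1, dtype=np.int64)
            self.pos = np.full((n, n), -1, dtype=np.int64)
            e = start.edge_array()
            for k in range(e.shape[0]):
                self.ei[k], self.ej[k] = e[k, 0], e[k, 1]
                self.pos[e[k, 0], e[k, 1]] = k
            self.ne = e.shape[0]
        else:
            self.ei = np.empty(1, dtype=np.int64)
            self.ej = np.empty(1, dtype=np.int64)
            self.pos = np.empty((1, 1), dtype=np.int64)
            self.ne = 0
        self._ss = np.random.SeedSequence(control.seed)
        self._n_seeds = 0

    def _next_seed(self) -> int:
        self._n_seeds += 1
        return int(self._ss.generate_state(self._n_seeds, dtype=np.uint32)[-1])

    def _common_args(self):
        return (self.A, self.z, self.X, self.terms, self.D, self.tmut, self.has_mutual)

    def run(self, n_props: int) -> None:
        kernel = _kernels.mh_advance_tnt if self.tnt else _kernels.mh_advance_uniform
        self.ne = kernel(
            *self._common_args(), int(n_props), self._next_seed(),
            self.ei, self.ej, self.pos, self.ne,
        )

    def burn(self) -> None:
        burn, _ = self.control.resolved(self.n_nodes)
        self.run(burn)

    def draw_statistics(self, n_draws: int, interval: int | None = None) -> np.ndarray:
        _, default_interval = self.control.resolved(self.n_nodes)
        interval = default_interval if interval is None else interval
        kernel = _kernels.mh_stats_tnt if self.tnt else _kernels.mh_stats_uniform
        out, self.ne = kernel(
            *self._common_args(), int(interval), int(n_draws), self._next_seed(),
            self.ei, self.ej, self.pos, self.ne,
        )
        return out

    def draw_networks(self, n_draws: int, interval: int | None = None) -> list:
        _, default_interval = self.control.resolved(self.n_nodes)
        interval = default_interval if interval is None else interval
        nets = []
        for _ in range(n_draws):
            self.run(interval)
            nets.append(DirectedNetwork.from_adjacency(self.A, self.node_ids))
        return nets

    def draw_state_codes(self, n_draws: int, interval: int = 1) -> np.ndarray:
        """Integer-coded full dyad states (tiny n only); for oracle checks."""
        dyads = dyad_order(self.n_nodes)
        if dyads.shape[0] > 62:
            raise ValidationError("state codes limited to 62 dyads")
        kernel = _kernels.mh_codes_tnt if self.tnt else _kernels.mh_codes_uniform
        out, self.ne = kernel(
            *self._common_args(), int(interval), int(n_draws), self._next_seed(),
            self.ei, self.ej, self.pos, self.ne, dyads,
        )
        return out

    def network(self) -> DirectedNetwork:
        return DirectedNetwork.from_adjacency(self.A, self.node_ids)


def mh_sample(
    spec: ModelSpec,
    theta,
    attrs: NodeAttributeTable,
    n_nodes: int | None = None,
    control: SamplerControl | None = None,
    n_draws: int = 1,
) -> list:
    """Draw ``n_draws`` networks from the model after burn-in.

    Identical inputs (including the control seed) give identical output.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    sampler = GraphSampler(spec, theta, attrs, n_nodes, control)
    sampler.burn()
    return sampler.draw_networks(n_draws)


def sample_statistics(
    spec: ModelSpec,
    theta,
    attrs: NodeAttributeTable,
    control: SamplerControl,
    n_draws: int,
    start: DirectedNetwork | None = None,
    interval: int | None = None,
    guard_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Burn in and collect a (n_draws, k) statistics sample.

    When ``guard_reference`` (typically the observed statistics) is given,
    the draw aborts with :class:`DegeneracyError` if the running mean of any
    statistic drifts monotonically past 5x its reference value.
    """
    sampler = GraphSampler(spec, theta, attrs, control=control, start=start)
    sampler.burn()
    Z = sampler.draw_statistics(n_draws, interval=interval)
    if guard_reference is not None and n_draws >= 8:
        _degeneracy_guard(Z, np.asarray(guard_reference, dtype=float), spec)
    return Z


def _degeneracy_guard(Z: np.ndarray, ref: np.ndarray, spec: ModelSpec) -> None:
    n_draws = Z.shape[0]
    quarters = [Z[: (q + 1) * n_draws // 4].mean(axis=0) for q in range(4)]
    floor = np.maximum(np.abs(ref), 1.0)
    for k, name in enumerate(spec.names):
        means = [q[k] for q in quarters]
        monotone = all(means[i + 1] > means[i] for i in range(3))
        if monotone and means[-1] > 5.0 * floor[k]:
            raise DegeneracyError(
                f"simulated statistic {name!r} drifts monotonically past 5x its "
                f"reference value ({means[-1]:.1f} vs {ref[k]:.1f})",
                term=name,
                diagnostics={"running_means": means, "reference": float(ref[k])},
            )


def dyad_order(n_nodes: int) -> np.ndarray:
    """Row-major enumeration of the n(n-1) ordered pairs; fixed convention."""
    out = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    return np.array(out, dtype=np.int64)


@dataclass
class ExactLikelihoodTable:
    """Exact enumeration of all ``2^(n(n-1))`` digraphs on n labelled nodes."""

    spec: ModelSpec
    theta: np.ndarray
    n_nodes: int
    dyads: np.ndarray           # (d, 2) dyad order defining the state bit codes
    statistics: np.ndarray      # (S, k)
    log_weights: np.ndarray     # theta . z per state
    log_normalizer: float       # log c

    @property
    def normalizer(self) -> float:
        return float(np.exp(self.log_normalizer))

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights - self.log_normalizer)

    def expectations(self) -> np.ndarray:
        """Exact E[z(Y)] under the model."""
        return self.probabilities @ self.statistics

    def covariance(self) -> np.ndarray:
        p = self.probabilities
        mu = p @ self.statistics
        Zc = self.statistics - mu
        return (Zc * p[:, None]).T @ Zc

    def state_code(self, network: DirectedNetwork) -> int:
        A = network.adjacency()
        code = 0
        for b, (i, j) in enumerate(self.dyads):
            if A[i, j]:
                code |= 1 << b
        return code

    def log_probability(self, network: DirectedNetwork) -> float:
        return float(self.log_weights[self.state_code(network)] - self.log_normalizer)


def enumerate_distribution(
    spec: ModelSpec,
    theta,
    attrs: NodeAttributeTable,
    n_nodes: int | None = None,
) -> ExactLikelihoodTable:
    """Exact weights exp(theta . z(y)) and normalizer c over all digraphs."""
    node_ids = tuple(attrs.frame.index)
    n = len(node_ids)
    if n_nodes is not None and n_nodes != n:
        raise ValidationError(f"n_nodes={n_nodes} but attribute table has {n} rows")
    d = n * (n - 1)
    if d > ENUMERATION_BOUND:
        raise ValidationError(
            f"enumeration requires n(n-1) <= {ENUMERATION_BOUND} dyads, got {d}"
        )
    theta = spec.align_theta(theta)
    X = attrs.matrix(node_ids)
    dyads = dyad_order(n)
    S = 1 << d
    bits = ((np.arange(S, dtype=np.int64)[:, None] >> np.arange(d)[None, :]) & 1).astype(
        np.float64
    )
    dyad_index = {(int(i), int(j)): b for b, (i, j) in enumerate(dyads)}
    Z = np.empty((S, len(spec)), dtype=np.float64)
    from .terms import _term_edge_indicator  # per-dyad indicators

    src, dst = dyads[:, 0], dyads[:, 1]
    for k, term in enumerate(spec.terms):
        if term.kind == "mutual":
            acc = np.zeros(S)
            for i in range(n):
                for j in range(i + 1, n):
                    acc += bits[:, dyad_index[(i, j)]] * bits[:, dyad_index[(j, i)]]
            Z[:, k] = acc
        else:
            coef = _term_edge_indicator(term, X, src, dst).astype(np.float64)
            Z[:, k] = bits @ coef
    logw = Z @ theta
    logc = float(logsumexp(logw))
    return ExactLikelihoodTable(spec, theta, n, dyads, Z, logw, logc)
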