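"""ERGM model specifications and sufficient statistics.

A model is an ordered list of terms; the probability of a digraph ``y`` is
``P(y) = exp(theta . z(y)) / c(theta)`` where ``z`` stacks one count per
term.  Supported terms (all within-dyad):

``edges``
    number of ties — the density intercept.
``mutual``
    number of reciprocated (mutual) unordered pairs.
``nodematch(attr)``
    uniform homophily: ties whose endpoints share ``attr``.
``nodematch_level(attr, level)``
    differential homophily: ties with both endpoints at ``level``.
``nodeifactor(attr, level)``
    receiver effect: ties whose receiver has ``level``.
``nodemix(attr, sender_level, receiver_level)``
    ties in one (sender level, receiver level) mixing cell.

The bundled ``adoc`` preset is the full reply-network model used throughout
the package: edges + reciprocity + gender homophily + 7 per-topic homophily
terms + a receiver-experience effect + the four polarized emotion mixing
cells (every cell involving neutral emotion is the reference category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .network import ATTRIBUTES, ATTRIBUTE_LEVELS, DirectedNetwork, NodeAttributeTable

# integer codes used by the numba kernels
KIND_EDGES, KIND_MUTUAL, KIND_NODEMATCH, KIND_NODEMATCH_LEVEL = 0, 1, 2, 3
KIND_NODEIFACTOR, KIND_NODEMIX = 4, 5

_KIND_NAMES = {
    "edges": KIND_EDGES,
    "mutual": KIND_MUTUAL,
    "nodematch": KIND_NODEMATCH,
    "nodematch_level": KIND_NODEMATCH_LEVEL,
    "nodeifactor": KIND_NODEIFACTOR,
    "nodemix": KIND_NODEMIX,
}
_ATTR_INDEX = {a: k for k, a in enumerate(ATTRIBUTES)}


@dataclass(frozen=True)
class Term:
    kind: str
    attribute: str | None = None
    level: int | None = None
    level2: int | None = None  # receiver level for nodemix

    def __post_init__(self):
        if self.kind not in _KIND_NAMES:
            raise ValidationError(f"unknown term kind {self.kind!r}")
        needs_attr = self.kind not in ("edges", "mutual")
        if needs_attr:
            if self.attribute not in _ATTR_INDEX:
                raise ValidationError(f"unknown attribute {self.attribute!r}")
            levels = ATTRIBUTE_LEVELS[self.attribute]
            if self.kind in ("nodematch_level", "nodeifactor", "nodemix"):
                if self.level not in levels:
                    raise ValidationError(
                        f"level {self.level!r} absent from {self.attribute!r} coding scheme"
                    )
            if self.kind == "nodemix":
                if self.level2 not in levels:
                    raise ValidationError(
                        f"level {self.level2!r} absent from {self.attribute!r} coding scheme"
                    )
        elif self.attribute is not None or self.level is not None:
            raise ValidationError(f"term {self.kind!r} takes no attribute")

    @property
    def name(self) -> str:
        if self.kind in ("edges", "mutual"):
            return self.kind
        if self.kind == "nodematch":
            return f"nodematch.{self.attribute}"
        if self.kind == "nodematch_level":
            return f"nodematch.{self.attribute}.{self.level}"
        if self.kind == "nodeifactor":
            return f"nodeifactor.{self.attribute}.{self.level}"
        return f"nodemix.{self.attribute}.{self.level}.{self.level2}"

    def encode(self) -> tuple:
        a = _ATTR_INDEX.get(self.attribute, -1)
        return (
            _KIND_NAMES[self.kind],
            a,
            -1 if self.level is None else self.level,
            -1 if self.level2 is None else self.level2,
        )


class ModelSpec:
    """Ordered, duplicate-free list of ERGM terms."""

    def __init__(self, terms: Iterable[Term]):
        terms = tuple(terms)
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate term(s): {dupes}")
        if not terms:
            raise ValidationError("model spec has no terms")
        self.terms = terms

    # -- interrogation -----------------------------------------------------
    @property
    def names(self) -> tuple:
        return tuple(t.name for t in self.terms)

    def __len__(self):
        return len(self.terms)

    def __eq__(self, other):
        return isinstance(other, ModelSpec) and self.terms == other.terms

    def __repr__(self):
        return f"ModelSpec({list(self.names)})"

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"term {name!r} not in spec") from None

    def has(self, name: str) -> bool:
        return name in self.names

    def drop(self, name: str) -> "ModelSpec":
        idx = self.index(name)
        return ModelSpec(self.terms[:idx] + self.terms[idx + 1 :])

    def encode(self) -> np.ndarray:
        """(k, 4) int64 term codes consumed by the numba kernels."""
        return np.array([t.encode() for t in self.terms], dtype=np.int64)

    def align_theta(self, theta) -> np.ndarray:
        """Coerce a dict (name -> value) or sequence into the spec's order."""
        if isinstance(theta, dict):
            missing = [n for n in self.names if n not in theta]
            if missing:
                raise ValidationError(f"theta missing term(s): {missing}")
            extra = [n for n in theta if n not in self.names]
            if extra:
                raise ValidationError(f"theta has unknown term(s): {extra}")
            vec = np.array([theta[n] for n in self.names], dtype=np.float64)
        else:
            vec = np.asarray(theta, dtype=np.float64)
            if vec.shape != (len(self),):
                raise ValidationError(
                    f"theta has length {vec.size}, spec has {len(self)} terms"
                )
        if not np.all(np.isfinite(vec)):
            raise ValidationError("theta must be finite")
        return vec

    # -- serialization -----------------------------------------------------
    def to_list(self) -> list:
        out = []
        for t in self.terms:
            d = {"kind": t.kind}
            if t.attribute is not None:
                d["attribute"] = t.attribute
            if t.level is not None:
                d["level"] = int(t.level)
            if t.level2 is not None:
                d["level2"] = int(t.level2)
            out.append(d)
        return out

    @classmethod
    def from_list(cls, items: Sequence[dict]) -> "ModelSpec":
        return cls(Term(**item) for item in items)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_list(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_list(yaml.safe_load(text))

    @classmethod
    def preset(cls, name: str) -> "ModelSpec":
        if name == "adoc":
            return adoc_spec()
        raise ValidationError(f"unknown preset {name!r}")


def adoc_spec() -> ModelSpec:
    """The full reply-network model specification (14 terms)."""
    terms = [Term("edges"), Term("mutual"), Term("nodematch", "gender")]
    terms += [Term("nodematch_level", "topic_preference", l) for l in range(1, 8)]
    terms += [Term("nodeifactor", "experience", 1)]
    terms += [
        Term("nodemix", "emotion_polarity", 2, 2),
        Term("nodemix", "emotion_polarity", 1, 1),
        Term("nodemix", "emotion_polarity", 2, 1),
        Term("nodemix", "emotion_polarity", 1, 2),
    ]
    return ModelSpec(terms)


def _term_edge_indicator(term: Term, attrs: np.ndarray, src: np.ndarray, dst: np.ndarray):
    """Per-edge 0/1 contribution of a non-mutual term, vectorized."""
    kind = term.kind
    if kind == "edges":
        return np.ones(src.shape[0], dtype=np.int64)
    a = _ATTR_INDEX[term.attribute]
    x_s, x_r = attrs[src, a], attrs[dst, a]
    if kind == "nodematch":
        return (x_s == x_r).astype(np.int64)
    if kind == "nodematch_level":
        return ((x_s == term.level) & (x_r == term.level)).astype(np.int64)
    if kind == "nodeifactor":
        return (x_r == term.level).astype(np.int64)
    # nodemix
    return ((x_s == term.level) & (x_r == term.level2)).astype(np.int64)


def global_statistics(
    network: DirectedNetwork, attrs: NodeAttributeTable, spec: ModelSpec
) -> np.ndarray:
    """Sufficient statistics z(y), one non-negative count per spec term."""
    X = attrs.matrix(network.node_ids)
    e = network.edge_array()
    src, dst = e[:, 0], e[:, 1]
    A = network.adjacency()
    out = np.empty(len(spec), dtype=np.float64)
    for k, term in enumerate(spec.terms):
        if term.kind == "mutual":
            # each mutual pair contributes to two edges; halve
            out[k] = A[dst, src].sum() / 2.0 if len(src) else 0.0
        else:
            out[k] = _term_edge_indicator(term, X, src, dst).sum()
    return out


def change_statistics(
    network: DirectedNetwork,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    i: int,
    j: int,
) -> np.ndarray:
    """z(y with y_ij=1) - z(y with y_ij=0), other entries of y held fixed."""
    if i == j:
        raise ValidationError("change statistic undefined on the diagonal (i == j)")
    n = network.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise ValidationError(f"dyad ({i}, {j}) outside [0, {n})")
    X = attrs.matrix(network.node_ids)
    A = network.adjacency()
    out = np.empty(len(spec), dtype=np.float64)
    si = np.array([i]), np.array([j])
    for k, term in enumerate(spec.terms):
        if term.kind == "mutual":
            out[k] = float(A[j, i])
        else:
            out[k] = float(_term_edge_indicator(term, X, si[0], si[1])[0])
    return out


def dyad_change_matrix(
    spec: ModelSpec, X: np.ndarray, A: np.ndarray, i: int
) -> np.ndarray:
    """Change statistics for all dyads (i, j), j = 0..n-1, as an (n, k) array.

    Row ``i`` (the diagonal) is meaningless and must be masked by the caller.
    Used by the pseudolikelihood builder; ``X`` is the (n, 4) attribute
    matrix and ``A`` the current adjacency.
    """
    n = A.shape[0]
    out = np.empty((n, len(spec)), dtype=np.float64)
    for k, term in enumerate(spec.terms):
        if term.kind == "edges":
            out[:, k] = 1.0
        elif term.kind == "mutual":
            out[:, k] = A[:, i]
        else:
            a = _ATTR_INDEX[term.attribute]
            x_s, x_r = X[i, a], X[:, a]
            if term.kind == "nodematch":
                out[:, k] = x_r == x_s
            elif term.kind == "nodematch_level":
                out[:, k] = (x_s == term.level) & (x_r == term.level)
            elif term.kind == "nodeifactor":
                out[:, k] = x_r == term.level
            else:
                out[:, k] = (x_s == term.level) & (x_r == term.level2)
    return out


def static_logodds_matrix(
    spec: ModelSpec, theta: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """(n, n) matrix of theta . delta(i, j) over all *dyad-independent* terms.

    The only state-dependent term in this family is ``mutual``; the sampler
    adds ``theta_mutual * y_ji`` on the fly.  Diagonal entries are unused.
    """
    n = X.shape[0]
    D = np.zeros((n, n), dtype=np.float64)
    for k, term in enumerate(spec.terms):
        t = theta[k]
        if t == 0.0 or term.kind == "mutual":
            continue
        if term.kind == "edges":
            D += t
            continue
        a = _ATTR_INDEX[term.attribute]
        x = X[:, a]
        if term.kind == "nodematch":
            D += t * (x[:, None] == x[None, :])
        elif term.kind == "nodematch_level":
            m = x == term.level
            D += t * (m[:, None] & m[None, :])
        elif term.kind == "nodeifactor":
            D += t * (x == term.level)[None, :]
        else:
            D += t * ((x == term.level)[:, None] & (x == term.level2)[None, :])
    return D
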