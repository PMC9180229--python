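"""Coding of raw user records into node attributes, and robustness sweeps.

Raw records carry, per user, a gender label, a registration time and a list
of texts each scored for sentiment and assigned one of seven topics.  Coding
is rank-based and therefore invariant to any strictly increasing transform
of the sentiment scale:

* gender: male -> 1, female -> 0;
* emotion polarity: users ranked by mean sentiment (ties broken by their
  order in the user table); the top ``ceil(q N)`` coded positive (2), the
  bottom ``ceil(q N)`` negative (1), the rest neutral (0), q = 0.10 by
  default;
* experience: the ``ceil((1 - f) N)`` most recently registered users coded
  inexperienced (0), the rest experienced (1), f = 0.75 by default;
* topic preference: the modal topic over the user's texts, ties broken by
  the smallest topic code.

The robustness sweep refits the model after dropping the gender term (M1)
and after recoding experience at fractions 70/73/77/80% (M2-M5), mirroring
the study's sensitivity analysis, and a flip detector reports terms whose
sign or significance class departs from the baseline fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError, AdocnetError
from .network import DirectedNetwork, NodeAttributeTable
from .terms import ModelSpec, adoc_spec

BASELINE_FRACTION = 0.75


@dataclass
class CodingThresholds:
    experienced_fraction: float = BASELINE_FRACTION
    polarity_fraction: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.experienced_fraction < 1.0:
            raise ValidationError("experienced_fraction must be in (0, 1)")
        if not 0.0 < self.polarity_fraction < 1.0:
            raise ValidationError("polarity_fraction must be in (0, 1)")
        if 2 * self.polarity_fraction >= 1.0:
            raise ValidationError("2 * polarity_fraction must be < 1")


@dataclass
class RawRecords:
    """Raw user table + long-format text table.

    ``users``: columns user_id, gender ('male'/'female'), registration_time.
    ``texts``: columns user_id, sentiment (real), topic (1..7).
    """

    users: pd.DataFrame
    texts: pd.DataFrame

    def __post_init__(self):
        for col in ("user_id", "gender", "registration_time"):
            if col not in self.users.columns:
                raise ValidationError(f"users table missing column {col!r}")
        for col in ("user_id", "sentiment", "topic"):
            if col not in self.texts.columns:
                raise ValidationError(f"texts table missing column {col!r}")
        dup = self.users["user_id"][self.users["user_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate user_id(s): {sorted(set(dup))[:5]}")
        bad_gender = set(self.users["gender"].unique()) - {"male", "female"}
        if bad_gender:
            raise ValidationError(f"unknown gender label(s): {sorted(bad_gender)}")
        topics = self.texts["topic"]
        bad = ~topics.isin(range(1, 8))
        if bad.any():
            rows = self.texts.index[bad][:5].tolist()
            raise ValidationError(f"topic labels outside 1..7 at row(s) {rows}")
        unknown = set(self.texts["user_id"]) - set(self.users["user_id"])
        if unknown:
            raise ValidationError(f"texts reference unknown user(s): {sorted(unknown)[:5]}")

    @property
    def user_ids(self) -> tuple:
        return tuple(self.users["user_id"])

    def __eq__(self, other):
        return (
            isinstance(other, RawRecords)
            and self.users.reset_index(drop=True).equals(other.users.reset_index(drop=True))
            and self.texts.reset_index(drop=True).equals(other.texts.reset_index(drop=True))
        )


def _tail_count(fraction: float, n: int) -> int:
    return math.ceil(fraction * n)


def code_attributes(
    records: RawRecords, thresholds: CodingThresholds | None = None
) -> NodeAttributeTable:
    """Code raw records into the four node attributes (see module docstring)."""
    thresholds = thresholds or CodingThresholds()
    users = records.users.reset_index(drop=True)
    n = len(users)
    texts = records.texts
    counts = texts.groupby("user_id").size()
    missing = [u for u in users["user_id"] if u not in counts.index]
    if missing:
        raise ValidationError(f"user(s) with zero texts: {missing[:5]}")

    gender = users["gender"].map({"male": 1, "female": 0}).to_numpy()

    # emotion polarity: single stable ranking by (mean sentiment, table order)
    mean_sent = texts.groupby("user_id")["sentiment"].mean()
    scores = mean_sent.reindex(users["user_id"]).to_numpy()
    order = np.argsort(scores, kind="stable")  # ascending; ties keep table order
    m_pol = _tail_count(thresholds.polarity_fraction, n)
    emotion = np.zeros(n, dtype=np.int64)
    emotion[order[:m_pol]] = 1          # most negative
    emotion[order[n - m_pol:]] = 2      # most positive

    # experience: most recently registered ceil((1-f)N) users are inexperienced
    reg = users["registration_time"].to_numpy()
    reg_order = np.argsort(reg, kind="stable")  # ascending: earliest first
    m_inexp = _tail_count(1.0 - thresholds.experienced_fraction, n)
    experience = np.ones(n, dtype=np.int64)
    experience[reg_order[n - m_inexp:]] = 0

    # topic preference: modal topic, ties -> smallest code
    topic_counts = texts.groupby(["user_id", "topic"]).size().unstack(fill_value=0)
    topic_pref = topic_counts.idxmax(axis=1).reindex(users["user_id"]).to_numpy()

    frame = pd.DataFrame(
        {
            "gender": gender,
            "experience": experience,
            "emotion_polarity": emotion,
            "topic_preference": topic_pref.astype(np.int64),
        },
        index=pd.Index(users["user_id"], name="user_id"),
    )
    return NodeAttributeTable(frame)


# ---------------------------------------------------------------------------
# robustness sweep
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-term estimates and stars across robustness model columns."""

    models: tuple
    estimates: pd.DataFrame      # terms x models, NaN where absent
    stars: pd.DataFrame          # terms x models, '' where absent/undefined
    converged: dict
    baseline: str = "M0"
    meta: dict = field(default_factory=dict)

    def terms(self) -> tuple:
        return tuple(self.estimates.index)

    def to_frame(self) -> pd.DataFrame:
        out = {}
        for m in self.models:
            out[(m, "estimate")] = self.estimates[m]
            out[(m, "stars")] = self.stars[m]
        frame = pd.DataFrame(out)
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame

    @classmethod
    def from_values(cls, estimates: pd.DataFrame, stars: pd.DataFrame, baseline="M0"):
        models = tuple(estimates.columns)
        return cls(
            models=models,
            estimates=estimates,
            stars=stars.reindex(estimates.index).fillna(""),
            converged={m: True for m in models},
            baseline=baseline,
        )


@dataclass
class SignFlip:
    term: str
    model: str
    kind: str            # 'sign' or 'significance'
    baseline_value: float
    value: float
    detail: str = ""


def robustness_sweep(
    records: RawRecords,
    network: DirectedNetwork,
    fractions: Sequence[float] = (0.70, 0.73, 0.75, 0.77, 0.80),
    *,
    polarity_fraction: float = 0.10,
    spec: ModelSpec | None = None,
    method: str = "mple",
    seed: int | None = None,
    control_kwargs: dict | None = None,
) -> ComparisonTable:
    """Refit the model across robustness columns M0..M5.

    M0 is the baseline (experienced fraction 0.75, full spec), M1 drops the
    gender homophily term at the baseline coding, and the remaining columns
    recode experience at the other fractions in the order given.  A column
    whose fit fails is flagged and the sweep continues.
    """
    from .estimation import EstimationControl, mcmc_mle, mple, wald_report

    spec = spec or adoc_spec()
    fractions = list(fractions)
    if BASELINE_FRACTION not in fractions:
        raise ValidationError(f"fractions must include the baseline {BASELINE_FRACTION}")
    missing = set(network.node_ids) - set(records.user_ids)
    if missing:
        raise ValidationError(f"records missing network node(s): {sorted(missing)[:5]}")
    alt_fractions = [f for f in fractions if f != BASELINE_FRACTION]
    columns = [("M0", BASELINE_FRACTION, spec)]
    columns.append(("M1", BASELINE_FRACTION, spec.drop("nodematch.gender")))
    for idx, f in enumerate(alt_fractions):
        columns.append((f"M{idx + 2}", f, spec))

    ss = np.random.SeedSequence(0 if seed is None else seed)
    child_seeds = ss.generate_state(len(columns), dtype=np.uint32).tolist()

    est = pd.DataFrame(index=list(spec.names), dtype=float)
    stars = pd.DataFrame(index=list(spec.names), dtype=object)
    converged, meta = {}, {"fractions": {}}
    cache = {}
    for (name, f, col_spec), cseed in zip(columns, child_seeds):
        if f not in cache:
            cache[f] = code_attributes(
                records,
                CodingThresholds(experienced_fraction=f, polarity_fraction=polarity_fraction),
            )
        attrs = cache[f]
        meta["fractions"][name] = f
        try:
            if method == "mple":
                fit = mple(network, attrs, col_spec)
            elif method == "mcmcmle":
                kwargs = dict(control_kwargs or {})
                fit = mcmc_mle(
                    network, attrs, col_spec, EstimationControl(seed=int(cseed), **kwargs)
                )
            else:
                raise ValidationError(f"unknown method {method!r}")
        except AdocnetError as exc:
            est[name] = np.nan
            stars[name] = ""
            converged[name] = False
            meta.setdefault("errors", {})[name] = str(exc)
            continue
        report = wald_report(fit).set_index("term")
        est[name] = report["estimate"].reindex(est.index)
        stars[name] = report["stars"].reindex(stars.index).fillna("")
        converged[name] = bool(fit.converged)
    return ComparisonTable(
        models=tuple(n for n, _, _ in columns),
        estimates=est,
        stars=stars.fillna(""),
        converged=converged,
        meta=meta,
    )


def sign_consistency_report(comparison: ComparisonTable) -> list:
    """Terms whose sign or significance class differs from the baseline column.

    The significance class is coarse: starred (p < 0.05) vs unstarred.  A
    term absent from a column (e.g. gender in M1) is skipped.  The returned
    list is empty when every column is fully consistent with the baseline.
    """
    if len(comparison.models) < 2:
        raise ValidationError("comparison needs at least 2 model columns")
    base = comparison.baseline
    flips = []
    for term in comparison.terms():
        b_est = comparison.estimates.loc[term, base]
        b_star = comparison.stars.loc[term, base]
        if not np.isfinite(b_est):
            continue
        for model in comparison.models:
            if model == base:
                continue
            v = comparison.estimates.loc[term, model]
            if not np.isfinite(v):
                continue
            if np.sign(v) != np.sign(b_est) and (v != 0 or b_est != 0):
                flips.append(
                    SignFlip(
                        term, model, "sign", float(b_est), float(v),
                        detail=f"{'+' if b_est > 0 else '-'} -> {'+' if v > 0 else '-'}",
                    )
                )
            elif bool(comparison.stars.loc[term, model]) != bool(b_star):
                flips.append(
                    SignFlip(
                        term, model, "significance", float(b_est), float(v),
                        detail=f"{b_star or 'n.s.'} -> {comparison.stars.loc[term, model] or 'n.s.'}",
                    )
                )
    return flips
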