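"""Synthetic reply-community generator with known ERGM ground truth.

No raw data from the original community is available, so every pipeline
stage is exercised on generated data instead: users with gender,
registration time and sentiment/topic-scored texts are drawn first, coded
through :mod:`adocnet.coding`, and a reply network is then simulated from a
ground-truth coefficient vector *conditional on the coded attributes* — the
same attributes the estimation stage later sees.

The default configuration emulates the reference scenario the package was
built around: a community of 6,158 users and 16,521 directed reply ties
(mean degree ~2.68), a 75/25 experienced/inexperienced split, 10/10/80
positive/negative/neutral emotion polarity, seven topic-preference
categories, and the published coefficient vector of the fitted
reply-network model as ground truth.  The edges (density) coefficient is
not part of that vector and is calibrated by bisection so the simulated
mean degree matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .coding import CodingThresholds, RawRecords, code_attributes
from .errors import DegeneracyError, ValidationError
from .network import DirectedNetwork, NodeAttributeTable
from .sampler import GraphSampler, SamplerControl, mh_sample
from .terms import ModelSpec, adoc_spec

REFERENCE_N_USERS = 6158
REFERENCE_N_EDGES = 16521
REFERENCE_MEAN_DEGREE = REFERENCE_N_EDGES / REFERENCE_N_USERS  # ~2.683

#: published coefficient vector of the reference reply-network model
#: (all hypothesis terms; the edges intercept is calibrated, not published)
REFERENCE_THETA = {
    "mutual": 2.898,
    "nodematch.gender": -0.005,
    "nodematch.topic_preference.1": 0.308,   # pathology popularization
    "nodematch.topic_preference.2": -0.295,  # generalized-anxiety symptoms
    "nodematch.topic_preference.3": -0.084,  # panic attack records
    "nodematch.topic_preference.4": -0.021,  # emotional catharsis
    "nodematch.topic_preference.5": 0.098,   # drug efficacy
    "nodematch.topic_preference.6": 0.094,   # hypochondriasis diagnosis
    "nodematch.topic_preference.7": 0.073,   # social support
    "nodeifactor.experience.1": 0.103,
    "nodemix.emotion_polarity.2.2": 0.413,
    "nodemix.emotion_polarity.1.1": -0.487,
    "nodemix.emotion_polarity.2.1": 0.534,
    "nodemix.emotion_polarity.1.2": -1.191,
}

#: published standard errors and p-values of the same model, for tests and
#: report fixtures (index-aligned with REFERENCE_THETA)
REFERENCE_SD = {
    "mutual": 0.297,
    "nodematch.gender": 0.023,
    "nodematch.topic_preference.1": 0.101,
    "nodematch.topic_preference.2": 0.077,
    "nodematch.topic_preference.3": 0.073,
    "nodematch.topic_preference.4": 0.059,
    "nodematch.topic_preference.5": 0.059,
    "nodematch.topic_preference.6": 0.098,
    "nodematch.topic_preference.7": 0.066,
    "nodeifactor.experience.1": 0.025,
    "nodemix.emotion_polarity.2.2": 0.094,
    "nodemix.emotion_polarity.1.1": 0.127,
    "nodemix.emotion_polarity.2.1": 0.090,
    "nodemix.emotion_polarity.1.2": 0.142,
}


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic community.

    Defaults emulate the reference scenario at full scale; pass
    ``n_users=200`` for the test-scale variant used in the recovery
    experiments.
    """

    seed: int
    n_users: int = REFERENCE_N_USERS
    male_probability: float = 0.5
    registration_span_days: float = 3650.0   # uniform over a 10-year window
    texts_per_user_mean: float = 4.0         # 1 + Poisson(mean - 1)
    class_fractions: tuple = (0.10, 0.10, 0.80)  # positive, negative, neutral
    class_locations: tuple = (4.0, -4.0, 0.0)    # latent mean sentiment per class
    text_score_sd: float = 1.0
    topic_concentration: float = 0.5         # symmetric Dirichlet over 7 topics
    theta: dict = field(default_factory=lambda: dict(REFERENCE_THETA))
    edges_coefficient: float | None = None   # None -> calibrate
    target_mean_degree: float = REFERENCE_MEAN_DEGREE
    experienced_fraction: float = 0.75
    polarity_fraction: float = 0.10

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("GeneratorConfig.seed is mandatory")
        if self.n_users < 2:
            raise ValidationError("n_users must be >= 2")
        if not 0 <= self.male_probability <= 1:
            raise ValidationError("male_probability must be in [0, 1]")
        if len(self.class_fractions) != 3 or sum(self.class_fractions) > 1.0 + 1e-9:
            raise ValidationError("class_fractions must be 3 values summing to <= 1")
        if self.texts_per_user_mean < 1:
            raise ValidationError("texts_per_user_mean must be >= 1")


@dataclass
class SyntheticBundle:
    records: RawRecords
    attributes: NodeAttributeTable
    network: DirectedNetwork
    spec: ModelSpec
    theta: dict                  # full ground truth including calibrated edges
    latent_classes: np.ndarray   # 2 positive-prone, 1 negative-prone, 0 neutral
    config: GeneratorConfig

    @property
    def theta_vector(self) -> np.ndarray:
        return self.spec.align_theta(self.theta)


def _draw_records(config: GeneratorConfig, rng: np.random.Generator):
    n = config.n_users
    width = len(str(n))
    user_ids = [f"u{k:0{width}d}" for k in range(1, n + 1)]
    gender = np.where(rng.random(n) < config.male_probability, "male", "female")
    registration = rng.uniform(0.0, config.registration_span_days, size=n).round(4)
    p_pos, p_neg, p_neu = config.class_fractions
    classes = rng.choice(
        np.array([2, 1, 0]), size=n, p=np.array([p_pos, p_neg, p_neu]) / sum(config.class_fractions)
    )
    loc = {2: config.class_locations[0], 1: config.class_locations[1], 0: config.class_locations[2]}
    n_texts = 1 + rng.poisson(config.texts_per_user_mean - 1.0, size=n)
    topic_probs = rng.dirichlet(np.full(7, config.topic_concentration), size=n)
    rows_user, rows_sent, rows_topic = [], [], []
    for k in range(n):
        m = int(n_texts[k])
        rows_user.extend([user_ids[k]] * m)
        rows_sent.append(rng.normal(loc[int(classes[k])], config.text_score_sd, size=m))
        rows_topic.append(rng.choice(np.arange(1, 8), size=m, p=topic_probs[k]))
    users = pd.DataFrame(
        {"user_id": user_ids, "gender": gender, "registration_time": registration}
    )
    texts = pd.DataFrame(
        {
            "user_id": rows_user,
            "sentiment": np.round(np.concatenate(rows_sent), 6),
            "topic": np.concatenate(rows_topic).astype(np.int64),
        }
    )
    return RawRecords(users, texts), classes


def calibrate_edges_coefficient(
    spec: ModelSpec,
    theta_without_edges: dict,
    attrs: NodeAttributeTable,
    target_mean_degree: float,
    control: SamplerControl,
    tolerance: float = 0.05,
    n_draws: int = 16,
    max_bisect: int = 40,
) -> float:
    """Bisection on the edges coefficient until the simulated mean degree is
    within ``tolerance`` (relative) of the target.

    Starts from the analytic logit of the target density (exact when all
    other coefficients are zero) and widens a bracket around it when needed.
    """
    n = len(attrs)
    density = target_mean_degree / (n - 1)
    if not 0.0 < density < 1.0:
        raise ValidationError(f"target density {density:.4g} outside (0, 1)")
    if not spec.has("edges"):
        raise ValidationError("spec must contain an edges term to calibrate")
    edges_idx = spec.index("edges")
    base = dict(theta_without_edges)
    base.pop("edges", None)
    ss = np.random.SeedSequence(control.seed)
    counter = [0]

    def simulate_mean_degree(te: float) -> float:
        counter[0] += 1
        seed = int(ss.generate_state(counter[0], dtype=np.uint32)[-1])
        theta = dict(base)
        theta["edges"] = te
        sampler = GraphSampler(
            spec, theta, attrs,
            control=SamplerControl(seed=seed, burn_in=control.burn_in,
                                   interval=control.interval, tnt=control.tnt),
        )
        sampler.burn()
        Z = sampler.draw_statistics(n_draws)
        mean_edges = float(Z[:, edges_idx].mean())
        if mean_edges > 5.0 * target_mean_degree * n and te < logit(density):
            raise DegeneracyError(
                "edge calibration drifted to a dense degenerate regime; "
                "rescale the non-edges coefficients",
            )
        return mean_edges / n

    def ok(value: float) -> bool:
        return abs(value - target_mean_degree) <= tolerance * target_mean_degree

    te0 = float(logit(density))
    d0 = simulate_mean_degree(te0)
    if ok(d0):
        return te0
    # bracket the target
    step = 1.0
    if d0 > target_mean_degree:
        hi, d_hi = te0, d0
        lo = te0 - step
        d_lo = simulate_mean_degree(lo)
        while d_lo > target_mean_degree:
            if ok(d_lo):
                return lo
            step *= 2.0
            lo -= step
            if lo < te0 - 24:
                raise ValidationError("edge calibration failed to bracket the target")
            d_lo = simulate_mean_degree(lo)
        if ok(d_lo):
            return lo
    else:
        lo, d_lo = te0, d0
        hi = te0 + step
        d_hi = simulate_mean_degree(hi)
        while d_hi < target_mean_degree:
            if ok(d_hi):
                return hi
            step *= 2.0
            hi += step
            if hi > te0 + 24:
                raise ValidationError("edge calibration failed to bracket the target")
            d_hi = simulate_mean_degree(hi)
        if ok(d_hi):
            return hi
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        d_mid = simulate_mean_degree(mid)
        if ok(d_mid):
            return mid
        if d_mid > target_mean_degree:
            hi = mid
        else:
            lo = mid
    raise ValidationError(
        f"edge calibration did not reach {tolerance:.0%} of the target in "
        f"{max_bisect} bisection steps"
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticBundle:
    """Draw users, code attributes, calibrate density, simulate the network."""
    ss = np.random.SeedSequence(config.seed)
    s_records, s_calib, s_net = (
        int(s.generate_state(1, dtype=np.uint32)[0]) for s in ss.spawn(3)
    )
    rng = np.random.default_rng(s_records)
    records, classes = _draw_records(config, rng)
    attrs = code_attributes(
        records,
        CodingThresholds(
            experienced_fraction=config.experienced_fraction,
            polarity_fraction=config.polarity_fraction,
        ),
    )
    spec = adoc_spec()
    theta = dict(config.theta)
    if config.edges_coefficient is None:
        te = calibrate_edges_coefficient(
            spec, theta, attrs, config.target_mean_degree,
            SamplerControl(seed=s_calib),
        )
    else:
        te = float(config.edges_coefficient)
    theta["edges"] = te
    network = mh_sample(
        spec, theta, attrs, n_nodes=config.n_users,
        control=SamplerControl(seed=s_net), n_draws=1,
    )[0]
    return SyntheticBundle(records, attrs, network, spec, theta, classes, config)
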