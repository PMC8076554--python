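"""Salience as expected information gain, and Bayesian belief updating.

A fixation policy is scored by the mutual information between the latent
room identity and the retinal images the policy would produce:

    I[X, Y | pi] = H[P(y | pi)]  -  E_{P(x | pi)} H[P(y | x, pi)]
                   (predictive entropy)   (expected ambiguity)

which also equals the KL divergence between joint and marginals and the
expected KL from prior to posterior; :func:`mutual_information_oracle`
evaluates all three by direct summation as a numeric cross-check.

The renderer is deterministic, so the outcome alphabet is built by
clustering the per-room renders: images within a max-abs pixel tolerance
are one outcome, and a cluster's probability is the summed belief of its
member rooms.  In that noiseless reading the expected ambiguity is
exactly zero and salience reduces to predictive entropy.  A discrete
sensory noise model (e.g. the eyes-closed channel, where every intensity
bin is equiprobable) can be supplied to make the ambiguity term bite.

Observing an actual render updates the belief by exact Bayes over rooms:
the likelihood of a room is 1 if its render matches the observation
within tolerance, else 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .render import BinocularRender, Lesion, LightSource, render_binocular
from .scene import RoomLibrary, SurfaceMesh, assemble_room
from .viewpoint import (
    DEFAULT_BASELINE,
    EyeDirection,
    HeadPose,
    RetinalArray,
    build_retinal_array,
)

__all__ = [
    "Belief",
    "Policy",
    "Outcome",
    "OutcomeDistribution",
    "PolicyScore",
    "SalienceReport",
    "RenderContext",
    "InconsistentObservationError",
    "entropy_bits",
    "mutual_information_oracle",
    "predictive_outcomes",
    "expected_ambiguity",
    "expected_information_gain",
    "rank_policies",
    "update_belief",
    "eyes_closed_channel",
    "demo_policy",
    "demo_context",
    "DEMO_VIEW_HEADINGS",
]

_LN2 = math.log(2.0)

#: head headings (rad) that point the demo viewer at each corner site.
DEMO_VIEW_HEADINGS = {
    "southeast": -math.pi / 4,
    "northeast": math.pi / 4,
    "southwest": -3 * math.pi / 4,
    "northwest": 3 * math.pi / 4,
}


class InconsistentObservationError(ValueError):
    """No room in the library could have produced the observation."""


def as_belief(p, n_rooms: Optional[int] = None) -> np.ndarray:
    """Validate a probability vector over rooms."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("belief must be non-negative and sum to 1")
    if n_rooms is not None and len(p) != n_rooms:
        raise ValueError(f"belief length {len(p)} != room count {n_rooms}")
    return p


Belief = np.ndarray  # probability vector over rooms


@dataclass(frozen=True)
class Policy:
    """A candidate fixation: where to stand/face and where to point the eyes."""

    label: str
    pose: HeadPose
    eyes: EyeDirection = EyeDirection()

    def _key(self) -> tuple:
        return (self.pose.place, self.pose.head_dir, self.eyes.ego_dir,
                self.eyes.convergence)


@dataclass
class RenderContext:
    """Shared rendering configuration plus per-room caches.

    Bundles the retinal array, light, baseline, blur width and assembly
    resolution so that every policy/room render in a planning problem is
    produced under identical imaging conditions.
    """

    array: RetinalArray
    light: LightSource
    baseline: float = DEFAULT_BASELINE
    sigma_freq: Optional[float] = None
    resolution: int = 8
    _meshes: Dict[str, SurfaceMesh] = field(default_factory=dict, repr=False)
    _renders: Dict[tuple, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    def room_mesh(self, room) -> SurfaceMesh:
        if room.label not in self._meshes:
            self._meshes[room.label] = assemble_room(room, self.resolution)
        return self._meshes[room.label]

    def render(self, room, policy: Policy) -> Tuple[np.ndarray, np.ndarray]:
        """Blurred retinal image pair for a room under a policy (cached)."""
        key = (room.label,) + policy._key()
        if key not in self._renders:
            result = render_binocular(
                policy.pose, policy.eyes, self.array, self.room_mesh(room),
                self.light, sigma_freq=self.sigma_freq, baseline=self.baseline,
            )
            self._renders[key] = result.retinal
        return self._renders[key]


@dataclass(frozen=True)
class Outcome:
    """One predicted observation: a representative image pair and its probability."""

    images: Tuple[np.ndarray, np.ndarray]
    probability: float
    rooms: Tuple[int, ...]  # member room indices


@dataclass(frozen=True)
class OutcomeDistribution:
    outcomes: Tuple[Outcome, ...]
    tol: float

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([o.probability for o in self.outcomes])


def _pair_distance(a: Tuple[np.ndarray, np.ndarray],
                   b: Tuple[np.ndarray, np.ndarray]) -> float:
    return max(
        float(np.max(np.abs(a[0] - b[0]))) if a[0].size else 0.0,
        float(np.max(np.abs(a[1] - b[1]))) if a[1].size else 0.0,
    )


def predictive_outcomes(belief: Belief, policy: Policy, library: RoomLibrary,
                        ctx: RenderContext, tol: float = 1e-6) -> OutcomeDistribution:
    """Cluster the per-room renders of a policy into a finite outcome alphabet.

    Rooms with zero belief are not rendered.  Two renders belong to the
    same outcome when their max-abs pixel difference (over both eyes) is
    within ``tol``; each cluster's probability is the summed belief of its
    member rooms.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    belief = as_belief(belief, len(library.rooms))
    reps: List[Tuple[np.ndarray, np.ndarray]] = []
    probs: List[float] = []
    members: List[List[int]] = []
    for idx, (room, p) in enumerate(zip(library.rooms, belief)):
        if p == 0:
            continue
        images = ctx.render(room, policy)
        for c, rep in enumerate(reps):
            if _pair_distance(images, rep) <= tol:
                probs[c] += p
                members[c].append(idx)
                break
        else:
            reps.append(images)
            probs.append(float(p))
            members.append([idx])
    outcomes = tuple(
        Outcome(images=rep, probability=p, rooms=tuple(m))
        for rep, p, m in zip(reps, probs, members)
    )
    return OutcomeDistribution(outcomes=outcomes, tol=float(tol))


def entropy_bits(dist) -> float:
    """Shannon entropy -sum p log2 p, with 0 log 0 = 0."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("entropy_bits requires a probability vector")
    return float(-xlogy(p, p).sum() / _LN2) + 0.0  # avoid -0.0


def mutual_information_oracle(joint: np.ndarray) -> Tuple[float, float, float]:
    """The three equivalent mutual-information expressions, by direct summation.

    ``joint[y, x]`` is the outcome-by-cause probability table.  Returns
    (KL of joint vs product of marginals, expected KL from prior to
    posterior, predictive entropy minus expected ambiguity), all in bits.
    """
    p = np.asarray(joint, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("joint must be a probability table")
    py = p.sum(axis=1)          # outcome marginal
    px = p.sum(axis=0)          # cause marginal (the prior)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / (py[:, None] * px[None, :])
        kl_joint = float(np.sum(xlogy(p, np.where(p > 0, ratio, 1.0))) / _LN2)

        # E_{P(y)} KL[ P(x|y) || P(x) ]
        expected_kl = 0.0
        for y in range(p.shape[0]):
            if py[y] == 0:
                continue
            post = p[y] / py[y]
            expected_kl += py[y] * float(
                np.sum(xlogy(post, np.where(post > 0, post / px, 1.0))) / _LN2
            )

        # H[P(y)] - E_{P(x)} H[P(y|x)]
        pred_entropy = float(-xlogy(py, py).sum() / _LN2)
        ambiguity = 0.0
        for x in range(p.shape[1]):
            if px[x] == 0:
                continue
            cond = p[:, x] / px[x]
            ambiguity += px[x] * float(-xlogy(cond, cond).sum() / _LN2)

    return kl_joint + 0.0, expected_kl + 0.0, (pred_entropy - ambiguity) + 0.0


NoiseModel = Callable[[Tuple[np.ndarray, np.ndarray]], Dict[Hashable, float]]


def eyes_closed_channel(n_bins: int) -> NoiseModel:
    """Maximally ambiguous sensory channel: every intensity bin equiprobable.

    Models the eyes-closed (or lights-off) condition for a single retinal
    cell with ``n_bins`` discretized intensity levels; the conditional
    outcome distribution is uniform regardless of the scene, so the
    expected ambiguity is log2(n_bins) bits.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    def channel(images) -> Dict[Hashable, float]:
        return {k: 1.0 / n_bins for k in range(n_bins)}

    return channel


def _joint_table(belief: Belief, policy: Policy, library: RoomLibrary,
                 ctx: RenderContext, noise_model: Optional[NoiseModel],
                 tol: float) -> np.ndarray:
    """Joint P(outcome, room) table under a policy.

    Noiseless: outcomes are render clusters and P(y|room) is a point mass.
    With a noise model: outcomes are the union of the models' supports.
    """
    belief = as_belief(belief, len(library.rooms))
    if noise_model is None:
        dist = predictive_outcomes(belief, policy, library, ctx, tol)
        joint = np.zeros((len(dist.outcomes), len(library.rooms)))
        for y, outcome in enumerate(dist.outcomes):
            for x in outcome.rooms:
                joint[y, x] = belief[x]
        return joint
    conditionals: List[Dict[Hashable, float]] = []
    keys: List[Hashable] = []
    for room, p in zip(library.rooms, belief):
        if p == 0:
            conditionals.append({})
            continue
        table = noise_model(ctx.render(room, policy))
        conditionals.append(table)
        for k in table:
            if k not in keys:
                keys.append(k)
    joint = np.zeros((len(keys), len(library.rooms)))
    for x, (p, table) in enumerate(zip(belief, conditionals)):
        for y, k in enumerate(keys):
            joint[y, x] = p * table.get(k, 0.0)
    return joint


def expected_ambiguity(belief: Belief, policy: Policy, library: RoomLibrary,
                       ctx: RenderContext, noise_model: Optional[NoiseModel] = None,
                       tol: float = 1e-6) -> float:
    """E_{P(x|pi)} H[P(y|x,pi)] in bits.

    Exactly zero for the deterministic renderer without a noise model
    (each room yields one outcome with certainty).
    """
    belief = as_belief(belief, len(library.rooms))
    if noise_model is None:
        return 0.0
    total = 0.0
    for room, p in zip(library.rooms, belief):
        if p == 0:
            continue
        table = noise_model(ctx.render(room, policy))
        total += p * entropy_bits(list(table.values()))
    return total


def expected_information_gain(belief: Belief, policy: Policy, library: RoomLibrary,
                              ctx: RenderContext,
                              noise_model: Optional[NoiseModel] = None,
                              tol: float = 1e-6) -> float:
    """Expected information gain (bits): predictive entropy - expected ambiguity.

    Computed on the discrete joint outcome-by-room table, where the three
    mutual-information expressions coincide.
    """
    joint = _joint_table(belief, policy, library, ctx, noise_model, tol)
    _, _, gain = mutual_information_oracle(joint)
    return gain


@dataclass(frozen=True)
class PolicyScore:
    label: str
    predictive_entropy: float
    expected_ambiguity: float
    info_gain: float


@dataclass(frozen=True)
class SalienceReport:
    """Per-policy salience quantities, sorted by descending information gain."""

    scores: Tuple[PolicyScore, ...]

    @property
    def ranking(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "policy": [s.label for s in self.scores],
            "predictive_entropy_bits": [s.predictive_entropy for s in self.scores],
            "expected_ambiguity_bits": [s.expected_ambiguity for s in self.scores],
            "info_gain_bits": [s.info_gain for s in self.scores],
            "rank": np.arange(1, len(self.scores) + 1),
        })


def rank_policies(belief: Belief, policies: Sequence[Policy], library: RoomLibrary,
                  ctx: RenderContext, noise_model: Optional[NoiseModel] = None,
                  tol: float = 1e-6) -> SalienceReport:
    """Score and sort candidate policies by expected information gain.

    Ties break lexicographically by policy label, so the report is fully
    deterministic.
    """
    if not policies:
        raise ValueError("at least one policy is required")
    belief = as_belief(belief, len(library.rooms))
    scores = []
    for policy in policies:
        joint = _joint_table(belief, policy, library, ctx, noise_model, tol)
        py = joint.sum(axis=1)
        pred = entropy_bits(py) if py.size else 0.0
        amb = expected_ambiguity(belief, policy, library, ctx, noise_model, tol)
        _, _, gain = mutual_information_oracle(joint)
        scores.append(PolicyScore(policy.label, pred, amb, gain))
    scores.sort(key=lambda s: (-s.info_gain, s.label))
    return SalienceReport(scores=tuple(scores))


def update_belief(belief: Belief, observed: Tuple[np.ndarray, np.ndarray],
                  policy: Policy, library: RoomLibrary, ctx: RenderContext,
                  tol: float = 1e-6) -> np.ndarray:
    """Exact Bayes over rooms given an observed retinal image pair.

    A room's likelihood is 1 if rendering it under the policy reproduces
    the observation within ``tol`` (max-abs pixel difference), else 0.
    Raises :class:`InconsistentObservationError` when no plausible room
    matches, rather than returning an all-zero posterior.
    """
    belief = as_belief(belief, len(library.rooms))
    likelihood = np.zeros(len(library.rooms))
    for idx, (room, p) in enumerate(zip(library.rooms, belief)):
        if p == 0:
            continue
        images = ctx.render(room, policy)
        likelihood[idx] = 1.0 if _pair_distance(images, observed) <= tol else 0.0
    posterior = belief * likelihood
    total = posterior.sum()
    if total == 0:
        raise InconsistentObservationError(
            f"observation under policy {policy.label!r} matches no plausible room"
        )
    return posterior / total


def demo_policy(corner: str, eye_height: float = 1.2) -> Policy:
    """A fixation policy aiming the head at one corner of the demo room."""
    heading = DEMO_VIEW_HEADINGS[corner]
    return Policy(
        label=corner,
        pose=HeadPose(place=(0.0, 0.0, eye_height), head_dir=(heading, 0.0)),
        eyes=EyeDirection(),
    )


def demo_context(n_rows: int = 32, n_cols: int = 32,
                 angular_extent: float = math.radians(40.0)) -> RenderContext:
    """Rendering conditions for the demonstration world."""
    return RenderContext(
        array=build_retinal_array(n_rows, n_cols, angular_extent),
        light=LightSource(),
    )
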