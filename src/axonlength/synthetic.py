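"""Seed-reproducible synthetic axons with exactly known path length.

Two families of geometry are generated:

* **Isotropic polylines** — connected chains whose segment directions are
  independent draws from the uniform distribution on the unit sphere.  For such
  zero-anisotropy curves the ratio of 3D length to planar-projection length is
  analytically 4/π, which makes them the reference object for validating the
  projection-correction method.

* **Branching arbors** in four qualitative architectures commonly used to
  classify long-range projection neurons: class 1 *focal* (a long trunk ending
  in a single dense terminal cluster), class 2 *multi-focal* (a trunk with
  several separate clusters), class 3 *disperse* (a sparse arbor spread over a
  large region) and class 4 *local* (an arbor in the immediate vicinity of the
  soma).  These are schematic stand-ins for curated reconstructions: total
  length is controlled exactly, per-class geometry only qualitatively.

Directional persistence is parameterized by a von Mises–Fisher concentration
``kappa`` about the growing branch's current heading; ``kappa = 0`` recovers
isotropic growth.  All randomness flows through ``numpy.random.default_rng``
(PCG64), so identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .morphology import AXON, ROOT_PARENT, SOMA, MorphPoint, NeuronMorphology, SegmentSet

__all__ = [
    "SynthParams",
    "isotropic_polyline",
    "synth_axon",
    "fiber_slab",
    "direction_second_moment",
]


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on S² via normalized Gaussian triples."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero triple has probability 0; guard anyway
    bad = norms[:, 0] == 0.0
    while bad.any():
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norms[:, 0] == 0.0
    return v / norms


def _vmf_direction(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    """One draw from the von Mises–Fisher distribution with mean ``mu``.

    Uses the inverse-CDF form for the cosine of the polar angle,
    w = 1 + log(u + (1-u) e^{-2κ}) / κ, plus a uniform azimuth.
    """
    if kappa <= 0.0:
        return _uniform_sphere(rng, 1)[0]
    u = rng.random()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    # orthonormal basis around mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def isotropic_polyline(n_segments: int, segment_length: float, seed: int | None = None) -> SegmentSet:
    """Connected polyline with iid uniform-sphere segment directions.

    ``total_length`` is exactly ``n_segments * segment_length``; identical
    seeds give identical geometry.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    rng = np.random.default_rng(seed)
    dirs = _uniform_sphere(rng, n_segments)
    pts = np.vstack([np.zeros(3), np.cumsum(dirs * segment_length, axis=0)])
    return SegmentSet(pts[:-1], pts[1:])


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the schematic arbor generator (lengths in µm).

    Defaults are placeholders chosen at thalamocortical scale — no published
    per-class morphometry constrains them (see the methods note).
    """

    class_label: int = 1
    target_length: float = 30_000.0
    segment_length: float = 10.0
    n_clusters: int = 3
    trunk_length: float = 4_000.0
    cluster_radius: float = 250.0
    dispersion_radius: float = 1_500.0
    direction_concentration: float = 0.0  # vMF kappa; 0 = isotropic growth
    branch_prob: float = 0.06
    seed: int | None = None

    def validate(self) -> None:
        if self.class_label not in (1, 2, 3, 4):
            raise ValueError("class_label must be 1-4")
        if self.target_length <= 0 or self.segment_length <= 0:
            raise ValueError("target_length and segment_length must be positive")
        if self.direction_concentration < 0:
            raise ValueError("direction_concentration (kappa) must be >= 0")
        if self.class_label in (1, 2, 3) and self.trunk_length >= self.target_length:
            raise ValueError("trunk_length must be smaller than target_length")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if min(self.cluster_radius, self.dispersion_radius) <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.branch_prob < 1.0:
            raise ValueError("branch_prob must be in [0, 1)")


class _TreeBuilder:
    """Accumulates SWC points while growing segments of fixed length."""

    def __init__(self, rng: np.random.Generator, segment_length: float) -> None:
        self.rng = rng
        self.seg_len = segment_length
        soma = MorphPoint(1, SOMA, 0.0, 0.0, 0.0, 5.0, ROOT_PARENT)
        self.points: list[MorphPoint] = [soma]
        self.pos: dict[int, np.ndarray] = {1: np.zeros(3)}

    def add(self, parent_id: int, new_pos: np.ndarray) -> int:
        nid = len(self.points) + 1
        x, y, z = (float(v) for v in new_pos)
        self.points.append(MorphPoint(nid, AXON, x, y, z, 0.5, parent_id))
        self.pos[nid] = np.asarray(new_pos, dtype=float)
        return nid

    def grow_trunk(self, start_id: int, direction: np.ndarray, length: float) -> int:
        """Nearly straight run of ``length`` from ``start_id`` along ``direction``."""
        n_full, rem = divmod(length, self.seg_len)
        node = start_id
        heading = direction / np.linalg.norm(direction)
        for _ in range(int(n_full)):
            d = _vmf_direction(self.rng, heading, 200.0)  # slight jitter only
            node = self.add(node, self.pos[node] + d * self.seg_len)
        if rem > 1e-12:
            node = self.add(node, self.pos[node] + heading * rem)
        return node

    def grow_cluster(
        self,
        start_id: int,
        center: np.ndarray,
        radius: float,
        budget: float,
        kappa: float,
        branch_prob: float,
    ) -> None:
        """Branching random walk confined to a ball, consuming exactly ``budget``.

        Tips extend by vMF steps about their heading; directions leaving the
        ball are resampled (then pulled toward the center as a last resort).
        The final step is trimmed so the consumed length is exact.
        """
        rng = self.rng
        heading = _uniform_sphere(rng, 1)[0]
        tips: list[tuple[int, np.ndarray]] = [(start_id, heading)]
        remaining = budget
        while remaining > 1e-9:
            step = min(self.seg_len, remaining)
            i = rng.integers(len(tips))
            node, heading = tips[i]
            p = self.pos[node]
            d = None
            for _ in range(30):
                cand = _vmf_direction(rng, heading, kappa)
                if np.linalg.norm(p + cand * step - center) <= radius:
                    d = cand
                    break
            if d is None:
                d = center - p
                d = d / np.linalg.norm(d)
            new = self.add(node, p + d * step)
            tips[i] = (new, d)
            remaining -= step
            if remaining > self.seg_len and rng.random() < branch_prob:
                tips.append((new, _uniform_sphere(rng, 1)[0]))

    def build(self, name: str, class_label: int) -> NeuronMorphology:
        return NeuronMorphology(self.points, name=name, class_label=class_label)


def synth_axon(p: SynthParams) -> NeuronMorphology:
    """Generate a schematic axonal arbor of one of the four classes.

    The axonal path length equals ``target_length`` up to the trim tolerance
    (well within 1%; the last step of each growth phase is shortened to close
    the length budget exactly).
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    tb = _TreeBuilder(rng, p.segment_length)
    kappa = p.direction_concentration
    trunk_dir = _uniform_sphere(rng, 1)[0]

    if p.class_label == 1:
        end = tb.grow_trunk(1, trunk_dir, p.trunk_length)
        tb.grow_cluster(end, tb.pos[end], p.cluster_radius,
                        p.target_length - p.trunk_length, kappa, p.branch_prob)
    elif p.class_label == 2:
        # attach one cluster at the end of each trunk stage, spaced well apart
        stage = p.trunk_length / p.n_clusters
        budget = (p.target_length - p.trunk_length) / p.n_clusters
        node = 1
        for _ in range(p.n_clusters):
            node = tb.grow_trunk(node, trunk_dir, stage)
            tb.grow_cluster(node, tb.pos[node], p.cluster_radius,
                            budget, kappa, p.branch_prob)
    elif p.class_label == 3:
        end = tb.grow_trunk(1, trunk_dir, p.trunk_length)
        tb.grow_cluster(end, tb.pos[end], p.dispersion_radius,
                        p.target_length - p.trunk_length, kappa,
                        p.branch_prob / 2.0)
    else:  # class 4: local arbor around the soma, no trunk
        tb.grow_cluster(1, np.zeros(3), p.cluster_radius,
                        p.target_length, kappa, p.branch_prob)

    return tb.build(
        name=f"synth_c{p.class_label}_s{p.seed}", class_label=p.class_label
    )


def fiber_slab(
    total_length: float,
    slab_thickness: float,
    kappa: float = 0.0,
    seed: int | None = None,
    segment_length: float = 10.0,
) -> SegmentSet:
    """Unbranched fiber confined to the slab ``0 <= z <= slab_thickness``.

    Growth directions are vMF about the current heading (isotropic for
    ``kappa=0``); steps crossing a slab face are split at the face and the
    z-direction reflected, so every stored segment lies inside the slab and the
    total length is exactly ``total_length`` (last step trimmed).

    Note the reflections mildly perturb the direction distribution near the
    faces, so the 4/π projection identity holds only approximately for thin
    slabs; use :func:`isotropic_polyline` for the analytic check.
    """
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be positive")
    if total_length <= 0 or segment_length <= 0:
        raise ValueError("lengths must be positive")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    pos = np.array([0.0, 0.0, slab_thickness / 2.0])
    heading = _uniform_sphere(rng, 1)[0]
    p0s, p1s = [], []
    remaining = total_length
    while remaining > 1e-9:
        step = min(segment_length, remaining)
        d = _vmf_direction(rng, heading, kappa)
        heading = d
        left = step
        while left > 1e-12:
            if d[2] > 0:
                t_face = (slab_thickness - pos[2]) / d[2]
            elif d[2] < 0:
                t_face = -pos[2] / d[2]
            else:
                t_face = np.inf
            adv = min(left, t_face)
            new = pos + d * adv
            new[2] = min(max(new[2], 0.0), slab_thickness)  # clamp face rounding
            if adv > 1e-12:
                p0s.append(pos.copy())
                p1s.append(new.copy())
            pos = new
            left -= adv
            if adv == t_face and left > 1e-12:
                d = d.copy()
                d[2] = -d[2]
                heading = d
        remaining -= step
    return SegmentSet(np.array(p0s), np.array(p1s))


def direction_second_moment(s: SegmentSet) -> np.ndarray:
    """Length-weighted second-moment matrix of segment directions.

    ``M = Σ w_i d_i d_iᵀ`` with unit directions ``d_i`` and weights
    ``w_i = length_i / total``.  Trace is 1; for an isotropic set the spectrum
    approaches (1/3, 1/3, 1/3), while a dominant direction (e.g. a long
    unbranched trunk) inflates the leading eigenvalue — a scalar summary of
    anisotropy, the property that breaks the 4/π projection factor.
    """
    if len(s) == 0:
        raise ValueError("no geometry: SegmentSet is empty")
    v = s.p1 - s.p0
    lens = s.lengths
    keep = lens > 0
    d = v[keep] / lens[keep, None]
    w = lens[keep] / lens[keep].sum()
    return (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
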