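"""Ground-truth scene generation for simulated differentiation cultures.

A *scene* is the complete truth about one simulated microscope field: a set of
elongated multinucleated myotubes (always positive for the differentiation
marker eMHC), each holding >= 2 nuclei strictly inside its outline, plus a
population of mononucleated cells that may or may not express eMHC.  Every
downstream stage (rendering, segmentation, ROI assignment, fusion metrics) can
be scored against this truth exactly.

Myotubes are modelled as capsules (line segments dilated by half the tube
width) whose area scales with the number of nuclei they must hold; placement
and within-tube nucleus positions use seeded rejection sampling with a minimum
pairwise nucleus separation, so that a noiseless render yields disjoint,
individually countable nuclei.
"""

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CrowdedFieldError, ParameterError
from .geometry import (
    capsule_polygon,
    points_in_polygon,
    points_segment_distance,
    segment_segment_distance,
)

__all__ = [
    "NucleiPerMyotubeSampler",
    "FixedListSampler",
    "GeometricShiftedSampler",
    "NegativeBinomialShiftedSampler",
    "sampler_from_spec",
    "SceneParams",
    "Myotube",
    "MonoCell",
    "Scene",
    "generate_scene",
]


# ---------------------------------------------------------------------------
# Nuclei-per-myotube samplers: every myotube has at least 2 nuclei.
# ---------------------------------------------------------------------------

class NucleiPerMyotubeSampler:
    """Distribution over integers >= 2 (nuclei counts of fusing myotubes)."""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def to_spec(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class FixedListSampler(NucleiPerMyotubeSampler):
    """Deterministic counts; cycled if more myotubes than list entries."""

    values: tuple

    def __post_init__(self):
        vals = tuple(int(v) for v in self.values)
        if len(vals) == 0 or any(v < 2 for v in vals):
            raise ParameterError("fixed nuclei counts must be a non-empty list of integers >= 2")
        object.__setattr__(self, "values", vals)

    def sample(self, rng, size):
        return np.resize(np.asarray(self.values, dtype=int), size)

    def to_spec(self):
        return {"kind": "fixed", "values": list(self.values)}


@dataclass(frozen=True)
class GeometricShiftedSampler(NucleiPerMyotubeSampler):
    """2 + (Geometric(p) - 1): support {2, 3, ...}, mean 1 + 1/p."""

    p: float

    def __post_init__(self):
        if not 0.0 < self.p <= 1.0:
            raise ParameterError("geometric p must be in (0, 1]")

    @classmethod
    def from_mean(cls, mean: float) -> "GeometricShiftedSampler":
        if mean <= 2.0:
            raise ParameterError("mean nuclei per myotube must exceed 2")
        return cls(p=1.0 / (mean - 1.0))

    def sample(self, rng, size):
        return 1 + rng.geometric(self.p, size=size)

    def to_spec(self):
        return {"kind": "geometric_shifted", "p": self.p}


@dataclass(frozen=True)
class NegativeBinomialShiftedSampler(NucleiPerMyotubeSampler):
    """2 + NegativeBinomial(n, p): overdispersed alternative to the geometric."""

    n: float
    p: float

    def __post_init__(self):
        if self.n <= 0 or not 0.0 < self.p <= 1.0:
            raise ParameterError("negative binomial needs n > 0 and p in (0, 1]")

    def sample(self, rng, size):
        return 2 + rng.negative_binomial(self.n, self.p, size=size)

    def to_spec(self):
        return {"kind": "negative_binomial_shifted", "n": self.n, "p": self.p}


def sampler_from_spec(spec) -> NucleiPerMyotubeSampler:
    """Build a sampler from a config mapping (YAML/JSON friendly)."""
    if isinstance(spec, NucleiPerMyotubeSampler):
        return spec
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ParameterError(f"sampler spec must be a mapping with a 'kind' key, got {spec!r}")
    kind = spec["kind"]
    if kind == "fixed":
        return FixedListSampler(tuple(spec["values"]))
    if kind == "geometric_shifted":
        if "mean" in spec:
            return GeometricShiftedSampler.from_mean(float(spec["mean"]))
        return GeometricShiftedSampler(float(spec["p"]))
    if kind == "negative_binomial_shifted":
        return NegativeBinomialShiftedSampler(float(spec["n"]), float(spec["p"]))
    raise ParameterError(f"unknown sampler kind {kind!r}")


# ---------------------------------------------------------------------------
# Parameters and scene containers
# ---------------------------------------------------------------------------

DEFAULT_NUCLEUS_RADIUS_PX = 4.0


def _default_sampler() -> NucleiPerMyotubeSampler:
    # mean 8 nuclei per myotube with a geometric tail reaching the >= 15 and,
    # rarely, the >= 50 size classes seen in differentiated cultures
    return GeometricShiftedSampler.from_mean(8.0)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one simulated field.

    Defaults emulate a day-4 differentiated C2C12-like culture imaged at high
    magnification: a 512 px square field at 0.2 um/px (~102 um across), a
    handful of myotubes with a geometric nuclei-count distribution (mean ~8),
    and a background of mononucleated cells of which a minority express the
    differentiation marker.
    """

    field_width_px: int = 512
    field_height_px: int = 512
    pixel_size_um: float = 0.2
    n_myotubes: int = 6
    nuclei_per_myotube_sampler: NucleiPerMyotubeSampler = field(default_factory=_default_sampler)
    n_mononucleated: int = 40
    fraction_mono_emhc_positive: float = 0.2
    nucleus_radius_px: float = DEFAULT_NUCLEUS_RADIUS_PX
    # 2 * radius makes noiseless disks disjoint; the extra 3 px keeps them from
    # touching diagonally (which would merge 8-connected particles) and keeps
    # mildly blurred disks separable.
    min_nucleus_separation_px: float = 2 * DEFAULT_NUCLEUS_RADIUS_PX + 3
    seed: int = 0

    def __post_init__(self):
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ParameterError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        if self.n_myotubes < 0 or self.n_mononucleated < 0:
            raise ParameterError("object counts must be non-negative")
        if not 0.0 <= self.fraction_mono_emhc_positive <= 1.0:
            raise ParameterError("fraction_mono_emhc_positive must be in [0, 1]")
        if self.nucleus_radius_px <= 0:
            raise ParameterError("nucleus_radius_px must be positive")
        if self.min_nucleus_separation_px < 0:
            raise ParameterError("min_nucleus_separation_px must be >= 0")


@dataclass(frozen=True)
class Myotube:
    polygon: np.ndarray          # (M, 2) vertices, CCW, simple
    nuclei: np.ndarray           # (K, 2) centers, strictly inside polygon
    emhc_positive: bool = True   # myotubes are differentiated by definition


@dataclass(frozen=True)
class MonoCell:
    center: tuple
    emhc_positive: bool


@dataclass(frozen=True)
class Scene:
    """Ground truth for one field; the unit every stage is scored against."""

    myotubes: tuple
    mono_cells: tuple
    field_width_px: int
    field_height_px: int
    pixel_size_um: float
    nucleus_radius_px: float
    mono_cyto_radius_px: float

    @property
    def total_nuclei(self) -> int:
        return sum(len(m.nuclei) for m in self.myotubes) + len(self.mono_cells)

    @property
    def nucleus_centers(self) -> np.ndarray:
        """All ground-truth nucleus centers, myotube nuclei first."""
        parts = [m.nuclei for m in self.myotubes if len(m.nuclei)]
        parts.append(np.array([c.center for c in self.mono_cells], dtype=float).reshape(-1, 2))
        return np.vstack(parts) if parts else np.empty((0, 2))

    @property
    def true_differentiation_index(self) -> float:
        """Fraction of all nuclei residing in eMHC-positive cells."""
        total = self.total_nuclei
        if total == 0:
            return 0.0
        in_pos = sum(len(m.nuclei) for m in self.myotubes)
        in_pos += sum(1 for c in self.mono_cells if c.emhc_positive)
        return in_pos / total

    @property
    def nuclei_per_myotube(self) -> list:
        return [len(m.nuclei) for m in self.myotubes]

    def to_dict(self) -> dict:
        return {
            "field": {
                "width_px": self.field_width_px,
                "height_px": self.field_height_px,
                "pixel_size_um": self.pixel_size_um,
                "nucleus_radius_px": self.nucleus_radius_px,
                "mono_cyto_radius_px": self.mono_cyto_radius_px,
            },
            "myotubes": [
                {
                    "polygon": np.asarray(m.polygon, dtype=float).tolist(),
                    "nuclei": np.asarray(m.nuclei, dtype=float).tolist(),
                    "emhc_positive": bool(m.emhc_positive),
                }
                for m in self.myotubes
            ],
            "mono_cells": [
                {"center": [float(c.center[0]), float(c.center[1])],
                 "emhc_positive": bool(c.emhc_positive)}
                for c in self.mono_cells
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        f = d["field"]
        myotubes = tuple(
            Myotube(
                polygon=np.asarray(m["polygon"], dtype=float),
                nuclei=np.asarray(m["nuclei"], dtype=float).reshape(-1, 2),
                emhc_positive=bool(m.get("emhc_positive", True)),
            )
            for m in d["myotubes"]
        )
        monos = tuple(
            MonoCell(center=(float(c["center"][0]), float(c["center"][1])),
                     emhc_positive=bool(c["emhc_positive"]))
            for c in d["mono_cells"]
        )
        return cls(
            myotubes=myotubes,
            mono_cells=monos,
            field_width_px=int(f["width_px"]),
            field_height_px=int(f["height_px"]),
            pixel_size_um=float(f["pixel_size_um"]),
            nucleus_radius_px=float(f["nucleus_radius_px"]),
            mono_cyto_radius_px=float(f["mono_cyto_radius_px"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "Scene":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_PLACE_ATTEMPTS = 400          # capsule placements tried per myotube
_NUCLEUS_ATTEMPT_FACTOR = 400  # per-nucleus rejection-sampling attempts
_AREA_PER_NUCLEUS_FACTOR = 2.4  # usable capsule area per nucleus, in sep^2 units


@dataclass(frozen=True)
class _Capsule:
    e1: np.ndarray
    e2: np.ndarray
    width: float


def _sample_capsule_layout(rng, params: SceneParams, count: int, existing: Sequence[_Capsule]):
    """Choose a capsule large enough for `count` nuclei and place it without
    overlapping previously placed capsules."""
    w, h = params.field_width_px, params.field_height_px
    sep = max(params.min_nucleus_separation_px, 2.0)
    r = params.nucleus_radius_px
    usable_area = count * _AREA_PER_NUCLEUS_FACTOR * sep * sep
    l_max = 0.72 * min(w, h)
    m_needed = usable_area / (2.0 * l_max)
    for _ in range(_PLACE_ATTEMPTS):
        m = max(m_needed, 0.35 * sep) * rng.uniform(1.0, 1.5)
        length = usable_area / (2.0 * m)
        width = 2.0 * (m + r + 1.0)
        margin = width / 2.0 + 2.0
        if 2 * margin >= min(w, h):
            continue
        angle = rng.uniform(0.0, np.pi)
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        u = np.array([np.cos(angle), np.sin(angle)])
        e1 = np.array([cx, cy]) - 0.5 * length * u
        e2 = np.array([cx, cy]) + 0.5 * length * u
        if not (margin <= min(e1[0], e2[0]) and max(e1[0], e2[0]) <= w - margin
                and margin <= min(e1[1], e2[1]) and max(e1[1], e2[1]) <= h - margin):
            continue
        cand = _Capsule(e1=e1, e2=e2, width=width)
        if all(
            segment_segment_distance(cand.e1, cand.e2, c.e1, c.e2)
            > (cand.width + c.width) / 2.0 + 2.0
            for c in existing
        ):
            poly = capsule_polygon((cx, cy), angle, length, width)
            return cand, poly
    raise CrowdedFieldError(
        f"could not place a myotube for {count} nuclei after {_PLACE_ATTEMPTS} attempts; "
        "relax n_myotubes, the nuclei-per-myotube distribution, "
        "min_nucleus_separation_px, or enlarge the field"
    )


def _sample_nuclei_in_capsule(rng, cap: _Capsule, params: SceneParams, count: int) -> np.ndarray:
    """Rejection-sample `count` centers inside the capsule's inner region
    (margin = radius + 1 from the boundary) with minimum pairwise separation."""
    r = params.nucleus_radius_px
    sep = params.min_nucleus_separation_px
    m = cap.width / 2.0 - r - 1.0
    u = cap.e2 - cap.e1
    length = float(np.hypot(*u))
    u = u / length if length > 0 else np.array([1.0, 0.0])
    n_vec = np.array([-u[1], u[0]])
    placed: list = []
    attempts = 0
    max_attempts = _NUCLEUS_ATTEMPT_FACTOR * count
    while len(placed) < count:
        attempts += 1
        if attempts > max_attempts:
            raise CrowdedFieldError(
                f"could not place {count} nuclei in one myotube after {max_attempts} attempts; "
                "reduce min_nucleus_separation_px or the requested nuclei count"
            )
        t = rng.uniform(-0.5 * length - m, 0.5 * length + m)
        s = rng.uniform(-m, m)
        p = cap.e1 + (t + 0.5 * length) * u + s * n_vec
        if points_segment_distance(p[None, :], cap.e1, cap.e2)[0] > m:
            continue
        if placed and np.min(np.hypot(*((np.array(placed) - p).T))) < sep:
            continue
        placed.append(p)
    return np.array(placed)


def generate_scene(params: SceneParams) -> Scene:
    """Generate a ground-truth scene by seeded rejection sampling.

    Myotubes are placed largest-first (big capsules are hardest to fit), mono
    cells are kept clear of every myotube outline so that the planted
    differentiation index is exactly recoverable from the rendered channels.

    Raises
    ------
    CrowdedFieldError
        when the field cannot hold the requested objects at the requested
        separation; the message names the parameters to relax.
    """
    rng = np.random.default_rng(params.seed)
    sampler = sampler_from_spec(params.nuclei_per_myotube_sampler) \
        if not isinstance(params.nuclei_per_myotube_sampler, NucleiPerMyotubeSampler) \
        else params.nuclei_per_myotube_sampler

    counts = np.asarray(sampler.sample(rng, params.n_myotubes), dtype=int)
    if counts.size and counts.min() < 2:
        raise ParameterError("nuclei_per_myotube_sampler produced a count < 2")

    order = np.argsort(-counts)  # place the largest myotubes first
    capsules: list = []
    polys: list = []
    nuclei_sets: list = []
    for idx in order:
        cap, poly = _sample_capsule_layout(rng, params, int(counts[idx]), capsules)
        nuclei = _sample_nuclei_in_capsule(rng, cap, params, int(counts[idx]))
        inside = points_in_polygon(nuclei, poly)
        if not inside.all():  # pragma: no cover - guarded by the placement margin
            raise CrowdedFieldError("internal: sampled nucleus fell outside its polygon")
        capsules.append(cap)
        polys.append(poly)
        nuclei_sets.append(nuclei)

    myotubes = tuple(Myotube(polygon=p, nuclei=n) for p, n in zip(polys, nuclei_sets))

    # mononucleated cells: outside every myotube, separated from all nuclei
    cyto_r = 2.0 * params.nucleus_radius_px
    sep = params.min_nucleus_separation_px
    margin = cyto_r + 1.0
    all_nuclei = [pt for n in nuclei_sets for pt in n]
    centers: list = []
    attempts = 0
    max_attempts = _NUCLEUS_ATTEMPT_FACTOR * max(params.n_mononucleated, 1)
    while len(centers) < params.n_mononucleated:
        attempts += 1
        if attempts > max_attempts:
            raise CrowdedFieldError(
                f"could not place {params.n_mononucleated} mononucleated cells after "
                f"{max_attempts} attempts; reduce n_mononucleated or enlarge the field"
            )
        p = np.array([
            rng.uniform(margin, params.field_width_px - margin),
            rng.uniform(margin, params.field_height_px - margin),
        ])
        if any(
            points_segment_distance(p[None, :], c.e1, c.e2)[0] < c.width / 2.0 + cyto_r + 2.0
            for c in capsules
        ):
            continue
        pool = all_nuclei + centers
        if pool and np.min(np.hypot(*((np.array(pool) - p).T))) < sep:
            continue
        centers.append(p)

    n_pos = int(round(params.fraction_mono_emhc_positive * params.n_mononucleated))
    flags = np.zeros(params.n_mononucleated, dtype=bool)
    flags[rng.permutation(params.n_mononucleated)[:n_pos]] = True
    monos = tuple(
        MonoCell(center=(float(c[0]), float(c[1])), emhc_positive=bool(f))
        for c, f in zip(centers, flags)
    )

    return Scene(
        myotubes=myotubes,
        mono_cells=monos,
        field_width_px=params.field_width_px,
        field_height_px=params.field_height_px,
        pixel_size_um=params.pixel_size_um,
        nucleus_radius_px=params.nucleus_radius_px,
        mono_cyto_radius_px=cyto_r,
    )
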