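"""Freshness grading of segmented heads by yellow-bud proportion.

The pipeline per head: (1) map masked RGB pixels to a blue-deficit
discriminant channel ``g = (R + G - 2B + 510) / 4`` (yellow buds score high,
green buds mid-range, in [0, 255]); (2) choose a binarization threshold by
Otsu's between-class-variance criterion, either by exhaustive traversal of
all 256 integer thresholds or by particle swarm optimization over the same
fitness; (3) the fraction of masked pixels above the threshold is the
yellow-area fraction; (4) an ordinal freshness level is assigned under one
of two standards:

* ``original`` — the 0/1/3/5/7/9 sensory scale (no yellow / trace <1% /
  ~5% / ~50% / 50-75% / fully yellow), with bud-count conditions
  approximated by area-fraction cut points;
* ``merged`` — the 5-level commercial scale: 0 (none), 1 (<1%), 2 (<5%),
  3 (5-10%), 4 (>10%).

The population yellowness degree is Y = sum(M1*N1) / (M2*N2), where M1 is a
head's level, N1 the head count at that level, M2 the standard's highest
level and N2 the total number of heads; Y is in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradingStandard", "HeadGrade", "PopulationGrade", "PSOConfig",
           "ORIGINAL_STANDARD", "MERGED_STANDARD", "get_standard",
           "yellow_discriminant", "between_class_variance", "otsu_threshold",
           "pso_threshold", "yellow_fraction", "assign_level",
           "population_yellowness", "grade_pipeline", "grading_accuracy",
           "HeadGrader"]

# Heads whose discriminant standard deviation falls below this floor are
# treated as uniformly green (level 0): Otsu on a near-constant channel
# would otherwise split measurement noise into a spurious "yellow" class.
VARIANCE_FLOOR_SD = 2.0


@dataclass(frozen=True)
class GradingStandard:
    """Ordered freshness levels with yellow-area-fraction conditions."""

    name: str
    levels: tuple[int, ...]

    @property
    def m2(self) -> int:
        """Highest level value (the M2 of the yellowness degree)."""
        return self.levels[-1]


ORIGINAL_STANDARD = GradingStandard("original", (0, 1, 3, 5, 7, 9))
MERGED_STANDARD = GradingStandard("merged", (0, 1, 2, 3, 4))

# Area-fraction cut points for the original sensory scale.  Levels 0 and 1
# are defined by bud counts in the sensory protocol; with no bud-instance
# detection they are approximated by 0 and (0, 1%).  The 3/5 and 5/7 cuts
# are midpoints between the named anchor fractions (5%, 50%, 75%).
_ORIGINAL_CUTS = (0.01, 0.275, 0.625)
_FULL_YELLOW = 1.0 - 1e-9


class PSOConfig:
    """Particle-swarm settings for threshold search on [0, 255]."""

    def __init__(self, n_particles: int = 20, inertia: float = 0.7,
                 cognitive: float = 1.5, social: float = 1.5,
                 iterations: int = 50, bounds: tuple[float, float] = (0.0, 255.0),
                 seed: int = 0):
        if n_particles < 1 or iterations < 1:
            raise ValueError("n_particles and iterations must be >= 1")
        if inertia <= 0 or cognitive <= 0 or social <= 0:
            raise ValueError("inertia/cognitive/social must be positive")
        if not bounds[0] < bounds[1]:
            raise ValueError("bounds must be ordered")
        self.n_particles = n_particles
        self.inertia = inertia
        self.cognitive = cognitive
        self.social = social
        self.iterations = iterations
        self.bounds = bounds
        self.seed = seed


@dataclass
class HeadGrade:
    yellow_fraction: float
    level: int
    threshold_used: int | None
    standard: str
    note: str = ""


@dataclass
class PopulationGrade:
    level_counts: dict[int, int]
    total: int
    yellowness_degree: float
    standard: str


def get_standard(name) -> GradingStandard:
    if isinstance(name, GradingStandard):
        return name
    try:
        return {"original": ORIGINAL_STANDARD, "merged": MERGED_STANDARD}[name]
    except KeyError:
        raise ValueError(f"unknown grading standard {name!r}") from None


def yellow_discriminant(image: np.ndarray, head_mask: np.ndarray) -> np.ndarray:
    """Blue-deficit gray values of the masked pixels.

    g = clip((R + G - 2B + 510) / 4, 0, 255), rounded to integers.  Yellow
    (high R+G, low B) maps near 255, neutral grays to 128, blue to 0.
    Returns a 1-D array over the mask's nonzero pixels (row-major order).
    """
    image = np.asarray(image)
    mask = np.asarray(head_mask).astype(bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty head mask")
    rgb = image[mask].astype(float)
    g = (rgb[:, 0] + rgb[:, 1] - 2.0 * rgb[:, 2] + 510.0) / 4.0
    return np.clip(np.rint(g), 0, 255).astype(np.int64)


def _histogram(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.size < 2 or values.min() < 0 or values.max() > 255:
        raise ValueError("need >= 2 values in [0, 255]")
    v = np.rint(values).astype(np.int64)
    if np.unique(v).size < 2:
        raise ValueError("constant input: threshold undefined")
    return np.bincount(v, minlength=256).astype(float)


def _variance_curve(hist: np.ndarray) -> np.ndarray:
    """Between-class variance w0*w1*(mu0 - mu1)^2 for every t in 0..255,
    where class 0 is {values <= t} and class 1 is {values > t}."""
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    c_n = np.cumsum(hist)
    c_s = np.cumsum(hist * levels)
    n0, s0 = c_n, c_s
    n1, s1 = total - c_n, c_s[-1] - c_s
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(n0 > 0, s0 / n0, 0.0)
        mu1 = np.where(n1 > 0, s1 / n1, 0.0)
    var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    var[(n0 == 0) | (n1 == 0)] = 0.0
    return var


def between_class_variance(values: np.ndarray, threshold: float) -> float:
    """Otsu fitness of the split {<= t, > t} at integer t = round(threshold)."""
    hist = _histogram(values)
    t = int(np.clip(np.rint(threshold), 0, 255))
    return float(_variance_curve(hist)[t])


def otsu_threshold(values: np.ndarray) -> int:
    """Exhaustive traversal of all integer thresholds 0..255; returns the
    smallest t maximizing the between-class variance."""
    var = _variance_curve(_histogram(values))
    return int(np.argmax(var))  # argmax returns the first (smallest) maximizer


def pso_threshold(values: np.ndarray, config: PSOConfig | None = None) -> int:
    """Particle-swarm search for the Otsu-optimal threshold.

    Standard velocity update v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    with positions clipped to the bounds; the fitness of a particle is the
    between-class variance at round(x).  Deterministic per config.seed.
    """
    if config is None:
        config = PSOConfig()
    hist = _histogram(values)
    curve = _variance_curve(hist)

    def fitness(x: np.ndarray) -> np.ndarray:
        t = np.clip(np.rint(x), 0, 255).astype(int)
        return curve[t]

    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    x = rng.uniform(lo, hi, size=config.n_particles)
    v = np.zeros_like(x)
    pbest = x.copy()
    pbest_fit = fitness(x)
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g], pbest_fit[g]
    for _ in range(config.iterations):
        r1 = rng.random(config.n_particles)
        r2 = rng.random(config.n_particles)
        v = (config.inertia * v + config.cognitive * r1 * (pbest - x)
             + config.social * r2 * (gbest - x))
        x = np.clip(x + v, lo, hi)
        fit = fitness(x)
        improved = fit > pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g], pbest_fit[g]
    return int(np.clip(np.rint(gbest), 0, 255))


def yellow_fraction(gray_values: np.ndarray, threshold: float) -> float:
    """Fraction of masked pixels strictly above the threshold."""
    values = np.asarray(gray_values)
    if values.size == 0:
        raise ValueError("no gray values")
    return float(np.count_nonzero(values > threshold)) / values.size


def assign_level(fraction: float, standard="merged") -> int:
    """Map a yellow-area fraction to an ordinal freshness level."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    std = get_standard(standard)
    if std.name == "merged":
        if fraction == 0.0:
            return 0
        if fraction < 0.01:
            return 1
        if fraction < 0.05:
            return 2
        if fraction <= 0.10:   # level 4 is printed ">10%", so 10% is level 3
            return 3
        return 4
    # original sensory scale
    if fraction == 0.0:
        return 0
    if fraction < _ORIGINAL_CUTS[0]:
        return 1
    if fraction < _ORIGINAL_CUTS[1]:
        return 3
    if fraction < _ORIGINAL_CUTS[2]:
        return 5
    if fraction < _FULL_YELLOW:
        return 7
    return 9


def population_yellowness(levels, standard) -> PopulationGrade:
    """Yellowness degree Y = sum(M1*N1) / (M2*N2) over a graded population."""
    levels = list(levels)
    if not levels:
        raise ValueError("no graded heads")
    std = get_standard(standard)
    allowed = set(std.levels)
    bad = [lv for lv in levels if lv not in allowed]
    if bad:
        raise ValueError(
            f"levels {sorted(set(bad))} are not part of the {std.name} "
            "standard; populations graded under mixed standards cannot be "
            "combined")
    counts = {lv: levels.count(lv) for lv in std.levels}
    n2 = len(levels)
    y = sum(lv * n for lv, n in counts.items()) / (std.m2 * n2)
    return PopulationGrade(level_counts=counts, total=n2,
                           yellowness_degree=float(y), standard=std.name)


def grade_pipeline(image: np.ndarray, head_mask: np.ndarray,
                   standard="merged",
                   pso_config: PSOConfig | None = None) -> HeadGrade:
    """Full per-head grading: discriminant -> PSO-Otsu threshold -> yellow
    fraction -> level, with provenance.

    A head whose discriminant channel is near-constant (standard deviation
    below the variance floor) is uniformly green: level 0, no threshold.
    """
    std = get_standard(standard)
    gray = yellow_discriminant(image, head_mask)
    if float(gray.std()) < VARIANCE_FLOOR_SD:
        return HeadGrade(yellow_fraction=0.0, level=0, threshold_used=None,
                         standard=std.name,
                         note="near-constant discriminant; graded level 0")
    t = pso_threshold(gray, pso_config)
    frac = yellow_fraction(gray, t)
    return HeadGrade(yellow_fraction=frac,
                     level=assign_level(frac, std),
                     threshold_used=t, standard=std.name)


def grading_accuracy(predicted_levels, true_levels) -> float:
    """Proportion of heads whose assigned level matches the reference."""
    p = list(predicted_levels)
    t = list(true_levels)
    if len(p) != len(t) or not p:
        raise ValueError("level sequences must be nonempty and equal length")
    return sum(a == b for a, b in zip(p, t)) / len(p)


class HeadGrader:
    """Convenience object applying :func:`grade_pipeline` to collections."""

    def __init__(self, standard="merged", pso_config: PSOConfig | None = None):
        self.standard = get_standard(standard)
        self.pso_config = pso_config

    def grade(self, image, head_mask) -> HeadGrade:
        return grade_pipeline(image, head_mask, self.standard, self.pso_config)

    def grade_many(self, images, masks) -> list[HeadGrade]:
        return [self.grade(im, mk) for im, mk in zip(images, masks)]

    def population(self, grades) -> PopulationGrade:
        return population_yellowness([g.level for g in grades], self.standard)
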