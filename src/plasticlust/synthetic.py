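"""Synthetic lifespan expression data with known (planted) structure.

The generator emulates the statistical shape of postmortem developmental
datasets: a few dozen subjects whose ages span 21 days to ~80 years, a
handful of proteins whose expression follows smooth lifespan trajectories
(monotone up or down, inverted-U, undulating, flat), many uninformative
noise features, optional replicate runs per subject, and optional extreme
outlier subjects.

Lifespan stages are planted by adding, on top of each informative feature's
smooth trajectory, a piecewise-constant shift that changes at stage
boundaries equally spaced on the log-age axis (human developmental stages -
infancy, childhood, adolescence, adulthood, aging - occupy roughly
geometric age intervals, so log spacing is the natural choice).  The
planted stage labels define the "true k" that elbow selection and cluster
recovery are scored against.

Default conditions (frozen design choices, see docs/methods.md): 31
subjects, ages log-uniform on (0.05, 80) years, 6 stages, 5 informative +
45 noise features, baseline 4, trajectory amplitude 8 (a ~3-fold
developmental change, typical of synaptic proteins quantified by Western
blot), noise SD 0.5 (~10% CV at adult expression levels), stage weight
0.85.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from .errors import ParameterError

__all__ = [
    "TrajectorySpec",
    "LifespanTruth",
    "generate_lifespan_dataset",
    "generate_paired_omics",
    "bin_stratified_ages",
    "default_specs",
    "varied_specs",
    "PRESETS",
    "generate_preset",
]

_SHAPES = ("increase", "decrease", "inverted_u", "undulating", "flat")


@dataclass
class TrajectorySpec:
    """Shape of one informative feature's lifespan trajectory.

    ``amplitude`` is the full dynamic range of the trajectory in expression
    units; ``noise_sd`` the SD of additive Gaussian measurement noise;
    ``peak_age`` (years) positions the inverted-U maximum; ``period`` is the
    undulation period as a fraction of the log-age axis.
    """

    name: str
    shape: str
    amplitude: float = 8.0
    noise_sd: float = 0.5
    peak_age: float | None = None
    period: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ParameterError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("amplitude and noise_sd must be >= 0")
        if self.shape == "flat" and self.amplitude > 0:
            raise ParameterError("a flat trajectory with amplitude > 0 is contradictory")
        if self.shape == "inverted_u" and self.peak_age is None:
            self.peak_age = 2.0
        if self.shape == "undulating" and self.period is None:
            self.period = 0.45


@dataclass
class LifespanTruth:
    """Everything the generator planted, for scoring recovery."""

    stage_of: np.ndarray  # planted stage (0-based) per sample row
    boundaries: np.ndarray  # stage boundary ages in years (len n_stages - 1)
    informative: list[str]
    outlier_samples: list[str]
    signal: np.ndarray  # noiseless expression matrix (pre-outlier-shift)
    specs: list[TrajectorySpec]
    age_range: tuple[float, float]
    stage_weight: float
    baseline: float


def _log_frac(ages: np.ndarray, age_range: tuple[float, float]) -> np.ndarray:
    lo, hi = age_range
    return (np.log(ages) - math.log(lo)) / (math.log(hi) - math.log(lo))


def _shape_curve(spec: TrajectorySpec, t: np.ndarray, age_range: tuple[float, float]) -> np.ndarray:
    if spec.shape == "increase":
        return t
    if spec.shape == "decrease":
        return 1.0 - t
    if spec.shape == "inverted_u":
        tp = _log_frac(np.array([spec.peak_age]), age_range)[0]
        return np.exp(-((t - tp) ** 2) / (2 * 0.18**2))
    if spec.shape == "undulating":
        return 0.5 + 0.5 * np.sin(2 * math.pi * t / spec.period - math.pi / 2)
    return np.zeros_like(t)  # flat


def default_specs(amplitude: float = 8.0, noise_sd: float = 0.5) -> list[TrajectorySpec]:
    """The five default informative trajectories: one rising, one falling,
    an early and a late inverted-U, and an undulating curve."""
    return [
        TrajectorySpec("traj_up", "increase", amplitude, noise_sd),
        TrajectorySpec("traj_down", "decrease", amplitude, noise_sd),
        TrajectorySpec("traj_peak_early", "inverted_u", amplitude, noise_sd, peak_age=2.0),
        TrajectorySpec("traj_peak_late", "inverted_u", amplitude, noise_sd, peak_age=18.0),
        TrajectorySpec("traj_wave", "undulating", amplitude, noise_sd, period=0.45),
    ]


def varied_specs(n: int, amplitude: float = 8.0, noise_sd: float = 0.5, seed: int = 0) -> list[TrajectorySpec]:
    """``n`` informative trajectories cycling through the shape families
    with randomised peak ages and periods; used to emulate protein panels
    larger than the five defaults."""
    rng = np.random.default_rng(seed)
    shapes = ["increase", "decrease", "inverted_u", "undulating"]
    specs = []
    for i in range(n):
        shape = shapes[i % len(shapes)]
        kw = {}
        if shape == "inverted_u":
            kw["peak_age"] = float(rng.uniform(0.5, 40.0))
        if shape == "undulating":
            kw["period"] = float(rng.uniform(0.3, 0.8))
        specs.append(TrajectorySpec(f"traj{i:03d}_{shape}", shape, amplitude, noise_sd, **kw))
    return specs


def bin_stratified_ages(
    n: int,
    age_range: tuple[float, float] = (0.05, 80.0),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    edges: np.ndarray | None = None,
) -> np.ndarray:
    """Ages allocated as evenly as possible across the six lifespan age
    bins (<1, 1-5, 5-12, 12-20, 20-55, >55 years), log-uniform within each
    bin; guarantees every bin is populated for n >= 6 (needed by the
    age-binned pair-correlation procedure)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = age_range
    if edges is None:
        edges = np.array([1.0, 5.0, 12.0, 20.0, 55.0])
    bounds = np.concatenate([[lo], np.clip(edges, lo, hi), [hi]])
    n_bins = len(bounds) - 1
    counts = np.full(n_bins, n // n_bins)
    counts[: n % n_bins] += 1
    ages = []
    for b in range(n_bins):
        u = rng.uniform(math.log(bounds[b]), math.log(bounds[b + 1]), counts[b])
        ages.append(np.exp(u))
    return np.sort(np.concatenate(ages))


def _stratified_log_ages(n: int, n_stages: int, age_range: tuple[float, float], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Log-uniform ages allocated as evenly as possible across the equal
    log-width stage intervals, so every planted stage is populated."""
    lo, hi = age_range
    counts = np.full(n_stages, n // n_stages)
    counts[: n % n_stages] += 1
    t = []
    stage = []
    for s in range(n_stages):
        u = rng.uniform(s / n_stages, (s + 1) / n_stages, counts[s])
        t.append(u)
        stage.append(np.full(counts[s], s))
    t = np.concatenate(t)
    stage = np.concatenate(stage)
    order = np.argsort(t)
    t, stage = t[order], stage[order]
    ages = lo * np.exp(t * (math.log(hi) - math.log(lo)))
    return ages, stage


def generate_lifespan_dataset(
    n_subjects: int = 31,
    age_range: tuple[float, float] = (0.05, 80.0),
    specs: list[TrajectorySpec] | None = None,
    n_noise_features: int = 45,
    n_stages: int = 6,
    n_outliers: int = 0,
    n_replicates: int = 1,
    seed: int | np.random.SeedSequence = 0,
    stage_weight: float = 0.85,
    baseline: float = 4.0,
    noise_feature_sd: float = 0.5,
    outlier_shift_sd: float = 6.0,
    ages: np.ndarray | None = None,
) -> tuple[ExpressionDataset, LifespanTruth]:
    """Generate a lifespan dataset with planted stages, noise features and
    (optionally) outlier subjects and replicate runs.

    Informative feature ``j`` of subject ``i`` is

    ``baseline + A_j * [(1 - w) g_j(t_i) + w g_j(t_center(stage_i))] + noise``

    where ``t`` is the log-age fraction, ``g_j`` the trajectory shape and
    ``w = stage_weight`` the share of the dynamic range carried by the
    piecewise-constant stage shift.  Outlier subjects get additive shifts of
    ``outlier_shift_sd`` feature SDs on a random quarter of the features.

    Returns the dataset and a :class:`LifespanTruth` record.
    """
    if specs is None:
        specs = default_specs()
    if n_subjects < 2 * n_stages:
        raise ParameterError(f"need n_subjects >= 2 * n_stages = {2 * n_stages}, got {n_subjects}")
    if not 0 <= stage_weight <= 1:
        raise ParameterError("stage_weight must lie in [0, 1]")
    if n_outliers < 0 or n_outliers > n_subjects // 3:
        raise ParameterError("n_outliers must be small relative to n_subjects")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    if ages is None:
        ages, stage = _stratified_log_ages(n_subjects, n_stages, age_range, rng)
    else:
        # caller-supplied ages (e.g. a real study's sampling design);
        # stages follow from the planted log-age boundaries
        ages = np.sort(np.asarray(ages, dtype=float))
        if ages.shape != (n_subjects,):
            raise ParameterError("ages must have length n_subjects")
        if ages.min() < age_range[0] or ages.max() > age_range[1]:
            raise ParameterError("supplied ages fall outside age_range")
        stage = np.clip(
            (_log_frac(ages, age_range) * n_stages).astype(int), 0, n_stages - 1
        )
    t = _log_frac(ages, age_range)
    centers_t = (np.arange(n_stages) + 0.5) / n_stages

    p_inf = len(specs)
    p = p_inf + n_noise_features
    feature_names = [s.name for s in specs] + [f"noise{j:03d}" for j in range(n_noise_features)]

    # subject-level noiseless signal
    signal = np.empty((n_subjects, p))
    for j, sp in enumerate(specs):
        g_t = _shape_curve(sp, t, age_range)
        g_c = _shape_curve(sp, centers_t[stage], age_range)
        signal[:, j] = baseline + sp.amplitude * ((1 - stage_weight) * g_t + stage_weight * g_c)
    signal[:, p_inf:] = baseline

    # outlier subjects: large shifts on a random quarter of the features
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    outlier_idx = sorted(rng.choice(n_subjects, size=n_outliers, replace=False).tolist()) if n_outliers else []
    shifted = signal.copy()
    feat_sd = np.array([sp.noise_sd for sp in specs] + [noise_feature_sd] * n_noise_features)
    scale = np.maximum(signal.std(axis=0), feat_sd)
    for i in outlier_idx:
        n_hit = max(3, p // 4)
        hit = rng.choice(p, size=min(n_hit, p), replace=False)
        sign = rng.choice([-1.0, 1.0], size=hit.size)
        shifted[i, hit] += sign * outlier_shift_sd * scale[hit]

    # expand to replicate runs and add measurement noise
    rows, row_ages, row_stage, ids = [], [], [], []
    run_of: dict[str, str] = {}
    noise_sd_vec = feat_sd
    for i in range(n_subjects):
        for r in range(n_replicates):
            sid = subject_ids[i] if n_replicates == 1 else f"{subject_ids[i]}_r{r + 1}"
            ids.append(sid)
            if n_replicates > 1:
                run_of[sid] = subject_ids[i]
            rows.append(shifted[i] + rng.normal(0.0, noise_sd_vec, size=p))
            row_ages.append(ages[i])
            row_stage.append(stage[i])
    values = np.vstack(rows)

    data = ExpressionDataset(
        values=values,
        feature_names=feature_names,
        sample_ids=ids,
        ages=np.array(row_ages),
        run_of=run_of or None,
    )
    boundary_t = np.arange(1, n_stages) / n_stages
    lo, hi = age_range
    boundaries = lo * np.exp(boundary_t * (math.log(hi) - math.log(lo)))
    outlier_samples = [s for s in ids if (run_of.get(s, s) if run_of else s) in {subject_ids[i] for i in outlier_idx}]
    sig_rows = np.repeat(signal, n_replicates, axis=0)
    truth = LifespanTruth(
        stage_of=np.array(row_stage),
        boundaries=boundaries,
        informative=[s.name for s in specs],
        outlier_samples=outlier_samples,
        signal=sig_rows,
        specs=list(specs),
        age_range=age_range,
        stage_weight=stage_weight,
        baseline=baseline,
    )
    return data, truth


# ---------------------------------------------------------------------------
# paired omics
# ---------------------------------------------------------------------------

def _smooth_noise_curve(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random smooth function of log-age (sum of three sinusoids); noise
    that lives at the trajectory level rather than the sample level."""
    out = np.zeros_like(t)
    for _ in range(3):
        f = rng.uniform(0.5, 3.0)
        phi = rng.uniform(0, 2 * math.pi)
        out += rng.normal() * np.sin(2 * math.pi * f * t + phi)
    return out


def _bin_standardize(values: np.ndarray, ages: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Center/scale a curve by the mean and SD of its six age-bin means, so
    that target correlations are expressed on the bin-mean scale that
    pair_correlations measures."""
    idx = np.digitize(ages, edges, right=False)
    means = np.array([values[idx == b].mean() for b in range(len(edges) + 1) if np.any(idx == b)])
    mu, sd = means.mean(), means.std(ddof=1)
    if sd <= 0:
        sd = 1.0
    return (values - mu) / sd


def generate_paired_omics(
    base: ExpressionDataset,
    target_r: float,
    seed: int | np.random.SeedSequence = 0,
    truth: LifespanTruth | None = None,
    ages: np.ndarray | None = None,
    measurement_sd: float = 0.1,
    bin_edges: np.ndarray | None = None,
) -> ExpressionDataset:
    """A companion dataset (e.g. genes paired to proteins) whose per-feature
    lifespan trajectories correlate with the base trajectories at
    ``target_r`` on the age-bin-mean scale.

    Each paired feature is ``target_r * s + sqrt(1 - target_r^2) * u`` where
    ``s`` is the base feature's (noiseless, if ``truth`` is given) trajectory
    and ``u`` an independent smooth trajectory, both standardised on their
    age-bin means.  With ``ages=None`` an independent subject set of the same
    size is drawn; pass ``ages=base.ages`` to reuse the base subjects.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ParameterError(f"target_r must lie in [-1, 1], got {target_r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if bin_edges is None:
        bin_edges = np.array([1.0, 5.0, 12.0, 20.0, 55.0])

    if truth is not None:
        age_range = truth.age_range
    else:
        age_range = (float(base.ages.min()) * 0.999, float(base.ages.max()) * 1.001)

    if ages is None:
        n = base.n_samples
        # bin-stratified so every lifespan age bin is populated, as the
        # pair-correlation procedure requires
        new_ages = bin_stratified_ages(n, age_range, rng, edges=bin_edges)
    else:
        new_ages = np.asarray(ages, dtype=float)
        n = new_ages.shape[0]
    t = _log_frac(np.clip(new_ages, age_range[0], age_range[1]), age_range)

    p = base.n_features
    values = np.empty((n, p))
    for j in range(p):
        if truth is not None:
            sp_map = {s.name: s for s in truth.specs}
            name = base.feature_names[j]
            if name in sp_map:
                sp = sp_map[name]
                n_st = len(truth.boundaries) + 1
                centers_t = (np.arange(n_st) + 0.5) / n_st
                stage = np.clip((t * n_st).astype(int), 0, n_st - 1)
                s_curve = (1 - truth.stage_weight) * _shape_curve(sp, t, age_range) + truth.stage_weight * _shape_curve(sp, centers_t[stage], age_range)
            else:
                s_curve = np.zeros(n)  # noise feature: no trajectory to couple to
        else:
            order = np.argsort(base.ages)
            s_curve = np.interp(new_ages, base.ages[order], base.values[order, j])
        if np.ptp(s_curve) > 0:
            s_std = _bin_standardize(s_curve, new_ages, bin_edges)
        else:
            s_std = np.zeros(n)
        u = _smooth_noise_curve(t, rng)
        u_std = _bin_standardize(u, new_ages, bin_edges)
        values[:, j] = target_r * s_std + math.sqrt(max(0.0, 1 - target_r**2)) * u_std
        if measurement_sd > 0:
            values[:, j] += rng.normal(0.0, measurement_sd, size=n)

    return ExpressionDataset(
        values=values,
        feature_names=[f"{f}_paired" for f in base.feature_names],
        sample_ids=[f"G{i + 1:03d}" for i in range(n)],
        ages=new_ages,
    )


# ---------------------------------------------------------------------------
# presets mirroring the three dataset sizes of the motivating study
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # 7-protein pilot panel: all features informative, replicate runs kept
    "small7": dict(
        n_subjects=31,
        specs_n_informative=7,
        n_noise_features=0,
        n_replicates=3,
        n_stages=6,
    ),
    # 23-protein panel: 5 informative trajectories + 18 uninformative
    "full23": dict(
        n_subjects=31,
        specs_n_informative=5,
        n_noise_features=18,
        n_replicates=1,
        n_stages=6,
    ),
    # 95-protein high-density array: 5 informative + 90 uninformative
    "wide95": dict(
        n_subjects=31,
        specs_n_informative=5,
        n_noise_features=90,
        n_replicates=1,
        n_stages=6,
    ),
}


def generate_preset(name: str, seed: int | np.random.SeedSequence = 0, **overrides) -> tuple[ExpressionDataset, LifespanTruth]:
    """Generate one of the named presets (``small7``, ``full23``, ``wide95``)."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    n_inf = cfg.pop("specs_n_informative")
    cfg.update(overrides)
    if "specs" not in cfg:
        cfg["specs"] = default_specs() if n_inf == 5 else varied_specs(n_inf, seed=17)
    return generate_lifespan_dataset(seed=seed, **cfg)
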