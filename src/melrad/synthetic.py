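"""Synthetic PET phantoms and two-center radiomic cohorts.

The study population this package was written for is not redistributable, so
every downstream stage is exercised on simulated stand-ins with the same
statistical structure:

* :func:`generate_phantom` builds SUV volumes containing a liver reference
  sphere, hyper-metabolic lesions (optionally with speckled texture so that
  texture features are non-degenerate), hot "organ" spheres meant to be
  excluded, and additive Gaussian noise.
* :func:`generate_cohort` builds a development cohort (default n=95, 1-year
  progression rate 0.484) and a testing cohort (default n=59, rate 0.407)
  of radiomic feature tables with center-specific additive/multiplicative
  batch effects, a small set of outcome-associated features, and
  proportional-hazards PFS/OS times with censoring.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SuvVolume, sphere_mask

__all__ = [
    "Sphere",
    "Lesion",
    "PhantomSpec",
    "PhantomResult",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "one_year_progression_rate",
    "summarize_outcomes",
]

#: Baseline prevalence of binary clinical covariates, (development, testing),
#: mirroring typical metastatic-melanoma ICI cohorts.
COVARIATE_PREVALENCE = {
    "brain_metastases": (0.168, 0.152),
    "hepatic_metastases": (0.253, 0.237),
    "corticosteroids": (0.263, 0.237),
    "elevated_ldh": (0.232, 0.525),
    "ecog_1": (0.316, 0.678),
    "age_over_65": (0.55, 0.55),
    "male": (0.526, 0.610),
    "combo_regimen": (0.337, 0.390),
}


@dataclass(frozen=True)
class Sphere:
    """A sphere in physical coordinates (mm), with an SUV amplitude."""

    center: tuple[float, float, float]
    radius: float
    suv: float = 0.0


@dataclass(frozen=True)
class Lesion(Sphere):
    texture: str = "smooth"  # "smooth" | "speckled"
    speckle_sigma: float = 0.3

    def __post_init__(self):
        if self.texture not in ("smooth", "speckled"):
            raise ValueError(f"unknown lesion texture {self.texture!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model for a synthetic SUV volume.

    Lesion amplitudes must exceed the segmentation threshold implied by the
    liver statistics (1.5 * mean + 2 * SD); the liver sphere must be disjoint
    from every lesion; all spheres must fit inside the grid.
    """

    shape: tuple[int, int, int] = (48, 32, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background: float = 1.0
    liver_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    liver_mean: float = 2.0
    liver_sd: float = 0.25
    liver_diameter: float = 30.0
    lesions: tuple[Lesion, ...] = (
        Lesion(center=(76.0, 32.0, 32.0), radius=8.0, suv=8.0,
               texture="speckled"),
    )
    exclusion_spheres: tuple[Sphere, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        extent = [
            (0.0, (n - 1) * s) for n, s in zip(self.shape, self.spacing)
        ]

        def check_inside(name, center, radius):
            for (lo, hi), c in zip(extent, center):
                if c - radius < lo - 1e-9 or c + radius > hi + 1e-9:
                    raise ValueError(
                        f"{name} (center {tuple(center)}, radius {radius} mm) "
                        f"lies outside the grid extent {extent}"
                    )

        check_inside("liver sphere", self.liver_center, self.liver_diameter / 2)
        implied_t = 1.5 * self.liver_mean + 2.0 * self.liver_sd
        liver_r = self.liver_diameter / 2
        for i, les in enumerate(self.lesions):
            check_inside(f"lesion {i}", les.center, les.radius)
            if les.suv <= implied_t:
                raise ValueError(
                    f"lesion {i} amplitude {les.suv} does not exceed the "
                    f"implied PERCIST threshold {implied_t:.3g}"
                )
            gap = np.linalg.norm(
                np.asarray(les.center) - np.asarray(self.liver_center)
            )
            if gap <= liver_r + les.radius:
                raise ValueError(f"lesion {i} overlaps the liver sphere")
        for i, sph in enumerate(self.exclusion_spheres):
            check_inside(f"exclusion sphere {i}", sph.center, sph.radius)


@dataclass
class PhantomResult:
    volume: SuvVolume
    lesion_mask: np.ndarray
    liver_center: tuple[float, float, float]
    exclusion_masks: list[np.ndarray]
    spec: PhantomSpec


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a PhantomSpec into an SUV volume with ground truth.

    Deterministic under a fixed seed. The ground-truth lesion mask is the
    union of the lesion spheres on the phantom's native grid.
    """
    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.shape, float(spec.background))

    liver = sphere_mask(
        spec.shape, spec.spacing, spec.liver_center, spec.liver_diameter / 2
    )
    data[liver] = rng.normal(spec.liver_mean, spec.liver_sd, int(liver.sum()))

    lesion_mask = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesions:
        m = sphere_mask(spec.shape, spec.spacing, les.center, les.radius)
        if les.texture == "speckled":
            # lognormal multiplier with unit mean: non-trivial intra-lesion
            # texture without changing the expected amplitude
            mult = rng.lognormal(
                mean=-0.5 * les.speckle_sigma**2,
                sigma=les.speckle_sigma,
                size=int(m.sum()),
            )
            data[m] = les.suv * mult
        else:
            data[m] = les.suv
        lesion_mask |= m

    exclusion_masks = []
    for sph in spec.exclusion_spheres:
        m = sphere_mask(spec.shape, spec.spacing, sph.center, sph.radius)
        if sph.suv > 0:
            data[m] = sph.suv
        exclusion_masks.append(m)

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, spec.shape)
    np.clip(data, 0.0, None, out=data)

    return PhantomResult(
        volume=SuvVolume(data, spec.spacing),
        lesion_mask=lesion_mask,
        liver_center=spec.liver_center,
        exclusion_masks=exclusion_masks,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Two-center radiomic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for a two-center feature/outcome cohort.

    Features are drawn standard normal; the ``signal_indices`` features are
    shifted by ``effect_size`` SD for 1-year progressors; each center then
    applies a location/scale batch effect ``x -> delta * x + gamma``.
    PFS times follow an exponential proportional-hazards model on the latent
    1-year risk: non-progressors survive the first 12 months and continue
    with baseline hazard, progressors fail within 12 months at hazard
    ``baseline_hazard * exp(log_hazard_ratio)``. OS is PFS plus an
    exponential post-progression increment, so OS >= PFS by construction.
    """

    n_per_center: tuple[int, int] = (95, 59)
    n_features: int = 856
    signal_indices: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 1.0
    gamma: tuple[float, float] = (0.0, 0.5)
    delta: tuple[float, float] = (1.0, 1.25)
    event_prob: tuple[float, float] = (0.484, 0.407)
    baseline_hazard: float = 0.057      # per month, non-progressor tail
    log_hazard_ratio: float = 1.0       # ~= log 2.7, progressor vs not
    post_progression_rate: float = 0.116  # median ~6 months to death
    censor_horizon: float = 60.0        # months, administrative
    dropout_rate: float = 0.2           # uniform dropout after month 12
    feature_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.delta):
            raise ValueError("multiplicative batch effect delta must be > 0")
        if any(not 0 < p < 1 for p in self.event_prob):
            raise ValueError("event probabilities must lie in (0, 1)")
        if any(not 0 <= i < self.n_features for i in self.signal_indices):
            raise ValueError("signal feature indices outside feature count")
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must equal n_features")
        if self.baseline_hazard <= 0 or self.post_progression_rate <= 0:
            raise ValueError("hazards must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def _default_feature_names(spec: CohortSpec) -> list[str]:
    if spec.feature_names is not None:
        return list(spec.feature_names)
    try:
        from .radiomics.registry import default_registry

        reg = default_registry()
        if spec.n_features == len(reg):
            return list(reg.identifiers)
    except Exception:  # pragma: no cover - registry always importable
        pass
    width = len(str(spec.n_features))
    return [f"F{i:0{width}d}" for i in range(spec.n_features)]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a two-center cohort.

    Returns ``(features, outcomes)``: the feature table has ``patient_id``,
    ``batch`` and one column per feature; the outcome table has the 1-year
    progression status, PFS/OS times (months) and event flags, and binary
    clinical covariates. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = _default_feature_names(spec)

    feat_frames, out_frames = [], []
    for c, (n, p_event) in enumerate(zip(spec.n_per_center, spec.event_prob)):
        center = f"center{c + 1}"
        ids = [f"C{c + 1}-{i + 1:03d}" for i in range(n)]

        status = rng.random(n) < p_event  # 1-year progression (incl. death)

        X = rng.standard_normal((n, spec.n_features))
        for j in spec.signal_indices:
            X[status, j] += spec.effect_size
        X = spec.delta[c] * X + spec.gamma[c]

        # --- survival times -------------------------------------------------
        lam0 = spec.baseline_hazard
        lam1 = lam0 * np.exp(spec.log_hazard_ratio)
        pfs = np.empty(n)
        pfs_event = np.zeros(n, dtype=bool)
        # progressors: exponential at the elevated hazard, conditioned on
        # failing within the first 12 months (inverse-CDF of the truncation)
        n1 = int(status.sum())
        u = rng.random(n1)
        pfs[status] = -np.log(1 - u * (1 - np.exp(-12.0 * lam1))) / lam1
        pfs_event[status] = True
        # non-progressors: survive 12 months, then memoryless baseline tail
        n0 = n - n1
        tail = 12.0 + rng.exponential(1.0 / lam0, n0)
        cens = np.full(n0, spec.censor_horizon)
        drop = rng.random(n0) < spec.dropout_rate
        cens[drop] = rng.uniform(12.0, spec.censor_horizon, int(drop.sum()))
        pfs[~status] = np.minimum(tail, cens)
        pfs_event[~status] = tail <= cens

        os_raw = pfs + rng.exponential(1.0 / spec.post_progression_rate, n)
        os_event = np.zeros(n, dtype=bool)
        os_time = np.where(os_raw <= spec.censor_horizon, os_raw,
                           spec.censor_horizon)
        # death observed when progression was observed and the post-progression
        # increment falls before the horizon
        os_event = pfs_event & (os_raw <= spec.censor_horizon)

        out = pd.DataFrame(
            {
                "patient_id": ids,
                "batch": center,
                "one_year_dp": status.astype(int),
                "pfs_months": np.round(pfs, 4),
                "pfs_event": pfs_event.astype(int),
                "os_months": np.round(os_time, 4),
                "os_event": os_event.astype(int),
            }
        )
        for cov, prev in COVARIATE_PREVALENCE.items():
            out[cov] = (rng.random(n) < prev[c]).astype(int)
        out_frames.append(out)

        feat = pd.DataFrame(X, columns=names)
        feat.insert(0, "patient_id", ids)
        feat.insert(1, "batch", center)
        feat_frames.append(feat)

    features = pd.concat(feat_frames, ignore_index=True)
    outcomes = pd.concat(out_frames, ignore_index=True)
    return features, outcomes


def one_year_progression_rate(n_events: int, n_total: int) -> float:
    """1-year progression rate in percent, from event counts."""
    if n_total <= 0 or not 0 <= n_events <= n_total:
        raise ValueError("invalid event counts")
    return 100.0 * n_events / n_total


def summarize_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-batch cohort summary: size, 1-year events and rate (%)."""
    rows = []
    for batch, grp in outcomes.groupby("batch", sort=True):
        n = len(grp)
        ev = int(grp["one_year_dp"].sum())
        rows.append(
            {
                "batch": batch,
                "n": n,
                "one_year_events": ev,
                "one_year_rate_pct": one_year_progression_rate(ev, n),
                "median_pfs_months": float(grp["pfs_months"].median()),
            }
        )
    return pd.DataFrame(rows)
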