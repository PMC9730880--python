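"""Synthetic phantoms, growth cohorts, survival data and the worked-example
cohort.

Every generator is a pure function of its parameters and seed.  The phantom
generator encodes the intensity signature attributed to lesions at risk of
hyperprogression — elevated, uniform average intensity without hot- or cold
spots — as class-conditional parameter presets; the growth generator uses the
volume-equivalent exponential diameter law D(t) = D0 * exp(g * t / 3) so that
the configured per-class rate g is exactly the growth statistic the
classifier recovers on jitter-free cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import substream
from .imaging import LesionMask, LesionVolume

__all__ = [
    "PhantomParams",
    "GrowthClassSpec",
    "Stratum",
    "SurvivalSpec",
    "CohortRecipe",
    "generate_lesion_phantom",
    "class_conditional_phantom_params",
    "generate_growth_cohort",
    "generate_survival",
    "build_figure2_fixture",
    "default_cohort_recipe",
    "make_feature_table",
]


# ---------------------------------------------------------------------------
# Lesion phantoms


@dataclass
class PhantomParams:
    """Ellipsoidal lesion phantom on a regular grid.

    Intensities are Gaussian inside the lesion (``mean_intensity`` +/-
    ``intensity_sd``) over a constant background, with optional Gaussian
    focal hotspots.  Units are HU for CT and SUV for PET.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_radius_mm: tuple[float, float, float] = (12.0, 10.0, 9.0)
    mean_intensity: float = 50.0
    intensity_sd: float = 10.0
    n_hotspots: int = 0
    hotspot_amplitude: float = 0.0
    hotspot_sigma_mm: float = 3.0
    background_intensity: float = 0.0
    seed: int = 0


def generate_lesion_phantom(params: PhantomParams,
                            modality: str = "CT") -> tuple[LesionVolume, LesionMask]:
    """Generate one ellipsoidal lesion phantom and its binary mask.

    The mask thresholds the implicit ellipsoid equation at voxel centers;
    the lesion must fit in the grid with a two-voxel margin per axis.
    """
    shape = np.asarray(params.grid_shape, dtype=int)
    sp = np.asarray(params.spacing_mm, dtype=float)
    radius = np.asarray(params.lesion_radius_mm, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("lesion radius must be positive")
    half_extent = (shape - 1) * sp / 2.0
    for a in range(3):
        if radius[a] + 2 * sp[a] > half_extent[a]:
            raise ValueError(
                f"lesion exceeds grid on axis {a}: semi-axis {radius[a]:g} mm "
                f"+ 2-voxel margin ({2 * sp[a]:g} mm) > half extent "
                f"{half_extent[a]:g} mm")

    center = (shape - 1) / 2.0 * sp
    idx = np.indices(shape).astype(float)
    coords = idx * sp.reshape(3, 1, 1, 1)
    q = sum(((coords[a] - center[a]) / radius[a]) ** 2 for a in range(3))
    mask = q <= 1.0

    rng = np.random.default_rng(params.seed)
    vol = np.full(shape, float(params.background_intensity))
    vol[mask] = rng.normal(params.mean_intensity, params.intensity_sd,
                           int(mask.sum()))
    if params.n_hotspots > 0:
        centers = np.argwhere(mask)
        picks = centers[rng.integers(0, len(centers), params.n_hotspots)]
        for c in picks:
            d2 = sum(((coords[a] - c[a] * sp[a]) ** 2) for a in range(3))
            vol += mask * params.hotspot_amplitude * np.exp(
                -d2 / (2 * params.hotspot_sigma_mm**2))

    labels, ncomp = ndimage.label(mask)  # 6-connectivity by default
    if ncomp != 1:
        raise RuntimeError("phantom mask is not a single connected component")
    return (LesionVolume(vol, sp, np.zeros(3), modality),
            LesionMask(mask, sp, np.zeros(3)))


def class_conditional_phantom_params(hpl: bool, modality: str,
                                     seed: int) -> PhantomParams:
    """Phantom presets encoding the hyperprogression intensity signature.

    HPL-class lesions: elevated uniform mean intensity, low noise, no
    hotspots.  Non-HPL lesions: lower mean, higher heterogeneity, focal
    hotspots.
    """
    if modality == "CT":
        if hpl:
            return PhantomParams(mean_intensity=70.0, intensity_sd=4.0,
                                 n_hotspots=0, hotspot_amplitude=0.0, seed=seed)
        return PhantomParams(mean_intensity=40.0, intensity_sd=15.0,
                             n_hotspots=3, hotspot_amplitude=40.0, seed=seed)
    if hpl:
        return PhantomParams(mean_intensity=6.0, intensity_sd=0.4,
                             n_hotspots=0, hotspot_amplitude=0.0, seed=seed)
    return PhantomParams(mean_intensity=4.0, intensity_sd=1.2,
                         n_hotspots=3, hotspot_amplitude=4.0, seed=seed)


# ---------------------------------------------------------------------------
# Growth cohorts

# Volume growth rates (per day) of the three lesion archetypes, chosen so the
# archetypal diameter courses over -90/0/+90 day scans are 20->20->20 mm
# (stable), 14->20->26 mm (progressive, growth decelerating: ratio ~0.74) and
# 19->20->26 mm (hyperprogressive: ratio ~5.1), all far from the RECIST and
# doubling decision boundaries.
_G_SLOW_PRE = 3.0 * math.log(20.0 / 14.0) / 90.0
_G_POST = 3.0 * math.log(26.0 / 20.0) / 90.0
_G_HPL_PRE = 3.0 * math.log(20.0 / 19.0) / 90.0


@dataclass
class GrowthClassSpec:
    """Diameter trajectory of one lesion class."""

    name: str
    d_base_mm: float
    g_pre: float   # volume growth rate before treatment, per day
    g_post: float  # volume growth rate after treatment, per day
    is_hpl: bool = False


DEFAULT_CLASSES = {
    "stable": GrowthClassSpec("stable", 20.0, 0.0, 0.0),
    "pd_slow": GrowthClassSpec("pd_slow", 20.0, _G_SLOW_PRE, _G_POST),
    "hpl": GrowthClassSpec("hpl", 20.0, _G_HPL_PRE, _G_POST, is_hpl=True),
}


@dataclass
class Stratum:
    n_patients: int
    lesions_per_class: dict[str, int]
    timepoints_days: tuple[float, float, float] = (-90.0, 0.0, 90.0)
    jitter_sd: float = 0.0  # lognormal sigma on diameters; 0 = exact
    group: str = ""         # survival group label; defaults to dominant class


@dataclass
class SurvivalSpec:
    """Exponential survival per patient group (hazards per month)."""

    hazard_per_group: dict[str, float] = field(default_factory=dict)
    censoring_hazard: float = 0.0


@dataclass
class CohortRecipe:
    strata: list[Stratum]
    classes: dict[str, GrowthClassSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES))
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0


def _lesion_diameters(spec: GrowthClassSpec, t: tuple[float, float, float],
                      jitter_sd: float, rng: np.random.Generator
                      ) -> tuple[float, float, float]:
    t_pre, t_base, t_fu = t
    d_base = spec.d_base_mm
    d_pre = d_base * math.exp(-spec.g_pre * (t_base - t_pre) / 3.0)
    d_fu = d_base * math.exp(spec.g_post * (t_fu - t_base) / 3.0)
    if jitter_sd > 0:
        jit = rng.lognormal(0.0, jitter_sd, 3)
        d_pre, d_base, d_fu = d_pre * jit[0], d_base * jit[1], d_fu * jit[2]
    for d in (d_pre, d_base, d_fu):
        if d <= 0:
            raise ValueError("growth model produced a non-positive diameter")
    return d_pre, d_base, d_fu


def generate_growth_cohort(recipe: CohortRecipe
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-lesion longitudinal diameters for a patient cohort.

    Returns ``(patients, lesions)`` tables; ``lesions`` carries the
    ground-truth class in ``true_class`` and ``true_hpl``.
    """
    rng = substream(recipe.seed, "growth")
    start = pd.Timestamp("2020-01-01")
    patients, lesions = [], []
    pidx = 0
    for si, st in enumerate(recipe.strata):
        dominant = max(st.lesions_per_class, key=st.lesions_per_class.get)
        group = st.group or dominant
        for _ in range(st.n_patients):
            pidx += 1
            pid = f"P{pidx:04d}"
            patients.append({"patient_id": pid, "group": group,
                             "stratum": si})
            li = 0
            for cname, count in st.lesions_per_class.items():
                spec = recipe.classes[cname]
                for _ in range(count):
                    li += 1
                    d_pre, d_base, d_fu = _lesion_diameters(
                        spec, st.timepoints_days, st.jitter_sd, rng)
                    t_pre, t_base, t_fu = st.timepoints_days
                    lesions.append({
                        "patient_id": pid,
                        "lesion_id": f"{pid}_L{li:02d}",
                        "site": "unspecified",
                        "treatment_start": start.date().isoformat(),
                        "date_prebaseline":
                            (start + pd.Timedelta(days=t_pre)).date().isoformat(),
                        "date_baseline":
                            (start + pd.Timedelta(days=t_base)).date().isoformat(),
                        "date_followup":
                            (start + pd.Timedelta(days=t_fu)).date().isoformat(),
                        "t_pre_days": t_pre, "t_base_days": t_base,
                        "t_fu_days": t_fu,
                        "d_prebaseline_mm": d_pre,
                        "d_baseline_mm": d_base,
                        "d_followup_mm": d_fu,
                        "new_lesions_flag": False,
                        "true_class": cname,
                        "true_hpl": spec.is_hpl,
                    })
    return pd.DataFrame(patients), pd.DataFrame(lesions)


def generate_survival(groups: list[str] | np.ndarray,
                      hazard_per_group: dict[str, float],
                      seed: int,
                      censoring_hazard: float = 0.0) -> pd.DataFrame:
    """Exponential event times per group with independent exponential censoring.

    Hazards are per month; returns columns ``time`` (months) and ``event``.
    """
    for g, h in hazard_per_group.items():
        if h <= 0:
            raise ValueError(f"group {g!r}: hazard must be > 0")
    rng = substream(seed, "survival")
    groups = np.asarray(groups)
    t_event = np.array([rng.exponential(1.0 / hazard_per_group[g])
                        for g in groups])
    if censoring_hazard > 0:
        t_cens = rng.exponential(1.0 / censoring_hazard, len(groups))
    else:
        t_cens = np.full(len(groups), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"group": groups, "time": time, "event": event})


def default_cohort_recipe(n_patients: int = 60, jitter_sd: float = 0.0,
                          seed: int = 0) -> CohortRecipe:
    """A mixed cohort: 70% stable-dominant, 15% slow-PD, 15% HPL patients."""
    n_npd = int(round(0.70 * n_patients))
    n_pd = int(round(0.15 * n_patients))
    n_hpd = n_patients - n_npd - n_pd
    strata = [
        Stratum(n_npd, {"stable": 6}, jitter_sd=jitter_sd, group="nPD"),
        Stratum(n_pd, {"pd_slow": 5}, jitter_sd=jitter_sd, group="PD-nHPD"),
        Stratum(n_hpd, {"hpl": 3, "pd_slow": 2, "stable": 1},
                jitter_sd=jitter_sd, group="PD-HPD"),
    ]
    survival = SurvivalSpec(
        hazard_per_group={"nPD": 0.012, "PD-nHPD": 0.055, "PD-HPD": 0.10},
        censoring_hazard=0.01)
    return CohortRecipe(strata, survival=survival, seed=seed)


# ---------------------------------------------------------------------------
# Deterministic worked-example cohort (published classification counts)

_FIXTURE_DIAMS = {
    "stable": (20.0, 20.0, 20.0),
    "pd_slow": (14.0, 20.0, 26.0),
    "hpl": (19.0, 20.0, 26.0),
}
# Lesion mixes of the 8 hyperprogressing patients.
_HPD_HPL_COUNTS = [4, 4, 4, 4, 4, 3, 3, 3]
_HPD_SLOW_COUNTS = [2, 2, 1, 1, 1, 1, 1, 1]


def build_figure2_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 56-patient / 330-lesion worked-example cohort.

    Lesion strata: 261 stable (20->20->20 mm), 40 slowly progressing
    (14->20->26 mm) and 29 hyperprogressing (19->20->26 mm) lesions, all
    scanned at -90/0/+90 days, allocated over 42 non-progressing, 6
    progressing and 8 hyperprogressing patients.  No new lesions.
    """
    start = pd.Timestamp("2020-01-01")
    patients, lesions = [], []

    def add_patient(pid: str, group: str, mix: list[tuple[str, int]],
                    os_months: float, event: int) -> None:
        patients.append({"patient_id": pid, "group": group,
                         "os_months": os_months, "event": event})
        li = 0
        for cname, count in mix:
            d_pre, d_base, d_fu = _FIXTURE_DIAMS[cname]
            for _ in range(count):
                li += 1
                lesions.append({
                    "patient_id": pid, "lesion_id": f"{pid}_L{li:02d}",
                    "site": "unspecified",
                    "treatment_start": start.date().isoformat(),
                    "date_prebaseline":
                        (start - pd.Timedelta(days=90)).date().isoformat(),
                    "date_baseline": start.date().isoformat(),
                    "date_followup":
                        (start + pd.Timedelta(days=90)).date().isoformat(),
                    "t_pre_days": -90.0, "t_base_days": 0.0, "t_fu_days": 90.0,
                    "d_prebaseline_mm": d_pre, "d_baseline_mm": d_base,
                    "d_followup_mm": d_fu,
                    "new_lesions_flag": False,
                    "true_class": cname, "true_hpl": cname == "hpl",
                })

    pid = 0
    # 42 non-progressing patients, 6 stable lesions each; mostly censored
    # long survival with a few late deaths so hazard fits stay regular.
    for i in range(42):
        pid += 1
        death = i % 7 == 3  # occasional deaths spread from 7 months on
        add_patient(f"P{pid:03d}", "nPD", [("stable", 6)],
                    os_months=4.0 + i if death else 36.0 + i,
                    event=int(death))
    # 6 progressing, non-hyperprogressing patients with 5 slow-PD lesions;
    # the first also carries one of the 9 extra stable lesions.
    npd_os = [15.0, 16.0, 14.0, 17.0, 13.0, 15.0]
    for i in range(6):
        pid += 1
        mix = [("pd_slow", 5)] + ([("stable", 1)] if i == 0 else [])
        add_patient(f"P{pid:03d}", "PD-nHPD", mix, os_months=npd_os[i], event=1)
    # 8 hyperprogressing patients; each carries one extra stable lesion.
    hpd_os = [10.0, 9.0, 11.0, 10.0, 8.0, 12.0, 10.0, 9.0]
    for i in range(8):
        pid += 1
        mix = [("hpl", _HPD_HPL_COUNTS[i]), ("pd_slow", _HPD_SLOW_COUNTS[i]),
               ("stable", 1)]
        add_patient(f"P{pid:03d}", "PD-HPD", mix, os_months=hpd_os[i], event=1)

    return pd.DataFrame(patients), pd.DataFrame(lesions)


# ---------------------------------------------------------------------------
# Synthetic feature tables for modeling benchmarks


def make_feature_table(n_patients: int = 60, lesions_per_patient: int = 5,
                       n_ct: int = 20, n_pet: int = 20,
                       n_informative: int = 3, effect: float = 1.0,
                       positive_rate: float = 0.25,
                       permute_labels: bool = False,
                       seed: int = 0) -> pd.DataFrame:
    """Gaussian lesion x feature table with a known class signal.

    The first ``n_informative`` CT features are shifted by ``effect`` standard
    deviations in positive lesions; labels cluster by patient (a per-patient
    propensity drawn first).  With ``permute_labels`` the labels are shuffled
    across lesions after generation, destroying any association.
    Columns: ``ct_f00`` .., ``pet_f00`` .., ``label``, ``patient_id``.
    """
    rng = substream(seed, "feature-table")
    n = n_patients * lesions_per_patient
    pids = np.repeat([f"P{i:04d}" for i in range(n_patients)],
                     lesions_per_patient)
    prop = rng.beta(1.2, 1.2 * (1 - positive_rate) / positive_rate, n_patients)
    labels = (rng.random(n) < np.repeat(prop, lesions_per_patient)).astype(int)
    X = rng.normal(size=(n, n_ct + n_pet))
    X[:, :n_informative] += effect * labels[:, None]
    if permute_labels:
        labels = rng.permutation(labels)
    cols = [f"ct_f{i:02d}" for i in range(n_ct)] + \
           [f"pet_f{i:02d}" for i in range(n_pet)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = labels
    df["patient_id"] = pids
    return df
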