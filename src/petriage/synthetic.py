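"""Synthetic cohort, longitudinal-trajectory and PET-phantom generation.

The generator emulates the statistical structure of a memory-clinic cohort
in which three neuropsychological memory tests frequently disagree:

* baseline score tables whose per-group means and SDs match the published
  demographic table (certain-impaired / certain-healthy / uncertain),
  with roughly 73% of samples falling into the uncertain stratum;
* 15-item geriatric depression scale (GDS) responses in which the
  "energy" item separates certain from uncertain samples and the
  "memory" item tracks true impairment;
* longitudinal CDR-Memory trajectories whose monthly slopes are drawn
  from the published 95% CI ranges (impaired 0.0046-0.0076/month,
  healthy 0.0011-0.0020/month), with proportional MMSE/ADAS decline;
* phantom SUV volumes on a geometric atlas, with AD-pattern and
  depression-pattern regional hypometabolism and Gaussian voxel noise.

Scores are discrete (integers or half steps), so generation draws from the
group's normal, rounds/clips, and rejection-samples until the triage rule
reproduces the intended certainty label; the table moments are targets,
not exact constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import nibabel as nib
import yaml

from . import triage as _triage
from .petprep import BrainVolume, apply_mask, smooth, suv_to_suvr
from .triage import CERTAIN_HEALTHY, CERTAIN_IMPAIRED, UNCERTAIN

# --------------------------------------------------------------------------
# constants

GROUPS = (CERTAIN_IMPAIRED, CERTAIN_HEALTHY, UNCERTAIN)

IMPAIRED = "impaired"
HEALTHY = "healthy"

#: Short names of the 15 GDS items, in questionnaire order.
GDS_ITEMS = (
    "satisfy", "drop", "empty", "bored", "spirit",
    "afraid", "happy", "help", "home", "memory",
    "alive", "worth", "energy", "hope", "better",
)

#: ROIs required by the geometric atlas.
ROI_NAMES = (
    "pons", "precuneus", "inferior_temporal", "posterior_cingulate",
    "hippocampus", "parahippocampus", "medial_orbitofrontal",
    "anterior_cingulate", "insula", "angular", "middle_cingulate",
    "frontal", "cerebellum",
)

#: Regions carrying the AD-like hypometabolism pattern.
AD_PATTERN = frozenset({
    "precuneus", "inferior_temporal", "posterior_cingulate", "hippocampus",
    "parahippocampus", "angular", "middle_cingulate", "frontal",
})

#: Regions carrying the depression-like hypometabolism pattern.
DEPRESSION_PATTERN = frozenset({
    "medial_orbitofrontal", "anterior_cingulate", "insula",
    "hippocampus", "parahippocampus",
})

# ROI sphere centres in grid fractions (x, y, z); the brain "cerebrum" is an
# ellipsoid and the pons sits below it, outside the brain mask.  Centres are
# at least 0.126 grid fractions apart while sphere radii are 0.055, so the
# labels are pairwise disjoint at any grid size.
_ROI_CENTERS = {
    "pons": (0.50, 0.34, 0.10),
    "cerebellum": (0.38, 0.30, 0.26),
    "frontal": (0.50, 0.76, 0.62),
    "medial_orbitofrontal": (0.50, 0.70, 0.42),
    "anterior_cingulate": (0.50, 0.60, 0.60),
    "middle_cingulate": (0.50, 0.48, 0.68),
    "posterior_cingulate": (0.50, 0.36, 0.64),
    "precuneus": (0.50, 0.26, 0.55),
    "angular": (0.70, 0.32, 0.60),
    "inferior_temporal": (0.74, 0.52, 0.38),
    "insula": (0.67, 0.62, 0.50),
    "hippocampus": (0.63, 0.45, 0.35),
    "parahippocampus": (0.58, 0.34, 0.30),
}
_ROI_RADIUS_FRAC = 0.055
_BRAIN_CENTER = (0.50, 0.50, 0.55)
_BRAIN_SEMI = (0.44, 0.46, 0.40)


class GeneratorError(ValueError):
    pass


class AtlasSizingError(GeneratorError):
    pass


# --------------------------------------------------------------------------
# configuration


@dataclass
class VolumeParams:
    """Phantom-volume model parameters.

    Voxel value = baseline * (1 - delta_ad * severity * [AD ROI])
                           * (1 - delta_dep * [non-energetic] * [depression ROI])
    plus Gaussian noise; pons voxels are set to ``pons_intensity`` before
    noise.  Severity is 1 for certain-impaired and 0 for healthy; impaired
    uncertain samples carry their latent severity draw (in (0.5, 1)), or
    ``mild_fraction`` when no draw is attached to the sample.
    """

    grid_edge: int = 32
    voxel_mm: float = 2.0
    baseline: float = 1.3
    delta_ad: float = 0.15
    delta_dep: float = 0.08
    noise_sd: float = 0.05
    pons_intensity: float = 1.0
    mild_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.delta_ad < 1 and 0 <= self.delta_dep < 1):
            raise GeneratorError("effect fractions must lie in [0, 1)")
        if self.noise_sd < 0:
            raise GeneratorError("noise SD must be >= 0")
        if not (0 <= self.mild_fraction <= 1):
            raise GeneratorError("mild_fraction must lie in [0, 1]")


def _table1_defaults() -> dict:
    # per-group (mean, sd) of the three memory scores and demographics
    return {
        CERTAIN_IMPAIRED: {
            "mmse_recall": (0.19, 0.39), "adas_recall": (8.49, 2.45),
            "cdr_memory": (1.36, 0.51), "age": (75.68, 7.26),
            "education": (6.50, 3.40), "sex_f": 0.4135, "apoe4": 0.6827,
        },
        CERTAIN_HEALTHY: {
            "mmse_recall": (2.87, 0.33), "adas_recall": (25.02, 1.84),
            "cdr_memory": (0.00, 0.00), "age": (74.58, 5.87),
            "education": (6.75, 3.39), "sex_f": 0.5225, "apoe4": 0.2169,
        },
        UNCERTAIN: {
            "mmse_recall": (2.02, 1.09), "adas_recall": (17.54, 3.92),
            "cdr_memory": (0.49, 0.35), "age": (75.65, 7.46),
            "education": (6.57, 3.42), "sex_f": 0.3837, "apoe4": 0.4597,
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the published cohort structure: group proportions
    (312, 333, 1741)/2386, the demographic table's score means/SDs, CDR
    slope ranges whose midpoints are 0.0061 (impaired) and 0.00155
    (healthy) per month, and GDS-energy "yes" proportions
    (0.8027, 0.7644, 0.6955).
    """

    n_samples: int = 2386
    group_proportions: tuple[float, float, float] = (
        312 / 2386, 333 / 2386, 1741 / 2386,
    )
    score_params: dict = field(default_factory=_table1_defaults)
    slope_ranges: dict = field(default_factory=lambda: {
        IMPAIRED: (0.0046, 0.0076),
        HEALTHY: (0.0011, 0.0020),
    })
    gds_energy_props: dict = field(default_factory=lambda: {
        CERTAIN_IMPAIRED: 0.8027, CERTAIN_HEALTHY: 0.7644, UNCERTAIN: 0.6955,
    })
    # depression-keyed response probability of the GDS memory item per
    # latent state, and of the 13 remaining non-anchored items
    gds_memory_props: dict = field(default_factory=lambda: {
        IMPAIRED: 0.5, HEALTHY: 0.1,
    })
    gds_other_prop: float = 0.1
    # longitudinal model: per-visit score noise SDs, the factor by which
    # noise inflates for non-energetic subjects, and how fast MMSE/ADAS
    # decline per unit of CDR-Memory slope
    visit_noise_sd: dict = field(default_factory=lambda: {
        "mmse_recall": 0.3, "adas_recall": 1.5, "cdr_memory": 0.15,
    })
    non_energetic_noise_factor: float = 1.5
    mmse_decline_per_cdr: float = 3.0
    adas_decline_per_cdr: float = 20.0
    volume_params: VolumeParams = field(default_factory=VolumeParams)
    seed: int = 0
    max_resample: int = 1000

    def __post_init__(self) -> None:
        if isinstance(self.volume_params, dict):
            self.volume_params = VolumeParams(**self.volume_params)
        props = np.asarray(self.group_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise GeneratorError("group proportions must be 3 non-negative fractions summing to 1")
        for group, params in self.score_params.items():
            for key in ("mmse_recall", "adas_recall", "cdr_memory", "age", "education"):
                if params[key][1] < 0:
                    raise GeneratorError(f"negative SD for {group}/{key}")
        for state, (lo, hi) in self.slope_ranges.items():
            if lo > hi:
                raise GeneratorError(f"empty slope range for {state}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("group_proportions",):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


# --------------------------------------------------------------------------
# atlas


@dataclass
class RoiAtlas:
    """Integer label grid plus name map and brain mask.

    ``labels`` is indexed [x, y, z]; 0 is background.  ``brain_mask`` is an
    ellipsoidal "cerebrum" that contains every cerebral ROI but not the
    pons (the SUVr reference region lies below the cerebrum).
    """

    labels: np.ndarray
    names: dict[int, str]
    brain_mask: np.ndarray
    voxel_mm: float

    def roi_mask(self, name: str) -> np.ndarray:
        for label, n in self.names.items():
            if n == name:
                return self.labels == label
        raise KeyError(f"unknown ROI {name!r}")

    def pattern_mask(self, names) -> np.ndarray:
        mask = np.zeros(self.labels.shape, dtype=bool)
        for name in names:
            mask |= self.roi_mask(name)
        return mask

    def save(self, labels_path, names_path) -> None:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(labels_path))
        with open(names_path, "w") as fh:
            json.dump({str(k): v for k, v in self.names.items()}, fh, indent=1)


def build_atlas(grid_edge: int, voxel_mm: float = 2.0) -> RoiAtlas:
    """Deterministic geometric atlas: ROI spheres inside an ellipsoid brain.

    The same ``grid_edge`` always yields a voxel-identical atlas.  Grids
    smaller than 16 voxels per edge cannot hold all 13 regions disjointly.
    """
    if grid_edge < 16:
        raise AtlasSizingError(
            f"grid edge {grid_edge} too small to place all ROIs disjointly (need >= 16)"
        )
    e = grid_edge
    radius = _ROI_RADIUS_FRAC * e
    coords = np.stack(
        np.meshgrid(np.arange(e), np.arange(e), np.arange(e), indexing="ij"),
        axis=-1,
    ).astype(np.float64)

    labels = np.zeros((e, e, e), dtype=np.int16)
    names: dict[int, str] = {}
    for label, name in enumerate(ROI_NAMES, start=1):
        c = np.asarray(_ROI_CENTERS[name]) * (e - 1)
        dist2 = ((coords - c) ** 2).sum(-1)
        sphere = dist2 <= radius**2
        # guarantee at least the voxel nearest the centre
        cz = tuple(np.clip(np.round(c).astype(int), 0, e - 1))
        sphere[cz] = True
        if (labels[sphere] != 0).any():
            raise AtlasSizingError(f"ROI {name} overlaps a previously placed ROI")
        labels[sphere] = label
        names[label] = name

    bc = np.asarray(_BRAIN_CENTER) * (e - 1)
    semi = np.asarray(_BRAIN_SEMI) * (e - 1)
    ellipsoid = (((coords - bc) / semi) ** 2).sum(-1) <= 1.0
    pons = labels == [k for k, v in names.items() if v == "pons"][0]
    brain_mask = (ellipsoid | ((labels != 0) & ~pons)) & ~pons
    return RoiAtlas(labels=labels, names=names, brain_mask=brain_mask, voxel_mm=voxel_mm)


# --------------------------------------------------------------------------
# cohort generation


def _round_half_step(values: np.ndarray, levels) -> np.ndarray:
    levels = np.asarray(levels, dtype=float)
    idx = np.abs(values[:, None] - levels[None, :]).argmin(axis=1)
    return levels[idx]


def _draw_scores(rng: np.random.Generator, params: dict, n: int) -> dict:
    mmse = np.clip(np.round(rng.normal(*params["mmse_recall"], n)), 0, 3).astype(int)
    adas = np.clip(np.round(rng.normal(*params["adas_recall"], n)), 0, 30).astype(int)
    cdr = _round_half_step(rng.normal(*params["cdr_memory"], n), _triage.CDR_LEVELS)
    return {"mmse_recall": mmse, "adas_recall": adas, "cdr_memory": cdr}


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one baseline cohort table.

    Every sample is assigned an intended certainty group by the configured
    proportions; scores are redrawn (up to ``config.max_resample`` times)
    until the triage rule reproduces that intent.  The returned frame has
    one row per sample with demographics, the three memory scores, the 15
    binary GDS items (1 = depression-keyed response), the latent
    ``true_state``, and placeholder ``diagnosis`` columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    group_idx = rng.choice(3, size=n, p=np.asarray(config.group_proportions))
    groups = [GROUPS[i] for i in group_idx]

    rows = []
    for i, group in enumerate(groups):
        params = config.score_params[group]
        for attempt in range(config.max_resample):
            s = _draw_scores(rng, params, 1)
            label = _triage.assign_group(
                int(s["mmse_recall"][0]), int(s["adas_recall"][0]), float(s["cdr_memory"][0])
            )
            if label == group:
                break
        else:
            raise GeneratorError(
                f"could not draw scores consistent with intended group {group!r} "
                f"within {config.max_resample} attempts; score parameters conflict "
                "with the triage thresholds"
            )
        if group == CERTAIN_IMPAIRED:
            true_state, severity = IMPAIRED, 1.0
        elif group == CERTAIN_HEALTHY:
            true_state, severity = HEALTHY, 0.0
        else:
            # latent severity draw; impaired uncertain cases carry their
            # (mild, varied) severity into the phantom volume
            u = rng.uniform()
            true_state = IMPAIRED if u > 0.5 else HEALTHY
            severity = u if u > 0.5 else 0.0

        energetic = int(rng.uniform() < config.gds_energy_props[group])
        gds = {}
        for item in GDS_ITEMS:
            if item == "energy":
                gds[f"gds_{item}"] = 1 - energetic
            elif item == "memory":
                gds[f"gds_{item}"] = int(
                    rng.uniform() < config.gds_memory_props[true_state]
                )
            else:
                gds[f"gds_{item}"] = int(rng.uniform() < config.gds_other_prop)

        rows.append({
            "id": f"S{i:05d}",
            "age": rng.normal(*params["age"]),
            "sex": "F" if rng.uniform() < params["sex_f"] else "M",
            "education": max(0.0, rng.normal(*params["education"])),
            "apoe4": int(rng.uniform() < params["apoe4"]),
            "mmse_recall": int(s["mmse_recall"][0]),
            "adas_recall": int(s["adas_recall"][0]),
            "cdr_memory": float(s["cdr_memory"][0]),
            "latent_severity": severity,
            **gds,
            "gds_total": int(sum(gds.values())),
            "energetic": energetic,
            "true_state": true_state,
            "triage_label": group,
            "diagnosis": "none",
            "diagnosis_prob": np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# longitudinal trajectories


def generate_longitudinal(
    cohort: pd.DataFrame,
    interval: float = 6.0,
    horizon: float = 96.0,
    config: GeneratorConfig | None = None,
    noise_scale: float = 1.0,
    return_slopes: bool = False,
):
    """Draw per-visit score trajectories for every cohort sample.

    Visits occur at every multiple of ``interval`` in
    ``[interval, horizon]`` months.  Each sample's CDR-Memory slope is
    drawn uniformly from its latent state's configured range; MMSE and
    ADAS recall decline proportionally (``mmse_decline_per_cdr`` and
    ``adas_decline_per_cdr`` score units per unit CDR slope).  Visit noise
    is Gaussian, inflated by ``non_energetic_noise_factor`` for
    non-energetic subjects, and scores are clipped to their ranges.
    """
    if config is None:
        config = GeneratorConfig()
    if interval <= 0 or horizon < interval:
        raise GeneratorError("need interval > 0 and horizon >= interval")
    if "true_state" not in cohort.columns or cohort["true_state"].isna().any():
        raise GeneratorError("every sample needs a true_state to generate visits")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    months = np.arange(interval, horizon + 1e-9, interval)
    sd = config.visit_noise_sd
    frames = []
    slopes = {}
    for _, row in cohort.iterrows():
        lo, hi = config.slope_ranges[row["true_state"]]
        slope = rng.uniform(lo, hi)
        slopes[row["id"]] = slope
        factor = 1.0 if row.get("energetic", 1) else config.non_energetic_noise_factor
        k = len(months)
        noise = {
            t: rng.normal(0.0, sd[t] * factor * noise_scale, k) for t in sd
        }
        cdr = np.clip(row["cdr_memory"] + slope * months + noise["cdr_memory"], 0, 3)
        mmse = np.clip(
            row["mmse_recall"] - config.mmse_decline_per_cdr * slope * months
            + noise["mmse_recall"], 0, 3,
        )
        adas = np.clip(
            row["adas_recall"] - config.adas_decline_per_cdr * slope * months
            + noise["adas_recall"], 0, 30,
        )
        frames.append(pd.DataFrame({
            "sample_id": row["id"], "months": months,
            "mmse_recall": mmse, "adas_recall": adas, "cdr_memory": cdr,
        }))
    visits = pd.concat(frames, ignore_index=True)
    if return_slopes:
        return visits, pd.Series(slopes, name="true_slope")
    return visits


# --------------------------------------------------------------------------
# phantom volumes


def _severity(sample, mild_fraction: float) -> float:
    if sample["true_state"] == HEALTHY:
        return 0.0
    if sample["triage_label"] == CERTAIN_IMPAIRED:
        return 1.0
    # impaired uncertain: the latent severity draw when available (cohort
    # rows carry it); a fixed mild fraction for hand-built samples
    try:
        sev = float(sample["latent_severity"])
    except (KeyError, IndexError, TypeError, ValueError):
        return mild_fraction
    return sev if np.isfinite(sev) else mild_fraction


def generate_volume(
    sample, atlas: RoiAtlas, config: GeneratorConfig, seed
) -> BrainVolume:
    """Render one phantom SUV volume for a cohort row.

    ``sample`` is a cohort row (mapping with ``triage_label``,
    ``true_state`` and ``energetic``).  ``seed`` drives only this volume's
    noise, so volumes are independently reproducible.
    """
    vp = config.volume_params
    if atlas.labels.shape != (vp.grid_edge,) * 3:
        raise GeneratorError(
            f"atlas grid {atlas.labels.shape} does not match configured "
            f"edge {vp.grid_edge}"
        )
    sev = _severity(sample, vp.mild_fraction)
    non_energetic = 1.0 - float(sample["energetic"])

    data = np.full(atlas.labels.shape, vp.baseline, dtype=np.float64)
    ad = atlas.pattern_mask(AD_PATTERN)
    dep = atlas.pattern_mask(DEPRESSION_PATTERN)
    data *= 1.0 - vp.delta_ad * sev * ad
    data *= 1.0 - vp.delta_dep * non_energetic * dep
    data[atlas.roi_mask("pons")] = vp.pons_intensity
    if vp.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, vp.noise_sd, data.shape)
    data = np.clip(data, 0.0, None).astype(np.float32)
    return BrainVolume(data=data, voxel_mm=vp.voxel_mm, mask=atlas.brain_mask)


def volumes_for_cohort(
    cohort: pd.DataFrame,
    atlas: RoiAtlas,
    config: GeneratorConfig,
    seed: int,
    fwhm_mm: float = 8.0,
    prepared: bool = True,
) -> np.ndarray:
    """Render one volume per cohort row, optionally fully preprocessed.

    With ``prepared=True`` each volume is pons-normalised to SUVr,
    smoothed, and zeroed outside the brain mask — the input format of the
    classifier.  Returns a float32 array of shape (n, edge, edge, edge).
    """
    pons = atlas.roi_mask("pons")
    out = np.empty((len(cohort),) + atlas.labels.shape, dtype=np.float32)
    for i, (_, row) in enumerate(cohort.iterrows()):
        vol = generate_volume(row, atlas, config, seed=[seed, i])
        if prepared:
            vol = suv_to_suvr(vol, pons)
            vol = smooth(vol, fwhm_mm)
            out[i] = np.where(atlas.brain_mask, vol.data, 0.0)
        else:
            out[i] = vol.data
    return out


def masked_feature_matrix(volumes: np.ndarray, atlas: RoiAtlas) -> np.ndarray:
    """Stack in-mask voxel vectors (one row per volume) for baseline models."""
    rows = []
    for vol in volumes:
        vec, _ = apply_mask(
            BrainVolume(data=vol, voxel_mm=atlas.voxel_mm, mask=atlas.brain_mask)
        )
        rows.append(vec)
    return np.asarray(rows)
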