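"""Synthetic cohorts with the covariate structure the analysis assumes.

Every non-gross value is generated from the additive model the downstream
harmonization and inference stages posit:

    value = baseline_region
            + group_effect * I(patient)
            + age_slope * age
            + gender_offset * I(male)
            + scanner_shift
            + scanner_scale * eps,     eps ~ Normal(0, noise_sd^2)

Scanner shifts are specified in standardized units (multiples of the
measure's noise SD) so the same config field is meaningful across measures.
Gross volumes are generated hierarchically: a hemisphere total, split into
GM/WM/LV shares by a Dirichlet draw, so the cortical-volume normalization has
a well-defined denominator.  Regions are statistically independent given the
covariates — a documented simplification; real regional morphometrics are
spatially correlated.

The default cohort mirrors the study structure: 19 patients with a preserved
left hemisphere, 13 with a preserved right hemisphere, 51 controls, two
scanners with the study's per-group split, pediatric-to-young-adult ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import META_COLUMNS, TABLE_COLUMNS, validate_metadata, validate_table
from .vocab import CORTICAL_MEASURES, RegionVocabulary

# Per-measure defaults: baseline at the region-multiplier midpoint, residual
# noise SD, age slope (per year), male-minus-female offset.  Units are the
# measure's natural units (mm, mm^2, mm^3).
MEASURE_DEFAULTS: dict[str, dict[str, float]] = {
    "thickness": dict(baseline=2.55, noise_sd=0.12, age_slope=-0.012, gender_offset=0.02),
    "area": dict(baseline=2400.0, noise_sd=230.0, age_slope=8.0, gender_offset=190.0),
    "volume": dict(baseline=5600.0, noise_sd=540.0, age_slope=-14.0, gender_offset=420.0),
    "subcortical_volume": dict(baseline=3400.0, noise_sd=340.0, age_slope=-6.0, gender_offset=260.0),
}

# Hemisphere gross total (mm^3) and GM/WM/LV Dirichlet concentration.
GROSS_TOTAL_MEAN = 470_000.0
GROSS_TOTAL_SD = 32_000.0
GROSS_SHARES_ALPHA = (110.0, 86.0, 4.0)  # GM, WM, LV


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic case-control cohort.

    ``group_effects`` maps ``(region, measure)`` to the raw patient-minus-
    control effect in the measure's units; unlisted cells have zero effect
    (the null condition).  ``scanner_shift``/``scanner_scale`` give each
    scanner's additive effect (in units of the measure's noise SD) and
    multiplicative residual-scale factor.
    """

    n_patients_lh: int = 19  # preserved LH (right-hemisphere surgery)
    n_patients_rh: int = 13  # preserved RH (left-hemisphere surgery)
    n_controls: int = 51
    age_range: tuple[float, float] = (6.0, 25.0)
    gender_balance: float = 0.5
    scanners: tuple[str, ...] = ("verio", "prisma")
    # P(first scanner) per group: 36/51 controls, 13/32 patients on scanner 1
    scanner_assignment: dict[str, float] = field(
        default_factory=lambda: {"control": 36 / 51, "patient": 13 / 32}
    )
    scanner_shift: dict[str, float] = field(
        default_factory=lambda: {"verio": 0.0, "prisma": 0.5}
    )
    scanner_scale: dict[str, float] = field(
        default_factory=lambda: {"verio": 1.0, "prisma": 1.2}
    )
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)
    age_slopes: dict[str, float] = field(default_factory=dict)
    gender_offsets: dict[str, float] = field(default_factory=dict)
    ablation_fraction: dict[str, float] = field(
        default_factory=lambda: {"LH": 7 / 19, "RH": 2 / 13}
    )
    measures: tuple[str, ...] = ("thickness", "area", "volume", "subcortical_volume", "gross_volume")
    cortical_regions: tuple[str, ...] | None = None  # None -> full vocabulary
    subcortical_regions: tuple[str, ...] | None = None
    match_control_ages: bool = False  # resample patient ages with jitter for controls
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients_lh", "n_patients_rh", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for s, v in self.scanner_scale.items():
            if v <= 0:
                raise ValueError(f"scanner_scale[{s!r}] must be strictly positive")
        for m, v in self.noise_sd.items():
            if v < 0:
                raise ValueError(f"noise_sd[{m!r}] must be non-negative")
        if not (0.0 <= self.gender_balance <= 1.0):
            raise ValueError("gender_balance must be in [0, 1]")

    def param(self, measure: str, name: str) -> float:
        override = getattr(self, {"baseline": "baseline", "noise_sd": "noise_sd",
                                  "age_slope": "age_slopes", "gender_offset": "gender_offsets"}[name])
        if measure in override:
            return override[measure]
        return MEASURE_DEFAULTS[measure][name]


def _region_multipliers(n: int) -> np.ndarray:
    """Deterministic per-region baseline spread (0.6x .. 1.4x)."""
    if n == 1:
        return np.ones(1)
    return np.linspace(0.6, 1.4, n)


def generate_cohort(
    config: CohortConfig, vocab: RegionVocabulary | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; deterministic given ``config.seed``.

    Returns ``(table, meta)``: a long-format morphometric table and a
    metadata frame, both validated.  Patients carry records only for their
    preserved hemisphere; controls for both.
    """
    vocab = vocab or RegionVocabulary()
    cortical = tuple(config.cortical_regions or vocab.cortical)
    subcortical = tuple(config.subcortical_regions or vocab.subcortical)
    rng = np.random.default_rng(config.seed)

    rows_meta: list[dict] = []
    groups = (
        [("patient", "LH")] * config.n_patients_lh
        + [("patient", "RH")] * config.n_patients_rh
        + [("control", "both")] * config.n_controls
    )
    width = len(str(len(groups)))
    pat_ages: list[float] = []
    for i, (grp, hemi) in enumerate(groups):
        prefix = {"LH": "pl", "RH": "pr", "both": "c"}[hemi]
        sid = f"{prefix}{i + 1:0{width}d}"
        if grp == "control" and config.match_control_ages and pat_ages:
            age = float(np.clip(rng.choice(pat_ages) + rng.normal(0.0, 1.0), *config.age_range))
        else:
            age = float(rng.uniform(*config.age_range))
        if grp == "patient":
            pat_ages.append(age)
        gender = "M" if rng.random() < config.gender_balance else "F"
        p_first = config.scanner_assignment[grp]
        scanner = config.scanners[0] if rng.random() < p_first else config.scanners[-1]
        if grp == "patient":
            procedure = "ablation" if rng.random() < config.ablation_fraction[hemi] else "resection"
            ilae = "high" if rng.random() < 0.5 else "low"
        else:
            procedure, ilae = "none", "none"
        rows_meta.append(
            dict(subject_id=sid, group=grp, age=round(age, 2), gender=gender, scanner=scanner,
                 preserved_hemisphere=hemi, procedure=procedure, ilae_binned=ilae)
        )
    meta = pd.DataFrame(rows_meta, columns=META_COLUMNS)
    validate_metadata(meta)

    is_pat = (meta["group"] == "patient").to_numpy(float)
    is_male = (meta["gender"] == "M").to_numpy(float)
    ages = meta["age"].to_numpy(float)
    shift = meta["scanner"].map(config.scanner_shift).to_numpy(float)
    scale = meta["scanner"].map(config.scanner_scale).to_numpy(float)
    # rows a subject contributes: preserved hemisphere, or both for controls
    hemi_of = {
        sid: (["LH", "RH"] if h == "both" else [h])
        for sid, h in zip(meta["subject_id"], meta["preserved_hemisphere"])
    }

    frames: list[pd.DataFrame] = []
    n_sub = len(meta)

    def block_frame(measure: str, regions: tuple[str, ...], vals: np.ndarray, hemi: str) -> pd.DataFrame:
        keep = np.array([hemi in hemi_of[sid] for sid in meta["subject_id"]])
        sids = meta["subject_id"].to_numpy()[keep]
        v = vals[keep]
        return pd.DataFrame(
            {
                "subject_id": np.repeat(sids, len(regions)),
                "hemisphere": hemi,
                "region": np.tile(regions, len(sids)),
                "measure": measure,
                "value": v.ravel(),
            }
        )

    for measure in config.measures:
        if measure == "gross_volume":
            continue
        regions = cortical if measure in CORTICAL_MEASURES else subcortical
        base = config.param(measure, "baseline") * _region_multipliers(len(regions))
        sd = config.param(measure, "noise_sd")
        a = config.param(measure, "age_slope")
        g = config.param(measure, "gender_offset")
        eff = np.array([config.group_effects.get((r, measure), 0.0) for r in regions])
        for hemi in ("LH", "RH"):
            eps = rng.normal(0.0, sd, size=(n_sub, len(regions)))
            vals = (
                base[None, :]
                + eff[None, :] * is_pat[:, None]
                + a * ages[:, None]
                + g * is_male[:, None]
                + (shift * sd)[:, None]
                + scale[:, None] * eps
            )
            frames.append(block_frame(measure, regions, np.clip(vals, 0.0, None), hemi))

    if "gross_volume" in config.measures:
        age_mid = float(np.mean(config.age_range))
        for hemi in ("LH", "RH"):
            totals = (
                GROSS_TOTAL_MEAN
                + 1500.0 * (ages - age_mid)
                + 22_000.0 * is_male
                + rng.normal(0.0, GROSS_TOTAL_SD, n_sub) * scale
                + shift * GROSS_TOTAL_SD * 0.1
            )
            shares = rng.dirichlet(GROSS_SHARES_ALPHA, size=n_sub)
            comps = totals[:, None] * shares  # GM, WM, LV
            for k, gross in enumerate(("GM", "WM", "LV")):
                e = config.group_effects.get((gross, "gross_volume"), 0.0)
                comps[:, k] = np.clip(comps[:, k] + e * is_pat, 1.0, None)
            frames.append(block_frame("gross_volume", ("GM", "WM", "LV"), comps, hemi))

    table = pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]
    table = table.sort_values(TABLE_COLUMNS[:4], kind="mergesort").reset_index(drop=True)
    validate_table(table)
    return table, meta


def null_config(**overrides) -> CohortConfig:
    """A cohort with no group effect anywhere (all other structure intact)."""
    return CohortConfig(**overrides)
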