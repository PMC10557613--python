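"""End-to-end study orchestration.

``run_study`` takes a morphometric table plus metadata and produces, per
group contrast and measure family: a univariate permutation-GLM table
(group beta, raw p, BH-adjusted q within the family, BIC Bayes factor per
region), a forward logistic selection path, plus a demographic matching
report and seizure-outcome (ILAE) selection models for the patients.

Contrasts compare the preserved hemisphere of a patient group to the same
hemisphere of the controls, or the two patient groups to each other (each
contributing its preserved hemisphere).  The default three contrasts are
preserved-LH patients vs controls' LH, preserved-RH patients vs controls'
RH, and preserved-LH vs preserved-RH patients.

Preprocessing runs in the configurable order harmonize -> winsorize ->
normalize by default; harmonization is skipped automatically for
single-scanner tables (where it is the identity anyway).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PermutationGLMTester
from .io import validate_metadata, validate_table
from .matching import matching_report
from .preprocess import harmonize_table, normalize_csa, normalize_cv, winsorize_table
from .selection import ForwardLogisticSelector
from .vocab import RegionVocabulary

GROUP_SPECS = ("patient_lh", "patient_rh", "control_lh", "control_rh")

DEFAULT_CONTRASTS = (
    ("patient_lh", "control_lh"),
    ("patient_rh", "control_rh"),
    ("patient_lh", "patient_rh"),
)


@dataclass
class StudyConfig:
    """Configuration of one full analysis run."""

    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    measure_families: tuple[str, ...] = (
        "gross_volume", "thickness", "area", "volume", "subcortical_volume",
    )
    n_perm: int = 1000
    alpha: float = 0.05
    tie_rule: str = "strict"
    preprocess_order: tuple[str, ...] = ("harmonize", "winsorize", "normalize")
    winsor_limits: tuple[float, float] = (5.0, 95.0)
    harmonize: str = "auto"  # 'auto' | 'always' | 'never'
    subset_filters: dict = field(default_factory=dict)  # column -> allowed value(s)
    run_selection: bool = True
    run_ilae: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        for key in ("measure_families", "preprocess_order"):
            if key in d:
                d[key] = tuple(d[key])
        if "winsor_limits" in d:
            d["winsor_limits"] = tuple(d["winsor_limits"])
        return cls(**d)


def _select_group(spec: str, meta: pd.DataFrame) -> tuple[pd.Index, str]:
    """Subjects matching a group spec and the hemisphere they contribute."""
    if spec not in GROUP_SPECS:
        raise ValueError(f"unknown group spec {spec!r}; expected one of {GROUP_SPECS}")
    kind, hemi = spec.rsplit("_", 1)
    hemi = hemi.upper()
    if kind == "patient":
        sel = meta[(meta["group"] == "patient") & (meta["preserved_hemisphere"] == hemi)]
    else:
        sel = meta[meta["group"] == "control"]
    return sel["subject_id"], hemi


def _wide_block(
    table: pd.DataFrame, measure: str, subjects: pd.Index, hemi: str
) -> pd.DataFrame:
    block = table[
        (table["measure"] == measure)
        & (table["hemisphere"] == hemi)
        & (table["subject_id"].isin(subjects))
    ]
    return block.pivot(index="subject_id", columns="region", values="value")


def preprocess_table(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    config: StudyConfig,
    vocab: RegionVocabulary | None = None,
) -> pd.DataFrame:
    """Run the configured preprocessing stages in order."""
    vocab = vocab or RegionVocabulary()
    out = table
    for stage in config.preprocess_order:
        if stage == "harmonize":
            n_scanners = meta["scanner"].nunique()
            if config.harmonize == "always" or (config.harmonize == "auto" and n_scanners > 1):
                out = harmonize_table(out, meta, vocab)
        elif stage == "winsorize":
            out = winsorize_table(out, meta, *config.winsor_limits)
        elif stage == "normalize":
            if (out["measure"] == "area").any():
                present = tuple(sorted(set(out.loc[out["measure"] == "area", "region"])))
                out = normalize_csa(out, vocab, regions=present)
            if (out["measure"] == "volume").any() and (out["measure"] == "gross_volume").any():
                out = normalize_cv(out, vocab)
        else:
            raise ValueError(f"unknown preprocessing stage {stage!r}")
    return out


def _apply_filters(meta: pd.DataFrame, filters: dict) -> pd.DataFrame:
    out = meta
    for col, allowed in filters.items():
        if col not in meta.columns:
            raise ValueError(f"subset filter on unknown column {col!r}")
        allowed = [allowed] if np.isscalar(allowed) else list(allowed)
        # controls (procedure/ilae 'none') are never dropped by patient filters
        keep = out[col].isin(allowed) | (out["group"] == "control")
        out = out[keep]
        if out.empty:
            raise ValueError(f"subset filter {col}={allowed} removed every subject")
    return out


def run_study(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    config: StudyConfig | None = None,
    vocab: RegionVocabulary | None = None,
) -> dict:
    """Run the full analysis; returns a dict of tidy result DataFrames.

    Keys: ``univariate``, ``selection``, ``ilae``, ``matching``, ``config``.
    Deterministic given the config seed: each (contrast, family) univariate
    block draws from its own substream derived from ``config.seed``.
    """
    config = config or StudyConfig()
    vocab = vocab or RegionVocabulary()
    validate_table(table, vocab)
    validate_metadata(meta)
    missing_meta = set(table["subject_id"]) - set(meta["subject_id"])
    if missing_meta:
        raise ValueError(f"subjects without metadata: {sorted(missing_meta)[:5]}")
    for a, b in config.contrasts:
        if a == b:
            raise ValueError(f"contrast compares group {a!r} with itself")

    meta = _apply_filters(meta, config.subset_filters)
    table = table[table["subject_id"].isin(meta["subject_id"])]

    processed = preprocess_table(table, meta, config, vocab)

    uni_rows = []
    sel_rows = []
    tasks = [
        (contrast, family)
        for contrast in config.contrasts
        for family in config.measure_families
        if (processed["measure"] == family).any()
    ]
    m_idx = meta.set_index("subject_id")
    for i, ((spec_a, spec_b), family) in enumerate(tasks):
        subj_a, hemi_a = _select_group(spec_a, meta)
        subj_b, hemi_b = _select_group(spec_b, meta)
        if len(subj_a) == 0 or len(subj_b) == 0:
            raise ValueError(
                f"contrast {spec_a} vs {spec_b}: empty group after filters "
                f"{config.subset_filters or '{}'}"
            )
        wa = _wide_block(processed, family, subj_a, hemi_a)
        wb = _wide_block(processed, family, subj_b, hemi_b)
        if set(wa.index) & set(wb.index):
            raise ValueError(f"contrast {spec_a} vs {spec_b}: groups share subjects")
        wide = pd.concat([wa, wb]).dropna(axis=0)  # listwise deletion
        in_a = set(wa.index)
        group = np.array([1.0 if s in in_a else 0.0 for s in wide.index])
        sub = m_idx.loc[wide.index]
        cov = np.column_stack(
            [sub["age"].to_numpy(float), (sub["gender"] == "M").to_numpy(float)]
        )
        seed_j = int(np.random.SeedSequence(config.seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        tester = PermutationGLMTester(
            n_perm=config.n_perm, alpha=config.alpha,
            tie_rule=config.tie_rule, random_state=seed_j,
        ).fit(wide, group, covariates=cov)
        res = tester.results_.copy()
        res.insert(0, "contrast", f"{spec_a}_vs_{spec_b}")
        res.insert(1, "measure", family)
        res["seed"] = seed_j
        uni_rows.append(res)

        if config.run_selection:
            sel = ForwardLogisticSelector(entry_alpha=config.alpha).fit(wide, group)
            path = sel.path_.copy()
            path.insert(0, "outcome", "group_membership")
            path.insert(1, "contrast", f"{spec_a}_vs_{spec_b}")
            path.insert(2, "measure", family)
            sel_rows.append(path)

    ilae_rows = []
    if config.run_ilae:
        pats = meta[(meta["group"] == "patient") & (meta["ilae_binned"] != "none")]
        if pats["ilae_binned"].nunique() == 2:
            for family in config.measure_families:
                if not (processed["measure"] == family).any():
                    continue
                blocks = []
                for hemi in ("LH", "RH"):
                    ids = pats.loc[pats["preserved_hemisphere"] == hemi, "subject_id"]
                    if len(ids):
                        blocks.append(_wide_block(processed, family, ids, hemi))
                wide = pd.concat(blocks).dropna(axis=0)
                y = (m_idx.loc[wide.index, "ilae_binned"] == "high").astype(int).to_numpy()
                if len(np.unique(y)) < 2:
                    continue
                sel = ForwardLogisticSelector(entry_alpha=config.alpha).fit(wide, y)
                path = sel.path_.copy()
                path.insert(0, "outcome", "ilae_bin")
                path.insert(1, "contrast", "patients_pooled")
                path.insert(2, "measure", family)
                ilae_rows.append(path)

    empty_sel = pd.DataFrame(
        columns=["outcome", "contrast", "measure", "step", "predictor",
                 "entry_p", "r2_cumulative", "separated"]
    )

    def _concat(frames: list[pd.DataFrame], empty: pd.DataFrame) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else empty.copy()

    return {
        "univariate": _concat(uni_rows, pd.DataFrame()),
        "selection": _concat(sel_rows, empty_sel),
        "ilae": _concat(ilae_rows, empty_sel),
        "matching": matching_report(meta),
        "config": asdict(config),
    }


def write_study(result: dict, outdir: str | Path) -> list[Path]:
    """Write every result table (and the config echo) as tidy files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("univariate", "selection", "ilae", "matching"):
        path = outdir / f"{name}.csv"
        result[name].to_csv(path, index=False)
        written.append(path)
    cfg = outdir / "config.json"
    cfg.write_text(json.dumps(result["config"], indent=2, sort_keys=True, default=list) + "\n")
    written.append(cfg)
    return written
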