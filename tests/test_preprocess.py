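"""Harmonization, winsorization, and CSA/CV normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemimorph import (
    CohortConfig,
    MorphoValidationError,
    RegionVocabulary,
    ScannerHarmonizer,
    Winsorizer,
    generate_cohort,
    harmonize_table,
    normalize_csa,
    normalize_cv,
    winsorize,
    winsorize_table,
)

from conftest import make_tidy


def _covariates(rng, n):
    return np.column_stack(
        [rng.integers(0, 2, n), rng.uniform(8, 24, n), rng.integers(0, 2, n)]
    )


# --------------------------------------------------------------------- harmonizer


def test_single_scanner_is_identity(rng):
    n = 60
    cov = _covariates(rng, n)
    X = 2.5 + 0.3 * cov[:, [0]] - 0.01 * cov[:, [1]] + rng.normal(0, 0.2, (n, 3))
    scanner = np.repeat("verio", n)
    h = ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)
    assert np.allclose(h.gamma_, 0.0, atol=1e-12)
    assert np.allclose(h.delta_, 1.0)
    out = h.transform(X, scanner=scanner, covariates=cov)
    assert np.allclose(out, X, atol=1e-9)


def _two_scanner_cohort(n_per, shift_sd, scale, seed):
    cfg = CohortConfig(
        seed=seed,
        n_patients_lh=n_per,
        n_patients_rh=1,
        n_controls=n_per,
        cortical_regions=("precentral",),
        measures=("thickness",),
        scanner_assignment={"control": 0.5, "patient": 0.5},
        scanner_shift={"verio": 0.0, "prisma": shift_sd},
        scanner_scale={"verio": 1.0, "prisma": scale},
        group_effects={("precentral", "thickness"): -0.15},
    )
    table, meta = generate_cohort(cfg)
    lh = table[table["hemisphere"] == "LH"]
    wide = lh.pivot(index="subject_id", columns="region", values="value")
    sub = meta.set_index("subject_id").loc[wide.index]
    cov = np.column_stack(
        [
            (sub["group"] == "patient").to_numpy(float),
            sub["age"].to_numpy(float),
            (sub["gender"] == "M").to_numpy(float),
        ]
    )
    return wide.to_numpy(), sub["scanner"].to_numpy(), cov, sub, table, meta


def test_recovers_additive_shift():
    """Mean recovered shift over replicate cohorts matches the injection."""
    shifts = []
    for seed in range(21, 26):
        X, scanner, cov, *_ = _two_scanner_cohort(200, 1.0, 1.0, seed=seed)
        h = ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)
        shifts.append(h.shift_between("verio", "prisma")[0])
    assert np.mean(shifts) == pytest.approx(1.0, abs=0.1)


def test_recovers_multiplicative_scale():
    """Mean recovered scale ratio over replicate cohorts matches the injection."""
    scales = []
    for seed in range(21, 26):
        X, scanner, cov, *_ = _two_scanner_cohort(200, 0.0, 2.0, seed=seed)
        h = ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)
        scales.append(h.scale_between("verio", "prisma")[0])
    assert np.mean(scales) == pytest.approx(2.0, abs=0.15)


def test_harmonized_residual_means_agree_across_scanners():
    X, scanner, cov, *_ = _two_scanner_cohort(200, 1.0, 1.5, seed=23)
    h = ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)
    out = h.fit_transform(X, scanner=scanner, covariates=cov)
    D = np.column_stack([np.ones(len(out)), cov])
    resid = out - D @ np.linalg.lstsq(D, out, rcond=None)[0]
    means = [resid[scanner == s].mean() for s in ("verio", "prisma")]
    sds = [resid[scanner == s].std() for s in ("verio", "prisma")]
    assert abs(means[0] - means[1]) < 0.02
    assert sds[1] / sds[0] == pytest.approx(1.0, abs=0.1)


def test_group_effect_preserved_after_harmonization():
    X, scanner, cov, sub, table, meta = _two_scanner_cohort(200, 1.0, 1.5, seed=24)
    harmonized = harmonize_table(table, meta)
    lh = harmonized[harmonized["hemisphere"] == "LH"].merge(meta, on="subject_id")
    lh = lh[lh["preserved_hemisphere"].isin(["LH", "both"])]
    # regress out age/gender-free raw group difference pre vs post
    raw = table[table["hemisphere"] == "LH"].merge(meta, on="subject_id")
    raw = raw[raw["preserved_hemisphere"].isin(["LH", "both"])]

    def gdiff(df):
        g = df.groupby("group")["value"].mean()
        return g["patient"] - g["control"]

    assert gdiff(lh) == pytest.approx(gdiff(raw), rel=0.10)


def test_too_few_subjects_per_scanner_errors(rng):
    X = rng.normal(size=(5, 2))
    cov = _covariates(rng, 5)
    scanner = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(ValueError, match="'b'"):
        ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)


def test_unseen_scanner_errors(rng):
    X = rng.normal(size=(20, 2))
    cov = _covariates(rng, 20)
    scanner = np.repeat("a", 20)
    h = ScannerHarmonizer().fit(X, scanner=scanner, covariates=cov)
    with pytest.raises(KeyError, match="b"):
        h.transform(X, scanner=np.repeat("b", 20), covariates=cov)


# --------------------------------------------------------------------- winsorizer


def test_constant_vector_unchanged():
    x = np.full(10, 3.3)
    assert np.array_equal(winsorize(x), x)


def test_hand_computed_percentiles_1_to_20():
    x = np.arange(1.0, 21.0)
    out = winsorize(x, 5, 95)
    # linear-interpolation percentiles of 1..20: P5 = 1.95, P95 = 19.05
    assert out.min() == pytest.approx(np.percentile(x, 5))
    assert out.min() == pytest.approx(1.95)
    assert out.max() == pytest.approx(19.05)
    # interior values untouched, order preserved
    assert np.all(np.diff(out) >= 0)
    assert out[10] == x[10]


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=80),
    st.integers(0, 40),
    st.integers(60, 100),
)
def test_winsorize_bounded_and_idempotent(values, lo, hi):
    x = np.array(values)
    w = Winsorizer(lo, hi).fit(x.reshape(-1, 1))
    out = w.transform(x.reshape(-1, 1))
    assert out.min() >= np.percentile(x, lo) - 1e-9
    assert out.max() <= np.percentile(x, hi) + 1e-9
    assert np.array_equal(w.transform(out), out)  # idempotent under same bounds


def test_empty_stratum_errors():
    with pytest.raises(ValueError, match="empty"):
        Winsorizer().fit(np.empty((0, 1)))


def test_table_winsorization_stratified_by_group_and_hemisphere(small_cohort):
    table, meta = small_cohort
    out = winsorize_table(table, meta)
    assert len(out) == len(table)
    df = (
        out.merge(meta[["subject_id", "group"]], on="subject_id")
        .set_index(["group", "hemisphere", "region", "measure"])
        .sort_index()
    )
    src = table.merge(meta[["subject_id", "group"]], on="subject_id")
    for keys, block in src.groupby(["group", "hemisphere", "region", "measure"]):
        lo, hi = np.percentile(block["value"], [5, 95])
        got = df.loc[keys, "value"]
        assert got.min() >= lo - 1e-9 and got.max() <= hi + 1e-9


# ------------------------------------------------------------------ normalization


def _area_table(values, regions=None):
    vocab = RegionVocabulary()
    regions = regions or vocab.cortical
    return make_tidy([("s1", "LH", r, "area", v) for r, v in zip(regions, values)])


def test_equal_areas_normalize_to_one():
    t = _area_table(np.full(34, 1234.5))
    out = normalize_csa(t)
    assert np.allclose(out["value"], 1.0)


def test_normalized_areas_sum_to_34_and_scale_invariant(rng):
    vals = rng.uniform(500, 5000, 34)
    out1 = normalize_csa(_area_table(vals))
    out2 = normalize_csa(_area_table(2.0 * vals))
    assert out1["value"].sum() == pytest.approx(34.0)
    assert np.allclose(out1["value"], out2["value"])


def test_missing_area_region_errors():
    t = _area_table(np.full(33, 100.0), regions=RegionVocabulary().cortical[:33])
    with pytest.raises(MorphoValidationError, match="insula"):
        normalize_csa(t)


def test_cv_normalization_arithmetic():
    t = make_tidy(
        [
            ("s1", "LH", "precentral", "volume", 5000.0),
            ("s1", "LH", "GM", "gross_volume", 250000.0),
            ("s1", "LH", "WM", "gross_volume", 245000.0),
            ("s1", "LH", "LV", "gross_volume", 5000.0),
        ]
    )
    out = normalize_cv(t)
    got = out[out["measure"] == "volume"]["value"].item()
    assert got == pytest.approx(100.0 * 5000.0 / 500000.0)  # 1.0%


def test_cv_missing_gross_errors():
    t = make_tidy(
        [
            ("s1", "LH", "precentral", "volume", 5000.0),
            ("s1", "LH", "GM", "gross_volume", 250000.0),
        ]
    )
    with pytest.raises(MorphoValidationError, match="gross"):
        normalize_cv(t)


def test_thickness_passes_through_normalization(small_cohort):
    table, _ = small_cohort
    present = tuple(sorted(set(table.loc[table["measure"] == "area", "region"])))
    out = normalize_cv(normalize_csa(table, regions=present))
    thick_in = table[table["measure"] == "thickness"].reset_index(drop=True)
    thick_out = out[out["measure"] == "thickness"].reset_index(drop=True)
    pd.testing.assert_frame_equal(thick_in, thick_out)
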