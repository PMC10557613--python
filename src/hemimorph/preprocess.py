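"""Scanner harmonization, winsorization, and CSA/CV normalization.

The three preprocessing stages applied before inference:

* :class:`ScannerHarmonizer` removes per-scanner additive (location) and
  multiplicative (scale) effects from each feature while preserving the
  covariate structure (group, age, gender).
* :class:`Winsorizer` clips each feature to its 5th..95th percentiles; the
  table-level :func:`winsorize_table` applies it separately for patients and
  controls, by hemisphere, per region-measure.
* :func:`normalize_csa` divides each cortical surface area by the subject-
  hemisphere's mean regional area; :func:`normalize_cv` expresses each
  cortical volume as a percentage of the hemisphere total (GM + WM + LV).
  Cortical thickness is never normalized.

The estimators follow the scikit-learn fit/transform contract and operate on
(n_subjects, n_features) arrays; the ``*_table`` helpers adapt them to the
long-format morphometric table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .io import TABLE_COLUMNS, MorphoValidationError
from .vocab import RegionVocabulary


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be a 1-D or 2-D array")
    return X


class ScannerHarmonizer(TransformerMixin, BaseEstimator):
    """Location/scale harmonization across scanners, preserving covariates.

    Per feature, the data are modelled as a linear combination of the
    covariates of interest (group, age, gender) and scanner::

        x = b0 + b1*group + b2*age + b3*gender + c_s + delta_s * e

    fit by least squares with scanner indicator columns (first scanner as
    reference).  The scanner coefficient ``c_s`` is the additive effect;
    the multiplicative effect ``delta_s`` is the ratio of the within-scanner
    residual SD to the pooled residual SD.  Modelling scanner explicitly
    keeps the additive effect identified even when scanner assignment is
    correlated with group — the situation the explicit scanner term exists
    for.  ``transform`` subtracts ``c_s``, rescales residuals by
    ``1/delta_s``, and re-adds the covariate structure.

    With a single scanner the model is the identity (gamma=0, delta=1) up to
    floating point.

    Parameters
    ----------
    min_per_scanner : minimum subjects required per scanner at fit time.

    Attributes
    ----------
    coef_ : (1+n_covariates, n_features) covariate coefficients (intercept first).
    scanners_ : fitted scanner labels (first is the reference).
    shift_raw_ : (n_scanners, n_features) additive effects c_s in data units.
    gamma_ : c_s standardized by the pooled residual SD.
    delta_ : (n_scanners, n_features) residual scale relative to pooled.
    pooled_sd_ : (n_features,) pooled residual SD.
    """

    def __init__(self, min_per_scanner: int = 2):
        self.min_per_scanner = min_per_scanner

    def _cov_design(self, covariates, n: int) -> np.ndarray:
        C = _as_2d(covariates)
        if C.shape[0] != n:
            raise ValueError("covariates and X have different numbers of rows")
        return np.column_stack([np.ones(n), C])

    def fit(self, X, y=None, *, scanner, covariates):
        X = _as_2d(X)
        scanner = np.asarray(scanner)
        n = X.shape[0]
        D_cov = self._cov_design(covariates, n)
        labels, counts = np.unique(scanner, return_counts=True)
        for lab, cnt in zip(labels, counts):
            if cnt < self.min_per_scanner:
                raise ValueError(
                    f"scanner {lab!r} has only {cnt} subjects "
                    f"(need >= {self.min_per_scanner})"
                )
        dummies = np.column_stack(
            [(scanner == lab).astype(float) for lab in labels[1:]]
        ) if len(labels) > 1 else np.empty((n, 0))
        D = np.column_stack([D_cov, dummies])
        coef, *_ = np.linalg.lstsq(D, X, rcond=None)
        k_cov = D_cov.shape[1]
        shift = np.vstack([np.zeros((1, X.shape[1])), coef[k_cov:]])  # ref row 0
        R = X - D @ coef
        pooled_sd = R.std(axis=0, ddof=1)
        if np.any(pooled_sd <= 0):
            raise ValueError("zero residual variance; cannot harmonize a constant feature")
        if len(labels) == 1:
            delta = np.ones((1, X.shape[1]))
        else:
            delta = np.stack(
                [R[scanner == lab].std(axis=0, ddof=1) for lab in labels]
            ) / pooled_sd
            if np.any(delta <= 0):
                raise ValueError("zero within-scanner residual variance")
        self.coef_ = coef[:k_cov]
        self.scanners_ = list(labels)
        self.shift_raw_ = shift
        self.gamma_ = shift / pooled_sd
        self.delta_ = delta
        self.pooled_sd_ = pooled_sd
        return self

    def transform(self, X, *, scanner, covariates):
        X = _as_2d(X)
        scanner = np.asarray(scanner)
        unseen = set(scanner) - set(self.scanners_)
        if unseen:
            raise KeyError(f"scanner(s) not seen at fit time: {sorted(unseen)}")
        D_cov = self._cov_design(covariates, X.shape[0])
        fitted = D_cov @ self.coef_
        idx = np.array([self.scanners_.index(s) for s in scanner])
        resid = (X - fitted - self.shift_raw_[idx]) / self.delta_[idx]
        return fitted + resid

    def fit_transform(self, X, y=None, *, scanner, covariates):
        return self.fit(X, scanner=scanner, covariates=covariates).transform(
            X, scanner=scanner, covariates=covariates
        )

    def shift_between(self, scanner_a: str, scanner_b: str, units: str = "reference") -> np.ndarray:
        """Estimated additive effect of b relative to a.

        ``units='raw'`` returns the effect in data units; ``'reference'``
        (default) standardizes by scanner a's residual SD, the natural scale
        when a is the unaffected reference; ``'pooled'`` by the pooled
        residual SD.
        """
        ia, ib = self.scanners_.index(scanner_a), self.scanners_.index(scanner_b)
        raw = self.shift_raw_[ib] - self.shift_raw_[ia]
        if units == "raw":
            return raw
        if units == "reference":
            return raw / (self.pooled_sd_ * self.delta_[ia])
        if units == "pooled":
            return raw / self.pooled_sd_
        raise ValueError("units must be 'raw', 'reference' or 'pooled'")

    def scale_between(self, scanner_a: str, scanner_b: str) -> np.ndarray:
        """Estimated multiplicative effect of b relative to a."""
        ia, ib = self.scanners_.index(scanner_a), self.scanners_.index(scanner_b)
        return self.delta_[ib] / self.delta_[ia]


class Winsorizer(TransformerMixin, BaseEstimator):
    """Clip each feature to learned lower/upper percentiles.

    Percentiles use linear interpolation between order statistics.  Fitting
    and transforming the same data replaces values above the upper and below
    the lower percentile with the percentile values; re-applying a fitted
    transform is idempotent.
    """

    def __init__(self, lower: float = 5.0, upper: float = 95.0):
        self.lower = lower
        self.upper = upper

    def fit(self, X, y=None):
        if not (0.0 <= self.lower < self.upper <= 100.0):
            raise ValueError("need 0 <= lower < upper <= 100")
        X = _as_2d(X)
        if X.shape[0] == 0:
            raise ValueError("cannot winsorize an empty stratum")
        self.lower_bounds_ = np.percentile(X, self.lower, axis=0, method="linear")
        self.upper_bounds_ = np.percentile(X, self.upper, axis=0, method="linear")
        return self

    def transform(self, X):
        X = _as_2d(X)
        return np.clip(X, self.lower_bounds_, self.upper_bounds_)


def winsorize(values, lower: float = 5.0, upper: float = 95.0) -> np.ndarray:
    """Winsorize a single vector in place of its own percentiles."""
    values = np.asarray(values, dtype=float)
    out = Winsorizer(lower, upper).fit_transform(values.reshape(-1, 1))
    return out.ravel()


def winsorize_table(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    lower: float = 5.0,
    upper: float = 95.0,
    split_patient_hemi: bool = False,
) -> pd.DataFrame:
    """Winsorize per (group, hemisphere, region, measure) stratum.

    Patients are pooled into one group regardless of preserved hemisphere
    unless ``split_patient_hemi`` is set, in which case LH- and RH-preserved
    patients form separate strata.
    """
    df = table.merge(meta[["subject_id", "group", "preserved_hemisphere"]], on="subject_id")
    if split_patient_hemi:
        df["stratum_group"] = np.where(
            df["group"] == "patient", "patient_" + df["preserved_hemisphere"], "control"
        )
    else:
        df["stratum_group"] = df["group"]
    keys = ["stratum_group", "hemisphere", "region", "measure"]
    df["value"] = df.groupby(keys, sort=False)["value"].transform(
        lambda v: winsorize(v.to_numpy(), lower, upper)
    )
    return df[TABLE_COLUMNS].sort_values(TABLE_COLUMNS[:4], kind="mergesort").reset_index(drop=True)


def harmonize_table(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    vocab: RegionVocabulary | None = None,
) -> pd.DataFrame:
    """Fit and apply :class:`ScannerHarmonizer` per (hemisphere, measure) block.

    Features are regions; covariates are group (patient=1), age, and gender
    (M=1).  Single-scanner tables pass through (identity model).
    """
    vocab = vocab or RegionVocabulary()
    m = meta.set_index("subject_id")
    out = []
    for (hemi, measure), block in table.groupby(["hemisphere", "measure"], sort=False):
        wide = block.pivot(index="subject_id", columns="region", values="value")
        sub = m.loc[wide.index]
        cov = np.column_stack(
            [
                (sub["group"] == "patient").to_numpy(float),
                sub["age"].to_numpy(float),
                (sub["gender"] == "M").to_numpy(float),
            ]
        )
        h = ScannerHarmonizer().fit(wide.to_numpy(), scanner=sub["scanner"].to_numpy(), covariates=cov)
        adj = h.transform(wide.to_numpy(), scanner=sub["scanner"].to_numpy(), covariates=cov)
        long = pd.DataFrame(adj, index=wide.index, columns=wide.columns).reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="value"
        )
        long["hemisphere"] = hemi
        long["measure"] = measure
        out.append(long[TABLE_COLUMNS])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(TABLE_COLUMNS[:4], kind="mergesort").reset_index(drop=True)


def fit_harmonization(table, meta, vocab=None):  # spec-level convenience
    """Fit one :class:`ScannerHarmonizer` per (hemisphere, measure) block."""
    vocab = vocab or RegionVocabulary()
    m = meta.set_index("subject_id")
    models = {}
    for (hemi, measure), block in table.groupby(["hemisphere", "measure"], sort=False):
        wide = block.pivot(index="subject_id", columns="region", values="value")
        sub = m.loc[wide.index]
        cov = np.column_stack(
            [
                (sub["group"] == "patient").to_numpy(float),
                sub["age"].to_numpy(float),
                (sub["gender"] == "M").to_numpy(float),
            ]
        )
        models[(hemi, measure)] = (
            ScannerHarmonizer().fit(wide.to_numpy(), scanner=sub["scanner"].to_numpy(), covariates=cov),
            list(wide.columns),
        )
    return models


def apply_harmonization(models, table, meta):
    """Apply fitted per-block harmonizers to a (possibly new) table."""
    m = meta.set_index("subject_id")
    out = []
    for (hemi, measure), block in table.groupby(["hemisphere", "measure"], sort=False):
        if (hemi, measure) not in models:
            raise KeyError(f"no harmonization model for block {(hemi, measure)}")
        model, regions = models[(hemi, measure)]
        wide = block.pivot(index="subject_id", columns="region", values="value")[regions]
        sub = m.loc[wide.index]
        cov = np.column_stack(
            [
                (sub["group"] == "patient").to_numpy(float),
                sub["age"].to_numpy(float),
                (sub["gender"] == "M").to_numpy(float),
            ]
        )
        adj = model.transform(wide.to_numpy(), scanner=sub["scanner"].to_numpy(), covariates=cov)
        long = pd.DataFrame(adj, index=wide.index, columns=regions).reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="value"
        )
        long["hemisphere"] = hemi
        long["measure"] = measure
        out.append(long[TABLE_COLUMNS])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(TABLE_COLUMNS[:4], kind="mergesort").reset_index(drop=True)


def normalize_csa(
    table: pd.DataFrame,
    vocab: RegionVocabulary | None = None,
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Divide each cortical area by the subject-hemisphere mean regional area.

    Requires the full cortical region set (all 34 by default; ``regions``
    narrows it for partial tables) for every subject-hemisphere that has any
    area value; after normalization the values average exactly 1.
    """
    vocab = vocab or RegionVocabulary()
    expected = set(regions) if regions is not None else set(vocab.cortical)
    df = table.copy()
    is_area = df["measure"] == "area"
    n_regions = len(expected)
    for (sid, hemi), block in df[is_area].groupby(["subject_id", "hemisphere"], sort=False):
        missing = expected - set(block["region"])
        if missing:
            raise MorphoValidationError(
                f"normalize_csa: {sid}/{hemi} missing areas for {sorted(missing)}"
            )
        if len(block) != n_regions:
            raise MorphoValidationError(f"normalize_csa: {sid}/{hemi} has extra area rows")
        df.loc[block.index, "value"] = block["value"] / block["value"].mean()
    return df


def normalize_cv(table: pd.DataFrame, vocab: RegionVocabulary | None = None) -> pd.DataFrame:
    """Express each cortical volume as % of hemisphere total (GM + WM + LV)."""
    vocab = vocab or RegionVocabulary()
    df = table.copy()
    gross = df[df["measure"] == "gross_volume"].pivot_table(
        index=["subject_id", "hemisphere"], columns="region", values="value"
    )
    is_vol = df["measure"] == "volume"
    for (sid, hemi), block in df[is_vol].groupby(["subject_id", "hemisphere"], sort=False):
        try:
            g = gross.loc[(sid, hemi)]
            total = float(g["GM"] + g["WM"] + g["LV"])
        except KeyError as exc:
            raise MorphoValidationError(
                f"normalize_cv: missing gross volumes for {sid}/{hemi}"
            ) from exc
        if not np.isfinite(total) or total <= 0:
            raise MorphoValidationError(f"normalize_cv: invalid hemisphere total for {sid}/{hemi}")
        df.loc[block.index, "value"] = 100.0 * block["value"] / total
    return df
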