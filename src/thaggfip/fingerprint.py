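"""Per-sample fingerprint assembly, encoding, correlations and elastic net.

The fingerprint table collects one row per light-chain sample and one
column per measured parameter: dimer fractions, melting temperatures under
several conditions, turbidity maximum, concentration slopes of Tm and
Tagg, aggregate size at 70 deg C, refolding categories, the folding free
energy dG(37 C), the m-value, protease digestibility, and whether amyloid
forms at acidic pH.  Some entries are ordered categories rather than
numbers, and some are missing.

For multivariate statistics the table is made fully numeric: refolding
extent by DSF maps small/medium/large to 0.33/0.50/0.66, refolding at 2 M
urea maps 0/<50/>50 to 0/1/2, remaining non-numeric cells become missing,
missing values are mean-imputed, and every column is standardised to zero
mean and unit variance.  Pairwise-complete Pearson and Spearman
correlation matrices and an elastic-net regression against a clinical
target (grid-searched with 4-fold cross-validation on negative mean
squared error) complete the analysis.  At fingerprint-study sample sizes
such models are exploratory: in-sample correlations of a cross-validation-
selected model are inflated (Freedman's paradox), so the summary reports
both the CV score and the in-sample correlation side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold

__all__ = [
    "REFOLD_DSF_SCALE",
    "REFOLD_UREA_SCALE",
    "DEFAULT_COLUMN_KINDS",
    "DEFAULT_ENET_FEATURES",
    "FingerprintTable",
    "EncodedMatrix",
    "CorrelationResult",
    "ElasticNetSummary",
    "encode_categoricals",
    "decode_categoricals",
    "correlation_matrices",
    "encode_matrix",
    "elastic_net_cv",
]

#: Refolding extent by DSF (no urea): ordered categories on an arbitrary
#: numeric scale.
REFOLD_DSF_SCALE = {"small": 0.33, "medium": 0.50, "large": 0.66}

#: Refolding at 2 M urea: ordered categorical scale.
REFOLD_UREA_SCALE = {"0": 0, "<50": 1, ">50": 2}

#: Column registry: parameter name -> kind ("numeric", one of the two
#: ordered-categorical scales, or "flag" for yes/no columns).
DEFAULT_COLUMN_KINDS: dict[str, str] = {
    "dimer_sds_page": "numeric",
    "dimer_ms": "numeric",
    "dimer_auc": "numeric",
    "tm_dsf_ph5": "numeric",
    "t_max_turb_ph5": "numeric",
    "tm_dsc_ph74": "numeric",
    "tm_dsf_ph74": "numeric",
    "dtm_dlogc_ph74": "numeric",
    "tagg_dsf_ph74": "numeric",
    "dtagg_dlogc_ph74": "numeric",
    "cumul_radius_70C": "numeric",
    "refold_dsf_no_urea": "refold_dsf",
    "refold_dsf_2M_urea": "refold_urea",
    "refold_dsc": "numeric",
    "dG_37C": "numeric",
    "m_value": "numeric",
    "digestibility_trypsin": "numeric",
    "acid_amyloid": "flag",
}

#: Feature subset used for the clinical elastic-net model; internally
#: highly correlated duplicates (e.g. three dimerisation assays) reduced
#: to one representative each.
DEFAULT_ENET_FEATURES = [
    "tm_dsf_ph5",
    "t_max_turb_ph5",
    "tm_dsc_ph74",
    "dtm_dlogc_ph74",
    "dtagg_dlogc_ph74",
    "cumul_radius_70C",
    "dimer_auc",
    "refold_dsc",
    "dG_37C",
    "digestibility_trypsin",
]

_FLAG_SCALE = {"no": 0, "yes": 1}
_SCALES = {
    "refold_dsf": REFOLD_DSF_SCALE,
    "refold_urea": REFOLD_UREA_SCALE,
    "flag": _FLAG_SCALE,
}


@dataclass
class FingerprintTable:
    """Samples x parameters table with a typed column registry."""

    data: pd.DataFrame
    column_kinds: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_KINDS))

    def __post_init__(self) -> None:
        unknown = set(self.data.columns) - set(self.column_kinds)
        if unknown:
            raise ValueError(f"columns missing from the registry: {sorted(unknown)}")

    def mask_values(self, exclusions: Mapping[str, Sequence[str]]) -> "FingerprintTable":
        """Blank listed (sample, column) cells, e.g. a dG value whose fit
        is unreliable for one sample; returns a new table."""
        df = self.data.copy()
        for sample, cols in exclusions.items():
            for col in cols:
                df.loc[sample, col] = np.nan
        return FingerprintTable(df, dict(self.column_kinds))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class EncodedMatrix:
    """Numeric matrix after encoding, mean imputation and standardisation."""

    values: np.ndarray
    columns: list[str]
    index: list[str]
    means: np.ndarray
    sds: np.ndarray
    imputed: np.ndarray  # boolean mask of imputed cells

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.columns)


def _encode_cell(value, scale: Mapping[str, float], column: str, row) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    key = str(value).strip().lower()
    table = {str(k).lower(): v for k, v in scale.items()}
    if key not in table:
        raise ValueError(
            f"unrecognised category {value!r} in column {column!r}, row {row!r}; "
            f"expected one of {sorted(scale)}"
        )
    return float(table[key])


def encode_categoricals(table: FingerprintTable) -> pd.DataFrame:
    """Replace categorical cells by their registered numeric codes.

    Numeric columns pass through (non-numeric tokens there become NaN,
    matching the treatment of qualitative entries such as ">1000" that
    carry no exact value).
    """
    df = table.data.copy()
    for col in df.columns:
        kind = table.column_kinds[col]
        if kind == "numeric":
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            scale = _SCALES[kind]
            df[col] = [
                _encode_cell(v, scale, col, idx) for idx, v in df[col].items()
            ]
    return df


def decode_categoricals(encoded: pd.DataFrame, column_kinds: Mapping[str, str]) -> pd.DataFrame:
    """Inverse of :func:`encode_categoricals` for the categorical columns."""
    df = encoded.copy()
    for col in df.columns:
        kind = column_kinds[col]
        if kind == "numeric":
            continue
        inverse = {v: k for k, v in _SCALES[kind].items()}
        df[col] = [inverse[v] if v in inverse else np.nan for v in df[col]]
    return df


@dataclass
class CorrelationResult:
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    pearson_psd: bool
    spearman_psd: bool


def _is_psd(mat: pd.DataFrame, tol: float = 1e-8) -> bool:
    m = mat.to_numpy(dtype=float)
    if np.isnan(m).any():
        return False
    eig = np.linalg.eigvalsh((m + m.T) / 2.0)
    return bool(eig.min() >= -tol)


def correlation_matrices(
    data: pd.DataFrame | FingerprintTable,
    min_pairs: int = 3,
) -> CorrelationResult:
    """Pairwise-complete Pearson and Spearman correlation matrices.

    Each entry uses all rows where both columns are observed; entries with
    fewer than ``min_pairs`` complete pairs are missing.  Pairwise deletion
    can make such matrices indefinite — the result carries a PSD flag so
    downstream use can detect this rather than proceed silently.
    """
    if isinstance(data, FingerprintTable):
        data = encode_categoricals(data)
    data = data.apply(pd.to_numeric, errors="coerce")
    pearson = data.corr(method="pearson", min_periods=min_pairs)
    spearman = data.corr(method="spearman", min_periods=min_pairs)
    return CorrelationResult(
        pearson=pearson,
        spearman=spearman,
        pearson_psd=_is_psd(pearson),
        spearman_psd=_is_psd(spearman),
    )


def encode_matrix(
    table: FingerprintTable | pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> EncodedMatrix:
    """Encode, mean-impute and standardise the table for model fitting.

    Missing values are set to the column mean before standardisation; each
    non-constant column then has mean 0 and SD 1 (population SD, so a
    rescaled raw column yields the identical encoded column).
    """
    df = encode_categoricals(table) if isinstance(table, FingerprintTable) else table.copy()
    if columns is not None:
        df = df[list(columns)]
    values = df.to_numpy(dtype=float)
    imputed = np.isnan(values)
    col_means = np.nanmean(values, axis=0)
    values = np.where(imputed, col_means[np.newaxis, :], values)
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    safe_sds = np.where(sds > 0, sds, 1.0)
    standardised = (values - means) / safe_sds
    return EncodedMatrix(
        values=standardised,
        columns=list(df.columns),
        index=[str(i) for i in df.index],
        means=means,
        sds=sds,
        imputed=imputed,
    )


@dataclass
class ElasticNetSummary:
    alpha: float
    l1_ratio: float
    coefficients: pd.Series
    nonzero: list[str]
    cv_score: float  # mean CV negative MSE of the selected model
    in_sample_r: float
    n_samples: int
    intercept: float = 0.0


def elastic_net_cv(
    matrix: EncodedMatrix | np.ndarray,
    target: Sequence[float],
    alpha_grid: Sequence[float] | None = None,
    l1_grid: Sequence[float] | None = None,
    seed: int = 0,
    folds: int = 4,
    feature_names: Sequence[str] | None = None,
) -> ElasticNetSummary:
    """Grid-searched elastic net predicting a clinical value per sample.

    4-fold cross-validation with negative mean squared error selects the
    penalty strength and L1/L2 mixing ratio; the winning model is refit on
    all samples (no held-out validation set — at these sample sizes one
    cannot be afforded, which is exactly why the in-sample correlation
    must be read next to the CV score).
    """
    if isinstance(matrix, EncodedMatrix):
        X = matrix.values
        names = list(matrix.columns)
    else:
        X = np.asarray(matrix, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
    y = np.asarray(target, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("target length must match the number of samples")
    if X.shape[0] < 8:
        raise ValueError("need at least 8 samples for 4-fold cross-validation")
    if np.std(y) == 0:
        raise ValueError("target is constant; nothing to model")
    if X.shape[0] < 3 * X.shape[1]:
        warnings.warn(
            f"only {X.shape[0]} samples for {X.shape[1]} features: model "
            "selection is prone to overfitting and Freedman's-paradox-style "
            "spurious support; treat the in-sample correlation as optimistic",
            stacklevel=2,
        )

    alpha_grid = (
        np.logspace(-2, 2, 10) if alpha_grid is None else np.asarray(alpha_grid)
    )
    l1_grid = np.linspace(0.1, 1.0, 10) if l1_grid is None else np.asarray(l1_grid)

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        ElasticNet(max_iter=50000, tol=1e-6),
        param_grid={"alpha": alpha_grid, "l1_ratio": l1_grid},
        scoring="neg_mean_squared_error",
        cv=cv,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    best = search.best_estimator_
    coef = pd.Series(best.coef_, index=names)
    pred = best.predict(X)
    if np.std(pred) > 0:
        r = float(stats.pearsonr(y, pred)[0])
    else:
        r = np.nan
    return ElasticNetSummary(
        alpha=float(search.best_params_["alpha"]),
        l1_ratio=float(search.best_params_["l1_ratio"]),
        coefficients=coef,
        nonzero=[n for n, c in coef.items() if abs(c) > 1e-10],
        cv_score=float(search.best_score_),
        in_sample_r=r,
        n_samples=int(X.shape[0]),
        intercept=float(best.intercept_),
    )
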