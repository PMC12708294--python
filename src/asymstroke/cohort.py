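"""Cohort data model, quality control and synthetic patient generator.

The codebook covers the 34 coded indicators: admission scales (ADL coded
PQ3, GCS coded PQ5, CDR, ASPECTS, mRS, HIS), infarct volume (VOL), lesion
location flags (affected hemisphere CE1, cerebellar / language-area /
Broca / Wernicke damage), admission biochemistry (including C-reactive
protein, BIOC4), postoperative labs and ASPECTS (PSQ3), glycated
haemoglobin (BIOC19), discharge mRS (PSQ6), and the language item-9
pre/post pair from which LANG is derived.

LANG is the postoperative minus preoperative item-9 score; LANG < 0 is
coded as improvement, everything else as non-improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    symbol: str | None
    kind: str  # continuous | integer | binary
    vmin: float | None = None
    vmax: float | None = None
    # per-sex generator parameters: (male, female) means/SDs or prevalences
    means: tuple[float, float] | None = None
    sds: tuple[float, float] | None = None
    prevalences: tuple[float, float] | None = None


def _cont(name, symbol, m_mean, m_sd, f_mean, f_sd, vmin=None, vmax=None, kind="continuous"):
    return ColumnSpec(name, symbol, kind, vmin, vmax, (m_mean, f_mean), (m_sd, f_sd))


def _bin(name, symbol, m_prev, f_prev):
    return ColumnSpec(name, symbol, "binary", 0, 1, prevalences=(m_prev, f_prev))


#: Indicator columns in reporting order (gender and the item-9 pair are
#: handled separately; LANG is derived).
CODEBOOK: tuple[ColumnSpec, ...] = (
    _cont("age", None, 69.39, 10.72, 73.51, 9.38, 18, 110, kind="integer"),
    _cont("adl", "PQ3", 20.69, 15.46, 20.24, 15.69, 0, 100, kind="integer"),
    _cont("gcs", "PQ5", 8.90, 2.22, 8.54, 2.58, 3, 15, kind="integer"),
    _cont("cdr", None, 8.88, 4.80, 9.37, 4.86, 0, 18, kind="integer"),
    _cont("aspects_admission", None, 9.58, 0.78, 9.60, 0.71, 0, 10, kind="integer"),
    _cont("mrs_admission", None, 4.35, 0.70, 4.33, 0.74, 0, 6, kind="integer"),
    _cont("his", None, 10.60, 2.05, 10.68, 2.35, 0, 18, kind="integer"),
    _cont("infarct_volume_ml", "VOL", 22.72, 6.65, 15.19, 6.36, 0, None),
    _bin("hemisphere_left", "CE1", 43 / 101, 23 / 63),
    _bin("cerebellar_damage", None, 26 / 101, 19 / 63),
    _bin("language_area_damage", None, 7 / 101, 3 / 63),
    _bin("broca_damage", None, 2 / 101, 0 / 63),
    _bin("wernicke_damage", None, 5 / 101, 3 / 63),
    _cont("potassium", None, 4.01, 0.42, 3.88, 0.48, 0, None),
    _cont("sodium", None, 137.08, 3.58, 137.36, 3.61, 0, None),
    _cont("chloride", None, 102.89, 3.33, 102.48, 4.20, 0, None),
    _cont("co2_binding", None, 26.01, 19.13, 23.91, 2.94, 0, None),
    _cont("neutrophils", None, 7.18, 8.83, 7.18, 4.08, 0, None),
    _cont("lymphocytes", None, 1.57, 1.61, 1.35, 0.69, 0, None),
    _cont("monocytes", None, 0.55, 0.44, 0.53, 0.47, 0, None),
    _cont("crp", "BIOC4", 11.83, 21.67, 12.79, 19.94, 0, None),
    _cont("inr", None, 1.13, 0.13, 1.13, 0.12, 0, None),
    _cont("d_dimer", None, 610.68, 1184.42, 436.51, 364.69, 0, None),
    _cont("fibrinogen", None, 64.63, 608.56, 3.99, 0.91, 0, None),
    _cont("ldh", None, 208.32, 48.95, 234.25, 71.64, 0, None),
    _cont("glucose", None, 7.14, 2.78, 8.06, 4.40, 0, None),
    _cont("aspects_postop", "PSQ3", 7.11, 2.79, 6.83, 2.69, 0, 10, kind="integer"),
    _cont("triglycerides", None, 1.36, 0.76, 1.36, 0.78, 0, None),
    _cont("total_cholesterol", None, 4.38, 1.21, 4.14, 1.27, 0, None),
    _cont("hdl", None, 1.14, 0.31, 1.23, 0.32, 0, None),
    _cont("ldl", None, 2.74, 0.83, 2.61, 0.83, 0, None),
    _cont("hba1c", "BIOC19", 6.76, 1.69, 6.68, 1.71, 0, None),
    _cont("mrs_discharge", "PSQ6", 3.38, 1.14, 3.67, 1.28, 0, 6, kind="integer"),
)

INDICATOR_COLUMNS = tuple(c.name for c in CODEBOOK)
BINARY_COLUMNS = tuple(c.name for c in CODEBOOK if c.kind == "binary")
CONTINUOUS_COLUMNS = tuple(c.name for c in CODEBOOK if c.kind != "binary")
#: Sparsely measured follow-up columns, dropped during quality control.
EXCESS_MISSING_COLUMNS = ("mrs_3month", "mrs_12month", "homocysteine")

ALL_COLUMNS = ("patient_id", "gender") + INDICATOR_COLUMNS + (
    "nihss9_pre", "nihss9_post", "lang")

_RANGES = {c.name: (c.vmin, c.vmax) for c in CODEBOOK}
_RANGES.update({"nihss9_pre": (0, 3), "nihss9_post": (0, 3), "lang": (-3, 3)})


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def compute_lang(pre_item9: int, post_item9: int) -> tuple[int, int]:
    """LANG score and improvement class from the item-9 pre/post pair.

    LANG = post - pre; class 1 (improvement) iff LANG < 0, else 0.
    """
    pre, post = int(pre_item9), int(post_item9)
    if pre != pre_item9 or post != post_item9:
        raise ValueError("item-9 scores must be integers")
    for label, v in (("pre", pre), ("post", post)):
        if not 0 <= v <= 3:
            raise ValueError(f"item-9 {label} score {v} out of range 0-3")
    lang = post - pre
    return lang, int(lang < 0)


@dataclass
class CohortTable:
    """Validated patient table plus provenance of where it came from."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def improvement_class(self) -> pd.Series:
        return (self.data["lang"] < 0).astype(int)


def _validate_frame(df: pd.DataFrame) -> None:
    unknown = [c for c in df.columns
               if c not in ALL_COLUMNS and c not in EXCESS_MISSING_COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s): {unknown}")
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError("patient_id values must be unique")
    bad_gender = set(df["gender"].dropna()) - {"male", "female"}
    if bad_gender:
        raise ValueError(f"gender must be male/female, got {sorted(bad_gender)}")
    for col, (lo, hi) in _RANGES.items():
        vals = df[col].dropna()
        if lo is not None and (vals < lo).any():
            row = int(df.index[df[col] < lo][0])
            raise ValueError(f"row {row}, field {col}: value below range "
                             f"{lo}-{hi if hi is not None else 'inf'}")
        if hi is not None and (vals > hi).any():
            row = int(df.index[df[col] > hi][0])
            raise ValueError(f"row {row}, field {col}: value above range {lo}-{hi}")
    complete = df.dropna(subset=["nihss9_pre", "nihss9_post", "lang"])
    expected = complete["nihss9_post"] - complete["nihss9_pre"]
    if not np.allclose(complete["lang"], expected):
        row = int(complete.index[~np.isclose(complete["lang"], expected)][0])
        raise ValueError(f"row {row}: supplied LANG is inconsistent with the "
                         "item-9 pre/post pair")


def load_cohort(csv_path, codebook=CODEBOOK) -> CohortTable:
    """Read, type and validate a cohort CSV.

    LANG is recomputed from the item-9 pair and checked against any
    supplied LANG column; range violations report the offending row/field.
    """
    df = pd.read_csv(csv_path)
    _validate_frame(df)
    missingness = {c: int(df[c].isna().sum()) for c in df.columns if c != "patient_id"}
    return CohortTable(df, {"source": str(csv_path), "kind": "real",
                            "missingness": missingness})


def drop_incomplete(table: CohortTable, exclude_vars=EXCESS_MISSING_COLUMNS):
    """Drop listed high-missingness variables, then complete-case filter.

    Returns the filtered table and a report with the before/after counts
    and the per-variable missing counts that drove the filtering.
    """
    df = table.data
    exclude_vars = [v for v in exclude_vars]
    unknown = [v for v in exclude_vars if v not in df.columns]
    if unknown:
        raise ValueError(f"exclude_vars not in table: {unknown}")
    kept = df.drop(columns=exclude_vars)
    missing_counts = {c: int(kept[c].isna().sum()) for c in kept.columns}
    filtered = kept.dropna().reset_index(drop=True)
    report = {
        "n_before": len(df),
        "n_after": len(filtered),
        "excluded_variables": list(exclude_vars),
        "missing_counts": missing_counts,
    }
    prov = dict(table.provenance)
    prov["quality_control"] = report
    return CohortTable(filtered, prov), report


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters; continuous defaults follow the per-sex summaries.

    ``outcome_coefs`` drive a latent linear model for the post-pre language
    change on standardized (gcs, adl, mrs_discharge, infarct_volume_ml);
    positive coefficients push toward non-improvement.
    """

    n_male: int = 101
    n_female: int = 63
    outcome_coefs: dict = field(default_factory=lambda: {
        "gcs": 0.40, "adl": 0.10, "mrs_discharge": 0.25,
        "infarct_volume_ml": -0.15,
    })
    outcome_noise_sd: float = 1.0
    pre_item9_mean: float = 1.6
    pre_item9_sd: float = 0.9
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # column -> (mean_m, sd_m, mean_f, sd_f)

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("group sizes must be non-negative")
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be > 0")


def _draw_column(spec: ColumnSpec, sex_idx: np.ndarray, rng: np.random.Generator,
                 overrides: dict) -> np.ndarray:
    n = sex_idx.size
    if spec.kind == "binary":
        prev = np.asarray(spec.prevalences)[sex_idx]
        return (rng.random(n) < prev).astype(int)
    means, sds = spec.means, spec.sds
    if spec.name in overrides:
        m_m, s_m, m_f, s_f = overrides[spec.name]
        means, sds = (m_m, m_f), (s_m, s_f)
    vals = rng.normal(np.asarray(means)[sex_idx], np.asarray(sds)[sex_idx])
    if spec.vmin is not None:
        vals = np.maximum(vals, spec.vmin)
    if spec.vmax is not None:
        vals = np.minimum(vals, spec.vmax)
    if spec.kind == "integer":
        vals = np.round(vals)
    else:
        vals = np.round(vals, 4)
    return vals


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_cohort(params: SimulationParams | None = None,
                    n_enrolled: int | None = None) -> CohortTable:
    """Draw a synthetic cohort; deterministic per seed.

    Indicators are independent truncated (rounded, for integer scales)
    normals within sex; the language outcome follows the explicit latent
    model so that e.g. admission GCS correlates positively with LANG.

    When ``n_enrolled`` exceeds the analysed size, the extra patients each
    carry one missing value in a retained indicator, and three sparsely
    measured follow-up columns (3-/12-month mRS, homocysteine) are added
    with heavy missingness — so complete-case filtering after excluding
    those columns recovers exactly ``n_male + n_female`` rows.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    n_core = params.n_male + params.n_female
    n_total = n_core if n_enrolled is None else int(n_enrolled)
    if n_total < n_core:
        raise ValueError("n_enrolled must be >= n_male + n_female")
    n_extra = n_total - n_core

    extra_male = int(rng.binomial(n_extra, 0.5)) if n_extra else 0
    sex_idx = np.concatenate([
        np.zeros(params.n_male + extra_male, dtype=int),
        np.ones(params.n_female + (n_extra - extra_male), dtype=int),
    ])
    perm = rng.permutation(n_total)
    sex_idx = sex_idx[perm]
    # mark which rows are the "extra" enrolled patients to receive missingness
    extra_flags = np.zeros(n_total, dtype=bool)
    if n_extra:
        is_male = sex_idx == 0
        extra_rows = np.concatenate([
            np.flatnonzero(is_male)[:extra_male],
            np.flatnonzero(~is_male)[: n_extra - extra_male],
        ])
        extra_flags[extra_rows] = True

    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n_total)],
        "gender": np.where(sex_idx == 0, "male", "female"),
    })
    for spec in CODEBOOK:
        df[spec.name] = _draw_column(spec, sex_idx, rng, params.overrides)

    pre = np.clip(np.round(rng.normal(params.pre_item9_mean, params.pre_item9_sd,
                                      n_total)), 0, 3).astype(int)
    latent = rng.normal(0.0, params.outcome_noise_sd, n_total)
    for col, coef in params.outcome_coefs.items():
        latent = latent + coef * _standardize(df[col].to_numpy(dtype=float))
    post = np.clip(pre + np.round(latent).astype(int), 0, 3)
    df["nihss9_pre"] = pre
    df["nihss9_post"] = post
    df["lang"] = post - pre

    if n_extra:
        retained = list(INDICATOR_COLUMNS)
        for row in np.flatnonzero(extra_flags):
            col = retained[int(rng.integers(len(retained)))]
            df.loc[row, col] = np.nan
        for col in EXCESS_MISSING_COLUMNS:
            vals = np.round(rng.normal(10.0, 3.0, n_total), 2)
            mask = rng.random(n_total) < 0.6
            df[col] = np.where(mask, np.nan, vals)

    prov = {"kind": "synthetic", "seed": params.seed,
            "n_male": params.n_male, "n_female": params.n_female,
            "n_enrolled": n_total,
            "outcome_coefs": dict(params.outcome_coefs),
            "outcome_noise_sd": params.outcome_noise_sd}
    return CohortTable(df, prov)
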