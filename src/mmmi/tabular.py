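"""Clinicopathological record handling.

Covers the tabular side of the pipeline: rule-based extraction of structured
variables from semi-structured report text, categorical encoding, chained
multivariate imputation, the AJCC nodal-status rule, molecular subtype
assignment, and the attentive tabular representation used by the model.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .network import ModelConfig, TabularEncoder

log = logging.getLogger(__name__)

__all__ = [
    "VARIABLES", "LN_CLASSES", "PatientRecord", "EncodedTable",
    "extract_structured", "encode_categoricals", "impute_chained",
    "classify_ln_status", "assign_molecular_subtype", "tabular_encode",
    "TabularRepresentation",
]

LN_CLASSES = ["negative", "itc", "micro", "macro"]

# Variable registry: clinical ordering of levels (encoding itself is
# lexicographic, see encode_categoricals). "continuous" marks numeric fields.
VARIABLES: dict[str, list | str] = {
    "age": "continuous",
    "menopause": ["premenopausal", "menopause"],
    "tumor_size_cat": ["<=2cm", ">2cm"],
    "histological_grade": ["1", "2", "3"],
    "mitosis": ["1", "2", "3"],
    "gland_formation": ["1", "2", "3"],
    "nuclear_atypia": ["1", "2", "3"],
    "stroma_change": ["collagenous", "fibroblastic", "myxoid"],
    "tumor_location": ["UOQ", "UIQ", "LOQ", "LIQ"],
    "vascular_invasion": ["absent", "present"],
    "nerve_invasion": ["absent", "present"],
    "ER": ["negative", "positive"],
    "PR": ["negative", "positive"],
    "HER2": ["negative", "positive"],
    "Ki67": ["<20%", ">=20%"],
    "TILs": ["low", "middle", "high"],
    "BI_RADS": ["4a", "4b", "4c", "5"],
}

UNKNOWN_LEVEL = "__unknown__"


@dataclass
class PatientRecord:
    """One patient's structured variables plus the 4-class nodal label.

    ``None`` marks a missing value (allowed before imputation only).
    """

    patient_id: str
    values: dict = field(default_factory=dict)
    ln_status: str | None = None

    def __post_init__(self):
        if self.ln_status is not None and self.ln_status not in LN_CLASSES:
            raise ValueError(f"ln_status must be one of {LN_CLASSES}")
        for k, v in self.values.items():
            levels = VARIABLES.get(k)
            if v is not None and isinstance(levels, list) and str(v) not in levels:
                raise ValueError(f"{k}={v!r} not in levels {levels}")


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, **{v: r.values.get(v) for v in VARIABLES}}
        row["ln_status"] = r.ln_status
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rule-based extraction from semi-structured report text
# ---------------------------------------------------------------------------

def extract_structured(report_text: str, rules: dict) -> PatientRecord:
    """Fill a (partial) record from report text via regex rules.

    ``rules`` maps variable name -> {"pattern": regex with one group,
    "lexicon": {matched string (lowercased) -> level}}.  Unmatched variables
    are left missing; extraction never raises on unmatched text.
    """
    for var, rule in rules.items():
        if not isinstance(rule, dict) or "pattern" not in rule:
            raise ValueError(f"malformed rule for {var!r}: need a 'pattern'")
    values: dict = {}
    for var, rule in rules.items():
        m = re.search(rule["pattern"], report_text, flags=re.IGNORECASE)
        if not m:
            continue
        token = (m.group(1) if m.groups() else m.group(0)).strip().lower()
        lexicon = {str(k).lower(): v for k, v in rule.get("lexicon", {}).items()}
        if token in lexicon:
            values[var] = lexicon[token]
        elif not rule.get("lexicon"):
            values[var] = token
    pid = values.pop("patient_id", "")
    return PatientRecord(patient_id=str(pid), values=values)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedTable:
    """Numeric coding of a record table.

    ``matrix`` holds per-variable integer codes (float dtype; NaN = missing),
    ``encoders`` the level -> code maps (consecutive integers from 0 in
    lexicographic level order), ``missing_mask`` flags the originally missing
    cells.
    """

    matrix: np.ndarray
    columns: list
    encoders: dict
    missing_mask: np.ndarray
    patient_ids: list
    labels: np.ndarray | None = None

    def decode(self) -> pd.DataFrame:
        inv = {v: {c: lvl for lvl, c in m.items()} for v, m in self.encoders.items()}
        out = {}
        for j, col in enumerate(self.columns):
            vals = self.matrix[:, j]
            if col in inv:
                out[col] = [None if np.isnan(v) else inv[col].get(int(v), UNKNOWN_LEVEL)
                            for v in vals]
            else:
                out[col] = [None if np.isnan(v) else v for v in vals]
        df = pd.DataFrame(out, index=self.patient_ids)
        df.index.name = "patient_id"
        return df

    def copy(self) -> "EncodedTable":
        return EncodedTable(self.matrix.copy(), list(self.columns),
                            {k: dict(v) for k, v in self.encoders.items()},
                            self.missing_mask.copy(), list(self.patient_ids),
                            None if self.labels is None else self.labels.copy())


def encode_categoricals(records, encoders: dict | None = None) -> EncodedTable:
    """Encode categorical variables as consecutive integer codes.

    Accepts a list of :class:`PatientRecord` or an equivalent DataFrame with a
    ``patient_id`` column and optional ``ln_status``.  Level -> code maps are
    lexicographic over the observed levels (matching the behaviour of a plain
    label encoder), so two shuffled copies of the same records produce
    identical maps.  Continuous variables pass through unencoded.

    Passing fitted ``encoders`` applies them instead (transform time); a
    level unseen at fit time is mapped to a reserved "unknown" code and
    logged — clinical deployments hit this.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    cols = [c for c in df.columns if c not in ("patient_id", "ln_status")]
    n = len(df)
    matrix = np.full((n, len(cols)), np.nan)
    fit = encoders is None
    encoders = {} if fit else {k: dict(v) for k, v in encoders.items()}
    for j, col in enumerate(cols):
        series = df[col]
        if (col not in encoders and (VARIABLES.get(col) == "continuous"
                                     or pd.api.types.is_numeric_dtype(series))):
            matrix[:, j] = pd.to_numeric(series, errors="coerce").to_numpy(float)
            continue
        if fit:
            observed = sorted({str(v) for v in series.dropna()})
            encoders[col] = {lvl: code for code, lvl in enumerate(observed)}
        mapping = encoders[col]
        for i, v in enumerate(series):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            key = str(v)
            if key not in mapping:
                log.warning("unseen level %r for %s; coded as unknown", v, col)
                mapping.setdefault(UNKNOWN_LEVEL, len(mapping))
                key = UNKNOWN_LEVEL
            matrix[i, j] = mapping[key]
    labels = None
    if "ln_status" in df.columns and df["ln_status"].notna().all():
        labels = df["ln_status"].map({c: i for i, c in enumerate(LN_CLASSES)}).to_numpy()
    return EncodedTable(matrix, cols, encoders, np.isnan(matrix),
                        [str(p) for p in df.get("patient_id", range(n))], labels)


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------

def impute_chained(table: EncodedTable, n_iter: int = 10,
                   seed: int = 0) -> EncodedTable:
    """Multivariate imputation by chained equations, predictive-mean matching.

    Missing cells are initialised to the column median of observed values;
    each sweep regresses every incomplete variable on all others and replaces
    each hole with the observed value of the nearest-prediction donor (PMM
    with 5 donors, seeded draw).  Observed cells are never altered.
    """
    out = table.copy()
    X = out.matrix
    miss = out.missing_mask
    if miss.all(axis=0).any():
        bad = [out.columns[j] for j in np.where(miss.all(axis=0))[0]]
        raise ValueError(f"fully missing variable(s): {bad}")
    if not miss.any():
        return out
    rng = np.random.default_rng(seed)
    n, p = X.shape
    for j in range(p):
        col = X[:, j]
        if miss[:, j].any():
            col[miss[:, j]] = np.median(col[~miss[:, j]])
    for _ in range(n_iter):
        for j in range(p):
            mj = miss[:, j]
            if not mj.any():
                continue
            others = np.delete(X, j, axis=1)
            reg = LinearRegression().fit(others[~mj], X[~mj, j])
            pred_obs = reg.predict(others[~mj])
            pred_mis = reg.predict(others[mj])
            obs_vals = X[~mj, j]
            # PMM: for each hole pick one of the 5 observed donors whose
            # predicted value is closest to the hole's prediction
            order = np.argsort(np.abs(pred_obs[None, :] - pred_mis[:, None]),
                               axis=1)[:, :5]
            pick = rng.integers(0, order.shape[1], size=order.shape[0])
            X[mj, j] = obs_vals[order[np.arange(len(pick)), pick]]
    out.missing_mask = np.zeros_like(miss)
    assert not np.isnan(X).any()
    return out


# ---------------------------------------------------------------------------
# gold-standard label rules
# ---------------------------------------------------------------------------

def classify_ln_status(tumor_cell_count: int, focus_size_mm: float) -> str:
    """AJCC nodal bucket from deposit cell count and largest focus size.

    macro: focus > 2 mm; micro: 0.2 mm < focus <= 2 mm; ITC: <=200 scattered
    cells or clusters <= 0.2 mm; negative: no cells and no focus.  The size
    rule takes precedence when both criteria are available; a deposit of more
    than 200 cells without a measurable focus is treated as micrometastasis
    (it exceeds the ITC cell-count ceiling).
    """
    if tumor_cell_count < 0 or focus_size_mm < 0:
        raise ValueError("counts and sizes must be nonnegative")
    if focus_size_mm > 2.0:
        return "macro"
    if focus_size_mm > 0.2:
        return "micro"
    if tumor_cell_count == 0 and focus_size_mm == 0:
        return "negative"
    if tumor_cell_count <= 200 or focus_size_mm <= 0.2:
        if tumor_cell_count > 200:
            return "micro"
        return "itc"
    return "micro"


def assign_molecular_subtype(er: bool, pr: bool, her2: bool) -> str:
    """Luminal if hormone-receptor positive; else HER2-overexpression if
    HER2 positive; else triple-negative (TNBC)."""
    if er or pr:
        return "Luminal"
    if her2:
        return "HER2-overexpression"
    return "TNBC"


# ---------------------------------------------------------------------------
# learned representation
# ---------------------------------------------------------------------------

@dataclass
class TabularRepresentation:
    embedding: np.ndarray          # (n_patients, embed_dim)
    feature_masks: np.ndarray      # (n_steps, n_patients, n_variables)
    columns: list


def standardize(matrix: np.ndarray, stats: tuple | None = None):
    """Column z-scoring; constant columns are centred only."""
    if stats is None:
        mu = matrix.mean(axis=0)
        sd = matrix.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu, sd = stats
    return (matrix - mu) / sd, (mu, sd)


def tabular_encode(table: EncodedTable, encoder: TabularEncoder | None = None,
                   config: ModelConfig | None = None,
                   seed: int = 0) -> TabularRepresentation:
    """Run the attentive encoder over a complete table.

    Returns the per-patient embedding and the per-decision-step feature masks
    (nonnegative, rows summing to one) used for importance aggregation.
    """
    if np.isnan(table.matrix).any():
        raise ValueError("table has missing values; impute first")
    X, _ = standardize(table.matrix)
    if encoder is None:
        cfg = config or ModelConfig(n_variables=X.shape[1])
        if cfg.n_variables != X.shape[1]:
            raise ValueError("config n_variables does not match table")
        encoder = TabularEncoder(cfg, np.random.default_rng(seed))
    from .autodiff import Tensor
    emb, masks = encoder(Tensor(X))
    return TabularRepresentation(emb.data, np.stack([m.data for m in masks]),
                                 list(table.columns))
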