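"""Record structuring: extraction, encoding, imputation, label rules and the
attentive representation."""

import numpy as np
import pandas as pd
import pytest

from mmmi.network import ModelConfig, TabularEncoder
from mmmi.tabular import (EncodedTable, PatientRecord, UNKNOWN_LEVEL,
                          assign_molecular_subtype, classify_ln_status,
                          encode_categoricals, extract_structured,
                          impute_chained, records_to_frame, tabular_encode)

RULES = {
    "ER": {"pattern": r"ER[:\s]+(\w+)",
           "lexicon": {"positive": "positive", "negative": "negative"}},
    "HER2": {"pattern": r"HER2\s*(\d)\+",
             "lexicon": {"3": "positive", "2": "positive",
                         "1": "negative", "0": "negative"}},
    "TILs": {"pattern": r"TILs?\s+(\w+)",
             "lexicon": {"low": "low", "middle": "middle", "high": "high"}},
}

# ten toy semi-structured reports with gold missingness annotation
REPORTS = [
    ("ER: positive (90%); HER2 3+", {"ER", "HER2"}),
    ("ER: negative; HER2 0+; TILs high", {"ER", "HER2", "TILs"}),
    ("", set()),
    ("HER2 1+ only", {"HER2"}),
    ("TILs middle, receptor unknown", {"TILs"}),
    ("ER: positive", {"ER"}),
    ("ER: borderline; HER2 2+", {"HER2"}),   # token not in lexicon
    ("no markers reported", set()),
    ("TILs low; ER: negative; HER2 3+", {"ER", "HER2", "TILs"}),
    ("HER2 2+; TILs high", {"HER2", "TILs"}),
]


def test_extraction_direct_lexicon_hits():
    rec = extract_structured("ER: positive (90%); HER2 3+", RULES)
    assert rec.values == {"ER": "positive", "HER2": "positive"}


def test_extraction_empty_string_all_missing():
    assert extract_structured("", RULES).values == {}


def test_extraction_fixture_missingness_matches_gold():
    for text, gold in REPORTS:
        rec = extract_structured(text, RULES)
        assert set(rec.values) == gold


def test_extraction_malformed_rules_rejected():
    with pytest.raises(ValueError):
        extract_structured("x", {"ER": "not-a-dict"})


def _toy_records():
    return [
        PatientRecord("a", {"TILs": "low", "ER": "positive"}, "negative"),
        PatientRecord("b", {"TILs": "high", "ER": "negative"}, "macro"),
        PatientRecord("c", {"TILs": "middle", "ER": "positive"}, "micro"),
    ]


def test_encode_lexicographic_consecutive_codes():
    table = encode_categoricals(_toy_records())
    assert table.encoders["TILs"] == {"high": 0, "low": 1, "middle": 2}
    j = table.columns.index("TILs")
    assert list(table.matrix[:, j]) == [1.0, 0.0, 2.0]


def test_encode_decode_roundtrip():
    recs = _toy_records()
    table = encode_categoricals(recs)
    decoded = table.decode()
    frame = records_to_frame(recs).set_index("patient_id")
    for var in ("TILs", "ER"):
        assert list(decoded[var]) == list(frame[var])


def test_encode_order_independent():
    recs = _toy_records()
    a = encode_categoricals(recs)
    b = encode_categoricals(list(reversed(recs)))
    assert a.encoders == b.encoders


def test_unseen_level_coded_as_reserved_unknown():
    fitted = encode_categoricals(_toy_records())
    df = records_to_frame(_toy_records())
    df.loc[0, "TILs"] = "weird"
    table = encode_categoricals(df, encoders=fitted.encoders)
    j = table.columns.index("TILs")
    assert table.encoders["TILs"][UNKNOWN_LEVEL] == 3
    assert table.matrix[0, j] == 3.0


def test_record_level_validation():
    with pytest.raises(ValueError):
        PatientRecord("x", {"ER": "maybe"})
    with pytest.raises(ValueError):
        PatientRecord("x", {}, "unknown-status")


# -- imputation ---------------------------------------------------------------

def test_impute_complete_table_unchanged(small_cohort):
    table = encode_categoricals(small_cohort.records)
    out = impute_chained(table, seed=1)
    assert np.array_equal(out.matrix, table.matrix)


def test_impute_preserves_observed_and_is_seeded(rng):
    n = 200
    base = rng.integers(0, 3, size=(n, 4)).astype(float)
    miss = rng.random((n, 4)) < 0.15
    mat = base.copy()
    mat[miss] = np.nan
    t = EncodedTable(mat, list("abcd"), {}, np.isnan(mat),
                     [str(i) for i in range(n)])
    o1 = impute_chained(t, seed=3)
    o2 = impute_chained(t, seed=3)
    assert np.array_equal(o1.matrix, o2.matrix)
    assert not np.isnan(o1.matrix).any()
    assert np.array_equal(o1.matrix[~miss], base[~miss])


def test_impute_recovers_planted_deterministic_copy(rng):
    # column 1 is an exact copy of column 0; 20% MCAR holes in the copy
    n = 500
    x = rng.integers(0, 5, size=n).astype(float)
    noise = rng.integers(0, 3, size=(n, 2)).astype(float)
    mat = np.column_stack([x, x.copy(), noise])
    holes = rng.random(n) < 0.2
    mat[holes, 1] = np.nan
    t = EncodedTable(mat, list("abcde"), {}, np.isnan(mat),
                     [str(i) for i in range(n)])
    out = impute_chained(t, seed=0)
    recovered = (out.matrix[holes, 1] == x[holes]).mean()
    assert recovered >= 0.9


def test_impute_fully_missing_variable_errors():
    mat = np.array([[1.0, np.nan], [2.0, np.nan]])
    t = EncodedTable(mat, ["a", "b"], {}, np.isnan(mat), ["0", "1"])
    with pytest.raises(ValueError, match="fully missing"):
        impute_chained(t)


# -- label rules --------------------------------------------------------------

@pytest.mark.parametrize("count,size,expected", [
    (150, 0.1, "itc"),        # scattered cells, tiny focus
    (0, 2.0, "micro"),        # boundary inclusive: >0.2 and <=2
    (0, 2.01, "macro"),       # strictly above 2 mm
    (0, 0.2, "itc"),          # cluster exactly at the ITC ceiling
    (0, 0.21, "micro"),
    (0, 0.0, "negative"),
    (201, 0.0, "micro"),      # above the ITC cell-count ceiling
    (200, 0.0, "itc"),
    (500, 5.0, "macro"),
])
def test_ln_status_buckets(count, size, expected):
    assert classify_ln_status(count, size) == expected


def test_ln_status_partitions_quarter_plane(rng):
    counts = rng.integers(0, 400, size=200)
    sizes = rng.uniform(0, 4, size=200)
    for c, s in zip(counts, sizes):
        assert classify_ln_status(int(c), float(s)) in (
            "negative", "itc", "micro", "macro")
    with pytest.raises(ValueError):
        classify_ln_status(-1, 0.5)
    with pytest.raises(ValueError):
        classify_ln_status(10, -0.5)


@pytest.mark.parametrize("er,pr,her2,expected", [
    (True, False, True, "Luminal"),
    (True, True, False, "Luminal"),
    (False, True, True, "Luminal"),
    (False, False, True, "HER2-overexpression"),
    (False, False, False, "TNBC"),
])
def test_molecular_subtype_assignment(er, pr, her2, expected):
    assert assign_molecular_subtype(er, pr, her2) == expected


def test_molecular_subtype_total_on_binary_triples():
    outs = {assign_molecular_subtype(*t)
            for t in [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]}
    assert outs == {"Luminal", "HER2-overexpression", "TNBC"}


# -- learned representation ---------------------------------------------------

def test_constant_table_gives_constant_embeddings():
    mat = np.ones((6, 5))
    t = EncodedTable(mat, list("abcde"), {}, np.zeros_like(mat, bool),
                     [str(i) for i in range(6)])
    rep = tabular_encode(t, config=ModelConfig(n_variables=5, embed_dim=8,
                                               feature_dim=4))
    assert np.allclose(rep.embedding, rep.embedding[0])


def test_embedding_shape_and_mask_validity(small_cohort):
    t = encode_categoricals(small_cohort.records)
    cfg = ModelConfig(n_variables=len(t.columns), embed_dim=16, feature_dim=4)
    rep = tabular_encode(t, config=cfg)
    assert rep.embedding.shape == (len(small_cohort.records), 16)
    assert rep.feature_masks.shape[0] == cfg.n_steps
    assert (rep.feature_masks >= 0).all() and np.isfinite(rep.feature_masks).all()
    assert np.allclose(rep.feature_masks.sum(axis=-1), 1.0)


def test_tabular_encode_rejects_missing():
    mat = np.array([[1.0, np.nan]])
    t = EncodedTable(mat, ["a", "b"], {}, np.isnan(mat), ["0"])
    with pytest.raises(ValueError, match="missing"):
        tabular_encode(t)
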