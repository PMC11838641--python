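"""Note featurization: tokenization, n-grams, lexicon, embeddings, clusters."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from hdproxy import (
    FeatureMatrix,
    Lexicon,
    build_feature_matrix,
    cluster_features,
    default_stopwords,
    extract_ngrams,
    hash_embedder,
    load_stopwords,
    match_lexicon,
    tokenize,
)
from hdproxy.features import ContextualHashEmbedder


# ---------------------------------------------------------------------------
# tokenize
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Chest pain, worse at night.", ["chest", "pain", "worse", "at", "night"]),
        ("", []),
        ("BP 140/90", ["bp", "140", "90"]),
        ("  ---  ", []),
        ("Mixed-CASE tokens_here", ["mixed", "case", "tokens", "here"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


@settings(max_examples=50, derandomize=True)
@given(st.text(max_size=80))
def test_tokenize_output_is_lower_alnum(text):
    for tok in tokenize(text):
        assert tok and tok == tok.lower()
        assert all(c.isalnum() for c in tok)


# ---------------------------------------------------------------------------
# n-grams
# ---------------------------------------------------------------------------


def test_ngrams_filter_then_pair():
    docs = [[["chest", "pain", "in", "the", "morning"]]]
    out = extract_ngrams(docs, stopwords={"in", "the"}, n_max=2)
    assert out[0] == {"chest", "pain", "morning", "chest_pain", "pain_morning"}


def test_ngrams_all_stopwords_gives_nothing():
    out = extract_ngrams([[["the", "a", "in"]]], stopwords={"the", "a", "in"})
    assert out[0] == set()


def test_ngrams_never_span_documents():
    out = extract_ngrams([[["a"], ["b"]]], stopwords=set(), n_max=2)
    assert out[0] == {"a", "b"}


def test_ngrams_unigram_only_mode():
    out = extract_ngrams([[["x", "y"]]], stopwords=set(), n_max=1)
    assert out[0] == {"x", "y"}


def test_ngrams_rejects_higher_order():
    with pytest.raises(ValueError, match="n_max"):
        extract_ngrams([[["a"]]], stopwords=set(), n_max=3)


def test_ngrams_idempotent_in_document_multiplicity(small_cohort):
    _, cohort, _ = small_cohort
    docs = [cohort.note_token_docs(i) for i in range(cohort.n)]
    doubled = [d + d for d in docs]
    assert extract_ngrams(docs) == extract_ngrams(doubled)


def test_default_stopword_list_shipped():
    sw = default_stopwords()
    assert {"a", "the", "in", "on"} <= sw
    assert 120 <= len(sw) <= 200


def test_stopword_file_override(tmp_path):
    (tmp_path / "sw.txt").write_text("alpha\nbeta\n")
    assert load_stopwords(tmp_path / "sw.txt") == {"alpha", "beta"}


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


def test_lexicon_longest_match_suppresses_nested():
    lex = Lexicon.from_terms({"chest pain": "C1", "pain": "C2"})
    out = match_lexicon([[["chest", "pain"]]], lex)
    assert out[0] == {"C1"}


def test_lexicon_single_token_match():
    lex = Lexicon.from_terms({"pain": "C2"})
    assert match_lexicon([[["no", "pain"]]], lex)[0] == {"C2"}


def test_lexicon_no_match():
    lex = Lexicon.from_terms({"pain": "C2"})
    assert match_lexicon([[["all", "clear"]]], lex)[0] == set()


def test_lexicon_resumes_after_span():
    # after matching "a b", scanning resumes at "c": "b c" must not match
    lex = Lexicon.from_terms({"a b": "X", "b c": "Y", "c": "Z"})
    assert match_lexicon([[["a", "b", "c"]]], lex)[0] == {"X", "Z"}


def test_lexicon_validation():
    with pytest.raises(ValueError):
        Lexicon({})
    with pytest.raises(ValueError):
        Lexicon({("term",): ""})


def test_lexicon_csv_roundtrip(tmp_path):
    lex = Lexicon.from_terms({"chest pain": "C1", "dyspnea": "C2"})
    lex.to_csv(tmp_path / "lex.csv")
    assert Lexicon.from_csv(tmp_path / "lex.csv").entries == lex.entries


# ---------------------------------------------------------------------------
# embedding providers
# ---------------------------------------------------------------------------


def test_hash_embedder_deterministic_unit_norm():
    emb = hash_embedder(32, seed=1)
    v1 = emb.embed(["pain"], 0)
    v2 = emb.embed(["pain", "relief"], 0)  # same token, context ignored
    np.testing.assert_array_equal(v1, v2)
    assert abs(np.linalg.norm(v1) - 1.0) < 1e-12
    emb_b = hash_embedder(32, seed=1)
    np.testing.assert_array_equal(v1, emb_b.embed(["pain"], 0))


def test_hash_embedder_vocabulary_spread():
    """Over 1,000 distinct tokens no two vectors are near-parallel."""
    emb = hash_embedder(64, seed=0)
    V = np.stack([emb.embed([f"t{i}"], 0) for i in range(1000)])
    G = V @ V.T
    np.fill_diagonal(G, 0.0)
    assert np.abs(G).max() < 0.9


def test_contextual_embedder_depends_on_context():
    emb = ContextualHashEmbedder(32, seed=0)
    v_a = emb.embed(["left", "pain", "right"], 1)
    v_b = emb.embed(["other", "pain", "words"], 1)
    assert not np.allclose(v_a, v_b)
    # determinism within identical context
    np.testing.assert_array_equal(v_a, emb.embed(["left", "pain", "right"], 1))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _toy_cohort(note_tokens):
    """Minimal cohort-like object for cluster_features."""
    from hdproxy import Cohort

    n = len(note_tokens)
    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "A": [i % 2 for i in range(n)],
            "time_days": [10.0] * n,
            "event": [0] * n,
            "age": [70.0] * n,
            "sex": [0] * n,
        }
    )
    notes = [[(-5, tuple(toks))] if toks else [] for toks in note_tokens]
    return Cohort(
        patients=patients,
        claims_codes=[frozenset()] * n,
        ehr_codes=[frozenset()] * n,
        notes=notes,
        researcher_covariates=("age", "sex"),
    )


class _PlantedEmbedder:
    """Embeds tokens starting 'a' near the origin and 'b' near (10,...)."""

    dim = 4
    contextual = False

    def embed(self, tokens, position):
        tok = tokens[position]
        rng = np.random.default_rng(abs(hash(tok)) % (2**31))
        base = 0.0 if tok.startswith("a") else 10.0
        return base + 0.05 * rng.standard_normal(self.dim)


def test_cluster_k1_marks_every_noted_patient():
    cohort = _toy_cohort([["x", "y"], ["z"], []])
    _, feats = cluster_features(cohort, hash_embedder(8, 0), "word", k=1, seed=0)
    np.testing.assert_array_equal(feats[:, 0], [1.0, 1.0, 0.0])


def test_cluster_two_separated_groups():
    """Two well-separated clouds: k=2 features separate the groups exactly,
    matching an exact 2-means run on the same embedded points."""
    tokens_g1 = [[f"a{i}", f"a{i+1}"] for i in range(6)]
    tokens_g2 = [[f"b{i}", f"b{i+1}"] for i in range(6)]
    cohort = _toy_cohort(tokens_g1 + tokens_g2)
    _, feats = cluster_features(cohort, _PlantedEmbedder(), "word", k=2, seed=0)
    g1 = feats[:6]
    g2 = feats[6:]
    assert (g1 == g1[0]).all() and (g2 == g2[0]).all()
    assert not np.array_equal(g1[0], g2[0])
    assert g1[0].sum() == 1 and g2[0].sum() == 1


def test_cluster_no_notes_patient_all_zero(small_cohort):
    _, cohort, _ = small_cohort
    _, feats = cluster_features(cohort, hash_embedder(16, 0), "word", k=5, seed=0)
    empty = [i for i in range(cohort.n) if not cohort.notes[i]]
    if empty:
        assert (feats[empty] == 0).all()


def test_cluster_k_exceeding_units_raises():
    cohort = _toy_cohort([["only"], ["only"]])
    with pytest.raises(ValueError, match="exceeds"):
        cluster_features(cohort, hash_embedder(8, 0), "word", k=5, seed=0)


def test_word_cluster_depends_only_on_token_set():
    """Identical token sets (any multiplicity/order) give identical rows."""
    cohort_a = _toy_cohort([["x", "y", "z"], ["z", "y", "x", "x"]])
    _, feats = cluster_features(cohort_a, hash_embedder(8, 3), "word", k=2, seed=1)
    np.testing.assert_array_equal(feats[0], feats[1])


def _exact_two_means(points):
    """Best 2-means objective via Lloyd from every point-pair seed."""
    best = np.inf
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            centers = points[[i, j]].astype(float).copy()
            for _ in range(100):
                d = ((points[:, None, :] - centers[None]) ** 2).sum(-1)
                lab = d.argmin(1)
                new = np.array(
                    [
                        points[lab == c].mean(0) if (lab == c).any() else centers[c]
                        for c in range(2)
                    ]
                )
                if np.allclose(new, centers):
                    break
                centers = new
            obj = ((points - centers[lab]) ** 2).sum()
            best = min(best, obj)
    return best


def test_minibatch_kmeans_matches_exact_two_means_oracle(rng):
    """Full-batch mini-batch k-means with restarts reaches within 1% of the
    brute-force best 2-partition objective on a small instance."""
    from sklearn.cluster import MiniBatchKMeans

    points = np.vstack(
        [rng.normal(0, 1, (20, 3)), rng.normal(4, 1, (20, 3))]
    )
    exact = _exact_two_means(points)
    km = MiniBatchKMeans(n_clusters=2, batch_size=len(points), n_init=20,
                         max_iter=100, random_state=0).fit(points)
    d = ((points - km.cluster_centers_[km.labels_]) ** 2).sum()
    assert d <= exact * 1.01


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------


def test_claims_block_prevalences():
    from hdproxy import Cohort

    patients = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "A": [1, 0, 0],
            "time_days": [1.0, 2.0, 3.0],
            "event": [0, 0, 0],
            "age": [70.0, 71, 72],
            "sex": [0, 1, 0],
        }
    )
    cohort = Cohort(
        patients=patients,
        claims_codes=[frozenset({"c1"}), frozenset({"c1", "c2"}), frozenset()],
        ehr_codes=[frozenset()] * 3,
        notes=[[] for _ in range(3)],
        researcher_covariates=("age", "sex"),
    )
    fm = build_feature_matrix(cohort, ["claims"])
    assert fm.n_features == 2
    np.testing.assert_allclose(sorted(fm.meta["prevalence"]), [1 / 3, 2 / 3])


def test_empty_sources_rejected(small_cohort):
    _, cohort, _ = small_cohort
    with pytest.raises(ValueError, match="at least one"):
        build_feature_matrix(cohort, [])
    with pytest.raises(ValueError, match="unknown source"):
        build_feature_matrix(cohort, ["bogus"])


def test_full_assembly_block_conservation(small_cohort):
    _, cohort, _ = small_cohort
    lex = Lexicon.from_terms({"w0001": "C1", "w0002 w0003": "C2"})
    fm = build_feature_matrix(
        cohort,
        ["researcher", "claims", "ehr_code", "ngram", "lexicon", "cluster_word"],
        lexicon=lex, k=4, embed_dim=8,
    )
    per_block = fm.meta["source"].value_counts()
    assert per_block.sum() == fm.n_features
    assert per_block["researcher"] == len(cohort.researcher_covariates)
    assert per_block["cluster_word"] == 4
    # prevalence always equals exact column mean
    np.testing.assert_allclose(
        fm.meta["prevalence"], np.asarray(fm.values.mean(axis=0)).ravel()
    )


def test_feature_matrix_row_permutation_invariance(small_cohort):
    """Permuting patients permutes rows and leaves metadata unchanged."""
    _, cohort, _ = small_cohort
    fm = build_feature_matrix(cohort, ["researcher", "claims"])
    perm = np.random.default_rng(0).permutation(cohort.n)
    import copy

    cohort2 = copy.copy(cohort)
    cohort2.patients = cohort.patients.iloc[perm].reset_index(drop=True)
    cohort2.claims_codes = [cohort.claims_codes[i] for i in perm]
    cohort2.ehr_codes = [cohort.ehr_codes[i] for i in perm]
    cohort2.notes = [cohort.notes[i] for i in perm]
    fm2 = build_feature_matrix(cohort2, ["researcher", "claims"])
    assert fm2.names == fm.names
    np.testing.assert_allclose(
        fm2.values.toarray(), fm.values.toarray()[perm], atol=0
    )


def test_binary_invariant_enforced():
    meta = pd.DataFrame({"name": ["x"], "source": ["claims"], "is_binary": [True]})
    with pytest.raises(ValueError, match="0/1"):
        FeatureMatrix(sp.csr_matrix(np.array([[0.5], [1.0]])), meta)


def test_duplicate_names_rejected():
    meta = pd.DataFrame(
        {"name": ["x", "x"], "source": ["claims"] * 2, "is_binary": [True] * 2}
    )
    with pytest.raises(ValueError, match="duplicate"):
        FeatureMatrix(sp.csr_matrix(np.zeros((2, 2))), meta)


def test_feature_matrix_mtx_roundtrip(tmp_path, small_cohort):
    _, cohort, _ = small_cohort
    fm = build_feature_matrix(cohort, ["researcher", "claims", "ngram"])
    fm.save(tmp_path / "fm")
    back = FeatureMatrix.load(tmp_path / "fm")
    assert back.names == fm.names
    np.testing.assert_allclose(back.values.toarray(), fm.values.toarray())
    assert (tmp_path / "fm.mtx").exists()  # MatrixMarket text format
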