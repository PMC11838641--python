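"""Binary patient-level features from codes and free-text notes.

Implements the five note-featurization schemes used for high-dimensional
proxy adjustment — bag-of-n-grams, lexicon/concept matching, and three
embedding-cluster schemes (word, contextual word, sentence) — plus the
assembly of the full candidate feature matrix from researcher-specified
covariates, claims codes, EHR codes and the NLP blocks.

All NLP output is reduced to dichotomous presence indicators per patient:
an n-gram, concept, or embedding cluster contributes a 1 for a patient iff
it occurs in (or one of the patient's units is assigned to it from) any of
that patient's pre-index documents.  Binary features keep the downstream
penalized propensity model's functional form simple and are the
representation the adjustment pipeline expects.

Pretrained embedding models are deliberately not bundled: any object
satisfying the small ``EmbedderProvider`` protocol (``dim`` attribute and
``embed(tokens, position)``) can be plugged in.  The built-in providers
map tokens to fixed pseudo-random unit vectors keyed by a hash of the
token (and, in the contextual variant, its flanking tokens), giving
deterministic, genuinely context-sensitive stand-ins at desk scale.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.cluster import MiniBatchKMeans

__all__ = [
    "FeatureMatrix",
    "Lexicon",
    "ClusterModel",
    "EmbedderProvider",
    "HashEmbedder",
    "ContextualHashEmbedder",
    "hash_embedder",
    "default_stopwords",
    "load_stopwords",
    "tokenize",
    "extract_ngrams",
    "match_lexicon",
    "cluster_features",
    "build_feature_matrix",
    "SOURCE_TAGS",
]

SOURCE_TAGS = (
    "researcher",
    "claims",
    "ehr_code",
    "ngram",
    "lexicon",
    "cluster_word",
    "cluster_contextual",
    "cluster_sentence",
)

_PREFIX = {
    "researcher": "rs",
    "claims": "clm",
    "ehr_code": "ehr",
    "ngram": "ng",
    "lexicon": "lex",
    "cluster_word": "cw",
    "cluster_contextual": "cc",
    "cluster_sentence": "cs",
}

_TOKEN_RE = re.compile(r"[a-z0-9]+")


# ---------------------------------------------------------------------------
# feature matrix container
# ---------------------------------------------------------------------------


class FeatureMatrix:
    """Sparse patients x features matrix with per-feature metadata.

    ``values`` is CSR; binary columns hold {0, 1} entries, continuous
    columns (e.g. age) are exempt from the binary contract and flagged in
    ``meta.is_binary``.  ``meta`` has one row per column with ``name``
    (unique), ``source`` (one of :data:`SOURCE_TAGS`), ``is_binary`` and
    ``prevalence`` — the exact column mean.
    """

    def __init__(self, values: sp.spmatrix | np.ndarray, meta: pd.DataFrame):
        values = sp.csr_matrix(values, dtype=float)
        meta = meta.reset_index(drop=True).copy()
        if values.shape[1] != len(meta):
            raise ValueError("meta must have one row per feature column")
        required = {"name", "source", "is_binary"}
        if not required.issubset(meta.columns):
            raise ValueError(f"meta must contain columns {sorted(required)}")
        if meta["name"].duplicated().any():
            dupes = meta.loc[meta["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        bad = set(meta["source"]) - set(SOURCE_TAGS)
        if bad:
            raise ValueError(f"unknown source tags {sorted(bad)}; valid: {SOURCE_TAGS}")
        if values.shape[0] > 0 and len(values.data):
            binary_cols = meta.index[meta["is_binary"]].to_numpy()
            if len(binary_cols):
                sub = values[:, binary_cols]
                if len(sub.data) and not np.isin(sub.data, (0.0, 1.0)).all():
                    raise ValueError("binary feature columns must contain only 0/1")
        self.values = values
        meta["prevalence"] = np.asarray(values.mean(axis=0)).ravel()
        self.meta = meta

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return self.meta["name"].tolist()

    def select(self, mask_or_names) -> "FeatureMatrix":
        """Column subset by boolean mask or name list (order preserved)."""
        if isinstance(mask_or_names, (list, tuple, set, frozenset)) or (
            isinstance(mask_or_names, np.ndarray) and mask_or_names.dtype.kind in "OU"
        ):
            wanted = set(mask_or_names)
            mask = self.meta["name"].isin(wanted).to_numpy()
        else:
            mask = np.asarray(mask_or_names, dtype=bool)
        idx = np.flatnonzero(mask)
        return FeatureMatrix(self.values[:, idx], self.meta.iloc[idx])

    def select_sources(self, sources: Iterable[str]) -> "FeatureMatrix":
        return self.select(self.meta["source"].isin(set(sources)).to_numpy())

    @classmethod
    def hstack(cls, blocks: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not blocks:
            raise ValueError("no blocks to stack")
        values = sp.hstack([b.values for b in blocks], format="csr")
        meta = pd.concat([b.meta for b in blocks], ignore_index=True)
        return cls(values, meta)

    def save(self, prefix: str | Path) -> None:
        """Write `<prefix>.mtx` (MatrixMarket) + `<prefix>.features.csv`."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(self.values))
        self.meta.to_csv(prefix.with_suffix(".features.csv"), index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        values = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        meta = pd.read_csv(prefix.with_suffix(".features.csv"))
        return cls(values, meta)


# ---------------------------------------------------------------------------
# tokenization and stop words
# ---------------------------------------------------------------------------


def tokenize(text: str) -> list[str]:
    """Lowercase and split on maximal runs of non-alphanumeric characters.

    Digits are retained ("BP 140/90" -> ["bp", "140", "90"]); empty tokens
    are dropped and order is preserved.
    """
    return _TOKEN_RE.findall(text.lower())


def default_stopwords() -> frozenset:
    """The packaged ~150-word English function-word list."""
    global _STOPWORDS
    if _STOPWORDS is None:
        text = resources.files("hdproxy").joinpath("data/stopwords.txt").read_text()
        _STOPWORDS = frozenset(w for w in text.split() if w)
    return _STOPWORDS


_STOPWORDS = None


def load_stopwords(path: str | Path) -> frozenset:
    """Load a user stop-word list: plain text, one token per line."""
    return frozenset(w for w in Path(path).read_text().split() if w)


# ---------------------------------------------------------------------------
# n-grams
# ---------------------------------------------------------------------------


def extract_ngrams(
    documents_by_patient: Sequence[Sequence[Sequence[str]]],
    stopwords: frozenset | set = None,
    n_max: int = 2,
) -> list[set]:
    """Per-patient sets of unigram/bigram presence features.

    Stop words are removed first; bigrams are consecutive pairs of the
    *filtered* sequence and never span document boundaries.  A feature is
    present iff the n-gram occurs in any of the patient's documents, so
    the result is idempotent in document multiplicity.
    """
    if n_max not in (1, 2):
        raise ValueError("n_max must be 1 or 2 (unigrams and bigrams only)")
    if stopwords is None:
        stopwords = default_stopwords()
    out: list[set] = []
    for docs in documents_by_patient:
        grams: set = set()
        for doc in docs:
            kept = [t for t in doc if t not in stopwords]
            grams.update(kept)
            if n_max == 2:
                grams.update(f"{a}_{b}" for a, b in zip(kept, kept[1:]))
        out.append(grams)
    return out


# ---------------------------------------------------------------------------
# lexicon / concept matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lexicon:
    """Term -> concept mapping for lexical concept extraction.

    ``entries`` maps token tuples (one or more tokens) to concept
    identifiers; build from strings with :meth:`from_terms` or from a
    two-column CSV (term, concept_id) with :meth:`from_csv`.
    """

    entries: Mapping[tuple, str]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("lexicon must be non-empty")
        for term, concept in self.entries.items():
            if not term or any(not t for t in term):
                raise ValueError("lexicon terms must be non-empty token tuples")
            if not concept:
                raise ValueError(f"empty concept id for term {term}")

    @classmethod
    def from_terms(cls, mapping: Mapping[str, str]) -> "Lexicon":
        return cls({tuple(tokenize(term)): cid for term, cid in mapping.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        df = pd.read_csv(path)
        return cls.from_terms(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_csv(self, path: str | Path) -> None:
        rows = [(" ".join(term), cid) for term, cid in sorted(self.entries.items())]
        pd.DataFrame(rows, columns=["term", "concept_id"]).to_csv(path, index=False)

    @property
    def max_len(self) -> int:
        return max(len(t) for t in self.entries)


def match_lexicon(
    documents_by_patient: Sequence[Sequence[Sequence[str]]], lexicon: Lexicon
) -> list[set]:
    """Greedy longest-match concept extraction per patient.

    Scans each tokenized document left to right; at each position the
    longest matching lexicon term wins, the concept is emitted, and the
    scan resumes after the matched span (nested shorter matches are
    suppressed).  A concept is present for a patient iff it matched in
    any document.
    """
    entries = lexicon.entries
    max_len = lexicon.max_len
    out: list[set] = []
    for docs in documents_by_patient:
        concepts: set = set()
        for doc in docs:
            doc = tuple(doc)
            i, n = 0, len(doc)
            while i < n:
                for span in range(min(max_len, n - i), 0, -1):
                    concept = entries.get(doc[i : i + span])
                    if concept is not None:
                        concepts.add(concept)
                        i += span
                        break
                else:
                    i += 1
        out.append(concepts)
    return out


# ---------------------------------------------------------------------------
# embedding providers
# ---------------------------------------------------------------------------


class EmbedderProvider(Protocol):
    dim: int
    contextual: bool

    def embed(self, tokens: Sequence[str], position: int) -> np.ndarray: ...


def _hash_rng(key: str) -> np.random.Generator:
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


class HashEmbedder:
    """Deterministic non-contextual token embedder.

    Each token maps to a fixed pseudo-random unit-norm vector keyed by
    (token, seed); identical tokens always receive identical vectors,
    irrespective of position or context.
    """

    contextual = False

    def __init__(self, dim: int, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, key: str) -> np.ndarray:
        v = self._cache.get(key)
        if v is None:
            rng = _hash_rng(f"{self.seed}\x00{key}")
            v = rng.standard_normal(self.dim)
            v /= np.linalg.norm(v)
            self._cache[key] = v
        return v

    def embed(self, tokens: Sequence[str], position: int) -> np.ndarray:
        return self._vector(f"tok\x00{tokens[position]}")

    def embed_token(self, token: str) -> np.ndarray:
        return self._vector(f"tok\x00{token}")

    def embed_sentence(self, tokens: Sequence[str]) -> np.ndarray:
        """Mean of token vectors (the non-contextual sentence embedding)."""
        if not tokens:
            raise ValueError("cannot embed an empty sentence")
        return np.mean([self.embed(tokens, i) for i in range(len(tokens))], axis=0)


class ContextualHashEmbedder(HashEmbedder):
    """Context-sensitive variant: the token vector is perturbed by a hashed
    vector of its two flanking tokens, so the same token embeds differently
    in different contexts (the contextual-word stand-in)."""

    contextual = True

    def __init__(self, dim: int, seed: int = 0, context_weight: float = 0.5):
        super().__init__(dim, seed)
        self.context_weight = float(context_weight)

    def embed(self, tokens: Sequence[str], position: int) -> np.ndarray:
        tok = tokens[position]
        prev = tokens[position - 1] if position > 0 else "<s>"
        nxt = tokens[position + 1] if position + 1 < len(tokens) else "</s>"
        v = self._vector(f"tok\x00{tok}") + self.context_weight * self._vector(
            f"ctx\x00{prev}\x00{nxt}"
        )
        return v / np.linalg.norm(v)


def hash_embedder(dim: int, seed: int = 0, contextual: bool = False) -> HashEmbedder:
    """Factory for the built-in deterministic embedding providers."""
    cls = ContextualHashEmbedder if contextual else HashEmbedder
    return cls(dim, seed)


# ---------------------------------------------------------------------------
# embedding clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    seed: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")


def _patient_units(cohort, unit: str) -> list[list]:
    """Per-patient deduplicated embeddable units.

    word: distinct tokens; contextual_word: distinct (prev, token, next)
    triples; sentence: documents (token tuples).  Per-patient
    deduplication makes the word-cluster feature map a function of each
    patient's token set; multiplicity across patients is retained when
    pooling for the clustering fit.
    """
    out = []
    for docs in (c for c in _iter_docs(cohort)):
        if unit == "word":
            units = sorted({t for doc in docs for t in doc})
        elif unit == "contextual_word":
            seen = set()
            for doc in docs:
                for i, t in enumerate(doc):
                    prev = doc[i - 1] if i > 0 else "<s>"
                    nxt = doc[i + 1] if i + 1 < len(doc) else "</s>"
                    seen.add((prev, t, nxt))
            units = sorted(seen)
        elif unit == "sentence":
            units = sorted({tuple(doc) for doc in docs if len(doc)})
        else:
            raise ValueError("unit must be one of {'word', 'contextual_word', 'sentence'}")
        out.append(units)
    return out


def _iter_docs(cohort):
    for i in range(cohort.n):
        yield [tokens for _, tokens in cohort.notes[i]]


def _embed_unit(provider, unit_kind: str, unit) -> np.ndarray:
    if unit_kind == "word":
        return provider.embed((unit,), 0)
    if unit_kind == "contextual_word":
        prev, tok, nxt = unit
        return provider.embed((prev, tok, nxt), 1)
    # sentence
    if hasattr(provider, "embed_sentence") and not provider.contextual:
        return provider.embed_sentence(unit)
    return np.mean([provider.embed(unit, i) for i in range(len(unit))], axis=0)


def cluster_features(
    cohort,
    provider: EmbedderProvider,
    unit: str,
    k: int,
    seed: int = 0,
    batch_size: int = 1024,
    max_iter: int = 100,
) -> tuple[ClusterModel, np.ndarray]:
    """Embedding-cluster features: mini-batch k-means over pooled units.

    All patients' units (deduplicated within patient) are embedded and
    pooled; mini-batch k-means (k-means++ init, fixed seed) is fit on the
    pool; a patient's feature ``c`` is 1 iff any of their units falls in
    cluster ``c``.  Returns the fitted :class:`ClusterModel` and an
    ``n_patients x k`` binary array.  Patients without notes get all-zero
    rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_patient = _patient_units(cohort, unit)
    unique_units: dict = {}
    patient_idx: list[list[int]] = []
    for units in per_patient:
        idxs = []
        for u in units:
            j = unique_units.get(u)
            if j is None:
                j = len(unique_units)
                unique_units[u] = j
            idxs.append(j)
        patient_idx.append(idxs)
    n_unique = len(unique_units)
    if n_unique == 0:
        raise ValueError("cohort has no embeddable units (no note tokens)")
    if k > n_unique:
        raise ValueError(f"k={k} exceeds the {n_unique} distinct units available")
    emb = np.empty((n_unique, provider.dim))
    for u, j in unique_units.items():
        emb[j] = _embed_unit(provider, unit, u)
    # pool with across-patient multiplicity for the fit
    pool_idx = np.concatenate([np.asarray(ix, dtype=int) for ix in patient_idx if ix])
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        max_iter=max_iter,
        n_init=3,
        init="k-means++",
    )
    km.fit(emb[pool_idx])
    assign = km.predict(emb)
    features = np.zeros((cohort.n, k))
    for i, idxs in enumerate(patient_idx):
        if idxs:
            features[i, np.unique(assign[np.asarray(idxs)])] = 1.0
    model = ClusterModel(k=k, centroids=km.cluster_centers_.copy(), seed=seed)
    return model, features


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------


def _researcher_block(cohort) -> FeatureMatrix:
    cols, names, is_binary = [], [], []
    for name in cohort.researcher_covariates:
        x = cohort.patients[name].to_numpy(dtype=float)
        binary = bool(np.isin(x, (0.0, 1.0)).all())
        cols.append(x)
        names.append(f"{_PREFIX['researcher']}:{name}")
        is_binary.append(binary)
    values = sp.csr_matrix(np.column_stack(cols))
    meta = pd.DataFrame({"name": names, "source": "researcher", "is_binary": is_binary})
    return FeatureMatrix(values, meta)


def _indicator_block(sets: Sequence[frozenset], source: str) -> FeatureMatrix:
    all_codes = sorted(set().union(*sets)) if sets else []
    idx = {c: j for j, c in enumerate(all_codes)}
    rows, cols = [], []
    for i, s in enumerate(sets):
        for c in s:
            rows.append(i)
            cols.append(idx[c])
    values = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(sets), len(all_codes))
    )
    meta = pd.DataFrame(
        {
            "name": [f"{_PREFIX[source]}:{c}" for c in all_codes],
            "source": source,
            "is_binary": True,
        }
    )
    return FeatureMatrix(values, meta)


def _setlist_block(sets: Sequence[set], source: str) -> FeatureMatrix:
    return _indicator_block([frozenset(s) for s in sets], source)


def build_feature_matrix(
    cohort,
    sources: Sequence[str],
    *,
    lexicon: Lexicon | None = None,
    embed_dim: int = 32,
    embed_seed: int = 0,
    k: int = 500,
    cluster_seed: int = 0,
    stopwords: frozenset | None = None,
    ngram_max: int = 2,
    providers: Mapping[str, EmbedderProvider] | None = None,
) -> FeatureMatrix:
    """Assemble the candidate feature matrix from the requested sources.

    Column blocks are concatenated in the order given by ``sources``.
    Dichotomous researcher covariates pass through as-is; continuous ones
    (age) are retained unchanged and flagged non-binary in the metadata.
    NLP blocks default to the built-in hash embedders; pass ``providers``
    (keyed by cluster source tag) to substitute real embedding models.
    """
    if not sources:
        raise ValueError("at least one source tag is required")
    unknown = [s for s in sources if s not in SOURCE_TAGS]
    if unknown:
        raise ValueError(f"unknown source tags {unknown}; valid tags: {SOURCE_TAGS}")
    providers = dict(providers or {})
    docs_by_patient = None

    def docs():
        nonlocal docs_by_patient
        if docs_by_patient is None:
            docs_by_patient = [cohort.note_token_docs(i) for i in range(cohort.n)]
        return docs_by_patient

    blocks = []
    for source in sources:
        if source == "researcher":
            blocks.append(_researcher_block(cohort))
        elif source == "claims":
            blocks.append(_indicator_block(cohort.claims_codes, "claims"))
        elif source == "ehr_code":
            blocks.append(_indicator_block(cohort.ehr_codes, "ehr_code"))
        elif source == "ngram":
            grams = extract_ngrams(docs(), stopwords=stopwords, n_max=ngram_max)
            blocks.append(_setlist_block(grams, "ngram"))
        elif source == "lexicon":
            if lexicon is None:
                raise ValueError("source 'lexicon' requires a lexicon")
            concepts = match_lexicon(docs(), lexicon)
            blocks.append(_setlist_block(concepts, "lexicon"))
        else:  # cluster schemes
            unit = {
                "cluster_word": "word",
                "cluster_contextual": "contextual_word",
                "cluster_sentence": "sentence",
            }[source]
            provider = providers.get(source)
            if provider is None:
                provider = hash_embedder(
                    embed_dim, embed_seed, contextual=(unit == "contextual_word")
                )
            _, feats = cluster_features(cohort, provider, unit, k, seed=cluster_seed)
            meta = pd.DataFrame(
                {
                    "name": [f"{_PREFIX[source]}:{j:04d}" for j in range(feats.shape[1])],
                    "source": source,
                    "is_binary": True,
                }
            )
            blocks.append(FeatureMatrix(sp.csr_matrix(feats), meta))
    return FeatureMatrix.hstack(blocks)
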