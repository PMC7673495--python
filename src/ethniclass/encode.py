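"""Design-matrix construction.

Multi-valued token groups (name entities, letters, substrings, phonemes)
are count-vectorized over vocabularies fitted on the training partition;
single-valued categoricals (the four location features, sex) are one-hot
encoded; numeric name statistics are scaled to zero mean and unit
variance (population variance; constant columns map to zero). The
benchmark "dummy" group is a label-independent random string feature and
random numeric feature.

``CensusFeaturizer`` is a scikit-learn transformer over a raw DataFrame
with ``name``/``location``/``sex`` columns; the module-level functions
(`fit_vocabulary`, `vectorize`, ...) expose the individual encoding steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import name_features
from .ingest import clean_name, split_name
from .location_features import parse_location
from .name_features import NUMERIC_STAT_NAMES

FEATURE_GROUPS = ("basic", "substrings", "numeric", "phonetic", "location", "sex", "dummy")
#: Individual name groups subject to the a-priori selection criterion.
NAME_GROUPS = ("basic", "substrings", "numeric", "phonetic")

N_DUMMY_TOKENS = 1000


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named composition of feature groups — the unit of feature-set
    selection."""

    name: str
    groups: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")


def _spec(name, *groups):
    return FeatureSetSpec(name, frozenset(groups))


#: The candidate feature sets of the selection protocol, in evaluation order.
PRESETS: dict[str, FeatureSetSpec] = {
    s.name: s
    for s in (
        _spec("Dummy features only", "dummy"),
        _spec("Sex only", "sex"),
        _spec("Basic name features", "basic"),
        _spec("Name substring features", "substrings"),
        _spec("Numeric name features", "numeric"),
        _spec("Phonetic name features", "phonetic"),
        _spec("All name features", *NAME_GROUPS),
        _spec("All location features", "location"),
        _spec("All name and location features", *NAME_GROUPS, "location"),
    )
}


def resolve_spec(spec) -> FeatureSetSpec:
    if isinstance(spec, FeatureSetSpec):
        return spec
    if isinstance(spec, str):
        try:
            return PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown feature set {spec!r}; presets: {sorted(PRESETS)}"
            ) from None
    raise TypeError(f"feature set must be a name or FeatureSetSpec, got {type(spec)}")


def fit_vocabulary(tokens, group: str = "") -> dict[str, int]:
    """Deterministic token -> column-index mapping (lexicographic order),
    fitted on training-partition tokens only."""
    vocab = sorted(set(tokens))
    if not vocab:
        raise ValueError(f"no tokens to build a vocabulary for group {group!r}")
    return {tok: j for j, tok in enumerate(vocab)}


def vectorize(token_lists, vocab: dict[str, int]) -> sp.csr_matrix:
    """Count-vectorize per-record token lists against a fitted vocabulary.

    Entry (i, j) is the multiplicity of token j in record i (0/1 when the
    extractor deduplicated); out-of-vocabulary tokens are ignored.
    """
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for tokens in token_lists:
        for tok in tokens:
            j = vocab.get(tok)
            if j is not None:
                indices.append(j)
                data.append(1)
        indptr.append(len(indices))
    mat = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(indptr) - 1, len(vocab)),
    )
    mat.sum_duplicates()
    return mat


def one_hot(values, encoder: OneHotEncoder) -> sp.csr_matrix:
    """Apply a fitted one-hot encoder; unknown categories encode all-zero."""
    arr = np.asarray(list(values), dtype=object).reshape(-1, 1)
    return encoder.transform(arr).tocsr()


def scale_numeric(stats: np.ndarray, scaler: StandardScaler) -> np.ndarray:
    """Z-scale numeric columns with training moments (population variance;
    constant columns map to 0)."""
    return scaler.transform(np.asarray(stats, dtype=np.float64))


class CensusFeaturizer(TransformerMixin, BaseEstimator):
    """Transform raw census-style records into a sparse design matrix.

    Parameters
    ----------
    feature_set : str or FeatureSetSpec, default "All name and location features"
        Which feature groups to encode. Presets reproduce the candidate
        rows of the selection protocol.
    dedup_tokens : bool, default True
        Collapse within-cell duplicate tokens before counting (per-record
        values then are 0/1). ``False`` counts multiplicities.
    strip_apostrophes : bool, default True
        Name-cleaning policy for apostrophes/hyphens.
    random_state : int or None
        Seed for the label-independent dummy features.

    The featurizer is fitted on the training partition only: vocabularies,
    one-hot categories and scaling moments never see test rows.
    """

    def __init__(
        self,
        feature_set="All name and location features",
        dedup_tokens: bool = True,
        strip_apostrophes: bool = True,
        name_col: str = "name",
        location_col: str = "location",
        sex_col: str = "sex",
        random_state=None,
    ):
        self.feature_set = feature_set
        self.dedup_tokens = dedup_tokens
        self.strip_apostrophes = strip_apostrophes
        self.name_col = name_col
        self.location_col = location_col
        self.sex_col = sex_col
        self.random_state = random_state

    # -- parsing ---------------------------------------------------------

    def _parse(self, X: pd.DataFrame):
        spec = resolve_spec(self.feature_set)
        need_names = bool(set(NAME_GROUPS) & spec.groups)
        need_loc = "location" in spec.groups
        parsed = []
        for _, row in X.iterrows():
            rec = {}
            if need_names:
                cleaned = clean_name(
                    str(row[self.name_col]), strip_apostrophes=self.strip_apostrophes
                )
                rec["bundle"] = name_features.extract_all(
                    split_name(cleaned if cleaned else "unknown"),
                    dedup=self.dedup_tokens,
                )
            if need_loc:
                rec["location"] = parse_location(str(row[self.location_col]))
            if "sex" in spec.groups:
                rec["sex"] = str(row[self.sex_col]).strip().lower()
            parsed.append(rec)
        return spec, parsed

    @staticmethod
    def _group_tokens(rec, group: str) -> list[str]:
        bundle = rec["bundle"]
        if group == "basic":
            return bundle.basic_group
        if group == "substrings":
            return bundle.substring_tokens
        if group == "phonetic":
            return bundle.phonetic_tokens
        raise KeyError(group)

    # -- sklearn API -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) == 0:
            raise ValueError("cannot fit a featurizer on an empty record table")
        spec, parsed = self._parse(X)
        self.spec_ = spec
        self.vocabularies_ = {}
        for group in ("basic", "substrings", "phonetic"):
            if group in spec.groups:
                all_tokens = (t for rec in parsed for t in self._group_tokens(rec, group))
                self.vocabularies_[group] = fit_vocabulary(all_tokens, group)
        if "numeric" in spec.groups:
            stats = np.array([rec["bundle"].numerics.as_tuple() for rec in parsed])
            self.scaler_ = StandardScaler().fit(stats)  # population variance
        self.onehot_encoders_ = {}
        for col, values in self._categorical_columns(spec, parsed):
            enc = OneHotEncoder(handle_unknown="ignore", sparse_output=True)
            enc.fit(np.asarray(values, dtype=object).reshape(-1, 1))
            self.onehot_encoders_[col] = enc
        self.feature_names_out_ = self._feature_names(spec)
        self.n_features_out_ = len(self.feature_names_out_)
        return self

    @staticmethod
    def _categorical_columns(spec, parsed):
        if "location" in spec.groups:
            for fieldname in ("full_string", "province", "district", "subdistrict"):
                yield (
                    f"location_{fieldname}",
                    [getattr(rec["location"], fieldname) for rec in parsed],
                )
        if "sex" in spec.groups:
            yield "sex", [rec["sex"] for rec in parsed]

    def _feature_names(self, spec) -> list[str]:
        names: list[str] = []
        for group in ("basic", "substrings", "phonetic"):
            if group in spec.groups:
                names.extend(sorted(self.vocabularies_[group], key=self.vocabularies_[group].get))
        if "numeric" in spec.groups:
            names.extend(f"numeric:{s}" for s in NUMERIC_STAT_NAMES)
        for col, enc in self.onehot_encoders_.items():
            names.extend(f"{col}={c}" for c in enc.categories_[0])
        if "dummy" in spec.groups:
            names.extend(["dummy:string", "dummy:numeric"])
        return names

    def transform(self, X: pd.DataFrame) -> sp.csr_matrix:
        check_is_fitted(self, "spec_")
        spec, parsed = self._parse(X)
        blocks: list[sp.spmatrix] = []
        for group in ("basic", "substrings", "phonetic"):
            if group in spec.groups:
                blocks.append(
                    vectorize(
                        [self._group_tokens(rec, group) for rec in parsed],
                        self.vocabularies_[group],
                    )
                )
        if "numeric" in spec.groups:
            stats = np.array([rec["bundle"].numerics.as_tuple() for rec in parsed])
            blocks.append(sp.csr_matrix(scale_numeric(stats, self.scaler_)))
        for col, values in self._categorical_columns(spec, parsed):
            blocks.append(one_hot(values, self.onehot_encoders_[col]))
        if "dummy" in spec.groups:
            rng = np.random.default_rng(self.random_state)
            dummy = np.column_stack(
                [
                    rng.integers(0, N_DUMMY_TOKENS, size=len(parsed)).astype(float),
                    rng.uniform(0.0, 1.0, size=len(parsed)),
                ]
            )
            blocks.append(sp.csr_matrix(dummy))
        out = sp.hstack(blocks, format="csr")
        assert out.shape[1] == self.n_features_out_
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


def assemble(records: pd.DataFrame, spec, featurizer: CensusFeaturizer | None = None):
    """Fit-or-apply convenience wrapper returning (matrix, featurizer).

    When *featurizer* is None a new one is fitted on *records* (which must
    then be the training partition); otherwise the fitted encoders are
    applied unchanged.
    """
    if featurizer is None:
        featurizer = CensusFeaturizer(feature_set=spec)
        return featurizer.fit_transform(records), featurizer
    return featurizer.transform(records), featurizer
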