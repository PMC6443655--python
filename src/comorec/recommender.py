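"""Item-based recommender over diagnosis-code co-occurrence.

Diseases play the role of items and patients the role of users: the
patient x disease-category incidence matrix is binarized, item-item
similarity is the Jaccard index between the patient sets of two
categories, and querying a disease returns the top-K most similar
categories.  A held-out single-item protocol estimates top-N precision
and recall on a test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .claims import (
    ClaimsDataset,
    ClaimsError,
    CodeRange,
    ConfigurationError,
    category_of,
    in_any_range,
    normalize_code,
)

log = logging.getLogger(__name__)


@dataclass
class IncidenceMatrix:
    """Sparse binary patients x disease-codes presence matrix.

    The code index is sorted lexicographically; this canonical order is
    also the tie-break order for equal similarities downstream.
    """

    patient_index: list[str]
    category_index: list[str]
    presence: sp.csr_matrix
    n_dropped_patients: int = 0

    def column_of(self, category: str) -> int:
        try:
            return self.category_index.index(normalize_code(category))
        except ValueError:
            raise ClaimsError(f"unknown category {category!r}") from None


@dataclass
class SimilarityModel:
    """Symmetric disease x disease Jaccard similarity matrix in [0, 1]."""

    category_index: list[str]
    sim: np.ndarray
    empty_categories: frozenset[str] = frozenset()

    def similarity(self, a: str, b: str) -> float:
        ia = self.category_index.index(normalize_code(a))
        ib = self.category_index.index(normalize_code(b))
        return float(self.sim[ia, ib])


@dataclass
class Recommendation:
    """Ranked recommendations for one query disease (query never included)."""

    query: str
    ranked: list[tuple[str, float]]

    @property
    def categories(self) -> list[str]:
        return [c for c, _ in self.ranked]


@dataclass
class RSValidation:
    """Held-out evaluation summary: mean precision/recall at n_rec."""

    mean_precision: float
    mean_recall: float
    n_eval_patients: int
    n_rec: int
    n_skipped: int = 0


def build_incidence(
    dataset: ClaimsDataset, code_level: str = "category"
) -> IncidenceMatrix:
    """Build the binary patients x codes matrix at category or full-code level.

    Patients with no diagnoses are dropped (count logged); duplicate codes
    within a patient contribute a single 1.
    """
    if code_level not in ("category", "full"):
        raise ConfigurationError(f"code_level must be 'category' or 'full'")
    if len(dataset) == 0:
        raise ClaimsError("cannot build incidence from an empty dataset")

    kept: list[tuple[str, frozenset[str]]] = []
    n_dropped = 0
    for rec in dataset:
        codes = rec.categories if code_level == "category" else rec.diagnoses
        if codes:
            kept.append((rec.patient_id, codes))
        else:
            n_dropped += 1
    if n_dropped:
        log.info("build_incidence: dropped %d diagnosis-free patient(s)", n_dropped)
    if not kept:
        raise ClaimsError("no patients with diagnoses")

    categories = sorted({c for _, codes in kept for c in codes})
    col = {c: j for j, c in enumerate(categories)}
    rows, cols = [], []
    for i, (_, codes) in enumerate(kept):
        for c in codes:
            rows.append(i)
            cols.append(col[c])
    presence = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(kept), len(categories)),
    )
    return IncidenceMatrix(
        patient_index=[pid for pid, _ in kept],
        category_index=categories,
        presence=presence,
        n_dropped_patients=n_dropped,
    )


def train_test_split(
    dataset: ClaimsDataset, train_fraction: float, seed: int
) -> tuple[ClaimsDataset, ClaimsDataset]:
    """Deterministic patient-level partition into train/test datasets."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0,1)")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(dataset) if i in train_idx]
    test = [r for i, r in enumerate(dataset) if i not in train_idx]
    return (
        ClaimsDataset(train, provenance=f"{dataset.provenance}[train]"),
        ClaimsDataset(test, provenance=f"{dataset.provenance}[test]"),
    )


def jaccard_similarity(m: IncidenceMatrix) -> SimilarityModel:
    """Jaccard similarity |P_a & P_b| / |P_a | P_b| between all code pairs.

    P_x is the set of patients carrying code x.  Codes carried by zero
    patients get similarity 0 to everything, including themselves, and
    are flagged in the model.
    """
    presence = m.presence
    counts = np.asarray(presence.sum(axis=0)).ravel().astype(np.float64)
    inter = np.asarray((presence.T @ presence).todense(), dtype=np.float64)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    empty = frozenset(
        c for c, n in zip(m.category_index, counts) if n == 0
    )
    return SimilarityModel(
        category_index=list(m.category_index), sim=sim, empty_categories=empty
    )


def recommend(
    model: SimilarityModel,
    query: str,
    k: int,
    exclusions: tuple[CodeRange, ...] | list[CodeRange] = (),
    *,
    exclude_before_ranking: bool = False,
) -> Recommendation:
    """Top-k categories most similar to the query, with range exclusions.

    By default all categories except the query are ranked by similarity
    (ties broken lexicographically), the top k are taken, and only then
    are categories inside the exclusion ranges removed — mirroring an
    extract-then-exclude candidate workflow, so fewer than k survivors
    may remain.  With ``exclude_before_ranking`` the filter is applied
    before the cut and exactly k survivors are returned when available.
    """
    query = normalize_code(query)
    if query not in model.category_index:
        raise ClaimsError(f"query category {query!r} not in model")
    if k < 1:
        raise ConfigurationError("k must be >= 1")

    qi = model.category_index.index(query)
    candidates = [
        (c, float(model.sim[qi, j]))
        for j, c in enumerate(model.category_index)
        if c != query and c not in model.empty_categories
    ]
    if exclude_before_ranking:
        candidates = [
            (c, s)
            for c, s in candidates
            if not in_any_range(category_of(c), exclusions)
        ]
    candidates.sort(key=lambda cs: (-cs[1], cs[0]))
    top = candidates[:k]
    if not exclude_before_ranking:
        top = [
            (c, s) for c, s in top if not in_any_range(category_of(c), exclusions)
        ]
    return Recommendation(query=query, ranked=top)


def evaluate_rs(
    model: SimilarityModel,
    test: ClaimsDataset,
    n_rec: int,
    seed: int = 0,
) -> RSValidation:
    """Single-held-out-item top-N evaluation of the similarity model.

    For each test patient with >= 2 distinct categories, one category
    known to the model is held out uniformly at random as the query; the
    model's top ``n_rec`` recommendations are compared against the
    patient's remaining categories.  Per patient, precision = hits/n_rec
    and recall = hits/|remaining|; the unweighted means over eligible
    patients are returned.  Deterministic under a fixed seed.
    """
    if n_rec < 1:
        raise ConfigurationError("n_rec must be >= 1")
    rng = np.random.default_rng(seed)
    known = set(model.category_index) - set(model.empty_categories)

    precisions, recalls = [], []
    n_skipped = 0
    rec_cache: dict[str, list[str]] = {}
    for rec in test:
        cats = sorted(rec.categories)
        queryable = [c for c in cats if c in known]
        if len(cats) < 2 or not queryable:
            n_skipped += 1
            continue
        query = queryable[rng.integers(len(queryable))]
        remaining = set(cats) - {query}
        if query not in rec_cache:
            rec_cache[query] = recommend(model, query, n_rec).categories
        hits = len(set(rec_cache[query]) & remaining)
        precisions.append(hits / n_rec)
        recalls.append(hits / len(remaining))
    if not precisions:
        raise ClaimsError("no eligible test patients for evaluation")
    if n_skipped:
        log.info("evaluate_rs: skipped %d ineligible patient(s)", n_skipped)
    return RSValidation(
        mean_precision=float(np.mean(precisions)),
        mean_recall=float(np.mean(recalls)),
        n_eval_patients=len(precisions),
        n_rec=n_rec,
        n_skipped=n_skipped,
    )
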