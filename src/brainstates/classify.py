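"""Pairwise condition classification of unthresholded correlation matrices.

A linear SVM separates the two conditions; performance is estimated by
leave-one-subject-out cross-validation (both paired samples of a subject
held out per fold) and its significance by paired label permutation.
Hyperplane weights are mapped back onto edges, split by sign into per-
condition importance maps, and the top classifying edges are counted by
anatomical kind (subdivision-class pair x correlation sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.svm import SVC

from .atlas import CORTICAL, ConnectivityMatrix, ROIAtlas, ValidationError


def vectorize_features(matrix: ConnectivityMatrix) -> np.ndarray:
    """Upper triangle (i < j, row-major) of the correlation matrix."""
    return matrix.upper_triangle()


def devectorize(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_features`: symmetric matrix, zero diagonal."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


@dataclass
class ClassificationResult:
    comparison: str
    subjects: list[str]
    fold_true: np.ndarray
    fold_pred: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    weight_matrix: np.ndarray = field(repr=False)
    svm_cost: float = 1.0
    p_perm: float | None = None
    p_perm_bonferroni: float | None = None
    n_perm: int = 0


def _stack(group_a: list[ConnectivityMatrix], group_b: list[ConnectivityMatrix]):
    if len(group_a) != len(group_b):
        raise ValidationError("groups must have equal size (paired design)")
    subj_a = [m.subject for m in group_a]
    subj_b = [m.subject for m in group_b]
    if any(subj_a) and any(subj_b) and subj_a != subj_b:
        raise ValidationError("groups must be paired by subject, in the same order")
    x = np.vstack([vectorize_features(m) for m in group_a + group_b])
    n = len(group_a)
    y = np.concatenate([np.ones(n), -np.ones(n)])  # class A coded +1
    return x, y, subj_a if any(subj_a) else [f"s{i}" for i in range(n)]


def _loocv_predictions(gram: np.ndarray, y: np.ndarray, n_subj: int,
                       cost: float) -> np.ndarray:
    """Subject-wise LOOCV on a precomputed linear kernel; returns predictions."""
    pred = np.empty_like(y)
    idx = np.arange(len(y))
    for s in range(n_subj):
        test = np.array([s, s + n_subj])
        train = np.setdiff1d(idx, test)
        clf = SVC(kernel="precomputed", C=cost)
        clf.fit(gram[np.ix_(train, train)], y[train])
        pred[test] = clf.predict(gram[np.ix_(test, train)])
    return pred


def loocv_classify(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    svm_cost: float = 1.0,
    comparison: str = "A vs B",
) -> ClassificationResult:
    """Leave-one-subject-out linear-SVM classification of paired groups.

    One fold per subject: both of that subject's samples are held out, the
    SVM is trained on the remaining 2(n-1) samples, and both held-out
    samples are predicted. Accuracy is the percentage of correct held-out
    predictions; sensitivity/specificity are the per-class percentages
    (class A / class B). The reported weight matrix comes from the SVM
    trained on all samples, mapped back onto edges.
    """
    x, y, subjects = _stack(group_a, group_b)
    n_subj = len(group_a)
    gram = x @ x.T
    pred = _loocv_predictions(gram, y, n_subj, svm_cost)
    correct = pred == y
    acc = 100.0 * correct.mean()
    sens = 100.0 * correct[:n_subj].mean()
    spec = 100.0 * correct[n_subj:].mean()
    final = SVC(kernel="precomputed", C=svm_cost).fit(gram, y)
    w_vec = final.dual_coef_[0] @ x[final.support_]
    return ClassificationResult(
        comparison=comparison,
        subjects=subjects,
        fold_true=y,
        fold_pred=pred,
        accuracy=float(acc),
        sensitivity=float(sens),
        specificity=float(spec),
        weight_matrix=devectorize(w_vec, group_a[0].n),
        svm_cost=svm_cost,
    )


def permutation_test(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    observed_accuracy: float,
    n_perm: int = 10_000,
    seed: int = 0,
    svm_cost: float = 1.0,
    family_size: int = 1,
) -> tuple[float, float]:
    """Paired label-permutation p for a LOOCV accuracy.

    Each permutation independently flips each subject's pair of labels
    with probability 1/2 (the exchangeable operations under the paired
    null), reruns the full LOOCV, and records the accuracy.
    p = (1 + #{perm >= observed}) / (n_perm + 1); the Bonferroni-adjusted
    value multiplies by ``family_size``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x, y, _ = _stack(group_a, group_b)
    n_subj = len(group_a)
    gram = x @ x.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flip = rng.integers(0, 2, size=n_subj).astype(bool)
        y_perm = y.copy()
        y_perm[:n_subj][flip] *= -1
        y_perm[n_subj:][flip] *= -1
        pred = _loocv_predictions(gram, y_perm, n_subj, svm_cost)
        if 100.0 * (pred == y_perm).mean() >= observed_accuracy:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return p, min(1.0, p * family_size)


@dataclass
class ImportanceMap:
    """Per-condition sparse evidence maps.

    An edge belongs to a condition's map when its signed contribution to
    the SVM decision pushes that condition's (correctly classified)
    samples toward their own side of the hyperplane. Map values are
    |weight| x mean correlation over that condition's correctly
    classified samples, so the value's sign is the sign of the underlying
    correlation: a negative map entry marks a negative correlation
    driving the classification.
    """

    map_a: np.ndarray = field(repr=False)
    map_b: np.ndarray = field(repr=False)
    label_a: str = "A"
    label_b: str = "B"


def importance_maps(
    result: ClassificationResult,
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
) -> ImportanceMap:
    """Per-condition evidence maps from hyperplane weights.

    With class A coded +1, an edge contributes to classifying A when
    ``w * mean_A > 0`` (its typical value in A pushes the decision
    function positive), and to classifying B when ``w * mean_B < 0``.
    Each map holds |w| x mean correlation of that class's correctly
    classified held-out samples on its contributing edges. The two
    supports may overlap at sign-discordant edges (an edge positive in
    one condition and negative in the other discriminates in both
    directions).
    """
    n_subj = len(group_a)
    correct = result.fold_pred == result.fold_true
    ok_a = [m for m, c in zip(group_a, correct[:n_subj]) if c]
    ok_b = [m for m, c in zip(group_b, correct[n_subj:]) if c]
    if not ok_a or not ok_b:
        raise ValidationError("a class has zero correctly classified samples")
    mean_a = np.mean([m.values for m in ok_a], axis=0)
    mean_b = np.mean([m.values for m in ok_b], axis=0)
    w = result.weight_matrix
    map_a = np.where(w * mean_a > 0, np.abs(w) * mean_a, 0.0)
    map_b = np.where(w * mean_b < 0, np.abs(w) * mean_b, 0.0)
    np.fill_diagonal(map_a, 0.0)
    np.fill_diagonal(map_b, 0.0)
    a_lab, _, b_lab = result.comparison.partition(" vs ")
    return ImportanceMap(map_a, map_b, a_lab or "A", b_lab or "B")


def top_edges(weight_matrix: np.ndarray, fraction: float = 0.01
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges ranked by |weight|, top round(fraction * M); (i, j, w) arrays."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    n = weight_matrix.shape[0]
    m = n * (n - 1) // 2
    k = int(np.floor(fraction * m + 0.5))
    iu, ju = np.triu_indices(n, k=1)
    w = weight_matrix[iu, ju]
    order = np.argsort(-np.abs(w), kind="stable")
    if fraction == 1.0:
        order = order[np.abs(w[order]) > 0]
    else:
        order = order[:k]
    return iu[order], ju[order], w[order]


# ---------------------------------------------------------------------------
# edge taxonomy

#: subdivision -> taxonomy class
_CLASS = {**{s: "cortex" for s in CORTICAL},
          "Thl": "thalamus", "BG": "striatum", "Crbl": "cerebellum",
          "BS": "brainstem"}

_PREFIX = {"thalamus": "thalamo", "striatum": "striato",
           "cerebellum": "cerebello", "brainstem": "brainstem",
           "cortex": "cortico"}
_SUFFIX = {"thalamus": "thalamic", "striatum": "striatal",
           "cerebellum": "cerebellar", "brainstem": "brainstem",
           "cortex": "cortical"}
_ORDER = ["thalamus", "striatum", "cerebellum", "brainstem", "cortex"]


def edge_kind_name(sub_i: str, sub_j: str) -> str:
    """Canonical pair name, e.g. 'thalamo-cortical' or 'cortico-cortical'."""
    a, b = sorted((_CLASS[sub_i], _CLASS[sub_j]), key=_ORDER.index)
    return f"{_PREFIX[a]}-{_SUFFIX[b]}"


@dataclass
class EdgeKindCounts:
    """Counts of classified edges by {class pair} x {positive, negative}."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {k: 100.0 * v / t for k, v in self.counts.items()} if t else {}

    def modal_kind(self) -> str:
        return max(self.counts, key=self.counts.get)


def classify_edge_kinds(
    edges: tuple[np.ndarray, np.ndarray, np.ndarray],
    atlas: ROIAtlas,
    sign_source: np.ndarray,
) -> EdgeKindCounts:
    """Assign each edge a kind: anatomical class pair x correlation sign.

    ``sign_source`` is the importance map of the contributing condition;
    its sign at the edge says whether a positive or a negative correlation
    drove the classification.
    """
    subdiv = atlas.subdivision
    counts: dict[str, int] = {}
    for i, j, _ in zip(*edges):
        sign = "positive" if sign_source[i, j] >= 0 else "negative"
        key = f"{edge_kind_name(subdiv[i], subdiv[j])}, {sign}"
        counts[key] = counts.get(key, 0) + 1
    return EdgeKindCounts(counts)


def compare_edge_distributions(
    counts_a: EdgeKindCounts, counts_b: EdgeKindCounts
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2 x k contingency table of edge kinds.

    Kinds absent from both conditions are dropped; no continuity
    correction is applied; df = k - 1.
    """
    kinds = sorted(set(counts_a.counts) | set(counts_b.counts))
    table = np.array([[counts_a.counts.get(k, 0) for k in kinds],
                      [counts_b.counts.get(k, 0) for k in kinds]], float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 0, 1.0
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
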