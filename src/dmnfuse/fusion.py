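"""Joint ICA fusion of multi-seed connectivity maps.

The selected seeds' maps are concatenated per subject into joint features
(rows of ``X``, one block of V voxels per seed) and the linear model

    X = A S

is fitted: ``S`` (K x NV) holds K joint spatial sources spanning all seed
blocks, and ``A`` (M x K) the per-subject mixing coefficients that all blocks
of one source share.  Estimation reduces the subject dimension to K by
economy SVD with whitening and runs Infomax ICA in the whitened space; the
mixing matrix is recovered through the whitening pseudo-inverse.  Held-out
subjects are projected onto the learned sources by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .connectivity import MapTable
from .infomax import infomax

DEFAULT_K = 8  #: default model order of the joint decomposition


@dataclass
class JointFeatureMatrix:
    """Concatenated, block-normalized maps: row i is subject i's joint feature."""

    X: np.ndarray  # (M, N*V)
    seed_order: list[str]
    block_norms: np.ndarray  # (N,)
    row_labels: list[tuple[str, str]]  # (subject_id, group)
    n_voxels: int

    @property
    def groups(self) -> list[str]:
        return [g for _, g in self.row_labels]


class JointFeatureBuilder(BaseEstimator, TransformerMixin):
    """Builds joint feature matrices with training-set block normalization.

    Each map is centered to zero mean across voxels (a per-subject operation),
    then each seed block is divided by the training cohort's root mean square
    over that block, so every block contributes equal mean sum-of-squares.
    The learned ``block_norms_`` are reused verbatim for held-out subjects.
    """

    def __init__(self, seed_subset: Sequence[str] = ()):
        self.seed_subset = seed_subset

    def _stack(self, maps: MapTable, subjects: Sequence[str]) -> np.ndarray:
        """(M, N, V) array of per-map voxel-centered values, in seed_subset order."""
        if not self.seed_subset:
            raise ValueError("seed_subset must be nonempty")
        idx = []
        for s in self.seed_subset:
            if s not in maps.seed_names:
                raise KeyError(f"seed {s!r} not present in the map table")
            idx.append(maps.seed_names.index(s))
        rows = []
        for sid in subjects:
            if sid not in maps.subjects:
                raise KeyError(f"missing maps for subject {sid!r}")
            rows.append(maps.subjects.index(sid))
        block = maps.data[np.ix_(rows, idx)]
        return block - block.mean(axis=2, keepdims=True)

    def fit(self, maps: MapTable, subjects: Sequence[str] | None = None) -> "JointFeatureBuilder":
        subjects = list(maps.subjects) if subjects is None else list(subjects)
        centered = self._stack(maps, subjects)
        ss = np.mean(centered**2, axis=(0, 2))  # per-seed mean sum-of-squares
        if np.any(ss == 0):
            ss = np.where(ss == 0, 1.0, ss)
        self.block_norms_ = np.sqrt(ss)
        self.voxel_index_ = maps.voxel_index.copy()
        self.n_voxels_ = maps.data.shape[2]
        return self

    def transform(self, maps: MapTable, subjects: Sequence[str] | None = None) -> JointFeatureMatrix:
        check_is_fitted(self, "block_norms_")
        if maps.voxel_index.shape != self.voxel_index_.shape or not np.array_equal(
            maps.voxel_index, self.voxel_index_
        ):
            raise ValueError("voxel index differs from the one used at fit time")
        subjects = list(maps.subjects) if subjects is None else list(subjects)
        centered = self._stack(maps, subjects)
        scaled = centered / self.block_norms_[None, :, None]
        m = scaled.shape[0]
        groups = {s: g for s, g in zip(maps.subjects, maps.groups)}
        return JointFeatureMatrix(
            X=scaled.reshape(m, -1),
            seed_order=list(self.seed_subset),
            block_norms=self.block_norms_.copy(),
            row_labels=[(s, groups[s]) for s in subjects],
            n_voxels=self.n_voxels_,
        )


def build_joint_features(
    maps: MapTable, subjects: Sequence[str], seed_subset: Sequence[str]
) -> JointFeatureMatrix:
    """Fit-and-transform convenience over :class:`JointFeatureBuilder`."""
    b = JointFeatureBuilder(seed_subset=seed_subset)
    return b.fit(maps, subjects).transform(maps, subjects)


class JointICA(BaseEstimator, TransformerMixin):
    """Joint ICA decomposition X = A S at model order ``n_components``.

    fit() pipeline: column-center X, reduce the subject dimension to K via
    economy SVD with whitening, run Infomax, back-reconstruct the mixing
    matrix through the whitening pseudo-inverse, then fix the sign of each
    source (largest-magnitude entry positive) and order sources by decreasing
    variance of their mixing column.

    Attributes
    ----------
    components_ : (K, NV) joint sources S.
    mixing_ : (M, K) training mixing coefficients A.
    mean_ : (NV,) column means removed before decomposition.
    unmixing_ : (K, K) Infomax unmixing matrix in the whitened space.
    whitening_ : (K, M) operator taking centered X rows to whitened space.
    dewhitening_ : (M, K) its pseudo-inverse.
    converged_, n_iter_ : Infomax convergence status.
    """

    def __init__(
        self,
        n_components: int = DEFAULT_K,
        random_state: int | None = None,
        max_iter: int = 512,
        tol: float = 1e-7,
        learning_rate: float = 1e-3,
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.learning_rate = learning_rate

    def fit(self, X, y=None) -> "JointICA":
        X = np.asarray(getattr(X, "X", X), dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x joint features)")
        m, nv = X.shape
        k = self.n_components
        if m < 2:
            raise ValueError("need at least 2 subjects")
        if k > min(m, nv):
            raise ValueError(f"n_components={k} exceeds min(M, NV)={min(m, nv)}")

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol_rank = s[0] * max(m, nv) * np.finfo(float).eps
        rank = int((s > tol_rank).sum())
        if k > rank:
            raise ValueError(f"n_components={k} exceeds rank(X)={rank}")

        # whitened data: K x NV with unit sample covariance across components
        scale = np.sqrt(nv)
        Z = scale * Vt[:k]
        self.whitening_ = scale * (U[:, :k] / s[:k]).T  # (K, M): W_wh @ Xc = Z... rowspace op
        self.dewhitening_ = U[:, :k] * s[:k] / scale  # (M, K)

        rng = np.random.default_rng(self.random_state)
        W, converged, n_iter = infomax(
            Z,
            rng,
            l_rate=self.learning_rate,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.converged_ = converged
        self.n_iter_ = n_iter

        S = W @ Z  # (K, NV)
        A = self.dewhitening_ @ np.linalg.inv(W)  # (M, K); A @ S = rank-K approx of Xc

        # resolve ICA ambiguities: sign, then order by mixing-column variance
        signs = np.sign(S[np.arange(k), np.argmax(np.abs(S), axis=1)])
        signs[signs == 0] = 1.0
        S = S * signs[:, None]
        A = A * signs[None, :]
        order = np.argsort(-A.var(axis=0), kind="stable")
        self.components_ = S[order]
        self.mixing_ = A[:, order]
        self.unmixing_ = (W * signs[:, None])[order]
        self.singular_values_ = s
        self._components_pinv = np.linalg.pinv(self.components_)
        return self

    def transform(self, X) -> np.ndarray:
        """Least-squares coefficients of (centered) rows of X on the sources."""
        check_is_fitted(self, "components_")
        X = np.asarray(getattr(X, "X", X), dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.components_.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.components_.shape[1]}"
            )
        return (X - self.mean_) @ self._components_pinv

    def inverse_transform(self, A: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(A) @ self.components_ + self.mean_


def fit_joint_ica(
    X: JointFeatureMatrix | np.ndarray, k: int = DEFAULT_K, rng_seed: int | None = None
) -> JointICA:
    """Fit the X = A S joint decomposition at model order ``k``."""
    return JointICA(n_components=k, random_state=rng_seed).fit(X)


def project_subjects(
    test_maps: MapTable,
    decomp: JointICA,
    builder: JointFeatureBuilder,
    subjects: Sequence[str] | None = None,
) -> np.ndarray:
    """Project held-out subjects onto fitted sources using training state.

    The joint features are built with the *training* block norms and the
    coefficients solve ``argmin_a ||x - a^T S||^2`` via the pseudo-inverse of
    S.  Applied to a training subject this reproduces its row of the mixing
    matrix up to the PCA truncation residual.
    """
    feats = builder.transform(test_maps, subjects)
    return decomp.transform(feats.X)


@dataclass
class SourceGroupStats:
    """Group comparison of the mixing columns: which source differs most."""

    t_values: np.ndarray
    p_values: np.ndarray
    most_different: int


def rank_sources(A: np.ndarray, groups: Sequence[str]) -> SourceGroupStats:
    """Pooled two-sample t per mixing column; most different = argmax |t|.

    Ties resolve to the lower source index.
    """
    A = np.asarray(A, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    g1, g2 = A[groups == labels[0]], A[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
    return SourceGroupStats(
        t_values=np.asarray(t), p_values=np.asarray(p), most_different=int(np.argmax(np.abs(t)))
    )


def split_joint_source(
    decomp: JointICA, source_index: int, seed_subset: Sequence[str]
) -> dict[str, np.ndarray]:
    """Cut source row ``source_index`` at block boundaries: one map per seed."""
    check_is_fitted(decomp, "components_")
    k, nv = decomp.components_.shape
    if not 0 <= source_index < k:
        raise IndexError(f"source_index {source_index} out of range [0, {k})")
    n = len(seed_subset)
    if nv % n:
        raise ValueError(f"{nv} joint features do not split into {n} equal blocks")
    v = nv // n
    row = decomp.components_[source_index]
    return {s: row[i * v : (i + 1) * v] for i, s in enumerate(seed_subset)}
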