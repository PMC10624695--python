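"""Nearest affine-subspace classifier on scattering feature vectors.

Each class ``k`` is modeled by the affine space

    A_{d,k} = mean_k + span(top-d principal directions of class k)

estimated from the training scattering vectors of that class, and a sample is
assigned to the class whose affine space it is closest to in Euclidean
residual ``|| v - P_{A_{d,k}}(v) ||_2``.  The principal directions are the
leading eigenvectors of the class sample covariance, obtained via the SVD of
the centered class rows (never forming the N_J x N_J covariance, which would
cost O(N_J^3)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassAffineModel", "ScatteringClassifier", "fit", "residual", "predict"]


@dataclass
class ClassAffineModel:
    """One class's affine approximation space: mean + orthonormal basis."""

    label: str
    mean: np.ndarray
    basis: np.ndarray  # (n_features, d_k), orthonormal columns
    d_k: int

    def residual(self, v: np.ndarray) -> float:
        w = v - self.mean
        if self.d_k:
            w = w - self.basis @ (self.basis.T @ w)
        return float(np.linalg.norm(w))


@dataclass
class ScatteringClassifier:
    """Per-class affine PCA models plus the argmin-residual decision rule."""

    models: list[ClassAffineModel] = field(default_factory=list)
    n_features: int = 0
    d: int = 0
    fitted: bool = False

    @property
    def classes(self) -> list[str]:
        return [m.label for m in self.models]

    def residuals(self, features: np.ndarray) -> np.ndarray:
        """(n, K) matrix of distances to each class's affine space."""
        if not self.fitted:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} != model width {self.n_features}"
            )
        out = np.empty((X.shape[0], len(self.models)))
        for k, m in enumerate(self.models):
            W = X - m.mean
            if m.d_k:
                W = W - (W @ m.basis) @ m.basis.T
            out[:, k] = np.linalg.norm(W, axis=1)
        return out

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels by minimal residual (ties -> smallest class index) and the
        (n, K) score matrix of negated residuals for AUC computation."""
        res = self.residuals(features)
        idx = np.argmin(res, axis=1)  # argmin returns the first minimum
        labels = np.array([self.models[i].label for i in idx])
        return labels, -res

    def save(self, path) -> None:
        meta = {
            "format_version": 1,
            "n_features": self.n_features,
            "d": self.d,
            "labels": [m.label for m in self.models],
            "d_k": [m.d_k for m in self.models],
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, m in enumerate(self.models):
            arrays[f"mean_{i}"] = m.mean
            arrays[f"basis_{i}"] = m.basis
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ScatteringClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            models = [
                ClassAffineModel(
                    label=lab,
                    mean=z[f"mean_{i}"],
                    basis=z[f"basis_{i}"],
                    d_k=dk,
                )
                for i, (lab, dk) in enumerate(zip(meta["labels"], meta["d_k"]))
            ]
        clf = cls(models=models, n_features=meta["n_features"], d=meta["d"], fitted=True)
        return clf


def fit(features: np.ndarray, labels, d: int) -> ScatteringClassifier:
    """Fit one affine PCA model per class.

    Per class: the mean is the sample mean and the basis holds the top
    ``d_k = min(d, n_k - 1, N_J)`` right singular vectors of the centered
    class rows (the leading covariance eigenvectors).  Eigenvector signs are
    fixed deterministically by making each column's largest-magnitude entry
    positive.  Classes are ordered by sorted label.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    models = []
    for lab in sorted(np.unique(y).tolist()):
        rows = X[y == lab]
        if rows.shape[0] == 0:
            raise ValueError(f"class {lab!r} has no training samples")
        mean = rows.mean(axis=0)
        d_k = min(d, rows.shape[0] - 1, X.shape[1])
        if d_k > 0:
            centered = rows - mean
            _, s, Vt = np.linalg.svd(centered, full_matrices=False)
            # drop numerically-zero directions (identical training rows)
            rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
            d_k = min(d_k, rank)
            basis = Vt[:d_k].T
            for c in range(d_k):
                imax = np.argmax(np.abs(basis[:, c]))
                if basis[imax, c] < 0:
                    basis[:, c] = -basis[:, c]
        if d_k == 0:
            basis = np.zeros((X.shape[1], 0))
        models.append(
            ClassAffineModel(label=str(lab), mean=mean, basis=basis, d_k=d_k)
        )
    return ScatteringClassifier(
        models=models, n_features=X.shape[1], d=d, fitted=True
    )


def residual(classifier: ScatteringClassifier, feature_vector: np.ndarray, k: int) -> float:
    """Distance from one feature vector to class k's affine space."""
    return classifier.residuals(feature_vector)[0, k]


def predict(classifier: ScatteringClassifier, features: np.ndarray):
    """Module-level alias of :meth:`ScatteringClassifier.predict`."""
    return classifier.predict(features)
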