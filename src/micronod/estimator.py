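"""Scikit-learn style estimator wrapping the numpy CNN engine.

``CNNPatchClassifier`` trains one of the three architectures (M1, M2, M3)
on normalised intensity patches with SGD + momentum and two-class
cross-entropy, the published optimiser settings being the defaults
(learning rate 1e-4, momentum 0.9, batch 128).  It follows the estimator
contract — ``get_params``/``set_params``, ``fit``/``predict``/
``predict_proba``, trailing-underscore fitted attributes — so it composes
with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .architectures import build_architecture
from .nn import SGDMomentum, compile_network

__all__ = ["CNNPatchClassifier", "TrainHistory"]


class TrainHistory:
    """Per-iteration training accuracy and loss."""

    def __init__(self) -> None:
        self.accuracy: list[float] = []
        self.loss: list[float] = []

    def record(self, acc: float, loss: float) -> None:
        if not (np.isfinite(acc) and np.isfinite(loss)):
            raise FloatingPointError(
                f"non-finite training state (acc={acc}, loss={loss})"
            )
        self.accuracy.append(float(acc))
        self.loss.append(float(loss))

    def __len__(self) -> int:
        return len(self.loss)


class CNNPatchClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier for micro-nodule vs non-nodule patches.

    Parameters
    ----------
    model : {"M1", "M2", "M3"}
        Architecture depth: 1, 2 or 4 convolutional layers.
    input_size : int or None
        Patch side length (16, 32 or 64); inferred from X when None.
    learning_rate, momentum, epochs, batch_size
        SGD settings; 50 epochs is the baseline, 120 the published
        optimum for M2 at full scale.
    random_state : int or None
        Seeds weight initialisation, shuffling and dropout.

    Inputs are zero-centred and scaled to unit variance with statistics
    computed on the training set (stored as ``center_`` / ``scale_`` and
    re-applied at prediction time): windowed CT intensities occupy a
    narrow band of [0, 1], and centring keeps gradient magnitudes
    commensurate with the small fixed learning rate.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Always [0, 1] (0 = non-nodule, 1 = micro-nodule).
    spec_ : ArchitectureSpec
        The compiled layer specification.
    network_ : Network
        The trained numpy network.
    history_ : TrainHistory
        Per-iteration training accuracy and loss.
    """

    def __init__(
        self,
        model: str = "M2",
        input_size: int | None = None,
        learning_rate: float = 1e-4,
        momentum: float = 0.9,
        epochs: int = 50,
        batch_size: int = 128,
        random_state: int | None = None,
    ) -> None:
        self.model = model
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_x(self, X, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] > 4:  # flattened square patches
            side = int(round(np.sqrt(X.shape[1])))
            if side * side != X.shape[1]:
                raise ValueError("flattened input is not square")
            X = X.reshape(X.shape[0], side, side)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(
                f"expected (n, size, size) patches, got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("patches must be finite")
        size = X.shape[1]
        if fitting:
            if self.input_size is not None and size != self.input_size:
                raise ValueError(
                    f"patch size {size} does not match input_size "
                    f"{self.input_size}"
                )
        elif size != self.input_size_:
            raise ValueError(
                f"patch size {size} differs from fitted size {self.input_size_}"
            )
        return X[..., None]  # add channel axis

    def fit(self, X, y) -> "CNNPatchClassifier":
        Xc = self._validate_x(X, fitting=True)
        y = np.asarray(y)
        if y.shape != (Xc.shape[0],):
            raise ValueError("y must be one label per patch")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be 0 (non-nodule) or 1 (micro-nodule)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        y = y.astype(int)

        self.input_size_ = Xc.shape[1]
        self.center_ = float(Xc.mean())
        scale = float(Xc.std())
        self.scale_ = scale if scale > 0 else 1.0
        Xc = (Xc - self.center_) / self.scale_
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.input_size_ * self.input_size_
        self.spec_ = build_architecture(self.model, self.input_size_)
        seed = self.random_state if self.random_state is not None else 0
        self.network_ = compile_network(self.spec_, seed=seed)
        self.history_ = TrainHistory()

        optimizer = SGDMomentum(self.network_.parameters,
                                self.learning_rate, self.momentum)
        rng = np.random.default_rng(None if self.random_state is None
                                    else seed + 1)
        n = Xc.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss, acc = self.network_.loss_and_backward(
                    Xc[idx], y[idx], train=True
                )
                self.history_.record(acc, loss)
                optimizer.step(self.network_.gradients)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise NotFittedError(
                "this CNNPatchClassifier instance is not fitted yet"
            )

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes_``."""
        self._check_fitted()
        Xc = self._validate_x(X, fitting=False)
        Xc = (Xc - self.center_) / self.scale_
        return self.network_.predict_proba(Xc)

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the micro-nodule class (column 1)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Thresholded labels; a tied probability predicts class 1."""
        scores = self.decision_scores(X)
        return (scores >= 0.5).astype(int)
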