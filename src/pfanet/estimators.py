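"""Scikit-learn estimator interface.

:class:`FeedbackNetClassifier` wraps the training harness as an sklearn
classifier, so the credit-assignment rules compose with pipelines and model
selection.  All constructor parameters map one-to-one onto
:class:`~pfanet.updates.TrainConfig` fields.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core_net import softmax
from .harness import run_experiment
from .tasks import LabeledDataset
from .updates import TrainConfig


class FeedbackNetClassifier(ClassifierMixin, BaseEstimator):
    """Multilayer classifier trained with a configurable credit-assignment rule.

    Parameters
    ----------
    algorithm : {"bp", "fa", "dfa", "sf", "kp", "pfa", "pfa_o"}
        Error-propagation rule for the backward pass.  ``pfa`` routes errors
        through an expanded intermediate population via a fixed random matrix
        B and a plastic matrix R whose product comes to align with W^T.
    hidden_layer_sizes : tuple of int
        Hidden-layer widths; the softmax read-out is appended automatically.
    expansion_ratio : float
        Intermediate-population size over next-layer size (product rules).
    sparsity : float in [0, 1)
        Fraction of feedback entries clamped to zero for the whole run.
    learning_rate, learning_rate_r : float
        SGD step sizes for the forward weights and the plastic feedback
        (``None`` ties them, as in the plain update rule).
    weight_decay_initial, weight_decay, initial_decay_epochs :
        Two-phase multiplicative decay for W and R: the larger initial value
        runs for the first ``initial_decay_epochs`` epochs.

    Attributes
    ----------
    classes_ : ndarray of the class labels seen in fit.
    network_ : the trained :class:`~pfanet.core_net.Network`.
    feedback_ : the trained :class:`~pfanet.error_rules.FeedbackState`.
    history_ : :class:`~pfanet.harness.RunResult` epoch log.
    loss_curve_ : list of per-epoch mean training losses.

    Examples
    --------
    >>> from pfanet import gen_teacher_task
    >>> data = gen_teacher_task(20, 2, 1200, seed=3)
    >>> clf = FeedbackNetClassifier(algorithm="pfa", hidden_layer_sizes=(32,),
    ...                             max_epochs=10, random_state=0)
    >>> clf.fit(data.X_train, data.y_train).score(data.X_test, data.y_test) > 0.8
    True
    """

    def __init__(self, algorithm="pfa", hidden_layer_sizes=(64,),
                 activation="relu", learning_rate=0.05, learning_rate_r=None,
                 weight_decay=1e-4, weight_decay_initial=1e-3,
                 initial_decay_epochs=5, weight_decay_r=None,
                 expansion_ratio=10.0, sparsity=0.0, batch_size=32,
                 max_epochs=20, momentum=0.0, r_init="random",
                 random_state=None):
        self.algorithm = algorithm
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.learning_rate = learning_rate
        self.learning_rate_r = learning_rate_r
        self.weight_decay = weight_decay
        self.weight_decay_initial = weight_decay_initial
        self.initial_decay_epochs = initial_decay_epochs
        self.weight_decay_r = weight_decay_r
        self.expansion_ratio = expansion_ratio
        self.sparsity = sparsity
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.momentum = momentum
        self.r_init = r_init
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            algorithm=self.algorithm,
            hidden_sizes=tuple(self.hidden_layer_sizes),
            activation=self.activation,
            lr=self.learning_rate,
            lr_r=self.learning_rate_r,
            wd_initial=self.weight_decay_initial,
            wd_main=self.weight_decay,
            wd_initial_epochs=self.initial_decay_epochs,
            wd_r=self.weight_decay_r,
            batch_size=self.batch_size,
            epochs=self.max_epochs,
            seed=0 if self.random_state is None else int(self.random_state),
            expansion_ratio=self.expansion_ratio,
            sparsity=self.sparsity,
            momentum=self.momentum,
            r_init=self.r_init,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        y_enc = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        data = LabeledDataset(np.asarray(X, float), y_enc, X[:0], y_enc[:0],
                              n_classes=len(self.classes_),
                              provenance={"kind": "user"})
        net, fb, result = run_experiment(self._config(), data)
        self.network_ = net
        self.feedback_ = fb
        self.history_ = result
        self.loss_curve_ = list(result.train_loss)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        return self.network_.forward(X)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        check_is_fitted(self, "network_")
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
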