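"""Neural regressors mapping (temperature, duty cycle, capacitance) to moisture %.

Two single-hidden-layer networks, both scikit-learn estimators:

* :class:`ELMRegressor` -- an extreme learning machine: the hidden layer's
  input weights and biases are random (or externally supplied) and only the
  output weights are learned, as the minimum-norm least-squares solution of
  ``H @ beta = y`` where ``H`` is the hidden activation matrix.  No iteration.
* :class:`BPRegressor` -- a classic feed-forward network trained by plain
  full-batch gradient-descent backpropagation on the mean squared error, with
  sigmoid hidden units and a linear output node.  Training halts when the MSE
  reaches ``target_error`` or after ``max_epochs``.

:class:`SSATunedRegressor` wraps either network and lets the sparrow search
optimizer choose its random degrees of freedom inside the box [-1, 1]^p:
for the ELM the hidden input weights and biases (fitness = training RMSE with
beta re-solved per candidate); for the BP network the initial weight vector,
from which gradient descent then fine-tunes.  ``init_mode="logistic"`` gives
the chaos-initialized (LCSSA) variants.

Both base estimators standardize their inputs internally using statistics
learned from the training split only; the moisture target stays in percent.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .metrics import rmse
from .ssa import SsaConfig, optimize

__all__ = [
    "ELMRegressor",
    "BPRegressor",
    "SSATunedRegressor",
    "elm_param_count",
    "bp_param_count",
    "unpack_elm_params",
    "unpack_bp_params",
    "bp_loss_grad",
    "hidden_nodes_rule",
    "elm_fit",
    "elm_predict",
    "bp_fit",
    "ssa_tune",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


_ACTIVATIONS = {"sigmoid": _sigmoid, "tanh": np.tanh}


def _rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def elm_param_count(hidden_units: int, n_features: int) -> int:
    """Length of the flattened (input weights, biases) ELM search vector."""
    return hidden_units * n_features + hidden_units


def unpack_elm_params(theta: np.ndarray, hidden_units: int, n_features: int):
    """Split a flat vector into (hidden_units x n_features) weights and biases."""
    theta = np.asarray(theta, dtype=float).ravel()
    expected = elm_param_count(hidden_units, n_features)
    if theta.size != expected:
        raise ValueError(f"expected {expected} parameters, got {theta.size}")
    w = theta[: hidden_units * n_features].reshape(hidden_units, n_features)
    b = theta[hidden_units * n_features :]
    return w, b


def bp_param_count(n_features: int, hidden_units: int) -> int:
    """Length of the flattened BP weight/bias vector (both layers)."""
    return hidden_units * n_features + hidden_units + hidden_units + 1


def unpack_bp_params(theta: np.ndarray, n_features: int, hidden_units: int):
    """Split a flat vector into (W1, b1, w2, b2)."""
    theta = np.asarray(theta, dtype=float).ravel()
    expected = bp_param_count(n_features, hidden_units)
    if theta.size != expected:
        raise ValueError(f"expected {expected} parameters, got {theta.size}")
    h, p = hidden_units, n_features
    w1 = theta[: h * p].reshape(h, p)
    b1 = theta[h * p : h * p + h]
    w2 = theta[h * p + h : h * p + 2 * h]
    b2 = float(theta[-1])
    return w1, b1, w2, b2


def _pack_bp_params(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def bp_loss_grad(theta: np.ndarray, Xs: np.ndarray, y: np.ndarray, hidden_units: int):
    """MSE loss and its gradient w.r.t. the packed BP parameter vector.

    Forward map: ``h = sigmoid(Xs @ W1.T + b1)``, ``yhat = h @ w2 + b2``;
    gradients by the chain rule on ``mean((yhat - y)^2)``.
    """
    n, p = Xs.shape
    w1, b1, w2, b2 = unpack_bp_params(theta, p, hidden_units)
    hid = _sigmoid(Xs @ w1.T + b1)
    yhat = hid @ w2 + b2
    err = yhat - y
    loss = float(np.mean(err * err))
    g_yhat = 2.0 * err / n
    g_w2 = hid.T @ g_yhat
    g_b2 = float(np.sum(g_yhat))
    g_hid = np.outer(g_yhat, w2)
    g_z = g_hid * hid * (1.0 - hid)
    g_w1 = g_z.T @ Xs
    g_b1 = g_z.sum(axis=0)
    return loss, _pack_bp_params(g_w1, g_b1, g_w2, g_b2)


class _StandardizingMixin:
    """Shared per-feature standardization frozen at fit time."""

    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.x_scale_ = scale
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        return (X - self.x_mean_) / self.x_scale_

    def _apply_scaler(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_scale_


class ELMRegressor(_StandardizingMixin, RegressorMixin, BaseEstimator):
    """Extreme learning machine regressor.

    Parameters
    ----------
    hidden_units : int, default 100
        Number of hidden neurons.
    activation : {"sigmoid", "tanh"}, default "sigmoid"
    standardize : bool, default True
        Standardize features with training-split statistics.
    hidden_params : array-like or None
        Optional flat vector of length ``hidden_units * (n_features + 1)``
        fixing the hidden input weights and biases (used by the sparrow-search
        tuner); when None they are drawn i.i.d. uniform on [-1, 1].
    random_state : int, Generator or None
        Seed for the random hidden parameters.

    Attributes
    ----------
    input_weights_ : ndarray (hidden_units, n_features)
    hidden_biases_ : ndarray (hidden_units,)
    output_weights_ : ndarray (hidden_units,)
        Minimum-norm least-squares solution of ``H @ beta = y``.
    """

    def __init__(
        self,
        hidden_units: int = 100,
        activation: str = "sigmoid",
        standardize: bool = True,
        hidden_params=None,
        random_state=None,
    ):
        self.hidden_units = hidden_units
        self.activation = activation
        self.standardize = standardize
        self.hidden_params = hidden_params
        self.random_state = random_state

    def _activation_fn(self):
        try:
            return _ACTIVATIONS[self.activation]
        except KeyError:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(_ACTIVATIONS)}"
            ) from None

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.hidden_units < 1:
            raise ValueError(f"hidden_units must be >= 1, got {self.hidden_units}")
        act = self._activation_fn()
        Xs = self._fit_scaler(X)
        p = X.shape[1]
        if self.hidden_params is not None:
            w, b = unpack_elm_params(self.hidden_params, self.hidden_units, p)
        else:
            rng = _rng(self.random_state)
            w = rng.uniform(-1.0, 1.0, size=(self.hidden_units, p))
            b = rng.uniform(-1.0, 1.0, size=self.hidden_units)
        hid = act(Xs @ w.T + b)
        if np.allclose(hid.std(axis=0), 0.0):
            warnings.warn(
                "degenerate hidden layer (all-constant activations); "
                "returning the minimum-norm solution anyway",
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(hid, y, rcond=None)
        self.input_weights_ = w
        self.hidden_biases_ = b
        self.output_weights_ = beta
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        Xs = self._apply_scaler(X)
        hid = self._activation_fn()(Xs @ self.input_weights_.T + self.hidden_biases_)
        return hid @ self.output_weights_


class BPRegressor(_StandardizingMixin, RegressorMixin, BaseEstimator):
    """Backpropagation-trained feed-forward regressor (one hidden layer).

    Sigmoid hidden units, linear output; plain full-batch gradient descent.
    ``coef_init`` (flat vector of length ``h*(p+1) + h + 1``) fixes the
    starting weights, which is how the sparrow-search tuner seeds training;
    ``max_epochs=0`` returns the initial network untrained.
    """

    def __init__(
        self,
        hidden_units: int = 5,
        learning_rate: float = 0.01,
        max_epochs: int = 10000,
        target_error: float = 0.01,
        standardize: bool = True,
        coef_init=None,
        random_state=None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.target_error = target_error
        self.standardize = standardize
        self.coef_init = coef_init
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.hidden_units < 1:
            raise ValueError(f"hidden_units must be >= 1, got {self.hidden_units}")
        if self.max_epochs < 0:
            raise ValueError(f"max_epochs must be >= 0, got {self.max_epochs}")
        Xs = self._fit_scaler(X)
        p = X.shape[1]
        n_params = bp_param_count(p, self.hidden_units)
        if self.coef_init is not None:
            theta = np.asarray(self.coef_init, dtype=float).ravel().copy()
            if theta.size != n_params:
                raise ValueError(f"coef_init must have length {n_params}, got {theta.size}")
        else:
            theta = _rng(self.random_state).uniform(-1.0, 1.0, size=n_params)
        loss_curve = []
        for _ in range(self.max_epochs):
            loss, grad = bp_loss_grad(theta, Xs, y, self.hidden_units)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"BP training diverged: non-finite loss {loss!r} at epoch "
                    f"{len(loss_curve)} (learning_rate={self.learning_rate})"
                )
            loss_curve.append(loss)
            if loss <= self.target_error:
                break
            theta -= self.learning_rate * grad
        w1, b1, w2, b2 = unpack_bp_params(theta, p, self.hidden_units)
        self.hidden_weights_ = w1
        self.hidden_biases_ = b1
        self.output_weights_ = w2
        self.output_bias_ = b2
        self.coef_vector_ = theta
        self.loss_curve_ = np.asarray(loss_curve)
        self.n_iter_ = len(loss_curve)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_vector_")
        X = check_array(X)
        Xs = self._apply_scaler(X)
        hid = _sigmoid(Xs @ self.hidden_weights_.T + self.hidden_biases_)
        return hid @ self.output_weights_ + self.output_bias_


class SSATunedRegressor(RegressorMixin, BaseEstimator):
    """Sparrow-search-tuned wrapper around :class:`ELMRegressor` / :class:`BPRegressor`.

    The optimizer searches the base model's random degrees of freedom inside
    ``[-weight_bound, weight_bound]^p`` with training-set RMSE as fitness:

    * ELM base: the flattened hidden input weights and biases
      (``hidden_units * (n_features + 1)`` dimensions); the output weights are
      re-solved by least squares for every candidate and again at the optimum.
    * BP base: the full initial weight vector
      (``h*(p+1) + h + 1`` dimensions), evaluated untrained (zero-epoch
      forward pass); ordinary backpropagation then fine-tunes from the best
      initialization found.

    ``init_mode="logistic"`` draws the initial flock from the chaotic
    Logistic map (the LCSSA variants); ``"uniform"`` gives plain SSA tuning.

    Attributes
    ----------
    estimator_ : fitted base estimator at the tuned optimum
    search_result_ : :class:`capmoist.ssa.OptimizeResult`
    history_ : ndarray, per-iteration best training RMSE (non-increasing)
    best_vector_ : ndarray, the tuned parameter vector
    """

    def __init__(
        self,
        estimator=None,
        pop_size: int = 20,
        max_iters: int = 20,
        init_mode: str = "logistic",
        safety_value: float = 0.8,
        finder_fraction: float = 0.2,
        scout_fraction: float = 0.2,
        weight_bound: float = 1.0,
        random_state=None,
    ):
        self.estimator = estimator
        self.pop_size = pop_size
        self.max_iters = max_iters
        self.init_mode = init_mode
        self.safety_value = safety_value
        self.finder_fraction = finder_fraction
        self.scout_fraction = scout_fraction
        self.weight_bound = weight_bound
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        base = clone(self.estimator) if self.estimator is not None else ELMRegressor()
        p = X.shape[1]
        if isinstance(base, ELMRegressor):
            dims = elm_param_count(base.hidden_units, p)

            def build(theta):
                return clone(base).set_params(hidden_params=np.asarray(theta, float))

            def objective(theta):
                model = build(theta).fit(X, y)
                return rmse(y, model.predict(X))

        elif isinstance(base, BPRegressor):
            dims = bp_param_count(p, base.hidden_units)

            def build(theta):
                return clone(base).set_params(coef_init=np.asarray(theta, float))

            def objective(theta):
                model = clone(base).set_params(
                    coef_init=np.asarray(theta, float), max_epochs=0
                ).fit(X, y)
                return rmse(y, model.predict(X))

        else:
            raise TypeError(
                f"estimator must be an ELMRegressor or BPRegressor, got {type(base).__name__}"
            )
        seed = int(_rng(self.random_state).integers(2**31))
        cfg = SsaConfig(
            dims=dims,
            lower_bounds=-self.weight_bound,
            upper_bounds=self.weight_bound,
            pop_size=self.pop_size,
            max_iters=self.max_iters,
            safety_value=self.safety_value,
            finder_fraction=self.finder_fraction,
            scout_fraction=self.scout_fraction,
            init_mode=self.init_mode,
            seed=seed,
        )
        result = optimize(objective, cfg)
        self.search_result_ = result
        self.history_ = result.history
        self.best_vector_ = result.best_position
        self.estimator_ = build(result.best_position).fit(X, y)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)


def hidden_nodes_rule(m: int, n: int, a: int) -> int:
    """Empirical hidden-layer sizing rule ``h = round(sqrt(m + n)) + a``.

    ``m`` input nodes, ``n`` output nodes, ``a`` an integer fudge constant in
    [1, 10].  With m=3 inputs, n=1 output and a=3 this gives the 5-node
    hidden layer used by the moisture BP network.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if not 1 <= a <= 10:
        raise ValueError(f"a must lie in [1, 10], got {a}")
    return int(round(math.sqrt(m + n))) + int(a)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator classes.

def elm_fit(X, y, hidden_count: int = 100, weights=None, random_state=None) -> ELMRegressor:
    """Fit an ELM; ``weights`` optionally fixes the flat hidden-parameter vector."""
    return ELMRegressor(
        hidden_units=hidden_count, hidden_params=weights, random_state=random_state
    ).fit(X, y)


def elm_predict(model: ELMRegressor, X):
    return model.predict(X)


def bp_fit(X, y, random_state=None, **params) -> BPRegressor:
    """Fit a BP network; keyword args pass through to :class:`BPRegressor`."""
    return BPRegressor(random_state=random_state, **params).fit(X, y)


def ssa_tune(
    model_kind: str,
    X,
    y,
    init_mode: str = "uniform",
    pop_size: int = 20,
    max_iters: int = 20,
    random_state=None,
    **estimator_params,
) -> SSATunedRegressor:
    """Fit a sparrow-search-tuned model of kind "ELM" or "BP"."""
    kind = model_kind.upper()
    if kind == "ELM":
        base = ELMRegressor(**estimator_params)
    elif kind == "BP":
        base = BPRegressor(**estimator_params)
    else:
        raise ValueError(f"model_kind must be 'ELM' or 'BP', got {model_kind!r}")
    return SSATunedRegressor(
        estimator=base,
        pop_size=pop_size,
        max_iters=max_iters,
        init_mode=init_mode,
        random_state=random_state,
    ).fit(X, y)
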