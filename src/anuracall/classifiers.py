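"""Frame-level classifiers and per-recording labelling.

From scratch: the minimum-distance classifier (per-class feature means,
Euclidean decision), the Gaussian maximum-likelihood classifier (full
covariance), LBG vector quantization, and a discrete hidden Markov model
(Baum-Welch training, scaled forward likelihood). Standard learners
(decision tree, kNN, SVM, logistic regression, a 10-unit feed-forward
network, linear discriminant, naive Bayes) are wrapped from scikit-learn
behind a single registry.

Training always uses the low-noise pattern frames only; recordings are
labelled by majority vote over their frame labels.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

#: canonical registry order (used for deterministic tie-breaks)
CLASSIFIER_ORDER = ("MinDis", "MaxLik", "DecTr", "kNN", "SVM", "LogReg",
                    "Neur", "Discr", "Bayes", "HMM")

#: pinned defaults of the wrapped learners, recorded in results files
REGISTRY_DEFAULTS = {
    "DecTr": {"criterion": "gini"},
    "kNN": {"n_neighbors": 5, "standardize": True},
    "SVM": {"kernel": "rbf", "multiclass": "one-vs-rest", "standardize": True},
    "LogReg": {"solver": "lbfgs", "max_iter": 1000},
    "Neur": {"hidden_layer_sizes": (10,), "max_iter": 500, "standardize": True},
    "Discr": {"solver": "svd"},
    "Bayes": {"kind": "gaussian-per-feature"},
    "MinDis": {"standardize": True},
    "MaxLik": {"regularization": 1e-6},
    "HMM": {"n_states": 3, "codebook_size": 32},
}


class MinimumDistanceClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-class-mean classifier.

    Training stores the per-class, per-feature arithmetic means mu_jk; a
    frame is assigned to the class minimizing the squared Euclidean distance
    sum_j (x_j - mu_jk)^2, ties broken toward the lowest class index.
    """

    def fit(self, X, y) -> "MinimumDistanceClassifier":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.means_ = np.vstack([X[y == k].mean(axis=0) for k in self.classes_])
        return self

    def decision_distances(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = check_array(X)
        if X.shape[1] != self.means_.shape[1]:
            raise ValueError(
                f"frame has {X.shape[1]} features, model expects "
                f"{self.means_.shape[1]}")
        diff = X[:, None, :] - self.means_[None, :, :]
        return np.sum(diff**2, axis=2)

    def predict(self, X) -> np.ndarray:
        # argmin keeps the first (lowest-index) class on exact ties
        return self.classes_[np.argmin(self.decision_distances(X), axis=1)]


class GaussianMaximumLikelihood(BaseEstimator, ClassifierMixin):
    """Per-class full-covariance Gaussian maximum-likelihood classifier.

    Each class is modelled as a multivariate normal with its sample mean and
    full sample covariance; prediction maximizes log density plus log prior.
    Covariances are ridge-regularized toward a scaled identity so classes
    with few frames remain usable.
    """

    def __init__(self, regularization: float = 1e-6, use_priors: bool = True):
        self.regularization = regularization
        self.use_priors = use_priors

    def fit(self, X, y) -> "GaussianMaximumLikelihood":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, self.covariances_, priors = [], [], []
        for k in self.classes_:
            xk = X[y == k]
            mu = xk.mean(axis=0)
            if xk.shape[0] > 1:
                cov = np.cov(xk, rowvar=False).reshape(d, d)
            else:
                cov = np.zeros((d, d))
            scale = max(np.trace(cov) / d, 1.0)
            reg = self.regularization
            # escalate the ridge until the covariance factorizes
            for _ in range(12):
                try:
                    np.linalg.cholesky(cov + reg * scale * np.eye(d))
                    break
                except np.linalg.LinAlgError:
                    reg *= 10
            else:
                raise ValueError(f"covariance of class {k} is singular")
            self.means_.append(mu)
            self.covariances_.append(cov + reg * scale * np.eye(d))
            priors.append(xk.shape[0])
        self.means_ = np.vstack(self.means_)
        self.covariances_ = np.stack(self.covariances_)
        priors = np.asarray(priors, dtype=float)
        self.priors_ = (priors / priors.sum() if self.use_priors
                        else np.full(len(priors), 1.0 / len(priors)))
        return self

    def log_likelihood(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = check_array(X)
        n, d = X.shape
        out = np.empty((n, len(self.classes_)))
        for j in range(len(self.classes_)):
            chol = np.linalg.cholesky(self.covariances_[j])
            diff = X - self.means_[j]
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, j] = -0.5 * (maha + logdet + d * np.log(2 * np.pi))
        return out

    def predict(self, X) -> np.ndarray:
        scores = self.log_likelihood(X) + np.log(self.priors_)[None, :]
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# LBG vector quantization

def _kmeans_refine(X: np.ndarray, codebook: np.ndarray, rng,
                   max_iter: int, tol: float
                   ) -> tuple[np.ndarray, list[float]]:
    distortions = []
    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - codebook[None, :, :]) ** 2, axis=2)
        assign = np.argmin(d2, axis=1)
        distortion = float(np.mean(d2[np.arange(len(X)), assign]))
        distortions.append(distortion)
        new = codebook.copy()
        for j in range(codebook.shape[0]):
            members = X[assign == j]
            if len(members):
                new[j] = members.mean(axis=0)
            else:  # dead cell: move to the sample farthest from its centroid
                far = int(np.argmax(d2[np.arange(len(X)), assign]))
                new[j] = X[far]
        if np.allclose(new, codebook, atol=tol):
            codebook = new
            break
        codebook = new
    return codebook, distortions


def lbg_codebook(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 50,
                 tol: float = 1e-8, split_eps: float = 0.01
                 ) -> tuple[np.ndarray, list[float]]:
    """Binary-splitting LBG codebook of ``k`` centroids (k a power of two).

    Starts from the global centroid, doubles the codebook by perturbing each
    centroid by +/- split_eps relative offsets, and refines with k-means
    after each split. Returns the codebook and the distortion history
    (non-increasing within each refinement)."""
    X = np.asarray(X, dtype=float)
    if k < 1 or (k & (k - 1)) != 0:
        raise ValueError("LBG codebook size must be a power of two")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"codebook size {k} exceeds {n_distinct} distinct frames")
    rng = np.random.default_rng(seed)
    codebook = X.mean(axis=0, keepdims=True)
    history: list[float] = []
    spread = np.maximum(X.std(axis=0), 1e-12)
    while codebook.shape[0] < k:
        delta = split_eps * spread
        codebook = np.vstack([codebook + delta, codebook - delta])
        codebook, dist = _kmeans_refine(X, codebook, rng, max_iter, tol)
        history.extend(dist)
    if codebook.shape[0] == 1:
        history.append(float(np.mean(np.sum((X - codebook[0]) ** 2, axis=1))))
    return codebook, history


def quantize(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Index of the nearest codeword for every row of ``X``."""
    d2 = np.sum((np.asarray(X)[:, None, :] - codebook[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# Discrete HMM

def forward_log_likelihood(startprob: np.ndarray, transmat: np.ndarray,
                           emissionprob: np.ndarray, obs: np.ndarray) -> float:
    """Scaled forward-algorithm log-likelihood of a discrete symbol sequence."""
    obs = np.asarray(obs, dtype=int)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    alpha = startprob * emissionprob[:, obs[0]]
    loglik = 0.0
    for t in range(obs.size):
        if t > 0:
            alpha = (alpha @ transmat) * emissionprob[:, obs[t]]
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        loglik += np.log(c)
        alpha = alpha / c
    return float(loglik)


def _baum_welch(sequences: list[np.ndarray], n_states: int, n_symbols: int,
                seed: int, n_iter: int, floor: float = 1e-6
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)

    def _rows(shape):
        m = rng.uniform(0.5, 1.5, size=shape)
        return m / m.sum(axis=-1, keepdims=True)

    pi = _rows(n_states)
    a = _rows((n_states, n_states))
    b = _rows((n_states, n_symbols))
    for _ in range(n_iter):
        pi_acc = np.zeros(n_states)
        a_acc = np.zeros((n_states, n_states))
        b_acc = np.zeros((n_states, n_symbols))
        for obs in sequences:
            T = obs.size
            alpha = np.zeros((T, n_states))
            scale = np.zeros(T)
            alpha[0] = pi * b[:, obs[0]]
            scale[0] = max(alpha[0].sum(), 1e-300)
            alpha[0] /= scale[0]
            for t in range(1, T):
                alpha[t] = (alpha[t - 1] @ a) * b[:, obs[t]]
                scale[t] = max(alpha[t].sum(), 1e-300)
                alpha[t] /= scale[t]
            beta = np.zeros((T, n_states))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[t] = a @ (b[:, obs[t + 1]] * beta[t + 1])
                beta[t] /= scale[t + 1]
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
            pi_acc += gamma[0]
            for t in range(T - 1):
                xi = (alpha[t][:, None] * a * b[:, obs[t + 1]][None, :]
                      * beta[t + 1][None, :]) / scale[t + 1]
                s = xi.sum()
                if s > 0:
                    a_acc += xi / s * gamma[t].sum()
            np.add.at(b_acc.T, obs, gamma)
        pi = pi_acc + floor
        pi /= pi.sum()
        a = a_acc + floor
        a /= a.sum(axis=1, keepdims=True)
        b = b_acc + floor
        b /= b.sum(axis=1, keepdims=True)
    return pi, a, b


class DiscreteHmmClassifier(BaseEstimator, ClassifierMixin):
    """Sequential classifier: LBG codebook + one discrete HMM per class.

    ``fit`` takes per-recording frame sequences (list of F_i x D arrays) and
    their recording labels; frames are vector-quantized with a shared LBG
    codebook and one HMM per class is trained by Baum-Welch. ``predict``
    assigns each sequence to the class with the highest forward
    log-likelihood.
    """

    def __init__(self, n_states: int = 3, codebook_size: int = 32,
                 n_iter: int = 20, seed: int = 0):
        self.n_states = n_states
        self.codebook_size = codebook_size
        self.n_iter = n_iter
        self.seed = seed

    def fit(self, sequences: list[np.ndarray], labels) -> "DiscreteHmmClassifier":
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        labels = np.asarray(labels)
        if len(sequences) != labels.size:
            raise ValueError("one label per sequence is required")
        for s in sequences:
            if len(s) == 0:
                raise ValueError("empty frame sequence")
        allx = np.vstack(sequences)
        self.scaler_ = StandardScaler().fit(allx)
        k = self.codebook_size
        n_distinct = np.unique(allx, axis=0).shape[0]
        while k > 1 and k > n_distinct:
            k //= 2
        self.codebook_, _ = lbg_codebook(self.scaler_.transform(allx), k,
                                         seed=self.seed)
        self.classes_ = np.unique(labels)
        self.models_ = {}
        for j, cls in enumerate(self.classes_):
            seqs = [quantize(self.scaler_.transform(s), self.codebook_)
                    for s, lab in zip(sequences, labels) if lab == cls]
            self.models_[cls] = _baum_welch(
                seqs, self.n_states, self.codebook_.shape[0],
                seed=self.seed + j, n_iter=self.n_iter)
        return self

    def score_sequences(self, sequences) -> np.ndarray:
        check_is_fitted(self, "models_")
        out = np.empty((len(sequences), len(self.classes_)))
        for i, s in enumerate(sequences):
            obs = quantize(self.scaler_.transform(s), self.codebook_)
            for j, cls in enumerate(self.classes_):
                pi, a, b = self.models_[cls]
                out[i, j] = forward_log_likelihood(pi, a, b, obs)
        return out

    def predict(self, sequences) -> np.ndarray:
        return self.classes_[np.argmax(self.score_sequences(sequences), axis=1)]


# ---------------------------------------------------------------------------
# registry

def make_classifier(kind: str, seed: int = 0, **hyperparams):
    """Instantiate a classifier by registry name with pinned defaults.

    Distance-based and neural learners are wrapped in a z-score
    standardization pipeline fitted on the training (pattern) frames.
    ``hyperparams`` override the registry defaults of the underlying
    estimator (e.g. ``n_neighbors`` for kNN).
    """
    def _scaled(estimator):
        return Pipeline([("scale", StandardScaler()), ("clf", estimator)])

    if kind == "MinDis":
        return _scaled(MinimumDistanceClassifier(**hyperparams))
    if kind == "MaxLik":
        return GaussianMaximumLikelihood(**hyperparams)
    if kind == "DecTr":
        return DecisionTreeClassifier(
            **{"criterion": "gini", "random_state": seed, **hyperparams})
    if kind == "kNN":
        return _scaled(KNeighborsClassifier(
            **{"n_neighbors": 5, **hyperparams}))
    if kind == "SVM":
        return _scaled(SVC(**{"kernel": "rbf",
                              "decision_function_shape": "ovr",
                              "random_state": seed, **hyperparams}))
    if kind == "LogReg":
        return LogisticRegression(**{"max_iter": 1000, **hyperparams})
    if kind == "Neur":
        return _scaled(MLPClassifier(
            **{"hidden_layer_sizes": (10,), "max_iter": 500,
               "random_state": seed, **hyperparams}))
    if kind == "Discr":
        return LinearDiscriminantAnalysis(**hyperparams)
    if kind == "Bayes":
        return GaussianNB(**hyperparams)
    if kind == "HMM":
        return DiscreteHmmClassifier(**{"seed": seed, **hyperparams})
    raise ValueError(f"unknown classifier kind {kind!r}")


def label_recording(frame_labels) -> object:
    """Majority vote over a recording's frame labels.

    Ties are broken toward the lowest class (sorted order) with a logged
    warning; empty input is rejected.
    """
    frame_labels = list(frame_labels)
    if not frame_labels:
        raise ValueError("cannot label a recording with no frames")
    values, counts = np.unique(np.asarray(frame_labels), return_counts=True)
    winners = values[counts == counts.max()]
    if winners.size > 1:
        logger.warning("majority-vote tie between %s; choosing %s",
                       list(winners), winners[0])
    return winners[0]
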