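"""A linear-chain conditional random field for B/I/O chemical tagging.

The model scores a label sequence as the sum of state scores (sparse
categorical features times per-label weights) and first-order transition
scores, with structurally forbidden transitions (``start -> I`` and
``O -> I``) masked out so every decoded sequence is a valid BIO chain.
Training maximises the L2-penalised conditional log-likelihood with
L-BFGS; gradients come from forward-backward expectations.  Per-token
marginal probabilities of the emitted labels are exposed as confidence
values for downstream post-processing and ranking.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``get_params``), with ``X`` a list of sentences, each a list of feature
string collections, and ``y`` the parallel label lists.
"""

from __future__ import annotations

import json
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

CLASSES = ("B", "I", "O")
_B, _I, _O = 0, 1, 2
_NEG = -1e4  # additive mask for forbidden transitions


def _log_norm(v: np.ndarray) -> float:
    m = v.max()
    return m + np.log(np.exp(v - m).sum())


class ChainCRF(BaseEstimator):
    """Linear-chain CRF over categorical presence features.

    Parameters
    ----------
    c2 : float
        L2 regularisation strength on all weights.
    max_iter : int
        Maximum L-BFGS iterations.
    tol : float
        Gradient-norm tolerance passed to the optimiser.

    Attributes
    ----------
    classes_ : tuple of str
        Label inventory, fixed to ``("B", "I", "O")``.
    feature_index_ : dict
        Feature string -> column index, in sorted feature order.
    state_weights_ : ndarray of shape (n_features, 3)
    trans_weights_ : ndarray of shape (3, 3)
    start_weights_ : ndarray of shape (3,)
    """

    def __init__(self, c2: float = 1.0, max_iter: int = 150, tol: float = 1e-5):
        self.c2 = c2
        self.max_iter = max_iter
        self.tol = tol

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _trans_mask() -> np.ndarray:
        mask = np.zeros((3, 3))
        mask[_O, _I] = _NEG
        return mask

    @staticmethod
    def _start_mask() -> np.ndarray:
        mask = np.zeros(3)
        mask[_I] = _NEG
        return mask

    def _design(self, X: Sequence[Sequence[Set[str]]], index: Dict[str, int]) -> sp.csr_matrix:
        rows, cols = [], []
        r = 0
        for sent in X:
            for feats in sent:
                for f in feats:
                    j = index.get(f)
                    if j is not None:
                        rows.append(r)
                        cols.append(j)
                r += 1
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(r, len(index)))

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        X = list(X)
        y = [list(labels) for labels in y]
        if not X:
            raise ValueError("training corpus is empty")
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of sentences")
        for sent, labels in zip(X, y):
            if len(sent) != len(labels):
                raise ValueError("sentence/label length mismatch")
            for lab in labels:
                if lab not in CLASSES:
                    raise ValueError(f"invalid label {lab!r}")
        if not any("B" in labels for labels in y):
            raise ValueError("training corpus contains no entity (B) labels")

        feature_set: Set[str] = set()
        for sent in X:
            for feats in sent:
                feature_set.update(feats)
        index = {f: j for j, f in enumerate(sorted(feature_set))}
        n_feat = len(index)

        Xm = self._design(X, index)
        lengths = [len(sent) for sent in X if len(sent)]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        y_idx = np.array(
            [CLASSES.index(lab) for labels, sent in zip(y, X) if len(sent) for lab in labels]
        )
        n_tok = int(offsets[-1])
        Y = np.zeros((n_tok, 3))
        Y[np.arange(n_tok), y_idx] = 1.0

        emp_state = (Xm.T @ Y)  # (F, 3)
        emp_trans = np.zeros((3, 3))
        emp_start = np.zeros(3)
        for s in range(len(lengths)):
            lo, hi = offsets[s], offsets[s + 1]
            seq = y_idx[lo:hi]
            emp_start[seq[0]] += 1
            for a, b in zip(seq, seq[1:]):
                emp_trans[a, b] += 1

        t_mask = self._trans_mask()
        s_mask = self._start_mask()
        n_param = n_feat * 3 + 9 + 3

        def unpack(w):
            Ws = w[: n_feat * 3].reshape(n_feat, 3)
            T = w[n_feat * 3 : n_feat * 3 + 9].reshape(3, 3)
            s0 = w[n_feat * 3 + 9 :]
            return Ws, T, s0

        def objective(w):
            Ws, T, s0 = unpack(w)
            Tm = T + t_mask
            s0m = s0 + s_mask
            S = np.asarray(Xm @ Ws)  # (N, 3) state scores
            loglik = float((emp_state * Ws).sum() + (emp_trans * T).sum() + emp_start @ s0)
            P = np.empty_like(S)
            exp_trans = np.zeros((3, 3))
            exp_start = np.zeros(3)
            for s in range(len(lengths)):
                lo, hi = int(offsets[s]), int(offsets[s + 1])
                Ss = S[lo:hi]
                L = hi - lo
                alpha = np.empty((L, 3))
                alpha[0] = s0m + Ss[0]
                for t in range(1, L):
                    prev = alpha[t - 1][:, None] + Tm
                    m = prev.max(axis=0)
                    alpha[t] = m + np.log(np.exp(prev - m).sum(axis=0)) + Ss[t]
                logZ = _log_norm(alpha[-1])
                beta = np.empty((L, 3))
                beta[-1] = 0.0
                for t in range(L - 2, -1, -1):
                    nxt = Tm + (Ss[t + 1] + beta[t + 1])[None, :]
                    m = nxt.max(axis=1)
                    beta[t] = m + np.log(np.exp(nxt - m[:, None]).sum(axis=1))
                P[lo:hi] = np.exp(alpha + beta - logZ)
                exp_start += P[lo]
                for t in range(L - 1):
                    pair = alpha[t][:, None] + Tm + (Ss[t + 1] + beta[t + 1])[None, :] - logZ
                    exp_trans += np.exp(pair)
                loglik -= logZ
            grad_state = np.asarray(Xm.T @ P) - emp_state  # expected - empirical
            grad_trans = exp_trans - emp_trans
            grad_start = exp_start - emp_start
            grad = np.concatenate([grad_state.ravel(), grad_trans.ravel(), grad_start])
            # negative penalised log-likelihood
            value = -loglik + self.c2 * float(w @ w)
            grad += 2.0 * self.c2 * w
            return value, grad

        w0 = np.zeros(n_param)
        result = minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-9},
        )
        Ws, T, s0 = unpack(result.x)
        self.classes_ = CLASSES
        self.feature_index_ = index
        self.state_weights_ = Ws
        self.trans_weights_ = T
        self.start_weights_ = s0
        self.n_iter_ = int(result.nit)
        return self

    # -- inference -----------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "state_weights_"):
            raise NotFittedError("ChainCRF is not fitted")

    def _state_scores(self, sent: Sequence[Set[str]]) -> np.ndarray:
        S = np.zeros((len(sent), 3))
        for t, feats in enumerate(sent):
            for f in feats:
                j = self.feature_index_.get(f)
                if j is not None:
                    S[t] += self.state_weights_[j]
        return S

    def predict(self, X) -> List[List[str]]:
        """Viterbi-decode the most probable valid BIO sequence per sentence."""
        self._check_fitted()
        return [labels for labels, _ in (self._viterbi(sent) for sent in X)]

    def _viterbi(self, sent) -> Tuple[List[str], float]:
        if not sent:
            return [], 0.0
        S = self._state_scores(sent)
        Tm = self.trans_weights_ + self._trans_mask()
        delta = self.start_weights_ + self._start_mask() + S[0]
        back = np.zeros((len(sent), 3), dtype=int)
        for t in range(1, len(sent)):
            cand = delta[:, None] + Tm
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + S[t]
        path = [int(delta.argmax())]
        for t in range(len(sent) - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        path.reverse()
        return [CLASSES[i] for i in path], float(delta.max())

    def predict_marginals(self, X) -> List[np.ndarray]:
        """Per-token posterior distributions over (B, I, O), one array
        of shape (len(sentence), 3) per sentence."""
        self._check_fitted()
        out = []
        Tm = self.trans_weights_ + self._trans_mask()
        s0m = self.start_weights_ + self._start_mask()
        for sent in X:
            L = len(sent)
            if L == 0:
                out.append(np.zeros((0, 3)))
                continue
            S = self._state_scores(sent)
            alpha = np.empty((L, 3))
            alpha[0] = s0m + S[0]
            for t in range(1, L):
                prev = alpha[t - 1][:, None] + Tm
                m = prev.max(axis=0)
                alpha[t] = m + np.log(np.exp(prev - m).sum(axis=0)) + S[t]
            logZ = _log_norm(alpha[-1])
            beta = np.empty((L, 3))
            beta[-1] = 0.0
            for t in range(L - 2, -1, -1):
                nxt = Tm + (S[t + 1] + beta[t + 1])[None, :]
                m = nxt.max(axis=1)
                beta[t] = m + np.log(np.exp(nxt - m[:, None]).sum(axis=1))
            out.append(np.exp(alpha + beta - logZ))
        return out

    def predict_with_confidence(self, X) -> List[Tuple[List[str], List[float]]]:
        """Viterbi labels plus the marginal probability of each emitted label."""
        self._check_fitted()
        results = []
        marginals = self.predict_marginals(X)
        for sent, marg in zip(X, marginals):
            labels, _ = self._viterbi(sent)
            confs = [float(marg[t, CLASSES.index(lab)]) for t, lab in enumerate(labels)]
            results.append((labels, confs))
        return results

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        features = sorted(self.feature_index_, key=self.feature_index_.get)
        return {
            "classes": list(self.classes_),
            "c2": self.c2,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "features": features,
            "state_weights": self.state_weights_.tolist(),
            "trans_weights": self.trans_weights_.tolist(),
            "start_weights": self.start_weights_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ChainCRF":
        model = cls(c2=payload["c2"], max_iter=payload["max_iter"], tol=payload["tol"])
        model.classes_ = tuple(payload["classes"])
        model.feature_index_ = {f: j for j, f in enumerate(payload["features"])}
        model.state_weights_ = np.array(payload["state_weights"])
        model.trans_weights_ = np.array(payload["trans_weights"])
        model.start_weights_ = np.array(payload["start_weights"])
        return model

    def save(self, path, metadata: dict = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)
        if metadata is not None:
            with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
                json.dump(metadata, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ChainCRF":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
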