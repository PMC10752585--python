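"""Arousal-state models: decision-line classifier, categorical HMM, AR-HMM.

Three layers of state segmentation over 10-s binned features:

* a rule classifier calling a bin *roaming* when mean centroid speed (mm/s)
  exceeds mean centroid angular speed (deg/s) / 450, else *dwelling*;
* a two-state categorical hidden Markov model trained by Baum-Welch on those
  labels, smoothing them into roaming/dwelling hidden states;
* a K-state autoregressive HMM over a 5-dimensional feature vector, with
  per-state linear dynamics x_t | x_{t-1}, z_t ~ N(A_k x_{t-1} + b_k, Q_k),
  fit by EM with an exact forward-backward E-step and closed-form weighted
  least-squares M-step, evaluated on held-out data against a multivariate
  Gaussian baseline.

Numerics: forward-backward uses per-step scaling (normalized alpha/beta with
the log-likelihood accumulated from the scaling constants), which protects
against underflow exactly as log-space recursions do; Viterbi is log-space.
Missing bins split sequences rather than being imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import STATE_DWELL, STATE_ROAM

__all__ = [
    "DECISION_LINE_SLOPE",
    "classify_roam_dwell_line",
    "split_on_missing",
    "labels_to_symbols",
    "CategoricalHMMParams",
    "fit_categorical_hmm",
    "decode_hmm",
    "ARHMMParams",
    "GaussianBaselineParams",
    "fit_arhmm",
    "fit_gaussian_baseline",
    "heldout_eval",
    "HeldoutResult",
    "decode_arhmm",
    "select_arhmm_K",
    "StateSequence",
]

#: roaming when speed (mm/s) > angular speed (deg/s) / DECISION_LINE_SLOPE
DECISION_LINE_SLOPE = 450.0


def classify_roam_dwell_line(speed: np.ndarray,
                             angular_speed: np.ndarray) -> np.ndarray:
    """Per-bin roam/dwell labels from the speed-vs-angular-speed line.

    A bin is roaming when mean centroid speed strictly exceeds mean centroid
    angular speed / 450 (the y = x/450 decision line); on or below the line
    is dwelling. Missing bins stay missing (None).
    """
    speed = np.asarray(speed, dtype=float)
    ang = np.asarray(angular_speed, dtype=float)
    if np.any(ang[np.isfinite(ang)] < 0):
        raise ValueError("angular speed must be non-negative")
    out = np.full(speed.shape, None, dtype=object)
    ok = np.isfinite(speed) & np.isfinite(ang)
    out[ok & (speed > ang / DECISION_LINE_SLOPE)] = STATE_ROAM
    out[ok & ~(speed > ang / DECISION_LINE_SLOPE)] = STATE_DWELL
    return out


def split_on_missing(values: np.ndarray) -> list[np.ndarray]:
    """Split a per-bin series into contiguous runs of non-missing entries."""
    arr = np.asarray(values, dtype=object)
    if arr.dtype == object:
        ok = np.array([v is not None and not (isinstance(v, float) and np.isnan(v))
                       for v in arr])
    else:
        ok = np.isfinite(arr)
    out = []
    t = 0
    n = len(arr)
    while t < n:
        if not ok[t]:
            t += 1
            continue
        start = t
        while t < n and ok[t]:
            t += 1
        out.append(arr[start:t])
    return out


def labels_to_symbols(labels: np.ndarray,
                      alphabet: tuple = (STATE_ROAM, STATE_DWELL)) -> np.ndarray:
    lookup = {lab: i for i, lab in enumerate(alphabet)}
    return np.array([lookup[v] for v in labels], dtype=int)


# ---------------------------------------------------------------------------
# scaled forward-backward core (shared by categorical and AR emissions)


def _forward_backward(init: np.ndarray, trans: np.ndarray,
                      obs_prob_log: np.ndarray):
    """Posteriors, expected transition counts and log-likelihood.

    ``obs_prob_log`` is the (T, K) log emission density. Returns
    (gamma (T, K), xi_sum (K, K), loglik).
    """
    T, K = obs_prob_log.shape
    shift = obs_prob_log.max(axis=1)
    shift[~np.isfinite(shift)] = 0.0
    B = np.exp(obs_prob_log - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = init * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        xi = alpha[t][:, None] * trans * bb[None, :]
        xi_sum += xi / c[t + 1]
        beta[t] = (trans @ bb) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, loglik


def _viterbi(init: np.ndarray, trans: np.ndarray,
             obs_prob_log: np.ndarray) -> np.ndarray:
    T, K = obs_prob_log.shape
    with np.errstate(divide="ignore"):
        lt = np.log(trans)
        delta = np.log(init) + obs_prob_log[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + lt
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + obs_prob_log[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# categorical HMM


@dataclass
class CategoricalHMMParams:
    """K hidden states emitting one of M symbols per bin."""

    initial: np.ndarray          # (K,)
    transitions: np.ndarray      # (K, K) row-stochastic
    emissions: np.ndarray        # (K, M) row-stochastic
    alphabet: tuple = (STATE_ROAM, STATE_DWELL)
    log_likelihood: float = np.nan
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False

    @property
    def K(self) -> int:
        return len(self.initial)


def _hmm_em(seqs: list[np.ndarray], K: int, M: int, rng: np.random.Generator,
            tol: float, max_iter: int):
    init = rng.dirichlet(np.ones(K))
    trans = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(trans, 0.9)
    emis = rng.dirichlet(np.ones(M), size=K)
    history = []
    prev = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        g0 = np.zeros(K)
        xi = np.zeros((K, K))
        ecount = np.zeros((K, M))
        for seq in seqs:
            with np.errstate(divide="ignore"):
                obs_log = np.log(emis[:, seq]).T        # (T, K)
            gamma, xs, l = _forward_backward(init, trans, obs_log)
            ll += l
            g0 += gamma[0]
            xi += xs
            for m in range(M):
                ecount[:, m] += gamma[seq == m].sum(axis=0)
        history.append(ll)
        if ll - prev < tol * abs(ll) and np.isfinite(prev):
            break
        prev = ll
        init = g0 / g0.sum()
        trans = (xi + 1e-12) / (xi + 1e-12).sum(axis=1, keepdims=True)
        emis = (ecount + 1e-12) / (ecount + 1e-12).sum(axis=1, keepdims=True)
    return init, trans, emis, np.asarray(history)


def fit_categorical_hmm(sequences: list[np.ndarray], K: int = 2, seed: int = 0,
                        tol: float = 1e-6, max_iter: int = 500,
                        n_restarts: int = 5,
                        alphabet: tuple = (STATE_ROAM, STATE_DWELL),
                        ) -> CategoricalHMMParams:
    """Baum-Welch fit of a K-state categorical HMM to label sequences.

    ``sequences`` holds either integer symbol arrays or label arrays over
    ``alphabet``; missing bins must already have split the sequences. The
    best of ``n_restarts`` seeded restarts is returned, with states relabeled
    so state 0 has the highest probability of emitting the first alphabet
    symbol (roaming). EM log-likelihood is non-decreasing per iteration.
    """
    seqs = []
    for s in sequences:
        s = np.asarray(s)
        if s.dtype.kind not in "iu":
            s = labels_to_symbols(s, alphabet)
        if len(s) >= 2:
            seqs.append(s.astype(int))
    if not seqs:
        raise ValueError("need at least one sequence of length >= 2")
    M = max(len(alphabet), max(int(s.max()) + 1 for s in seqs))
    concat = np.concatenate(seqs)
    if K == 1:
        freq = np.bincount(concat, minlength=M).astype(float)
        return CategoricalHMMParams(
            initial=np.ones(1), transitions=np.ones((1, 1)),
            emissions=(freq / freq.sum())[None, :], alphabet=alphabet,
            log_likelihood=float(np.sum(np.log((freq / freq.sum())[concat]))))
    degenerate = len(np.unique(concat)) == 1
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        init, trans, emis, hist = _hmm_em(seqs, K, M, rng, tol, max_iter)
        if best is None or hist[-1] > best[3][-1]:
            best = (init, trans, emis, hist)
    init, trans, emis, hist = best
    order = np.argsort(-emis[:, 0])          # state 0 = highest roam emission
    params = CategoricalHMMParams(
        initial=init[order], transitions=trans[np.ix_(order, order)],
        emissions=emis[order], alphabet=alphabet,
        log_likelihood=float(hist[-1]), ll_history=hist, degenerate=degenerate)
    return params


@dataclass
class StateSequence:
    """Decoded per-bin states with posteriors; -1 marks a missing bin."""

    states: np.ndarray           # (T,) int, -1 = missing
    posteriors: np.ndarray       # (T, K), NaN rows where missing
    K: int
    decode_method: str = "posterior-argmax"

    def __len__(self) -> int:
        return len(self.states)


def decode_hmm(params: CategoricalHMMParams, sequence: np.ndarray,
               method: str = "posterior-argmax") -> StateSequence:
    """Decode one symbol/label sequence (missing entries decoded as missing)."""
    arr = np.asarray(sequence)
    if arr.dtype.kind in "iu":
        sym = arr.astype(float)
    else:
        lookup = {lab: i for i, lab in enumerate(params.alphabet)}
        sym = np.array([np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                        else lookup[v] for v in arr], dtype=float)
    bad = np.isfinite(sym) & ((sym < 0) | (sym >= params.emissions.shape[1]))
    if bad.any():
        raise ValueError("symbol outside the emission alphabet")
    T = len(sym)
    K = params.K
    states = np.full(T, -1, dtype=int)
    post = np.full((T, K), np.nan)
    t = 0
    while t < T:
        if not np.isfinite(sym[t]):
            t += 1
            continue
        start = t
        while t < T and np.isfinite(sym[t]):
            t += 1
        seq = sym[start:t].astype(int)
        with np.errstate(divide="ignore"):
            obs_log = np.log(params.emissions[:, seq]).T
        gamma, _, _ = _forward_backward(params.initial, params.transitions, obs_log)
        post[start:t] = gamma
        if method == "viterbi":
            states[start:t] = _viterbi(params.initial, params.transitions, obs_log)
        else:
            states[start:t] = np.argmax(gamma, axis=1)
    return StateSequence(states=states, posteriors=post, K=K, decode_method=method)


# ---------------------------------------------------------------------------
# AR-HMM


@dataclass
class ARHMMParams:
    """K-state Markov chain with per-state linear-Gaussian dynamics."""

    initial: np.ndarray          # (K,)
    transitions: np.ndarray      # (K, K)
    A: np.ndarray                # (K, D, D) dynamics
    b: np.ndarray                # (K, D) bias
    Q: np.ndarray                # (K, D, D) noise covariance (SPD)
    feature_names: tuple = ()
    feature_mean: np.ndarray | None = None   # z-score transform, if used
    feature_std: np.ndarray | None = None
    log_likelihood: float = np.nan
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def K(self) -> int:
        return len(self.initial)

    @property
    def D(self) -> int:
        return self.A.shape[1]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return np.asarray(X, dtype=float)
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_std


def _ar_emission_logprob(X: np.ndarray, A: np.ndarray, b: np.ndarray,
                         Q: np.ndarray) -> np.ndarray:
    """(T-1, K) log N(x_t | A_k x_{t-1} + b_k, Q_k) for t = 1..T-1."""
    T, D = X.shape
    K = len(A)
    out = np.empty((T - 1, K))
    for k in range(K):
        resid = X[1:] - X[:-1] @ A[k].T - b[k]
        chol, low = cho_factor(Q[k], lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sol = cho_solve((chol, low), resid.T)
        maha = np.einsum("ij,ji->i", resid, sol)
        out[:, k] = -0.5 * (D * np.log(2 * np.pi) + logdet + maha)
    return out


def _check_sequences(sequences, D=None):
    seqs = []
    for X in sequences:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("each sequence must be a (T, D) array")
        if not np.isfinite(X).all():
            raise ValueError("sequences must be finite; split on missing bins first")
        if len(X) < 2:
            raise ValueError("each sequence needs length >= 2")
        if D is not None and X.shape[1] != D:
            raise ValueError(f"feature dimension mismatch: expected {D}")
        seqs.append(X)
    if not seqs:
        raise ValueError("need at least one sequence")
    return seqs


def _arhmm_mstep(seqs, gammas, K, D, ridge=1e-8, q_floor=1e-6):
    A = np.empty((K, D, D))
    b = np.empty((K, D))
    Q = np.empty((K, D, D))
    for k in range(K):
        Szz = np.zeros((D + 1, D + 1))
        Sxz = np.zeros((D, D + 1))
        Sxx = np.zeros((D, D))
        W = 0.0
        for X, g in zip(seqs, gammas):
            w = g[:, k]
            Z = np.hstack([X[:-1], np.ones((len(X) - 1, 1))])
            Xc = X[1:]
            wZ = Z * w[:, None]
            Szz += wZ.T @ Z
            Sxz += (Xc * w[:, None]).T @ Z
            Sxx += (Xc * w[:, None]).T @ Xc
            W += w.sum()
        Szz += ridge * np.eye(D + 1)
        coef = np.linalg.solve(Szz, Sxz.T).T        # (D, D+1)
        A[k] = coef[:, :D]
        b[k] = coef[:, D]
        # weighted residual covariance
        Qk = (Sxx - coef @ Sxz.T - Sxz @ coef.T + coef @ Szz @ coef.T) / max(W, 1e-12)
        Qk = 0.5 * (Qk + Qk.T)
        ev, U = np.linalg.eigh(Qk)
        Q[k] = (U * np.maximum(ev, q_floor)) @ U.T
    return A, b, Q


def _init_state_labels(seqs, K: int, rng: np.random.Generator,
                       use_kmeans: bool) -> list[np.ndarray]:
    """Hard state labels for the T-1 transition steps of each sequence."""
    if K == 1:
        return [np.zeros(len(X) - 1, dtype=int) for X in seqs]
    if use_kmeans:
        pairs = np.concatenate([np.hstack([X[:-1], X[1:]]) for X in seqs])
        try:
            from scipy.cluster.vq import kmeans2

            _, lab = kmeans2(pairs, K, minit="++", seed=rng, missing="raise")
            out = []
            pos = 0
            for X in seqs:
                n = len(X) - 1
                out.append(lab[pos:pos + n].astype(int))
                pos += n
            return out
        except Exception:
            pass                     # empty cluster etc.: fall through
    out = []
    for X in seqs:
        n = len(X) - 1
        block = max(10, n // (5 * K))
        n_blocks = -(-n // block)
        lab = np.repeat(rng.integers(0, K, n_blocks), block)[:n]
        out.append(lab.astype(int))
    return out


def fit_arhmm(sequences, K: int, seed: int = 0, tol: float = 1e-6,
              max_iter: int = 500, n_restarts: int = 5,
              standardize: bool = True, sort_feature: int | None = None,
              feature_names: tuple = ()) -> ARHMMParams:
    """EM fit of a K-state AR(1) HMM to feature sequences.

    The first observation of each sequence is conditioned on (the likelihood
    starts at t = 1). E-step: forward-backward over the AR emission
    densities. M-step: per-state weighted least squares for [A_k | b_k],
    weighted residual covariance for Q_k (eigenvalue-floored to stay SPD),
    row-normalized expected transition counts. States are sorted ascending by
    their weighted mean of ``sort_feature`` (default: feature 1, the midbody
    forward speed of the canonical 5-feature vector) so the last state is the
    fastest. Features are optionally z-scored; the transform is stored.
    """
    seqs = _check_sequences(sequences)
    D = seqs[0].shape[1]
    seqs = _check_sequences(seqs, D)
    if sort_feature is None:
        sort_feature = 1 if D >= 2 else 0
    mean = std = None
    if standardize:
        allx = np.concatenate(seqs)
        mean = allx.mean(axis=0)
        std = allx.std(axis=0)
        std[std == 0] = 1.0
        seqs = [(X - mean) / std for X in seqs]

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(n_restarts, 1)):
        # Initial hard assignment of time steps. A uniform random assignment
        # makes the first M-step average every state toward the same global
        # dynamics (a symmetric EM saddle), so the first restart clusters the
        # (x_{t-1}, x_t) transition pairs and the others assign contiguous
        # blocks, both of which preserve state-specific local structure.
        labels_per_seq = _init_state_labels(seqs, K, rng,
                                            use_kmeans=(restart == 0))
        gammas = []
        for lab in labels_per_seq:
            g = np.zeros((len(lab), K))
            g[np.arange(len(lab)), lab] = 1.0
            # tiny smoothing only: anything larger lets high-leverage points
            # from other states' operating regions swamp the first M-step
            gammas.append(g + 1e-3)
        gammas = [g / g.sum(axis=1, keepdims=True) for g in gammas]
        A, b, Q = _arhmm_mstep(seqs, gammas, K, D)
        init = np.full(K, 1.0 / K)
        trans = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(trans, 0.9)
        if K == 1:
            trans = np.ones((1, 1))

        history = []
        prev = -np.inf
        for _ in range(max_iter):
            ll = 0.0
            g0 = np.zeros(K)
            xi = np.zeros((K, K))
            gammas = []
            for X in seqs:
                obs_log = _ar_emission_logprob(X, A, b, Q)
                gamma, xs, l = _forward_backward(init, trans, obs_log)
                ll += l
                g0 += gamma[0]
                xi += xs
                gammas.append(gamma)
            history.append(ll)
            if np.isfinite(prev) and ll - prev < tol * abs(ll):
                break
            prev = ll
            init = g0 / g0.sum()
            if K > 1:
                trans = (xi + 1e-12) / (xi + 1e-12).sum(axis=1, keepdims=True)
            A, b, Q = _arhmm_mstep(seqs, gammas, K, D)
        if best is None or history[-1] > best[-1][-1]:
            best = (init, trans, A, b, Q, np.asarray(history))
    init, trans, A, b, Q, hist = best

    # sort states by their occupancy-weighted mean of the sort feature
    means = np.zeros(K)
    wsum = np.zeros(K)
    for X in seqs:
        obs_log = _ar_emission_logprob(X, A, b, Q)
        gamma, _, _ = _forward_backward(init, trans, obs_log)
        means += gamma.T @ X[1:, sort_feature]
        wsum += gamma.sum(axis=0)
    order = np.argsort(means / np.maximum(wsum, 1e-12))
    params = ARHMMParams(
        initial=init[order], transitions=trans[np.ix_(order, order)],
        A=A[order], b=b[order], Q=Q[order],
        feature_names=tuple(feature_names),
        feature_mean=mean, feature_std=std,
        log_likelihood=float(hist[-1]), ll_history=hist)
    return params


@dataclass
class GaussianBaselineParams:
    """i.i.d. multivariate Gaussian x_t ~ N(mu, Sigma) baseline."""

    mean: np.ndarray
    cov: np.ndarray
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return np.asarray(X, dtype=float)
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_std


def fit_gaussian_baseline(sequences, match: ARHMMParams | None = None
                          ) -> GaussianBaselineParams:
    """Fit the Gaussian baseline on the same conditional observations
    (t >= 1 of each sequence) that the AR-HMM likelihood scores, using the
    AR-HMM's standardization if ``match`` is given."""
    seqs = _check_sequences(sequences)
    fm = fs = None
    if match is not None and match.feature_mean is not None:
        fm, fs = match.feature_mean, match.feature_std
        seqs = [(X - fm) / fs for X in seqs]
    allx = np.concatenate([X[1:] for X in seqs])
    cov = np.cov(allx.T, bias=False)
    cov = np.atleast_2d(cov)
    ev, U = np.linalg.eigh(0.5 * (cov + cov.T))
    cov = (U * np.maximum(ev, 1e-8)) @ U.T
    return GaussianBaselineParams(mean=allx.mean(axis=0), cov=cov,
                                  feature_mean=fm, feature_std=fs)


def arhmm_loglik(params: ARHMMParams, sequences) -> tuple[float, int]:
    """Marginal log-likelihood of sequences under the AR-HMM (t >= 1)."""
    seqs = _check_sequences(sequences, params.D)
    total = 0.0
    n_obs = 0
    for X in seqs:
        Xs = params.standardize(X)
        obs_log = _ar_emission_logprob(Xs, params.A, params.b, params.Q)
        _, _, ll = _forward_backward(params.initial, params.transitions, obs_log)
        if params.feature_std is not None:
            ll -= (len(X) - 1) * np.log(params.feature_std).sum()
        total += ll
        n_obs += len(X) - 1
    return total, n_obs


@dataclass
class HeldoutResult:
    ll_arhmm: float
    ll_gaussian: float
    ratio: float                 # LL_arhmm / LL_gaussian
    n_obs: int

    @property
    def per_obs(self) -> tuple[float, float]:
        return self.ll_arhmm / self.n_obs, self.ll_gaussian / self.n_obs


def heldout_eval(arhmm: ARHMMParams, baseline: GaussianBaselineParams,
                 test_sequences) -> HeldoutResult:
    """Held-out log-likelihoods of both models and their ratio.

    Both models score the same observations (t >= 1 of each test sequence, on
    the original feature scale), so the log-likelihoods are comparable.
    """
    seqs = _check_sequences(test_sequences, arhmm.D)
    ll_ar, n_obs = arhmm_loglik(arhmm, seqs)
    if n_obs == 0:
        raise ValueError("empty test set")
    ll_g = 0.0
    chol, low = cho_factor(baseline.cov, lower=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    D = arhmm.D
    for X in seqs:
        Xs = baseline.standardize(X)[1:]
        resid = Xs - baseline.mean
        sol = cho_solve((chol, low), resid.T)
        maha = np.einsum("ij,ji->i", resid, sol)
        ll_g += float(-0.5 * (D * np.log(2 * np.pi) + logdet + maha).sum())
        if baseline.feature_std is not None:
            ll_g -= (len(X) - 1) * np.log(baseline.feature_std).sum()
    return HeldoutResult(ll_arhmm=ll_ar, ll_gaussian=ll_g,
                         ratio=ll_ar / ll_g, n_obs=n_obs)


def decode_arhmm(params: ARHMMParams, X: np.ndarray,
                 method: str = "posterior-argmax") -> StateSequence:
    """Decode one feature sequence; bin 0 has no AR emission and is missing."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.D:
        raise ValueError(f"expected a (T, {params.D}) sequence")
    if len(X) < 2:
        raise ValueError("sequence must have length >= 2")
    Xs = params.standardize(X)
    obs_log = _ar_emission_logprob(Xs, params.A, params.b, params.Q)
    gamma, _, _ = _forward_backward(params.initial, params.transitions, obs_log)
    T = len(X)
    states = np.full(T, -1, dtype=int)
    post = np.full((T, params.K), np.nan)
    post[1:] = gamma
    if method == "viterbi":
        states[1:] = _viterbi(params.initial, params.transitions, obs_log)
    else:
        states[1:] = np.argmax(gamma, axis=1)
    return StateSequence(states=states, posteriors=post, K=params.K,
                         decode_method=method)


def select_arhmm_K(sequences, K_grid, folds: int = 3, seed: int = 0,
                   **fit_kwargs) -> tuple[int, "object"]:
    """Cross-validated held-out log-likelihood over a grid of state counts.

    Sequences are split into ``folds`` groups; for each K the AR-HMM is fit
    on the training folds and scored (per-observation forward log-likelihood)
    on the held-out fold. Returns (argmax K, table) where the table is a
    pandas DataFrame with one row per K.
    """
    import pandas as pd

    K_grid = list(K_grid)
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    seqs = _check_sequences(sequences)
    folds = min(folds, len(seqs))
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(len(seqs)) % folds
    rows = []
    for K in K_grid:
        ll_total = 0.0
        n_total = 0
        for f in range(folds):
            train = [s for s, a in zip(seqs, assignment) if a != f or folds == 1]
            test = [s for s, a in zip(seqs, assignment) if a == f] \
                if folds > 1 else seqs
            if not train:
                raise ValueError("fold with empty training set")
            params = fit_arhmm(train, K=K, seed=seed + 1000 * K + f, **fit_kwargs)
            ll, n = arhmm_loglik(params, test)
            ll_total += ll
            n_total += n
        rows.append({"K": K, "heldout_ll": ll_total,
                     "heldout_ll_per_obs": ll_total / n_total, "n_obs": n_total})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["heldout_ll_per_obs"].idxmax(), "K"])
    return best, table
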