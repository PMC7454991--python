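"""Two-state hidden Markov model for incubation on/off-bout inference.

The hidden states are *on-bout* (parent on the nest, temperature rising or
holding near the incubation setpoint) and *off-bout* (parent away, egg
cooling toward ambient). The observation at each point is the temperature
change from the previous measurement.

Two emission semantics coexist:

* ``cdf`` — the decoding weights: the on-state weight of a change ``x`` is
  the normal CDF ``Phi((x - mu_on) / sigma_on)`` (increasing in ``x``) and
  the off-state weight is the complementary CDF under the off parameters
  (decreasing in ``x``). These monotone weights encode "the more positive
  the change, the more on-bout-like" directly.
* ``density`` — ordinary Gaussian densities, used internally by Baum-Welch
  so that the M-step has its standard closed form and the EM monotonicity
  guarantee holds. The ten estimated parameters are then handed to the CDF
  decoder.

The model carries exactly ten free values: two initial probabilities, four
transition probabilities, two observation means and two observation
standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .errors import (
    DegenerateEmissionError,
    InsufficientLabelsError,
    MomentError,
    ParameterError,
)
from .preprocess import ObservationSeries, Source, make_observations
from .trace_io import OFF, ON, LabelSet, ThermalTrace

log = logging.getLogger(__name__)

#: numerical floors
SIGMA_FLOOR = 1e-3
_WEIGHT_FLOOR = 1e-12
_PROB_FLOOR = 1e-12

_PARAM_KEYS = (
    "pi_on", "pi_off",
    "a_on_on", "a_on_off", "a_off_on", "a_off_off",
    "mu_on", "mu_off",
    "sigma_on", "sigma_off",
)


@dataclass(frozen=True)
class HMMParams:
    """The ten model values.

    Attributes
    ----------
    pi_on, pi_off
        Initial state probabilities (sum to 1).
    a_on_on, a_on_off, a_off_on, a_off_off
        Transition probabilities; each origin row sums to 1.
    mu_on, mu_off
        Mean temperature change per sample in each state (degC/sample).
    sigma_on, sigma_off
        Standard deviations of the per-sample change (degC/sample),
        floored at ``SIGMA_FLOOR``.
    """

    pi_on: float
    pi_off: float
    a_on_on: float
    a_on_off: float
    a_off_on: float
    a_off_off: float
    mu_on: float
    mu_off: float
    sigma_on: float
    sigma_off: float

    def __post_init__(self) -> None:
        tol = 1e-9
        if abs(self.pi_on + self.pi_off - 1.0) > tol:
            raise ParameterError("initial probabilities must sum to 1")
        if abs(self.a_on_on + self.a_on_off - 1.0) > tol:
            raise ParameterError("on-row transition probabilities must sum to 1")
        if abs(self.a_off_on + self.a_off_off - 1.0) > tol:
            raise ParameterError("off-row transition probabilities must sum to 1")
        for name in ("pi_on", "pi_off", "a_on_on", "a_on_off", "a_off_on", "a_off_off"):
            v = getattr(self, name)
            if not -tol <= v <= 1.0 + tol:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.sigma_on < SIGMA_FLOOR or self.sigma_off < SIGMA_FLOOR:
            raise ParameterError(
                f"standard deviations must be >= {SIGMA_FLOOR} degC/sample"
            )

    # -- array views -------------------------------------------------
    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi_on, self.pi_off])

    @property
    def transmat(self) -> np.ndarray:
        return np.array(
            [[self.a_on_on, self.a_on_off], [self.a_off_on, self.a_off_off]]
        )

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu_on, self.mu_off])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma_on, self.sigma_off])

    # -- construction ------------------------------------------------
    @classmethod
    def from_arrays(cls, pi, transmat, mu, sigma) -> "HMMParams":
        pi = np.asarray(pi, float)
        a = np.asarray(transmat, float)
        mu = np.asarray(mu, float)
        sigma = np.asarray(sigma, float)
        return cls(
            pi_on=float(pi[ON]), pi_off=float(pi[OFF]),
            a_on_on=float(a[ON, ON]), a_on_off=float(a[ON, OFF]),
            a_off_on=float(a[OFF, ON]), a_off_off=float(a[OFF, OFF]),
            mu_on=float(mu[ON]), mu_off=float(mu[OFF]),
            sigma_on=float(sigma[ON]), sigma_off=float(sigma[OFF]),
        )

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _PARAM_KEYS}

    # -- flat key=value config round-trip -----------------------------
    def to_file(self, path) -> None:
        """Write the ten parameters as a flat ``key = value`` config."""
        with open(path, "w") as fh:
            for k in _PARAM_KEYS:
                fh.write(f"{k} = {float(getattr(self, k))!r}\n")

    @classmethod
    def from_file(cls, path) -> "HMMParams":
        values: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParameterError(f"{path}: line {lineno}: expected key = value")
                k, v = (s.strip() for s in line.split("=", 1))
                if k not in _PARAM_KEYS:
                    raise ParameterError(f"{path}: line {lineno}: unknown key {k!r}")
                if k in values:
                    raise ParameterError(f"{path}: line {lineno}: duplicate key {k!r}")
                values[k] = float(v)
        missing = [k for k in _PARAM_KEYS if k not in values]
        if missing:
            raise ParameterError(f"{path}: missing keys {missing}")
        return cls(**values)


@dataclass(frozen=True)
class Posteriors:
    """Per-point state membership probabilities plus the data likelihood."""

    gamma: np.ndarray  # (T, 2); rows sum to 1
    log_likelihood: float


@dataclass(frozen=True)
class FitResult:
    """Outcome of Baum-Welch training."""

    params: HMMParams
    log_likelihoods: np.ndarray  # per-iteration training log-likelihood
    converged: bool

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihoods)


def _as_deltas(obs) -> np.ndarray:
    if isinstance(obs, ObservationSeries):
        return obs.deltas
    return np.asarray(obs, dtype=float)


def emission_weight(x, state: int, params: HMMParams):
    """CDF-based observation weight of change ``x`` under ``state``.

    On-state weight rises with ``x``; off-state weight falls with ``x``.
    Weights are clamped to ``[1e-12, 1]`` so log-space recursions stay
    finite.
    """
    x = np.asarray(x, dtype=float)
    if state == ON:
        w = ndtr((x - params.mu_on) / params.sigma_on)
    elif state == OFF:
        w = 1.0 - ndtr((x - params.mu_off) / params.sigma_off)
    else:
        raise ParameterError(f"unknown state {state!r}")
    return np.clip(w, _WEIGHT_FLOOR, 1.0)


def _log_emissions(deltas: np.ndarray, params: HMMParams, emission: str) -> np.ndarray:
    """(T, 2) matrix of log emission weights."""
    if emission == "cdf":
        b = np.column_stack(
            [emission_weight(deltas, ON, params), emission_weight(deltas, OFF, params)]
        )
        return np.log(b)
    if emission == "density":
        return np.column_stack(
            [
                norm.logpdf(deltas, params.mu_on, params.sigma_on),
                norm.logpdf(deltas, params.mu_off, params.sigma_off),
            ]
        )
    raise ParameterError(f"emission must be 'cdf' or 'density', got {emission!r}")


def viterbi(obs, params: HMMParams, emission: str = "cdf") -> np.ndarray:
    """Most probable state path under the given emission semantics.

    Computed in log space. Ties are broken by preferring to remain in the
    previous state, and by preferring *on* for the first point.

    Returns an integer array with ``ON`` (0) / ``OFF`` (1) per point.
    """
    deltas = _as_deltas(obs)
    if deltas.size < 1:
        raise ParameterError("need at least one observation")
    logB = _log_emissions(deltas, params, emission)
    logpi = np.log(np.clip(params.pi, _PROB_FLOOR, 1.0))
    logA = np.log(np.clip(params.transmat, _PROB_FLOOR, 1.0))
    T = len(deltas)
    delta = np.empty((T, 2))
    psi = np.zeros((T, 2), dtype=int)
    delta[0] = logpi + logB[0]
    for t in range(1, T):
        for s in (ON, OFF):
            stay = delta[t - 1, s] + logA[s, s]
            move = delta[t - 1, 1 - s] + logA[1 - s, s]
            if stay >= move:  # tie -> remain in previous state
                delta[t, s] = stay + logB[t, s]
                psi[t, s] = s
            else:
                delta[t, s] = move + logB[t, s]
                psi[t, s] = 1 - s
    path = np.empty(T, dtype=int)
    path[-1] = ON if delta[-1, ON] >= delta[-1, OFF] else OFF
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _forward_backward_arrays(deltas, params, emission):
    """Scaled forward-backward recursions.

    Returns (alpha_hat, beta_hat, B, log_likelihood) where alpha_hat rows
    are normalized and B is the linear-space emission matrix.
    """
    logB = _log_emissions(deltas, params, emission)
    B = np.exp(logB)
    A = params.transmat
    T = len(deltas)
    alpha = np.empty((T, 2))
    scale = np.empty(T)
    a0 = params.pi * B[0]
    scale[0] = a0.sum()
    if scale[0] <= 0:
        raise DegenerateEmissionError("all states have zero weight at point 1")
    alpha[0] = a0 / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        scale[t] = a.sum()
        if scale[t] <= 0:
            raise DegenerateEmissionError(f"all states have zero weight at point {t + 1}")
        alpha[t] = a / scale[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    return alpha, beta, B, float(np.log(scale).sum())


def forward_backward(obs, params: HMMParams, emission: str = "density") -> Posteriors:
    """Posterior state probabilities and total data log-likelihood.

    Uses per-step scaling so long traces do not underflow. ``gamma`` rows
    sum to 1; ``log_likelihood`` is the log of the sum over all state
    paths of (initial/transition probability x emission weight) products.
    """
    deltas = _as_deltas(obs)
    if deltas.size < 1:
        raise ParameterError("need at least one observation")
    alpha, beta, _, ll = _forward_backward_arrays(deltas, params, emission)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return Posteriors(gamma=gamma, log_likelihood=ll)


def default_init(obs) -> HMMParams:
    """Deterministic Baum-Welch starting point from a median split.

    Deltas at or below the median seed the off state's mean/SD (cooling is
    the more negative tail), deltas above seed the on state; transitions
    start at 0.9 self / 0.1 cross and the initial distribution is uniform.
    """
    deltas = _as_deltas(obs)
    med = np.median(deltas)
    lower = deltas[deltas <= med]
    upper = deltas[deltas > med]
    if upper.size == 0:  # fully degenerate data; split evenly
        half = len(deltas) // 2
        lower, upper = deltas[:half], deltas[half:]
    mu = np.array([upper.mean(), lower.mean()])
    sigma = np.array(
        [
            max(upper.std(ddof=1) if upper.size > 1 else 0.0, SIGMA_FLOOR),
            max(lower.std(ddof=1) if lower.size > 1 else 0.0, SIGMA_FLOOR),
        ]
    )
    return HMMParams.from_arrays(
        pi=[0.5, 0.5], transmat=[[0.9, 0.1], [0.1, 0.9]], mu=mu, sigma=sigma
    )


def baum_welch(
    obs,
    init: HMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 250,
    seed: int | None = None,
    n_starts: int = 1,
) -> FitResult:
    """Unsupervised maximum-likelihood estimation of the ten parameters.

    Iterates the expectation step (scaled forward-backward under Gaussian
    density emissions) and the closed-form maximization step until the
    relative log-likelihood improvement drops below ``tol`` or ``max_iter``
    is reached. The training log-likelihood is non-decreasing across
    iterations up to rounding.

    ``init`` defaults to the deterministic median split of
    :func:`default_init`. With ``n_starts > 1`` and a ``seed``, additional
    runs start from jittered copies of the initializer and the best final
    likelihood wins.

    If one state's expected occupancy collapses below one effective point a
    degenerate-fit warning is logged and its standard deviation is floored.
    """
    deltas = _as_deltas(obs)
    if deltas.size < 2:
        raise ParameterError("Baum-Welch needs at least 2 observations")
    base = init if init is not None else default_init(deltas)
    if max_iter == 0:
        return FitResult(base, np.empty(0), converged=False)

    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    for start in range(max(1, n_starts)):
        p = base if start == 0 else _jitter(base, rng)
        result = _baum_welch_single(deltas, p, tol, max_iter)
        if best is None or result.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = result
    return best


def _jitter(params: HMMParams, rng: np.random.Generator) -> HMMParams:
    mu = params.mu + rng.normal(0, np.maximum(params.sigma, 0.01))
    sigma = np.maximum(params.sigma * rng.uniform(0.5, 2.0, 2), SIGMA_FLOOR)
    stay = rng.uniform(0.6, 0.99, 2)
    return HMMParams.from_arrays(
        pi=[0.5, 0.5],
        transmat=[[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]],
        mu=mu,
        sigma=sigma,
    )


def _baum_welch_single(deltas, params, tol, max_iter) -> FitResult:
    lls: list[float] = []
    converged = False
    T = len(deltas)
    for _ in range(max_iter):
        alpha, beta, B, ll = _forward_backward_arrays(deltas, params, "density")
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # expected transition counts xi[i, j], summed over t
        A = params.transmat
        num = (
            alpha[:-1, :, None] * A[None, :, :] * (B[1:] * beta[1:])[:, None, :]
        )  # (T-1, 2, 2)
        num /= num.sum(axis=(1, 2), keepdims=True)
        xi_sum = num.sum(axis=0)

        occ = gamma.sum(axis=0)
        if np.any(occ < 1.0):
            log.warning(
                "degenerate fit: state occupancy %s below one effective point", occ
            )
        pi = gamma[0] / gamma[0].sum()
        denom = np.maximum(gamma[:-1].sum(axis=0), _PROB_FLOOR)
        transmat = xi_sum / denom[:, None]
        transmat /= transmat.sum(axis=1, keepdims=True)
        w = gamma / np.maximum(occ, _PROB_FLOOR)
        mu = (w * deltas[:, None]).sum(axis=0)
        var = (w * (deltas[:, None] - mu) ** 2).sum(axis=0)
        sigma = np.maximum(np.sqrt(var), SIGMA_FLOOR)
        params = HMMParams.from_arrays(pi, transmat, mu, sigma)
        lls.append(ll)
        if len(lls) >= 2:
            prev = lls[-2]
            if (ll - prev) <= tol * abs(prev):
                converged = True
                break
    return FitResult(params, np.array(lls), converged=converged)


def supervised_fit(obs, labels: LabelSet) -> HMMParams:
    """Exact maximum-likelihood parameters from hand-labeled points.

    The initial distribution is the indicator of the first labeled point's
    state; transition probabilities are normalized counts over consecutive
    labeled pairs; each state's mean and standard deviation (n-1
    denominator) come from the deltas at its labeled points, with the SD
    floored at ``SIGMA_FLOOR``.
    """
    deltas = _as_deltas(obs)
    if labels.last_index > len(deltas):
        raise ParameterError(
            f"labels extend to point {labels.last_index} but only "
            f"{len(deltas)} observations given"
        )
    states = labels.states
    if len(states) < 2:
        raise InsufficientLabelsError("need at least 2 labeled points")
    present = set(np.unique(states).tolist())
    if present != {ON, OFF}:
        raise InsufficientLabelsError(
            "labels must contain both on and off points; got only "
            + ("on" if present == {ON} else "off")
        )
    counts = np.zeros((2, 2))
    for a, b in zip(states[:-1], states[1:]):
        counts[a, b] += 1
    row = counts.sum(axis=1)
    if np.any(row == 0):
        raise InsufficientLabelsError("a state never occurs before another labeled point")
    transmat = counts / row[:, None]
    pi = np.zeros(2)
    pi[states[0]] = 1.0
    x = deltas[labels.first_index - 1 : labels.last_index]
    mu = np.empty(2)
    sigma = np.empty(2)
    for s in (ON, OFF):
        xs = x[states == s]
        if len(xs) < 2:
            raise MomentError(
                f"state {'on' if s == ON else 'off'} has {len(xs)} labeled point(s); "
                "need >= 2 to estimate moments"
            )
        mu[s] = xs.mean()
        sigma[s] = max(xs.std(ddof=1), SIGMA_FLOOR)
    return HMMParams.from_arrays(pi, transmat, mu, sigma)


def label_states(
    trace: ThermalTrace,
    params: HMMParams,
    source: Source | str = Source.RAW_EGG,
    window: int = 1,
    emission: str = "cdf",
) -> np.ndarray:
    """Decode a trace end-to-end: observations then Viterbi.

    Convenience composition of :func:`make_observations` and
    :func:`viterbi`; returns one ``ON``/``OFF`` code per trace point.
    """
    obs = make_observations(trace, source=source, window=window)
    return viterbi(obs, params, emission=emission)
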