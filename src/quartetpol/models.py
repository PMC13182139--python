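"""GTR+Γ+I likelihood machinery for species-quartets.

The model layer serves two purposes:

* fit a GTR+Γ+I substitution model with free branch lengths to a 4-taxon
  subalignment under each of the three quartet topologies, and
* turn a fitted model into exact probabilities for each of the 256
  nucleotide site patterns, from which the expected amount of convergent
  ("false synapomorphy") signal Nc is computed.

Likelihoods are computed by the pruning recursion on the unrooted quartet
tree; the model is time-reversible, so root placement does not affect the
likelihood and polarity enters only through pattern classification.
Because there are only 256 possible site patterns, the data collapse to a
pattern histogram and the cost of a likelihood evaluation is independent
of alignment length.

Rate-mixture convention: the GTR matrix is normalised to one expected
substitution per unit branch length, the discrete-gamma category rates
(median-of-category discretisation) are normalised to mean 1, and the
invariable class sits on top with weight ``p_inv``.  Branch lengths are
therefore expected substitutions per variable site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import gamma as gamma_dist

from .quartets import TOPOLOGIES, TOPOLOGY_IDS, _pattern_codes, class_masks

logger = logging.getLogger(__name__)

#: exchangeability order follows the usual lexicographic convention
RATE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
_CONST_CODES = np.array([0, 85, 170, 255])  # AAAA, CCCC, GGGG, TTTT
_CLASS_MASKS = class_masks()


class UninformativeQuartetError(ValueError):
    """Raised when a subalignment has no variable usable column to fit."""


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Γ+I parameterisation.

    ``rates`` are the six exchangeabilities (AC, AG, AT, CG, CT, GT) with
    GT fixed at 1; ``freqs`` the stationary base frequencies; ``alpha``
    the gamma shape; ``p_inv`` the invariable-site proportion.
    """

    rates: tuple[float, ...]
    freqs: tuple[float, ...]
    alpha: float
    p_inv: float
    n_gamma_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or len(self.freqs) != 4:
            raise ValueError("need 6 exchangeabilities and 4 frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if min(self.rates) <= 0 or self.alpha <= 0:
            raise ValueError("rates and alpha must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls(rates=(1.0,) * 6, freqs=(0.25,) * 4, alpha=100.0, p_inv=0.0)


@dataclass
class FittedQuartetModel:
    """ML parameters for one quartet topology on one subalignment.

    ``branch_lengths`` are ordered (pair-member 1, pair-member 2, third
    ingroup taxon, outgroup, internal branch) for the unrooted tree
    ((i,j),(k,O)) implied by ``topology``.
    """

    topology: str
    model: SubstitutionModel
    branch_lengths: np.ndarray  # (5,)
    log_likelihood: float
    converged: bool = True
    n_usable: int = 0

    def pattern_probabilities(self) -> np.ndarray:
        """Probabilities of the 256 (a,b,c,O) site patterns; sums to 1."""
        return pattern_probabilities(
            self.model, self.branch_lengths, self.topology
        )


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """GTR generator Q scaled to one expected substitution per unit time."""
    pi = np.asarray(model.freqs)
    r = np.zeros((4, 4))
    for (x, y), rate in zip(RATE_PAIRS, model.rates):
        i, j = "ACGT".index(x), "ACGT".index(y)
        r[i, j] = r[j, i] = rate
    Q = r * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def gamma_category_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Median-of-category discrete gamma rates, normalised to mean 1."""
    q = (np.arange(n_categories) + 0.5) / n_categories
    rates = gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
    return rates * n_categories / rates.sum()


def _transition_matrices(pi: np.ndarray, Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for an array of branch lengths via the reversible eigensystem."""
    d = np.sqrt(pi)
    B = Q * (d[:, None] / d[None, :])
    B = (B + B.T) / 2.0
    lam, V = np.linalg.eigh(B)
    W = V / d[:, None]
    Wi = V.T * d[None, :]
    E = np.exp(np.multiply.outer(lengths, lam))
    P = np.einsum("is,...s,sj->...ij", W, E, Wi)
    return np.clip(P, 0.0, None)


def pattern_probabilities(
    model: SubstitutionModel, branch_lengths: np.ndarray, topology: str
) -> np.ndarray:
    """Exact probabilities of the 256 nucleotide patterns (a,b,c,O).

    The tree is the unrooted quartet ((i,j),(k,O)) where (i,j) is the
    ingroup pair grouped by ``topology``; gamma categories and the
    invariable class are integrated out.
    """
    pi = np.asarray(model.freqs)
    Q = build_rate_matrix(model)
    cat_rates = gamma_category_rates(model.alpha, model.n_gamma_categories)
    t = np.asarray(branch_lengths, dtype=float)
    # (n_cat, 5) scaled lengths -> (n_cat, 5, 4, 4) transition matrices
    P = _transition_matrices(pi, Q, np.multiply.outer(cat_rates, t))
    Pi, Pj, Pk, Po, Pint = (P[:, b] for b in range(5))
    F = np.einsum("cui,cuj->cuij", Pi, Pj)
    G = np.einsum("cvu,cuij->cvij", Pint, F)
    L = np.einsum("v,cvij,cvk,cvo->ijko", pi, G, Pk, Po) / model.n_gamma_categories
    # arrange tip axes (i,j,k,O) into canonical (a,b,c,O) order
    if topology == "x2":          # (i,j,k) = (a,c,b)
        L = L.transpose(0, 2, 1, 3)
    elif topology == "x3":        # (i,j,k) = (b,c,a)
        L = L.transpose(2, 0, 1, 3)
    const = np.zeros((4, 4, 4, 4))
    for s in range(4):
        const[s, s, s, s] = pi[s]
    full = model.p_inv * const + (1.0 - model.p_inv) * L
    return full.ravel()


def _pairwise_jc_distances(counts: np.ndarray) -> np.ndarray:
    """JC-corrected pairwise distances among the 4 rows, from the histogram."""
    codes = np.arange(256)
    states = np.stack([codes // 64, (codes // 16) % 4, (codes // 4) % 4, codes % 4])
    total = counts.sum()
    D = np.zeros((4, 4))
    for x in range(4):
        for y in range(x + 1, 4):
            mism = counts[states[x] != states[y]].sum()
            p = min(mism / max(total, 1), 0.70)
            D[x, y] = D[y, x] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return D


def _initial_branch_lengths(counts: np.ndarray, topology: str) -> np.ndarray:
    D = _pairwise_jc_distances(counts)
    i, j = TOPOLOGIES[topology]
    k = ({0, 1, 2} - {i, j}).pop()
    t_pair = max(D[i, j] / 2.0, 1e-4)
    t_far = max(D[k, 3] / 2.0, 1e-4)
    cross = (D[i, k] + D[j, k] + D[i, 3] + D[j, 3]) / 4.0
    t_int = max(cross - t_pair - t_far, 1e-3)
    return np.array([t_pair, t_pair, t_far, t_far, t_int])


_LOG_T_BOUNDS = (np.log(1e-7), np.log(20.0))
_LOG_R_BOUNDS = (np.log(1e-3), np.log(1e3))
_LOG_A_BOUNDS = (np.log(0.02), np.log(99.0))
_Z_BOUNDS = (-9.0, 3.0)


def _unpack(params: np.ndarray, freqs: np.ndarray) -> tuple[SubstitutionModel, np.ndarray]:
    t = np.exp(params[:5])
    rates = tuple(np.exp(params[5:10])) + (1.0,)
    alpha = float(np.exp(params[10]))
    p_inv = float(1.0 / (1.0 + np.exp(-params[11])))
    model = SubstitutionModel(rates=rates, freqs=tuple(freqs), alpha=alpha, p_inv=p_inv)
    return model, t


def fit_gtr_gamma_i(
    rows: np.ndarray,
    usable: np.ndarray,
    topology: str,
    alpha0: float = 1.0,
    p_inv0: float = 0.3,
    max_iter: int = 300,
    n_restarts: int = 2,
) -> FittedQuartetModel:
    """Fit GTR+Γ+I with free branch lengths by bounded quasi-Newton.

    Starts from the conventional initial values (α=1, p_inv=0.3, equal
    exchangeabilities, branch lengths from JC-corrected pairwise
    differences); base frequencies are held at their empirical values.
    On reported non-convergence the optimiser is restarted from jittered
    points and the best solution kept.
    """
    counts = _pattern_codes(rows, usable).astype(float)
    n_usable = int(counts.sum())
    if counts[np.setdiff1d(np.arange(256), _CONST_CODES)].sum() == 0:
        raise UninformativeQuartetError(
            "subalignment has no variable usable column; mark quartet uninformative"
        )
    # empirical base frequencies with a pseudocount to avoid zeros
    codes = np.arange(256)
    states = np.stack([codes // 64, (codes // 16) % 4, (codes // 4) % 4, codes % 4])
    base_counts = np.array([counts[states[r] == s].sum() for r in range(4) for s in range(4)])
    base_counts = base_counts.reshape(4, 4).sum(axis=0) + 1.0
    freqs = base_counts / base_counts.sum()

    obs = counts > 0
    c_obs = counts[obs]

    def neg_loglik(params: np.ndarray) -> float:
        model, t = _unpack(params, freqs)
        p = pattern_probabilities(model, t, topology)[obs]
        return -float(c_obs @ np.log(np.maximum(p, 1e-300)))

    t0 = _initial_branch_lengths(counts, topology)
    x0 = np.concatenate(
        [
            np.log(t0),
            np.zeros(5),
            [np.log(alpha0)],
            [np.log(p_inv0 / (1.0 - p_inv0))],
        ]
    )
    bounds = (
        [_LOG_T_BOUNDS] * 5 + [_LOG_R_BOUNDS] * 5 + [_LOG_A_BOUNDS, _Z_BOUNDS]
    )
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    best = None
    rng = np.random.default_rng(0)
    starts = [x0]
    for attempt, start in enumerate(starts):
        res = optimize.minimize(
            neg_loglik,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success:
            break
        if attempt == len(starts) - 1 and len(starts) - 1 < n_restarts:
            starts.append(
                np.clip(
                    x0 + rng.normal(scale=0.5, size=x0.size),
                    [b[0] for b in bounds],
                    [b[1] for b in bounds],
                )
            )
    assert best is not None
    if not best.success:
        logger.warning(
            "optimizer did not report convergence for topology %s: %s",
            topology,
            best.message,
        )
    model, t = _unpack(best.x, freqs)
    return FittedQuartetModel(
        topology=topology,
        model=model,
        branch_lengths=t,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_usable=n_usable,
    )


def log_likelihood(
    model: SubstitutionModel,
    branch_lengths: np.ndarray,
    topology: str,
    rows: np.ndarray,
    usable: np.ndarray,
) -> float:
    """Pattern-histogram log likelihood of a subalignment under a model."""
    counts = _pattern_codes(rows, usable).astype(float)
    p = pattern_probabilities(model, branch_lengths, topology)
    obs = counts > 0
    return float(counts[obs] @ np.log(np.maximum(p[obs], 1e-300)))


def pattern_class_probability(fm: FittedQuartetModel, support_class: str) -> float:
    """Probability mass of the 12 strict-synapomorphy patterns of one class."""
    p = fm.pattern_probabilities()
    return float(p[_CLASS_MASKS[support_class]].sum())


def expected_convergent_count(
    fits: dict[str, FittedQuartetModel],
    x: str,
    n_usable: int,
    mode: str = "mean",
) -> float:
    """Expected count Nc(x) of x-supporting patterns arising when x is false.

    Averages (or maximises, ``mode="max"``) the probability of the
    x-supporting pattern class under the two rival fitted topologies and
    scales by the usable column count.
    """
    rivals = [fits[y] for y in TOPOLOGY_IDS if y != x]
    if len(rivals) != 2:
        raise ValueError("need fitted models for both rival topologies")
    probs = [pattern_class_probability(fy, x) for fy in rivals]
    agg = max(probs) if mode == "max" else float(np.mean(probs))
    return n_usable * agg


def convergence_estimates(
    fits: dict[str, FittedQuartetModel], n_usable: int, mode: str = "mean"
) -> dict[str, float]:
    """Nc for all three topologies."""
    return {
        x: expected_convergent_count(fits, x, n_usable, mode=mode)
        for x in TOPOLOGY_IDS
    }
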