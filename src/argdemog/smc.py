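"""Pairwise sequentially-Markovian-coalescent HMM for demography inference.

The model treats the TMRCA of one haplotype pair along the chromosome as a
hidden Markov chain over discretized time epochs. Transitions follow the
SMC recombination-and-recoalescence kernel (see :mod:`argdemog._hmm`);
emissions are the probability of observing heterozygous sites in a
fixed-width bin given the epoch's representative TMRCA. Baum-Welch EM
re-estimates the per-epoch coalescence rates ``lambda`` (a composite
likelihood pooled over haplotype pairs and chromosomes) while the scaled
mutation and recombination parameters ``theta`` and ``rho`` stay fixed at
user-supplied values.

All rates are kept in natural units: times in generations, ``lambda`` per
generation (diploid ``Ne = 1 / (2 lambda)``), ``theta``/``rho`` per bp per
generation.

:class:`PairwiseSMC` is a scikit-learn style estimator: ``fit`` consumes a
list of :class:`ObservationSequence`, ``predict`` posterior-decodes epoch
indices, and fitted attributes carry trailing underscores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import _hmm
from .coalsim import TmrcaTrack, VariantTable

__all__ = [
    "TimeGrid",
    "HmmParams",
    "ObservationSequence",
    "make_time_grid",
    "transition_matrix",
    "emission_probs",
    "PairwiseSMC",
    "fit_em",
    "posterior_decode",
    "cross_population_rates",
    "observations_from_variants",
    "disjoint_pairs",
    "cross_pairs",
]

LAMBDA_MIN = 1e-9  # per generation (Ne = 5e8)
LAMBDA_MAX = 1e-1  # per generation (Ne = 5)
_NQ = 32  # transition quadrature points per epoch


@dataclass(frozen=True)
class TimeGrid:
    """Epoch edges in generations; first edge 0, last edge +inf.

    ``anchor_rate`` is the exponential-prior rate (per generation) the grid
    was built from; it also fixes the epoch representative times used by
    the emission model, independent of the evolving ``lambda`` estimates.
    """

    boundaries: np.ndarray
    anchor_rate: float

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if len(b) < 3:
            raise ValueError("need at least two epochs")
        if b[0] != 0.0 or not np.isinf(b[-1]):
            raise ValueError("grid must start at 0 and end at +inf")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any(b[1:-1] <= 0):
            raise ValueError("interior edges must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.boundaries) - 1

    @property
    def representative_times(self) -> np.ndarray:
        """Conditional mean of the anchor exponential prior per epoch."""
        a = self.anchor_rate
        lo = self.boundaries[:-1]
        hi = self.boundaries[1:]
        out = np.empty(self.n_epochs)
        for i, (x, y) in enumerate(zip(lo, hi)):
            if np.isinf(y):
                out[i] = x + 1.0 / a
            else:
                d = y - x
                out[i] = x + 1.0 / a - d / np.expm1(a * d)
        return out

    def epoch_of(self, times) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.boundaries, np.asarray(times, dtype=float), side="right") - 1,
            0,
            self.n_epochs - 1,
        )


def make_time_grid(n_epochs: int, lambda_scale: float) -> TimeGrid:
    """Epoch edges at quantiles of an Exp(lambda_scale) coalescence prior."""
    if n_epochs < 2:
        raise ValueError("need n_epochs >= 2")
    if lambda_scale <= 0:
        raise ValueError("lambda_scale must be positive")
    q = np.arange(1, n_epochs) / n_epochs
    edges = -np.log1p(-q) / lambda_scale
    return TimeGrid(np.concatenate([[0.0], edges, [np.inf]]), anchor_rate=lambda_scale)


@dataclass(frozen=True)
class HmmParams:
    """Parameters of the pairwise SMC HMM (natural per-generation units)."""

    grid: TimeGrid
    lambdas: np.ndarray  # per-epoch pairwise coalescence rate per generation
    rho: float  # per-bp per-generation recombination rate
    theta: float  # per-bp per-generation mutation rate

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if len(lam) != self.grid.n_epochs:
            raise ValueError("lambdas length must match grid epochs")
        if np.any(lam <= 0):
            raise ValueError("lambdas must be positive")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def ne(self) -> np.ndarray:
        """Diploid effective sizes 1 / (2 lambda) per epoch."""
        return 1.0 / (2.0 * self.lambdas)

    def prior(self) -> np.ndarray:
        return _hmm.prior_mass(self.grid.boundaries, self.lambdas)


@dataclass
class ObservationSequence:
    """Binned het/called counts along one chromosome for one haplotype pair."""

    called: np.ndarray  # callable sites per bin
    het: np.ndarray  # heterozygous sites per bin
    bin_width: int
    pair: tuple = (0, 1)
    chrom: str = "chr1"

    def __post_init__(self):
        self.called = np.asarray(self.called, dtype=np.int64)
        self.het = np.asarray(self.het, dtype=np.int64)
        if self.called.shape != self.het.shape:
            raise ValueError("called and het must have the same shape")
        if np.any(self.het > self.called) or np.any(self.called > self.bin_width):
            raise ValueError("need het <= called <= bin_width per bin")
        if np.any(self.het < 0) or np.any(self.called < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.called)

    @property
    def het_rate(self) -> float:
        tot = self.called.sum()
        return float(self.het.sum() / tot) if tot else 0.0


def observations_from_variants(variants: VariantTable, pairs, mask=None,
                               bin_width: int = 100) -> list:
    """Binned observation sequences for haplotype ``pairs`` of one chromosome.

    ``mask`` is an optional set of (start, end) intervals to exclude;
    called sites per bin are the unmasked base pairs.
    """
    from . import intervals as iv

    L = int(variants.chrom_length)
    n_bins = int(np.ceil(L / bin_width))
    called = np.full(n_bins, bin_width, dtype=np.int64)
    called[-1] = L - (n_bins - 1) * bin_width
    keep_site = np.ones(variants.n_sites, dtype=bool)
    if mask is not None and len(np.atleast_2d(np.asarray(mask))) and np.size(mask):
        m = iv.normalize(mask)
        for s, e in m:
            s = int(max(0, np.floor(s)))
            e = int(min(L, np.ceil(e)))
            if s >= e:
                continue
            b0, b1 = s // bin_width, (e - 1) // bin_width
            if b0 == b1:
                called[b0] -= e - s
            else:
                called[b0] -= (b0 + 1) * bin_width - s
                called[b1] -= e - b1 * bin_width
                called[b0 + 1 : b1] -= bin_width
        pos = variants.positions
        idx = np.searchsorted(m[:, 0], pos, side="right") - 1
        inside = (idx >= 0) & (pos < m[np.clip(idx, 0, None), 1])
        keep_site = ~inside
    called = np.clip(called, 0, None)
    out = []
    for a, b in pairs:
        diff = (variants.genotypes[:, a] != variants.genotypes[:, b]) & keep_site
        het = np.bincount(
            (variants.positions[diff] // bin_width).astype(np.int64), minlength=n_bins
        )[:n_bins]
        het = np.minimum(het, called)
        out.append(ObservationSequence(called, het, bin_width, pair=(int(a), int(b))))
    return out


def disjoint_pairs(haplotypes) -> list:
    """Non-overlapping consecutive pairs (2i, 2i+1) of a haplotype list."""
    h = list(haplotypes)
    return [(h[2 * i], h[2 * i + 1]) for i in range(len(h) // 2)]


def cross_pairs(haps_a, haps_b, n_pairs=None) -> list:
    """Index-matched pairs across two haplotype lists."""
    m = min(len(haps_a), len(haps_b))
    if n_pairs is not None:
        m = min(m, n_pairs)
    return [(haps_a[i], haps_b[i]) for i in range(m)]


# ---------------------------------------------------------------------------
# Model pieces
# ---------------------------------------------------------------------------


def transition_matrix(params: HmmParams, bin_width: int = 1,
                      kernel: str = "smc") -> np.ndarray:
    """Row-stochastic epoch transition matrix over one bin.

    ``kernel="smc"`` (default) uses the SMC recombination density;
    ``kernel="smc_prime"`` adds the self-coalescence correction (the
    floating lineage may re-coalesce onto the branch it detached from,
    leaving the TMRCA unchanged), for sensitivity checks.
    """
    if kernel == "smc":
        G = _hmm.generator_perbp(params.grid.boundaries, params.lambdas, params.rho, _NQ)
        P1 = expm(bin_width * G)
    elif kernel == "smc_prime":
        P1 = _transition_perbp_smc_prime(params.grid.boundaries, params.lambdas,
                                         params.rho, _NQ)
        if bin_width > 1:
            P1 = np.linalg.matrix_power(P1, bin_width)
    else:
        raise ValueError(f"unknown transition kernel {kernel!r}")
    rows = P1.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        warnings.warn("transition rows renormalized (numerical underflow)")
        P1 = P1 / rows[:, None]
    return P1


def _transition_perbp_smc_prime(T, lam, r, nq, nu: int = 64) -> np.ndarray:
    """SMC' per-bp transition matrix by quadrature over detach heights.

    Below the current TMRCA ``t`` the floating lineage faces two standing
    lineages (hazard ``2 lambda``); half of those coalescences rejoin its
    own branch and leave the state unchanged. Above ``t`` a single
    ancestral lineage remains. Slower numpy path; used for sensitivity
    analyses only.
    """
    E = len(lam)
    Lam, S = _hmm.prior_survival(np.asarray(T, dtype=float), np.asarray(lam, dtype=float))
    Tf = np.asarray(T, dtype=float)

    def Lam_at(x):
        k = np.clip(np.searchsorted(Tf, x, side="right") - 1, 0, E - 1)
        return Lam[k] + lam[k] * (x - Tf[k])

    P = np.zeros((E, E))
    for i in range(E):
        for m in range(nq):
            v = (m + 0.5) / nq
            s_target = max(S[i] - v * (S[i] - S[i + 1]), 1e-300)
            t = Tf[i] + (-np.log(s_target) - Lam[i]) / lam[i]
            if not t > Tf[i]:
                t = Tf[i] * (1 + 1e-9) + 1e-9
            Lam_t = Lam_at(t)
            stay = np.exp(-2.0 * r * t)
            wr = 1.0 - stay
            row = np.zeros(E)
            row[i] += stay
            if wr > 0:
                u = (np.arange(nu) + 0.5) / nu * t
                Lam_u = Lam_at(u)
                # invisible self-coalescence mass below t
                row[i] += wr * np.mean(0.5 * (1.0 - np.exp(-2.0 * (Lam_t - Lam_u))))
                for j in range(E):
                    a = Tf[j]
                    b = min(Tf[j + 1], t)
                    mass = np.zeros(nu)
                    if b > a:  # visible re-coalescence below t
                        aa = np.maximum(a, u)
                        ok = aa < b
                        mass[ok] += 0.5 * (
                            np.exp(-2.0 * (Lam_at(aa[ok]) - Lam_u[ok]))
                            - np.exp(-2.0 * (Lam_at(b) - Lam_u[ok]))
                        )
                    if Tf[j + 1] > t:  # re-coalescence above t
                        lo = max(Tf[j], t)
                        hi = Tf[j + 1]
                        seg = np.exp(-(Lam_at(lo) - Lam_t)) - (
                            0.0 if np.isinf(hi) else np.exp(-(Lam_at(hi) - Lam_t))
                        )
                        mass += np.exp(-2.0 * (Lam_t - Lam_u)) * seg
                    row[j] += wr * float(np.mean(mass))
            P[i] += row / nq
        P[i] /= P[i].sum()
    return P


def _emission_lookup(params: HmmParams, bin_width: int, emission: str = "bernoulli"):
    """(bin_width+1, E) emission tables for het-absent / het-present bins."""
    tt = params.grid.representative_times
    p = -np.expm1(-2.0 * tt * params.theta)  # per-site het probability
    called = np.arange(bin_width + 1)[:, None]
    log_q = np.log1p(-p)[None, :]
    no_het = np.exp(called * log_q)
    some_het = -np.expm1(called * log_q)
    # guard: a zero-called bin is uninformative
    some_het[0, :] = 1.0
    if emission == "bernoulli":
        return no_het, some_het
    if emission == "binomial":
        return no_het, None  # binomial path computes per-bin rows directly
    raise ValueError(f"unknown emission model {emission!r}")


def emission_probs(params: HmmParams, called_sites: int, het_count: int,
                   emission: str = "bernoulli") -> np.ndarray:
    """Per-epoch likelihood of one observation bin."""
    if het_count > called_sites:
        raise ValueError("het_count cannot exceed called_sites")
    if called_sites == 0:
        return np.ones(params.grid.n_epochs)
    tt = params.grid.representative_times
    p = -np.expm1(-2.0 * tt * params.theta)
    if emission == "bernoulli":
        if het_count >= 1:
            return -np.expm1(called_sites * np.log1p(-p))
        return np.exp(called_sites * np.log1p(-p))
    if emission == "binomial":
        from scipy.special import gammaln

        k, n = het_count, called_sites
        logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return np.exp(logc + k * np.log(p) + (n - k) * np.log1p(-p))
    raise ValueError(f"unknown emission model {emission!r}")


def _emis_matrix(obs: ObservationSequence, params: HmmParams, emission: str):
    no_het, some_het = _emission_lookup(params, obs.bin_width, emission)
    if emission == "bernoulli":
        het_flag = obs.het > 0
        emis = np.where(het_flag[:, None], some_het[obs.called], no_het[obs.called])
        return np.ascontiguousarray(emis)
    # binomial
    tt = params.grid.representative_times
    p = -np.expm1(-2.0 * tt * params.theta)
    from scipy.special import gammaln

    k = obs.het[:, None].astype(float)
    n = obs.called[:, None].astype(float)
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        le = logc + k * np.log(p)[None, :] + (n - k) * np.log1p(-p)[None, :]
    emis = np.exp(le)
    emis[obs.called == 0] = 1.0
    return np.ascontiguousarray(emis)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class PairwiseSMC(BaseEstimator):
    """Pairwise SMC HMM estimator of piecewise-constant coalescence rates.

    Parameters
    ----------
    mu : per-bp per-generation mutation rate (fixed during EM).
    rho : per-bp per-generation recombination rate (fixed during EM).
    n_epochs : number of discretized time epochs.
    bin_width : observation bin width in bp.
    n_iter : Baum-Welch iterations.
    ne_anchor : diploid size anchoring the time grid; if None, estimated
        from the mean heterozygosity of the data as ``het / (4 mu)``.
    grid : optional explicit TimeGrid (overrides n_epochs/ne_anchor); use
        one shared grid when rate profiles must be comparable across fits.
    emission : "bernoulli" (het presence per bin; default) or "binomial"
        (het counts).
    init_lambdas : optional initial per-epoch rates.

    Attributes (after fit)
    ----------
    grid_ : TimeGrid used.
    lambdas_ : per-epoch coalescence rates (per generation).
    ne_ : diploid effective sizes per epoch.
    log_likelihood_path_ : composite log-likelihood per EM iteration.
    params_ : fitted HmmParams.
    """

    def __init__(self, mu=4.6e-9, rho=4.6e-10, n_epochs=32, bin_width=100,
                 n_iter=15, ne_anchor=None, grid=None, emission="bernoulli",
                 init_lambdas=None, m_step_maxiter=25):
        self.mu = mu
        self.rho = rho
        self.n_epochs = n_epochs
        self.bin_width = bin_width
        self.n_iter = n_iter
        self.ne_anchor = ne_anchor
        self.grid = grid
        self.emission = emission
        self.init_lambdas = init_lambdas
        self.m_step_maxiter = m_step_maxiter

    # -- internals ---------------------------------------------------------

    def _resolve_grid(self, X) -> TimeGrid:
        if self.grid is not None:
            return self.grid
        if self.ne_anchor is not None:
            ne0 = float(self.ne_anchor)
        else:
            tot_called = sum(int(o.called.sum()) for o in X)
            tot_het = sum(int(o.het.sum()) for o in X)
            if tot_called == 0:
                raise ValueError("all input bins are masked; nothing to fit")
            het_rate = max(tot_het / tot_called, 1e-8)
            ne0 = het_rate / (4.0 * self.mu)
        return make_time_grid(self.n_epochs, 1.0 / (2.0 * ne0))

    def _m_step(self, lam, C, n0, T):
        lo, hi = np.log(LAMBDA_MIN), np.log(LAMBDA_MAX)

        def negq(loglam):
            lam_ = np.exp(loglam)
            G = _hmm.generator_perbp(T, lam_, self.rho, _NQ)
            P = expm(self.bin_width * G)
            pi = _hmm.prior_mass(T, lam_)
            val = -(np.sum(n0 * np.log(pi + 1e-300)) + np.sum(C * np.log(P + 1e-300)))
            return val if np.isfinite(val) else 1e15

        x0 = np.log(lam)
        q0 = negq(x0)
        res = minimize(negq, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * len(lam),
                       options={"maxiter": self.m_step_maxiter})
        if res.fun <= q0:  # generalized EM: accept only improvements
            lam_new = np.exp(res.x)
        else:
            lam_new = lam
        if np.any(lam_new <= LAMBDA_MIN * 1.0001) or np.any(lam_new >= LAMBDA_MAX * 0.9999):
            warnings.warn("coalescence rates at clamp boundary")
        return lam_new

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit per-epoch coalescence rates to observation sequences ``X``."""
        if not X:
            raise ValueError("need at least one observation sequence")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        X = list(X)
        if sum(int(o.called.sum()) for o in X) == 0:
            raise ValueError("all input bins are masked; nothing to fit")
        grid = self._resolve_grid(X)
        T = grid.boundaries
        if self.init_lambdas is not None:
            lam = np.asarray(self.init_lambdas, dtype=float).copy()
        else:
            lam = np.full(grid.n_epochs, grid.anchor_rate)
        lam = np.clip(lam, LAMBDA_MIN, LAMBDA_MAX)
        path = []
        for _ in range(self.n_iter):
            params = HmmParams(grid, lam, self.rho, self.mu)
            P = transition_matrix(params, self.bin_width)
            pi = params.prior()
            loglik = 0.0
            C = np.zeros((grid.n_epochs, grid.n_epochs))
            n0 = np.zeros(grid.n_epochs)
            for obs in X:
                if obs.n_bins == 0:
                    continue
                emis = _emis_matrix(obs, params, self.emission)
                ll, g0, xi = _hmm.fb_em(emis, P, pi)
                loglik += ll
                n0 += g0
                C += xi
            path.append(loglik)
            lam = self._m_step(lam, C, n0, T)
        self.grid_ = grid
        self.lambdas_ = lam
        self.ne_ = 1.0 / (2.0 * lam)
        self.log_likelihood_path_ = np.asarray(path)
        self.params_ = HmmParams(grid, lam, self.rho, self.mu)
        self.n_iter_ = self.n_iter
        return self

    def score(self, X, y=None) -> float:
        """Composite log-likelihood of ``X`` under the fitted parameters."""
        params = self.params_
        P = transition_matrix(params, self.bin_width)
        pi = params.prior()
        tot = 0.0
        for obs in X:
            emis = _emis_matrix(obs, params, self.emission)
            ll, _ = _hmm.fb_posterior(emis, P, pi)
            tot += ll
        return tot

    def predict(self, X) -> list:
        """Posterior-decoded epoch index per bin for each sequence in X."""
        params = self.params_
        P = transition_matrix(params, self.bin_width)
        pi = params.prior()
        out = []
        for obs in X:
            emis = _emis_matrix(obs, params, self.emission)
            _, gamma = _hmm.fb_posterior(emis, P, pi)
            out.append(np.argmax(gamma, axis=1))  # ties -> lowest epoch
        return out

    def predict_track(self, obs: ObservationSequence) -> TmrcaTrack:
        """Decode one sequence to a TmrcaTrack of epoch indices."""
        idx = self.predict([obs])[0]
        starts = np.arange(len(idx), dtype=float) * obs.bin_width
        ends = starts + obs.bin_width
        return TmrcaTrack(starts, ends, idx.astype(float), "epoch-index").merged()


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_em(obs, init: HmmParams, n_iter: int, emission: str = "bernoulli",
           bin_width: int | None = None, m_step_maxiter: int = 25):
    """Baum-Welch on observation sequences from initial parameters.

    Returns (fitted HmmParams, per-iteration log-likelihood array).
    """
    bw = bin_width if bin_width is not None else (obs[0].bin_width if obs else 100)
    est = PairwiseSMC(
        mu=init.theta, rho=init.rho, bin_width=bw, n_iter=n_iter,
        grid=init.grid, emission=emission, init_lambdas=init.lambdas,
        m_step_maxiter=m_step_maxiter,
    ).fit(obs)
    return est.params_, est.log_likelihood_path_


def posterior_decode(obs: ObservationSequence, params: HmmParams,
                     emission: str = "bernoulli") -> TmrcaTrack:
    """Per-bin argmax posterior epoch indices as a TmrcaTrack."""
    est = PairwiseSMC(mu=params.theta, rho=params.rho, bin_width=obs.bin_width,
                      grid=params.grid, emission=emission)
    est.params_ = params
    return est.predict_track(obs)


def cross_population_rates(variant_tables, pop_a: str, pop_b: str, grid=None,
                           n_pairs: int = 4, mask=None, bin_width: int = 100,
                           mu: float = 4.6e-9, rho: float = 4.6e-10,
                           n_iter: int = 15, rng=None):
    """Within- and cross-population coalescence-rate profiles on one grid.

    ``variant_tables`` is a list of per-chromosome :class:`VariantTable`
    objects (treated as independent chromosomes of one sample). Returns a
    dict with keys ``"AA"``, ``"BB"``, ``"AB"`` holding
    :class:`~argdemog.metrics.CoalescenceRateProfile` objects that share
    one time grid, plus ``"grid"``.
    """
    from .metrics import CoalescenceRateProfile

    if isinstance(variant_tables, VariantTable):
        variant_tables = [variant_tables]
    vt0 = variant_tables[0]
    haps_a = list(vt0.samples_of(pop_a))
    haps_b = list(vt0.samples_of(pop_b))
    if len(haps_a) < 2 or len(haps_b) < 2:
        raise ValueError("need at least two haplotypes per population")
    pairs = {
        "AA": disjoint_pairs(haps_a)[:n_pairs],
        "BB": disjoint_pairs(haps_b)[:n_pairs],
        "AB": cross_pairs(haps_a, haps_b, n_pairs),
    }
    obs_sets = {
        key: [o for vt in variant_tables
              for o in observations_from_variants(vt, pp, mask=mask, bin_width=bin_width)]
        for key, pp in pairs.items()
    }
    if grid is None:
        pooled = [o for obs in obs_sets.values() for o in obs]
        grid = PairwiseSMC(mu=mu, bin_width=bin_width)._resolve_grid(pooled)
    profiles = {}
    for key, obs in obs_sets.items():
        est = PairwiseSMC(mu=mu, rho=rho, bin_width=bin_width, n_iter=n_iter,
                          grid=grid).fit(obs)
        label = {"AA": pop_a, "BB": pop_b, "AB": f"{pop_a}-{pop_b}"}[key]
        profiles[key] = CoalescenceRateProfile(grid=grid, rates=est.lambdas_, label=label)
    profiles["grid"] = grid
    return profiles
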