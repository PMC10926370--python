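"""Global ancestry estimation under the K-population admixture model.

Model: individual i has ancestry fractions q_i on the K-simplex;
population k has alt-allele frequency f_kj at site j.  The two allele
copies of genotype g_ij are i.i.d. Bernoulli with success probability
p_ij = sum_k q_ik f_kj, giving the binomial log-likelihood

    l(Q, F) = sum_{ij called} [ g_ij log p_ij + (2 - g_ij) log(1 - p_ij) ].

Fitting is plain EM over (Q, F) — provably monotone in l — with
frequencies clipped to [eps, 1-eps] so fixed differences cannot drive
log(0).  Two modes:

* unsupervised (:class:`AdmixtureEM.fit`): Q and F free, K=2 by
  default, seeded Dirichlet/perturbed-empirical initialisation;
* supervised projection (:meth:`AdmixtureEM.predict_proba` or
  :func:`project_ancestry`): F held fixed (e.g. empirical frequencies
  of classified pure reference panels) and each query individual's q
  maximised independently.

Label switching is resolved by correlating each fitted frequency row
with empirical alt frequencies of species-labelled anchor samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .variants import VariantTable

log = logging.getLogger(__name__)

EPS = 1e-6
ARMIGERA = "armigera"
ZEA = "zea"


def _as_matrix(G) -> np.ndarray:
    g = np.asarray(G, dtype=float)
    if g.ndim != 2:
        raise ValueError("G must be a 2-D (samples x sites) dosage matrix")
    valid = ~np.isnan(g)
    if not np.isin(g[valid], (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1, 2 or NaN")
    return g


def loglikelihood(G, Q, F) -> float:
    """Binomial admixture log-likelihood; missing genotypes contribute 0."""
    g = _as_matrix(G)
    Q = np.asarray(Q, float)
    F = np.asarray(F, float)
    if Q.shape[0] != g.shape[0] or F.shape[1] != g.shape[1] \
            or Q.shape[1] != F.shape[0]:
        raise ValueError("dimension mismatch between G, Q, F")
    p = Q @ F
    valid = ~np.isnan(g)
    gv = np.where(valid, g, 0.0)
    terms = gv * np.log(p) + (2.0 - gv) * np.log1p(-p)
    return float(terms[valid].sum())


def em_step(G, Q, F) -> tuple[np.ndarray, np.ndarray]:
    """One EM update of (Q, F); guaranteed not to decrease the likelihood.

    q'_ik averages, over individual i's called sites, the expected
    number of its two allele copies attributed to population k; f'_kj
    is the expected alt fraction of copies attributed to population k
    at site j.  Rows of Q' are renormalised; F' is clipped to
    [EPS, 1-EPS].
    """
    g = _as_matrix(G)
    Q = np.asarray(Q, float)
    F = np.asarray(F, float)
    valid = ~np.isnan(g)
    gv = np.where(valid, g, 0.0)
    gv_c = np.where(valid, 2.0 - gv, 0.0)
    p = Q @ F
    A = gv / p            # zeroed where missing via gv
    B = gv_c / (1.0 - p)
    j_called = valid.sum(axis=1).astype(float)

    Qn = np.empty_like(Q)
    Fn = np.empty_like(F)
    for k in range(Q.shape[1]):
        alt_resp = Q[:, k:k + 1] * F[k] * A        # E[# alt copies from pop k]
        ref_resp = Q[:, k:k + 1] * (1.0 - F[k]) * B
        Qn[:, k] = (alt_resp + ref_resp).sum(axis=1) / (2.0 * j_called)
        a_kj = alt_resp.sum(axis=0)
        b_kj = ref_resp.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Fn[k] = a_kj / (a_kj + b_kj)
        Fn[k, a_kj + b_kj == 0] = F[k, a_kj + b_kj == 0]
    Qn /= Qn.sum(axis=1, keepdims=True)
    return Qn, np.clip(Fn, EPS, 1.0 - EPS)


def _project_q(G, F, tol: float, max_iter: int) -> np.ndarray:
    """EM on Q only, F fixed; rows are independent maximisations."""
    g = _as_matrix(G)
    n, k = g.shape[0], F.shape[0]
    Q = np.full((n, k), 1.0 / k)
    valid = ~np.isnan(g)
    gv = np.where(valid, g, 0.0)
    gv_c = np.where(valid, 2.0 - gv, 0.0)
    j_called = valid.sum(axis=1).astype(float)
    dead = j_called == 0
    j_safe = np.where(dead, 1.0, j_called)
    for _ in range(max_iter):
        p = Q @ F
        with np.errstate(invalid="ignore"):
            A = gv / p
            B = gv_c / (1.0 - p)
        Qn = np.empty_like(Q)
        for kk in range(k):
            Qn[:, kk] = (Q[:, kk:kk + 1] * (F[kk] * A + (1.0 - F[kk]) * B)
                         ).sum(axis=1) / (2.0 * j_safe)
        Qn /= np.maximum(Qn.sum(axis=1, keepdims=True), 1e-300)
        Qn[dead] = 1.0 / k
        delta = np.abs(Qn - Q).max()
        Q = Qn
        if delta < tol:
            break
    Q[dead] = np.nan
    return Q


def panel_frequencies(G_armigera, G_zea, eps: float = EPS) -> np.ndarray:
    """Empirical alt-allele frequency matrix F (2 x J) from classified
    pure reference panels; row 0 = armigera, row 1 = zea; clipped."""
    fa = np.nanmean(_as_matrix(G_armigera), axis=0) / 2.0
    fz = np.nanmean(_as_matrix(G_zea), axis=0) / 2.0
    return np.clip(np.vstack([fa, fz]), eps, 1.0 - eps)


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture estimator (EM), K=2 by default.

    Parameters
    ----------
    n_populations : int, default 2
    tol : float, default 1e-6
        Stop when the log-likelihood improves by less than this.
    max_iter : int, default 2000
    random_state : int or None
        Seed for the Dirichlet/perturbation initialisation.  Identical
        seed and data give bit-identical results.
    projection_tol : float, default 1e-8
        Per-q convergence tolerance used by :meth:`predict_proba`.

    Attributes (after :meth:`fit`)
    ------------------------------
    Q_ : (n_samples, K) ancestry fractions, rows on the simplex
    F_ : (K, n_sites) fitted population allele frequencies (clipped)
    loglik_trace_ : per-iteration log-likelihood (non-decreasing)
    n_iter_, converged_ : fit diagnostics
    population_labels_ : list mapping Q columns to species names
    """

    def __init__(self, n_populations: int = 2, tol: float = 1e-6,
                 max_iter: int = 2000, random_state: int | None = None,
                 projection_tol: float = 1e-8):
        self.n_populations = n_populations
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.projection_tol = projection_tol

    # -- unsupervised fit --------------------------------------------------
    def fit(self, G, sample_labels=None) -> "AdmixtureEM":
        """Unsupervised EM fit of Q and F.

        ``sample_labels`` optionally gives a putative species label
        ('armigera'/'zea', anything else ignored) per sample, used only
        to anchor the arbitrary column order to species names.
        """
        g = _as_matrix(G)
        n, j = g.shape
        k = self.n_populations
        if n < k:
            raise ValueError(f"need at least {k} individuals")
        if (np.isnan(g).all(axis=1)).any():
            raise ValueError("every individual needs >= 1 called genotype")
        rng = np.random.default_rng(self.random_state)
        Q = rng.dirichlet(np.ones(k), size=n)
        emp = np.nanmean(g, axis=0) / 2.0
        F = np.clip(emp + rng.normal(0.0, 0.1, size=(k, j)), EPS, 1.0 - EPS)

        trace = [loglikelihood(g, Q, F)]
        converged = False
        for _ in range(self.max_iter):
            Q, F = em_step(g, Q, F)
            trace.append(loglikelihood(g, Q, F))
            if abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break
        self.Q_, self.F_ = Q, F
        self.loglik_trace_ = np.array(trace)
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.population_labels_ = self._align_labels(g, sample_labels)
        return self

    def _align_labels(self, g, sample_labels) -> list[str]:
        k = self.n_populations
        if sample_labels is None:
            sample_labels = [None] * g.shape[0]
        anchors = {}
        for species in (ARMIGERA, ZEA):
            rows = [i for i, lab in enumerate(sample_labels) if lab == species]
            if rows:
                anchors[species] = np.nanmean(g[rows], axis=0) / 2.0
        if len(anchors) < 1 or k != 2:
            warnings.warn("no anchor samples: columns labelled pop1/pop2",
                          stacklevel=2)
            order = np.argsort(-self.Q_[0])  # deterministic: first sample's q
            self.Q_ = self.Q_[:, order]
            self.F_ = self.F_[order]
            return [f"pop{i + 1}" for i in range(k)]
        # pick the column assignment maximising summed correlation to anchors
        def corr(a, b):
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                return 0.0
            return float(np.corrcoef(a[ok], b[ok])[0, 1])

        best, best_score = None, -np.inf
        for perm in ([0, 1], [1, 0]):
            score = sum(
                corr(self.F_[perm[s]], anchors[sp])
                for s, sp in enumerate((ARMIGERA, ZEA)) if sp in anchors
            )
            if score > best_score:
                best, best_score = perm, score
        self.Q_ = self.Q_[:, best]
        self.F_ = self.F_[best]
        return [ARMIGERA, ZEA]

    # -- supervised projection --------------------------------------------
    def predict_proba(self, G) -> np.ndarray:
        """Project query samples onto the fitted F (q free, F fixed).

        Individuals with zero called genotypes get NaN rows.
        """
        return _project_q(G, self.F_, self.projection_tol, self.max_iter)

    def estimate(self, samples: list[str]) -> pd.DataFrame:
        """Fitted Q as a tidy frame with species-named columns."""
        cols = [f"q_{lab}" for lab in self.population_labels_]
        out = pd.DataFrame(self.Q_, columns=cols)
        out.insert(0, "sample_id", samples)
        return out


def fit_unsupervised(G, K: int = 2, seed: int | None = None,
                     tol: float = 1e-6, max_iter: int = 2000,
                     sample_labels=None) -> AdmixtureEM:
    """Functional wrapper over :class:`AdmixtureEM.fit`."""
    return AdmixtureEM(n_populations=K, tol=tol, max_iter=max_iter,
                       random_state=seed).fit(G, sample_labels=sample_labels)


def fit_supervised(G_query, F_ref, tol: float = 1e-8,
                   max_iter: int = 5000) -> np.ndarray:
    """Per-individual ML ancestry with reference frequencies fixed.

    ``F_ref`` is a (2 x J) clipped frequency matrix, row 0 armigera,
    row 1 zea (see :func:`panel_frequencies`).  Returns (n, 2) q.
    """
    F = np.asarray(F_ref, float)
    if ((F <= 0) | (F >= 1)).any():
        raise ValueError("F_ref must be clipped to the open interval (0, 1)")
    return _project_q(G_query, F, tol, max_iter)


def classify_purity(Q: np.ndarray, population_labels: list[str],
                    samples: list[str], threshold: float = 0.99
                    ) -> tuple[list[str], list[str], list[str]]:
    """Split samples into (pure armigera, pure zea, hybrid) ids.

    A sample is pure-S iff its ancestry fraction for species S is
    >= ``threshold``; everything else is hybrid/admixed.
    """
    labels = list(population_labels)
    ia, iz = labels.index(ARMIGERA), labels.index(ZEA)
    pure_a, pure_z, hybrid = [], [], []
    for s, q in zip(samples, np.asarray(Q, float)):
        if q[ia] >= threshold:
            pure_a.append(s)
        elif q[iz] >= threshold:
            pure_z.append(s)
        else:
            hybrid.append(s)
    return pure_a, pure_z, hybrid
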