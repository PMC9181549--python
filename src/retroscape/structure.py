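"""Population structure from dominant markers: admixture model fitting and
Evanno ΔK model selection.

The model: accession i draws, independently at each locus l and for each of
its two haplotypes, a subpopulation of origin from its admixture vector Q_i;
a haplotype from subpopulation k carries the band-presence allele with
frequency f_kl.  A dominant marker shows the band unless both haplotypes
carry the absence allele, so with a_il = Σ_k Q_ik (1 − f_kl),

    log L = Σ_i Σ_l [ y_il · log(1 − a_il²) + (1 − y_il) · log(a_il²) ].

Q and f are estimated by EM (haplotype ancestries and hidden alleles are the
latent variables), which increases the log-likelihood monotonically.  The
number of subpopulations K is chosen with the ΔK statistic: the
second-order rate of change of L(K) across K, normalised by the
between-replicate standard deviation, peaks at the uppermost level of
genuine structure.

The API follows the model/results pattern: ``DominantAdmixture`` is built
from a band matrix, ``fit`` returns an ``AdmixtureResults`` with estimates,
per-replicate log-likelihoods and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_EPS = 1e-9


@dataclass
class AncestryEstimate:
    """One EM replicate's estimates."""

    Q: np.ndarray             # (n_accessions, K)
    allele_freqs: np.ndarray  # (K, n_loci)
    log_likelihood: float
    K_pop: int
    seed: int
    n_iter: int = 0
    converged: bool = True


class AdmixtureResults:
    """Fit results across replicates (best replicate exposed as the
    estimate)."""

    def __init__(self, model: "DominantAdmixture",
                 replicates: list[AncestryEstimate]):
        self.model = model
        self.replicates = replicates
        best = max(replicates, key=lambda r: r.log_likelihood)
        self.best = best
        self.K_pop = best.K_pop
        self.Q = best.Q
        self.allele_freqs = best.allele_freqs
        self.log_likelihood = best.log_likelihood

    @property
    def log_likelihoods(self) -> list[float]:
        return [r.log_likelihood for r in self.replicates]

    def q_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K_pop)]
        return pd.DataFrame(self.Q, index=self.model.accessions, columns=cols)

    def mean_q(self) -> pd.DataFrame:
        """Replicate-averaged Q after aligning columns (label switching)."""
        aligned = [align_columns(r.Q, self.Q) for r in self.replicates]
        cols = [f"Q{k + 1}" for k in range(self.K_pop)]
        return pd.DataFrame(np.mean(aligned, axis=0),
                            index=self.model.accessions, columns=cols)

    def assignments(self, threshold: float = 0.8) -> list[str]:
        return classify_admixed(self.Q, threshold=threshold)

    def summary(self, threshold: float = 0.8) -> str:
        lines = [
            "Dominant-marker admixture model",
            "=" * 46,
            f"accessions: {len(self.model.accessions)}    "
            f"loci: {self.model.n_loci}    K: {self.K_pop}",
            f"replicates: {len(self.replicates)}    "
            f"best log-likelihood: {self.log_likelihood:.3f}",
            f"replicate log-likelihoods: "
            + ", ".join(f"{v:.2f}" for v in self.log_likelihoods),
            "-" * 46,
        ]
        q = self.q_frame()
        labels = self.assignments(threshold)
        q = q.assign(assignment=labels)
        lines.append(q.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


class DominantAdmixture:
    """Admixture model for a binary (accession × locus) dominant-marker
    matrix."""

    def __init__(self, matrix: pd.DataFrame | np.ndarray):
        if isinstance(matrix, pd.DataFrame):
            self.accessions = list(matrix.index)
            y = matrix.to_numpy()
        else:
            y = np.asarray(matrix)
            self.accessions = [f"acc{i:02d}" for i in range(y.shape[0])]
        if not np.isin(y, [0, 1]).all():
            raise ValueError("matrix must be binary 0/1")
        self.y = y.astype(float)
        self.n_accessions, self.n_loci = y.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DominantAdmixture":
        return cls(df)

    # -- core EM ---------------------------------------------------------
    def _loglik(self, Q: np.ndarray, f: np.ndarray) -> float:
        a = np.clip(Q @ (1.0 - f), _EPS, 1.0 - _EPS)
        return float(np.sum(self.y * np.log1p(-(a ** 2))
                            + (1.0 - self.y) * 2.0 * np.log(a)))

    def _em(self, K: int, rng: np.random.Generator, max_iter: int,
            tol: float, seed_label: int) -> AncestryEstimate:
        n, L = self.n_accessions, self.n_loci
        y = self.y                                    # (n, L)
        Q = rng.dirichlet(np.ones(K), size=n)         # (n, K)
        f = rng.uniform(0.1, 0.9, size=(K, L))        # (K, L)
        prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            one_minus_f = 1.0 - f                     # (K, L)
            a = np.clip(Q @ one_minus_f, _EPS, 1.0 - _EPS)   # (n, L)
            # per-haplotype posterior over (subpop, allele):
            #   presence allele: only possible when y=1
            #   absence allele:  weight differs by y
            Qk = Q[:, :, None]                        # (n, K, 1)
            u_plus = Qk * f[None, :, :]               # (n, K, L)
            u_minus = Qk * one_minus_f[None, :, :]
            y3 = y[:, None, :] == 1.0
            # y=1: P(k,+|y) = Qf/(1-a²) [per haplotype], P(k,−|y) = Q(1−f)/(1+a)
            # y=0: P(k,+|y) = 0,                        P(k,−|y) = Q(1−f)/a
            w_plus = np.where(y3, u_plus / ((1.0 - a ** 2)[:, None, :]), 0.0)
            w_minus = np.where(y3,
                               u_minus / (1.0 + a)[:, None, :],
                               u_minus / a[:, None, :])
            # M-step
            resp = w_plus + w_minus                   # (n, K, L) haplotype resp.
            Q = resp.sum(axis=2)
            Q /= Q.sum(axis=1, keepdims=True)
            num = w_plus.sum(axis=0)                  # (K, L)
            den = resp.sum(axis=0)
            f = np.clip(num / np.maximum(den, _EPS), 0.0, 1.0)
            ll = self._loglik(Q, f)
            if ll < prev - 1e-6:
                raise RuntimeError(
                    f"EM log-likelihood decreased ({prev:.9f} -> {ll:.9f})")
            if abs(ll - prev) < tol:
                converged = True
                prev = ll
                break
            prev = ll
        return AncestryEstimate(Q=Q, allele_freqs=f, log_likelihood=prev,
                                K_pop=K, seed=seed_label, n_iter=it,
                                converged=converged)

    def fit(self, K_pop: int, n_replicates: int = 7, seed: int = 0,
            max_iter: int = 2000, tol: float = 1e-6) -> AdmixtureResults:
        """Fit K_pop subpopulations; ``n_replicates`` independent EM starts
        (the printed protocol ran seven replications per K; five is the
        conflicting alternative some runs used — set it explicitly if
        wanted)."""
        if K_pop < 1:
            raise ValueError("K_pop must be >= 1")
        if K_pop > self.n_accessions:
            raise ValueError("K_pop exceeds the number of accessions")
        ss = np.random.SeedSequence([seed, K_pop])
        reps = []
        for i, child in enumerate(ss.spawn(n_replicates)):
            rng = np.random.default_rng(child)
            reps.append(self._em(K_pop, rng, max_iter, tol, seed_label=i))
        return AdmixtureResults(self, reps)

    def fit_k_range(self, k_values: Sequence[int], n_replicates: int = 7,
                    seed: int = 0, max_iter: int = 2000, tol: float = 1e-6,
                    ) -> dict[int, AdmixtureResults]:
        return {K: self.fit(K, n_replicates=n_replicates, seed=seed,
                            max_iter=max_iter, tol=tol)
                for K in k_values}

    # -- Bayesian marginal likelihood (for ΔK model selection) -----------
    def marginal_likelihood(self, K_pop: int, n_replicates: int = 7,
                            seed: int = 0, n_burnin: int = 200,
                            n_samples: int = 300) -> list[float]:
        """Replicate estimates of Ln P(D) for ``K_pop`` subpopulations by
        Gibbs sampling of the same admixture model (alpha, the admixture
        concentration, inferred by Metropolis-Hastings), using the
        mean − ½·variance estimator of the posterior log-likelihood trace.

        Converged maximum-likelihood replicates are numerically identical,
        which degenerates the ΔK denominator; the Monte-Carlo spread of
        these estimates is what the ΔK statistic is calibrated for, so K
        selection uses them rather than the EM log-likelihoods.
        """
        if K_pop < 1:
            raise ValueError("K_pop must be >= 1")
        if K_pop > self.n_accessions:
            raise ValueError("K_pop exceeds the number of accessions")
        ss = np.random.SeedSequence([seed, K_pop, 2983])
        return [
            _gibbs_marginal_likelihood(self.y, K_pop,
                                       np.random.default_rng(child),
                                       n_burnin, n_samples)
            for child in ss.spawn(n_replicates)]

    def select_k(self, k_values: Sequence[int], n_replicates: int = 7,
                 seed: int = 0, n_burnin: int = 200,
                 n_samples: int = 300) -> "EvannoResult":
        """Evanno ΔK model selection over ``k_values`` (consecutive)."""
        logliks = {K: self.marginal_likelihood(K, n_replicates=n_replicates,
                                               seed=seed, n_burnin=n_burnin,
                                               n_samples=n_samples)
                   for K in k_values}
        return evanno_delta_k(logliks)


def _gibbs_marginal_likelihood(y: np.ndarray, K: int,
                               rng: np.random.Generator,
                               n_burnin: int, n_samples: int,
                               alpha_max: float = 10.0) -> float:
    """One chain: latent haplotype ancestries/alleles, Beta-Dirichlet
    conjugate updates for f and Q, MH update of the admixture concentration
    alpha; returns mean(logL) − ½ var(logL) over post-burn-in sweeps."""
    from scipy.special import gammaln

    n, L = y.shape
    y1 = y == 1.0
    Q = rng.dirichlet(np.ones(K), size=n)
    f = rng.uniform(0.1, 0.9, size=(K, L))
    alpha = 1.0
    trace = []

    def sample_cat(w: np.ndarray) -> np.ndarray:
        c = np.cumsum(w, axis=-1)
        u = rng.random(w.shape[:-1])[..., None] * c[..., -1:]
        return (u > c).sum(axis=-1)

    def log_p_q(al: float) -> float:
        return (n * (gammaln(K * al) - K * gammaln(al))
                + (al - 1.0) * np.log(np.clip(Q, 1e-12, 1.0)).sum())

    for t in range(n_burnin + n_samples):
        omf = 1.0 - f
        a = np.clip(Q @ omf, 1e-12, 1.0 - 1e-12)
        Qk = Q[:, :, None]
        up = Qk * f[None]                    # weight of state (k, presence)
        um = Qk * omf[None]                  # weight of state (k, absence)
        # haplotype 1: for y=1 the partner must rescue absence alleles
        w1p = np.where(y1[:, None, :], up, 0.0)
        w1m = np.where(y1[:, None, :], um * (1.0 - a)[:, None, :], um)
        s1 = sample_cat(np.moveaxis(np.concatenate([w1p, w1m], axis=1), 1, 2))
        h1_plus = s1 < K
        k1 = np.where(h1_plus, s1, s1 - K)
        # haplotype 2 conditional on haplotype 1
        w2p = np.where(y1[:, None, :], up, 0.0)
        w2m = np.where(y1[:, None, :] & ~h1_plus[:, None, :], 0.0, um)
        s2 = sample_cat(np.moveaxis(np.concatenate([w2p, w2m], axis=1), 1, 2))
        h2_plus = s2 < K
        k2 = np.where(h2_plus, s2, s2 - K)
        # conjugate updates
        n_plus = np.zeros((K, L))
        n_minus = np.zeros((K, L))
        r = np.zeros((n, K))
        for plus, karr in ((h1_plus, k1), (h2_plus, k2)):
            for kk in range(K):
                m = karr == kk
                n_plus[kk] += (m & plus).sum(axis=0)
                n_minus[kk] += (m & ~plus).sum(axis=0)
                r[:, kk] += m.sum(axis=1)
        f = rng.beta(1.0 + n_plus, 1.0 + n_minus)
        Q = rng.gamma(alpha + r)
        Q /= Q.sum(axis=1, keepdims=True)
        if K > 1:
            prop = abs(alpha + rng.normal(0.0, 0.1))
            if 0.0 < prop <= alpha_max and (
                    np.log(rng.random()) < log_p_q(prop) - log_p_q(alpha)):
                alpha = prop
        a = np.clip(Q @ (1.0 - f), 1e-12, 1.0 - 1e-12)
        ll = float(np.sum(np.where(y1, np.log1p(-a ** 2), 2.0 * np.log(a))))
        if t >= n_burnin:
            trace.append(ll)
    arr = np.asarray(trace)
    return float(arr.mean() - 0.5 * arr.var())


# ---------------------------------------------------------------------------
# label alignment, assignment, ΔK
# ---------------------------------------------------------------------------

def align_columns(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match Q_ref (greedy correlation
    matching); returns the permuted copy."""
    K = Q.shape[1]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            vi = Q[:, i] - Q[:, i].mean()
            vj = Q_ref[:, j] - Q_ref[:, j].mean()
            denom = np.sqrt((vi ** 2).sum() * (vj ** 2).sum())
            corr[i, j] = (vi * vj).sum() / denom if denom > 0 else 0.0
    perm = np.full(K, -1)
    used_i: set[int] = set()
    used_j: set[int] = set()
    for _ in range(K):
        best = None
        for i in range(K):
            if i in used_i:
                continue
            for j in range(K):
                if j in used_j:
                    continue
                if best is None or corr[i, j] > corr[best[0], best[1]]:
                    best = (i, j)
        perm[best[1]] = best[0]
        used_i.add(best[0])
        used_j.add(best[1])
    return Q[:, perm]


def classify_admixed(Q: np.ndarray, threshold: float = 0.8,
                     labels: Sequence[str] | None = None) -> list[str]:
    """Assign each accession to the subpopulation whose admixture
    coefficient Qi strictly exceeds ``threshold``; otherwise ``admixed``
    (Qi = 0.8 exactly is admixed)."""
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    out = []
    for row in Q:
        k = int(np.argmax(row))
        if row[k] > threshold:
            out.append(labels[k] if labels else f"subpop{k + 1}")
        else:
            out.append("admixed")
    return out


@dataclass
class EvannoResult:
    table: pd.DataFrame          # K, n_replicates, mean_L, sd_L, delta_k
    selected_k: int | None       # None when ΔK is degenerate everywhere
    degenerate: bool = False


def evanno_delta_k(logliks: Mapping[int, Sequence[float]]) -> EvannoResult:
    """ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) over
    replicate log-likelihoods; the selected K maximises ΔK.

    Requires at least three consecutive K values with ≥2 replicates each;
    zero replicate standard deviation at an interior K is an error
    (degenerate replicates); a ΔK that is zero everywhere (exactly linear
    L(K)) yields no selection and is flagged.
    """
    ks = sorted(logliks)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(logliks[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {k: float(np.std(logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            if sd[k] == 0.0:
                raise ValueError(f"K={k}: zero replicate standard deviation")
            dk = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1]) / sd[k]
        rows.append({"K": k, "n_replicates": len(logliks[k]),
                     "mean_L": mean[k], "sd_L": sd[k], "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    if np.allclose(interior["delta_k"], 0.0):
        return EvannoResult(table=table, selected_k=None, degenerate=True)
    sel = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return EvannoResult(table=table, selected_k=sel)
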