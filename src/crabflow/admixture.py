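"""Admixture inference on codominant genotypes.

A collapsed-data Gibbs sampler for the standard admixture model: each gene copy
carries a latent source cluster Z; cluster allele frequencies P and individual
ancestry vectors Q get conjugate Dirichlet updates. Replicate runs are aligned
by label permutation (exact search for K <= 8) and averaged; the number of
clusters is scored by the second-difference statistic on replicate evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


@dataclass
class AdmixtureFit:
    Q: np.ndarray  # (N, K) posterior-mean ancestry (Dirichlet-smoothed)
    Z_fraction: np.ndarray  # (N, K) posterior-mean fraction of gene copies
    # assigned to each cluster; unshrunken, preferred for threshold rules
    P: list  # per locus, (K, n_alleles) posterior-mean frequencies
    allele_codes: list  # per locus, integer codes indexing columns of P
    individual_ids: list
    locus_ids: list
    alpha: float
    loglik_trace: np.ndarray  # per retained sweep
    K: int
    seed: int
    n_sweeps: int
    burn_in: int

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.individual_ids, columns=cols)


def _flatten_calls(G: GenotypeMatrix):
    """Return (ind_idx, locus_idx, allele_idx, allele_codes) over observed copies."""
    codes = []
    ind_idx, locus_idx, allele_idx = [], [], []
    for l in range(G.n_loci):
        col = G.calls[:, l, :]
        observed = col[:, 0] > 0
        alleles = np.unique(col[observed])
        if alleles.size == 0:
            raise ValueError(f"locus {G.locus_ids[l]} has no observed calls")
        lookup = {a: i for i, a in enumerate(alleles)}
        codes.append(alleles)
        for copy in range(2):
            inds = np.nonzero(observed)[0]
            ind_idx.append(inds)
            locus_idx.append(np.full(inds.size, l))
            allele_idx.append(np.array([lookup[a] for a in col[inds, copy]]))
    return (
        np.concatenate(ind_idx),
        np.concatenate(locus_idx),
        np.concatenate(allele_idx),
        codes,
    )


def gibbs_admixture(
    G: GenotypeMatrix,
    K: int,
    n_sweeps: int = 2000,
    burn_in: int = 500,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
) -> AdmixtureFit:
    """Run the Gibbs sampler and return posterior means of Q and P.

    Per sweep: source clusters Z for each observed gene copy are drawn with
    P(Z=k) proportional to q_ik * p_k,l,allele; then P ~ Dirichlet(lam + copy
    counts) per cluster-locus and Q ~ Dirichlet(alpha + per-cluster copy counts)
    per individual. Missing calls are skipped. The log-likelihood
    log P(X | P, Q) is recorded for every retained sweep.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if burn_in >= n_sweeps:
        raise ValueError("burn_in must be smaller than n_sweeps")
    rng = np.random.default_rng(seed)
    ind_idx, locus_idx, allele_idx, codes = _flatten_calls(G)
    N, L, C = G.n_individuals, G.n_loci, ind_idx.size
    n_alleles = np.array([c.size for c in codes])
    A = int(n_alleles.max())
    valid = np.zeros((L, A), dtype=bool)
    for l in range(L):
        valid[l, : n_alleles[l]] = True

    flat_la = locus_idx * A + allele_idx  # flattened (locus, allele) index

    Q = rng.dirichlet(np.full(K, alpha), size=N)
    P = np.zeros((K, L, A))
    for l in range(L):
        P[:, l, : n_alleles[l]] = rng.dirichlet(np.full(n_alleles[l], lam), size=K)

    retained = n_sweeps - burn_in
    Q_sum = np.zeros((N, K))
    Z_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L, A))
    trace = np.empty(retained)
    copies_per_ind = np.bincount(ind_idx, minlength=N).astype(float)
    safe_copies = np.where(copies_per_ind > 0, copies_per_ind, 1.0)

    for sweep in range(n_sweeps):
        # (C, K) unnormalized source probabilities
        probs = Q[ind_idx] * P.reshape(K, L * A)[:, flat_la].T
        if K == 1:
            Z = np.zeros(C, dtype=np.int64)
        else:
            cum = np.cumsum(probs, axis=1)
            u = rng.random(C) * cum[:, -1]
            Z = np.minimum((u[:, None] > cum).sum(axis=1), K - 1)

        # update P
        counts_p = np.zeros((K, L * A))
        np.add.at(counts_p, (Z, flat_la), 1.0)
        counts_p = counts_p.reshape(K, L, A)
        g = rng.gamma(np.where(valid, lam + counts_p, 1.0))
        g[:, ~valid] = 0.0
        P = g / g.sum(axis=2, keepdims=True)

        # update Q
        counts_q = np.zeros((N, K))
        np.add.at(counts_q, (ind_idx, Z), 1.0)
        gq = rng.gamma(alpha + counts_q)
        # individuals with all calls missing: keep a prior draw
        gq[copies_per_ind == 0] = rng.gamma(alpha, size=(int((copies_per_ind == 0).sum()), K))
        Q = gq / gq.sum(axis=1, keepdims=True)

        if sweep >= burn_in:
            Q_sum += Q
            Z_sum += counts_q / safe_copies[:, None]
            P_sum += P
            lik = (Q[ind_idx] * P.reshape(K, L * A)[:, flat_la].T).sum(axis=1)
            trace[sweep - burn_in] = np.log(lik).sum()

    Q_mean = Q_sum / retained
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    Z_mean = Z_sum / retained
    Z_mean[copies_per_ind == 0] = 1.0 / K
    P_mean = P_sum / retained
    P_out = []
    for l in range(L):
        block = P_mean[:, l, : n_alleles[l]]
        P_out.append(block / block.sum(axis=1, keepdims=True))
    return AdmixtureFit(
        Q=Q_mean,
        Z_fraction=Z_mean,
        P=P_out,
        allele_codes=codes,
        individual_ids=list(G.individual_ids),
        locus_ids=list(G.locus_ids),
        alpha=alpha,
        loglik_trace=trace,
        K=K,
        seed=seed,
        n_sweeps=n_sweeps,
        burn_in=burn_in,
    )


def model_evidence(fit: AdmixtureFit | np.ndarray) -> float:
    """Deviance-style evidence L(K) = mean(trace) - var(trace)/2 (ddof=1)."""
    trace = fit.loglik_trace if isinstance(fit, AdmixtureFit) else np.asarray(fit, dtype=float)
    if trace.size == 0:
        raise ValueError("empty log-likelihood trace")
    var = trace.var(ddof=1) if trace.size > 1 else 0.0
    return float(trace.mean() - var / 2.0)


def evanno_delta_k(evidence: dict) -> pd.DataFrame:
    """Second-difference statistic over a contiguous K range.

    ``evidence`` maps K -> sequence of replicate L(K) values (>= 2 replicates,
    >= 3 consecutive K). Delta K is |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K));
    endpoints (and sd = 0 cases) are NaN-flagged rather than infinite.
    """
    ks = sorted(evidence)
    if len(ks) < 3:
        raise ValueError("needs >= 3 consecutive K values")
    if any(k2 - k1 != 1 for k1, k2 in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(evidence[k]) < 2:
            raise ValueError("needs >= 2 replicates per K")
    mean = {k: float(np.mean(evidence[k])) for k in ks}
    sd = {k: float(np.std(evidence[k], ddof=1)) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1 or sd[k] == 0.0:
            dk = np.nan
        else:
            dk = abs(mean[ks[i + 1]] - 2 * mean[k] + mean[ks[i - 1]]) / sd[k]
        rows.append((k, len(evidence[k]), mean[k], sd[k], dk))
    return pd.DataFrame(rows, columns=["K", "n_replicates", "mean_L", "sd_L", "delta_K"])


def align_replicates(q_list, reference: int = 0, method: str = "auto"):
    """Resolve label switching across replicate Q matrices.

    Each run's cluster columns are permuted to minimize the Frobenius distance
    to the reference run (exact search over all K! permutations for K <= 8,
    greedy column matching with lowest-index tie-breaking otherwise). Returns
    ``(aligned, permutations, distances)``.
    """
    q_list = [np.asarray(q, dtype=float) for q in q_list]
    if not q_list:
        raise ValueError("no runs to align")
    shape = q_list[0].shape
    if any(q.shape != shape for q in q_list):
        raise ValueError("replicate Q matrices differ in shape")
    K = shape[1]
    if method not in ("auto", "exact", "greedy"):
        raise ValueError("method must be auto, exact, or greedy")
    use_exact = method == "exact" or (method == "auto" and K <= 8)
    ref = q_list[reference]
    aligned, perms, dists = [], [], []
    for q in q_list:
        # cost[j, k] = squared distance between run column j and ref column k
        cost = ((q[:, :, None] - ref[:, None, :]) ** 2).sum(axis=0)
        if use_exact:
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(K)):
                c = cost[list(perm), range(K)].sum()
                if c < best_cost - 1e-15:
                    best, best_cost = perm, c
            perm = np.array(best)
        else:
            perm = np.full(K, -1)
            free = set(range(K))
            for k in range(K):  # ref column k takes its best free run column
                order = np.argsort(cost[:, k], kind="stable")
                for j in order:
                    if j in free:
                        perm[k] = j
                        free.remove(j)
                        break
        aligned.append(q[:, perm])
        perms.append(np.asarray(perm))
        dists.append(float(np.sqrt(((q[:, perm] - ref) ** 2).sum())))
    return aligned, perms, dists


def consensus_membership(aligned_q_list) -> np.ndarray:
    """Element-wise mean of aligned Q matrices, row-renormalized."""
    qs = [np.asarray(q, dtype=float) for q in aligned_q_list]
    if not qs:
        raise ValueError("no runs")
    mean = np.mean(qs, axis=0)
    return mean / mean.sum(axis=1, keepdims=True)
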