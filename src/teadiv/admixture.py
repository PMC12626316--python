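"""Bayesian admixture inference for codominant genotypes.

A Gibbs sampler for the independent-allele-frequency admixture model: each
allele copy of individual i has a latent cluster of origin z drawn from
Categorical(q_i), and given z the observed allele is drawn from that
cluster's frequency vector at the locus. Priors are Dirichlet(alpha = 1) on
the individual ancestry vectors q_i and Dirichlet(lambda = 1) on the
per-cluster per-locus allele frequencies; alpha is held fixed (no
hyperparameter update), which is sufficient for Delta-K based selection of
the cluster number.

Model log-evidence is summarised per run as
lnPD = mean(lnL) - var(lnL)/2 over retained sweeps, the standard estimator
the Evanno Delta-K statistic was designed around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "AdmixtureRun",
    "gibbs_admixture",
    "replicate_scan",
    "evanno_delta_k",
    "classify_membership",
    "align_clusters",
]


@dataclass
class AdmixtureRun:
    k: int
    q: pd.DataFrame  # individuals x K posterior-mean ancestry, rows sum to 1
    p: np.ndarray  # K x loci x alleles posterior-mean frequencies
    ln_pd: float
    seed: int | None
    sweeps: int
    burnin: int


def _encode(g: GenotypeMatrix):
    """Flatten non-missing allele copies to index arrays (individual, locus,
    allele-index) plus the per-locus allele label tables."""
    allele_tables = []
    n, L = g.n_individuals, g.n_loci
    idx = np.full((n, L, 2), -1, dtype=np.int64)
    for j in range(L):
        col = g.calls[:, j, :]
        labels = np.unique(col[col != MISSING])
        allele_tables.append(labels)
        lookup = {int(a): t for t, a in enumerate(labels)}
        for i in range(n):
            if col[i, 0] != MISSING:
                idx[i, j, 0] = lookup[int(col[i, 0])]
                idx[i, j, 1] = lookup[int(col[i, 1])]
    ok = idx[:, :, 0] >= 0
    i_of, l_of = np.nonzero(ok)
    i_of = np.repeat(i_of, 2)
    l_of = np.repeat(l_of, 2)
    a_of = idx[idx[:, :, 0] >= 0].ravel()
    return i_of, l_of, a_of, allele_tables


def gibbs_admixture(
    g: GenotypeMatrix,
    k: int,
    sweeps: int = 20_000,
    burnin: int = 5_000,
    seed: int | None = None,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> AdmixtureRun:
    """Run the Gibbs sampler at a fixed cluster count ``k``.

    Returns posterior-mean Q and P and the lnPD evidence summary. Identical
    seed and inputs give bit-identical results.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if g.missing_mask().all(axis=1).any():
        raise ValueError("an individual has no non-missing calls")
    n, L = g.n_individuals, g.n_loci
    i_of, l_of, a_of, allele_tables = _encode(g)
    amax = max(len(t) for t in allele_tables)
    valid = np.zeros((L, amax), dtype=bool)
    for j, t in enumerate(allele_tables):
        valid[j, : len(t)] = True
    if k >= 2 and all(len(t) < 2 for t in allele_tables):
        raise ValueError("need at least one polymorphic locus for k >= 2")

    rng = np.random.default_rng(seed)
    m = i_of.size
    q = np.full((n, k), 1.0 / k)
    p = np.where(valid, 1.0 / valid.sum(axis=1, keepdims=True), 0.0)
    p = np.broadcast_to(p, (k, L, amax)).copy()

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, L, amax))
    lnls = np.empty(sweeps - burnin)
    kept = 0
    for sweep in range(sweeps):
        # latent origins: w[c, k] = q[i_c, k] * p[k, l_c, a_c]
        w = q[i_of] * p[:, l_of, a_of].T
        denom = w.sum(axis=1)
        lnl = float(np.log(denom).sum())
        u = rng.random(m) * denom
        z = (np.cumsum(w, axis=1) <= u[:, None]).sum(axis=1)
        np.minimum(z, k - 1, out=z)
        # ancestry vectors
        cnt_q = np.zeros((n, k))
        np.add.at(cnt_q, (i_of, z), 1.0)
        gq = rng.gamma(alpha + cnt_q)
        q = gq / gq.sum(axis=1, keepdims=True)
        # allele frequencies
        cnt_p = np.zeros((k, L, amax))
        np.add.at(cnt_p, (z, l_of, a_of), 1.0)
        gp = np.where(valid, rng.gamma(lam + cnt_p), 0.0)
        p = gp / gp.sum(axis=2, keepdims=True)
        if sweep >= burnin:
            q_sum += q
            p_sum += p
            lnls[kept] = lnl
            kept += 1

    q_mean = q_sum / kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    ln_pd = float(np.mean(lnls) - (np.var(lnls, ddof=1) if kept > 1 else 0.0) / 2.0)
    return AdmixtureRun(
        k=k,
        q=pd.DataFrame(q_mean, index=g.individuals, columns=[f"Q{c+1}" for c in range(k)]),
        p=p_sum / kept,
        ln_pd=ln_pd,
        seed=seed,
        sweeps=sweeps,
        burnin=burnin,
    )


def replicate_scan(
    g: GenotypeMatrix,
    kmax: int = 5,
    reps: int = 10,
    sweeps: int = 20_000,
    burnin: int = 5_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Independent seeded runs for K = 1..kmax; returns the lnPD table
    (rows K, one column per replicate). Replicate seeds are derived
    deterministically from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(kmax * reps)
    out = np.empty((kmax, reps))
    for k in range(1, kmax + 1):
        for r in range(reps):
            child = children[(k - 1) * reps + r]
            run_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
            out[k - 1, r] = gibbs_admixture(
                g, k, sweeps=sweeps, burnin=burnin, seed=run_seed
            ).ln_pd
    return pd.DataFrame(
        out, index=pd.Index(range(1, kmax + 1), name="K"),
        columns=[f"rep{r+1}" for r in range(reps)],
    )


def evanno_delta_k(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno Delta-K model selection from a K x replicate lnPD table.

    Per replicate, L''(K) = L(K+1) - 2 L(K) + L(K-1); Delta-K(K) is the mean
    of |L''(K)| across replicates divided by the SD of L(K) across replicates,
    defined for 2 <= K <= Kmax-1. Returns the summary table and argmax K.
    """
    ks = list(table.index)
    if len(ks) < 3:
        raise ValueError("Delta-K needs Kmax >= 3")
    if table.shape[1] < 2:
        raise ValueError("Delta-K needs >= 2 replicates")
    vals = table.to_numpy(dtype=float)
    mean_l = vals.mean(axis=1)
    sd_l = vals.std(axis=1, ddof=1)
    lp = np.full(len(ks), np.nan)
    lp[1:] = mean_l[1:] - mean_l[:-1]
    lpp = np.full(len(ks), np.nan)
    dk = np.full(len(ks), np.nan)
    for t in range(1, len(ks) - 1):
        second = vals[t + 1] - 2.0 * vals[t] + vals[t - 1]
        lpp[t] = np.mean(np.abs(second))
        if sd_l[t] == 0:
            warnings.warn(f"zero replicate SD at K={ks[t]}: Delta-K set to inf")
            dk[t] = np.inf
        else:
            dk[t] = lpp[t] / sd_l[t]
    out = pd.DataFrame(
        {"mean_lnPD": mean_l, "sd_lnPD": sd_l, "Lprime": lp,
         "abs_Lsecond": lpp, "deltaK": dk},
        index=pd.Index(ks, name="K"),
    )
    best = int(out["deltaK"].idxmax())
    return out, best


def classify_membership(q: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Assign each individual to its argmax cluster; flag as admixed/complex
    when the top membership falls below ``threshold``."""
    arr = q.to_numpy(dtype=float)
    cluster = arr.argmax(axis=1) + 1
    max_q = arr.max(axis=1)
    return pd.DataFrame(
        {"cluster": cluster, "max_q": max_q, "admixed": max_q < threshold},
        index=q.index,
    )


def align_clusters(q: pd.DataFrame, reference: np.ndarray) -> pd.DataFrame:
    """Greedy column matching of an inferred Q to a reference Q (handles label
    switching at evaluation time only)."""
    a = q.to_numpy(dtype=float)
    ref = np.asarray(reference, dtype=float)
    k = a.shape[1]
    sim = a.T @ ref  # overlap between inferred and reference clusters
    order = [-1] * k
    used_rows, used_cols = set(), set()
    for _ in range(min(k, ref.shape[1])):
        best = None
        for i in range(k):
            if i in used_rows:
                continue
            for j in range(ref.shape[1]):
                if j in used_cols:
                    continue
                if best is None or sim[i, j] > best[0]:
                    best = (sim[i, j], i, j)
        _, i, j = best
        order[j] = i
        used_rows.add(i)
        used_cols.add(j)
    remaining = [i for i in range(k) if i not in used_rows]
    order = [o if o >= 0 else remaining.pop(0) for o in order]
    return q.iloc[:, order].set_axis(q.columns[: len(order)], axis=1)
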