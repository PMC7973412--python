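"""Kinship- and structure-adjusted single-marker association scans.

The model is a polygenic mixed model: trait = covariates (intercept + top
kinship principal components) + polygenic value with covariance
proportional to an allele-sharing kinship matrix + residual.  The variance
ratio is estimated once per scan by REML on the eigendecomposition of the
kinship matrix; each marker is then evaluated with a 1-df score test, the
p-value taken from the upper chi-square tail.  The fraction of phenotypic
variance attached to a marker is R2 = chi / (n - 2 + chi) with n the number
of non-missing genotype-phenotype pairs at that marker.

Multiple testing is controlled with Benjamini-Hochberg FDR; QTL are
declared from markers significant in at least a minimum number of
environments, delimited by LD blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .genotypes import CALL_B, GenotypeMatrix
from .ldblocks import LDBlock

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class SignificanceRule:
    """Declaration thresholds: FDR <= 0.1 significant, -log10 p >= 3 suggestive,
    significance required in at least ``min_environments`` environments."""

    fdr_threshold: float = 0.1
    suggestive_neglog10p: float = 3.0
    min_environments: int = 2

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.suggestive_neglog10p <= 0 or self.min_environments <= 0:
            raise ValueError("thresholds must be positive")


def kinship_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state allele-sharing kinship, scaled to [0, 1].

    For fully homozygous lines the sharing at a marker is 1 when both carry
    the same allele and 0 otherwise; the matrix entry is the mean over
    markers called in both individuals.  Unit diagonal, symmetric.
    """
    called = g.called_mask()
    if not called.any(axis=0).all():
        bad = list(g.individual_ids[~called.any(axis=0)])
        raise ValueError(f"individuals with no called genotypes: {bad}")
    x = np.where(called, g.calls, 0).astype(float)
    c = called.astype(float)
    both = c.T @ c
    share = x.T @ x + (c - x).T @ (c - x)  # matches at 1-alleles + matches at 0-alleles
    with np.errstate(invalid="ignore"):
        k = np.where(both > 0, share / np.maximum(both, 1), 0.0)
    np.fill_diagonal(k, 1.0)
    return pd.DataFrame(k, index=g.individual_ids, columns=g.individual_ids)


def _reml_delta(S: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Residual-likelihood estimate of delta = var_e / var_g for V ~ K + delta*I."""
    n, p = Xt.shape

    def neg_reml(log_delta: float) -> float:
        d = S + np.exp(log_delta)
        w = 1.0 / d
        xtwx = Xt.T @ (Xt * w[:, None])
        beta = np.linalg.solve(xtwx, Xt.T @ (yt * w))
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        sign, logdet_x = np.linalg.slogdet(xtwx)
        return 0.5 * (
            (n - p) * np.log(rss / (n - p)) + float(np.sum(np.log(d))) + logdet_x
        )

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def association_scan(
    g: GenotypeMatrix,
    phenotype: pd.Series,
    kinship: Optional[pd.DataFrame] = None,
    n_pcs: int = 2,
    environment: str = "",
) -> pd.DataFrame:
    """Mixed-model score-test scan of every marker against one trait vector.

    ``phenotype`` is indexed by individual (one environment's entry means);
    individuals with missing phenotype are dropped.  With an identity
    kinship and ``n_pcs=0`` the statistic reduces to the standard
    single-marker regression score chi-square.  Missing genotypes are
    mean-imputed for the statistic; the per-marker n used in R2 counts only
    non-missing pairs.

    Returns a frame sorted by genome coordinate with columns marker, chrom,
    bp, environment, n, chi2, p, q, r2, neglog10p.
    """
    pheno = phenotype.dropna()
    if pheno.std() == 0:
        raise ValueError("phenotype is constant")
    inds = [i for i in g.individual_ids if i in pheno.index]
    gs = g.select_individuals(np.asarray(g.individual_ids.isin(inds)))
    y = pheno.loc[gs.individual_ids].to_numpy(dtype=float)
    n = len(y)

    if kinship is None:
        k = np.eye(n)
    else:
        k = kinship.loc[gs.individual_ids, gs.individual_ids].to_numpy(dtype=float)
    S, U = np.linalg.eigh(k)
    S = np.clip(S, 0.0, None)

    X = [np.ones(n)]
    for j in range(n_pcs):
        X.append(U[:, -(j + 1)])
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"singular covariate matrix: rank {rank} < {X.shape[1]} columns "
            "(intercept + kinship principal components)"
        )

    yt = U.T @ y
    Xt = U.T @ X
    delta = _reml_delta(S, yt, Xt)
    d = S + delta
    w = 1.0 / d

    xtwx = Xt.T @ (Xt * w[:, None])
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (Xt.T @ (yt * w))
    r = w * (yt - Xt @ beta)  # = V^-1 (y - X beta) up to the var_g scale
    sigma2 = float(np.sum((yt - Xt @ beta) * r)) / (n - X.shape[1])

    calls = gs.calls.astype(float)
    called = gs.called_mask()
    dose = np.where(called, (gs.calls == CALL_B).astype(float), np.nan)
    n_pairs = called.sum(axis=1)
    means = np.nanmean(np.where(called, dose, np.nan), axis=1)
    dose_imp = np.where(called, dose, means[:, None])

    Gt = (U.T @ dose_imp.T).T  # markers x n, transformed genotypes
    # score and its variance under the projected metric
    WG = Gt * w[None, :]
    score = WG @ yt - (WG @ Xt) @ beta
    gw_x = WG @ Xt
    quad = np.einsum("ij,ij->i", WG, Gt) - np.einsum("ij,jk,ik->i", gw_x, xtwx_inv, gw_x)

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(quad > 1e-12, score**2 / (quad * sigma2), 0.0)
    mono = np.nanstd(dose, axis=1) == 0
    chi2 = np.where(mono, 0.0, chi2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    r2 = chi2 / (n_pairs - 2 + chi2)

    out = pd.DataFrame(
        {
            "marker": gs.marker_ids,
            "chrom": gs.markers["chrom"].to_numpy(),
            "bp": gs.markers["bp"].to_numpy(),
            "environment": environment,
            "n": n_pairs,
            "chi2": chi2,
            "p": p,
            "q": q,
            "r2": r2,
        }
    )
    out["neglog10p"] = -np.log10(out["p"])
    return out.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(chi2_values) -> float:
    """Genomic-control lambda: median observed chi-square over its null median."""
    return float(np.median(np.asarray(chi2_values)) / CHI2_MEDIAN_1DF)


def declare_qtl(
    results: Mapping[str, pd.DataFrame],
    rule: SignificanceRule = SignificanceRule(),
    blocks: Optional[Sequence[LDBlock]] = None,
) -> pd.DataFrame:
    """Aggregate per-environment scans into QTL regions.

    A marker is significant in an environment when q <= fdr_threshold and
    suggestive when -log10 p >= the suggestive threshold.  A QTL is an LD
    block containing at least one marker significant in at least
    ``min_environments`` environments; without blocks, qualifying markers
    are reported as point QTL (with a warning).

    Returns a frame with columns qtl, chrom, start, end, size_kb, n_markers,
    markers, environments.
    """
    if len(results) < rule.min_environments:
        raise ValueError(
            f"need scans from at least {rule.min_environments} environments, got {len(results)}"
        )
    env_hits: dict[str, set[str]] = {}
    coords: dict[str, tuple[str, int]] = {}
    for env, df in results.items():
        sig = df[df["q"] <= rule.fdr_threshold]
        for row in sig.itertuples(index=False):
            env_hits.setdefault(row.marker, set()).add(env)
            coords[row.marker] = (row.chrom, int(row.bp))
    qualifying = {m: envs for m, envs in env_hits.items() if len(envs) >= rule.min_environments}
    if not qualifying:
        return pd.DataFrame(
            columns=["qtl", "chrom", "start", "end", "size_kb", "n_markers", "markers", "environments"]
        )

    rows = []
    if blocks is None:
        warnings.warn("no LD blocks supplied; reporting point QTL", stacklevel=2)
        for m, envs in sorted(qualifying.items(), key=lambda kv: coords[kv[0]]):
            chrom, bp = coords[m]
            rows.append(
                {
                    "qtl": f"{chrom}:{bp}",
                    "chrom": chrom,
                    "start": bp,
                    "end": bp,
                    "size_kb": 0.0,
                    "n_markers": 1,
                    "markers": m,
                    "environments": ",".join(sorted(envs)),
                }
            )
        return pd.DataFrame(rows)

    per_block: dict[int, list[str]] = {}
    orphans: list[str] = []
    for m in qualifying:
        chrom, bp = coords[m]
        for bi, blk in enumerate(blocks):
            if blk.chrom == chrom and (m in blk.markers or blk.start <= bp <= blk.end):
                per_block.setdefault(bi, []).append(m)
                break
        else:
            orphans.append(m)  # between blocks: reported as a point QTL
    counter: dict[str, int] = {}
    for bi in sorted(per_block, key=lambda i: (blocks[i].chrom, blocks[i].start)):
        blk = blocks[bi]
        counter[blk.chrom] = counter.get(blk.chrom, 0) + 1
        members = sorted(per_block[bi])
        envs = sorted(set().union(*(qualifying[m] for m in members)))
        rows.append(
            {
                "qtl": f"{blk.chrom}_{counter[blk.chrom]}",
                "chrom": blk.chrom,
                "start": blk.start,
                "end": blk.end,
                "size_kb": blk.size_kb,
                "n_markers": len(members),
                "markers": ",".join(members),
                "environments": ",".join(envs),
            }
        )
    for m in sorted(orphans, key=lambda m: coords[m]):
        chrom, bp = coords[m]
        counter[chrom] = counter.get(chrom, 0) + 1
        rows.append(
            {
                "qtl": f"{chrom}_{counter[chrom]}",
                "chrom": chrom,
                "start": bp,
                "end": bp,
                "size_kb": 0.0,
                "n_markers": 1,
                "markers": m,
                "environments": ",".join(sorted(qualifying[m])),
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    out["qtl"] = [
        f"{chrom}_{k + 1}" for chrom, k in zip(out["chrom"], out.groupby("chrom").cumcount())
    ]
    return out
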