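"""Permutation and rank tests on community dissimilarities.

Implements PERMANOVA with sequential sums of squares, multivariate
homogeneity of group dispersions, tie-corrected Kruskal-Wallis tests and
standard multiplicity adjustments.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from resurvey.community import check_dissimilarity
from resurvey.ordination import build_design, _drop_collinear, _hat, pcoa


@dataclasses.dataclass
class PermanovaTable:
    """Sequential PERMANOVA decomposition.

    ``terms`` holds one row per term (df, ss, f, r2, p) plus residual and
    total rows; the permutation count and seed are embedded for
    reproducibility.
    """

    terms: pd.DataFrame
    n_perm: int
    seed: int
    n: int

    def as_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["n_perm"] = self.n_perm
        out["seed"] = self.seed
        return out


def permanova(
    dissim: pd.DataFrame,
    terms: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaTable:
    """Permutational multivariate ANOVA with sequential (Type I) SS.

    The total sum of squares is ``sum_{i<j} d_ij^2 / n``; term sums of
    squares are traces of successive hat-matrix projections of the
    Gower-centered matrix, and p-values come from free permutation of the
    units.  ``exact=True`` enumerates all n! permutations (identity
    included) instead of sampling, so p = #{F_perm >= F_obs}/n!.
    """
    arr = check_dissimilarity(dissim)
    n = arr.shape[0]
    if len(terms) != n:
        raise ValueError("terms table does not match the unit count")
    for name in terms.columns:
        col = terms[name]
        if not pd.api.types.is_numeric_dtype(col) and col.nunique() < 2:
            raise ValueError(f"term {name!r} has a single level")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() < 2:
            raise ValueError(f"term {name!r} is constant")
    d2 = arr**2
    nmat = d2.shape[0]
    j = np.eye(nmat) - np.ones((nmat, nmat)) / nmat
    g = -0.5 * j @ d2 @ j
    ss_total = float(np.trace(g))

    x, names, blocks = build_design(terms)
    x, kept = _drop_collinear(x, names)
    blocks = [(t, [kept.index(c) for c in cols if c in kept]) for t, cols in blocks]
    blocks = [(t, cols) for t, cols in blocks if cols]
    hats = []
    cum: list[int] = []
    for t, cols in blocks:
        cum += cols
        hats.append((t, len(cols), _hat(x[:, cum])))
    h_full = hats[-1][2] if hats else np.zeros((n, n))
    m_full = len(cum)
    df_res = n - 1 - m_full
    ss_model = float(np.sum(h_full * g))  # trace(H G)
    ss_res = ss_total - ss_model

    def term_ss(gg):
        out = []
        prev_tr = 0.0
        for _t, _df, h in hats:
            tr = float(np.sum(h * gg))
            out.append(tr - prev_tr)
            prev_tr = tr
        return out

    obs_ss = term_ss(g)
    obs_f = [
        (ss / df) / (ss_res / df_res) for (_t, df, _h), ss in zip(hats, obs_ss)
    ]

    counts = [0] * len(hats)
    if exact:
        import itertools
        import math

        n_total = math.factorial(n)
        perms = itertools.permutations(range(n))
    else:
        rng = np.random.default_rng(seed)
        n_total = n_perm
        perms = (rng.permutation(n) for _ in range(n_perm))
    for perm in perms:
        gp = g[np.ix_(perm, perm)]
        ss_model_p = float(np.sum(h_full * gp))
        res_p = (ss_total - ss_model_p) / df_res
        for i, ((_t, df, _h), ss_p) in enumerate(zip(hats, term_ss(gp))):
            if (ss_p / df) / res_p >= obs_f[i] - 1e-12:
                counts[i] += 1

    rows = []
    for i, (t, df, _h) in enumerate(hats):
        p = counts[i] / n_total if exact else (1 + counts[i]) / (1 + n_total)
        rows.append(
            {
                "term": t,
                "df": df,
                "ss": obs_ss[i],
                "f": obs_f[i],
                "r2": obs_ss[i] / ss_total,
                "p": p,
            }
        )
    rows.append(
        {"term": "Residual", "df": df_res, "ss": ss_res, "f": np.nan,
         "r2": ss_res / ss_total, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "ss": ss_total, "f": np.nan,
         "r2": 1.0, "p": np.nan}
    )
    return PermanovaTable(
        terms=pd.DataFrame(rows).set_index("term"),
        n_perm=n_perm, seed=seed, n=n,
    )


@dataclasses.dataclass
class DispersionResult:
    distances: pd.Series  # per-unit distance to its group center
    group_means: pd.Series
    f: float
    df: tuple[int, int]
    p: float
    center: str


def _geometric_median(points: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Weiszfeld iteration for the spatial median."""
    m = points.mean(axis=0)
    for _ in range(n_iter):
        dist = np.linalg.norm(points - m, axis=1)
        if (dist < 1e-12).any():
            return m
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < 1e-12:
            return new
        m = new
    return m


def beta_dispersion(
    dissim: pd.DataFrame,
    groups: Sequence,
    center: str = "spatial_median",
) -> DispersionResult:
    """Distances to group centers in full PCoA space, with one-way ANOVA.

    Negative-eigenvalue axes contribute with the usual sign convention:
    squared distances on imaginary axes are subtracted and the result is
    clipped at zero before the square root.
    """
    if center not in ("spatial_median", "centroid"):
        raise ValueError(f"unknown center {center!r}")
    pc = pcoa(dissim)
    groups = pd.Series(list(groups), index=pc.ids, name="group")
    if groups.nunique() < 2:
        raise ValueError("beta_dispersion needs at least two groups")
    real, imag = pc.coords, pc.imag_coords
    dist = pd.Series(0.0, index=pc.ids)
    for gname, idx in groups.groupby(groups).groups.items():
        sel = [pc.ids.index(i) for i in idx]
        pr, pi = real[sel], imag[sel]
        if center == "centroid":
            cr, ci = pr.mean(axis=0), pi.mean(axis=0) if pi.size else np.zeros(0)
        else:
            cr = _geometric_median(pr)
            ci = pi.mean(axis=0) if pi.size else np.zeros(0)
        d2 = ((pr - cr) ** 2).sum(axis=1)
        if pi.size:
            d2 = d2 - ((pi - ci) ** 2).sum(axis=1)
        dist.loc[idx] = np.sqrt(np.clip(d2, 0.0, None))
    samples = [dist[groups == gname].to_numpy() for gname in groups.unique()]
    a = groups.nunique()
    n = len(groups)
    if all(len(s) > 0 for s in samples) and n - a > 0:
        f, p = sps.f_oneway(*samples)
        if np.isnan(f):  # zero within-group variance everywhere
            f, p = 0.0, 1.0
    else:  # pragma: no cover - degenerate
        f, p = np.nan, np.nan
    return DispersionResult(
        distances=dist,
        group_means=dist.groupby(groups).mean(),
        f=float(f),
        df=(a - 1, n - a),
        p=float(p),
        center=center,
    )


@dataclasses.dataclass
class RankTestResult:
    h: float
    df: int
    p: float
    group_sizes: dict

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis rank-sum test.

    H is referred to a chi-squared distribution with (groups - 1) degrees
    of freedom.  With all observations tied, H = 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any((groups == g).sum() < 1 for g in labels):  # pragma: no cover
        raise ValueError("every group needs at least one value")
    n = values.size
    ranks = sps.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[groups == g].sum() ** 2 / (groups == g).sum() for g in labels
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0.0:  # all values identical
        return RankTestResult(
            h=0.0, df=labels.size - 1, p=1.0,
            group_sizes={str(g): int((groups == g).sum()) for g in labels},
        )
    h /= correction
    h = max(h, 0.0)
    df = labels.size - 1
    p = float(sps.chi2.sf(h, df))
    return RankTestResult(
        h=float(h), df=df, p=p,
        group_sizes={str(g): int((groups == g).sum()) for g in labels},
    )


def adjust_pvalues(pvalues: Sequence[float], method: str = "holm") -> np.ndarray:
    """Holm, Bonferroni or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p)
    adj = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    if method == "benjamini_hochberg":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * m / (rank + 1))
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown method {method!r}")
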