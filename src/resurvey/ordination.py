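"""Principal coordinates and distance-based constrained ordination (CAP).

The constrained analysis follows the classic two-step construction:
principal coordinates of the dissimilarity matrix are regressed on the
constraint design, constrained axes come from the SVD of the fitted
values, and residual axes from the residuals.  Permutation tests permute
the sampling units underlying the dissimilarities.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from resurvey.community import check_dissimilarity

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9


@dataclasses.dataclass
class PCoAResult:
    ids: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    coords: np.ndarray  # n x p, real axes only (positive eigenvalues)
    total_inertia: float  # sum of positive eigenvalues
    negative_inertia: float  # |sum of negative eigenvalues|
    imag_coords: np.ndarray  # n x q axes of negative eigenvalues (|lambda|)

    def as_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dissim: pd.DataFrame, correction: str = "none") -> PCoAResult:
    """Classical principal coordinates analysis (Gower, metric MDS).

    ``correction='lingoes'`` adds the constant that makes the configuration
    Euclidean when negative eigenvalues occur.
    """
    if correction not in ("none", "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")
    arr = check_dissimilarity(dissim)
    n = arr.shape[0]
    d2 = arr**2
    g = _gower_center(d2)
    eigval, eigvec = np.linalg.eigh(g)
    if correction == "lingoes" and eigval.min() < -_EIG_TOL:
        c = -eigval.min()
        d2 = d2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        g = _gower_center(d2)
        eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > _EIG_TOL * scale
    neg = eigval < -_EIG_TOL * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return PCoAResult(
        ids=[str(i) for i in dissim.index],
        eigenvalues=eigval,
        coords=coords,
        total_inertia=float(eigval[pos].sum()),
        negative_inertia=float(-eigval[neg].sum()),
        imag_coords=imag,
    )


def build_design(constraints: pd.DataFrame) -> tuple[np.ndarray, list[str], list[tuple[str, list[int]]]]:
    """Centered design matrix with dummy coding for categorical columns.

    Returns the matrix, its column names, and per-term column blocks (a
    categorical term owns all its dummy columns).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: list[tuple[str, list[int]]] = []
    for name in constraints.columns:
        col = constraints[name]
        idx0 = len(names)
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for lev in dummies.columns:
                cols.append(dummies[lev].to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        blocks.append((name, list(range(idx0, len(names)))))
    x = np.column_stack(cols) if cols else np.empty((len(constraints), 0))
    x = x - x.mean(axis=0, keepdims=True)
    return x, names, blocks


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[int]]:
    """Greedy removal of columns that add no rank; returns kept indices."""
    kept: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, kept + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8) > len(kept):
            kept.append(j)
        else:
            logger.warning("dropping collinear constraint column %s", names[j])
    return x[:, kept], kept


@dataclasses.dataclass
class CAPModel:
    """Distance-based constrained ordination fit."""

    ids: list[str]
    pcoa: PCoAResult
    design: np.ndarray  # n x m centered design (collinear columns dropped)
    design_names: list[str]
    term_blocks: list[tuple[str, list[int]]]  # in declared order
    eigenvalues: np.ndarray  # constrained axis eigenvalues
    scores_lc: np.ndarray  # linear-combination unit scores (n x k)
    scores_wa: np.ndarray  # weighted-average unit scores (n x k)
    axis_directions: np.ndarray  # p x k rotation of PCoA space
    residual_eigenvalues: np.ndarray
    residual_scores: np.ndarray
    total_inertia: float
    constrained_inertia: float
    biplot: pd.DataFrame  # constraint arrows in the constrained plane

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def rank(self) -> int:
        return self.design.shape[1]

    @property
    def r_squared(self) -> float:
        if self.total_inertia == 0:
            return 0.0
        return self.constrained_inertia / self.total_inertia

    def axis_percent(self) -> np.ndarray:
        """Explained-variance percentage per constrained axis."""
        return 100.0 * self.eigenvalues / self.total_inertia

    def species_scores(self, incidence: pd.DataFrame, k: int = 2) -> pd.DataFrame:
        """Presence-weighted average unit scores per species."""
        inc = incidence.loc[self.ids]
        w = np.asarray(inc, dtype=float)
        scores = self.scores_wa[:, :k]
        with np.errstate(invalid="ignore"):
            sp = (w.T @ scores) / w.sum(axis=0)[:, None]
        cols = [f"CAP{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(sp, index=inc.columns, columns=cols)

    def unit_scores(self, kind: str = "wa", k: int = 2) -> pd.DataFrame:
        scores = {"wa": self.scores_wa, "lc": self.scores_lc}[kind][:, :k]
        cols = [f"CAP{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=self.ids, columns=cols)


def cap(
    dissim: pd.DataFrame,
    constraints: pd.DataFrame | None,
    correction: str = "none",
) -> CAPModel:
    """Canonical analysis of principal coordinates (distance-based RDA)."""
    pc = pcoa(dissim, correction=correction)
    n = len(pc.ids)
    q = pc.coords
    if constraints is None or constraints.shape[1] == 0:
        x = np.empty((n, 0))
        names: list[str] = []
        blocks: list[tuple[str, list[int]]] = []
    else:
        if len(constraints) != n:
            raise ValueError("constraint table does not match the unit set")
        constraints = constraints.loc[pd.Index(pc.ids)] if set(
            map(str, constraints.index)
        ) == set(pc.ids) else constraints
        if constraints.isna().any().any():
            raise ValueError("constraints must be complete for every unit")
        x, names, blocks = build_design(constraints)
        x, kept = _drop_collinear(x, names)
        names = [names[j] for j in kept]
        blocks = [
            (t, [kept.index(j) for j in js if j in kept]) for t, js in blocks
        ]
        blocks = [(t, js) for t, js in blocks if js]
        if x.shape[1] >= n - 1:
            raise ValueError("too many constraint columns for the unit count")

    if x.shape[1] == 0:
        fitted = np.zeros_like(q)
        resid = q
    else:
        beta, *_ = np.linalg.lstsq(x, q, rcond=None)
        fitted = x @ beta
        resid = q - fitted

    def _axes(mat):
        if mat.size == 0 or min(mat.shape) == 0:
            return np.empty(0), np.empty((n, 0)), np.empty((q.shape[1], 0))
        u, s, vt = np.linalg.svd(mat, full_matrices=False)
        lam = s**2
        keep = lam > _EIG_TOL * max(lam.max(), 1.0)
        return lam[keep], (u[:, keep] * s[keep]), vt[keep].T

    lam_c, lc, dirs = _axes(fitted)
    k_max = min(x.shape[1], lam_c.size) if x.shape[1] else 0
    lam_c, lc, dirs = lam_c[:k_max], lc[:, :k_max], dirs[:, :k_max]
    lam_r, rs, _ = _axes(resid)
    wa = q @ dirs

    biplot = pd.DataFrame(index=names, columns=["CAP1", "CAP2"], dtype=float)
    if x.shape[1] and lam_c.size:
        k = min(2, lam_c.size)
        axes = lc[:, :k] / np.sqrt(lam_c[:k])  # unit-variance axis scores
        for j, name in enumerate(names):
            v = x[:, j]
            denom = np.linalg.norm(v)
            arrows = (axes.T @ v) / denom if denom > 0 else np.zeros(k)
            biplot.loc[name, [f"CAP{i + 1}" for i in range(k)]] = arrows

    return CAPModel(
        ids=pc.ids,
        pcoa=pc,
        design=x,
        design_names=names,
        term_blocks=blocks,
        eigenvalues=lam_c,
        scores_lc=lc,
        scores_wa=wa,
        axis_directions=dirs,
        residual_eigenvalues=lam_r,
        residual_scores=rs,
        total_inertia=pc.total_inertia,
        constrained_inertia=float(lam_c.sum()),
        biplot=biplot,
    )


@dataclasses.dataclass
class PermutationTestResult:
    term: str
    f: float
    df: tuple[int, int]
    ss: tuple[float, float]
    n_perm: int
    p: float
    seed: int
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hat(x: np.ndarray) -> np.ndarray:
    if x.shape[1] == 0:
        return np.zeros((x.shape[0], x.shape[0]))
    return x @ np.linalg.pinv(x)


def permutation_anova(
    model: CAPModel,
    n_perm: int = 999,
    seed: int = 0,
    by: str = "model",
) -> list[PermutationTestResult]:
    """Permutation test of the constrained inertia against a null model.

    ``by='model'`` tests the whole model; ``by='terms'`` tests each term
    sequentially (added in declared order) against the full-model residual.
    Units (rows of the principal-coordinate matrix) are permuted freely.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if by not in ("model", "terms"):
        raise ValueError("by must be 'model' or 'terms'")
    rng = np.random.default_rng(seed)
    q = model.pcoa.coords
    n = model.n
    x = model.design
    m = model.rank
    total = model.total_inertia
    h_full = _hat(x)
    ss_full = float(np.sum((h_full @ q) ** 2))
    ss_res = total - ss_full
    df_res = n - 1 - m

    def ss_of(h, qq):
        return float(np.sum((h @ qq) ** 2))

    results = []
    if by == "model":
        f_obs = (ss_full / m) / (ss_res / df_res) if m else 0.0
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ssp = ss_of(h_full, q[perm])
            f_p = (ssp / m) / ((total - ssp) / df_res) if m else 0.0
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        results.append(
            PermutationTestResult(
                term="model", f=f_obs, df=(m, df_res), ss=(ss_full, ss_res),
                n_perm=n_perm, p=p, seed=seed, n=n,
            )
        )
        return results

    # sequential terms, shared full-model residual
    hats = []
    cum_cols: list[int] = []
    for term, cols in model.term_blocks:
        cum_cols += cols
        hats.append((term, len(cols), _hat(x[:, cum_cols])))
    obs = []
    prev = np.zeros((n, n))
    for term, df_t, h in hats:
        ss_t = ss_of(h, q) - ss_of(prev, q)
        f_t = (ss_t / df_t) / (ss_res / df_res)
        obs.append((term, df_t, ss_t, f_t, h, prev))
        prev = h
    counts = [0] * len(obs)
    for _ in range(n_perm):
        qp = q[rng.permutation(n)]
        ss_full_p = ss_of(h_full, qp)
        res_p = (total - ss_full_p) / df_res
        for i, (term, df_t, _sst, f_t, h, hp) in enumerate(obs):
            ss_tp = ss_of(h, qp) - ss_of(hp, qp)
            if (ss_tp / df_t) / res_p >= f_t - 1e-12:
                counts[i] += 1
    for i, (term, df_t, ss_t, f_t, _h, _hp) in enumerate(obs):
        results.append(
            PermutationTestResult(
                term=term, f=f_t, df=(df_t, df_res), ss=(ss_t, ss_res),
                n_perm=n_perm, p=(1 + counts[i]) / (1 + n_perm), seed=seed, n=n,
            )
        )
    return results


def adjusted_r2(model: CAPModel) -> float:
    """Ezekiel-adjusted R-squared of the constrained ordination."""
    n, m = model.n, model.rank
    if m == 0:
        return 0.0
    if n - m - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    r2 = model.r_squared
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclasses.dataclass
class FittedVector:
    name: str
    direction: np.ndarray  # unit-norm direction cosines in the score plane
    r2: float
    p: float
    n_perm: int
    seed: int


def fit_vectors(
    model: CAPModel,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    kind: str = "wa",
) -> list[FittedVector]:
    """Least-squares arrows of numeric variables in the 2-D ordination."""
    scores = model.unit_scores(kind=kind, k=2).to_numpy()
    if scores.shape[1] < 2:
        raise ValueError("fit_vectors needs a 2-D ordination")
    s = scores - scores.mean(axis=0)
    rng = np.random.default_rng(seed)
    out = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        v = v - v.mean()
        vv = float(v @ v)
        if vv <= 0:
            raise ValueError(f"variable {name!r} has zero variance")

        def _r2(vec):
            b, *_ = np.linalg.lstsq(s, vec, rcond=None)
            fit = s @ b
            return float(fit @ fit) / float(vec @ vec), b

        r2, b = _r2(v)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else np.array([0.0, 0.0])
        count = 0
        for _ in range(n_perm):
            r2p, _ = _r2(rng.permutation(v))
            if r2p >= r2 - 1e-12:
                count += 1
        out.append(
            FittedVector(
                name=name, direction=direction, r2=r2,
                p=(1 + count) / (1 + n_perm), n_perm=n_perm, seed=seed,
            )
        )
    return out


def _marginal_test(
    dissim: pd.DataFrame,
    base: pd.DataFrame | None,
    extra: pd.DataFrame,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation F and p of ``extra`` added to the model with ``base``."""
    full_tab = extra if base is None or base.shape[1] == 0 else pd.concat(
        [base, extra], axis=1
    )
    pc = pcoa(dissim)
    q = pc.coords
    n = q.shape[0]
    total = pc.total_inertia
    xb, _, _ = build_design(base) if base is not None and base.shape[1] else (
        np.empty((n, 0)), [], []
    )
    xf, names_f, _ = build_design(full_tab)
    xf, _ = _drop_collinear(xf, names_f)
    hb, hf = _hat(xb), _hat(xf)
    mb, mf = np.linalg.matrix_rank(xb) if xb.size else 0, xf.shape[1]
    df_add = mf - mb
    if df_add <= 0:
        return 0.0, 1.0
    df_res = n - 1 - mf

    def f_stat(qq):
        ss_f = float(np.sum((hf @ qq) ** 2))
        ss_b = float(np.sum((hb @ qq) ** 2))
        return ((ss_f - ss_b) / df_add) / ((total - ss_f) / df_res)

    f_obs = f_stat(q)
    count = 0
    for _ in range(n_perm):
        if f_stat(q[rng.permutation(n)]) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (1 + n_perm)


@dataclasses.dataclass
class StepwiseResult:
    model: CAPModel
    selected: list[str]
    trace: list[dict]


def stepwise_select(
    dissim: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha_in: float = 0.05,
    alpha_out: float = 0.10,
    n_perm: int = 199,
    seed: int = 0,
    max_steps: int = 50,
) -> StepwiseResult:
    """Bidirectional permutation-based constraint selection.

    Repeatedly adds the candidate with the smallest marginal permutation
    p-value below ``alpha_in`` and drops any selected term whose marginal
    p-value rises above ``alpha_out``, until the selection is stable.
    Returns the final model (the null model when nothing is significant)
    together with the full selection trace.
    """
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    trace: list[dict] = []
    for _step in range(max_steps):
        changed = False
        base = candidates[selected] if selected else None
        best = None
        for name in candidates.columns:
            if name in selected:
                continue
            f, p = _marginal_test(
                dissim, base, candidates[[name]], n_perm, rng
            )
            trace.append({"action": "test_add", "term": name, "f": f, "p": p})
            if p < alpha_in and (best is None or p < best[1] or
                                 (p == best[1] and f > best[2])):
                best = (name, p, f)
        if best is not None:
            selected.append(best[0])
            trace.append({"action": "add", "term": best[0], "p": best[1]})
            changed = True
        # drop phase
        for name in list(selected):
            others = [t for t in selected if t != name]
            f, p = _marginal_test(
                dissim,
                candidates[others] if others else None,
                candidates[[name]],
                n_perm,
                rng,
            )
            trace.append({"action": "test_drop", "term": name, "f": f, "p": p})
            if p > alpha_out:
                selected.remove(name)
                trace.append({"action": "drop", "term": name, "p": p})
                changed = True
        if not changed:
            break
    model = cap(dissim, candidates[selected] if selected else None)
    return StepwiseResult(model=model, selected=selected, trace=trace)
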