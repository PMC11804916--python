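"""Data cleaning: missingness filtering, probabilistic-PCA imputation,
rank-based quantile normalization to z-scores, and polarity inversion.

The chain mirrors how item-level questionnaire tables are prepared for
correlation-network analysis:

1. ``filter_missing`` — iteratively drop subject rows / item columns whose
   missing fraction exceeds 30%, recomputing fractions after each removal.
2. ``PPCA(...).fit()`` + ``impute`` — EM for the probabilistic principal
   component analysis model with missing entries treated as latent;
   missing scores are replaced by conditional expectations.
3. ``quantile_normalize`` — per-item rank-based inverse-normal transform
   (Blom plotting positions), yielding z-scores.
4. ``orient_items`` — negate higher-is-better columns so that higher always
   means worse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import ndtri
from scipy.stats import rankdata

from .data import SymptomDataset

__all__ = [
    "FilterError",
    "filter_missing",
    "PPCA",
    "PPCAResults",
    "impute",
    "quantile_normalize",
    "orient_items",
    "preprocess",
]

_SIGMA2_FLOOR = 1e-12


class FilterError(RuntimeError):
    """Raised when missingness filtering deletes an entire axis."""


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------

def filter_missing(
    ds: SymptomDataset, row_max: float = 0.3, col_max: float = 0.3
) -> SymptomDataset:
    """Iteratively remove rows/columns with missing fraction above the bound.

    One row *or* column is removed per pass — the one with the highest
    missing fraction, recomputed after every removal, until no row exceeds
    ``row_max`` and no column exceeds ``col_max`` (strict inequality: a
    fraction exactly at the bound is kept).  Ties are broken toward rows,
    then toward the lowest index.

    Raises
    ------
    FilterError
        If every row or every column would be removed.
    """
    if not (0 < row_max < 1 and 0 < col_max < 1):
        raise ValueError("row_max and col_max must lie in (0, 1)")

    rows = list(range(ds.n_subjects))
    cols = list(range(ds.n_items))
    miss = np.isnan(ds.scores)

    while True:
        if not rows or not cols:
            raise FilterError(
                f"missingness filter removed an entire axis "
                f"({len(rows)} rows x {len(cols)} columns survive)"
            )
        sub = miss[np.ix_(rows, cols)]
        rfrac = sub.mean(axis=1)
        cfrac = sub.mean(axis=0)
        worst_r = int(np.argmax(rfrac))
        worst_c = int(np.argmax(cfrac))
        r_bad = rfrac[worst_r] > row_max
        c_bad = cfrac[worst_c] > col_max
        if not r_bad and not c_bad:
            break
        # remove the single worst offender; rows win ties
        if r_bad and (not c_bad or rfrac[worst_r] >= cfrac[worst_c]):
            del rows[worst_r]
        else:
            del cols[worst_c]

    out = ds.select_subjects(np.array(rows, dtype=int))
    return out.select_items([ds.labels[c] for c in cols])


# ---------------------------------------------------------------------------
# probabilistic PCA with missing data
# ---------------------------------------------------------------------------

def _group_by_pattern(mask: np.ndarray) -> dict[bytes, np.ndarray]:
    """Row indices grouped by observation pattern (key = packed bool row)."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(row.tobytes(), []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class PPCAResults:
    """Fitted probabilistic-PCA model.

    Attributes
    ----------
    mean : ndarray, shape (M,)
    loadings : ndarray, shape (M, k)
        The factor loading matrix W.
    sigma2 : float
        Isotropic residual variance.
    k : int
    loglik_trace : ndarray
        Observed-data log-likelihood after every EM iteration
        (non-decreasing up to numerical slack).
    converged : bool
    stopping_rule : str
        ``"tol"`` or ``"max_iter"``.
    item_labels : list of str or None
        Labels of the columns the model was fitted on, if known.
    """

    mean: np.ndarray
    loadings: np.ndarray
    sigma2: float
    k: int
    loglik_trace: np.ndarray
    converged: bool
    stopping_rule: str
    item_labels: list[str] | None = None

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def subspace(self) -> np.ndarray:
        """Orthonormal basis of the principal subspace span(W)."""
        q, _ = np.linalg.qr(self.loadings)
        return q

    def conditional_expectation(self, x: np.ndarray) -> np.ndarray:
        """Fill the NaN entries of score rows ``x`` with their conditional
        mean under the model, given each row's observed entries."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = x.copy()
        mask = ~np.isnan(x)
        W, mu, s2 = self.loadings, self.mean, self.sigma2
        for key, idx in _group_by_pattern(mask).items():
            obs = np.frombuffer(key, dtype=bool)
            mis = ~obs
            if not mis.any():
                continue
            if not obs.any():
                out[np.ix_(idx, np.where(mis)[0])] = mu[mis]
                continue
            Wo = W[obs]
            Mmat = Wo.T @ Wo + s2 * np.eye(self.k)
            t = np.linalg.solve(Mmat, Wo.T @ (x[np.ix_(idx, np.where(obs)[0])] - mu[obs]).T).T
            out[np.ix_(idx, np.where(mis)[0])] = mu[mis] + t @ W[mis].T
        return out

    def summary(self) -> str:
        lines = [
            "Probabilistic PCA (EM, missing data as latent)",
            f"  components (k) : {self.k}",
            f"  sigma^2        : {self.sigma2:.6g}",
            f"  log-likelihood : {self.loglik:.6g}",
            f"  iterations     : {self.n_iter} ({self.stopping_rule})",
            f"  converged      : {self.converged}",
        ]
        return "\n".join(lines)


class PPCA:
    """Probabilistic principal component analysis fitted by EM.

    The model is ``x = mu + W t + e`` with ``t ~ N(0, I_k)`` and isotropic
    noise ``e ~ N(0, sigma^2 I)``.  Missing entries are handled exactly by
    treating them as latent in the E-step, so the observed-data
    log-likelihood is non-decreasing across iterations.

    Parameters
    ----------
    data : SymptomDataset or ndarray
        Scores with NaN marking missing entries.
    k : int, optional
        Number of components.  Default: the smallest k whose leading
        eigenvalues of the pairwise-complete covariance capture >= 80% of
        the total variance, capped at min(10, M-1).
    """

    def __init__(self, data: SymptomDataset | np.ndarray, k: int | None = None):
        if isinstance(data, SymptomDataset):
            self.item_labels: list[str] | None = data.labels
            X = data.scores
        else:
            self.item_labels = None
            X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be 2-D")
        n, m = X.shape
        n_obs = (~np.isnan(X)).sum(axis=0)
        if (n_obs < 2).any():
            bad = [int(j) for j in np.where(n_obs < 2)[0]]
            raise ValueError(f"columns with < 2 observed values: {bad}")
        self.X = X
        self.n, self.m = n, m
        self.k = self._choose_rank() if k is None else int(k)
        if not 1 <= self.k <= m - 1:
            raise ValueError(f"k must satisfy 1 <= k <= M-1 = {m - 1}")

    def _choose_rank(self, target: float = 0.8) -> int:
        """Pilot rank: eigenvalues of the pairwise-complete covariance."""
        df = np.ma.masked_invalid(self.X)
        cov = np.ma.cov(df, rowvar=False, allow_masked=True).filled(0.0)
        vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        vals = np.clip(vals, 0.0, None)
        total = vals.sum()
        if total <= 0:
            return 1
        frac = np.cumsum(vals) / total
        k = int(np.searchsorted(frac, target) + 1)
        return max(1, min(k, 10, self.m - 1))

    # -- EM ------------------------------------------------------------
    def fit(
        self, tol: float = 1e-6, max_iter: int = 500, seed: int = 0
    ) -> PPCAResults:
        """Run EM until the relative log-likelihood change drops below
        ``tol`` or ``max_iter`` is reached (non-convergence only warns)."""
        X, n, m, k = self.X, self.n, self.m, self.k
        mask = ~np.isnan(X)
        groups = _group_by_pattern(mask)

        rng = np.random.default_rng(seed)
        col_mean = np.nanmean(X, axis=0)
        filled = np.where(mask, X, col_mean)
        mu = col_mean.copy()
        centered = filled - mu
        # SVD init plus a seeded jitter to break exact-degeneracy ties
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        scale = s[:k] / np.sqrt(max(n - 1, 1))
        W = (vt[:k].T * scale) + 1e-4 * rng.standard_normal((m, k))
        resid_var = float(np.sum(s[k:] ** 2) / max((n - 1) * m, 1))
        sigma2 = max(resid_var, 1e-3)

        trace: list[float] = []
        rule = "max_iter"
        converged = False
        prev = -np.inf
        for _ in range(max_iter):
            mu, W, sigma2 = self._em_step(X, groups, mu, W, sigma2)
            ll = self._observed_loglik(X, groups, mu, W, sigma2)
            trace.append(ll)
            if np.isfinite(prev):
                rel = abs(ll - prev) / max(abs(prev), 1.0)
                if rel < tol:
                    rule, converged = "tol", True
                    break
            prev = ll

        if not converged:
            warnings.warn(
                f"pPCA EM did not converge within {max_iter} iterations "
                f"(last log-likelihood {trace[-1]:.6g})",
                UserWarning,
                stacklevel=2,
            )
        return PPCAResults(
            mean=mu,
            loadings=W,
            sigma2=float(sigma2),
            k=k,
            loglik_trace=np.asarray(trace),
            converged=converged,
            stopping_rule=rule,
            item_labels=self.item_labels,
        )

    @staticmethod
    def _em_step(X, groups, mu, W, sigma2):
        """One exact EM step.

        Latent variables: the factor scores t and the missing entries x_m.
        The M-step regresses E[x] on [1, t] jointly (closed form), then
        updates sigma^2 from the expected residual sum of squares.
        """
        n, m = X.shape
        k = W.shape[1]
        Ik = np.eye(k)

        Sxz = np.zeros((m, k + 1))   # [sum E[x], sum E[x t']]
        Szz = np.zeros((k + 1, k + 1))
        Sx2 = np.zeros(m)            # sum_j E[x_j^2]

        for key, idx in groups.items():
            obs = np.frombuffer(key, dtype=bool)
            mis = ~obs
            oi = np.where(obs)[0]
            mi = np.where(mis)[0]
            r = len(idx)
            Xo = X[np.ix_(idx, oi)]
            Wo, Wm = W[oi], W[mi]

            Mmat = Wo.T @ Wo + sigma2 * Ik
            c, low = cho_factor(Mmat)
            T = cho_solve((c, low), Wo.T @ (Xo - mu[oi]).T).T      # (r, k)
            St = sigma2 * cho_solve((c, low), Ik)                  # posterior cov of t

            Ett = T.T @ T + r * St

            Szz[0, 0] += r
            tsum = T.sum(axis=0)
            Szz[0, 1:] += tsum
            Szz[1:, 0] += tsum
            Szz[1:, 1:] += Ett

            # observed coordinates
            Sxz[oi, 0] += Xo.sum(axis=0)
            Sxz[np.ix_(oi, np.arange(1, k + 1))] += Xo.T @ T
            Sx2[oi] += (Xo**2).sum(axis=0)

            if mi.size:
                Exm = mu[mi] + T @ Wm.T                            # (r, |m|)
                Sxz[mi, 0] += Exm.sum(axis=0)
                # E[x_m t'] = E[x_m] E[t]' + Cov(x_m, t) = Exm' T + r Wm St
                Sxz[np.ix_(mi, np.arange(1, k + 1))] += Exm.T @ T + r * (Wm @ St)
                var_m = np.einsum("ij,jk,ik->i", Wm, St, Wm) + sigma2
                Sx2[mi] += (Exm**2).sum(axis=0) + r * var_m

        C = np.linalg.solve(Szz, Sxz.T).T          # (m, k+1): [mu_new | W_new]
        mu_new = C[:, 0]
        W_new = C[:, 1:]
        # E||x - C z||^2 = sum_j (E[x_j^2] - c_j' Sxz_j)   since C = Sxz Szz^{-1}
        rss = float(np.sum(Sx2) - np.sum(C * Sxz))
        sigma2_new = max(rss / (n * m), _SIGMA2_FLOOR)
        return mu_new, W_new, sigma2_new

    @staticmethod
    def _observed_loglik(X, groups, mu, W, sigma2):
        """Observed-data log-likelihood: x_o ~ N(mu_o, W_o W_o' + sigma^2 I)."""
        ll = 0.0
        for key, idx in groups.items():
            obs = np.frombuffer(key, dtype=bool)
            oi = np.where(obs)[0]
            if oi.size == 0:
                continue
            Xo = X[np.ix_(idx, oi)] - mu[oi]
            Cov = W[oi] @ W[oi].T + sigma2 * np.eye(oi.size)
            c, low = cho_factor(Cov)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            quad = float(np.sum(Xo * cho_solve((c, low), Xo.T).T))
            r = len(idx)
            ll -= 0.5 * (r * (oi.size * np.log(2 * np.pi) + logdet) + quad)
        return ll


def fit_ppca_em(
    ds: SymptomDataset | np.ndarray,
    k: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> PPCAResults:
    """Functional wrapper around ``PPCA(ds, k).fit(...)``."""
    return PPCA(ds, k=k).fit(tol=tol, max_iter=max_iter, seed=seed)


def impute(ds: SymptomDataset, model: PPCAResults) -> SymptomDataset:
    """Replace missing entries with conditional expectations under ``model``.

    Observed entries are untouched; the output has no missing values.
    Raises if the model was fitted on a different item set.
    """
    if model.item_labels is not None and model.item_labels != ds.labels:
        raise ValueError(
            "model was fitted on a different item set than the dataset"
        )
    if model.item_labels is None and len(model.mean) != ds.n_items:
        raise ValueError(
            f"model dimension {len(model.mean)} != dataset items {ds.n_items}"
        )
    out = ds.copy()
    if not ds.is_complete:
        out.scores = model.conditional_expectation(ds.scores)
    return out


# ---------------------------------------------------------------------------
# quantile normalization and orientation
# ---------------------------------------------------------------------------

def blom_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one column.

    Uses Blom plotting positions (rank - 3/8)/(n + 1/4) with average ranks
    for ties; a constant column maps to all zeros (with a warning upstream).
    """
    n = len(x)
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.375) / (n + 0.25))


def quantile_normalize(ds: SymptomDataset) -> SymptomDataset:
    """Per-item rank-based quantile normalization to z-scores.

    Each column is independently mapped to the standard-normal quantiles of
    its Blom plotting positions; the within-column rank order is preserved.
    Requires complete data (impute first).
    """
    if not ds.is_complete:
        raise ValueError("quantile_normalize requires complete data; impute first")
    out = ds.copy()
    for j, it in enumerate(ds.items):
        col = ds.scores[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"item {it.label!r} is constant; normalized to all zeros",
                UserWarning,
                stacklevel=2,
            )
            out.scores[:, j] = 0.0
        else:
            out.scores[:, j] = blom_scores(col)
    return out


def orient_items(ds: SymptomDataset) -> SymptomDataset:
    """Negate higher-is-better columns so higher always means worse.

    Applied after normalization, a sign flip is equivalent to inverting the
    raw scores before the rank-symmetric transform.  Metadata polarity is
    updated, so a second application is the identity on oriented data
    (negation itself is an involution on the scores).
    """
    out = ds.copy()
    for j, it in enumerate(ds.items):
        if it.polarity == "higher_is_better":
            out.scores[:, j] = -out.scores[:, j]
            out.items[j] = it.inverted()
    return out


# ---------------------------------------------------------------------------
# convenience chain
# ---------------------------------------------------------------------------

def preprocess(
    ds: SymptomDataset,
    row_max: float = 0.3,
    col_max: float = 0.3,
    k: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[SymptomDataset, dict]:
    """Filter -> impute -> quantile-normalize -> orient, with provenance.

    Returns the cleaned dataset and a provenance dict recording dropped
    rows/items, the pPCA rank and convergence status, and the seed.
    """
    filtered = filter_missing(ds, row_max=row_max, col_max=col_max)
    dropped_items = [l for l in ds.labels if l not in set(filtered.labels)]
    prov: dict = {
        "cohort_id": ds.cohort_id,
        "n_subjects_in": ds.n_subjects,
        "n_subjects_kept": filtered.n_subjects,
        "dropped_items": dropped_items,
        "row_max": row_max,
        "col_max": col_max,
        "seed": seed,
    }
    if filtered.is_complete:
        prov["ppca"] = None
        complete = filtered
    else:
        model = PPCA(filtered, k=k).fit(tol=tol, max_iter=max_iter, seed=seed)
        complete = impute(filtered, model)
        prov["ppca"] = {
            "k": model.k,
            "sigma2": model.sigma2,
            "n_iter": model.n_iter,
            "converged": model.converged,
            "stopping_rule": model.stopping_rule,
        }
    normalized = quantile_normalize(complete)
    oriented = orient_items(normalized)
    return oriented, prov
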