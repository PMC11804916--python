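"""Between-group network comparison and scale-total group contrasts.

The permutation network-comparison test rebuilds each group's thresholded
correlation network under random relabelings of subjects and compares the
groups on global strength S = |GS(A) - GS(B)|.  Preprocessing (filtering,
imputation, normalization) is done once on the pooled data; only the group
labels are permuted.  Scale totals per clinical domain are contrasted with
one-way ANOVA and partial eta squared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .data import SymptomDataset
from .network import global_strength, network_density

__all__ = [
    "NCTResult",
    "NetworkComparisonTest",
    "nct_global_strength",
    "GroupComparisonResult",
    "oneway_anova_eta",
    "split_by_item",
    "total_scores",
]


# ---------------------------------------------------------------------------
# group splitting
# ---------------------------------------------------------------------------

def split_by_item(
    ds: SymptomDataset, item_label: str, cutoff: float = 0.0
) -> tuple[SymptomDataset, SymptomDataset]:
    """Split subjects by endorsement of one raw item.

    Subjects with a score strictly above ``cutoff`` form the first
    (endorsing, worry+) group; the rest form the second (worry-) group.
    The splitting item is removed from both outputs (its variance is
    truncated by the split, which would degrade the within-group networks).
    Subjects missing the splitting item are dropped with a warning.
    Raises if either group ends up empty.
    """
    if item_label not in ds.labels:
        raise KeyError(f"item {item_label!r} not in dataset")
    col = ds.column(item_label)
    known = ~np.isnan(col)
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} subject(s) missing {item_label!r} "
            "were dropped before the split",
            UserWarning,
            stacklevel=2,
        )
    plus_idx = np.where(known & (col > cutoff))[0]
    minus_idx = np.where(known & (col <= cutoff))[0]
    if plus_idx.size == 0 or minus_idx.size == 0:
        raise ValueError(
            f"degenerate split on {item_label!r} at cutoff {cutoff}: "
            f"{plus_idx.size} endorsing vs {minus_idx.size} non-endorsing"
        )
    plus = ds.select_subjects(plus_idx).drop_items([item_label])
    minus = ds.select_subjects(minus_idx).drop_items([item_label])
    plus.cohort_id = f"{ds.cohort_id}_worry_plus"
    minus.cohort_id = f"{ds.cohort_id}_worry_minus"
    return plus, minus


# ---------------------------------------------------------------------------
# permutation network-comparison test
# ---------------------------------------------------------------------------

@dataclass
class NCTResult:
    """Outcome of the global-strength permutation test.

    p follows the plus-one permutation estimator
    p = (1 + #{S_perm >= S_obs}) / (1 + n_perm), so it is never exactly 0.
    """

    s_obs: float
    p_value: float
    n_perm: int
    density_a: float
    density_b: float
    seed: int
    n_a: int
    n_b: int
    gs_a: float
    gs_b: float
    null_distribution: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "Network comparison test on global strength",
            f"  groups          : n={self.n_a} vs n={self.n_b}",
            f"  global strength : {self.gs_a:.3f} vs {self.gs_b:.3f}",
            f"  density         : {self.density_a:.3f} vs {self.density_b:.3f}",
            f"  S (|difference|): {self.s_obs:.3f}",
            f"  permutation p   : {self.p_value:.4f}  ({self.n_perm} permutations)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "s_obs": self.s_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "density_a": self.density_a,
            "density_b": self.density_b,
            "gs_a": self.gs_a,
            "gs_b": self.gs_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _thresholded_corr(X: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    """Correlation matrix -> thresholded weights; constant columns give
    zero-valued (edgeless) rows rather than NaNs, which can arise under
    permutation of near-constant items."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    if mode == "absolute":
        corr[np.abs(corr) < threshold] = 0.0
    else:
        corr[corr < threshold] = 0.0
    return corr


class NetworkComparisonTest:
    """Permutation test comparing two groups' networks on global strength.

    Parameters
    ----------
    a, b : SymptomDataset
        Preprocessed (complete, normalized) datasets on the same item set.
        Preprocessing must have been performed once on the pooled data so
        that permuting group labels is exchangeable under the null.
    threshold : float
        Correlation threshold used to rebuild each group's network.
    mode : str
        ``"absolute"`` or ``"signed"`` thresholding.

    Notes
    -----
    Both observed and permuted networks keep all items (isolated nodes are
    not dropped), so density is always measured against the same M(M-1)/2
    denominator.
    """

    def __init__(
        self,
        a: SymptomDataset,
        b: SymptomDataset,
        threshold: float = 0.2,
        mode: str = "absolute",
    ):
        if a.labels != b.labels:
            raise ValueError("groups must share an identical item set")
        if not (a.is_complete and b.is_complete):
            raise ValueError("NCT requires complete (imputed) data")
        if a.n_subjects < 10 or b.n_subjects < 10:
            raise ValueError(
                f"groups too small for a permutation test "
                f"(n={a.n_subjects} and n={b.n_subjects}; need >= 10 each)"
            )
        self.a, self.b = a, b
        self.threshold = threshold
        self.mode = mode

    def fit(
        self, n_perm: int = 1000, seed: int = 0, keep_null: bool = False
    ) -> NCTResult:
        if n_perm < 100:
            warnings.warn(
                f"n_perm={n_perm} gives a coarse p-value resolution",
                UserWarning,
                stacklevel=2,
            )
        # canonical pooled order makes the permutation null (and hence p)
        # invariant under swapping the two arguments
        key_a = (self.a.n_subjects, self.a.scores.tobytes())
        key_b = (self.b.n_subjects, self.b.scores.tobytes())
        first, second = (self.a, self.b) if key_a <= key_b else (self.b, self.a)
        na, nb = first.n_subjects, second.n_subjects
        pooled = np.vstack([first.scores, second.scores])

        wa = _thresholded_corr(self.a.scores, self.threshold, self.mode)
        wb = _thresholded_corr(self.b.scores, self.threshold, self.mode)
        gs_a, gs_b = global_strength(wa), global_strength(wb)
        s_obs = abs(gs_a - gs_b)

        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        n = na + nb
        for i in range(n_perm):
            perm = rng.permutation(n)
            xa = pooled[perm[:na]]
            xb = pooled[perm[na:]]
            sa = global_strength(_thresholded_corr(xa, self.threshold, self.mode))
            sb = global_strength(_thresholded_corr(xb, self.threshold, self.mode))
            null[i] = abs(sa - sb)

        p = (1 + int(np.sum(null >= s_obs - 1e-12))) / (1 + n_perm)
        return NCTResult(
            s_obs=float(s_obs),
            p_value=float(p),
            n_perm=n_perm,
            density_a=network_density(wa),
            density_b=network_density(wb),
            seed=seed,
            n_a=self.a.n_subjects,
            n_b=self.b.n_subjects,
            gs_a=float(gs_a),
            gs_b=float(gs_b),
            null_distribution=null if keep_null else None,
        )


def nct_global_strength(
    a: SymptomDataset,
    b: SymptomDataset,
    threshold: float = 0.2,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "absolute",
) -> NCTResult:
    """Functional wrapper around ``NetworkComparisonTest(a, b, ...).fit()``."""
    return NetworkComparisonTest(a, b, threshold=threshold, mode=mode).fit(
        n_perm=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# scale-total contrasts
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """One-way fixed-effects ANOVA with partial eta squared."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    eta_p2: float

    def summary(self) -> str:
        return (
            f"F({self.df_between},{self.df_within}) = {self.f_stat:.2f}, "
            f"P = {self.p_value:.4g}, eta_p^2 = {self.eta_p2:.3f}"
        )


def oneway_anova_eta(groups: list[np.ndarray]) -> GroupComparisonResult:
    """One-way ANOVA F, dfs, p, and partial eta squared
    SS_between / (SS_between + SS_within)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError(
                "F undefined: zero within-group variance with equal means"
            )
        return GroupComparisonResult(np.inf, df_b, df_w, 0.0,
                                     ss_between / (ss_between + ss_within))
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return GroupComparisonResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        eta_p2=ss_between / (ss_between + ss_within),
    )


def total_scores(
    ds: SymptomDataset, domain: str, exclude: str | None = None
) -> np.ndarray:
    """Per-subject sum over a domain's items (post-orientation z-scores).

    ``exclude`` drops the splitting item from its own domain's total."""
    labels = [
        it.label
        for it in ds.items
        if it.domain == domain and it.label != exclude
    ]
    if not labels:
        raise ValueError(f"no items in domain {domain!r}")
    cols = [ds.labels.index(l) for l in labels]
    return ds.scores[:, cols].sum(axis=1)
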