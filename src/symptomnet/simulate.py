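"""Synthetic multi-cohort symptom data with a latent-factor module structure.

The generator emulates the statistical structure that the network pipeline
assumes in real poststroke cohorts: items load on latent domain factors
(depression, anxiety, apathy, fatigue, cognition, ADL), the factors are
correlated, one "worry" item cross-loads on every factor (the bridge
symptom), items are binary, likert or continuous, and entries go missing
completely at random.

The measurement model for subject ``i`` and item ``j`` is

    x_ij = lambda_j' f_i + noise_sd * e_ij,
    f_i ~ N(0, Phi_s),   e_ij ~ N(0, 1),

where ``Phi_s`` is the factor correlation matrix with its off-diagonal
scaled by ``connectivity_scale`` (the knob that makes worry+ style groups
more densely connected than worry- style groups).  Binary and likert items
are discretized at fixed population quantiles of the item's normal marginal
so the latent ordering survives, attenuated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtri

from .data import SymptomDataset
from .items import ItemSpec, check_unique_labels

#: Latent domain factors, in loading-vector order.
FACTORS = ("depression", "anxiety", "apathy", "fatigue", "cognition", "adl")

_PSD_TOL = 1e-8


@dataclass
class CohortSpec:
    """Generating recipe for one synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Number of rows to draw.
    items : list of ItemSpec
        Item catalog; each item must carry a ``loadings`` tuple with one
        entry per latent factor.
    factor_correlations : ndarray, shape (k, k)
        Latent factor correlation matrix (unit diagonal, PSD).
    noise_sd : float
        Standard deviation of the item-specific Gaussian noise.
    missing_rate : float
        MCAR missingness probability per entry (default 0.05; keep < 0.3
        so the >30% missingness filter does not annihilate the data).
    connectivity_scale : float
        Multiplier on the off-diagonal factor correlations; > 1 densifies,
        < 1 sparsifies, the between-module item correlations.
    seed : int
        Seed for all randomness.
    cohort_id : str
        Label carried into the output dataset.
    """

    n_subjects: int
    items: list[ItemSpec]
    factor_correlations: np.ndarray
    noise_sd: float = 0.7
    missing_rate: float = 0.05
    connectivity_scale: float = 1.0
    seed: int = 0
    cohort_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        self.items = list(self.items)
        check_unique_labels(self.items)
        self.factor_correlations = np.asarray(self.factor_correlations, dtype=float)
        phi = self.factor_correlations
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ValueError("factor_correlations must be square")
        if not np.allclose(phi, phi.T, atol=1e-10):
            raise ValueError("factor_correlations must be symmetric")
        if not np.allclose(np.diag(phi), 1.0, atol=1e-10):
            raise ValueError("factor_correlations must have a unit diagonal")
        lo = np.linalg.eigvalsh(phi).min()
        if lo < -_PSD_TOL:
            raise ValueError(
                f"factor_correlations is not positive semidefinite "
                f"(smallest eigenvalue {lo:.3g})"
            )
        k = phi.shape[0]
        for it in self.items:
            if it.loadings is None:
                raise ValueError(f"item {it.label!r} has no factor loadings")
            if len(it.loadings) != k:
                raise ValueError(
                    f"item {it.label!r} has {len(it.loadings)} loadings "
                    f"for {k} factors"
                )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_rate >= 0.3:
            warnings.warn(
                "missing_rate >= 0.3 interacts badly with the 30% missingness "
                "filter; expect heavy row/column loss",
                UserWarning,
                stacklevel=2,
            )
        if self.connectivity_scale <= 0:
            raise ValueError("connectivity_scale must be positive")

    @property
    def n_factors(self) -> int:
        return self.factor_correlations.shape[0]

    @property
    def loading_matrix(self) -> np.ndarray:
        """Items-by-factors loading matrix Lambda."""
        return np.array([it.loadings for it in self.items], dtype=float)

    def scaled_factor_correlations(self) -> np.ndarray:
        """Phi with off-diagonal entries multiplied by connectivity_scale.

        Raises if the scaled matrix loses positive semidefiniteness.
        """
        phi = self.factor_correlations.copy()
        off = ~np.eye(phi.shape[0], dtype=bool)
        phi[off] *= self.connectivity_scale
        lo = np.linalg.eigvalsh(phi).min()
        if lo < -_PSD_TOL:
            raise ValueError(
                f"factor correlations are not positive semidefinite after "
                f"connectivity_scale={self.connectivity_scale:g} "
                f"(smallest eigenvalue {lo:.3g})"
            )
        return phi


# ---------------------------------------------------------------------------
# closed-form moments
# ---------------------------------------------------------------------------

def model_implied_covariance(spec: CohortSpec) -> np.ndarray:
    """Covariance of the continuous item scores: Lambda Phi_s Lambda' + noise_sd^2 I."""
    lam = spec.loading_matrix
    phi = spec.scaled_factor_correlations()
    return lam @ phi @ lam.T + spec.noise_sd**2 * np.eye(len(spec.items))


def model_implied_correlation(spec: CohortSpec) -> np.ndarray:
    """Model-implied item correlation matrix (continuous scale, before any
    binary/likert discretization, which only attenuates it)."""
    cov = model_implied_covariance(spec)
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, item: ItemSpec, item_sd: float) -> np.ndarray:
    """Cut a continuous score at fixed population quantiles.

    Binary items are median-split (threshold 0 for the symmetric latent
    score); likert items with k levels are cut at the k-1 equally spaced
    normal quantiles of the item's marginal.
    """
    if item.response_type == "continuous":
        return x
    if item.response_type == "binary":
        return (x > 0.0).astype(float)
    k = int(item.likert_levels)  # type: ignore[arg-type]
    cuts = ndtri(np.arange(1, k) / k) * item_sd
    return np.searchsorted(cuts, x, side="right").astype(float)


def generate_cohort(spec: CohortSpec) -> SymptomDataset:
    """Draw one cohort from the latent-factor measurement model.

    Fully reproducible for a fixed ``spec.seed``: the factor draws, the
    noise, and the MCAR mask each consume the generator in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    phi = spec.scaled_factor_correlations()
    lam = spec.loading_matrix
    n, m = spec.n_subjects, len(spec.items)

    # eigh-based square root: robust to the PSD boundary (e.g. scale -> 0)
    w, v = np.linalg.eigh(phi)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    factors = rng.standard_normal((n, spec.n_factors)) @ root.T
    noise = rng.standard_normal((n, m)) * spec.noise_sd
    latent = factors @ lam.T + noise

    cov = model_implied_covariance(spec)
    sds = np.sqrt(np.diag(cov))
    scores = np.empty_like(latent)
    for j, it in enumerate(spec.items):
        scores[:, j] = _discretize(latent[:, j], it, sds[j])

    if spec.missing_rate > 0:
        holes = rng.random((n, m)) < spec.missing_rate
        scores[holes] = np.nan

    return SymptomDataset(scores, list(spec.items), spec.cohort_id)


def make_two_group_dataset(
    base: CohortSpec,
    hub_label: str,
    dense_scale: float = 1.0,
    sparse_scale: float = 0.4,
) -> tuple[SymptomDataset, SymptomDataset]:
    """Generate a worry+-like (dense) and a worry--like (sparse) cohort pair.

    Both groups share the item catalog; they differ only in how strongly
    the latent factors intercorrelate (``connectivity_scale``).  The hub
    item is guaranteed nonzero loadings on every factor in both groups
    (zero entries are filled with a 0.25 cross-loading), so it bridges all
    modules the way worry does in poststroke symptom networks.

    Returns ``(dense, sparse)``.  ``dense_scale`` must be >= ``sparse_scale``
    (equality gives the null configuration with identical generating
    covariances).
    """
    labels = [it.label for it in base.items]
    if hub_label not in labels:
        raise KeyError(f"hub item {hub_label!r} not in the item catalog")
    if dense_scale < sparse_scale:
        raise ValueError("dense_scale must be >= sparse_scale")

    items = list(base.items)
    j = labels.index(hub_label)
    hub = items[j]
    loadings = tuple(
        l if l != 0.0 else 0.25 for l in (hub.loadings or ())
    )
    items[j] = replace(hub, loadings=loadings, worry=True)

    dense = replace(
        base,
        items=list(items),
        connectivity_scale=dense_scale,
        seed=base.seed,
        cohort_id=f"{base.cohort_id}_worry_plus",
    )
    sparse = replace(
        base,
        items=list(items),
        connectivity_scale=sparse_scale,
        seed=base.seed + 1,
        cohort_id=f"{base.cohort_id}_worry_minus",
    )
    return generate_cohort(dense), generate_cohort(sparse)


# ---------------------------------------------------------------------------
# default catalog
# ---------------------------------------------------------------------------

def _load(factor: str, value: float, cross: dict[str, float] | None = None) -> tuple[float, ...]:
    v = dict.fromkeys(FACTORS, 0.0)
    v[factor] = value
    if cross:
        v.update(cross)
    return tuple(v[f] for f in FACTORS)


def default_item_catalog() -> list[ItemSpec]:
    """A realistic 23-item catalog spanning the six domains.

    Depression/anxiety items are yes-no (GDS-style), apathy and fatigue
    items are ordinal (HAM-D/fatigue-scale-style), cognition is continuous
    (harmonized domain scores, higher = better), ADL items are ordinal
    function ratings (higher = more independent).  The worry item
    cross-loads on every factor: it is the designed bridge symptom.
    """
    dep = lambda lbl: ItemSpec(lbl, "depression", "higher_is_worse", "binary",
                               loadings=_load("depression", 0.7))
    cat = [
        dep("sad_mood"),
        dep("hopelessness"),
        dep("worthlessness"),
        dep("anhedonia"),
        dep("low_energy"),
        ItemSpec(
            "worry", "anxiety", "higher_is_worse", "binary",
            loadings=_load(
                "anxiety", 0.55,
                {"depression": 0.30, "apathy": 0.25, "fatigue": 0.25,
                 "cognition": 0.25, "adl": 0.25},
            ),
            worry=True,
        ),
        ItemSpec("tension", "anxiety", "higher_is_worse", "binary",
                 loadings=_load("anxiety", 0.7)),
        ItemSpec("fearfulness", "anxiety", "higher_is_worse", "binary",
                 loadings=_load("anxiety", 0.7)),
        ItemSpec("loss_of_interest", "apathy", "higher_is_worse", "likert", 4,
                 loadings=_load("apathy", 0.7)),
        ItemSpec("reduced_initiative", "apathy", "higher_is_worse", "likert", 4,
                 loadings=_load("apathy", 0.7)),
        ItemSpec("emotional_blunting", "apathy", "higher_is_worse", "likert", 4,
                 loadings=_load("apathy", 0.7)),
        ItemSpec("physical_fatigue", "fatigue", "higher_is_worse", "likert", 7,
                 loadings=_load("fatigue", 0.7)),
        ItemSpec("mental_fatigue", "fatigue", "higher_is_worse", "likert", 7,
                 loadings=_load("fatigue", 0.7)),
        ItemSpec("reduced_activity", "fatigue", "higher_is_worse", "likert", 7,
                 loadings=_load("fatigue", 0.7)),
        ItemSpec("memory", "cognition", "higher_is_better", "continuous",
                 loadings=_load("cognition", -0.7)),
        ItemSpec("executive_function", "cognition", "higher_is_better", "continuous",
                 loadings=_load("cognition", -0.7)),
        ItemSpec("language", "cognition", "higher_is_better", "continuous",
                 loadings=_load("cognition", -0.7)),
        ItemSpec("attention", "cognition", "higher_is_better", "continuous",
                 loadings=_load("cognition", -0.7)),
        ItemSpec("verbal_fluency", "cognition", "higher_is_better", "continuous",
                 loadings=_load("cognition", -0.7)),
        ItemSpec("self_care", "adl", "higher_is_better", "likert", 5,
                 loadings=_load("adl", -0.7)),
        ItemSpec("mobility", "adl", "higher_is_better", "likert", 5,
                 loadings=_load("adl", -0.7)),
        ItemSpec("household_tasks", "adl", "higher_is_better", "likert", 5,
                 loadings=_load("adl", -0.7)),
        ItemSpec("instrumental_adl", "adl", "higher_is_better", "likert", 5,
                 loadings=_load("adl", -0.7)),
    ]
    check_unique_labels(cat)
    return cat


def default_factor_correlations(
    psych: float = 0.3, cognition: float = 0.15
) -> np.ndarray:
    """Moderate correlations among the psychiatric factors, weaker ones
    involving cognition and ADL; unit diagonal."""
    k = len(FACTORS)
    phi = np.full((k, k), psych)
    for f in ("cognition", "adl"):
        i = FACTORS.index(f)
        phi[i, :] = cognition
        phi[:, i] = cognition
    phi[np.diag_indices(k)] = 1.0
    lo = np.linalg.eigvalsh(phi).min()
    if lo < -_PSD_TOL:  # pragma: no cover - defaults are safe
        raise ValueError(f"default factor correlations not PSD ({lo:.3g})")
    return phi


def worry_contrast_spec(
    n_subjects: int = 400,
    seed: int = 0,
    missing_rate: float = 0.0,
    cohort_id: str = "contrast",
) -> CohortSpec:
    """Base spec for worry+/worry- style two-group simulations.

    Uniform factor correlations of 0.35 make the between-module item
    correlations straddle the |r| = 0.2 network threshold when the
    off-diagonal is left at full strength (dense, worry+-like) versus
    scaled by 0.4 (sparse, worry--like), reproducing the observed
    dense-vs-sparse density ordering (approx. 0.23 vs 0.12 at the default
    catalog and n = 400 per group).
    """
    k = len(FACTORS)
    phi = np.full((k, k), 0.35)
    phi[np.diag_indices(k)] = 1.0
    return CohortSpec(
        n_subjects=n_subjects,
        items=default_item_catalog(),
        factor_correlations=phi,
        noise_sd=0.7,
        missing_rate=missing_rate,
        connectivity_scale=1.0,
        seed=seed,
        cohort_id=cohort_id,
    )


def default_cohort_spec(
    n_subjects: int = 500,
    seed: int = 0,
    missing_rate: float = 0.05,
    connectivity_scale: float = 1.0,
    cohort_id: str = "synthetic",
) -> CohortSpec:
    """Convenience spec with the default catalog and factor correlations.

    The worry item's sign convention: cognition/ADL loadings in the catalog
    are negative (higher = better), so positive factor correlations still
    produce the positive symptom-impairment associations seen after
    polarity inversion.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        items=default_item_catalog(),
        factor_correlations=default_factor_correlations(),
        noise_sd=0.7,
        missing_rate=missing_rate,
        connectivity_scale=connectivity_scale,
        seed=seed,
        cohort_id=cohort_id,
    )
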