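"""End-to-end orchestration: per-cohort runs, subgroup runs, worry contrast.

Every run executes the same chain — missingness filter, pPCA imputation,
quantile normalization, polarity inversion, correlation network,
|r| >= 0.2 threshold, isolated-node removal, spectral communities at
gamma = 0.4, and the three centrality measures — and records provenance so
each reported number is recomputable from the persisted intermediates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .centrality import (
    MEASURES,
    CentralityProfile,
    ModulePartition,
    UndefinedConsistencyError,
    centrality_consistency,
    newman_spectral_communities,
    top_items,
)
from .compare import (
    GroupComparisonResult,
    NCTResult,
    NetworkComparisonTest,
    oneway_anova_eta,
    split_by_item,
    total_scores,
)
from .data import SymptomDataset
from .network import (
    SymptomNetwork,
    build_network,
    drop_isolated_nodes,
    global_strength,
    network_density,
    write_network,
)
from .preprocess import preprocess

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, with the published defaults
    (|r| threshold 0.2, resolution gamma 0.4, 30% missingness bounds)."""

    threshold: float = 0.2
    gamma: float = 0.4
    row_max: float = 0.3
    col_max: float = 0.3
    ppca_k: int | None = None      # None = auto (>= 80% pilot variance)
    n_perm: int = 1000
    seed: int = 0
    worry_item: str | None = None
    worry_cutoff: float = 0.0
    subgroup_column: str | None = None
    min_cohort_size: int = 20
    min_group_size: int = 10
    threshold_mode: str = "absolute"   # or "signed": zero all r < threshold
    negative_edges: str = "absolute"   # or "discard" in graph measures
    top_k: int = 3
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(payload) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class CohortReport:
    """Everything the pipeline computed for one cohort (or subgroup)."""

    cohort_id: str
    provenance: dict
    n_subjects: int
    n_items: int
    dropped_isolated: list[str]
    density: float
    global_strength: float
    partition: ModulePartition
    centrality: CentralityProfile
    hubs: dict[str, list[str]]
    network: SymptomNetwork

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "provenance": self.provenance,
            "n_subjects": self.n_subjects,
            "n_items": self.n_items,
            "dropped_isolated": self.dropped_isolated,
            "density": self.density,
            "global_strength": self.global_strength,
            "modularity_q": self.partition.q_score,
            "gamma": self.partition.gamma,
            "n_communities": self.partition.n_communities,
            "assignment": self.partition.assignment.tolist(),
            "hubs": self.hubs,
        }

    def partition_table(self) -> pd.DataFrame:
        """TSV-ready table: item, domain, module id, three centralities."""
        df = self.centrality.to_frame()
        df.insert(1, "domain", [it.domain for it in self.network.items])
        df.insert(2, "module_id", self.partition.assignment)
        return df

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = self.cohort_id or "cohort"
        (out / f"{stem}_report.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.partition_table().to_csv(
            out / f"{stem}_centrality.tsv", sep="\t", index=False
        )
        write_network(
            self.network, out / f"{stem}_edges.tsv", out / f"{stem}_nodes.json"
        )


def _stage(stage: str):
    """Re-raise stage failures with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(stage, str(exc)) from exc
            return False

    return _Ctx()


def run_cohort(config: PipelineConfig, cohort: SymptomDataset) -> CohortReport:
    """Full single-cohort analysis; deterministic given config.seed."""
    with _stage("filter_missing"):
        clean, prov = preprocess(
            cohort,
            row_max=config.row_max,
            col_max=config.col_max,
            k=config.ppca_k,
            seed=config.seed,
        )
        if clean.n_subjects < config.min_cohort_size:
            raise ValueError(
                f"only {clean.n_subjects} subjects survive filtering "
                f"(minimum {config.min_cohort_size})"
            )

    with _stage("network_build"):
        net = build_network(
            clean, threshold=config.threshold, mode=config.threshold_mode
        )
        pruned = drop_isolated_nodes(net)
        dropped = sorted(set(net.labels) - set(pruned.labels))

    with _stage("graph_metrics"):
        partition = newman_spectral_communities(
            pruned, gamma=config.gamma, seed=config.seed,
            negative_edges=config.negative_edges,
        )
        profile = CentralityProfile.from_network(
            pruned, negative_edges=config.negative_edges
        )
        hubs = {
            m: top_items(profile, m, min(config.top_k, pruned.n_items))
            for m in MEASURES
        }

    report = CohortReport(
        cohort_id=cohort.cohort_id,
        provenance=prov,
        n_subjects=clean.n_subjects,
        n_items=pruned.n_items,
        dropped_isolated=dropped,
        density=network_density(pruned),
        global_strength=global_strength(pruned),
        partition=partition,
        centrality=profile,
        hubs=hubs,
        network=pruned,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def run_subgroups(
    config: PipelineConfig, cohort: SymptomDataset, by: str | None = None
) -> tuple[list[CohortReport], dict[str, pd.DataFrame]]:
    """One report per subgroup level plus pairwise centrality consistency.

    Levels with fewer than ``config.min_cohort_size`` subjects are skipped
    with a warning.  The consistency matrices hold the Pearson correlation
    of each centrality measure over shared items (NaN where undefined).
    """
    by = by or config.subgroup_column
    if by is None:
        raise ValueError("no subgroup column configured")
    if cohort.subject_data is None or by not in cohort.subject_data.columns:
        raise ValueError(f"subgroup column {by!r} not found in subject_data")

    levels = list(pd.unique(cohort.subject_data[by].dropna()))
    reports: list[CohortReport] = []
    for level in levels:
        idx = np.where((cohort.subject_data[by] == level).to_numpy())[0]
        if idx.size < config.min_cohort_size:
            warnings.warn(
                f"subgroup {by}={level!r} has only {idx.size} subjects; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        sub = cohort.select_subjects(idx)
        sub.cohort_id = f"{cohort.cohort_id}_{by}_{level}"
        reports.append(run_cohort(config, sub))

    consistency: dict[str, pd.DataFrame] = {}
    names = [r.cohort_id for r in reports]
    for measure in MEASURES:
        mat = pd.DataFrame(np.eye(len(reports)), index=names, columns=names)
        for i in range(len(reports)):
            for j in range(i + 1, len(reports)):
                try:
                    r = centrality_consistency(
                        reports[i].centrality, reports[j].centrality, measure
                    )
                except UndefinedConsistencyError:
                    r = np.nan
                mat.iloc[i, j] = mat.iloc[j, i] = r
        consistency[measure] = mat
    return reports, consistency


@dataclass
class WorryContrastResult:
    """Worry+/worry- analysis: per-group reports, NCT, and domain ANOVAs."""

    nct: NCTResult
    report_plus: CohortReport
    report_minus: CohortReport
    anovas: dict[str, GroupComparisonResult]

    def anova_table(self) -> pd.DataFrame:
        rows = [
            {
                "domain": d,
                "f_stat": r.f_stat,
                "df_between": r.df_between,
                "df_within": r.df_within,
                "p_value": r.p_value,
                "eta_p2": r.eta_p2,
            }
            for d, r in self.anovas.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = [self.nct.summary(), "", "Domain-total contrasts (worry+ vs worry-):"]
        for d, r in self.anovas.items():
            parts.append(f"  {d:<18} {r.summary()}")
        return "\n".join(parts)


def run_worry_contrast(
    config: PipelineConfig, cohort: SymptomDataset
) -> WorryContrastResult:
    """Split by worry endorsement, compare networks and domain totals.

    Pooled preprocessing happens once; the split uses the raw (pre-
    normalization) worry scores, and the worry item is excluded from the
    within-group networks and from its own domain's total.
    """
    if config.worry_item is None:
        raise ValueError("config.worry_item is not set")
    if config.worry_item not in cohort.labels:
        raise ValueError(
            f"worry item {config.worry_item!r} not present in the cohort"
        )

    with _stage("preprocess"):
        clean, prov = preprocess(
            cohort,
            row_max=config.row_max,
            col_max=config.col_max,
            k=config.ppca_k,
            seed=config.seed,
        )
    if config.worry_item not in clean.labels:
        raise PipelineStageError(
            "preprocess", f"worry item {config.worry_item!r} was filtered out"
        )

    # group membership from the raw scores of the surviving subjects
    raw_worry = cohort.column(config.worry_item)
    kept_rows = _surviving_rows(cohort, clean)
    raw_worry = raw_worry[kept_rows]
    known = ~np.isnan(raw_worry)
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} subject(s) missing the worry item were "
            "dropped from the contrast",
            UserWarning,
            stacklevel=2,
        )
    plus_mask = known & (raw_worry > config.worry_cutoff)
    minus_mask = known & (raw_worry <= config.worry_cutoff)
    if plus_mask.sum() == 0 or minus_mask.sum() == 0:
        raise ValueError(
            f"degenerate worry split: {int(plus_mask.sum())} worry+ vs "
            f"{int(minus_mask.sum())} worry-"
        )

    analysis = clean.drop_items([config.worry_item])
    plus = analysis.select_subjects(np.where(plus_mask)[0])
    minus = analysis.select_subjects(np.where(minus_mask)[0])
    plus.cohort_id = f"{cohort.cohort_id}_worry_plus"
    minus.cohort_id = f"{cohort.cohort_id}_worry_minus"

    with _stage("nct"):
        nct = NetworkComparisonTest(
            plus, minus, threshold=config.threshold, mode=config.threshold_mode
        ).fit(n_perm=config.n_perm, seed=config.seed)

    with _stage("group_networks"):
        rep_plus = _report_from_clean(config, plus, prov)
        rep_minus = _report_from_clean(config, minus, prov)

    with _stage("anova"):
        anovas: dict[str, GroupComparisonResult] = {}
        for domain in sorted({it.domain for it in analysis.items}):
            ga = total_scores(plus, domain, exclude=config.worry_item)
            gb = total_scores(minus, domain, exclude=config.worry_item)
            anovas[domain] = oneway_anova_eta([ga, gb])

    result = WorryContrastResult(nct, rep_plus, rep_minus, anovas)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep_plus.write(out)
        rep_minus.write(out)
        nct.write_json(out / f"{cohort.cohort_id}_nct.json")
        result.anova_table().to_csv(
            out / f"{cohort.cohort_id}_anova.tsv", sep="\t", index=False
        )
    return result


def _surviving_rows(raw: SymptomDataset, clean: SymptomDataset) -> np.ndarray:
    """Indices of raw rows that survived filtering (recomputed by rerunning
    the deterministic filter on the missingness mask alone)."""
    from .preprocess import filter_missing

    marker = SymptomDataset(
        np.where(np.isnan(raw.scores), np.nan,
                 np.arange(raw.n_subjects, dtype=float)[:, None]),
        raw.items,
        raw.cohort_id,
    )
    filtered = filter_missing(marker)
    rows = np.nanmax(filtered.scores, axis=1).astype(int)
    if len(rows) != clean.n_subjects:  # pragma: no cover - defensive
        raise RuntimeError("row bookkeeping out of sync with the filter")
    return rows


def _report_from_clean(
    config: PipelineConfig, clean: SymptomDataset, prov: dict
) -> CohortReport:
    """Network + metrics for an already-preprocessed group."""
    net = build_network(clean, threshold=config.threshold, mode=config.threshold_mode)
    pruned = drop_isolated_nodes(net)
    dropped = sorted(set(net.labels) - set(pruned.labels))
    partition = newman_spectral_communities(
        pruned, gamma=config.gamma, seed=config.seed,
        negative_edges=config.negative_edges,
    )
    profile = CentralityProfile.from_network(
        pruned, negative_edges=config.negative_edges
    )
    hubs = {
        m: top_items(profile, m, min(config.top_k, pruned.n_items))
        for m in MEASURES
    }
    return CohortReport(
        cohort_id=clean.cohort_id,
        provenance=dict(prov, group_n=clean.n_subjects),
        n_subjects=clean.n_subjects,
        n_items=pruned.n_items,
        dropped_isolated=dropped,
        density=network_density(pruned),
        global_strength=global_strength(pruned),
        partition=partition,
        centrality=profile,
        hubs=hubs,
        network=pruned,
    )
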