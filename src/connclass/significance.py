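"""Permutation significance, consensus connections and region weights.

The significance of an observed generalization rate is assessed by
re-running the full nested leave-one-out pipeline (feature selection
inside every fold) on label-permuted cohorts; the p-value uses the
add-one estimator p = (#{null GR >= observed} + 1) / (n + 1), which never
returns zero.  Connections selected in every cross-validation fold form
the consensus set; a region's weight is the number of consensus
connections incident to it.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CVResult, PipelineConfig, run_loocv
from .connectome import Cohort, EdgeIndex, RegionAtlas
from .group_stats import group_mean_matrices

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class PermutationResult:
    """Null distribution of the generalization rate under label shuffling."""

    observed_gr: float
    null_grs: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None


def permutation_test(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    exhaustive: bool = False,
    observed: CVResult | None = None,
) -> PermutationResult:
    """Label-permutation test of the LOOCV generalization rate.

    Whole-cohort labels are shuffled and the complete nested pipeline is
    re-run per permutation.  With ``exhaustive`` every distinct label
    assignment (including the identity) is enumerated instead, and the
    p-value is the exact exceedance fraction; this is only sensible for
    very small cohorts.
    """
    config = config or PipelineConfig()
    if observed is None:
        observed = run_loocv(cohort, config)
    obs_gr = observed.generalization_rate
    labels = np.asarray(cohort.labels)
    if exhaustive:
        n = len(labels)
        classes = sorted(set(labels))
        pos = [i for i in range(n) if labels[i] == classes[0]]
        null = []
        with warnings.catch_warnings():
            # p-ceiling advisories are meaningless under shuffled labels
            warnings.simplefilter("ignore", UserWarning)
            for chosen in itertools.combinations(range(n), len(pos)):
                perm = np.array([classes[1]] * n, dtype=object)
                perm[list(chosen)] = classes[0]
                null.append(
                    run_loocv(cohort.relabeled(perm), config).generalization_rate
                )
        null = np.asarray(null)
        p = float(np.sum(null >= obs_gr - 1e-12) / null.size)
        return PermutationResult(obs_gr, null, null.size, p, None)
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    with warnings.catch_warnings():
        # p-ceiling advisories are meaningless under shuffled labels
        warnings.simplefilter("ignore", UserWarning)
        for b in range(n_permutations):
            perm = rng.permutation(labels)
            null[b] = run_loocv(cohort.relabeled(perm), config).generalization_rate
            if (b + 1) % 500 == 0:
                logger.info("permutation %d/%d", b + 1, n_permutations)
    exceed = int(np.sum(null >= obs_gr - 1e-12))
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(obs_gr, null, n_permutations, float(p), seed)


# ---------------------------------------------------------------------------
# Consensus connections
# ---------------------------------------------------------------------------

@dataclass
class ConsensusEdge:
    """One connection selected in every cross-validation fold."""

    position: int  # feature position
    region_a: int  # 1-based, region_a < region_b
    region_b: int
    label_a: str
    label_b: str
    network: str
    subnetwork: str
    mean_p: float  # mean selection p-value across folds
    direction: str  # "increased" / "decreased" in patients


@dataclass
class ConsensusReport:
    edges: list[ConsensusEdge]
    n_regions: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(e.region_a, e.region_b) for e in self.edges]


def load_taxonomy() -> dict[tuple[int, int], tuple[str, str]]:
    """Packaged network/subnetwork tags keyed by 1-based region pair."""
    with resources.files("connclass.data").joinpath("consensus_edges.csv").open() as fh:
        table = pd.read_csv(fh)
    out = {}
    for _, row in table.iterrows():
        a, b = int(row["index_a"]), int(row["index_b"])
        key = (min(a, b), max(a, b))
        sub = row["subnetwork"]
        out[key] = (str(row["network"]), "" if pd.isna(sub) else str(sub))
    return out


def consensus_features(
    cv: CVResult,
    cohort: Cohort,
    atlas: RegionAtlas | None = None,
) -> ConsensusReport:
    """Intersect per-fold selections and annotate the surviving connections.

    The per-edge p-value is the mean of the fold-wise selection p-values;
    the direction compares group mean strengths on the full cohort.  Pairs
    present in the packaged taxonomy keep its network/subnetwork tags;
    other pairs get the lobe-pair tag from the atlas (empty without one).
    """
    if not cv.folds:
        raise ValueError("cross-validation result has no folds")
    atlas = atlas or cohort.atlas
    selections = [set(int(s) for s in f.selected) for f in cv.folds]
    consensus = sorted(set.intersection(*selections))
    edge_index = EdgeIndex(cohort.n_regions)
    mean_pat, mean_con = group_mean_matrices(cohort)
    taxonomy = load_taxonomy() if (
        atlas is not None and atlas.n_regions == cohort.n_regions == 90
    ) else {}
    edges = []
    for pos in consensus:
        i, j = edge_index.pair(pos)
        a, b = i + 1, j + 1
        p_folds = [
            float(f.p_selected[list(f.selected).index(pos)]) for f in cv.folds
        ]
        diff = mean_pat[i, j] - mean_con[i, j]
        if atlas is not None:
            label_a, label_b = atlas.label(a), atlas.label(b)
            lobes = sorted({atlas.lobe(a), atlas.lobe(b)})
            fallback = "-".join(lobes) if len(lobes) > 1 else f"intra-{lobes[0]}"
        else:
            label_a, label_b = f"region {a}", f"region {b}"
            fallback = ""
        network, subnetwork = taxonomy.get((a, b), (fallback, ""))
        edges.append(
            ConsensusEdge(
                position=pos, region_a=a, region_b=b,
                label_a=label_a, label_b=label_b,
                network=network, subnetwork=subnetwork,
                mean_p=float(np.mean(p_folds)),
                direction="increased" if diff > 0 else "decreased",
            )
        )
    return ConsensusReport(edges=edges, n_regions=cohort.n_regions)


def region_weights(report: ConsensusReport) -> dict[int, int]:
    """Incidence count of consensus connections per region (1-based keys).

    Every region appears, including those with weight zero; the weights sum
    to twice the number of consensus connections.
    """
    weights = {r: 0 for r in range(1, report.n_regions + 1)}
    for edge in report.edges:
        weights[edge.region_a] += 1
        weights[edge.region_b] += 1
    return weights


def benchmark_recovery(
    report: ConsensusReport, truth_pairs: list[tuple[int, int]]
) -> dict[str, float]:
    """Recall/precision of the consensus set against implanted edges."""
    truth = {(min(a, b), max(a, b)) for a, b in truth_pairs}
    found = set(report.pairs)
    hits = len(found & truth)
    return {
        "recall": hits / len(truth) if truth else float("nan"),
        "precision": hits / len(found) if found else float("nan"),
        "n_consensus": float(len(found)),
        "n_truth": float(len(truth)),
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_consensus_csv(report: ConsensusReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["roi_a", "roi_b", "network", "subnetwork", "mean_p", "direction"]
        )
        for e in report.edges:
            writer.writerow(
                [e.label_a, e.label_b, e.network, e.subnetwork,
                 f"{e.mean_p:.3g}", e.direction]
            )


def write_region_weights_csv(
    report: ConsensusReport, path: str | Path, atlas: RegionAtlas | None = None
) -> None:
    weights = region_weights(report)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "label", "weight"])
        for region, weight in sorted(weights.items()):
            label = atlas.label(region) if atlas is not None else ""
            writer.writerow([region, label, weight])


def write_permutation(result: PermutationResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = outdir / "permutation_summary.json"
    summary.write_text(
        json.dumps(
            {
                "observed_gr_pct": result.observed_gr,
                "n_permutations": result.n_permutations,
                "p_value": result.p_value,
                "seed": result.seed,
                "null_gr_mean_pct": float(np.mean(result.null_grs)),
            },
            indent=2,
        )
    )
    hist = outdir / "null_gr_histogram.csv"
    values, counts = np.unique(np.round(result.null_grs, 6), return_counts=True)
    with open(hist, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gr_pct", "count"])
        for v, c in zip(values, counts):
            writer.writerow([v, int(c)])
    return {"summary": summary, "histogram": hist}
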