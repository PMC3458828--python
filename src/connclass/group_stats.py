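"""Descriptive group comparisons of connectivity matrices.

Three summaries of a two-group cohort: per-group element-wise mean
matrices, an edge-wise significance matrix of two-sample t-test p-values,
and a comparison of per-subject mean nonzero strengths between groups.
The classical pooled-variance (Student) two-sample t-test is the default,
matching the edge-ranking statistic used by the classifier; Welch's
unequal-variance form is available via ``equal_var=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .connectome import CONTROL, PATIENT, Cohort, ConnectivityMatrix, devectorize, write_matrix


def two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test over columns; returns (t, p).

    Features constant and equal across both groups get t = 0, p = 1;
    features constant within groups but differing between them get an
    infinite t and p = 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        raise ValueError("need at least 3 samples with both groups present")
    if not equal_var and (n1 < 2 or n2 < 2):
        raise ValueError("Welch's test needs at least two subjects per group")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    # singleton groups contribute zero to the pooled sum of squares
    v1 = a.var(axis=0, ddof=1) if n1 > 1 else np.zeros(a.shape[1])
    v2 = b.var(axis=0, ddof=1) if n2 > 1 else np.zeros(b.shape[1])
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, 1.0)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero_se = se2 == 0
    same = zero_se & (diff == 0)
    apart = zero_se & (diff != 0)
    t = np.where(same, 0.0, t)
    t = np.where(apart, np.copysign(np.inf, diff), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(same, 1.0, p)
    p = np.where(apart, 0.0, p)
    return t, p


def mean_nonzero_strength(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Mean of the unique nonzero off-diagonal strengths (upper triangle)."""
    s = matrix.strengths if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    rows, cols = np.triu_indices(s.shape[0], k=1)
    vals = s[rows, cols]
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("matrix has no nonzero off-diagonal entries")
    return float(nz.mean())


def group_mean_matrices(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean matrix per group: (patients, controls)."""
    patients = cohort.group(PATIENT)
    controls = cohort.group(CONTROL)
    if not patients or not controls:
        raise ValueError("both groups must be non-empty")
    return (
        np.mean(np.stack(patients), axis=0),
        np.mean(np.stack(controls), axis=0),
    )


def edge_significance(
    cohort: Cohort, equal_var: bool = True, return_t: bool = False
):
    """Edge-wise two-sample t-test p-values as a symmetric R x R matrix.

    The diagonal is set to 1 by convention; edges with zero variance in
    both groups and equal means also get p = 1.  With ``return_t`` the
    matrix of signed t statistics (patient minus control) is returned too.
    """
    if cohort.n_patients < 2 or cohort.n_controls < 2:
        raise ValueError("need at least two subjects in each group")
    X = cohort.feature_matrix()
    y = cohort.y
    t, p = two_sample_t(X[y == 1], X[y == 0], equal_var=equal_var)
    p_mat = devectorize(p, cohort.n_regions)
    np.fill_diagonal(p_mat, 1.0)
    if return_t:
        t_mat = devectorize(np.where(np.isfinite(t), t, np.sign(t) * 1e308),
                            cohort.n_regions)
        return p_mat, t_mat
    return p_mat


@dataclass
class GroupSummary:
    """Group-level descriptive results for a cohort."""

    mean_matrix_patients: np.ndarray
    mean_matrix_controls: np.ndarray
    significance_matrix: np.ndarray
    per_subject_mean_nonzero: dict[str, float]
    mean_patients: float
    sd_patients: float
    mean_controls: float
    sd_controls: float
    comparison_p: float


def summarize_groups(cohort: Cohort, equal_var: bool = True) -> GroupSummary:
    """Full descriptive comparison of the two groups.

    The group contrast of overall connectivity is a two-sample t-test on
    per-subject mean nonzero strengths.
    """
    mean_p, mean_c = group_mean_matrices(cohort)
    sig = edge_significance(cohort, equal_var=equal_var)
    per_subject = {
        sid: mean_nonzero_strength(m)
        for sid, m in zip(cohort.subject_ids, cohort.matrices)
    }
    vals = np.array(list(per_subject.values()))
    pat = vals[cohort.y == 1]
    con = vals[cohort.y == 0]
    _, p = two_sample_t(pat[:, None], con[:, None], equal_var=equal_var)
    return GroupSummary(
        mean_matrix_patients=mean_p,
        mean_matrix_controls=mean_c,
        significance_matrix=sig,
        per_subject_mean_nonzero=per_subject,
        mean_patients=float(pat.mean()),
        sd_patients=float(pat.std(ddof=1)),
        mean_controls=float(con.mean()),
        sd_controls=float(con.std(ddof=1)),
        comparison_p=float(p[0]),
    )


def write_summary(summary: GroupSummary, outdir: str | Path) -> dict[str, Path]:
    """Write mean/significance matrices as delimited text plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mean_patients": outdir / "mean_matrix_patients.csv",
        "mean_controls": outdir / "mean_matrix_controls.csv",
        "significance": outdir / "significance_matrix.csv",
        "summary": outdir / "group_summary.json",
    }
    write_matrix(paths["mean_patients"], summary.mean_matrix_patients)
    write_matrix(paths["mean_controls"], summary.mean_matrix_controls)
    write_matrix(paths["significance"], summary.significance_matrix)
    payload = {
        "mean_nonzero_strength": {
            "patients": {"mean": summary.mean_patients, "sd": summary.sd_patients},
            "controls": {"mean": summary.mean_controls, "sd": summary.sd_controls},
            "comparison_p": summary.comparison_p,
        },
        "per_subject_mean_nonzero": summary.per_subject_mean_nonzero,
    }
    paths["summary"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
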